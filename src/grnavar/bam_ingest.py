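"""Streaming and filtering of barcode/UMI-tagged alignments.

The targeted gRNA library arrives as a coordinate-sorted BAM whose reads
carry a cell barcode and a UMI in SAM tags.  Two tag dialects are in common
use: Cell Ranger writes corrected barcodes to CB/UB and the guide annotation
to GN; Dropseq-tools uses XC/XM/gn.  Barcode and UMI sequencing-error
correction (1-Hamming) is the aligner pipeline's job and is not repeated
here; the only barcode rewriting applied is the optional lookup translation
used to reconcile feature-barcoding barcodes with expression barcodes.

Reads survive filtering iff they are primary, non-supplementary, mapped to
one of the artificial guide contigs, carry both tags, and their (possibly
translated) barcode is on the cell whitelist.  Every dropped read is counted
by reason; conservation (reads in == reads out + drops) is an invariant the
pipeline report relies on.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

#: tag names per dialect: (cell barcode, UMI, guide annotation)
DIALECT_TAGS = {
    "cellranger": ("CB", "UB", "GN"),
    "dropseq": ("XC", "XM", "gn"),
}

#: how many leading reads to sniff for dialect tags before giving up
_SNIFF_LIMIT = 10_000


class IngestError(ValueError):
    pass


def _strip_suffix(barcode: str) -> str:
    # Cell Ranger appends a GEM-well suffix ("-1"); tolerate it on either side
    return barcode.split("-")[0]


def load_whitelist(path: str | Path) -> set[str]:
    """One barcode per line; a trailing "-1"-style suffix is tolerated."""
    barcodes = {
        _strip_suffix(line.strip())
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }
    if not barcodes:
        raise IngestError(f"whitelist {path} is empty")
    return barcodes


def load_barcode_lookup(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping observed barcode -> whitelist barcode."""
    lookup: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, dst = line.split("\t")[:2]
        lookup[_strip_suffix(src)] = _strip_suffix(dst)
    return lookup


@dataclass
class TaggedRead:
    """One usable alignment with its barcode, UMI and guide annotation."""

    cell_barcode: str
    umi: str
    guide_annotation: str | None
    contig: str
    pos: int  # 0-based leftmost aligned reference position
    cigar: tuple[tuple[int, int], ...]  # pysam (op, length) pairs
    sequence: str  # full query sequence incl. soft-clipped bases
    aligned_sequence: str  # query sequence over the aligned interval
    is_secondary: bool = False
    is_supplementary: bool = False
    query_name: str = ""


@dataclass
class MoleculeGroup:
    """All reads sharing one (cell barcode, UMI) pair: one cDNA molecule."""

    cell_barcode: str
    umi: str
    reads: list[TaggedRead]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class FilterStats:
    """Per-reason drop counts; the QC ledger of the ingest stage."""

    total: int = 0
    secondary: int = 0
    supplementary: int = 0
    unmapped: int = 0
    missing_tags: int = 0
    off_target_contig: int = 0
    not_in_whitelist: int = 0
    emitted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))

    @property
    def dropped(self) -> int:
        return self.total - self.emitted

    def balances(self) -> bool:
        drops = (
            self.secondary
            + self.supplementary
            + self.unmapped
            + self.missing_tags
            + self.off_target_contig
            + self.not_in_whitelist
        )
        return self.total == self.emitted + drops


def _sniff_dialect(bam_path: str | Path, dialect: str) -> None:
    cb_tag, ub_tag, _ = DIALECT_TAGS[dialect]
    other = next(d for d in DIALECT_TAGS if d != dialect)
    ocb, oub, _ = DIALECT_TAGS[other]
    seen_any = False
    seen_other = False
    n_read = 0
    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            n_read += 1
            if n_read > _SNIFF_LIMIT:
                break
            if read.has_tag(cb_tag) or read.has_tag(ub_tag):
                seen_any = True
                break
            if read.has_tag(ocb) or read.has_tag(oub):
                seen_other = True
    if n_read == 0:  # empty BAM: nothing to sniff, filtering yields nothing
        return
    if not seen_any:
        hint = f"; tags {ocb}/{oub} are present — try dialect={other!r}" if seen_other else ""
        raise IngestError(
            f"no {cb_tag}/{ub_tag} tags in the first {_SNIFF_LIMIT} reads of "
            f"{bam_path} for dialect {dialect!r}{hint}"
        )


def _to_tagged(read: pysam.AlignedSegment, cb: str, umi: str, guide: str | None) -> TaggedRead:
    return TaggedRead(
        cell_barcode=cb,
        umi=umi,
        guide_annotation=guide,
        contig=read.reference_name,
        pos=read.reference_start,
        cigar=tuple(read.cigartuples or ()),
        sequence=read.query_sequence or "",
        aligned_sequence=read.query_alignment_sequence or "",
        is_secondary=read.is_secondary,
        is_supplementary=read.is_supplementary,
        query_name=read.query_name or "",
    )


def filter_alignments(
    bam_path: str | Path,
    whitelist: set[str],
    guide_contigs: set[str],
    *,
    lookup: dict[str, str] | None = None,
    dialect: str = "cellranger",
    stats: FilterStats | None = None,
) -> Iterator[TaggedRead]:
    """Yield usable gRNA-library reads; count every drop by reason."""
    if dialect not in DIALECT_TAGS:
        raise IngestError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECT_TAGS)}")
    cb_tag, ub_tag, gn_tag = DIALECT_TAGS[dialect]
    if not whitelist:
        raise IngestError("empty cell-barcode whitelist")
    _sniff_dialect(bam_path, dialect)
    lookup = lookup or {}
    st = stats if stats is not None else FilterStats()

    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            st.total += 1
            if read.is_secondary:
                st.secondary += 1
                continue
            if read.is_supplementary:
                st.supplementary += 1
                continue
            if read.is_unmapped:
                st.unmapped += 1
                continue
            if not (read.has_tag(cb_tag) and read.has_tag(ub_tag)):
                st.missing_tags += 1
                continue
            if read.reference_name not in guide_contigs:
                st.off_target_contig += 1
                continue
            cb = _strip_suffix(str(read.get_tag(cb_tag)))
            if cb not in whitelist:
                cb = lookup.get(cb, cb)
            if cb not in whitelist:
                st.not_in_whitelist += 1
                continue
            umi = str(read.get_tag(ub_tag))
            guide = str(read.get_tag(gn_tag)) if read.has_tag(gn_tag) else None
            st.emitted += 1
            yield _to_tagged(read, cb, umi, guide)


def group_molecules(reads: Iterable[TaggedRead]) -> list[MoleculeGroup]:
    """Partition reads into (cell barcode, UMI) molecule groups.

    Order of groups follows first appearance, making downstream tie-breaking
    deterministic for a fixed input BAM.
    """
    groups: "OrderedDict[tuple[str, str], list[TaggedRead]]" = OrderedDict()
    for read in reads:
        groups.setdefault((read.cell_barcode, read.umi), []).append(read)
    return [MoleculeGroup(cb, umi, rs) for (cb, umi), rs in groups.items()]
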
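"""Guide library loading and custom-reference construction.

Single-cell CRISPR screens read out which guide RNA (gRNA) each cell
expresses by sequencing a targeted gRNA library.  To recover guide-derived
reads with an ordinary splice-aware aligner, the designed cassette of every
guide (promoter / template-switch context + spacer + scaffold) is placed on
its own artificial contig.  This module loads and validates the guide design
table, substitutes each spacer into a cassette template, and emits the
artificial contigs as FASTA plus a matching GTF so the aligner annotates
guide reads with the guide name.  The host genome itself is never bundled;
users concatenate the emitted contigs onto their reference of choice.

Coordinates are 0-based half-open internally; GTF output uses the standard
1-based closed convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_RE = re.compile(r"^[ACGT]+$")

#: token marking where the spacer is substituted into the cassette template
SPACER_PLACEHOLDER = "[spacer]"

#: region label reserved for the spacer slot
SPACER_LABEL = "spacer"


class GuideLibraryError(ValueError):
    """Invalid guide design table or cassette template."""


@dataclass(frozen=True)
class GuideDesign:
    """One designed guide: unique id, spacer sequence, target gene, flag.

    The spacer is the variable ~G+20 bp region that base-pairs with the
    genomic target; ``targeting`` is False for non-targeting controls.
    """

    guide_id: str
    spacer: str
    target_gene: str = ""
    targeting: bool = True

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise GuideLibraryError("guide_id must be non-empty")
        if not self.spacer or not _DNA_RE.match(self.spacer):
            raise GuideLibraryError(
                f"guide {self.guide_id!r}: spacer must be non-empty A/C/G/T, "
                f"got {self.spacer!r}"
            )


@dataclass(frozen=True)
class CassetteRegion:
    label: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


@dataclass
class CassetteAnnotation:
    """Ordered, non-overlapping regions of one guide cassette contig.

    Exactly one region is labelled ``spacer``.  Regions are contiguous among
    themselves; contig positions before the first region are reported as
    ``upstream`` and after the last as ``downstream`` by the mutation
    annotator.
    """

    regions: list[CassetteRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        spacers = [r for r in self.regions if r.label == SPACER_LABEL]
        if len(spacers) != 1:
            raise GuideLibraryError(
                f"cassette annotation needs exactly one 'spacer' region, got {len(spacers)}"
            )
        for r in self.regions:
            if not (0 <= r.start < r.end):
                raise GuideLibraryError(f"invalid region bounds {r}")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.end != b.start:
                raise GuideLibraryError(
                    f"regions must be sorted and contiguous: {a} then {b}"
                )

    @property
    def spacer(self) -> CassetteRegion:
        return next(r for r in self.regions if r.label == SPACER_LABEL)

    @property
    def start(self) -> int:
        return self.regions[0].start

    @property
    def end(self) -> int:
        return self.regions[-1].end

    def label_at(self, pos: int) -> str:
        """Region label covering cassette position ``pos``.

        Positions outside the annotated span are ``upstream``/``downstream``.
        """
        if pos < self.start:
            return "upstream"
        for r in self.regions:
            if r.start <= pos < r.end:
                return r.label
        return "downstream"


@dataclass
class CustomReference:
    """One artificial contig per guide, with per-contig region annotation."""

    contigs: dict[str, str]
    annotations: dict[str, CassetteAnnotation]

    def __post_init__(self) -> None:
        if set(self.contigs) != set(self.annotations):
            raise GuideLibraryError("contigs and annotations must cover the same guide ids")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CustomReference):
            return NotImplemented
        return self.contigs == other.contigs and {
            g: a.regions for g, a in self.annotations.items()
        } == {g: a.regions for g, a in other.annotations.items()}

    @property
    def guide_ids(self) -> list[str]:
        return list(self.contigs)

    def spacer_sequence(self, guide_id: str) -> str:
        ann = self.annotations[guide_id]
        return self.contigs[guide_id][ann.spacer.start : ann.spacer.end]


# ---------------------------------------------------------------------------
# loading


def load_guide_library(
    path: str | Path,
    *,
    id_col: str = "guide_id",
    spacer_col: str = "spacer",
    gene_col: str = "target_gene",
    targeting_col: str = "targeting",
    sep: str | None = None,
) -> list[GuideDesign]:
    """Load and validate a guide design table (TSV/CSV).

    Column names are configurable; the gene and targeting columns are
    optional (missing targeting defaults to True, missing gene to "").
    Duplicate guide ids and duplicate spacers are hard errors: two guides
    sharing a spacer would make aligner annotation ambiguous.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise GuideLibraryError(f"no guides found in {path}")
    for col in (id_col, spacer_col):
        if col not in df.columns:
            raise GuideLibraryError(f"missing required column {col!r} in {path}")

    designs: list[GuideDesign] = []
    for _, row in df.iterrows():
        gene = str(row[gene_col]) if gene_col in df.columns and pd.notna(row.get(gene_col)) else ""
        if targeting_col in df.columns and pd.notna(row.get(targeting_col)):
            raw = str(row[targeting_col]).strip().lower()
            targeting = raw in {"1", "true", "yes", "y", "t"}
        else:
            targeting = True
        designs.append(
            GuideDesign(
                guide_id=str(row[id_col]).strip(),
                spacer=str(row[spacer_col]).strip().upper(),
                target_gene=gene,
                targeting=targeting,
            )
        )

    seen_ids: dict[str, str] = {}
    for d in designs:
        if d.guide_id in seen_ids:
            raise GuideLibraryError(f"duplicate guide_id {d.guide_id!r}")
        seen_ids[d.guide_id] = d.guide_id
    seen_spacers: dict[str, str] = {}
    for d in designs:
        if d.spacer in seen_spacers:
            raise GuideLibraryError(
                f"duplicate spacer shared by guides {seen_spacers[d.spacer]!r} "
                f"and {d.guide_id!r}"
            )
        seen_spacers[d.spacer] = d.guide_id
    return designs


def write_guide_library(designs: Sequence[GuideDesign], path: str | Path) -> None:
    """Write a guide design table as TSV (inverse of :func:`load_guide_library`)."""
    pd.DataFrame(
        {
            "guide_id": [d.guide_id for d in designs],
            "spacer": [d.spacer for d in designs],
            "target_gene": [d.target_gene for d in designs],
            "targeting": [str(d.targeting) for d in designs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference construction


def _split_template(template: str) -> tuple[str, str]:
    n = template.count(SPACER_PLACEHOLDER)
    if n != 1:
        raise GuideLibraryError(
            f"cassette template must contain exactly one {SPACER_PLACEHOLDER!r} "
            f"placeholder, found {n}"
        )
    up, down = template.split(SPACER_PLACEHOLDER)
    for part, name in ((up, "upstream"), (down, "downstream")):
        if part and not _DNA_RE.match(part):
            raise GuideLibraryError(f"{name} template context is not A/C/G/T")
    return up, down


def load_cassette_template(path: str | Path) -> str:
    """Read a cassette template from a single-record FASTA.

    The record sequence must contain the literal ``[spacer]`` placeholder
    once (FASTA tolerates the bracket characters).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GuideLibraryError(f"template FASTA must hold exactly one record, got {len(records)}")
    return str(records[0].seq)


def build_custom_reference(
    designs: Sequence[GuideDesign],
    template: str,
    context_length: int | None = None,
    *,
    upstream_label: str = "upstream_context",
    downstream_label: str = "scaffold",
) -> CustomReference:
    """Substitute each spacer into the cassette template, one contig per guide.

    ``template`` contains the literal ``[spacer]`` placeholder once; the text
    around it is the plasmid context carried onto every contig.  When
    ``context_length`` is given and the template context exceeds it, context
    is trimmed to the bases nearest the spacer, split between upstream and
    downstream in proportion to the template's own split (the template, not
    this function, decides how much flank sits on each side).
    """
    if not designs:
        raise GuideLibraryError("no guide designs supplied")
    up, down = _split_template(template)
    if context_length is not None:
        total = len(up) + len(down)
        if context_length > total:
            raise GuideLibraryError(
                f"context_length {context_length} exceeds template context {total}"
            )
        if context_length < total:
            keep_up = round(context_length * len(up) / total)
            keep_down = context_length - keep_up
            up = up[len(up) - keep_up :] if keep_up else ""
            down = down[:keep_down]

    contigs: dict[str, str] = {}
    annotations: dict[str, CassetteAnnotation] = {}
    for d in designs:
        seq = up + d.spacer + down
        regions: list[CassetteRegion] = []
        if up:
            regions.append(CassetteRegion(upstream_label, 0, len(up)))
        regions.append(CassetteRegion(SPACER_LABEL, len(up), len(up) + len(d.spacer)))
        if down:
            regions.append(
                CassetteRegion(downstream_label, len(up) + len(d.spacer), len(seq))
            )
        contigs[d.guide_id] = seq
        annotations[d.guide_id] = CassetteAnnotation(regions)
    return CustomReference(contigs, annotations)


# ---------------------------------------------------------------------------
# FASTA / GTF emission and round trip

_GTF_DIALECTS = ("cellranger", "dropseq")


def write_reference_fasta(reference: CustomReference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="")
        for gid, seq in reference.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_reference_gtf(
    reference: CustomReference, path: str | Path, dialect: str = "cellranger"
) -> None:
    """Emit one gene/transcript/exon spanning each contig, plus ``region``
    features carrying the cassette annotation.

    Aligner reference builders only consume the exon lines; the ``region``
    lines make FASTA+GTF a lossless serialization of the reference.  The
    ``dialect`` switches attribute naming between the Cell Ranger flavor
    (gene_id/gene_name/transcript_id/transcript_name) and the Dropseq-tools
    flavor (gene_id/gene_name only).
    """
    if dialect not in _GTF_DIALECTS:
        raise GuideLibraryError(f"unknown GTF dialect {dialect!r}; choose from {_GTF_DIALECTS}")
    lines: list[str] = [f"##grnavar-dialect: {dialect}"]
    for gid, seq in reference.contigs.items():
        end = len(seq)  # 1-based closed end == length
        if dialect == "cellranger":
            attrs = (
                f'gene_id "{gid}"; gene_name "{gid}"; '
                f'transcript_id "{gid}"; transcript_name "{gid}";'
            )
        else:
            attrs = f'gene_id "{gid}"; gene_name "{gid}";'
        for feature in ("gene", "transcript", "exon"):
            lines.append(
                "\t".join(
                    [gid, "grnavar", feature, "1", str(end), ".", "+", ".", attrs]
                )
            )
        for region in reference.annotations[gid].regions:
            rattrs = f'gene_id "{gid}"; region_label "{region.label}";'
            lines.append(
                "\t".join(
                    [
                        gid,
                        "grnavar",
                        "region",
                        str(region.start + 1),
                        str(region.end),
                        ".",
                        "+",
                        ".",
                        rattrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(fasta: str | Path, gtf: str | Path) -> CustomReference:
    """Reconstruct a :class:`CustomReference` from emitted FASTA + GTF."""
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    regions: dict[str, list[CassetteRegion]] = {gid: [] for gid in contigs}
    label_re = re.compile(r'region_label "([^"]+)"')
    for line in Path(gtf).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if fields[2] != "region":
            continue
        m = label_re.search(fields[8])
        if m is None or fields[0] not in regions:
            continue
        regions[fields[0]].append(
            CassetteRegion(m.group(1), int(fields[3]) - 1, int(fields[4]))
        )
    annotations = {gid: CassetteAnnotation(sorted(rs, key=lambda r: r.start)) for gid, rs in regions.items()}
    return CustomReference(contigs, annotations)


def write_reference(
    reference: CustomReference, outdir: str | Path, dialect: str = "cellranger"
) -> tuple[Path, Path]:
    """Write ``guides.fa`` and ``guides.gtf`` under ``outdir``; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "guides.fa"
    gtf = outdir / "guides.gtf"
    write_reference_fasta(reference, fasta)
    write_reference_gtf(reference, gtf, dialect=dialect)
    return fasta, gtf
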
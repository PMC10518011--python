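"""Per-molecule consensus calling for gRNA reads.

All reads sharing one (cell barcode, UMI) pair are assumed to come from the
same cDNA molecule, so disagreements among them are library-preparation or
sequencing errors.  Each group is collapsed to a single consensus sequence
in two plurality votes:

1. the guide annotation supported by the most reads is kept (a tie means no
   guide can be confidently called and the whole group is discarded);
2. among the reads carrying that annotation, the most frequent read sequence
   (over the aligned interval) becomes the consensus, with ties broken by a
   seeded uniform draw so runs are reproducible.

Molecules supported by a single read cannot be error-checked, so the default
filter keeps only molecules with at least 2 reads.  This is what removes
pure sequencing errors from the mutant-gRNA pool: an error seen in one read
of a multi-read molecule loses the plurality vote, and an error that is the
only read of its molecule is dropped by the read-support filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bam_ingest import DIALECT_TAGS, MoleculeGroup
from .guide_library import CustomReference

#: default pipeline seed for the consensus tie-break
DEFAULT_SEED = 17

CONSENSUS_TABLE = "consensus.sequence.gRNA.txt"
CONSENSUS_BAM = "consensus.bam"


@dataclass
class ConsensusMolecule:
    """The consensus call for one (cell barcode, UMI) molecule.

    ``sequence`` is the consensus over the aligned interval (soft clips
    excluded); ``full_sequence``/``cigar``/``pos`` come from the
    representative read and preserve the alignment for mutation annotation.
    ``n_reads`` counts the reads whose guide annotation matched the group
    call (the voting population); reads that lost the annotation vote are in
    ``n_excluded``.
    """

    cell_barcode: str
    umi: str
    guide_id: str
    sequence: str
    full_sequence: str
    contig: str
    pos: int
    cigar: tuple[tuple[int, int], ...]
    n_reads: int
    n_support: int
    n_excluded: int = 0

    @property
    def n_total(self) -> int:
        return self.n_reads + self.n_excluded


@dataclass
class ConsensusStats:
    groups_in: int = 0
    annotation_ties: int = 0
    no_annotation: int = 0
    called: int = 0
    below_min_reads: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def resolve_guide_annotation(group: MoleculeGroup) -> str | None:
    """Plurality vote over the reads' guide annotations; tie -> None."""
    counts = Counter(
        r.guide_annotation for r in group.reads if r.guide_annotation is not None
    )
    if not counts:
        return None
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def call_consensus(
    group: MoleculeGroup, rng: np.random.Generator
) -> ConsensusMolecule | None:
    """Collapse one molecule group to its consensus, or None on an
    unresolvable guide-annotation tie."""
    guide_id = resolve_guide_annotation(group)
    if guide_id is None:
        return None
    participating = [r for r in group.reads if r.guide_annotation == guide_id]
    votes = Counter(r.aligned_sequence for r in participating)
    top = max(votes.values())
    candidates = sorted(seq for seq, n in votes.items() if n == top)
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        chosen = candidates[int(rng.integers(len(candidates)))]
    representative = next(r for r in participating if r.aligned_sequence == chosen)
    return ConsensusMolecule(
        cell_barcode=group.cell_barcode,
        umi=group.umi,
        guide_id=guide_id,
        sequence=chosen,
        full_sequence=representative.sequence,
        contig=representative.contig,
        pos=representative.pos,
        cigar=representative.cigar,
        n_reads=len(participating),
        n_support=top,
        n_excluded=len(group.reads) - len(participating),
    )


def call_all_consensus(
    groups: list[MoleculeGroup],
    seed: int = DEFAULT_SEED,
    stats: ConsensusStats | None = None,
) -> list[ConsensusMolecule]:
    """Consensus-call every group with a single pipeline-level RNG."""
    rng = np.random.default_rng(seed)
    st = stats if stats is not None else ConsensusStats()
    out: list[ConsensusMolecule] = []
    for group in groups:
        st.groups_in += 1
        mol = call_consensus(group, rng)
        if mol is None:
            if any(r.guide_annotation is not None for r in group.reads):
                st.annotation_ties += 1
            else:
                st.no_annotation += 1
            continue
        st.called += 1
        out.append(mol)
    return out


def filter_consensus(
    molecules: list[ConsensusMolecule],
    min_reads: int = 2,
    *,
    count_all_reads: bool = False,
    stats: ConsensusStats | None = None,
) -> list[ConsensusMolecule]:
    """Keep molecules supported by at least ``min_reads`` reads.

    By default only annotation-concordant reads count toward the support;
    ``count_all_reads`` switches to the whole group size.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept = [
        m
        for m in molecules
        if (m.n_total if count_all_reads else m.n_reads) >= min_reads
    ]
    if stats is not None:
        stats.below_min_reads += len(molecules) - len(kept)
    return kept


# ---------------------------------------------------------------------------
# serialization


def _cigar_to_string(cigar: tuple[tuple[int, int], ...]) -> str:
    ops = "MIDNSHP=XB"
    return "".join(f"{length}{ops[op]}" for op, length in cigar) or "*"


def molecules_to_frame(molecules: list[ConsensusMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_barcode": [m.cell_barcode for m in molecules],
            "umi": [m.umi for m in molecules],
            "guide_id": [m.guide_id for m in molecules],
            "sequence": [m.sequence for m in molecules],
            "n_reads": [m.n_reads for m in molecules],
            "n_support": [m.n_support for m in molecules],
        }
    )


def write_consensus(
    molecules: list[ConsensusMolecule],
    outdir: str | Path,
    reference: CustomReference,
    dialect: str = "cellranger",
) -> tuple[Path, Path]:
    """Write the consensus table and a coordinate-sorted, indexed BAM.

    The BAM carries one representative alignment per molecule with the
    barcode/UMI/guide tags of the chosen dialect, so it remains consumable
    by standard tooling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / CONSENSUS_TABLE
    bam_path = outdir / CONSENSUS_BAM
    molecules_to_frame(molecules).to_csv(table_path, sep="\t", index=False)

    cb_tag, ub_tag, gn_tag = DIALECT_TAGS[dialect]
    contigs = list(reference.contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": gid, "LN": len(reference.contigs[gid])} for gid in contigs
            ],
        }
    )
    order = {gid: i for i, gid in enumerate(contigs)}
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for mol in sorted(molecules, key=lambda m: (order[m.contig], m.pos)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"{mol.cell_barcode}:{mol.umi}"
            seg.flag = 0
            seg.reference_id = order[mol.contig]
            seg.reference_start = mol.pos
            seg.mapping_quality = 255
            seg.cigartuples = list(mol.cigar)
            seg.query_sequence = mol.full_sequence
            seg.set_tag(cb_tag, mol.cell_barcode)
            seg.set_tag(ub_tag, mol.umi)
            seg.set_tag(gn_tag, mol.guide_id)
            seg.set_tag("cr", mol.n_reads)  # participating reads
            seg.set_tag("cs", mol.n_support)  # reads matching the consensus
            bam.write(seg)
    pysam.index(str(bam_path))
    return table_path, bam_path


def read_consensus_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_barcode": str, "umi": str})


def read_consensus_bam(
    path: str | Path, dialect: str = "cellranger"
) -> list[ConsensusMolecule]:
    """Reload consensus molecules from a ``consensus.bam`` written by
    :func:`write_consensus` (inverse up to the support tags)."""
    cb_tag, ub_tag, gn_tag = DIALECT_TAGS[dialect]
    out: list[ConsensusMolecule] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            out.append(
                ConsensusMolecule(
                    cell_barcode=str(read.get_tag(cb_tag)),
                    umi=str(read.get_tag(ub_tag)),
                    guide_id=str(read.get_tag(gn_tag)),
                    sequence=read.query_alignment_sequence or "",
                    full_sequence=read.query_sequence or "",
                    contig=read.reference_name,
                    pos=read.reference_start,
                    cigar=tuple(read.cigartuples or ()),
                    n_reads=int(read.get_tag("cr")) if read.has_tag("cr") else 1,
                    n_support=int(read.get_tag("cs")) if read.has_tag("cs") else 1,
                )
            )
    return out
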
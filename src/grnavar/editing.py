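"""Cas9 editing detection in the gene-expression library.

Cas9 cuts ~3 nt upstream of the PAM and repair by non-homologous end
joining leaves indels at the cut.  Transcriptome reads overlapping a small
window centred on the predicted cutsite therefore carry the editing
footprint.  For every guide target, reads are restricted to a symmetric
window (default 51 bp), kept only when they belong to the target gene
(exon-overlap assignment), deduplicated per (cell barcode, UMI) by a
*union* consensus — reads of one molecule start at different offsets, so
their per-position calls are united rather than voted read-against-read —
and classified:

* a deletion spanning the cutsite      -> ``cutsite_deletion`` (Cas9-induced);
* any other insertion/deletion         -> ``other_indel`` (reported, not Cas9);
* mismatches only                      -> ``mismatch_only``;
* perfect match over covered positions -> ``unedited``.

Spliced alignments (CIGAR N) are transcript structure, never deletions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .bam_ingest import DIALECT_TAGS, _strip_suffix

EDITING_TABLE = "editing.effect.txt"

DEFAULT_WINDOW = 51
CUT_OFFSET = 3  # nt upstream of the PAM

KLASSES = ("cutsite_deletion", "other_indel", "mismatch_only", "unedited")


class EditingError(ValueError):
    pass


@dataclass(frozen=True)
class CutsiteWindow:
    """Symmetric detection window around one guide's predicted cut."""

    guide_id: str
    gene: str
    chrom: str
    cutsite: int  # 0-based genomic position of the base 3 nt upstream of the PAM
    window_start: int
    window_end: int  # half-open

    @property
    def width(self) -> int:
        return self.window_end - self.window_start


def compute_cutsite(
    guide_id: str,
    gene: str,
    chrom: str,
    pam_position: int,
    strand: str,
    *,
    window: int = DEFAULT_WINDOW,
    cut_offset: int = CUT_OFFSET,
) -> CutsiteWindow:
    """Predicted cut position and detection window from the PAM coordinate.

    ``pam_position`` is the 0-based genomic position of the PAM's first
    base.  On the plus strand the cut falls ``cut_offset`` nt upstream
    (lower coordinate); the minus strand mirrors it.  The window must be
    odd so it is symmetric around the cutsite.
    """
    if window % 2 == 0 or window < 1:
        raise EditingError(f"window width must be odd and positive, got {window}")
    if strand not in ("+", "-"):
        raise EditingError(f"strand must be '+' or '-', got {strand!r}")
    cutsite = pam_position - cut_offset if strand == "+" else pam_position + cut_offset
    half = window // 2
    return CutsiteWindow(
        guide_id=guide_id,
        gene=gene,
        chrom=chrom,
        cutsite=cutsite,
        window_start=cutsite - half,
        window_end=cutsite + half + 1,
    )


def load_target_table(path: str | Path, *, window: int = DEFAULT_WINDOW) -> list[CutsiteWindow]:
    """Guide target table: guide_id, chrom, pam_position, strand, gene.

    Rows lacking PAM information are skipped with a warning record rather
    than failing the run.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    windows: list[CutsiteWindow] = []
    for _, row in df.iterrows():
        if pd.isna(row.get("pam_position")) or pd.isna(row.get("strand")):
            continue
        windows.append(
            compute_cutsite(
                str(row["guide_id"]),
                str(row.get("gene", "")),
                str(row["chrom"]),
                int(row["pam_position"]),
                str(row["strand"]),
                window=window,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# gene model and read selection


def load_exon_index(gtf_path: str | Path) -> dict[str, IntervalTree]:
    """Per-gene exon interval trees keyed by (chrom) -> tree of gene names.

    Returns a mapping chrom -> IntervalTree whose intervals carry the gene
    name; used for unambiguous exon-overlap gene assignment.
    """
    import pyranges

    gr = pyranges.read_gtf(str(gtf_path))
    df = gr.df
    exons = df[df.Feature == "exon"]
    name_col = "gene_name" if "gene_name" in exons.columns else "gene_id"
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, gene in zip(
        exons.Chromosome, exons.Start, exons.End, exons[name_col]
    ):
        if end > start:
            trees[str(chrom)][int(start) : int(end)] = str(gene)
    return dict(trees)


@dataclass
class WindowRead:
    cell_barcode: str
    umi: str
    pos: int
    cigar: tuple[tuple[int, int], ...]
    sequence: str


def window_reads(
    bam_path: str | Path,
    window: CutsiteWindow,
    exon_index: dict[str, IntervalTree],
    *,
    dialect: str = "cellranger",
    whitelist: set[str] | None = None,
) -> list[WindowRead]:
    """Reads overlapping the window that belong to the window's gene.

    A read is kept iff it is primary, non-supplementary, mapped, carries
    both barcode tags, overlaps the window, and its aligned blocks overlap
    an exon of the window's gene and of no other gene (unambiguous
    exon-overlap assignment).
    """
    cb_tag, ub_tag, _ = DIALECT_TAGS[dialect]
    tree = exon_index.get(window.chrom, IntervalTree())
    out: list[WindowRead] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(window.chrom, window.window_start, window.window_end):
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            if not (read.has_tag(cb_tag) and read.has_tag(ub_tag)):
                continue
            cb = _strip_suffix(str(read.get_tag(cb_tag)))
            if whitelist is not None and cb not in whitelist:
                continue
            genes: set[str] = set()
            for bstart, bend in read.get_blocks():
                for hit in tree.overlap(bstart, bend):
                    genes.add(hit.data)
            if genes != {window.gene}:
                continue
            out.append(
                WindowRead(
                    cell_barcode=cb,
                    umi=str(read.get_tag(ub_tag)),
                    pos=read.reference_start,
                    cigar=tuple(read.cigartuples or ()),
                    sequence=read.query_sequence or "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# union consensus over the window

_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)

#: per-position states in the union consensus
UNCOVERED = None


def _read_states(
    read: WindowRead, window: CutsiteWindow
) -> tuple[dict[int, str], dict[int, str]]:
    """Per-window-position state ('D' or the observed base) and insertion
    anchors (position -> inserted bases) for one read; positions are genomic."""
    states: dict[int, str] = {}
    insertions: dict[int, str] = {}
    rpos, qpos = read.pos, 0
    for op, length in read.cigar:
        if op in (_M, _EQ, _X):
            for i in range(length):
                p = rpos + i
                if window.window_start <= p < window.window_end:
                    states[p] = read.sequence[qpos + i]
            rpos += length
            qpos += length
        elif op == _D:
            for i in range(length):
                p = rpos + i
                if window.window_start <= p < window.window_end:
                    states[p] = "D"
            rpos += length
        elif op == _I:
            if window.window_start <= rpos < window.window_end:
                insertions[rpos] = read.sequence[qpos : qpos + length]
            qpos += length
        elif op == _N:
            rpos += length  # splice: transcript structure, not a deletion
        elif op in (_S,):
            qpos += length
        elif op in (_H, _P):
            continue
    return states, insertions


def union_consensus(
    reads: list[WindowRead], window: CutsiteWindow, ref_seq: str
) -> dict[int, str]:
    """Union of the reads' per-position calls across the window.

    ``ref_seq`` is the reference sequence of the window.  Positions covered
    by no read are absent from the result.  Conflicting states at one
    position are resolved by majority; a tie resolves to the reference
    match (the conservative call).  Insertion anchors are encoded as
    ``"I:<bases>"`` joined onto the state of the anchoring position.
    """
    if len(ref_seq) != window.width:
        raise EditingError("reference sequence length must equal the window width")
    votes: dict[int, Counter] = defaultdict(Counter)
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    n_reads_at: dict[int, int] = defaultdict(int)
    for read in reads:
        states, insertions = _read_states(read, window)
        for p, s in states.items():
            votes[p][s] += 1
            n_reads_at[p] += 1
        for p, bases in insertions.items():
            ins_votes[p][bases] += 1
    result: dict[int, str] = {}
    for p, counter in votes.items():
        ref_base = ref_seq[p - window.window_start]
        ranked = counter.most_common()
        top = ranked[0][1]
        winners = [s for s, n in counter.items() if n == top]
        if len(winners) == 1:
            state = winners[0]
        else:
            state = ref_base if ref_base in winners else sorted(winners)[0]
        result[p] = state
    for p, counter in ins_votes.items():
        # an insertion must be supported by a majority of the reads covering
        # the anchor position; a tie resolves to no insertion (match)
        bases, n = counter.most_common(1)[0]
        if p in n_reads_at and n * 2 > n_reads_at[p]:
            result[p] = result.get(p, ref_seq[p - window.window_start]) + f"+I:{bases}"
    return result


@dataclass
class EditingCall:
    """Per-molecule classification of the cutsite window."""

    cell_barcode: str
    umi: str
    gene: str
    guide_id: str
    klass: str
    events: str  # serialized deviations in genomic coordinates
    n_reads: int
    covered: int  # window positions covered by >=1 read


def call_editing(
    union: dict[int, str],
    window: CutsiteWindow,
    ref_seq: str,
    *,
    cell_barcode: str = "",
    umi: str = "",
    n_reads: int = 0,
) -> EditingCall:
    """Classify one molecule's union consensus against the window reference."""
    deletions: list[tuple[int, int]] = []
    mismatches: list[str] = []
    insertions: list[str] = []
    run_start: int | None = None
    for p in range(window.window_start, window.window_end):
        state = union.get(p)
        base = state.split("+I:")[0] if state is not None else None
        if base == "D":
            if run_start is None:
                run_start = p
        else:
            if run_start is not None:
                deletions.append((run_start, p))
                run_start = None
        if state is not None and "+I:" in state:
            insertions.append(f"{p}I:->{state.split('+I:')[1]}")
        if base is not None and base not in ("D",) and base != ref_seq[p - window.window_start]:
            mismatches.append(f"{p}M:{ref_seq[p - window.window_start]}>{base}")
    if run_start is not None:
        deletions.append((run_start, window.window_end))

    cutsite_hit = any(s <= window.cutsite < e for s, e in deletions)
    if cutsite_hit:
        klass = "cutsite_deletion"
    elif deletions or insertions:
        klass = "other_indel"
    elif mismatches:
        klass = "mismatch_only"
    else:
        klass = "unedited"
    tokens = [f"{s}D:{ref_seq[s - window.window_start:e - window.window_start]}>-" for s, e in deletions]
    tokens += insertions + mismatches
    return EditingCall(
        cell_barcode=cell_barcode,
        umi=umi,
        gene=window.gene,
        guide_id=window.guide_id,
        klass=klass,
        events=";".join(sorted(tokens)) or "none",
        n_reads=n_reads,
        covered=len(union),
    )


def detect_editing(
    bam_path: str | Path,
    windows: list[CutsiteWindow],
    exon_index: dict[str, IntervalTree],
    genome: "pyfaidx.Fasta | dict[str, str]",
    *,
    dialect: str = "cellranger",
    whitelist: set[str] | None = None,
) -> pd.DataFrame:
    """Run the full editing scan over every cutsite window.

    ``genome`` maps chromosome name to sequence (a ``pyfaidx.Fasta`` or a
    plain dict).  Returns one row per (window, cell, UMI) molecule.
    """
    rows: list[EditingCall] = []
    for window in windows:
        chrom_seq = genome[window.chrom]
        ref_seq = str(chrom_seq[window.window_start : window.window_end])
        reads = window_reads(
            bam_path, window, exon_index, dialect=dialect, whitelist=whitelist
        )
        groups: dict[tuple[str, str], list[WindowRead]] = defaultdict(list)
        for read in reads:
            groups[(read.cell_barcode, read.umi)].append(read)
        for (cb, umi), members in groups.items():
            union = union_consensus(members, window, ref_seq)
            rows.append(
                call_editing(
                    union,
                    window,
                    ref_seq,
                    cell_barcode=cb,
                    umi=umi,
                    n_reads=len(members),
                )
            )
    return pd.DataFrame(
        [vars(c) for c in rows],
        columns=[
            "cell_barcode",
            "umi",
            "gene",
            "guide_id",
            "klass",
            "events",
            "n_reads",
            "covered",
        ],
    )


def write_editing_table(calls: pd.DataFrame, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / EDITING_TABLE
    calls.to_csv(path, sep="\t", index=False)
    return path
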
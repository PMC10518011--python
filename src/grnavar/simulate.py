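"""Ground-truthed synthetic single-cell CRISPR screens.

Generates everything the pipeline consumes — guide library, custom
reference, tagged gRNA BAM, expression-window BAM with a miniature genome,
whitelist — together with truth tables that describe exactly what was
planted.  Reads are emitted pre-aligned (CIGARs computed from the planted
events), since the pipeline starts from aligner output.

The generator models the processes that create mutant gRNA molecules:

1. *virus pool* — a mutant guide amplified before transduction; every
   integration of it is wholly mutant and it recurs across many cells;
2. *transduction / rare sub-clone* — a mutant unique to one cell, carried
   by all of that cell's UMIs for the guide;
3. *integration duplication* — one cell expressing both the intact and a
   mutant copy, each with more than one UMI;
4. *cDNA preparation* — a single mutant UMI next to many intact UMIs;
5. *sequencing error* — a mutation present in one read of a multi-read UMI
   (injected via the per-base error rate), removed at consensus calling.

Per-guide UMI counts are bimodal by construction: log-normal in carrying
cells, low-mean ambient counts elsewhere — the structure the mixture-model
thresholding assumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .assignment import AssignmentResult
from .guide_library import (
    CassetteAnnotation,
    CustomReference,
    GuideDesign,
    build_custom_reference,
    write_guide_library,
    write_reference,
)
from .mutations import GuideVariant, MutationEvent, events_to_string

#: synthetic cassette template: promoter/TSO context, spacer slot, scaffold.
#: The scaffold begins with the GTTTT lower stem whose TTTT tetramer is the
#: hotspot for single-T deletions in real libraries.
DEFAULT_TEMPLATE = (
    "TGGAAAGGACGAAACACCG"  # U6 end / homology arm upstream of the spacer
    "[spacer]"
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGC"  # scaffold lower stem + context
)

_BASES = "ACGT"


def _int_to_dna(value: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(_BASES[value % 4])
        value //= 4
    return "".join(reversed(out))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults are desk-scale versions of a CROP-seq experiment: 120 guides
    (4 per target gene plus non-targeting controls), mostly singlet cells
    with a doublet fraction matching a low multiplicity of infection, a mean
    of 43 in-cell UMIs per guide per cell, ambient counts with mean ~1, and
    a mutant-integration mix proportioned to the scenario frequencies seen
    in deeply sequenced screens.
    """

    n_cells: int = 500
    n_guides: int = 120
    guides_per_gene: int = 4
    n_nontargeting: int = 20
    spacer_length: int = 20
    template: str = DEFAULT_TEMPLATE

    # cell composition (remainder after singlet+doublet is untransformed)
    fraction_singlet: float = 0.85
    fraction_doublet: float = 0.10

    # molecule counts
    mean_umis_per_cell: float = 43.0
    umi_sigma: float = 0.5  # log-normal shape of in-cell UMI counts
    ambient_rate: float = 0.05  # P(a non-carrying cell sees a guide at all)
    ambient_mean: float = 1.0  # mean ambient UMI count when present
    mean_reads_per_umi: float = 10.0
    reads_per_umi_min: int = 1

    # sequencing noise
    error_rate: float = 1e-3
    max_errors_per_molecule: int | None = None  # cap erroneous reads per UMI

    # mutant-integration scenario mix
    frac_pool_mutant: float = 0.20  # integration is a virus-pool mutant
    frac_transduction: float = 0.004
    frac_integration_dup: float = 0.014
    frac_cdna_prep: float = 0.185  # intact integrations gaining 1 mutant UMI

    # editing simulation
    editing_efficiency: float = 0.7
    expression_rate: float = 0.6  # P(a cell expresses a target gene at all)
    mean_expr_molecules: float = 3.0
    other_indel_rate: float = 0.03
    mismatch_rate: float = 0.05

    dialect: str = "cellranger"
    seed: int = 17

    def validate(self) -> None:
        fracs = [
            self.fraction_singlet,
            self.fraction_doublet,
            self.frac_pool_mutant,
            self.frac_transduction,
            self.frac_integration_dup,
            self.frac_cdna_prep,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.fraction_singlet + self.fraction_doublet > 1:
            raise ValueError("singlet + doublet fractions exceed 1")
        if self.frac_pool_mutant + self.frac_transduction + self.frac_integration_dup > 1:
            raise ValueError("scenario fractions exceed 1")
        if self.n_cells < 1 or self.n_guides < 1:
            raise ValueError("n_cells and n_guides must be positive")


@dataclass
class TruthTables:
    """Exactly what was planted, molecule by molecule.

    ``molecules``: one row per (cell, UMI) with the true sequence, scenario
    and read count.  ``cells``: per-cell carried components and the expected
    label.  ``variants``: the planted variant catalog (events + scenario).
    ``expression``: per expression-library molecule, the planted editing
    class at its gene's cutsite window.
    """

    molecules: pd.DataFrame
    cells: pd.DataFrame
    variants: pd.DataFrame
    expression: pd.DataFrame | None = None


@dataclass
class SimulatedScreen:
    config: SimulationConfig
    designs: list[GuideDesign]
    reference: CustomReference
    truth: TruthTables
    outdir: Path
    grna_bam: Path
    expression_bam: Path | None
    genome_fasta: Path | None
    genes_gtf: Path | None
    target_table: Path | None
    whitelist: Path
    reference_fasta: Path
    reference_gtf: Path


# ---------------------------------------------------------------------------
# guide designs and planted mutations


def make_guide_designs(config: SimulationConfig, rng: np.random.Generator) -> list[GuideDesign]:
    """Synthesize a guide library: ``guides_per_gene`` guides per target
    gene, the final ``n_nontargeting`` guides as controls."""
    n_targeting = config.n_guides - config.n_nontargeting
    if n_targeting < 0:
        raise ValueError("n_nontargeting exceeds n_guides")
    designs: list[GuideDesign] = []
    seen: set[str] = set()
    for i in range(config.n_guides):
        while True:
            spacer = "G" + "".join(
                rng.choice(list(_BASES), size=config.spacer_length - 1)
            )
            if spacer not in seen:
                seen.add(spacer)
                break
        if i < n_targeting:
            gene = f"GENE{i // config.guides_per_gene + 1:03d}"
            designs.append(GuideDesign(f"g_{gene}_{i % config.guides_per_gene + 1}", spacer, gene, True))
        else:
            designs.append(GuideDesign(f"g_NT_{i - n_targeting + 1}", spacer, "", False))
    return designs


def _sample_event(
    annotation: CassetteAnnotation,
    ref_seq: str,
    rng: np.random.Generator,
    used: set[tuple],
) -> tuple[MutationEvent, ...]:
    """Draw a fresh single-event mutation not yet used for this guide.

    Substitutions dominate (as in synthesized oligo pools) with a share of
    single-base deletions; positions span the annotated cassette so spectra
    cover promoter, spacer and scaffold.
    """
    lo, hi = annotation.start, annotation.end
    for _ in range(1000):
        pos = int(rng.integers(lo, hi))
        if rng.random() < 0.6:
            ref = ref_seq[pos]
            alt = _BASES[int(rng.integers(4))]
            if alt == ref:
                continue
            ev = MutationEvent(pos, "substitution", ref, alt, annotation.label_at(pos))
        else:
            ev = MutationEvent(pos, "deletion", ref_seq[pos], "", annotation.label_at(pos))
        key = (ev.position, ev.kind, ev.alt_allele)
        if key not in used:
            used.add(key)
            return (ev,)
    raise RuntimeError("event space exhausted")  # pragma: no cover


def apply_events(
    ref_seq: str, events: tuple[MutationEvent, ...]
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Build the mutant read sequence and its CIGAR from planted events.

    Supports substitution / deletion / insertion events (sorted,
    non-overlapping); the read spans the full contig.
    """
    seq_parts: list[str] = []
    cigar: list[tuple[int, int]] = []

    def _emit(op: int, length: int) -> None:
        if length == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    pos = 0
    for ev in sorted(events):
        if ev.position > pos:
            seq_parts.append(ref_seq[pos : ev.position])
            _emit(0, ev.position - pos)
            pos = ev.position
        if ev.kind == "substitution":
            seq_parts.append(ev.alt_allele)
            _emit(0, 1)
            pos += 1
        elif ev.kind == "deletion":
            _emit(2, len(ev.ref_allele))
            pos += len(ev.ref_allele)
        elif ev.kind == "insertion":
            seq_parts.append(ev.alt_allele)
            _emit(1, len(ev.alt_allele))
        else:
            raise ValueError(f"cannot synthesize event kind {ev.kind}")
    if pos < len(ref_seq):
        seq_parts.append(ref_seq[pos:])
        _emit(0, len(ref_seq) - pos)
    return "".join(seq_parts), tuple(cigar)


# ---------------------------------------------------------------------------
# the screen itself


def _lognormal_count(mean: float, sigma: float, rng: np.random.Generator) -> int:
    mu = np.log(mean) - sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, sigma))))


def simulate_screen(config: SimulationConfig, outdir: str | Path) -> SimulatedScreen:
    """Generate the full synthetic screen under ``outdir``.

    Byte-reproducible for a fixed config: the same seed yields identical
    BAMs and truth tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    designs = make_guide_designs(config, rng)
    reference = build_custom_reference(designs, config.template)
    ref_fasta, ref_gtf = write_reference(reference, outdir, dialect=config.dialect)
    write_guide_library(designs, outdir / "guides.tsv")

    guide_ids = [d.guide_id for d in designs]
    cells = [_int_to_dna(i, 16) for i in range(config.n_cells)]
    (outdir / "whitelist.txt").write_text("\n".join(cells) + "\n")

    # one virus-pool mutant variant per guide, pre-drawn so it recurs
    used_events: dict[str, set[tuple]] = {g: set() for g in guide_ids}
    pool_variant: dict[str, tuple[MutationEvent, ...]] = {}
    for gid in guide_ids:
        pool_variant[gid] = _sample_event(
            reference.annotations[gid], reference.contigs[gid], rng, used_events[gid]
        )

    # --- plan integrations per cell -------------------------------------
    mol_rows: list[dict] = []
    cell_rows: list[dict] = []
    variant_truth: dict[tuple[str, tuple[MutationEvent, ...]], dict] = {}

    def _note_variant(gid: str, events: tuple[MutationEvent, ...], scenario: str) -> None:
        key = (gid, events)
        entry = variant_truth.setdefault(
            key,
            {
                "guide_id": gid,
                "events": events_to_string(events),
                "scenario": scenario,
                "n_cells": 0,
                "n_umis": 0,
            },
        )
        entry["n_cells"] += 1

    mol_index = 0
    for ci, cell in enumerate(cells):
        u = rng.random()
        if u < config.fraction_singlet:
            carried = list(rng.choice(guide_ids, size=1, replace=False))
        elif u < config.fraction_singlet + config.fraction_doublet:
            carried = list(rng.choice(guide_ids, size=2, replace=False))
        else:
            carried = []

        components: list[tuple[str, str]] = []  # (guide_id, intact|mutant)
        for gid in carried:
            ann = reference.annotations[gid]
            ref_seq = reference.contigs[gid]
            n_umis = _lognormal_count(config.mean_umis_per_cell, config.umi_sigma, rng)
            v = rng.random()
            if v < config.frac_pool_mutant:
                events = pool_variant[gid]
                scenario = "virus_pool"
                plan = [(events, scenario)] * n_umis
                components.append((gid, "mutant"))
                _note_variant(gid, events, scenario)
            elif v < config.frac_pool_mutant + config.frac_transduction:
                events = _sample_event(ann, ref_seq, rng, used_events[gid])
                scenario = "transduction_or_subclone"
                plan = [(events, scenario)] * n_umis
                components.append((gid, "mutant"))
                _note_variant(gid, events, scenario)
            elif v < (
                config.frac_pool_mutant
                + config.frac_transduction
                + config.frac_integration_dup
            ):
                n_umis = max(n_umis, 4)
                n_mut = max(2, n_umis // 2)
                events = _sample_event(ann, ref_seq, rng, used_events[gid])
                scenario = "integration_duplication"
                plan = [(events, scenario)] * n_mut + [((), "intact")] * (n_umis - n_mut)
                components.append((gid, "intact"))
                components.append((gid, "mutant"))
                _note_variant(gid, events, scenario)
                _note_variant(gid, (), "intact")
            else:
                plan = [((), "intact")] * n_umis
                components.append((gid, "intact"))
                _note_variant(gid, (), "intact")
                if rng.random() < config.frac_cdna_prep and n_umis >= 2:
                    events = _sample_event(ann, ref_seq, rng, used_events[gid])
                    plan[0] = (events, "cdna_prep")
                    _note_variant(gid, events, "cdna_prep")

            for events, scenario in plan:
                mol_rows.append(
                    {
                        "cell_barcode": cell,
                        "umi": _int_to_dna(mol_index, 12),
                        "guide_id": gid,
                        "events": events_to_string(events),
                        "is_intact": not events,
                        "scenario": scenario,
                        "in_cell": True,
                        "_events": events,
                    }
                )
                mol_index += 1

        # ambient molecules: low-mean counts of guides the cell does not carry
        n_ambient_guides = rng.binomial(config.n_guides, config.ambient_rate)
        ambient_guides = rng.choice(guide_ids, size=n_ambient_guides, replace=False)
        for gid in ambient_guides:
            if gid in carried:
                continue
            count = 1 + rng.poisson(max(config.ambient_mean - 1.0, 0.0))
            for _ in range(count):
                mol_rows.append(
                    {
                        "cell_barcode": cell,
                        "umi": _int_to_dna(mol_index, 12),
                        "guide_id": gid,
                        "events": "intact",
                        "is_intact": True,
                        "scenario": "ambient",
                        "in_cell": False,
                        "_events": (),
                    }
                )
                mol_index += 1

        comp_set = sorted(set(components))
        if not comp_set:
            label = "none"
        elif len(comp_set) > 1:
            label = "multiplet"
        else:
            label = "single_intact" if comp_set[0][1] == "intact" else "single_mutant"
        cell_rows.append(
            {
                "cell_barcode": cell,
                "label": label,
                "guides": ",".join(sorted({g for g, _ in comp_set})),
                "components": ",".join(f"{g}:{k}" for g, k in comp_set),
            }
        )

    # --- emit reads ------------------------------------------------------
    grna_bam = outdir / "grna.bam"
    cb_tag, ub_tag, gn_tag = {
        "cellranger": ("CB", "UB", "GN"),
        "dropseq": ("XC", "XM", "gn"),
    }[config.dialect]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": g, "LN": len(reference.contigs[g])} for g in guide_ids],
        }
    )
    order = {g: i for i, g in enumerate(guide_ids)}

    read_counts: list[int] = []
    segments: list[pysam.AlignedSegment] = []
    for row in mol_rows:
        gid = row["guide_id"]
        true_seq, cigar = apply_events(reference.contigs[gid], row["_events"])
        n_reads = max(
            config.reads_per_umi_min, int(rng.poisson(config.mean_reads_per_umi))
        )
        errors_budget = (
            config.max_errors_per_molecule
            if config.max_errors_per_molecule is not None
            else n_reads
        )
        read_counts.append(n_reads)
        for r in range(n_reads):
            seq = true_seq
            if errors_budget > 0 and config.error_rate > 0:
                n_err = rng.binomial(len(seq), config.error_rate)
                if config.max_errors_per_molecule is not None:
                    n_err = min(n_err, 1)
                if n_err > 0:
                    errors_budget -= 1
                    positions = rng.choice(len(seq), size=n_err, replace=False)
                    s = list(seq)
                    for p in positions:
                        choices = [b for b in _BASES if b != s[p]]
                        s[p] = choices[int(rng.integers(3))]
                    seq = "".join(s)
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"m{len(read_counts) - 1}_r{r}"
            seg.flag = 0
            seg.reference_id = order[gid]
            seg.reference_start = 0
            seg.mapping_quality = 255
            seg.cigartuples = list(cigar)
            seg.query_sequence = seq
            seg.set_tag(cb_tag, row["cell_barcode"] + "-1")
            seg.set_tag(ub_tag, row["umi"])
            seg.set_tag(gn_tag, gid)
            segments.append(seg)
    segments.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    with pysam.AlignmentFile(str(grna_bam), "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.index(str(grna_bam))

    for row, n in zip(mol_rows, read_counts):
        row["n_reads"] = n
        del row["_events"]

    molecules = pd.DataFrame(mol_rows)
    cells_df = pd.DataFrame(cell_rows)
    variants_df = pd.DataFrame(variant_truth.values()) if variant_truth else pd.DataFrame(
        columns=["guide_id", "events", "scenario", "n_cells", "n_umis"]
    )
    if not molecules.empty and not variants_df.empty:
        umi_counts = molecules.groupby(["guide_id", "events"]).size()
        variants_df["n_umis"] = [
            int(umi_counts.get((g, e), 0))
            for g, e in zip(variants_df.guide_id, variants_df.events)
        ]
        # ambient molecules also contribute intact cells/UMIs; recount cells
        cell_counts = molecules.groupby(["guide_id", "events"]).cell_barcode.nunique()
        variants_df["n_cells"] = [
            int(cell_counts.get((g, e), 0))
            for g, e in zip(variants_df.guide_id, variants_df.events)
        ]

    truth = TruthTables(molecules=molecules, cells=cells_df, variants=variants_df)
    molecules.to_csv(outdir / "truth.molecules.tsv", sep="\t", index=False)
    cells_df.to_csv(outdir / "truth.cells.tsv", sep="\t", index=False)
    variants_df.to_csv(outdir / "truth.variants.tsv", sep="\t", index=False)

    expression_bam, genome_fasta, genes_gtf, target_table, expr_truth = (
        _simulate_expression(config, designs, cells_df, outdir, rng)
    )
    truth.expression = expr_truth
    if expr_truth is not None:
        expr_truth.to_csv(outdir / "truth.expression.tsv", sep="\t", index=False)

    return SimulatedScreen(
        config=config,
        designs=designs,
        reference=reference,
        truth=truth,
        outdir=outdir,
        grna_bam=grna_bam,
        expression_bam=expression_bam,
        genome_fasta=genome_fasta,
        genes_gtf=genes_gtf,
        target_table=target_table,
        whitelist=outdir / "whitelist.txt",
        reference_fasta=ref_fasta,
        reference_gtf=ref_gtf,
    )


# ---------------------------------------------------------------------------
# expression-window simulation (editing detection inputs)

_GENE_BLOCK = 2000
_EXON_PAD = 500
_READ_LEN = 60


def _simulate_expression(
    config: SimulationConfig,
    designs: list[GuideDesign],
    cells_df: pd.DataFrame,
    outdir: Path,
    rng: np.random.Generator,
) -> tuple[Path | None, Path | None, Path | None, Path | None, pd.DataFrame | None]:
    """Miniature genome + expression BAM covering each target's cutsite.

    One gene per target, one exon per gene, one cutsite per gene (attached
    to the gene's first guide).  Cells carrying an intact targeting guide
    are edited with probability ``editing_efficiency`` (a 6 bp deletion
    spanning the cut); a background of unedited, mismatch-only and
    off-cutsite-indel molecules is planted in all expressing cells.
    """
    genes: list[str] = []
    first_guide: dict[str, str] = {}
    for d in designs:
        if d.targeting and d.target_gene not in first_guide:
            first_guide[d.target_gene] = d.guide_id
            genes.append(d.target_gene)
    if not genes:
        return None, None, None, None, None

    chrom = "chrSim"
    genome_len = len(genes) * _GENE_BLOCK + _GENE_BLOCK
    genome = "".join(rng.choice(list(_BASES), size=genome_len))
    genome_fasta = outdir / "genome.fa"
    with genome_fasta.open("w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, genome_len, 80):
            fh.write(genome[i : i + 80] + "\n")
    pysam.faidx(str(genome_fasta))

    gene_exon: dict[str, tuple[int, int]] = {}
    gene_cut: dict[str, int] = {}
    gtf_lines = []
    target_rows = []
    for gi, gene in enumerate(genes):
        start = gi * _GENE_BLOCK + _EXON_PAD
        end = start + _GENE_BLOCK - 2 * _EXON_PAD
        gene_exon[gene] = (start, end)
        cutsite = (start + end) // 2
        gene_cut[gene] = cutsite
        attrs = f'gene_id "{gene}"; gene_name "{gene}"; transcript_id "{gene}.t1";'
        gtf_lines.append(
            "\t".join([chrom, "sim", "gene", str(start + 1), str(end), ".", "+", ".", attrs])
        )
        gtf_lines.append(
            "\t".join([chrom, "sim", "exon", str(start + 1), str(end), ".", "+", ".", attrs])
        )
        target_rows.append(
            {
                "guide_id": first_guide[gene],
                "chrom": chrom,
                "pam_position": cutsite + 3,  # plus strand: cut 3 nt upstream
                "strand": "+",
                "gene": gene,
            }
        )
    genes_gtf = outdir / "genes.gtf"
    genes_gtf.write_text("\n".join(gtf_lines) + "\n")
    target_table = outdir / "targets.tsv"
    pd.DataFrame(target_rows).to_csv(target_table, sep="\t", index=False)

    # which cells carry which intact targeting guides
    guide_gene = {d.guide_id: d.target_gene for d in designs if d.targeting}
    edited: dict[str, set[str]] = {}  # cell -> genes with Cas9 deletion
    for _, row in cells_df.iterrows():
        comps = str(row["components"]).split(",") if row["components"] else []
        for comp in comps:
            if not comp or ":" not in comp:
                continue
            gid, kind = comp.rsplit(":", 1)
            gene = guide_gene.get(gid)
            if gene is None or first_guide[gene] != gid:
                continue
            if kind == "intact" and rng.random() < config.editing_efficiency:
                edited.setdefault(row["cell_barcode"], set()).add(gene)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": genome_len}],
        }
    )
    segments: list[pysam.AlignedSegment] = []
    truth_rows: list[dict] = []
    mol_id = 0

    def _emit_molecule(cell: str, gene: str, kind: str) -> None:
        nonlocal mol_id
        cutsite = gene_cut[gene]
        umi = _int_to_dna(10_000_000 + mol_id, 12)
        mol_id += 1
        truth_rows.append({"cell_barcode": cell, "gene": gene, "umi": umi, "kind": kind})
        # two reads tiling the window from different starts
        for r, start in enumerate((cutsite - 40, cutsite - 20)):
            if kind == "cutsite_deletion":
                del_start, del_len = cutsite - 2, 6
            elif kind == "other_indel":
                del_start, del_len = cutsite + 10, 3
            else:
                del_start, del_len = None, 0
            seq_parts = []
            cigar: list[tuple[int, int]] = []
            rpos = start
            remaining = _READ_LEN
            while remaining > 0:
                if del_start is not None and rpos == del_start:
                    cigar.append((2, del_len))
                    rpos += del_len
                    del_start = None
                    continue
                nxt = del_start if (del_start is not None and del_start > rpos) else rpos + remaining
                chunk = min(nxt - rpos, remaining)
                seq_parts.append(genome[rpos : rpos + chunk])
                if cigar and cigar[-1][0] == 0:
                    cigar[-1] = (0, cigar[-1][1] + chunk)
                else:
                    cigar.append((0, chunk))
                rpos += chunk
                remaining -= chunk
            seq = "".join(seq_parts)
            if kind == "mismatch_only":
                s = list(seq)
                off = cutsite - 8 - start
                if 0 <= off < len(s):
                    s[off] = _BASES[(_BASES.index(s[off]) + 1) % 4]
                seq = "".join(s)
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"e{mol_id}_{r}"
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = start
            seg.mapping_quality = 255
            seg.cigartuples = cigar
            seg.query_sequence = seq
            seg.set_tag("CB", cell + "-1")
            seg.set_tag("UB", umi)
            segments.append(seg)

    for _, row in cells_df.iterrows():
        cell = row["cell_barcode"]
        for gene in genes:
            if rng.random() > config.expression_rate:
                continue
            n_mol = max(1, int(rng.poisson(config.mean_expr_molecules)))
            for _ in range(n_mol):
                if gene in edited.get(cell, set()):
                    _emit_molecule(cell, gene, "cutsite_deletion")
                elif rng.random() < config.other_indel_rate:
                    _emit_molecule(cell, gene, "other_indel")
                elif rng.random() < config.mismatch_rate:
                    _emit_molecule(cell, gene, "mismatch_only")
                else:
                    _emit_molecule(cell, gene, "unedited")

    segments.sort(key=lambda s: (s.reference_start, s.query_name))
    expression_bam = outdir / "expression.bam"
    with pysam.AlignmentFile(str(expression_bam), "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.index(str(expression_bam))
    return (
        expression_bam,
        genome_fasta,
        genes_gtf,
        target_table,
        pd.DataFrame(truth_rows, columns=["cell_barcode", "gene", "umi", "kind"]),
    )


# ---------------------------------------------------------------------------
# depth utilities


def downsample_reads(
    bam_path: str | Path, fraction: float, seed: int, out_path: str | Path
) -> Path:
    """Keep each read independently with probability ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(bam_path), "rb") as src:
        with pysam.AlignmentFile(str(out_path), "wb", header=src.header) as dst:
            for read in src.fetch(until_eof=True):
                if rng.random() < fraction:
                    dst.write(read)
    pysam.index(str(out_path))
    return Path(out_path)


def sequencing_saturation(n_reads: int, n_unique_molecules: int) -> float:
    """1 − unique molecules / reads: the fraction of duplicate reads."""
    if n_reads < 0 or n_unique_molecules < 0 or n_unique_molecules > n_reads:
        raise ValueError("need n_reads >= n_unique_molecules >= 0")
    if n_reads == 0:
        return 0.0
    return 1.0 - n_unique_molecules / n_reads


def assignment_concordance(
    truth_cells: pd.DataFrame,
    result: AssignmentResult,
    variants: list[GuideVariant],
) -> tuple[float, pd.DataFrame]:
    """Fraction of cells whose assigned guide set exactly matches truth.

    Comparison is at the parent-guide level (variant suffixes are run-local
    names).  Returns the concordance and a per-cell breakdown flagging
    missed guides, extra (ambient) guides and wrong labels.
    """
    parent = {v.variant_name: v.guide_id for v in variants}
    rows = []
    n_exact = 0
    for _, row in truth_cells.iterrows():
        cell = row["cell_barcode"]
        true_guides = set(str(row["guides"]).split(",")) - {"", "nan"}
        assigned = result.assignments.get(cell, [])
        got_guides = {parent.get(v, v) for v in assigned}
        missed = true_guides - got_guides
        extra = got_guides - true_guides
        exact = not missed and not extra
        n_exact += exact
        rows.append(
            {
                "cell_barcode": cell,
                "exact": exact,
                "n_missed": len(missed),
                "n_extra": len(extra),
                "true_label": row["label"],
                "called_label": result.labels.get(cell, "none"),
            }
        )
    breakdown = pd.DataFrame(rows)
    concordance = n_exact / len(truth_cells) if len(truth_cells) else 1.0
    return concordance, breakdown


def file_digest(path: str | Path) -> str:
    """MD5 of a file's bytes (reproducibility checks on emitted artifacts)."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
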
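"""End-to-end orchestration: filter -> consensus -> annotate -> assign (-> edits).

A :class:`PipelineConfig` (YAML-serializable) names the inputs and
parameters; :func:`run_pipeline` executes the stages in order, writes every
stage's table next to the outputs, and derives a summary report strictly
from those tables — every number in the report can be recomputed from the
TSVs on disk.  Drop and filter counts at every stage are the pipeline's
quality-control deliverable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bam_ingest, consensus as consensus_mod, mutations as mutations_mod
from .assignment import (
    AssignmentResult,
    assign_guides,
    build_count_matrix,
    write_assignments,
    write_count_matrix,
)
from .bam_ingest import FilterStats, filter_alignments, group_molecules, load_barcode_lookup, load_whitelist
from .consensus import ConsensusStats, call_all_consensus, filter_consensus, write_consensus
from .editing import detect_editing, load_exon_index, load_target_table, write_editing_table
from .guide_library import CustomReference, build_custom_reference, load_cassette_template, load_guide_library
from .mutations import (
    annotate_all,
    classify_source,
    collate_variants,
    mutation_spectrum,
    per_cell_mutation_frequency,
    write_mutation_table,
    write_spectrum,
)
from .simulate import downsample_reads, sequencing_saturation


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    grna_bam: str
    whitelist: str
    guides: str
    template: str  # cassette template FASTA (with the [spacer] placeholder)
    outdir: str
    barcode_lookup: str | None = None
    dialect: str = "cellranger"
    min_reads: int = 2
    count_all_reads: bool = False
    assignment_mode: str = "gmm"
    fixed_threshold: int = 3
    min_cells: int = 10
    gmm_scale: str = "log10"
    mask_tso: bool = False
    spectrum_weight: str = "cells"
    seed: int = 17
    threads: int = 1  # accepted for interface symmetry; results never depend on it
    # editing-detection inputs (optional)
    expression_bam: str | None = None
    genes_gtf: str | None = None
    target_table: str | None = None
    genome_fasta: str | None = None
    editing_window: int = 51

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self) -> None:
        for name in ("grna_bam", "whitelist", "guides", "template"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"config: input {name} does not exist: {p}")
        editing_inputs = (
            self.expression_bam,
            self.genes_gtf,
            self.target_table,
            self.genome_fasta,
        )
        if any(editing_inputs) and not all(editing_inputs):
            raise PipelineError(
                "config: editing detection needs expression_bam, genes_gtf, "
                "target_table and genome_fasta together"
            )


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: CustomReference
    molecules: list
    variants: list
    molecule_table: pd.DataFrame
    matrix: pd.DataFrame
    assignment: AssignmentResult
    source_calls: pd.DataFrame
    editing_calls: pd.DataFrame | None
    summary: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def assign_from_bam(
    grna_bam: str | Path,
    whitelist: set[str],
    reference: CustomReference,
    *,
    dialect: str = "cellranger",
    min_reads: int = 2,
    mode: str = "gmm",
    seed: int = 17,
):
    """In-memory filter -> consensus -> annotate -> assign, no files written.

    Returns ``(molecules, variants, molecule_table, assignment)``; used by
    the depth-accuracy harness and anywhere intermediate outputs are not
    needed.
    """
    stats = FilterStats()
    reads = filter_alignments(
        grna_bam, whitelist, set(reference.contigs), dialect=dialect, stats=stats
    )
    groups = group_molecules(reads)
    molecules = filter_consensus(call_all_consensus(groups, seed=seed), min_reads)
    annotated = annotate_all(molecules, reference)
    variants, table = collate_variants(annotated)
    matrix = build_count_matrix(table)
    assignment = assign_guides(matrix, variants, mode=mode, seed=seed)
    return molecules, variants, table, assignment


def depth_accuracy_sweep(
    screen,
    fractions: list[float],
    workdir: str | Path,
    *,
    seed: int = 17,
    min_reads: int = 2,
) -> pd.DataFrame:
    """Downsample the gRNA library and measure assignment concordance.

    Mirrors the depth-titration analysis: as reads are thinned, fewer UMIs
    survive the read-support filter and accuracy degrades.  Returns one row
    per fraction with the mean surviving UMIs per cell, the sequencing
    saturation and the exact-guide-set concordance against the simulation
    truth.
    """
    from .simulate import assignment_concordance  # local: avoid cycle at import

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    whitelist = load_whitelist(screen.whitelist)
    rows = []
    for frac in fractions:
        if frac >= 1.0:
            bam = screen.grna_bam
        else:
            bam = workdir / f"down_{frac:g}.bam"
            downsample_reads(screen.grna_bam, frac, seed, bam)
        stats = FilterStats()
        reads = filter_alignments(
            bam,
            whitelist,
            set(screen.reference.contigs),
            dialect=screen.config.dialect,
            stats=stats,
        )
        groups = group_molecules(reads)
        molecules = filter_consensus(call_all_consensus(groups, seed=seed), min_reads)
        annotated = annotate_all(molecules, screen.reference)
        variants, table = collate_variants(annotated)
        matrix = build_count_matrix(table)
        assignment = assign_guides(matrix, variants, mode="gmm", seed=seed)
        concordance, _ = assignment_concordance(screen.truth.cells, assignment, variants)
        in_cell = screen.truth.cells.label != "none"
        rows.append(
            {
                "fraction": frac,
                "reads": stats.emitted,
                "molecules": len(molecules),
                "mean_umis_per_cell": len(molecules) / max(int(in_cell.sum()), 1),
                "saturation": sequencing_saturation(stats.emitted, len(groups)),
                "concordance": concordance,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "pipeline.config.yaml")

    # --- reference -------------------------------------------------------
    designs = _stage("build-ref")(load_guide_library)(config.guides)
    template = _stage("build-ref")(load_cassette_template)(config.template)
    reference = _stage("build-ref")(build_custom_reference)(designs, template)

    # --- filter ----------------------------------------------------------
    whitelist = _stage("filter")(load_whitelist)(config.whitelist)
    lookup = (
        _stage("filter")(load_barcode_lookup)(config.barcode_lookup)
        if config.barcode_lookup
        else None
    )
    filter_stats = FilterStats()
    reads = _stage("filter")(list)(
        filter_alignments(
            config.grna_bam,
            whitelist,
            set(reference.contigs),
            lookup=lookup,
            dialect=config.dialect,
            stats=filter_stats,
        )
    )
    groups = group_molecules(reads)

    # --- consensus -------------------------------------------------------
    cstats = ConsensusStats()
    molecules = _stage("consensus")(call_all_consensus)(
        groups, seed=config.seed, stats=cstats
    )
    molecules = filter_consensus(
        molecules,
        config.min_reads,
        count_all_reads=config.count_all_reads,
        stats=cstats,
    )
    _stage("consensus")(write_consensus)(
        molecules, outdir, reference, dialect=config.dialect
    )

    # --- annotate --------------------------------------------------------
    annotation_errors: list[str] = []
    annotated = _stage("annotate")(annotate_all)(
        molecules, reference, errors=annotation_errors
    )
    variants, molecule_table = _stage("annotate")(collate_variants)(annotated)
    source_calls = _stage("annotate")(classify_source)(variants, molecule_table)
    cassette = next(iter(reference.annotations.values()))
    spectrum = _stage("annotate")(mutation_spectrum)(
        variants, cassette, mask_tso=config.mask_tso, weight=config.spectrum_weight
    )
    profiled_length = cassette.end - cassette.start
    cell_freq = per_cell_mutation_frequency(annotated, profiled_length)
    write_mutation_table(variants, source_calls, outdir)
    write_spectrum(spectrum, outdir)

    # --- assign ----------------------------------------------------------
    matrix = _stage("assign")(build_count_matrix)(molecule_table)
    assignment = _stage("assign")(assign_guides)(
        matrix,
        variants,
        mode=config.assignment_mode,
        fixed_threshold=config.fixed_threshold,
        min_cells=config.min_cells,
        seed=config.seed,
        gmm_scale=config.gmm_scale,
    )
    write_count_matrix(matrix, outdir / "matrix")
    write_assignments(assignment, outdir)

    # --- edits (optional) ------------------------------------------------
    editing_calls = None
    if config.expression_bam:
        import pyfaidx

        windows = _stage("edits")(load_target_table)(
            config.target_table, window=config.editing_window
        )
        exon_index = _stage("edits")(load_exon_index)(config.genes_gtf)
        genome = pyfaidx.Fasta(config.genome_fasta)
        editing_calls = _stage("edits")(detect_editing)(
            config.expression_bam,
            windows,
            exon_index,
            genome,
            dialect=config.dialect,
            whitelist=whitelist,
        )
        write_editing_table(editing_calls, outdir)

    # --- summary (derived from the stage outputs only) -------------------
    label_counts = pd.Series(assignment.labels).value_counts().to_dict() if assignment.labels else {}
    cells_with_assignment = {c for c, v in assignment.assignments.items() if v}
    intact_names = {v.variant_name for v in variants if v.is_intact}
    cells_with_mutant = {
        c
        for c, names in assignment.assignments.items()
        if any(n not in intact_names for n in names)
    }
    n_cells_total = len(whitelist)
    summary = {
        "cells_total": n_cells_total,
        "cells_assigned": len(cells_with_assignment),
        "cells_per_label": {k: int(v) for k, v in label_counts.items()},
        "variants_intact": sum(1 for v in variants if v.is_intact),
        "variants_mutant": sum(1 for v in variants if not v.is_intact),
        "pct_cells_with_mutant_grna": (
            100.0 * len(cells_with_mutant) / n_cells_total if n_cells_total else 0.0
        ),
        "filter_counts": filter_stats.as_dict(),
        "consensus_counts": cstats.as_dict(),
        "annotation_errors": len(annotation_errors),
        "molecules_surviving": len(molecules),
        "sequencing_saturation": sequencing_saturation(
            filter_stats.emitted, len(groups)
        ),
        "mean_mutations_per_cell_per_kb": (
            float(cell_freq.mean()) if len(cell_freq) else 0.0
        ),
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return PipelineResult(
        config=config,
        reference=reference,
        molecules=molecules,
        variants=variants,
        molecule_table=molecule_table,
        matrix=matrix,
        assignment=assignment,
        source_calls=source_calls,
        editing_calls=editing_calls,
        summary=summary,
    )
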
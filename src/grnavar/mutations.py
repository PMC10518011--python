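"""Mutation identification, variant naming, source classification, spectra.

Each consensus molecule is compared to its designed cassette by walking the
alignment CIGAR against the artificial contig: aligned blocks (M/=/X) are
compared base by base, and insertions (I), deletions (D), skipped regions
(N) and soft clips (S) are kept as events.  A molecule whose aligned span
matches the design perfectly is an intact gRNA; any event makes it a mutant
— deliberately stricter than the 1-Hamming tolerance used by feature
barcoding pipelines, because a single-base spacer or scaffold change can
already abolish guide function.

Molecules with identical (guide, event list) collapse into one *variant*,
named ``<guide_id>`` when intact and ``<guide_id>.<n>`` for mutants (suffix
ordered by descending UMI support, then first occurrence, so names are
stable across runs).

A mutant variant's likely origin is classified per cell from how its UMIs
co-occur with intact UMIs of the same guide:

* seen in more than one cell       -> amplified in the virus pool;
* sole guide sequence of its cell  -> transduction error or rare sub-clone;
* >1 mutant and >1 intact UMI      -> lentiviral integration/duplication;
* exactly 1 mutant UMI + intact    -> cDNA-preparation error.

Single-read sequencing errors never reach this stage: they are removed by
the consensus vote and the read-support filter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .consensus import ConsensusMolecule
from .guide_library import CassetteAnnotation, CustomReference

MUTATION_TABLE = "gRNA.mutation.txt"
SPECTRUM_TABLE = "mutation.spectrum.txt"

_KIND_LETTER = {
    "substitution": "M",
    "insertion": "I",
    "deletion": "D",
    "skip": "N",
    "softclip": "S",
}

SCENARIOS = (
    "virus_pool",
    "transduction_or_subclone",
    "integration_duplication",
    "cdna_prep",
    "ambiguous",
)


class AnnotationError(ValueError):
    """CIGAR inconsistent with the consensus sequence; molecule excluded."""


@dataclass(frozen=True, order=True)
class MutationEvent:
    """One deviation from the designed cassette.

    ``position`` is a 0-based cassette coordinate; insertions and soft clips
    are anchored to the reference base that follows them.  ``ref_allele`` is
    empty for insertions/soft clips, ``alt_allele`` empty for deletions and
    skips.  ``region`` is the cassette region label at the event's leftmost
    reference base ("upstream"/"downstream" outside the annotated span).
    """

    position: int
    kind: str
    ref_allele: str
    alt_allele: str
    region: str

    def token(self) -> str:
        ref = self.ref_allele or "-"
        alt = self.alt_allele or "-"
        return f"{self.position}{_KIND_LETTER[self.kind]}:{ref}>{alt}"


def events_to_string(events: tuple[MutationEvent, ...]) -> str:
    return ";".join(e.token() for e in events) if events else "intact"


@dataclass
class AnnotatedMolecule:
    molecule: ConsensusMolecule
    events: tuple[MutationEvent, ...]

    @property
    def is_intact(self) -> bool:
        return not self.events


@dataclass
class GuideVariant:
    """A distinct observed gRNA sequence: intact design or mutant."""

    guide_id: str
    variant_name: str
    events: tuple[MutationEvent, ...]
    n_cells: int
    n_umis: int

    @property
    def is_intact(self) -> bool:
        return not self.events


# ---------------------------------------------------------------------------
# CIGAR walk

# pysam numeric CIGAR ops
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)


def annotate_mutations(
    molecule: ConsensusMolecule, reference: CustomReference
) -> tuple[MutationEvent, ...]:
    """Itemize the molecule's deviations from its designed cassette.

    Walks the representative alignment's CIGAR against the guide contig.
    Returns events sorted by position; an empty tuple means intact.
    Raises :class:`AnnotationError` when the CIGAR does not account for the
    full query sequence.
    """
    if molecule.guide_id not in reference.contigs:
        raise AnnotationError(f"unknown guide contig {molecule.guide_id!r}")
    ref_seq = reference.contigs[molecule.contig]
    annotation = reference.annotations[molecule.contig]
    query = molecule.full_sequence

    consumed = sum(
        length for op, length in molecule.cigar if op in (_M, _I, _S, _EQ, _X)
    )
    if consumed != len(query):
        raise AnnotationError(
            f"CIGAR consumes {consumed} query bases but sequence has {len(query)}"
        )

    events: list[MutationEvent] = []
    rpos = molecule.pos
    qpos = 0
    for op, length in molecule.cigar:
        if op in (_M, _EQ, _X):
            if rpos + length > len(ref_seq):
                raise AnnotationError("alignment runs past the end of the contig")
            for i in range(length):
                ref_base = ref_seq[rpos + i]
                alt_base = query[qpos + i]
                if ref_base != alt_base:
                    events.append(
                        MutationEvent(
                            position=rpos + i,
                            kind="substitution",
                            ref_allele=ref_base,
                            alt_allele=alt_base,
                            region=annotation.label_at(rpos + i),
                        )
                    )
            rpos += length
            qpos += length
        elif op == _I:
            events.append(
                MutationEvent(
                    position=rpos,
                    kind="insertion",
                    ref_allele="",
                    alt_allele=query[qpos : qpos + length],
                    region=annotation.label_at(rpos),
                )
            )
            qpos += length
        elif op == _D:
            events.append(
                MutationEvent(
                    position=rpos,
                    kind="deletion",
                    ref_allele=ref_seq[rpos : rpos + length],
                    alt_allele="",
                    region=annotation.label_at(rpos),  # leftmost deleted base
                )
            )
            rpos += length
        elif op == _N:
            events.append(
                MutationEvent(
                    position=rpos,
                    kind="skip",
                    ref_allele=ref_seq[rpos : rpos + length],
                    alt_allele="",
                    region=annotation.label_at(rpos),
                )
            )
            rpos += length
        elif op == _S:
            # clipped bases deviate from the design but have no reference
            # coordinates; anchor the event at the alignment edge
            events.append(
                MutationEvent(
                    position=rpos,
                    kind="softclip",
                    ref_allele="",
                    alt_allele=query[qpos : qpos + length],
                    region=annotation.label_at(rpos),
                )
            )
            qpos += length
        elif op in (_H, _P):
            continue
        else:
            raise AnnotationError(f"unsupported CIGAR op {op}")
    return tuple(sorted(events))


def annotate_all(
    molecules: list[ConsensusMolecule],
    reference: CustomReference,
    errors: list[str] | None = None,
) -> list[AnnotatedMolecule]:
    """Annotate every molecule; malformed ones are excluded and recorded."""
    out: list[AnnotatedMolecule] = []
    for mol in molecules:
        try:
            out.append(AnnotatedMolecule(mol, annotate_mutations(mol, reference)))
        except AnnotationError as exc:
            if errors is not None:
                errors.append(f"{mol.cell_barcode}:{mol.umi}: {exc}")
    return out


# ---------------------------------------------------------------------------
# variant collation


def collate_variants(
    annotated: list[AnnotatedMolecule],
) -> tuple[list[GuideVariant], pd.DataFrame]:
    """Collapse molecules with identical (guide, events) into named variants.

    Returns the variant catalog and a per-molecule table with the assigned
    ``variant_name`` (columns: cell_barcode, umi, guide_id, variant_name,
    is_intact) used by cell assignment and source classification.
    """
    groups: dict[tuple[str, tuple[MutationEvent, ...]], list[AnnotatedMolecule]] = (
        defaultdict(list)
    )
    first_seen: dict[tuple[str, tuple[MutationEvent, ...]], int] = {}
    for i, am in enumerate(annotated):
        key = (am.molecule.guide_id, am.events)
        groups[key].append(am)
        first_seen.setdefault(key, i)

    variants: list[GuideVariant] = []
    names: dict[tuple[str, tuple[MutationEvent, ...]], str] = {}
    by_guide: dict[str, list[tuple[str, tuple[MutationEvent, ...]]]] = defaultdict(list)
    for guide_id, events in groups:
        by_guide[guide_id].append((guide_id, events))

    for guide_id, keys in by_guide.items():
        mutant_keys = [k for k in keys if k[1]]
        # suffix by descending UMI support, then order of first occurrence
        mutant_keys.sort(key=lambda k: (-len(groups[k]), first_seen[k]))
        for key in keys:
            if not key[1]:
                names[key] = guide_id
        for suffix, key in enumerate(mutant_keys, start=1):
            names[key] = f"{guide_id}.{suffix}"

    for key, members in groups.items():
        guide_id, events = key
        cells = {am.molecule.cell_barcode for am in members}
        variants.append(
            GuideVariant(
                guide_id=guide_id,
                variant_name=names[key],
                events=events,
                n_cells=len(cells),
                n_umis=len(members),
            )
        )
    variants.sort(key=lambda v: (v.guide_id, v.variant_name != v.guide_id, v.variant_name))

    table = pd.DataFrame(
        {
            "cell_barcode": [am.molecule.cell_barcode for am in annotated],
            "umi": [am.molecule.umi for am in annotated],
            "guide_id": [am.molecule.guide_id for am in annotated],
            "variant_name": [names[(am.molecule.guide_id, am.events)] for am in annotated],
            "is_intact": [am.is_intact for am in annotated],
        }
    )
    return variants, table


# ---------------------------------------------------------------------------
# source classification


def classify_source(
    variants: list[GuideVariant], molecule_table: pd.DataFrame
) -> pd.DataFrame:
    """Classify each (mutant variant, cell) occurrence into a likely origin.

    ``molecule_table`` is the per-molecule table from
    :func:`collate_variants`.  Returns one row per (variant_name, cell) with
    the scenario and the evidence counts (mutant/intact UMI counts for the
    guide in that cell).
    """
    n_cells_by_variant = {v.variant_name: v.n_cells for v in variants}
    intact_umis = (
        molecule_table[molecule_table.is_intact]
        .groupby(["cell_barcode", "guide_id"])
        .size()
    )
    rows: list[dict] = []
    mutants = molecule_table[~molecule_table.is_intact]
    for (cell, guide_id, variant_name), sub in mutants.groupby(
        ["cell_barcode", "guide_id", "variant_name"]
    ):
        n_mut = len(sub)
        n_int = int(intact_umis.get((cell, guide_id), 0))
        if n_cells_by_variant.get(variant_name, 0) > 1:
            scenario = "virus_pool"
        elif n_int == 0:
            scenario = "transduction_or_subclone"
        elif n_mut > 1 and n_int > 1:
            scenario = "integration_duplication"
        elif n_mut == 1 and n_int >= 1:
            scenario = "cdna_prep"
        else:
            scenario = "ambiguous"
        rows.append(
            {
                "variant_name": variant_name,
                "guide_id": guide_id,
                "cell_barcode": cell,
                "n_mutant_umis": n_mut,
                "n_intact_umis": n_int,
                "scenario": scenario,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_name",
            "guide_id",
            "cell_barcode",
            "n_mutant_umis",
            "n_intact_umis",
            "scenario",
        ],
    )


# ---------------------------------------------------------------------------
# mutation spectrum


def mutation_spectrum(
    variants: list[GuideVariant],
    cassette: CassetteAnnotation,
    *,
    mask_tso: bool = False,
    weight: str = "cells",
) -> pd.DataFrame:
    """Per-position mutation counts along the cassette.

    Every event contributes at its leftmost cassette position, weighted by
    the variant's cell support (or UMI support with ``weight="umis"``).
    With ``mask_tso``, counts at positions -2, -1 and 0 relative to the
    spacer start are zeroed: template-switch oligo artefacts concentrate
    there and would otherwise masquerade as mutations.
    """
    if weight not in ("cells", "umis"):
        raise ValueError("weight must be 'cells' or 'umis'")
    length = cassette.end
    counts = [0] * length
    for v in variants:
        w = v.n_cells if weight == "cells" else v.n_umis
        for e in v.events:
            if 0 <= e.position < length:
                counts[e.position] += w
    if mask_tso:
        s = cassette.spacer.start
        for pos in (s - 2, s - 1, s):
            if 0 <= pos < length:
                counts[pos] = 0
    return pd.DataFrame(
        {
            "position": range(length),
            "region": [cassette.label_at(p) for p in range(length)],
            "count": counts,
        }
    )


def per_cell_mutation_frequency(
    annotated: list[AnnotatedMolecule], profiled_length: int
) -> pd.Series:
    """Mutated positions per cell, scaled per 1000 profiled nucleotides.

    Normalising by the profiled gRNA length makes the statistic comparable
    across libraries that sequence different amounts of the cassette.
    """
    if profiled_length <= 0:
        raise ValueError("profiled_length must be positive")
    positions: dict[str, set[int]] = defaultdict(set)
    for am in annotated:
        positions.setdefault(am.molecule.cell_barcode, set())
        for e in am.events:
            positions[am.molecule.cell_barcode].add(e.position)
    freq = {
        cell: len(pos) / profiled_length * 1000.0 for cell, pos in positions.items()
    }
    return pd.Series(freq, name="mutations_per_cell_per_kb", dtype=float)


# ---------------------------------------------------------------------------
# output


def write_mutation_table(
    variants: list[GuideVariant],
    source_calls: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    """Write ``gRNA.mutation.txt``: one row per variant with its events,
    region summary, support and the distribution of source-scenario calls."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / MUTATION_TABLE
    scenario_summary: dict[str, str] = {}
    if not source_calls.empty:
        for variant_name, sub in source_calls.groupby("variant_name"):
            parts = [
                f"{scenario}:{n}"
                for scenario, n in sub.scenario.value_counts().items()
            ]
            scenario_summary[variant_name] = ",".join(sorted(parts))
    pd.DataFrame(
        {
            "variant_name": [v.variant_name for v in variants],
            "guide_id": [v.guide_id for v in variants],
            "events": [events_to_string(v.events) for v in variants],
            "regions": [
                ",".join(sorted({e.region for e in v.events})) or "intact"
                for v in variants
            ],
            "n_cells": [v.n_cells for v in variants],
            "n_umis": [v.n_umis for v in variants],
            "sources": [scenario_summary.get(v.variant_name, "") for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_spectrum(spectrum: pd.DataFrame, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / SPECTRUM_TABLE
    spectrum.to_csv(path, sep="\t", index=False)
    return path
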
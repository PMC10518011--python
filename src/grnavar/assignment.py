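"""Cells × guide-variants UMI counting and guide-to-cell assignment.

Droplets capture ambient (cell-free) guide molecules alongside the guides a
cell truly expresses, so raw UMI counts cannot be assigned directly.  Two
thresholding modes are offered:

* **fixed** — a user threshold ``t`` applied to every guide; a variant is
  assigned iff its UMI count is strictly greater than ``t``;
* **gmm** (default) — per guide, a two-component Gaussian mixture is fitted
  to log10 of the nonzero per-cell UMI counts, pooling the intact guide with
  all its mutant variants (a mutant competes for the same capture sites, so
  it belongs to the same expression distribution).  The component with the
  higher mean is the in-cell population; the threshold is the minimum raw
  count among observations assigned to it (posterior >= 0.5), and a variant
  is assigned iff its count reaches that minimum.

Cells are then labelled ``none`` / ``single_intact`` / ``single_mutant`` /
``multiplet``; multiplets (co-encapsulated cells or multiple integrations)
are flagged because their transcriptome no longer reflects one perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.mixture import GaussianMixture

from .mutations import GuideVariant

DEFAULT_FIXED_THRESHOLD = 3
DEFAULT_MIN_CELLS = 10

ASSIGNMENT_TABLE = "cell.assignment.txt"

LABELS = ("none", "single_intact", "single_mutant", "multiplet")


class AssignmentError(ValueError):
    pass


def build_count_matrix(molecule_table: pd.DataFrame) -> pd.DataFrame:
    """Distinct-UMI counts per (cell, variant) from the per-molecule table.

    Rows are cell barcodes, columns variant names (intact and mutant
    separately).  Each surviving consensus molecule contributes exactly one
    count, so the matrix total equals the number of molecules.
    """
    if molecule_table.empty:
        return pd.DataFrame(dtype=int)
    counts = (
        molecule_table.groupby(["cell_barcode", "variant_name"])
        .size()
        .unstack(fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    counts.index.name = "cell_barcode"
    return counts.loc[:, counts.sum(axis=0) > 0]


@dataclass
class ThresholdInfo:
    guide_id: str
    threshold: int
    method: str  # "gmm", "fixed", or a fallback reason
    n_nonzero: int = 0


def gmm_threshold(
    counts: np.ndarray,
    seed: int,
    *,
    min_cells: int = DEFAULT_MIN_CELLS,
    fallback: int = DEFAULT_FIXED_THRESHOLD,
    scale: str = "log10",
    min_separation: float = 0.5,
) -> tuple[int, str]:
    """Dynamic UMI threshold for one guide from its pooled per-cell counts.

    ``counts`` are the per-cell UMI totals for the guide (intact + variants
    pooled); zeros are excluded before fitting — cells that never saw the
    guide would otherwise dominate the mixture.  Returns ``(threshold,
    method)`` where method records whether the mixture fit was used or which
    fallback fired.  The threshold is the minimum raw count in the in-cell
    component, so assignment compares with ``>=``.
    """
    if scale not in ("log10", "linear"):
        raise AssignmentError("scale must be 'log10' or 'linear'")
    nonzero = np.asarray(counts, dtype=float)
    nonzero = nonzero[nonzero > 0]
    if nonzero.size < min_cells:
        return fallback, f"fallback_few_cells(n={nonzero.size})"
    if np.all(nonzero == nonzero[0]):
        return fallback, "fallback_degenerate"
    x = np.log10(nonzero) if scale == "log10" else nonzero
    try:
        gmm = GaussianMixture(
            n_components=2,
            random_state=int(seed) % (2**31),
            n_init=3,
            covariance_type="full",
        ).fit(x.reshape(-1, 1))
    except Exception:
        return fallback, "fallback_fit_failure"
    means = gmm.means_.ravel()
    # a genuine ambient/in-cell split is at least ~half a decade apart; a
    # smaller gap means the counts are unimodal and the split is arbitrary
    if scale == "log10":
        separation = float(means.max() - means.min())
    else:
        separation = (
            float(np.log10(means.max() / means.min())) if means.min() > 0 else np.inf
        )
    if separation < min_separation:
        return fallback, "fallback_unimodal"
    in_cell = int(np.argmax(means))
    posterior = gmm.predict_proba(x.reshape(-1, 1))[:, in_cell]
    members = nonzero[posterior >= 0.5]
    if members.size == 0:
        return fallback, "fallback_empty_component"
    return int(members.min()), "gmm"


def _parent_guide(variant_name: str, known_guides: set[str]) -> str:
    if variant_name in known_guides:
        return variant_name
    stem = variant_name.rsplit(".", 1)[0]
    return stem if stem in known_guides else variant_name


@dataclass
class AssignmentResult:
    """Per-cell assigned variants and label, plus per-guide thresholds."""

    assignments: dict[str, list[str]]
    labels: dict[str, str]
    thresholds: dict[str, ThresholdInfo]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        cells = sorted(self.assignments)
        return pd.DataFrame(
            {
                "cell_barcode": cells,
                "label": [self.labels[c] for c in cells],
                "n_assigned": [len(self.assignments[c]) for c in cells],
                "variants": [",".join(self.assignments[c]) for c in cells],
            }
        )


def assign_guides(
    matrix: pd.DataFrame,
    variants: list[GuideVariant],
    *,
    mode: str = "gmm",
    fixed_threshold: int = DEFAULT_FIXED_THRESHOLD,
    min_cells: int = DEFAULT_MIN_CELLS,
    seed: int = 17,
    gmm_scale: str = "log10",
) -> AssignmentResult:
    """Assign guide variants to cells with fixed or mixture thresholds.

    Fixed mode assigns a variant when its count exceeds the threshold
    (strictly more UMIs than ``t``); gmm mode assigns when the count reaches
    the in-cell minimum of the pooled mixture fit for the parent guide.
    """
    if mode not in ("fixed", "gmm"):
        raise AssignmentError(f"unknown assignment mode {mode!r}")
    intact_names = {v.variant_name for v in variants if v.is_intact}
    known_guides = {v.guide_id for v in variants}
    parent = {
        name: _parent_guide(name, known_guides) for name in (matrix.columns if not matrix.empty else [])
    }

    thresholds: dict[str, ThresholdInfo] = {}
    if matrix.empty:
        return AssignmentResult({}, {}, {}, mode)

    pooled: dict[str, np.ndarray] = {}
    for guide in sorted(set(parent.values())):
        cols = [c for c in matrix.columns if parent[c] == guide]
        pooled[guide] = matrix[cols].sum(axis=1).to_numpy()

    for guide in sorted(pooled):
        counts = pooled[guide]
        if mode == "fixed":
            thresholds[guide] = ThresholdInfo(
                guide, fixed_threshold, "fixed", int((counts > 0).sum())
            )
        else:
            thr, method = gmm_threshold(
                counts,
                seed,
                min_cells=min_cells,
                fallback=fixed_threshold,
                scale=gmm_scale,
            )
            thresholds[guide] = ThresholdInfo(guide, thr, method, int((counts > 0).sum()))

    assignments: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    values = matrix.to_numpy()
    columns = list(matrix.columns)
    for i, cell in enumerate(matrix.index):
        assigned: list[str] = []
        for j, name in enumerate(columns):
            count = values[i, j]
            info = thresholds[parent[name]]
            # fallback thresholds behave like fixed ones (strict >)
            strict = mode == "fixed" or info.method != "gmm"
            if (count > info.threshold) if strict else (count >= info.threshold):
                assigned.append(name)
        assignments[cell] = assigned
        if not assigned:
            labels[cell] = "none"
        elif len(assigned) > 1:
            labels[cell] = "multiplet"
        else:
            labels[cell] = (
                "single_intact" if assigned[0] in intact_names else "single_mutant"
            )
    return AssignmentResult(assignments, labels, thresholds, mode)


# ---------------------------------------------------------------------------
# output


def write_count_matrix(matrix: pd.DataFrame, outdir: str | Path) -> None:
    """MatrixMarket triplet with barcodes.tsv / features.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(
        matrix.to_numpy() if not matrix.empty else np.zeros((0, 0))
    )
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse, field="integer")
    (outdir / "barcodes.tsv").write_text(
        "\n".join(map(str, matrix.index)) + ("\n" if len(matrix.index) else "")
    )
    (outdir / "features.tsv").write_text(
        "\n".join(map(str, matrix.columns)) + ("\n" if len(matrix.columns) else "")
    )


def read_count_matrix(outdir: str | Path) -> pd.DataFrame:
    outdir = Path(outdir)
    sparse = scipy.io.mmread(str(outdir / "matrix.mtx"))
    barcodes = [l for l in (outdir / "barcodes.tsv").read_text().splitlines() if l]
    features = [l for l in (outdir / "features.tsv").read_text().splitlines() if l]
    df = pd.DataFrame(
        np.asarray(sparse.todense(), dtype=int), index=barcodes, columns=features
    )
    df.index.name = "cell_barcode"
    return df


def write_assignments(result: AssignmentResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / ASSIGNMENT_TABLE
    frame = result.to_frame()
    frame.to_csv(path, sep="\t", index=False)
    thr = pd.DataFrame(
        {
            "guide_id": [t.guide_id for t in result.thresholds.values()],
            "umi_threshold": [t.threshold for t in result.thresholds.values()],
            "method": [t.method for t in result.thresholds.values()],
            "n_nonzero_cells": [t.n_nonzero for t in result.thresholds.values()],
        }
    )
    thr.to_csv(outdir / "umi.thresholds.txt", sep="\t", index=False)
    return path
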
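"""Quantification of anatomical tracing datasets.

Operations on cell-count tables and fluorescence profiles produced upstream
by atlas-registered cell detection: per-subject normalized presynaptic
fractions (controls for transfection variability across injections),
antero-posterior axis distributions of labeled somata, double-label
percentages from dual retrograde tracing, laminar fractions, and
max-normalized axon-fluorescence profiles with their area under the curve.

The reference presynaptic count table for the ventral-CA1 retrograde tracing
cohort (four regions x five brains) ships with the package and loads via
:func:`load_reference_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellCountTable",
    "AxisDistribution",
    "LaminarProfile",
    "load_reference_counts",
    "read_cellcount_table",
    "normalized_fractions",
    "axis_distribution",
    "double_label_fraction",
    "layer_fractions",
    "laminar_profile",
]


@dataclass(frozen=True)
class CellCountTable:
    """Region x subject integer cell counts."""

    regions: tuple[str, ...]
    subjects: tuple[str, ...]
    counts: np.ndarray  # (n_regions, n_subjects) int

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region labels must be unique")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject labels must be unique")
        if self.counts.shape != (len(self.regions), len(self.subjects)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.regions), columns=list(self.subjects))


@dataclass(frozen=True)
class AxisDistribution:
    """Binned distribution of somata along the antero-posterior axis.

    Coordinates are mm relative to bregma, anterior positive. Fractions are
    normalized to the total labeled-cell count; the anterior/posterior split
    assigns the boundary coordinate itself (exactly at the split) to the
    posterior side.
    """

    bin_edges_mm: np.ndarray
    fractions: np.ndarray
    anterior_fraction: float
    posterior_fraction: float
    split_at_mm: float


@dataclass(frozen=True)
class LaminarProfile:
    """Max-normalized fluorescence intensity across the laminar depth axis."""

    depth: np.ndarray  # normalized position across layers
    intensity: np.ndarray  # unitless, normalized to the distal maximum
    region: str
    auc: float


def read_cellcount_table(path: str | Path) -> CellCountTable:
    """Read a region x subject count CSV (first column ``region``)."""
    df = pd.read_csv(path)
    if df.columns[0] != "region":
        raise ValueError(f"{path}: first column must be 'region'")
    df = df.set_index("region")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError(f"{path}: counts must be integers")
        counts = np.round(counts).astype(np.int64)
    return CellCountTable(
        regions=tuple(df.index.astype(str)),
        subjects=tuple(df.columns.astype(str)),
        counts=counts,
    )


def load_reference_counts() -> CellCountTable:
    """Load the packaged ventral-CA1 presynaptic count table (4 regions x 5 brains)."""
    with resources.as_file(
        resources.files("recogmem").joinpath("data/table1_presynaptic_counts.csv")
    ) as p:
        return read_cellcount_table(p)


def normalized_fractions(
    table: CellCountTable, reference_regions: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject fractions against a reference-region sum, plus medians.

    ``fraction(region, subject) = count(region, subject) / sum over the
    reference regions of counts for that subject``. Normalizing within each
    subject controls for injection-to-injection transfection variability.
    By default every region in the table is a reference region. Returns the
    fraction table and the across-subject median per region.
    """
    refs = tuple(reference_regions) if reference_regions is not None else table.regions
    missing = set(refs) - set(table.regions)
    if missing:
        raise ValueError(f"reference regions not in table: {sorted(missing)}")
    df = table.to_frame().astype(float)
    denom = df.loc[list(refs)].sum(axis=0)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero reference sum for subject(s) {list(zero.index)}")
    fractions = df.div(denom, axis=1)
    return fractions, fractions.median(axis=1)


def axis_distribution(
    coords_mm: np.ndarray, bin_mm: float = 1.0, split_at_mm: float = 0.0
) -> AxisDistribution:
    """Histogram soma coordinates along the AP axis, normalized to the total.

    Bins are half-open ``[edge, edge + bin_mm)`` on a grid aligned to integer
    multiples of ``bin_mm``; fractions sum to 1. The anterior fraction is the
    share of cells strictly anterior to (coordinate >) ``split_at_mm``.
    """
    x = np.asarray(coords_mm, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one cell coordinate")
    if bin_mm <= 0:
        raise ValueError("bin_mm must be positive")
    lo = np.floor(x.min() / bin_mm) * bin_mm
    hi = np.floor(x.max() / bin_mm) * bin_mm + bin_mm
    edges = np.arange(lo, hi + 0.5 * bin_mm, bin_mm)
    idx = np.floor((x - lo) / bin_mm).astype(int)
    idx = np.minimum(idx, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    fractions = counts / x.size
    anterior = float(np.count_nonzero(x > split_at_mm)) / x.size
    return AxisDistribution(
        bin_edges_mm=edges,
        fractions=fractions,
        anterior_fraction=anterior,
        posterior_fraction=1.0 - anterior,
        split_at_mm=split_at_mm,
    )


def double_label_fraction(n_double: int, n_vca1_labeled: int) -> float:
    """Percent of retrogradely labeled neurons carrying both tracers."""
    if n_vca1_labeled <= 0:
        raise ValueError("total labeled count must be positive")
    if not 0 <= n_double <= n_vca1_labeled:
        raise ValueError("double-labeled count must lie in [0, total]")
    return 100.0 * n_double / n_vca1_labeled


def layer_fractions(counts_per_layer: Sequence[float]) -> np.ndarray:
    """Per-layer fractions of labeled neurons (normalized to the total)."""
    c = np.asarray(counts_per_layer, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero counts")
    return c / total


def laminar_profile(
    distal: np.ndarray,
    proximal: np.ndarray,
    depth: np.ndarray | None = None,
) -> tuple[LaminarProfile, LaminarProfile]:
    """Max-normalized laminar fluorescence profiles and their AUCs.

    Both background-subtracted intensity series are divided by the maximum of
    the *distal* profile (the reference subregion); AUC is the trapezoidal
    integral over the depth axis (unit spacing by default).
    """
    d = np.asarray(distal, dtype=float)
    p = np.asarray(proximal, dtype=float)
    if d.shape != p.shape:
        raise ValueError("profiles must have equal length")
    if depth is None:
        depth = np.arange(d.size, dtype=float)
    else:
        depth = np.asarray(depth, dtype=float)
        if depth.shape != d.shape:
            raise ValueError("depth axis must match profile length")
    ref = d.max()
    if ref <= 0:
        raise ValueError("distal profile maximum must be positive")
    dn, pn = d / ref, p / ref
    return (
        LaminarProfile(depth=depth, intensity=dn, region="distal", auc=float(np.trapezoid(dn, depth))),
        LaminarProfile(depth=depth, intensity=pn, region="proximal", auc=float(np.trapezoid(pn, depth))),
    )
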
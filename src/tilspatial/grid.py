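"""Multiscale grid statistics: occupancy curves and box-count fractal dimensions.

The tissue is tiled with a grid of squares of side L (10–600 μm).  Each
square is assigned 1 or 0 according to a binary question, e.g. "is there at
least one stromal B cell in the square?".  Squares containing no cell at all
are omitted — they lie outside the tissue.  Two statistics summarise the
answer pattern across scales:

* **occupancy** — the fraction n(L)/N(L) of cell-containing squares answering
  yes, traced as a function of L and summarised by its area under the curve;
* **fractal dimension** — the least-squares slope s of ln n(L) versus
  ln(1/L) over a scale window; for an area-filling arrangement n ∝ 1/L² so
  s → 2, for an isolated point n is constant so s → 0.

The dispersion score Δs = s_large − s_small contrasts the slope over
200–600 μm with the slope over 10–40 μm: spatially dispersed cells look
two-dimensional at large scales and point-like at small scales (large Δs),
while a self-similar, clustered arrangement keeps the slope flat (small Δs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (LYMPHOCYTE_PHENOTYPES, PHENOTYPES, T_LINEAGE_PHENOTYPES,
                 PointPattern, TISSUE_CATEGORIES)

__all__ = [
    "DEFAULT_L_LADDER",
    "SMALL_SCALE_WINDOW",
    "LARGE_SCALE_WINDOW",
    "BinaryQuestion",
    "GridSpec",
    "BoxCountCurve",
    "FDFit",
    "FDDifference",
    "InsufficientScalesError",
    "question_mask",
    "overlay_counts",
    "occupancy_curve",
    "occupancy_auc",
    "fit_fractal_dimension",
    "fd_difference",
]

#: 13 geometrically spaced square sides covering 10–600 μm.
DEFAULT_L_LADDER: tuple[float, ...] = (
    10, 14, 20, 28, 40, 57, 80, 113, 160, 226, 320, 453, 600)
SMALL_SCALE_WINDOW: tuple[float, float] = (10.0, 40.0)
LARGE_SCALE_WINDOW: tuple[float, float] = (200.0, 600.0)

MEMBERSHIP_SCOPES = ("any", "isolated_only", "in_lc_only",
                     "in_heterotypic_lc", "in_pure_t_lc")


class InsufficientScalesError(ValueError):
    """Fewer than three usable scales remain inside the fit window."""


@dataclass(frozen=True)
class BinaryQuestion:
    """The yes/no question asked of every grid square.

    A square answers yes iff it contains at least one cell whose phenotype is
    in ``phenotype_set``, whose tissue category matches ``tissue_scope`` and
    whose cluster membership matches ``membership_scope``.  Membership scopes
    other than ``any`` require cluster results (see :func:`question_mask`).
    """

    phenotype_set: frozenset[str]
    tissue_scope: str = "any"
    membership_scope: str = "any"
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.phenotype_set:
            raise ValueError("phenotype_set must be non-empty")
        unknown = set(self.phenotype_set) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes {sorted(unknown)}")
        if self.tissue_scope not in ("any",) + TISSUE_CATEGORIES:
            raise ValueError(f"unknown tissue scope {self.tissue_scope!r}")
        if self.membership_scope not in MEMBERSHIP_SCOPES:
            raise ValueError(
                f"unknown membership scope {self.membership_scope!r}")

    @classmethod
    def b_cells(cls, tissue_scope: str = "any", **kw) -> "BinaryQuestion":
        return cls(frozenset({"B"}), tissue_scope, **kw)

    @classmethod
    def t_cells(cls, tissue_scope: str = "any", **kw) -> "BinaryQuestion":
        """All CD3+ lineages pooled (cytotoxic, helper, regulatory)."""
        return cls(frozenset(T_LINEAGE_PHENOTYPES), tissue_scope, **kw)

    @classmethod
    def lymphocytes(cls, tissue_scope: str = "any", **kw) -> "BinaryQuestion":
        return cls(frozenset(LYMPHOCYTE_PHENOTYPES), tissue_scope, **kw)


@dataclass(frozen=True)
class GridSpec:
    """Square side L and grid anchor (μm).  Squares are half-open
    ``[x0+iL, x0+(i+1)L) × [y0+jL, y0+(j+1)L)``."""

    L: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"square side must be > 0, got {self.L}")


@dataclass
class BoxCountCurve:
    """Per-scale box counts: n(L) yes-squares, N(L) cell-containing squares."""

    entries: pd.DataFrame  # columns: L, n, N, occupancy (L strictly increasing)

    def __post_init__(self) -> None:
        e = self.entries
        if not (np.diff(e["L"].to_numpy()) > 0).all():
            raise ValueError("L values must be strictly increasing")
        if ((e["n"] > e["N"]).any() or (e["n"] < 0).any()):
            raise ValueError("box counts must satisfy 0 <= n <= N")

    @property
    def L(self) -> np.ndarray:
        return self.entries["L"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.entries["n"].to_numpy(dtype=int)

    @property
    def N(self) -> np.ndarray:
        return self.entries["N"].to_numpy(dtype=int)

    @property
    def occupancy(self) -> np.ndarray:
        return self.entries["occupancy"].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclass
class FDFit:
    """Least-squares box-count slope over one scale window."""

    scale_window: tuple[float, float]
    slope_s: float
    intercept: float          # ln A of the power law n(L) = A / L^s
    r_squared: float
    n_scales: int
    normalized: bool = False  # slope of ln(n/N) instead of ln n

    def to_dict(self) -> dict:
        return {"scale_window": list(self.scale_window),
                "slope_s": self.slope_s, "intercept": self.intercept,
                "r_squared": self.r_squared, "n_scales": self.n_scales,
                "normalized": self.normalized}


@dataclass
class FDDifference:
    """Dispersion score Δs = s_large − s_small."""

    fit_small: FDFit
    fit_large: FDFit

    @property
    def s_small(self) -> float:
        return self.fit_small.slope_s

    @property
    def s_large(self) -> float:
        return self.fit_large.slope_s

    @property
    def delta_s(self) -> float:
        return self.s_large - self.s_small


def question_mask(pattern: PointPattern,
                  question: BinaryQuestion,
                  membership: "pd.Series | dict | None" = None) -> np.ndarray:
    """Boolean mask over pattern cells answering the question's filters.

    ``membership`` maps cell_id -> one of {"isolated", "pure_T",
    "heterotypic", "pure_B", "tls"...}; required whenever
    ``membership_scope != "any"`` (produced by
    ``clusters.membership_by_cell``).
    """
    mask = pattern.phenotype_mask(question.phenotype_set)
    mask &= pattern.tissue_mask(question.tissue_scope)
    scope = question.membership_scope
    if scope != "any":
        if membership is None:
            raise ValueError(
                f"membership scope {scope!r} requires cluster membership")
        mem = pattern.cells["cell_id"].map(membership)
        if scope == "isolated_only":
            mask &= (mem == "isolated").to_numpy()
        elif scope == "in_lc_only":
            mask &= mem.isin(["pure_T", "heterotypic", "pure_B"]).to_numpy()
        elif scope == "in_heterotypic_lc":
            mask &= (mem == "heterotypic").to_numpy()
        elif scope == "in_pure_t_lc":
            mask &= (mem == "pure_T").to_numpy()
    return mask


def _box_indices(xy: np.ndarray, grid: GridSpec,
                 extent: tuple[float, float, float, float] | None) -> np.ndarray:
    """Map coordinates to integer (i, j) box indices; cells exactly on the
    maximal edge of the extent are clamped into the last square."""
    x0, y0 = grid.origin
    ij = np.floor((xy - (x0, y0)) / grid.L).astype(np.int64)
    if extent is not None:
        xmin, ymin, xmax, ymax = extent
        imax = max(int(np.ceil((xmax - x0) / grid.L)) - 1, 0)
        jmax = max(int(np.ceil((ymax - y0) / grid.L)) - 1, 0)
        ij[:, 0] = np.clip(ij[:, 0], None, imax)
        ij[:, 1] = np.clip(ij[:, 1], None, jmax)
    return ij


def _pattern_extent(pattern: PointPattern) -> tuple[float, float, float, float]:
    if pattern.roi.boundary is not None:
        xmin, ymin, xmax, ymax = pattern.roi.boundary.bounds
    else:
        xy = pattern.coords
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
    return float(xmin), float(ymin), float(xmax), float(ymax)


def overlay_counts(pattern: PointPattern,
                   grid: GridSpec | float,
                   question: BinaryQuestion,
                   membership=None,
                   count_all_squares: bool = False,
                   ) -> tuple[int, int, float]:
    """Overlay one grid and answer the binary question per square.

    Returns ``(n, N, occupancy)`` where N counts squares holding at least one
    cell of any type (the tissue-omission rule), n counts squares holding at
    least one question-matching cell, and occupancy = n/N.

    ``count_all_squares=True`` makes N the full number of grid squares tiling
    the pattern extent — appropriate for simulated reference processes where
    there is no tissue to delimit.
    """
    if pattern.n_cells == 0:
        raise ValueError("cannot overlay a grid on a pattern with zero cells")
    extent = _pattern_extent(pattern)
    if isinstance(grid, (int, float)):
        grid = GridSpec(L=float(grid), origin=(extent[0], extent[1]))
    xy = pattern.coords
    ij = _box_indices(xy, grid, extent)
    # Collapse (i, j) to a single key for fast uniqueness.
    jspan = int(ij[:, 1].max() - ij[:, 1].min()) + 1
    keys = (ij[:, 0] - ij[:, 0].min()) * jspan + (ij[:, 1] - ij[:, 1].min())
    if count_all_squares:
        x0, y0 = grid.origin
        ncols = max(int(np.ceil((extent[2] - x0) / grid.L)), 1)
        nrows = max(int(np.ceil((extent[3] - y0) / grid.L)), 1)
        N = ncols * nrows
    else:
        N = int(np.unique(keys).size)
    qmask = question_mask(pattern, question, membership)
    n = int(np.unique(keys[qmask]).size)
    if N == 0:
        raise ValueError("no occupied squares (empty pattern)")
    return n, N, n / N


def occupancy_curve(pattern: PointPattern,
                    Ls: Sequence[float] = DEFAULT_L_LADDER,
                    question: BinaryQuestion | None = None,
                    membership=None,
                    count_all_squares: bool = False,
                    origin: tuple[float, float] | None = None,
                    ) -> BoxCountCurve:
    """Trace (n, N, occupancy) across the L ladder.

    The grid anchor defaults to the minimum corner of the ROI bounding box,
    shared across all L, so dyadic ladders nest.
    """
    if question is None:
        question = BinaryQuestion.lymphocytes()
    Ls = sorted(float(L) for L in Ls)
    if not Ls or Ls[0] <= 0:
        raise ValueError("Ls must be non-empty and positive")
    extent = _pattern_extent(pattern)
    anchor = origin if origin is not None else (extent[0], extent[1])
    rows = []
    for L in Ls:
        n, N, occ = overlay_counts(
            pattern, GridSpec(L=L, origin=anchor), question,
            membership=membership, count_all_squares=count_all_squares)
        rows.append((L, n, N, occ))
    return BoxCountCurve(pd.DataFrame(rows, columns=["L", "n", "N", "occupancy"]))


def occupancy_auc(curve: BoxCountCurve, abscissa: str = "log") -> float:
    """Trapezoidal area under occupancy vs ln L (default) or vs L.

    Integrating against ln L weights the 60-fold scale range uniformly per
    octave; a constant occupancy of 1 over [10, 600] μm gives ln 60 ≈ 4.094.
    """
    if len(curve.entries) < 2:
        raise ValueError("occupancy AUC needs at least 2 curve entries")
    x = np.log(curve.L) if abscissa == "log" else curve.L
    if abscissa not in ("log", "linear"):
        raise ValueError(f"unknown abscissa {abscissa!r}")
    return float(np.trapezoid(curve.occupancy, x))


def _fit_window(curve: BoxCountCurve, scale_window: tuple[float, float],
                normalized: bool) -> FDFit:
    lo, hi = scale_window
    sel = (curve.L >= lo) & (curve.L <= hi) & (curve.n > 0)
    L = curve.L[sel]
    y = curve.n[sel].astype(float)
    if normalized:
        y = y / curve.N[sel]
    if len(L) < 3:
        raise InsufficientScalesError(
            f"need >= 3 scales with n > 0 inside {scale_window}, have {len(L)}")
    # slope of ln n vs ln(1/L); natural logarithms
    res = stats.linregress(np.log(1.0 / L), np.log(y))
    return FDFit(scale_window=(float(lo), float(hi)),
                 slope_s=float(res.slope), intercept=float(res.intercept),
                 r_squared=float(res.rvalue ** 2), n_scales=int(len(L)),
                 normalized=normalized)


def fit_fractal_dimension(pattern: PointPattern,
                          question: BinaryQuestion,
                          Ls: Sequence[float] = DEFAULT_L_LADDER,
                          scale_window: tuple[float, float] = LARGE_SCALE_WINDOW,
                          membership=None,
                          normalized: bool = False,
                          count_all_squares: bool = False,
                          ) -> FDFit:
    """Box-count FD: least-squares slope of ln n(L) vs ln(1/L) in the window.

    Scales where n(L) = 0 are dropped; fewer than three surviving scales
    raises :class:`InsufficientScalesError`.  By default the slope uses the
    raw ln n(L); ``normalized=True`` fits ln(n/N) instead, which shifts the
    intercept by the tissue size but also absorbs the scale dependence of
    N(L) into the slope (useful for comparing curves across images, not for
    the dimension itself).
    """
    curve = occupancy_curve(pattern, Ls, question, membership=membership,
                            count_all_squares=count_all_squares)
    return _fit_window(curve, scale_window, normalized)


def fd_difference(pattern: PointPattern,
                  question: BinaryQuestion,
                  Ls_small: Sequence[float] | None = None,
                  Ls_large: Sequence[float] | None = None,
                  membership=None,
                  ) -> FDDifference:
    """Δs = s_large − s_small between the 200–600 and 10–40 μm windows."""
    ladder = np.asarray(DEFAULT_L_LADDER, dtype=float)
    if Ls_small is None:
        Ls_small = ladder[ladder <= SMALL_SCALE_WINDOW[1]]
    if Ls_large is None:
        Ls_large = ladder[ladder >= LARGE_SCALE_WINDOW[0]]
    fit_small = fit_fractal_dimension(
        pattern, question, Ls_small,
        scale_window=(min(Ls_small), max(Ls_small)), membership=membership)
    fit_large = fit_fractal_dimension(
        pattern, question, Ls_large,
        scale_window=(min(Ls_large), max(Ls_large)), membership=membership)
    return FDDifference(fit_small=fit_small, fit_large=fit_large)
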
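"""Synthetic marked point patterns emulating the tumor microenvironment.

Generates patient-like patterns with the statistical structure the analysis
assumes: cancer-cell islands interspersed with stroma, a dispersed
(homogeneous Poisson) lymphocyte component, a clustered (Thomas process)
component whose parents sit at a controlled offset from island boundaries,
B/T phenotype mixes, and good/poor outcome profiles that build in the
directions of the real effects — good outcomes get more, smaller lymphocyte
clusters placed nearer to islands and a denser dispersed B-cell background;
poor outcomes get fewer, larger, more distant clusters.

All generators are deterministic given their seed.  Points falling outside
the rectangular window are discarded (no toroidal wrap-around): the analysis
operates on bounded regions of interest where edge squares are kept if they
contain cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PointPattern, RegionOfInterest

__all__ = [
    "Window",
    "OutcomeProfile",
    "GOOD_PROFILE",
    "POOR_PROFILE",
    "DEFAULT_WINDOW",
    "POISSON_REFERENCE_INTENSITY",
    "sample_poisson",
    "sample_thomas",
    "make_cancer_islands",
    "CancerIslands",
    "synthesize_patient",
    "synthesize_cohort",
    "expected_poisson_occupancy",
]

#: Reference intensity of the uniform Poisson comparison process (points/mm²).
POISSON_REFERENCE_INTENSITY = 300.0


@dataclass(frozen=True)
class Window:
    """Rectangular simulation window, dimensions in μm."""

    width: float = 3000.0
    height: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window dimensions must be > 0")

    @property
    def area_mm2(self) -> float:
        return self.width * self.height / 1e6


DEFAULT_WINDOW = Window(3000.0, 3000.0)


@dataclass(frozen=True)
class OutcomeProfile:
    """Generator knobs for one outcome group.

    Rates are per mm²; lengths in μm.  ``lymphocyte_intensity`` drives the
    dispersed Poisson component, the ``cluster_*`` fields the Thomas
    component, ``island_*`` the cancer geometry, ``island_infiltration_rate``
    the density (per mm² of island area) of lymphocytes seeded inside
    islands, and ``lc_island_offset`` the mean distance from a cluster parent
    to the nearest island boundary.
    """

    lymphocyte_intensity: float = 120.0
    b_fraction: float = 0.3
    cluster_parent_intensity: float = 8.0
    mean_cluster_size: float = 20.0
    cluster_dispersion_sigma: float = 15.0
    island_count: int = 12
    island_radius_mean: float = 150.0
    island_infiltration_rate: float = 20.0
    lc_island_offset: float = 100.0

    def __post_init__(self) -> None:
        numeric = ("lymphocyte_intensity", "cluster_parent_intensity",
                   "mean_cluster_size", "cluster_dispersion_sigma",
                   "island_radius_mean", "island_infiltration_rate",
                   "lc_island_offset")
        for name in numeric:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.island_count < 0:
            raise ValueError("island_count must be >= 0")
        if not 0.0 <= self.b_fraction <= 1.0:
            raise ValueError("b_fraction must lie in [0, 1]")


# Default profiles: effect directions built in (good = dispersed B cells,
# many small clusters near islands; poor = confined B cells, few large
# clusters far from islands).  Magnitudes are plausible for a 3x3 mm field
# and are documented constants, not claims about real tissue biology.
GOOD_PROFILE = OutcomeProfile(
    lymphocyte_intensity=150.0, b_fraction=0.30,
    cluster_parent_intensity=10.0, mean_cluster_size=15.0,
    cluster_dispersion_sigma=15.0, island_count=12,
    island_radius_mean=150.0, island_infiltration_rate=30.0,
    lc_island_offset=60.0)

POOR_PROFILE = OutcomeProfile(
    lymphocyte_intensity=50.0, b_fraction=0.35,
    cluster_parent_intensity=5.0, mean_cluster_size=40.0,
    cluster_dispersion_sigma=15.0, island_count=12,
    island_radius_mean=150.0, island_infiltration_rate=10.0,
    lc_island_offset=220.0)

# Fixed split of the T lineage into subtypes, roughly helper-heavy as in
# multiplex panels (helper : cytotoxic : regulatory).
T_SUBTYPE_SPLIT = (("T_helper", 0.50), ("T_CD8", 0.35), ("Treg", 0.15))


def _cells_frame(xy: np.ndarray, phenotypes, tissues, prefix: str) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [f"{prefix}{i:06d}" for i in range(len(xy))],
        "x": xy[:, 0], "y": xy[:, 1],
        "phenotype": phenotypes, "tissue_category": tissues})


def sample_poisson(intensity: float,
                   window: Window = DEFAULT_WINDOW,
                   seed: int = 0,
                   phenotype: str = "B",
                   tissue_category: str = "stroma") -> PointPattern:
    """Homogeneous Poisson pattern at ``intensity`` points/mm²."""
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area_mm2)
    xy = rng.uniform((0, 0), (window.width, window.height), size=(n, 2))
    roi = RegionOfInterest(area_mm2=window.area_mm2)
    return PointPattern(
        _cells_frame(xy, phenotype, tissue_category, "p"), roi,
        patient_id=f"poisson_{seed}")


def sample_thomas(parent_intensity: float,
                  mean_offspring: float,
                  sigma: float,
                  window: Window = DEFAULT_WINDOW,
                  seed: int = 0,
                  phenotype: str = "B",
                  tissue_category: str = "stroma") -> PointPattern:
    """Thomas cluster process: Poisson parents, Poisson(mean_offspring)
    offspring per parent with isotropic Gaussian(sigma) displacement.
    Offspring outside the window are discarded."""
    for name, v in (("parent_intensity", parent_intensity),
                    ("mean_offspring", mean_offspring), ("sigma", sigma)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(parent_intensity * window.area_mm2)
    parents = rng.uniform((0, 0), (window.width, window.height),
                          size=(n_parents, 2))
    pieces = []
    for px, py in parents:
        k = rng.poisson(mean_offspring)
        if k == 0:
            continue
        pts = rng.normal((px, py), sigma, size=(k, 2))
        pieces.append(pts)
    xy = np.concatenate(pieces) if pieces else np.empty((0, 2))
    inside = ((xy[:, 0] >= 0) & (xy[:, 0] <= window.width)
              & (xy[:, 1] >= 0) & (xy[:, 1] <= window.height))
    xy = xy[inside]
    roi = RegionOfInterest(area_mm2=window.area_mm2)
    return PointPattern(
        _cells_frame(xy, phenotype, tissue_category, "t"), roi,
        patient_id=f"thomas_{seed}")


@dataclass
class CancerIslands:
    """Union-of-discs island geometry plus the cancer cells sampled on it."""

    centers: np.ndarray      # (k, 2) μm
    radii: np.ndarray        # (k,) μm
    cells: pd.DataFrame      # cancer cells on the discs

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean disc-containment mask for an (n, 2) coordinate array."""
        xy = np.atleast_2d(xy)
        if len(self.centers) == 0:
            return np.zeros(len(xy), dtype=bool)
        d2 = ((xy[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return (d2 <= (self.radii ** 2)[None, :]).any(axis=1)

    def signed_distance_to_boundary(self, xy: np.ndarray) -> np.ndarray:
        """Distance to the nearest disc boundary (negative inside)."""
        xy = np.atleast_2d(xy)
        d = np.sqrt(((xy[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2))
        return (d - self.radii[None, :]).min(axis=1)

    @property
    def area_mm2(self) -> float:
        # Discs are placed non-overlapping, so areas add.
        return float((math.pi * self.radii ** 2).sum() / 1e6)


def make_cancer_islands(count: int,
                        radius_mean: float,
                        window: Window = DEFAULT_WINDOW,
                        seed: int = 0,
                        cancer_intensity: float = 2000.0,
                        radius_cv: float = 0.2) -> CancerIslands:
    """Place ``count`` non-overlapping discs inside the window and sample
    cancer cells on them at ``cancer_intensity`` per mm² of island area.

    Disc radii are truncated-normal around ``radius_mean`` with coefficient
    of variation ``radius_cv``.  Placement is dart-throwing with rejection;
    if the window cannot hold the requested discs a ValueError is raised.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(seed)
    centers, radii = [], []
    attempts = 0
    while len(centers) < count:
        if attempts > 1000 * max(count, 1):
            raise ValueError(
                f"could not place {count} non-overlapping discs of radius "
                f"~{radius_mean} in a {window.width}x{window.height} window")
        attempts += 1
        r = abs(rng.normal(radius_mean, radius_cv * radius_mean))
        r = max(r, 0.2 * radius_mean)
        if 2 * r >= min(window.width, window.height):
            continue
        cx = rng.uniform(r, window.width - r)
        cy = rng.uniform(r, window.height - r)
        ok = all((cx - ox) ** 2 + (cy - oy) ** 2 > (r + orr) ** 2
                 for (ox, oy), orr in zip(centers, radii))
        if ok:
            centers.append((cx, cy))
            radii.append(r)
    centers_arr = np.asarray(centers, dtype=float).reshape(-1, 2)
    radii_arr = np.asarray(radii, dtype=float)

    pieces = []
    for (cx, cy), r in zip(centers_arr, radii_arr):
        n = rng.poisson(cancer_intensity * math.pi * r * r / 1e6)
        theta = rng.uniform(0, 2 * math.pi, n)
        rad = r * np.sqrt(rng.uniform(0, 1, n))
        pieces.append(np.column_stack(
            [cx + rad * np.cos(theta), cy + rad * np.sin(theta)]))
    xy = np.concatenate(pieces) if pieces else np.empty((0, 2))
    cells = _cells_frame(xy, "cancer", "cancer_island", "k")
    return CancerIslands(centers=centers_arr, radii=radii_arr, cells=cells)


def _assign_phenotypes(rng: np.random.Generator, n: int,
                       b_fraction: float) -> np.ndarray:
    """B with probability b_fraction, else a T-lineage subtype."""
    out = np.empty(n, dtype=object)
    is_b = rng.uniform(size=n) < b_fraction
    out[is_b] = "B"
    n_t = int((~is_b).sum())
    subtypes = [name for name, _ in T_SUBTYPE_SPLIT]
    probs = [p for _, p in T_SUBTYPE_SPLIT]
    out[~is_b] = rng.choice(subtypes, size=n_t, p=probs)
    return out


def synthesize_patient(profile: OutcomeProfile,
                       window: Window = DEFAULT_WINDOW,
                       seed: int = 0,
                       patient_id: str | None = None,
                       outcome: str = "unlabeled") -> PointPattern:
    """Compose one patient pattern from a profile.

    Cancer cells sit on islands; lymphocytes arise from three components —
    a dispersed Poisson field over the whole window, island infiltrators on
    the discs, and a Thomas-type clustered component whose parents are
    placed ``lc_island_offset`` (mean) outside the nearest island boundary.
    Tissue category is assigned by disc containment; the ROI is the window.
    """
    rng = np.random.default_rng(seed)
    islands = make_cancer_islands(
        profile.island_count, profile.island_radius_mean, window,
        seed=rng.integers(2 ** 31))

    lymph_pieces: list[np.ndarray] = []

    # Dispersed Poisson component over the whole window.
    n_disp = rng.poisson(profile.lymphocyte_intensity * window.area_mm2)
    if n_disp:
        lymph_pieces.append(
            rng.uniform((0, 0), (window.width, window.height), size=(n_disp, 2)))

    # Island infiltrators, per mm² of island area.
    if len(islands.centers) and profile.island_infiltration_rate > 0:
        for (cx, cy), r in zip(islands.centers, islands.radii):
            k = rng.poisson(
                profile.island_infiltration_rate * math.pi * r * r / 1e6)
            if k:
                theta = rng.uniform(0, 2 * math.pi, k)
                rad = r * np.sqrt(rng.uniform(0, 1, k))
                lymph_pieces.append(np.column_stack(
                    [cx + rad * np.cos(theta), cy + rad * np.sin(theta)]))

    # Clustered component: parents offset from island boundaries.
    n_parents = rng.poisson(profile.cluster_parent_intensity * window.area_mm2)
    parents = []
    for _ in range(n_parents):
        if len(islands.centers):
            j = rng.integers(len(islands.centers))
            cx, cy = islands.centers[j]
            r = islands.radii[j]
            offset = max(10.0, rng.normal(profile.lc_island_offset,
                                          0.25 * max(profile.lc_island_offset, 1.0)))
            theta = rng.uniform(0, 2 * math.pi)
            px = cx + (r + offset) * math.cos(theta)
            py = cy + (r + offset) * math.sin(theta)
        else:
            px = rng.uniform(0, window.width)
            py = rng.uniform(0, window.height)
        if 0 <= px <= window.width and 0 <= py <= window.height:
            parents.append((px, py))
    for px, py in parents:
        k = rng.poisson(profile.mean_cluster_size)
        if k:
            lymph_pieces.append(
                rng.normal((px, py), profile.cluster_dispersion_sigma,
                           size=(k, 2)))

    lxy = np.concatenate(lymph_pieces) if lymph_pieces else np.empty((0, 2))
    inside = ((lxy[:, 0] >= 0) & (lxy[:, 0] <= window.width)
              & (lxy[:, 1] >= 0) & (lxy[:, 1] <= window.height))
    lxy = lxy[inside]
    phenos = _assign_phenotypes(rng, len(lxy), profile.b_fraction)
    in_island = islands.contains(lxy) if len(lxy) else np.zeros(0, dtype=bool)
    tissues = np.where(in_island, "cancer_island", "stroma")

    lymph = _cells_frame(lxy, phenos, tissues, "l")
    cells = pd.concat([islands.cells, lymph], ignore_index=True)
    roi = RegionOfInterest(area_mm2=window.area_mm2)
    return PointPattern(cells, roi,
                        patient_id=patient_id or f"synthetic_{seed}",
                        outcome=outcome)


def synthesize_cohort(n_good: int = 24,
                      n_poor: int = 12,
                      profiles: tuple[OutcomeProfile, OutcomeProfile] | None = None,
                      window: Window = DEFAULT_WINDOW,
                      seed: int = 0,
                      ) -> tuple[list[PointPattern], pd.DataFrame]:
    """Generate a labeled cohort plus a synthetic relapse-free-survival table.

    Poor patients relapse within 3 years (6–36 months, event = 1); good
    patients are event-free for at least 5 years (censored at 60–120
    months, event = 0), matching the outcome definitions.  Per-patient
    sub-seeds are spawned from ``(seed, index)`` so each patient's pattern
    is independent of cohort ordering.
    """
    if n_good < 0 or n_poor < 0:
        raise ValueError("cohort sizes must be >= 0")
    good_profile, poor_profile = profiles or (GOOD_PROFILE, POOR_PROFILE)
    patterns: list[PointPattern] = []
    rows = []
    for idx in range(n_good + n_poor):
        outcome = "good" if idx < n_good else "poor"
        profile = good_profile if outcome == "good" else poor_profile
        sub = np.random.SeedSequence(entropy=(int(seed), idx))
        child_rng = np.random.default_rng(sub)
        pat_seed = int(child_rng.integers(2 ** 31))
        pid = f"{outcome}_{idx:03d}"
        patterns.append(synthesize_patient(
            profile, window, seed=pat_seed, patient_id=pid, outcome=outcome))
        if outcome == "poor":
            t = float(child_rng.uniform(6.0, 36.0))
            event = 1
        else:
            t = float(child_rng.uniform(60.0, 120.0))
            event = 0
        rows.append((pid, outcome, t, event))
    rfs = pd.DataFrame(rows, columns=["patient_id", "outcome",
                                      "rfs_months", "event"])
    return patterns, rfs


def expected_poisson_occupancy(intensity: float, L: float) -> float:
    """Closed-form occupancy of a homogeneous Poisson process.

    The chance that a square of side L (μm) holds at least one point is
    1 − exp(−λ L²) with λ the intensity converted to points/μm².
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if not L > 0:
        raise ValueError("L must be > 0")
    lam_per_um2 = intensity / 1e6
    return 1.0 - math.exp(-lam_per_um2 * L * L)
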
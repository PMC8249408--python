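"""Region-resolved densities, membership fractions, and LC–island distances.

Densities always use the full region-of-interest area as denominator — the
pathologist's outline — never the island or stromal area alone, so densities
over disjoint tissue scopes add exactly to the overall density.  The
distance from a lymphocyte cluster to cancer tissue is the minimum Euclidean
distance between any cluster member and any cancer-phenotype cell carrying
the cancer-island tissue mark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .clusters import LymphocyteCluster, membership_by_cell
from .io import LYMPHOCYTE_PHENOTYPES, PointPattern

__all__ = [
    "DensityResult",
    "ClusterDistance",
    "region_density",
    "membership_fractions",
    "cluster_island_distance",
    "cluster_island_distances",
    "size_distance_correlation",
]


@dataclass(frozen=True)
class DensityResult:
    phenotype_set: frozenset[str]
    tissue_scope: str
    membership_scope: str
    count: int
    density: float  # cells per mm² of ROI


@dataclass(frozen=True)
class ClusterDistance:
    cluster_id: int
    distance_um: float


def region_density(pattern: PointPattern,
                   phenotype_set: Iterable[str],
                   tissue_scope: str = "any",
                   membership_scope: str = "any",
                   membership: dict | None = None) -> DensityResult:
    """Count cells matching phenotype/tissue/membership filters per mm² of ROI."""
    if not pattern.roi.area_mm2 > 0:
        raise ValueError("ROI area must be positive")
    phenotype_set = frozenset(phenotype_set)
    mask = pattern.phenotype_mask(phenotype_set)
    mask &= pattern.tissue_mask(tissue_scope)
    if membership_scope != "any":
        if membership is None:
            raise ValueError("membership scope requires cluster membership map")
        mem = pattern.cells["cell_id"].map(membership)
        if membership_scope == "isolated_only":
            mask &= (mem == "isolated").to_numpy()
        elif membership_scope == "in_lc_only":
            mask &= mem.isin(["pure_T", "heterotypic", "pure_B"]).to_numpy()
        elif membership_scope == "in_heterotypic_lc":
            mask &= (mem == "heterotypic").to_numpy()
        elif membership_scope == "in_pure_t_lc":
            mask &= (mem == "pure_T").to_numpy()
        else:
            raise ValueError(f"unknown membership scope {membership_scope!r}")
    count = int(mask.sum())
    return DensityResult(phenotype_set, tissue_scope, membership_scope,
                         count, count / pattern.roi.area_mm2)


def membership_fractions(pattern: PointPattern,
                         clusters: list[LymphocyteCluster],
                         isolated: set[str]) -> dict[str, dict[str, float | None]]:
    """Fractions of lymphocytes that are isolated / in an LC / in a TLS.

    Keyed by scope: "all", each tissue category, and each lymphocyte
    phenotype group ("B", "T").  Scopes with zero lymphocytes report None
    for every fraction (undefined, never silently zero).  Within a scope,
    isolated + in_lc = 1 and in_tls <= in_lc.
    """
    df = pattern.cells
    lmask = pattern.lymphocyte_mask
    mem = membership_by_cell(pattern, clusters, isolated)
    tls_ids = {cid for cl in clusters if cl.is_tls for cid in cl.members}

    in_lc = df["cell_id"].map(
        lambda c: mem.get(c, "isolated") != "isolated").to_numpy()
    in_tls = df["cell_id"].isin(tls_ids).to_numpy()

    scopes = {
        "all": lmask,
        "cancer_island": lmask & pattern.tissue_mask("cancer_island"),
        "stroma": lmask & pattern.tissue_mask("stroma"),
        "B": lmask & pattern.phenotype_mask({"B"}),
        "T": lmask & pattern.phenotype_mask(
            LYMPHOCYTE_PHENOTYPES - {"B"}),
    }
    out: dict[str, dict[str, float | None]] = {}
    for name, smask in scopes.items():
        total = int(smask.sum())
        if total == 0:
            out[name] = {"isolated": None, "in_lc": None, "in_tls": None}
            continue
        frac_lc = float((smask & in_lc).sum() / total)
        out[name] = {
            "isolated": 1.0 - frac_lc,
            "in_lc": frac_lc,
            "in_tls": float((smask & in_tls).sum() / total),
        }
    return out


def _cancer_island_coords(pattern: PointPattern) -> np.ndarray:
    mask = (pattern.phenotype_mask({"cancer"})
            & pattern.tissue_mask("cancer_island"))
    return pattern.coords[mask]


def cluster_island_distance(cluster: LymphocyteCluster,
                            pattern: PointPattern,
                            _tree: cKDTree | None = None,
                            ) -> ClusterDistance | None:
    """Shortest distance from any cluster member to any cancer-island cell.

    Exact minimum over all (member, cancer cell) pairs, evaluated through a
    k-d tree over the cancer cells (the tree returns exact nearest
    neighbours).  Returns None with a warning when the pattern has no cancer
    cells.
    """
    if _tree is None:
        targets = _cancer_island_coords(pattern)
        if len(targets) == 0:
            warnings.warn(f"pattern {pattern.patient_id}: no cancer cells; "
                          "cluster-island distance undefined", stacklevel=2)
            return None
        _tree = cKDTree(targets)
    idx = pattern.cells.set_index("cell_id")
    members_xy = idx.loc[cluster.members, ["x", "y"]].to_numpy(dtype=float)
    dists, _ = _tree.query(members_xy, k=1)
    return ClusterDistance(cluster.cluster_id, float(np.min(dists)))


def cluster_island_distances(clusters: Sequence[LymphocyteCluster],
                             pattern: PointPattern,
                             ) -> list[ClusterDistance | None]:
    """Vectorised :func:`cluster_island_distance` over many clusters."""
    targets = _cancer_island_coords(pattern)
    if len(targets) == 0:
        if clusters:
            warnings.warn(f"pattern {pattern.patient_id}: no cancer cells; "
                          "cluster-island distances undefined", stacklevel=2)
        return [None] * len(clusters)
    tree = cKDTree(targets)
    return [cluster_island_distance(cl, pattern, _tree=tree)
            for cl in clusters]


def size_distance_correlation(per_patient: Sequence[tuple[float, float]],
                              ) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-patient mean LC size and mean
    LC-island distance."""
    if len(per_patient) < 3:
        raise ValueError("need at least 3 patients for a correlation")
    arr = np.asarray(per_patient, dtype=float)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p)
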
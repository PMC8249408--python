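"""Lymphocyte-cluster detection, typing, TLS flags, and size distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilspatial.clusters import (ClusterParams, EmptyDistributionError,
                                 LymphocyteCluster, classify_cluster,
                                 composition_proportions, detect_clusters,
                                 detect_tls, membership_by_cell,
                                 size_distribution)
from conftest import make_pattern, random_lymphocyte_pattern


def brute_force_dbscan(xy, eps=20.0, min_pts=5):
    """Independent density-connectivity oracle: neighborhood graph over core
    points plus transitive closure; border points join their first core
    neighbor in input order.  Returns labels (-1 = noise)."""
    n = len(xy)
    d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    neighbors = d <= eps
    core = neighbors.sum(1) >= min_pts  # self-inclusive
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack, labels[i] = [i], cluster
        while stack:
            j = stack.pop()
            for k in np.where(neighbors[j])[0]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels, core


class TestDetectClusters:
    def test_five_collinear_cells_form_one_cluster(self, collinear_lymphocytes):
        clusters, isolated = detect_clusters(collinear_lymphocytes)
        assert len(clusters) == 1
        assert clusters[0].size_s == 5
        assert not isolated

    def test_four_close_cells_stay_isolated(self):
        pat = make_pattern([(0, 0, "T", "stroma"), (10, 0, "T", "stroma"),
                            (0, 10, "T", "stroma"), (10, 10, "T", "stroma")])
        clusters, isolated = detect_clusters(pat)
        assert clusters == [] and len(isolated) == 4

    def test_widely_spaced_cells_never_cluster(self):
        rng = np.random.default_rng(0)
        # jittered 100-point lattice with nearest-neighbor spacing > 20 um
        base = np.stack(np.meshgrid(np.arange(10) * 60.0,
                                    np.arange(10) * 60.0), -1).reshape(-1, 2)
        xy = base + rng.uniform(-5, 5, base.shape)
        pat = make_pattern([(x, y, "T", "stroma") for x, y in xy])
        clusters, isolated = detect_clusters(pat)
        assert clusters == [] and len(isolated) == 100

    def test_clustering_ignores_non_lymphocytes(self):
        rows = [(10.0 * i, 0.0, "cancer", "cancer_island") for i in range(5)]
        clusters, isolated = detect_clusters(make_pattern(rows))
        assert clusters == [] and isolated == set()

    def test_partition_covers_all_lymphocytes(self):
        rng = np.random.default_rng(42)
        pat = random_lymphocyte_pattern(rng, 150)
        clusters, isolated = detect_clusters(pat)
        member_ids = [cid for cl in clusters for cid in cl.members]
        assert len(member_ids) == len(set(member_ids))  # no overlaps
        assert set(member_ids) | isolated == set(pat.cells["cell_id"])
        assert not (set(member_ids) & isolated)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_density_connectivity(self, seed):
        rng = np.random.default_rng(seed)
        pat = random_lymphocyte_pattern(rng, 150, extent=300.0)
        clusters, isolated = detect_clusters(pat)
        labels, core = brute_force_dbscan(pat.coords)
        # core-point partition must agree exactly (border ties may differ
        # between implementations; ours pins them to input order)
        ids = pat.cells["cell_id"].to_numpy()
        ours = {}
        for ci, cl in enumerate(clusters):
            for cid in cl.members:
                ours[cid] = ci
        mapping = {}
        for i in np.where(core)[0]:
            cid = ids[i]
            assert cid in ours, "core point missing from detected clusters"
            key = labels[i]
            mapping.setdefault(key, ours[cid])
            assert mapping[key] == ours[cid]
        assert len(set(mapping.values())) == len(mapping)  # bijection
        assert len(clusters) == len(mapping)
        # noise agrees exactly: a point is isolated iff not density-reachable
        assert isolated == set(ids[labels == -1])


class TestClassify:
    @pytest.mark.parametrize("comp,expected", [
        ({"T": 5}, "pure_T"),
        ({"T_CD8": 2, "T_helper": 2, "Treg": 1}, "pure_T"),
        ({"B": 5}, "pure_B"),
        ({"B": 3, "T": 7}, "heterotypic"),
    ])
    def test_typing_by_composition(self, comp, expected):
        cl = LymphocyteCluster(0, [f"m{i}" for i in range(sum(comp.values()))],
                               comp, (0.0, 0.0))
        assert classify_cluster(cl) == expected

    def test_proportions_sum_to_one(self):
        cl = LymphocyteCluster(0, [f"m{i}" for i in range(10)],
                               {"B": 3, "T": 7}, (0.0, 0.0))
        props = cl.lymphocyte_proportions()
        assert props["B"] == pytest.approx(0.3)
        assert sum(props.values()) == pytest.approx(1.0)


def _disc_pattern(n, radius, center=(500.0, 500.0), phenotype="T", seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * math.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    rows = [(center[0] + ri * math.cos(t), center[1] + ri * math.sin(t),
             phenotype, "stroma") for ri, t in zip(r, theta)]
    return make_pattern(rows)


class TestTLS:
    def test_dense_disc_of_200_is_tls(self):
        pat = _disc_pattern(200, radius=60.0)
        clusters, _ = detect_clusters(pat)
        flagged = detect_tls(pat, clusters)
        assert len(flagged) == 1 and flagged[0].is_tls

    def test_199_in_disc_is_not_tls(self):
        pat = _disc_pattern(199, radius=60.0)
        clusters, _ = detect_clusters(pat)
        assert detect_tls(pat, clusters) == []

    def test_spread_out_200_is_not_tls(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1000.0, size=(200, 2))
        pat = make_pattern([(x, y, "T", "stroma") for x, y in xy])
        clusters, _ = detect_clusters(pat)
        assert detect_tls(pat, clusters) == []

    def test_sliding_circle_oracle_agrees(self):
        # exhaustive check: center a 70 um circle on every member
        for n, radius, expect in ((200, 60.0, True), (250, 140.0, False)):
            pat = _disc_pattern(n, radius=radius, seed=4)
            clusters, _ = detect_clusters(pat)
            detect_tls(pat, clusters)
            got = any(cl.is_tls for cl in clusters)
            xy = pat.coords
            d2 = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
            oracle = bool(((d2 <= 70.0 ** 2).sum(1) >= 200).any())
            assert got == oracle == expect

    def test_tls_flag_never_changes_membership(self):
        pat = _disc_pattern(220, radius=60.0)
        clusters, isolated = detect_clusters(pat)
        before = [list(cl.members) for cl in clusters]
        detect_tls(pat, clusters)
        assert [list(cl.members) for cl in clusters] == before
        tls_members = {cid for cl in clusters if cl.is_tls
                       for cid in cl.members}
        lc_members = {cid for cl in clusters for cid in cl.members}
        assert tls_members <= lc_members


def _mk_cluster(cid, size, lc_type):
    comp = ({"T": size} if lc_type == "pure_T" else
            {"B": max(1, size // 3), "T": size - max(1, size // 3)})
    cl = LymphocyteCluster(cid, [f"x{cid}_{i}" for i in range(size)],
                           comp, (0.0, 0.0))
    cl.lc_type = lc_type
    return cl


class TestSizeDistribution:
    def test_hand_computed_distribution(self):
        clusters = [_mk_cluster(0, 5, "heterotypic"),
                    _mk_cluster(1, 5, "heterotypic"),
                    _mk_cluster(2, 10, "heterotypic")]
        dist = size_distribution(clusters, "heterotypic", "good")
        assert dist.total_N == 20
        assert dist.counts_P == {5: 2, 10: 1}
        assert dist.normalized[5] == pytest.approx(0.1)
        assert dist.check_normalization() == pytest.approx(1.0, abs=1e-15)
        assert dist.cumulative_f[5] == pytest.approx(0.5)
        assert dist.cumulative_f[10] == pytest.approx(1.0)

    def test_tabular_export_mirrors_distribution(self, tmp_path):
        clusters = [_mk_cluster(0, 5, "heterotypic"),
                    _mk_cluster(1, 10, "heterotypic")]
        dist = size_distribution(clusters, "heterotypic")
        dist.to_tsv(tmp_path / "dist.tsv")
        import pandas as pd
        frame = pd.read_csv(tmp_path / "dist.tsv", sep="\t")
        assert list(frame.columns) == ["s", "P", "P_over_N", "f"]
        assert frame["f"].iloc[-1] == pytest.approx(1.0)

    def test_single_cluster_distribution(self):
        dist = size_distribution([_mk_cluster(0, 5, "pure_T")], "pure_T")
        assert dist.normalized == {5: pytest.approx(0.2)}
        assert dist.cumulative_f[5] == pytest.approx(1.0)

    def test_empty_type_raises(self):
        with pytest.raises(EmptyDistributionError):
            size_distribution([_mk_cluster(0, 5, "pure_T")], "heterotypic")

    def test_pure_b_not_a_distribution_type(self):
        with pytest.raises(ValueError):
            size_distribution([], "pure_B")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=5, max_value=400),
                    min_size=1, max_size=60))
    def test_normalization_identity_for_any_sizes(self, sizes):
        clusters = [_mk_cluster(i, s, "heterotypic")
                    for i, s in enumerate(sizes)]
        dist = size_distribution(clusters, "heterotypic")
        assert dist.check_normalization() == pytest.approx(1.0, abs=1e-12)
        f = list(dist.cumulative_f.values())
        assert all(b >= a - 1e-12 for a, b in zip(f, f[1:]))
        assert f[-1] == pytest.approx(1.0, abs=1e-12)


class TestComposition:
    def test_single_cluster_proportions(self):
        props = composition_proportions([_mk_cluster(0, 10, "heterotypic")],
                                        "heterotypic")
        assert props["B"] == pytest.approx(0.3)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_mean_over_clusters_unweighted(self):
        a = LymphocyteCluster(0, [f"a{i}" for i in range(10)],
                              {"B": 2, "T": 8}, (0, 0))
        b = LymphocyteCluster(1, [f"b{i}" for i in range(100)],
                              {"B": 40, "T": 60}, (0, 0))
        a.lc_type = b.lc_type = "heterotypic"
        props = composition_proportions([a, b], "heterotypic")
        assert props["B"] == pytest.approx(0.3)  # (0.2 + 0.4) / 2, sizes ignored


class TestMembershipMap:
    def test_every_lymphocyte_mapped_once(self):
        rng = np.random.default_rng(9)
        pat = random_lymphocyte_pattern(rng, 120)
        clusters, isolated = detect_clusters(pat)
        mem = membership_by_cell(pat, clusters, isolated)
        assert set(mem) == set(pat.cells["cell_id"])
        assert set(mem.values()) <= {"isolated", "pure_T", "heterotypic",
                                     "pure_B"}
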
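"""Correlation networks: correlation, binarization, selection, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaconn.network import (
    CorrMatrix,
    ThresholdSelectionError,
    binarize,
    connectivity_report,
    correlation_matrix,
    default_grid,
    interhemispheric_matrix,
    partition_edges,
    select_threshold,
    threshold_sweep,
)
from metaconn.simulate import CovarianceProfile, generate_group, make_default_cohort
from metaconn.suvr import SuvrDataset

from conftest import random_dataset
from oracles import (
    connected_nodes_brute,
    correlation_matrix_brute,
    count_edges_brute,
    make_toy_atlas,
    partition_brute,
    select_threshold_brute,
)


def toy_dataset(toy_atlas, n_subjects, rng, label="T"):
    values = rng.uniform(0.5, 2.0, size=(n_subjects, len(toy_atlas)))
    return SuvrDataset(
        group_label=label,
        subject_ids=[f"{label}{i}" for i in range(n_subjects)],
        region_names=list(toy_atlas.names),
        values=values,
    )


def full_corr(values, label="T"):
    n = values.shape[0]
    names = [f"Toy{k}_{s}" for k in range(n // 2) for s in ("L", "R")][:n]
    return CorrMatrix("FULL", label, names, names, values, n_subjects=10)


def symmetric_random_corr(n, rng):
    a = rng.uniform(-1, 1, size=(n, n))
    c = (a + a.T) / 2
    np.fill_diagonal(c, 1.0)
    return c


class TestCorrelationMatrix:
    def test_perfect_linear_dependence(self, atlas, rng):
        ds = random_dataset(atlas, 30, rng)
        ds.values[:, 1] = 2.0 * ds.values[:, 0]
        c = correlation_matrix(ds)
        assert c.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self, atlas, rng):
        ds = random_dataset(atlas, 30, rng)
        ds.values[:, 2] = 5.0 - ds.values[:, 0]
        c = correlation_matrix(ds)
        assert c.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force(self, atlas, rng):
        ds = random_dataset(atlas, 50, rng)
        c = correlation_matrix(ds)
        np.testing.assert_allclose(
            c.values, correlation_matrix_brute(ds.values), atol=1e-12
        )

    def test_symmetric_unit_diagonal(self, atlas, rng):
        c = correlation_matrix(random_dataset(atlas, 12, rng))
        np.testing.assert_array_equal(c.values, c.values.T)
        np.testing.assert_array_equal(np.diag(c.values), np.ones(90))

    def test_zero_variance_region_named(self, atlas, rng):
        ds = random_dataset(atlas, 10, rng)
        ds.values[:, 3] = 1.0
        with pytest.raises(ValueError, match=atlas.names[3]):
            correlation_matrix(ds)

    def test_too_few_subjects(self, atlas, rng):
        with pytest.raises(ValueError, match="at least 3"):
            correlation_matrix(random_dataset(atlas, 2, rng))

    def test_subject_relabeling_leaves_matrix_unchanged(self, atlas, rng):
        ds = random_dataset(atlas, 25, rng)
        perm = rng.permutation(25)
        shuffled = SuvrDataset(
            ds.group_label,
            [ds.subject_ids[i] for i in perm],
            list(ds.region_names),
            ds.values[perm],
        )
        np.testing.assert_allclose(
            correlation_matrix(ds).values,
            correlation_matrix(shuffled).values,
            atol=1e-12,
        )


class TestInterhemisphericMatrix:
    def test_entries_match_full_matrix(self, atlas, rng):
        ds = random_dataset(atlas, 40, rng)
        full = correlation_matrix(ds)
        inter = interhemispheric_matrix(ds, atlas)
        i = full.row_regions.index("Cuneus_L")
        j = full.col_regions.index("Cuneus_R")
        k = inter.row_regions.index("Cuneus_L")
        l = inter.col_regions.index("Cuneus_R")
        assert inter.values[k, l] == full.values[i, j]
        assert inter.values.shape == (45, 45)
        # homologues sit on the diagonal
        assert k == l

    def test_independent_hemispheres_give_small_entries(self, atlas):
        profile = CovarianceProfile(
            "NULL", 5000, homologue_r=0.0, base_within_lobe_r=0.0,
            cross_block_r=0.0, attenuation=0.0,
        )
        ds = generate_group(profile, atlas, seed=21)
        inter = interhemispheric_matrix(ds, atlas)
        assert np.abs(inter.values).max() < 0.05


class TestBinarize:
    def test_identity_matrix_no_edges(self, rng):
        c = full_corr(np.eye(8))
        net = binarize(c, 0.5)
        assert net.n_edges == 0
        assert net.n_connected_nodes == 0

    def test_complete_graph_at_90(self, atlas, rng):
        vals = np.full((90, 90), 0.9)
        np.fill_diagonal(vals, 1.0)
        c = CorrMatrix("FULL", "G", atlas.names, atlas.names, vals, 10)
        net = binarize(c, 0.78)
        assert net.n_edges == 90 * 89 // 2 == 4005
        assert net.n_connected_nodes == 90

    def test_edge_count_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11)) * 2
            c = symmetric_random_corr(n, rng)
            tau = float(rng.uniform(0.05, 0.95))
            net = binarize(full_corr(c), tau)
            assert net.n_edges == count_edges_brute(c, tau)
            assert net.n_connected_nodes == connected_nodes_brute(c, tau)

    def test_tie_is_an_edge(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.78
        net = binarize(full_corr(c), 0.78)
        assert net.n_edges == 1  # r == tau counts as a link

    def test_interhemi_counts_all_cells(self, rng):
        vals = rng.uniform(-1, 1, size=(5, 5))
        names_l = [f"Toy{k}_L" for k in range(5)]
        names_r = [f"Toy{k}_R" for k in range(5)]
        c = CorrMatrix("INTERHEMI", "G", names_l, names_r, vals, 10)
        net = binarize(c, 0.3)
        assert net.n_edges == int((vals >= 0.3).sum())  # diagonal included

    def test_negative_correlations_never_edges(self, rng):
        c = -np.abs(symmetric_random_corr(10, rng))
        np.fill_diagonal(c, 1.0)
        assert binarize(full_corr(c), 0.5).n_edges == 0

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            binarize(full_corr(np.eye(4)), 1.5)


class TestThresholdSweep:
    def test_default_grid_has_21_values(self):
        grid = default_grid()
        assert len(grid) == 21
        assert grid[0] == pytest.approx(0.50)
        assert grid[-1] == pytest.approx(0.90)
        np.testing.assert_allclose(np.diff(grid), 0.02)

    def test_sweep_yields_one_network_per_grid_value(self, rng):
        nets = threshold_sweep(full_corr(symmetric_random_corr(12, rng)))
        assert len(nets) == 21

    def test_monotone_in_threshold(self, rng):
        for _ in range(10):
            nets = threshold_sweep(full_corr(symmetric_random_corr(16, rng)))
            edges = [n.n_edges for n in nets]
            nodes = [n.n_connected_nodes for n in nets]
            assert edges == sorted(edges, reverse=True)
            assert nodes == sorted(nodes, reverse=True)

    def test_singleton_grid_equals_binarize(self, rng):
        c = full_corr(symmetric_random_corr(8, rng))
        (net,) = threshold_sweep(c, [0.9])
        ref = binarize(c, 0.9)
        np.testing.assert_array_equal(net.adjacency, ref.adjacency)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(full_corr(np.eye(4)), [])

    def test_non_increasing_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            threshold_sweep(full_corr(np.eye(4)), [0.5, 0.5])


class TestSelectThreshold:
    def test_uniform_offdiagonal(self):
        vals = np.full((90, 90), 0.85)
        np.fill_diagonal(vals, 1.0)
        names = [f"Toy{k}_{s}" for k in range(45) for s in ("L", "R")]
        c = CorrMatrix("FULL", "NC", names, names, vals, 10)
        assert select_threshold(c) == pytest.approx(0.84)

    def test_bottleneck_node_governs(self):
        vals = np.full((90, 90), 0.85)
        vals[0, :] = vals[:, 0] = 0.55  # node 0's best link is 0.55
        np.fill_diagonal(vals, 1.0)
        names = [f"Toy{k}_{s}" for k in range(45) for s in ("L", "R")]
        c = CorrMatrix("FULL", "NC", names, names, vals, 10)
        assert select_threshold(c) == pytest.approx(0.54)

    def test_matches_exhaustive_search_on_synthetic_nc(self, atlas):
        cohort = make_default_cohort(seed=1)
        c = correlation_matrix(cohort["NC"])
        expected = select_threshold_brute(c.values, default_grid())
        assert select_threshold(c) == pytest.approx(expected)

    def test_matches_exhaustive_search_on_random_matrices(self, rng):
        checked = 0
        for _ in range(30):
            a = rng.uniform(0.2, 0.95, size=(10, 10))
            c = (a + a.T) / 2
            np.fill_diagonal(c, 1.0)
            expected = select_threshold_brute(c, default_grid())
            cm = full_corr(c)
            if expected is None:
                with pytest.raises(ThresholdSelectionError):
                    select_threshold(cm)
            else:
                assert select_threshold(cm) == pytest.approx(expected)
                checked += 1
        assert checked > 0

    def test_smallest_rule(self):
        vals = np.full((4, 4), 0.85)
        np.fill_diagonal(vals, 1.0)
        c = full_corr(vals)
        assert select_threshold(c, rule="smallest") == pytest.approx(0.50)

    def test_no_coverage_reports_best(self):
        c = full_corr(np.eye(6))
        with pytest.raises(ThresholdSelectionError, match="0 nodes"):
            select_threshold(c)


class TestPartitionEdges:
    def test_homologue_edge_is_inter(self, atlas):
        vals = np.eye(90)
        i = atlas.names.index("Cuneus_L")
        j = atlas.names.index("Cuneus_R")
        vals[i, j] = vals[j, i] = 0.9
        c = CorrMatrix("FULL", "G", atlas.names, atlas.names, vals, 10)
        part = partition_edges(binarize(c, 0.5), atlas)
        assert (part.intra_left, part.intra_right, part.inter) == (0, 0, 1)
        assert part.lobe_pair_counts == {("OCCIPITAL", "OCCIPITAL"): 1}

    def test_complete_graph_counts(self, atlas):
        vals = np.full((90, 90), 0.9)
        np.fill_diagonal(vals, 1.0)
        c = CorrMatrix("FULL", "G", atlas.names, atlas.names, vals, 10)
        part = partition_edges(binarize(c, 0.78), atlas)
        assert part.inter == 45 * 45 == 2025
        assert part.intra_left == part.intra_right == 45 * 44 // 2 == 990
        assert part.total == 4005

    def test_matches_brute_force_on_toy_atlases(self, rng):
        for _ in range(20):
            toy = make_toy_atlas(int(rng.integers(2, 6)), rng)
            n = len(toy)
            c = symmetric_random_corr(n, rng)
            cm = CorrMatrix("FULL", "G", toy.names, toy.names, c, 10)
            net = binarize(cm, float(rng.uniform(0.1, 0.9)))
            part = partition_edges(net, toy)
            il, ir, inter, lobes = partition_brute(net.edge_list, toy)
            assert (part.intra_left, part.intra_right, part.inter) == (il, ir, inter)
            assert part.lobe_pair_counts == lobes
            assert part.intra_left + part.intra_right + part.inter == part.total
            assert sum(part.lobe_pair_counts.values()) == part.total


class TestConnectivityReport:
    def test_partition_identity_and_consistency(self, atlas):
        report = connectivity_report(make_default_cohort(seed=2), atlas)
        for g in report.group_order:
            part = report.partitions[g]
            assert part.intra_left + part.intra_right + part.inter == part.total
            assert sum(part.lobe_pair_counts.values()) == part.total
            # INTERHEMI suprathreshold cells == inter class of FULL partition
            assert report.interhemi_networks[g].n_edges == part.inter

    def test_identical_groups_identical_counts(self, atlas, rng):
        base = random_dataset(atlas, 60, rng, "NC")
        cohort = {
            g: SuvrDataset(g, list(base.subject_ids), list(base.region_names),
                           base.values.copy())
            for g in ("NC", "sMCI", "pMCI", "AD")
        }
        report = connectivity_report(cohort, atlas, tau=0.5)
        counts = {g: report.networks[g].n_edges for g in report.group_order}
        assert len(set(counts.values())) == 1

    def test_fixed_tau_respected(self, atlas):
        report = connectivity_report(make_default_cohort(seed=3), atlas, tau=0.8)
        assert report.threshold == 0.8
        assert report.tau_mode == "fixed"

    def test_summary_frame_schema(self, atlas):
        report = connectivity_report(make_default_cohort(seed=2), atlas)
        frame = report.summary_frame()
        assert list(frame["group"]) == ["NC", "sMCI", "pMCI", "AD"]
        assert (
            frame["intra_edges"] + frame["inter_edges"] == frame["total_edges"]
        ).all()

    def test_lobe_pair_tables(self, atlas):
        report = connectivity_report(make_default_cohort(seed=2), atlas)
        pairs = report.lobe_pair_frame()
        assert len(pairs) == 28  # 7 categories -> 7*8/2 unordered pairs
        ratios = report.lobe_pair_ratios()
        counts = pairs.set_index("lobe_pair")
        mask = counts["NC"] > 0
        np.testing.assert_allclose(
            ratios.loc[mask, "sMCI/NC"],
            counts.loc[mask, "sMCI"] / counts.loc[mask, "NC"],
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_region_permutation_equivariance(seed):
    """Permuting region columns (with matching labels) permutes the matrix."""
    rng = np.random.default_rng(seed)
    n = 10
    values = rng.uniform(0.5, 2.0, size=(12, n))
    names = [f"Toy{k}_{s}" for k in range(n // 2) for s in ("L", "R")]
    ds = SuvrDataset("G", [f"s{i}" for i in range(12)], names, values)
    base = correlation_matrix(ds).values
    perm = rng.permutation(n)
    ds2 = SuvrDataset(
        "G", list(ds.subject_ids), [names[i] for i in perm], values[:, perm]
    )
    permuted = correlation_matrix(ds2).values
    np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)
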
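"""Two-point estimation against a grid-search likelihood oracle, grouping,
SARF seriation against brute force, and map assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.io import CODE_A, CODE_B, CODE_H, GenotypeMatrix
from crossqtl.linkmap import (
    EstimationError,
    count_table,
    f2_joint_probs,
    order_group,
)


def grid_oracle(counts, step=1e-4):
    """Exhaustive grid search of the F2 two-point likelihood."""
    rs = np.arange(0.0, 0.5 + step / 2, step)
    c = 1.0 - rs
    ll = (
        (counts[2, 2] + counts[0, 0]) * np.log(np.clip(c * c / 4, 1e-300, None))
        + (counts[2, 0] + counts[0, 2]) * np.log(np.clip(rs * rs / 4, 1e-300, None))
        + (counts[2, 1] + counts[1, 2] + counts[1, 0] + counts[0, 1])
        * np.log(np.clip(rs * c / 2, 1e-300, None))
        + counts[1, 1] * np.log((c * c + rs * rs) / 2)
    )
    j = int(np.argmax(ll))
    lod = (ll[j] - ll[-1]) / np.log(10.0)
    return rs[j], max(lod, 0.0)


def calls_from_table(counts):
    """Expand a 9-cell count table into two call vectors."""
    a, b = [], []
    for ga in range(3):
        for gb in range(3):
            a.extend([ga] * counts[ga, gb])
            b.extend([gb] * counts[ga, gb])
    return np.array(a, dtype=np.int8), np.array(b, dtype=np.int8)


def test_joint_probs_rows_are_f2_marginals():
    p = f2_joint_probs(0.2)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert p.sum(axis=1) == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)


class TestEstimateRf:
    def test_complete_linkage(self):
        calls = np.array([CODE_A] * 5 + [CODE_H] * 10 + [CODE_B] * 5, dtype=np.int8)
        est = cq.estimate_rf(calls, calls)
        assert est.r_hat == pytest.approx(0.0, abs=1e-6)
        # LOD against the grid oracle (n_A log10 4 + n_H log10 2 + n_B log10 4)
        counts = count_table(calls, calls)
        r_o, lod_o = grid_oracle(counts)
        expected = 10 * np.log10(4.0) + 10 * np.log10(2.0)
        assert est.lod == pytest.approx(lod_o, abs=1e-3)
        assert est.lod == pytest.approx(expected, abs=1e-3)

    def test_independent_markers(self):
        rng = np.random.default_rng(8)
        a = rng.choice([0, 1, 2], size=200, p=[0.25, 0.5, 0.25]).astype(np.int8)
        b = rng.choice([0, 1, 2], size=200, p=[0.25, 0.5, 0.25]).astype(np.int8)
        est = cq.estimate_rf(a, b)
        assert abs(est.r_hat - 0.5) < 0.05
        assert est.lod < 1.0

    def test_fixed_table_matches_grid_oracle(self):
        counts = np.array([[30, 6, 1], [5, 60, 7], [2, 5, 28]])
        a, b = calls_from_table(counts)
        est = cq.estimate_rf(a, b)
        r_o, lod_o = grid_oracle(counts)
        assert est.r_hat == pytest.approx(r_o, abs=1e-4)
        assert est.lod == pytest.approx(lod_o, abs=1e-3)
        assert est.n_informative == counts.sum()

    def test_no_joint_calls_rejected(self):
        a = np.array([CODE_A, -1], dtype=np.int8)
        b = np.array([-1, CODE_B], dtype=np.int8)
        with pytest.raises(EstimationError):
            cq.estimate_rf(a, b)


def test_pairwise_em_matches_grid_oracle_on_random_tables(rng):
    """200 random 9-cell tables: EM r-hat within 1e-4 of the exhaustive
    grid oracle (and the bounded-optimiser path agrees)."""
    n_tables = 200
    pairs, tables = [], []
    for _ in range(n_tables):
        r = rng.uniform(0.0, 0.5)
        n = int(rng.integers(30, 200))
        p = f2_joint_probs(r).ravel()
        counts = rng.multinomial(n, p).reshape(3, 3)
        tables.append(counts)
        pairs.append(calls_from_table(counts))
    length = max(len(a) for a, _ in pairs)
    calls = np.full((length, 2 * n_tables), -1, dtype=np.int8)
    for k, (a, b) in enumerate(pairs):
        calls[: len(a), 2 * k] = a
        calls[: len(b), 2 * k + 1] = b
    g = GenotypeMatrix(
        [f"i{t}" for t in range(length)],
        pd.DataFrame(index=pd.Index([f"m{t}" for t in range(2 * n_tables)],
                                    name="marker")),
        calls,
    )
    r_hat, lod, n_inf = cq.pairwise_rf(g)
    worst = 0.0
    for k, counts in enumerate(tables):
        r_o, lod_o = grid_oracle(counts)
        worst = max(worst, abs(r_hat[2 * k, 2 * k + 1] - r_o))
        assert lod[2 * k, 2 * k + 1] == pytest.approx(lod_o, abs=2e-3)
        assert n_inf[2 * k, 2 * k + 1] == counts.sum()
    assert worst <= 1e-4
    # spot-check the single-pair optimiser agrees with the EM matrix
    a, b = pairs[0]
    est = cq.estimate_rf(a, b)
    assert est.r_hat == pytest.approx(r_hat[0, 1], abs=1e-4)


class TestGrouping:
    def _mats(self, lod_ab):
        names = ["a", "b"]
        r = np.array([[0.0, 0.1], [0.1, 0.0]])
        lod = np.array([[0.0, lod_ab], [lod_ab, 0.0]])
        return names, r, lod

    def test_threshold_inclusive(self):
        names, r, lod = self._mats(5.0)
        assert cq.group_markers(names, r, lod, lod_min=5.0) == [["a", "b"]]
        names, r, lod = self._mats(4.999)
        assert cq.group_markers(names, r, lod, lod_min=5.0) == [["a"], ["b"]]

    def test_r_max_also_required(self):
        names = ["a", "b"]
        r = np.array([[0.0, 0.46], [0.46, 0.0]])
        lod = np.array([[0.0, 9.0], [9.0, 0.0]])
        assert cq.group_markers(names, r, lod, r_max=0.45) == [["a"], ["b"]]

    def test_input_order_invariant(self):
        rng = np.random.default_rng(3)
        m = 12
        r = rng.uniform(0, 0.5, (m, m))
        lod = rng.uniform(0, 10, (m, m))
        r, lod = (r + r.T) / 2, (lod + lod.T) / 2
        names = [f"m{j}" for j in range(m)]
        base = cq.group_markers(names, r, lod)
        perm = rng.permutation(m)
        shuffled = cq.group_markers(
            [names[j] for j in perm], r[np.ix_(perm, perm)], lod[np.ix_(perm, perm)]
        )
        assert base == shuffled

    def test_recovers_three_chromosomes(self):
        cfg = cq.CrossConfig(
            n_individuals=200,
            chromosomes=[("c1", 60.0), ("c2", 60.0), ("c3", 60.0)],
            marker_spacing_cm=5.0, missing_rate=0.0, seed=6,
        )
        g, _, _ = cq.simulate_cross(cfg)
        r, lod, _ = cq.pairwise_rf(g)
        groups = cq.group_markers(g.marker_names, r, lod, lod_min=5.0, r_max=0.45)
        big = [gr for gr in groups if len(gr) > 1]
        assert len(big) == 3
        for gr in big:
            assert len({m.split("_")[0] for m in gr}) == 1

    def test_singleton_unplaced_by_mapper(self):
        cfg = cq.CrossConfig(
            n_individuals=150, chromosomes=[("c1", 40.0)],
            marker_spacing_cm=5.0, missing_rate=0.0, seed=6,
        )
        g, _, _ = cq.simulate_cross(cfg)
        # append an unlinked marker simulated independently
        rng = np.random.default_rng(1)
        iso = rng.choice([0, 1, 2], size=150, p=[0.25, 0.5, 0.25]).astype(np.int8)
        markers = pd.concat(
            [g.markers, pd.DataFrame(index=pd.Index(["isolated"], name="marker"))]
        )
        g2 = GenotypeMatrix(g.individuals, markers, np.hstack([g.calls, iso[:, None]]))
        res = cq.LinkageMapper(g2).fit()
        assert res.build_log.unplaced == ["isolated"]
        assert "isolated" not in res.map.table.index


class TestOrdering:
    def _name_index(self, names):
        return {m: j for j, m in enumerate(names)}

    def test_triangle(self):
        names = ["a", "b", "c"]
        r = np.array([[0, 0.05, 0.10], [0.05, 0, 0.05], [0.10, 0.05, 0]])
        lod = 10.0 - 10 * r
        order = order_group(names, r, lod, self._name_index(names))
        assert order == ["a", "b", "c"]  # canonical: first name < last name

    def test_matches_brute_force_on_small_groups(self, rng):
        for _ in range(25):
            m = int(rng.integers(4, 9))
            names = [f"m{j}" for j in range(m)]
            true_pos = np.sort(rng.uniform(0, 60, m))
            r_true = 0.5 * (1 - np.exp(-2 * np.abs(true_pos[:, None] - true_pos) / 100))
            noise = rng.normal(0, 0.01, (m, m))
            r = np.clip(r_true + (noise + noise.T) / 2, 0, 0.5)
            np.fill_diagonal(r, 0)
            lod = 12 * (0.5 - r)
            order = order_group(names, r, lod, self._name_index(names))
            idx = self._name_index(names)
            got = sum(r[idx[a], idx[b]] for a, b in zip(order, order[1:]))
            best = min(
                sum(r[idx[a], idx[b]] for a, b in zip(perm, perm[1:]))
                for perm in itertools.permutations(names)
            )
            assert got <= best + 1e-9

    def test_simulated_chromosome_recovered(self):
        hits = 0
        for seed in range(40):
            cfg = cq.CrossConfig(
                n_individuals=500, chromosomes=[("c1", 95.0)],
                marker_spacing_cm=5.0, missing_rate=0.0, seed=seed,
            )
            g, _, _ = cq.simulate_cross(cfg)
            r, lod, _ = cq.pairwise_rf(g)
            order = order_group(
                g.marker_names, r, lod, self._name_index(g.marker_names)
            )
            truth = g.marker_names
            hits += order == truth or order == truth[::-1]
        assert hits >= 38  # >= 95% of seeds


class TestBuildMap:
    def test_two_marker_positions(self):
        r = np.array([[0.0, 0.1], [0.1, 0.0]])
        gmap, _ = cq.build_map([["a", "b"]], r, {"a": 0, "b": 1})
        pos = gmap.table["cm"].tolist()
        assert pos[0] == 0.0
        assert pos[1] == pytest.approx(25 * np.log(1.2 / 0.8), abs=1e-9)

    def test_single_marker_group(self):
        r = np.zeros((1, 1))
        gmap, _ = cq.build_map([["solo"]], r, {"solo": 0})
        assert gmap.table.loc["solo", "cm"] == 0.0
        assert gmap.total_length_cm == 0.0

    def test_split_at_unlinked_junction(self):
        r = np.array(
            [[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        gmap, log = cq.build_map([["a", "b", "c"]], r, {"a": 0, "b": 1, "c": 2})
        assert gmap.n_groups == 2
        assert log.splits == [("b", "c")]

    def test_length_invariant_under_group_reversal(self):
        rng = np.random.default_rng(5)
        m = 10
        pos = np.sort(rng.uniform(0, 80, m))
        r = 0.5 * (1 - np.exp(-2 * np.abs(pos[:, None] - pos) / 100))
        names = [f"m{j}" for j in range(m)]
        idx = {n: j for j, n in enumerate(names)}
        fwd, _ = cq.build_map([names], r, idx)
        rev, _ = cq.build_map([names[::-1]], r, idx)
        assert fwd.total_length_cm == pytest.approx(rev.total_length_cm, abs=1e-9)


def test_haldane_map_length_recovery_n500():
    """Like-for-like recovery: Haldane simulation, Haldane estimation,
    n=500; total map length within 5% of the marker-covered length."""
    cfg = cq.CrossConfig(
        n_individuals=500,
        chromosomes=[("c1", 100.0), ("c2", 100.0), ("c3", 100.0)],
        marker_spacing_cm=2.5, missing_rate=0.1, seed=12,
    )
    g, _, truth = cq.simulate_cross(cfg)
    res = cq.LinkageMapper(g, map_function="haldane").fit()
    assert res.n_groups == 3
    covered = truth.true_map.total_length_cm
    assert abs(res.total_length_cm - covered) / covered < 0.05


def test_study_map_has_22_groups(study_map):
    assert study_map.n_groups == 22
    assert study_map.n_placed >= 830
    assert 0.9 < study_map.total_length_cm / 1933.0 < 1.1
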
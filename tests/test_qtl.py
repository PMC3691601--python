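"""QTL machinery: HMM genotype probabilities against an enumeration oracle,
Haley-Knott LOD against the normal equations, permutation thresholds,
stepwise search, credible intervals, PVE algebra and effect summaries."""

import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.gmap import GeneticMap
from crossqtl.io import CODE_A, CODE_B, CODE_H, MISSING, GenotypeMatrix
from crossqtl.qtl import GenoProbGrid, f2_transition


def _geno(calls, cms, lg="c1"):
    calls = np.array(calls, dtype=np.int8)
    names = [f"m{j}" for j in range(calls.shape[1])]
    markers = pd.DataFrame(
        {"lg": lg, "cm": cms}, index=pd.Index(names, name="marker")
    )
    g = GenotypeMatrix([f"i{k}" for k in range(calls.shape[0])], markers, calls)
    return g, GeneticMap(markers.copy())


class TestGenoProb:
    def test_called_states_dominate_with_concordant_flanks(self):
        g, gmap = _geno([[CODE_A, CODE_A, CODE_A]], [0.0, 10.0, 20.0])
        probs = cq.calc_genoprob(g, gmap, step_cm=0, error_rate=1e-4)
        assert np.all(probs.probs[0, :, 2] >= 0.999)

    def test_missing_midpoint_matches_enumeration_oracle(self):
        """Missing call midway between two A-homozygotes 20 cM apart:
        brute-force path enumeration over the 27 three-locus states."""
        g, gmap = _geno([[CODE_A, MISSING, CODE_A]], [0.0, 10.0, 20.0])
        eps = 1e-4
        probs = cq.calc_genoprob(g, gmap, step_cm=0, error_rate=eps)
        r = cq.kosambi_inv(10.0)
        T = f2_transition(r)
        prior = np.array([0.25, 0.5, 0.25])
        emit_A = np.array([eps / 2, eps / 2, 1 - eps])
        post = np.zeros(3)
        total = 0.0
        for s0 in range(3):
            for s1 in range(3):
                for s2 in range(3):
                    w = prior[s0] * emit_A[s0] * T[s0, s1] * T[s1, s2] * emit_A[s2]
                    post[s1] += w
                    total += w
        post /= total
        assert probs.probs[0, 1, :] == pytest.approx(post, abs=1e-12)

    def test_triples_normalised_on_simulated_panel(self):
        cfg = cq.CrossConfig(
            n_individuals=60, chromosomes=[("c1", 50.0), ("c2", 40.0)],
            marker_spacing_cm=5.0, missing_rate=0.3, seed=2,
        )
        g, _, truth = cq.simulate_cross(cfg)
        probs = cq.calc_genoprob(g, truth.true_map, step_cm=1.0)
        assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)
        assert (probs.positions["marker"].notna()).sum() == g.n_markers

    def test_unknown_marker_named_in_error(self):
        g, gmap = _geno([[CODE_A, CODE_A]], [0.0, 10.0])
        gmap2 = GeneticMap(gmap.table.iloc[:1].copy())
        with pytest.raises(KeyError, match="m1"):
            cq.calc_genoprob(g, gmap2)


def _hand_grid(y=None, n=8, seed=0):
    """Tiny two-position probability grid with fixed triples."""
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet([1, 1, 1], size=(n, 2))
    positions = pd.DataFrame(
        {"lg": ["c1", "c1"], "cm": [0.0, 5.0], "marker": ["m0", "m1"]}
    )
    return GenoProbGrid(
        [f"i{k}" for k in range(n)], positions, raw, 1e-4, 5.0
    )


class TestScanHk:
    def test_constant_phenotype_gives_zero_curve(self):
        probs = _hand_grid()
        y = pd.Series(np.ones(8), index=probs.individuals)
        curve = cq.scan_hk(probs, y)
        assert np.all(curve.lod == 0.0)

    def test_matches_normal_equations_oracle(self):
        """Worked 8-individual fixture vs an independent least-squares fit."""
        probs = _hand_grid(seed=3)
        y = pd.Series(
            [0.3, -1.2, 0.8, 2.0, -0.5, 1.1, 0.0, -0.7], index=probs.individuals
        )
        curve = cq.scan_hk(probs, y)
        yv = y.to_numpy()
        n = len(yv)
        rss0 = ((yv - yv.mean()) ** 2).sum()
        for j in range(probs.n_positions):
            pa = probs.probs[:, j, 2] - probs.probs[:, j, 0]
            pdom = probs.probs[:, j, 1]
            X = np.column_stack([np.ones(n), pa, pdom])
            beta = np.linalg.solve(X.T @ X, X.T @ yv)
            rss1 = ((yv - X @ beta) ** 2).sum()
            assert curve.lod[j] == pytest.approx(
                0.5 * n * np.log10(rss0 / rss1), abs=1e-8
            )

    def test_lod_invariant_under_affine_rescaling(self):
        probs = _hand_grid(seed=4)
        y = pd.Series(
            [1.0, 2.0, 0.5, -1.0, 3.0, 0.0, 1.5, -0.5], index=probs.individuals
        )
        base = cq.scan_hk(probs, y)
        scaled = cq.scan_hk(probs, 7.3 * y - 2.1)
        assert np.allclose(base.lod, scaled.lod, atol=1e-8)

    def test_missing_phenotypes_complete_cased(self):
        probs = _hand_grid(seed=5)
        y = pd.Series(
            [1.0, np.nan, 0.5, -1.0, np.nan, 0.0, 1.5, -0.5],
            index=probs.individuals,
        )
        curve = cq.scan_hk(probs, y)
        assert curve.n_used == 6


class TestPermThreshold:
    def test_alpha_one_gives_smallest_maximum(self):
        probs = _hand_grid(seed=6)
        y = pd.Series(np.arange(8.0), index=probs.individuals)
        thr, maxima = cq.perm_threshold(probs, y, n_perm=25, alpha=1.0, seed=1)
        assert thr == pytest.approx(maxima.min())

    def test_deterministic_given_seed(self):
        probs = _hand_grid(seed=6)
        y = pd.Series(np.arange(8.0), index=probs.individuals)
        t1, m1 = cq.perm_threshold(probs, y, n_perm=50, seed=9)
        t2, m2 = cq.perm_threshold(probs, y, n_perm=50, seed=9)
        assert t1 == t2 and np.array_equal(m1, m2)
        t3, _ = cq.perm_threshold(probs, y, n_perm=50, seed=10)
        assert t1 != t3

    def test_order_statistic_rule(self):
        probs = _hand_grid(seed=7)
        y = pd.Series(np.random.default_rng(0).normal(size=8),
                      index=probs.individuals)
        thr, maxima = cq.perm_threshold(probs, y, n_perm=19, alpha=0.05, seed=3)
        # ceil(0.95 * 20) = 19 -> largest of 19 maxima
        assert thr == pytest.approx(np.sort(maxima)[18])


@pytest.fixture(scope="module")
def one_qtl_panel():
    cfg = cq.CrossConfig(
        n_individuals=160,
        chromosomes=[("c1", 80.0), ("c2", 80.0), ("c3", 80.0)],
        marker_spacing_cm=2.5, missing_rate=0.1, seed=21,
    )
    a, d = cq.target_pve_to_effect(0.4, 0.5, 1.0)
    g, phen, truth = cq.simulate_cross(
        cfg,
        [cq.TraitArchitecture("t", qtls=[("c2", 40.0, a, d)]),
         cq.TraitArchitecture("null", qtls=[])],
    )
    probs = cq.calc_genoprob(g, truth.true_map)
    return phen, probs


class TestStepwise:
    def test_null_trait_empty_model(self, one_qtl_panel):
        phen, probs = one_qtl_panel
        model = cq.stepwise_qtl(probs, phen["null"], main_penalty=4.0)
        assert model.n_qtl == 0
        assert model.plod == 0.0

    def test_single_qtl_recovered(self, one_qtl_panel):
        phen, probs = one_qtl_panel
        model = cq.stepwise_qtl(probs, phen["t"], main_penalty=4.0)
        assert model.n_qtl == 1
        q = model.qtls[0]
        assert q["lg"] == "c2"
        assert abs(q["cm"] - 40.0) < 10.0
        assert model.pve == pytest.approx(0.4, abs=0.15)
        assert q["add"] > 0

    def test_penalty_validation(self, one_qtl_panel):
        phen, probs = one_qtl_panel
        with pytest.raises(ValueError):
            cq.stepwise_qtl(probs, phen["t"], main_penalty=0.0)


class TestBayesInterval:
    def _curve(self, lod, cms=None, lg="c1"):
        lod = np.asarray(lod, dtype=float)
        cms = np.arange(len(lod), dtype=float) if cms is None else cms
        positions = pd.DataFrame({"lg": lg, "cm": cms, "marker": None})
        return cq.LodCurve("t", positions, lod, 100)

    def test_single_spike(self):
        curve = self._curve([0, 0, 9.0, 0, 0])
        ci = cq.bayes_interval(curve, "c1", prob=0.95)
        assert (ci.lo_cm, ci.hi_cm) == (2.0, 2.0)
        assert not ci.degenerate

    def test_symmetric_triangle_matches_enumeration(self):
        lod = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        curve = self._curve(lod)
        ci = cq.bayes_interval(curve, "c1", prob=0.9)
        # direct cumulative enumeration over unique LOD levels, high to low:
        # take whole levels until the posterior mass reaches the target
        w = 10.0**lod
        w = w / w.sum()
        included = np.zeros(len(lod), dtype=bool)
        for level in sorted(set(lod), reverse=True):
            included |= lod == level
            if w[included].sum() >= 0.9:
                break
        idx = np.flatnonzero(included)
        assert ci.lo_cm == idx.min() and ci.hi_cm == idx.max()
        assert 3.0 - ci.lo_cm == ci.hi_cm - 3.0  # symmetric about the peak

    def test_sharper_peak_never_wider(self):
        lod = np.array([0.2, 1.1, 2.7, 4.0, 2.2, 0.9, 0.1])
        base = cq.bayes_interval(self._curve(lod), "c1")
        sharp = cq.bayes_interval(self._curve(2 * lod), "c1")
        assert sharp.hi_cm - sharp.lo_cm <= base.hi_cm - base.lo_cm

    def test_flat_curve_degenerate(self):
        curve = self._curve([0.0] * 5)
        ci = cq.bayes_interval(curve, "c1")
        assert ci.degenerate
        assert (ci.lo_cm, ci.hi_cm) == (0.0, 4.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            cq.bayes_interval(self._curve([1.0]), "nope")


class TestPve:
    def test_paper_scale_arithmetic(self):
        assert cq.pve(5.01, 160) == pytest.approx(0.1343, abs=5e-5)
        assert cq.pve(5.21, 160) == pytest.approx(0.1393, abs=5e-5)
        assert cq.pve(0.0, 77) == 0.0

    def test_monotone_in_lod_and_n(self):
        lods = np.linspace(0, 20, 30)
        vals = [cq.pve(l, 160) for l in lods]
        assert np.all(np.diff(vals) > 0)
        ns = [50, 100, 200, 400]
        vals_n = [cq.pve(5.0, n) for n in ns]
        assert np.all(np.diff(vals_n) < 0)


class TestQtlEffects:
    def _panel(self, means, n_per=30, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        calls = np.array(
            [CODE_B] * n_per + [CODE_H] * n_per + [CODE_A] * n_per, dtype=np.int8
        )[:, None]
        y = np.concatenate(
            [rng.normal(means[k], sd, n_per) for k in range(3)]
        )
        markers = pd.DataFrame({"lg": "c1", "cm": [0.0]},
                               index=pd.Index(["m0"], name="marker"))
        g = GenotypeMatrix([f"i{k}" for k in range(3 * n_per)], markers, calls)
        gmap = GeneticMap(markers.copy())
        return g, gmap, pd.Series(y, index=g.individuals)

    def test_effect_decomposition(self):
        g, gmap, y = self._panel(means=[0.0, 1.0, 2.0])  # B, H, A
        eff = cq.qtl_effects(g, gmap, "c1", 0.0, y)
        assert eff["add_effect"] == pytest.approx(1.0, abs=0.1)
        assert eff["dom_effect"] == pytest.approx(0.0, abs=0.1)
        assert eff["dominance"] == "additive"

    def test_incomplete_dominance(self):
        g, gmap, y = self._panel(means=[0.0, 1.5, 2.0], seed=1)
        eff = cq.qtl_effects(g, gmap, "c1", 0.0, y)
        assert eff["dominance"] == "incomplete dominance"

    def test_overdominance(self):
        g, gmap, y = self._panel(means=[0.0, 3.0, 2.0], seed=2)
        eff = cq.qtl_effects(g, gmap, "c1", 0.0, y)
        assert eff["dominance"] == "overdominance"

    def test_empty_class_degrades(self):
        g, gmap, y = self._panel(means=[0.0, 1.0, 2.0])
        g.calls[g.calls == CODE_H] = MISSING
        eff = cq.qtl_effects(g, gmap, "c1", 0.0, y)
        assert eff["classes"]["H"]["n"] == 0
        assert eff["dominance"] == "undetermined"


def test_results_summary_mentions_threshold_and_model(study_probs, study_panel):
    _, phen, _ = study_panel
    g_m, probs = study_probs
    res = cq.QTLModel(
        phen["dorsal_fin_xanthophores"], probs, trait="dorsal_fin_xanthophores"
    ).fit(n_perm=100, seed=5)
    text = res.summary()
    assert "threshold" in text and "LOD" in text
    assert res.threshold is not None


def test_no_permutations_warns_and_skips_model():
    probs = _hand_grid(seed=8)
    y = pd.Series(np.random.default_rng(1).normal(size=8), index=probs.individuals)
    with pytest.warns(UserWarning, match="skipped"):
        res = cq.QTLModel(y, probs).fit(n_perm=0)
    assert res.threshold is None and res.qtl_model is None
    assert res.curve is not None
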
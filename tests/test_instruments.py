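"""Instrument QC: clumping, pruning, risk scores, F statistics, Steiger."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from collidermr.containers import DataError, GenotypeMatrix, InstrumentSet, ParameterError
from collidermr._regression import FitError
from collidermr.instruments import (
    clump,
    conditional_f,
    genetic_risk_score,
    ld_prune_pairwise,
    mean_f_statistic,
    snp_r2_individual,
    steiger_filter,
)
from collidermr.simulate import SimulationConfig, simulate_genotypes, simulate_two_exposure_cohort


def make_variants(n, chrom="1", spacing=10_000, pvals=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": [1_000_000 + i * spacing for i in range(n)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta_ext": rng.normal(0.1, 0.02, n),
            "se_ext": 0.01,
            "p_ext": pvals if pvals is not None else rng.uniform(1e-12, 1e-8, n),
        }
    )


def brute_force_clump(variants, ld, window_kb, r2_threshold):
    """Independent enumeration of the greedy rule, written longhand."""
    remaining = variants.sort_values(["p_ext", "chrom", "pos", "id"]).to_dict("records")
    kept = []
    while remaining:
        head = remaining.pop(0)
        kept.append(head["id"])
        survivors = []
        for v in remaining:
            same = v["chrom"] == head["chrom"]
            near = abs(v["pos"] - head["pos"]) <= window_kb * 1000
            if same and near and ld[frozenset((head["id"], v["id"]))] > r2_threshold:
                continue
            survivors.append(v)
        remaining = survivors
    return kept


class TestClump:
    def test_independent_variants_all_retained(self):
        v = make_variants(6)
        ld = {frozenset((a, b)): 0.0 for a in v["id"] for b in v["id"] if a != b}
        out = clump(v, ld, window_kb=50, r2_threshold=0.001)
        assert sorted(out.ids) == sorted(v["id"])

    def test_dominant_variant_wins(self):
        v = make_variants(2, spacing=10_000, pvals=[1e-10, 1e-8])
        ld = {frozenset(("rs0", "rs1")): 1.0}
        out = clump(v, ld, window_kb=50, r2_threshold=0.001)
        assert out.ids == ["rs0"]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        v = make_variants(10, spacing=20_000, rng=rng)
        ld = {}
        for i in range(10):
            for j in range(i + 1, 10):
                ld[frozenset((f"rs{i}", f"rs{j}"))] = float(rng.uniform(0, 0.5))
        out = clump(v, ld, window_kb=50, r2_threshold=0.1)
        assert out.ids == brute_force_clump(v, ld, 50, 0.1)

    def test_missing_ld_entry_raises(self):
        v = make_variants(2, spacing=10_000)
        with pytest.raises(DataError, match="missing LD"):
            clump(v, {}, window_kb=50, r2_threshold=0.001)

    def test_outside_window_needs_no_ld(self):
        v = make_variants(2, spacing=200_000)
        out = clump(v, {}, window_kb=50, r2_threshold=0.001)
        assert len(out) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        v = make_variants(8, rng=rng)
        ld = {
            frozenset((f"rs{i}", f"rs{j}")): float(rng.uniform(0, 1))
            for i in range(8)
            for j in range(i + 1, 8)
        }
        once = clump(v, ld, 50, 0.05)
        twice = clump(once.table, ld, 50, 0.05)
        assert once.ids == twice.ids


def _geno_from_matrix(X, variants):
    ids = list(variants["id"])
    return GenotypeMatrix(pd.DataFrame(X, columns=ids), variants)


class TestPrune:
    def _chain_fixture(self):
        # Markov chain of dosage-like columns: A~B strongly (r2 ~ 0.5),
        # B~C just above threshold (r2 ~ 0.09), hence A~C below it (~0.045)
        rng = np.random.default_rng(2)
        n = 20_000
        a = rng.standard_normal(n)
        b = np.sqrt(0.5) * a + np.sqrt(0.5) * rng.standard_normal(n)
        c = 0.3 * b + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        v = make_variants(3, pvals=[1e-12, 1e-10, 1e-8])
        gm = _geno_from_matrix(np.column_stack([a, b, c]), v)
        r2 = np.corrcoef(np.column_stack([a, b, c]), rowvar=False) ** 2
        assert r2[0, 1] > 0.05 and r2[1, 2] > 0.05 and r2[0, 2] < 0.05
        return InstrumentSet(v), gm

    def test_duplicate_column_keeps_smaller_p(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.4, 500).astype(float)
        v = make_variants(2, pvals=[1e-9, 1e-6])
        gm = _geno_from_matrix(np.column_stack([col, col]), v)
        out = ld_prune_pairwise(InstrumentSet(v), gm)
        assert out.ids == ["rs0"]

    def test_literal_mode_keeps_larger_p(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.4, 500).astype(float)
        v = make_variants(2, pvals=[1e-9, 1e-6])
        gm = _geno_from_matrix(np.column_stack([col, col]), v)
        out = ld_prune_pairwise(InstrumentSet(v), gm, literal=True)
        assert out.ids == ["rs1"]

    def test_below_threshold_is_noop(self):
        gm = simulate_genotypes(3000, 5, seed=10)
        v = gm.variants.copy()
        v["p_ext"] = np.linspace(1e-10, 1e-6, 5)
        v["beta_ext"] = 0.1
        v["se_ext"] = 0.01
        inst = InstrumentSet(v)
        out = ld_prune_pairwise(inst, gm)
        assert out.ids == inst.ids

    def test_chain_retains_ends(self):
        inst, gm = self._chain_fixture()
        out = ld_prune_pairwise(inst, gm)
        assert out.ids == ["rs0", "rs2"]

    def test_idempotent(self):
        inst, gm = self._chain_fixture()
        once = ld_prune_pairwise(inst, gm)
        assert ld_prune_pairwise(once, gm).ids == once.ids

    def test_monomorphic_column_raises(self):
        v = make_variants(2)
        gm = _geno_from_matrix(
            np.column_stack([np.ones(100), np.random.default_rng(0).binomial(2, 0.3, 100)]),
            v,
        )
        with pytest.raises(DataError, match="monomorphic"):
            ld_prune_pairwise(InstrumentSet(v), gm)


class TestGeneticRiskScore:
    def test_zero_weights(self):
        gm = simulate_genotypes(50, 4, seed=0)
        v = gm.variants.copy()
        v["weight"] = 0.0
        assert np.all(genetic_risk_score(gm, InstrumentSet(v)) == 0.0)

    def test_single_variant_identity(self):
        gm = simulate_genotypes(50, 3, seed=1)
        v = gm.variants.iloc[[1]].copy()
        v["weight"] = 1.0
        score = genetic_risk_score(gm, InstrumentSet(v.reset_index(drop=True)))
        assert np.array_equal(score, gm.values()[:, 1])

    def test_matrix_product_oracle(self, rng):
        gm = simulate_genotypes(5, 3, seed=2)
        v = gm.variants.copy()
        v["weight"] = rng.normal(size=3)
        score = genetic_risk_score(gm, InstrumentSet(v))
        manual = np.array(
            [sum(w * d for w, d in zip(v["weight"], row)) for row in gm.values()]
        )
        assert np.allclose(score, manual, atol=1e-12)

    def test_linearity(self, rng):
        gm = simulate_genotypes(30, 4, seed=3)
        w1, w2 = rng.normal(size=4), rng.normal(size=4)
        v = gm.variants.copy()

        def score(w):
            t = v.copy()
            t["weight"] = w
            return genetic_risk_score(gm, InstrumentSet(t))

        assert np.allclose(score(w1 + w2), score(w1) + score(w2), atol=1e-12)

    def test_missing_variant_raises(self):
        gm = simulate_genotypes(10, 2, seed=4)
        v = gm.variants.copy()
        v.loc[0, "id"] = "rs_absent"
        v["weight"] = 1.0
        with pytest.raises(DataError):
            genetic_risk_score(gm, InstrumentSet(v))


class TestInstrumentStrength:
    def test_null_mean_f_near_one(self, rng):
        G = rng.binomial(2, 0.3, size=(5000, 20)).astype(float)
        x = rng.standard_normal(5000)
        d = mean_f_statistic(G, x)
        # mean of 20 approx-F(1, n) variables; sd ~ sqrt(2/20)
        assert abs(d["mean_f"] - 1.0) < 4 * np.sqrt(2 / 20)

    def test_single_instrument_f_equals_t_squared(self, rng):
        G = rng.binomial(2, 0.3, size=(800, 1)).astype(float)
        x = 0.2 * G[:, 0] + rng.standard_normal(800)
        d = mean_f_statistic(G, x)
        fit = sm.OLS(x, sm.add_constant(G)).fit()
        assert d["mean_f"] == pytest.approx(float(fit.tvalues[1] ** 2), rel=1e-8)
        assert d["joint_f"] == pytest.approx(float(fit.tvalues[1] ** 2), rel=1e-8)

    def test_joint_f_matches_r2_relation(self, rng):
        n, m = 4000, 10
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        x = G @ np.full(m, 0.1) + rng.standard_normal(n)
        d = mean_f_statistic(G, x)
        r2 = sm.OLS(x, sm.add_constant(G)).fit().rsquared
        expected = (r2 / (1 - r2)) * ((n - m - 1) / m)
        assert d["joint_f"] == pytest.approx(expected, rel=1e-8)

    def test_covariate_adjustment_changes_f(self, rng):
        n = 2000
        G = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        u = rng.standard_normal(n)
        x = G @ np.full(5, 0.2) + 2 * u + rng.standard_normal(n)
        unadj = mean_f_statistic(G, x)["joint_f"]
        adj = mean_f_statistic(G, x, covariates=u[:, None])["joint_f"]
        assert adj > unadj  # removing confounder noise sharpens the first stage


class TestConditionalF:
    def test_disjoint_strong_sets_close_to_marginal(self):
        cfg = SimulationConfig(
            n_individuals=6000, n_snps_per_exposure=15, gamma_scale=0.3, seed=31
        )
        geno, cohort, truth = simulate_two_exposure_cohort(cfg)
        cf = conditional_f(geno, cohort[["x1", "x2"]])
        for col, ids in (("x1", truth.snp_ids_x1), ("x2", truth.snp_ids_x2)):
            marginal = mean_f_statistic(geno, cohort[col].to_numpy())["joint_f"]
            assert cf[col] == pytest.approx(marginal, rel=0.10)

    def test_proportional_gammas_collapse(self, rng):
        n, m = 20_000, 12
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        gamma = rng.uniform(0.1, 0.3, m)
        x1 = G @ gamma + rng.standard_normal(n)
        x2 = G @ (2 * gamma) + rng.standard_normal(n)
        with pytest.warns(UserWarning, match="conditional F"):
            cf = conditional_f(G, pd.DataFrame({"x1": x1, "x2": x2}))
        assert cf["x1"] < 2 and cf["x2"] < 2

    def test_single_exposure_rejected(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 5)).astype(float)
        with pytest.raises(ParameterError):
            conditional_f(G, pd.DataFrame({"x": rng.standard_normal(100)}))


class TestSteiger:
    def _inst(self, ids):
        v = make_variants(len(ids))
        v["id"] = ids
        return InstrumentSet(v)

    def test_definition(self):
        inst = self._inst(["a"])
        kept = steiger_filter(inst, {"a": 0.01}, {"y": {"a": 0.001}})
        assert kept.ids == ["a"]
        dropped = steiger_filter(inst, {"a": 0.001}, {"y": {"a": 0.01}})
        assert dropped.ids == []

    def test_empty_set(self):
        v = make_variants(0)
        out = steiger_filter(InstrumentSet(v), {}, {"y": {}})
        assert out.ids == []

    def test_missing_r2_raises(self):
        inst = self._inst(["a"])
        with pytest.raises(DataError):
            steiger_filter(inst, {}, {})

    def test_rescaling_invariance(self, rng):
        ids = [f"v{i}" for i in range(6)]
        inst = self._inst(ids)
        t = {i: float(rng.uniform(0.001, 0.02)) for i in ids}
        c = {"y": {i: float(rng.uniform(0.001, 0.02)) for i in ids}}
        base = steiger_filter(inst, t, c).ids
        scaled = steiger_filter(
            inst, {k: 7.3 * v for k, v in t.items()},
            {"y": {k: 7.3 * v for k, v in c["y"].items()}},
        ).ids
        assert base == scaled

    def test_variance_decay_along_causal_chain(self):
        # G -> X -> Y: every SNP explains more of X than of Y (attenuation
        # by beta^2 < 1), so filtering retains ~all when X is the target and
        # ~none when Y is
        rng = np.random.default_rng(17)
        n, m = 100_000, 12
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        x = G @ np.full(m, 0.15) + rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        ids = [f"s{i}" for i in range(m)]
        inst = self._inst(ids)
        rx = {ids[j]: snp_r2_individual(G[:, j], x) for j in range(m)}
        ry = {ids[j]: snp_r2_individual(G[:, j], y) for j in range(m)}
        assert len(steiger_filter(inst, rx, {"y": ry})) == m
        assert len(steiger_filter(inst, ry, {"x": rx})) == 0
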
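"""Association pipeline: filtering, rank-INT, covariate screen, regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from casebias.assoc import (filter_taxa, fit_snp_taxon, fit_taxon_disease,
                            per_level_bonferroni, rank_int,
                            select_level_covariates, stratified_analysis,
                            AssocResult)


class TestRankInt:
    def test_frozen_three_value_oracle(self):
        """Quantiles of (r - 3/8) / (n + 1/4) for ranks of [1.2, 5.0, 3.3]."""
        out = rank_int([1.2, 5.0, 3.3])
        assert out == pytest.approx([-0.8694, 0.8694, 0.0], abs=1e-4)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.exponential(2.0, 50)
        assert np.allclose(rank_int(x), rank_int(np.log1p(x)))
        assert np.allclose(rank_int(x), rank_int(x * 7.3 + 2.0))

    def test_no_tie_output_sums_to_zero(self, rng):
        x = rng.standard_normal(41)
        assert rank_int(x).sum() == pytest.approx(0.0, abs=1e-10)

    def test_zero_mass_forms_tied_block(self):
        x = np.r_[np.zeros(10), [1.0, 2.0, 3.0]]
        out = rank_int(x)
        assert np.unique(out[:10]).size == 1
        assert (out[10:] > out[0]).all()

    def test_output_passes_normality_check(self, rng):
        x = rng.exponential(1.0, 182)  # heavily skewed input
        _, p = stats.shapiro(rank_int(x))
        assert p > 0.01

    @pytest.mark.parametrize("bad", [[1.0, 1.0, 1.0], [1.0, 2.0],
                                     [1.0, np.nan, 2.0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            rank_int(bad)


class TestFilterTaxa:
    @staticmethod
    def _table(fracs, n=50, seed=0):
        rng = np.random.default_rng(seed)
        cols = {}
        for i, f in enumerate(fracs):
            nonzero = int(round(f * n))
            v = np.zeros(n)
            if nonzero:
                v[rng.choice(n, nonzero, replace=False)] = rng.exponential(
                    1.0, nonzero)
            cols[f"t{i}"] = v
        return pd.DataFrame(cols)

    def test_screening_funnel_897_to_320(self):
        """577 of 897 taxa under 20% prevalence leaves 320 retained."""
        fracs = [0.1] * 577 + [0.5] * 320
        table = self._table(fracs, n=20, seed=1)
        out = filter_taxa(table, ranks={c: "genus" for c in table.columns})
        assert len(out.retained) == 320
        assert (out.dropped["reason"] == "low-prevalence").sum() == 577

    def test_boundary_taxon_at_exactly_20_percent_retained(self):
        table = self._table([0.20, 0.18], n=50)
        out = filter_taxa(table, ranks={"t0": "genus", "t1": "genus"})
        assert out.retained == ["t0"]

    def test_zero_threshold_is_identity(self):
        table = self._table([0.1, 0.9], n=50)
        out = filter_taxa(table, ranks={"t0": "genus", "t1": "genus"},
                          min_nonzero_frac=0.0)
        assert out.retained == ["t0", "t1"]

    def test_ledger_and_retained_partition_input(self):
        table = self._table([0.1, 0.5, 0.05, 0.9], n=40, seed=2)
        out = filter_taxa(table, ranks={c: "genus" for c in table.columns})
        assert sorted(out.retained + out.dropped["taxon"].tolist()) == \
            sorted(table.columns)

    def test_all_dropped_is_error(self):
        table = self._table([0.05, 0.04], n=50)
        with pytest.raises(ValueError):
            filter_taxa(table, ranks={"t0": "genus", "t1": "genus"})

    def test_unannotated_taxa_dropped_when_required(self):
        table = self._table([0.9, 0.9], n=30)
        out = filter_taxa(table, ranks={"t0": "genus", "t1": "genus"},
                          lineages={"t0": "p__1|c__1|o__1|f__1|g__t0",
                                    "t1": ""},
                          require_annotation=True)
        assert out.retained == ["t0"]
        assert (out.dropped["reason"] == "unannotated").sum() == 1


class TestCovariateScreen:
    def test_independent_noise_selects_nothing(self, rng):
        y = rng.standard_normal(300)
        cands = pd.DataFrame(rng.standard_normal((300, 5)),
                             columns=list("abcde"))
        g = rng.binomial(2, 0.3, 300).astype(float)
        assert select_level_covariates(y, cands, g) == []

    def test_shared_noise_component_improves_precision(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        shared = rng.standard_normal(n)
        y = -0.3 * g + shared + 0.5 * rng.standard_normal(n)
        cands = pd.DataFrame({"peer": shared + 0.3 * rng.standard_normal(n),
                              "noise": rng.standard_normal(n)})
        chosen = select_level_covariates(y, cands, g)
        assert "peer" in chosen
        base = fit_snp_taxon(y, g)
        adj = fit_snp_taxon(y, g, C=cands[chosen])
        assert adj.se < base.se

    def test_genotype_associated_candidate_excluded(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal(n) + 0.8 * g * 0  # null outcome
        collider = 0.9 * g + 0.3 * rng.standard_normal(n)
        cands = pd.DataFrame({"collider": collider + y})
        chosen = select_level_covariates(y, cands, g)
        assert "collider" not in chosen


class TestRegressions:
    def test_perfect_fit_recovers_scale_ratio(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        y = 2.0 * (g - g.mean())
        res = fit_snp_taxon(y, g)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-10

    def test_parameter_recovery_with_confounders(self, rng):
        n = 1_000
        g = rng.binomial(2, 0.3, n).astype(float)
        Z = pd.DataFrame({"age": rng.normal(40, 10, n),
                          "sex": rng.binomial(1, 0.5, n).astype(float)})
        y = -0.4 * g + 0.01 * Z["age"].to_numpy() + rng.standard_normal(n)
        res = fit_snp_taxon(y, g, Z=Z)
        assert abs(res.beta - (-0.4)) < 3 * res.se

    def test_irrelevant_covariate_barely_moves_estimate(self, rng):
        n = 800
        g = rng.binomial(2, 0.3, n).astype(float)
        y = -0.3 * g + rng.standard_normal(n)
        base = fit_snp_taxon(y, g)
        noise = pd.DataFrame({"x": rng.standard_normal(n)})
        adj = fit_snp_taxon(y, g, C=noise)
        assert abs(adj.beta - base.beta) < base.se

    def test_constant_genotype_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_snp_taxon(rng.standard_normal(50), np.ones(50))

    def test_logistic_recovery(self, rng):
        n = 4_000
        b = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-0.5 * b - 0.2)))
        d = rng.binomial(1, p)
        res = fit_taxon_disease(b, d)
        assert abs(res.beta - (-0.5)) < 3 * res.se

    def test_logistic_null_p_uniform(self):
        """Type-I calibration of the case-control taxon test."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            b = rng.standard_normal(400)
            d = rng.binomial(1, 0.4, 400)
            pvals.append(fit_taxon_disease(b, d).p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_taxon_disease(rng.standard_normal(30), np.ones(30))

    def test_perfect_separation_flagged_not_crashed(self):
        b = np.r_[np.zeros(20) - 2.0, np.zeros(20) + 2.0]
        d = np.r_[np.zeros(20), np.ones(20)]
        res = fit_taxon_disease(b, d)
        assert res.missing and res.flag == "perfect separation"


class TestMultiplicityAndStrata:
    @staticmethod
    def _results(ps, rank="genus"):
        return [AssocResult(taxon=f"t{i}", predictor="NOD2", stratum="IBD",
                            beta=-0.1, se=0.05, p=p, n=100, rank=rank)
                for i, p in enumerate(ps)]

    def test_genus_level_threshold(self):
        res = self._results(np.linspace(1e-5, 0.9, 63))
        per_level_bonferroni(res)
        thr = 0.05 / 63
        for r in res:
            assert r.candidate == (r.p < thr)

    def test_single_test_threshold_is_alpha(self):
        res = self._results([0.04])
        per_level_bonferroni(res)
        assert res[0].candidate

    def test_empty_level_no_flags(self):
        assert per_level_bonferroni([]) == []

    @staticmethod
    def _stratified_setup(rng, effect_cd=-0.5, effect_uc=0.0, n=400):
        meta = pd.DataFrame({
            "d": np.ones(n, dtype=int),
            "subtype": rng.choice(["CD", "UC"], n),
            "ileal": rng.binomial(1, 0.6, n),
        })
        g = rng.binomial(2, 0.3, n).astype(float)
        is_cd = (meta["subtype"] == "CD").to_numpy()
        y = np.where(is_cd, effect_cd * g, effect_uc * g) + rng.standard_normal(n)
        transformed = pd.DataFrame({"tax1": y})
        return transformed, pd.Series(g), meta

    def test_subtype_specific_effect_detected(self, rng):
        transformed, g, meta = self._stratified_setup(rng)
        res = stratified_analysis(transformed, g, meta, {"tax1": "genus"})
        by = {r.stratum: r for r in res}
        assert abs(by["CD"].beta) > abs(by["UC"].beta)
        assert not by["IBD"].missing

    def test_constant_genotype_stratum_yields_missing_record(self, rng):
        transformed, g, meta = self._stratified_setup(rng, n=120)
        g.loc[(meta["subtype"] == "UC").to_numpy()] = 1.0
        res = stratified_analysis(transformed, g, meta, {"tax1": "genus"})
        uc = [r for r in res if r.stratum == "UC"][0]
        assert uc.missing and np.isnan(uc.beta)

    def test_cd_strata_partition_cd(self, rng):
        transformed, g, meta = self._stratified_setup(rng)
        res = stratified_analysis(transformed, g, meta, {"tax1": "genus"})
        by = {r.stratum: r for r in res}
        assert by["CDil"].n + by["CDni"].n == by["CD"].n
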
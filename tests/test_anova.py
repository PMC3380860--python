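"""Gene-wise ANOVA vs a brute-force least-squares oracle; FDR; rates; selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from specifex import anova, normalization, synthetic


def _ls_anova_oracle(y, design, factors):
    """Sequential sum-of-squares ANOVA via explicit least squares.

    For balanced orthogonal designs the order does not matter, so this doubles
    as a Type-III oracle.  Returns {factor: (ss, F, p)} plus residual ss/df.
    """
    from scipy import stats

    n = len(y)

    def dummies(subset):
        cols = [np.ones((n, 1))]
        for f in subset:
            codes, levels = pd.factorize(design[f], sort=True)
            for lv in range(1, len(levels)):
                cols.append((codes == lv).astype(float)[:, None])
        return np.hstack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = rss(dummies(factors))
    df_res = n - dummies(factors).shape[1]
    out = {}
    for f in factors:
        others = [g for g in factors if g != f]
        ss = rss(dummies(others)) - full
        df_f = design[f].nunique() - 1
        F = (ss / df_f) / (full / df_res)
        out[f] = (ss, F, float(stats.f.sf(F, df_f, df_res)))
    return out, full, df_res


def _toy_design(n_couples=2, cohorts=False):
    rows = []
    for c in range(n_couples):
        for role in ("patient", "control"):
            for t in ("thapsigargin", "vehicle"):
                rows.append({
                    "sample_id": f"c{c}{role[0]}{t[0]}",
                    "role": role, "couple_id": f"c{c}", "treatment": t,
                })
    return pd.DataFrame(rows)


class TestGenewiseAnova:
    @pytest.mark.parametrize("n_couples,seed", [(2, 0), (3, 1), (4, 2)])
    def test_matches_least_squares_oracle(self, n_couples, seed):
        design = _toy_design(n_couples)
        rng = np.random.default_rng(seed)
        C = pd.DataFrame(rng.normal(8, 1, (5, len(design))),
                         index=[f"g{i}" for i in range(5)],
                         columns=design["sample_id"])
        res = anova.genewise_anova(C, design, ["role", "couple_id", "treatment"])
        for gi, g in enumerate(C.index):
            oracle, rss_full, df_res = _ls_anova_oracle(
                C.iloc[gi].to_numpy(), design, ["role", "couple_id", "treatment"]
            )
            assert df_res == res.residual_df
            assert res.residual_ss[g] == pytest.approx(rss_full, rel=1e-8)
            for f, (ss, F, p) in oracle.items():
                assert res.tables[f].at[g, "ss"] == pytest.approx(ss, rel=1e-8)
                assert res.tables[f].at[g, "F"] == pytest.approx(F, rel=1e-8)
                assert res.tables[f].at[g, "p"] == pytest.approx(p, rel=1e-6)

    def test_ss_decomposition_is_additive(self):
        design = _toy_design(3)
        rng = np.random.default_rng(3)
        C = pd.DataFrame(rng.normal(0, 1, (20, len(design))), columns=design["sample_id"])
        res = anova.genewise_anova(C, design, ["role", "couple_id", "treatment"])
        total = ((C.to_numpy() - C.to_numpy().mean(1, keepdims=True)) ** 2).sum(1)
        recomposed = res.residual_ss.to_numpy() + sum(
            res.tables[f]["ss"].to_numpy() for f in res.factors
        )
        assert np.allclose(recomposed, total, rtol=1e-8)

    def test_zero_variance_convention(self):
        design = _toy_design(2)
        C = pd.DataFrame(np.full((1, len(design)), 5.0), index=["flat"],
                         columns=design["sample_id"])
        res = anova.genewise_anova(C, design, ["role", "couple_id", "treatment"])
        assert "flat" in res.zero_variance
        for f in res.factors:
            assert res.tables[f].at["flat", "F"] == 0.0
            assert res.tables[f].at["flat", "p"] == 1.0

    def test_unbalanced_design_rejected(self):
        design = _toy_design(2).iloc[:-1]
        C = pd.DataFrame(np.random.default_rng(0).normal(size=(2, len(design))),
                         columns=design["sample_id"])
        with pytest.raises(ValueError, match="unbalanced"):
            anova.genewise_anova(C, design, ["role", "couple_id", "treatment"])

    def test_noise_free_simulation_separates_classes(self, noise_free_bundle, corrected_noise_free):
        b, C = noise_free_bundle, corrected_noise_free
        d = b.design[b.design.cohort == "EIF2B"]
        res = anova.genewise_anova(C[d.sample_id.tolist()], d,
                                   ["role", "couple_id", "treatment"])
        tr = b.truth.set_index("gene_id")
        de = tr[tr["class"].isin(["shared_de", "specific_down", "specific_up"])].index
        nulls = tr[tr["class"] == "null"].index
        assert (res.p("role").loc[de] < 1e-10).all()
        assert (res.tables["role"].loc[nulls, "F"] == 0).all()


class TestFdrAdjust:
    def test_hand_computed_bh(self):
        q = anova.fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_edge_cases(self):
        assert np.allclose(anova.fdr_adjust(np.array([1.0, 1.0])), 1.0)
        assert anova.fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        with pytest.raises(ValueError):
            anova.fdr_adjust(np.array([1.5]))

    def test_order_preserving_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = anova.fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_false_discovery_proportion_controlled(self):
        """Under a complete null, mean FDP at q<=0.0012 stays at the nominal
        level (200 simulations of 2000 uniform p-values)."""
        rng = np.random.default_rng(42)
        fdps = []
        for _ in range(200):
            q = anova.fdr_adjust(rng.uniform(size=2000))
            n_disc = int((q <= 0.0012).sum())
            fdps.append(1.0 if n_disc else 0.0)  # all discoveries are false
        # E[FDP] <= q under independence; MC error for 200 Bernoulli(0.0012)
        assert np.mean(fdps) <= 0.0012 + 3 * np.sqrt(0.0012 / 200)


class TestExpressionRate:
    def test_identical_rows_rate_one(self):
        design = _toy_design(2)
        C = pd.DataFrame(np.full((1, len(design)), 8.0), index=["g"],
                         columns=design["sample_id"])
        rr = anova.expression_rate(C, design)
        assert rr.rates.at["g", "rate"] == pytest.approx(1.0)
        assert rr.rates.at["g", "direction"] == "neutral"

    def test_hand_computed_two_couple_example(self):
        rows = []
        for c, (p_val, c_val) in enumerate([(7.2, 8.0), (6.8, 8.5)]):
            for role, v in (("patient", p_val), ("control", c_val)):
                rows.append({"sample_id": f"c{c}{role[0]}", "role": role,
                             "couple_id": f"c{c}", "treatment": "vehicle"})
        design = pd.DataFrame(rows)
        C = pd.DataFrame([[7.2, 8.0, 6.8, 8.5]], index=["g"],
                         columns=["c0p", "c0c", "c1p", "c1c"])
        rr = anova.expression_rate(C, design)
        assert rr.rates.at["g", "rate"] == pytest.approx((0.9 + 0.8) / 2)
        assert rr.rates.at["g", "direction"] == "under"

    def test_noise_free_rate_recovers_implanted(self, noise_free_bundle, corrected_noise_free):
        b, C = noise_free_bundle, corrected_noise_free
        d = b.design[b.design.cohort == "EIF2B"]
        rr = anova.expression_rate(C[d.sample_id.tolist()], d)
        tr = b.truth.set_index("gene_id")
        spec = tr[tr["class"].isin(["specific_down", "specific_up"])]
        assert np.allclose(rr.rates.loc[spec.index, "rate"], spec["implanted_rate"],
                           atol=1e-12)
        dirs = rr.rates.loc[spec.index, "direction"]
        assert (dirs[spec["class"] == "specific_down"] == "under").all()
        assert (dirs[spec["class"] == "specific_up"] == "over").all()


class TestSelectSpecific:
    def _inputs(self):
        genes = pd.Index(["a", "b", "c", "d"])
        q_de = pd.Series([0.0005, 0.0005, 0.5, 0.0005], index=genes)
        q_cross = pd.Series([0.0005, 0.5, 0.0005, 0.0005], index=genes)
        rates = anova.RateResult(
            rates=pd.DataFrame({"rate": [0.8, 0.8, 0.8, 0.95],
                                "direction": ["under"] * 4}, index=genes),
            per_couple=pd.DataFrame(index=genes),
        )
        return q_de, q_cross, rates

    def test_threshold_logic(self):
        q_de, q_cross, rates = self._inputs()
        sel = anova.select_specific(q_de, q_cross, rates)
        assert sel.genes == ["a"]  # b fails cross, c fails DE, d fails rate
        assert sel.stage_counts["de_pass"] == 3

    def test_near_miss_rate_excluded(self):
        q_de, q_cross, rates = self._inputs()
        sel = anova.select_specific(q_de, q_cross, rates)
        assert "d" not in sel.genes  # significant q but rate 0.95 inside (0.9, 1.05)

    def test_empty_de_set_is_valid(self):
        q_de, q_cross, rates = self._inputs()
        sel = anova.select_specific(q_de * 0 + 1.0, q_cross, rates)
        assert sel.genes == []
        assert np.isnan(sel.pct_under)

    def test_relaxing_thresholds_never_shrinks(self):
        q_de, q_cross, rates = self._inputs()
        base = anova.select_specific(q_de, q_cross, rates)
        for kwargs in (dict(fdr_threshold=0.6), dict(cross_threshold=0.6),
                       dict(rate_low=0.96), dict(rate_high=1.0)):
            wider = anova.select_specific(q_de, q_cross, rates, **{
                **dict(fdr_threshold=0.0012, cross_threshold=0.0012,
                       rate_low=0.9, rate_high=1.05), **kwargs})
            assert set(base.genes) <= set(wider.genes)

    def test_missing_gene_alignment_error(self):
        q_de, q_cross, rates = self._inputs()
        with pytest.raises(ValueError, match="missing"):
            anova.select_specific(q_de, q_cross.drop("a"), rates)
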
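"""Ct collapsing, dCt/ddCt quantification, Mann-Whitney exact test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specifex import qpcr


def _table(rows):
    defaults = {"rt_batch": 1, "replicate": 1, "censored": False}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def _replicates(sample, gene, cts, censored=False, **meta):
    return [
        {"sample_id": sample, "gene": gene, "rt_batch": 1 + i // 2,
         "replicate": 1 + i % 2, "ct": c, "censored": censored, **meta}
        for i, c in enumerate(cts)
    ]


class TestCollapseReplicates:
    def test_arithmetic_mean(self):
        t = _table(_replicates("s1", "GX", [20.1, 20.3, 19.9, 20.1]))
        out = qpcr.collapse_replicates(t)
        assert out.loc[0, "ct"] == pytest.approx(20.1)
        assert out.loc[0, "n_replicates"] == 4
        assert not out.loc[0, "qc_flag"]

    def test_wide_spread_flagged_but_kept(self):
        t = _table(_replicates("s1", "GX", [20.0, 21.2, 20.1, 20.3]))
        out = qpcr.collapse_replicates(t)
        assert out.loc[0, "qc_flag"]
        assert out.loc[0, "ct"] == pytest.approx(np.mean([20.0, 21.2, 20.1, 20.3]))

    def test_all_censored_record(self):
        t = _table(_replicates("s1", "GX", [40.0] * 4, censored=True))
        out = qpcr.collapse_replicates(t)
        assert out.loc[0, "censored"]
        assert np.isnan(out.loc[0, "ct"])


class TestDeltaCt:
    def test_single_reference(self):
        t = qpcr.collapse_replicates(_table(
            _replicates("s1", "GX", [25.0] * 4) + _replicates("s1", "B2M", [20.0] * 4)
        ))
        d = qpcr.delta_ct(t, "B2M")
        assert d.loc[0, "delta_ct"] == pytest.approx(5.0)
        assert d.attrs["reference_genes"] == ["B2M"]

    def test_mean_of_two_references(self):
        t = qpcr.collapse_replicates(_table(
            _replicates("s1", "GX", [25.0] * 4)
            + _replicates("s1", "GAPDH", [18.0] * 4)
            + _replicates("s1", "HPRT", [22.0] * 4)
        ))
        d = qpcr.delta_ct(t, ["GAPDH", "HPRT"])
        assert d.loc[0, "delta_ct"] == pytest.approx(5.0)  # vs mean Ct 20

    def test_censored_reference_drops_sample(self):
        t = qpcr.collapse_replicates(_table(
            _replicates("s1", "GX", [25.0] * 4)
            + _replicates("s1", "B2M", [40.0] * 4, censored=True)
            + _replicates("s2", "GX", [24.0] * 4)
            + _replicates("s2", "B2M", [20.0] * 4)
        ))
        d = qpcr.delta_ct(t, "B2M")
        assert d["sample_id"].tolist() == ["s2"]

    def test_missing_reference_errors(self):
        t = qpcr.collapse_replicates(_table(_replicates("s1", "GX", [25.0] * 4)))
        with pytest.raises(KeyError):
            qpcr.delta_ct(t, "B2M")


def _delta_frame(entries):
    return pd.DataFrame([
        {"sample_id": f"{c}{r[0]}", "gene": g, "couple_id": c, "role": r,
         "treatment": t, "delta_ct": v, "n_replicates": 4, "censored": cen}
        for (g, c, r, t, v, cen) in entries
    ])


class TestCoupleRate:
    def test_closed_forms(self):
        d = _delta_frame([
            ("G", "c1", "patient", "s", 6.0, False), ("G", "c1", "control", "s", 5.0, False),
            ("G", "c2", "patient", "s", 4.0, False), ("G", "c2", "control", "s", 5.0, False),
            ("H", "c1", "patient", "s", 5.0, False), ("H", "c1", "control", "s", 5.0, False),
            ("H", "c2", "patient", "s", 5.0, False), ("H", "c2", "control", "s", 5.0, False),
        ])
        rates, pc = qpcr.couple_expression_rate(d)
        assert pc.at["G", "c1"] == pytest.approx(0.5)   # ddCt +1
        assert pc.at["G", "c2"] == pytest.approx(2.0)   # ddCt -1
        assert rates["H"] == pytest.approx(1.0)

    def test_censored_couple_skipped(self):
        d = _delta_frame([
            ("G", "c1", "patient", "s", 6.0, True), ("G", "c1", "control", "s", 5.0, False),
            ("G", "c2", "patient", "s", 4.0, False), ("G", "c2", "control", "s", 5.0, False),
        ])
        rates, pc = qpcr.couple_expression_rate(d)
        assert "c1" not in pc.columns or np.isnan(pc.at["G", "c1"])
        assert rates["G"] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=30)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_reference_shift_invariance(self, shift):
        """Adding a constant to all dCts of one sample's genes cancels in the
        2^-ddCt rate only via the reference; shifting every sample's dCt by
        the same constant leaves rates unchanged."""
        base = _delta_frame([
            ("G", "c1", "patient", "s", 6.2, False), ("G", "c1", "control", "s", 5.1, False),
            ("G", "c2", "patient", "s", 4.7, False), ("G", "c2", "control", "s", 5.0, False),
        ])
        shifted = base.copy()
        shifted["delta_ct"] = shifted["delta_ct"] + shift
        r1, _ = qpcr.couple_expression_rate(base)
        r2, _ = qpcr.couple_expression_rate(shifted)
        assert r1["G"] == pytest.approx(r2["G"], rel=1e-9)

    def test_noise_free_end_to_end_fold_recovery(self, noise_free_bundle):
        """Generator -> collapse -> dCt -> couple rate recovers every implanted
        fold to 1e-12 relative error."""
        from specifex import synthetic

        tr = noise_free_bundle.truth
        panel = synthetic.generate_qpcr_panel(
            tr, synthetic.FIBROBLAST_PANEL,
            synthetic.QpcrPanelConfig(ct_noise_sd=0.0, seed=1),
        )
        collapsed = qpcr.collapse_replicates(panel)
        delta = qpcr.delta_ct(collapsed, "B2M")
        rates, _ = qpcr.couple_expression_rate(delta[delta["cohort"] == "EIF2B"])
        truth_rates = tr.set_index("gene_id").loc[rates.index, "implanted_rate"]
        assert np.allclose(rates, truth_rates, rtol=1e-12)


class TestRelativeExpression:
    def test_closed_forms_and_censoring(self):
        d = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"], "gene": ["G"] * 3,
            "delta_ct": [0.0, 10.0, np.nan], "n_replicates": [4, 4, 0],
            "censored": [False, False, True],
        })
        out = qpcr.relative_expression(d)
        assert out["expression"].tolist()[:2] == pytest.approx([1.0, 2.0**-10])
        assert out.loc[2, "expression"] == 0.0
        assert out.loc[2, "censored"]


def _exact_mw_oracle(a, b):
    """Two-sided Mann-Whitney p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum((x > y) for x in aa for y in bb)

    u_obs = sum((x > y) for x in a for y in b)
    us = [u_stat(c) for c in itertools.combinations(range(n + m), n)]
    lo = min(u_obs, n * m - u_obs)
    p = sum(1 for u in us if u <= lo or u >= n * m - lo) / len(us)
    return u_obs, p


class TestMannWhitney:
    def test_enumeration_examples(self):
        U, p = qpcr.mann_whitney([1, 2], [3, 4])
        assert U == 0 and p == pytest.approx(2 / 6)
        U, p = qpcr.mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0 and p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = qpcr.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 5), (6, 6), (2, 6)])
    def test_matches_full_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(10):
            vals = rng.choice(np.arange(100), size=na + nb, replace=False).astype(float)
            a, b = vals[:na], vals[na:]
            U, p = qpcr.mann_whitney(a, b)
            U_o, p_o = _exact_mw_oracle(a, b)
            assert U == U_o
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            qpcr.mann_whitney([], [1.0])
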
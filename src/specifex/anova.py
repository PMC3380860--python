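"""Gene-wise multi-factor ANOVA, FDR control, expression rates, specificity.

Each gene is fitted with an additive (no-interaction) fixed-effects ANOVA over
the declared design factors.  Two models mirror the study design:

* per-cohort ("M1"/"M2"): factors status (patient vs control), couple (1..10)
  and treatment (thapsigargin vs vehicle) over that cohort's 40 arrays;
* cross-cohort: factors cohort (EIF2B patients vs OL patients) and treatment,
  the couple-to-couple variance absorbed into the residual.

Designs must be balanced and orthogonal, so factor sums of squares are
computed from level-mean contrasts and add up with the residual to the total
sum of squares.  Everything is vectorized across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "RateResult",
    "SpecificGeneSet",
    "genewise_anova",
    "fdr_adjust",
    "expression_rate",
    "select_specific",
]

_ZERO_TOL = 1e-12


@dataclass
class AnovaResult:
    """Per-gene factor decomposition: SS, df, F, p per factor + residual."""

    factors: list[str]
    tables: dict[str, pd.DataFrame]  # factor -> DataFrame(ss, F, p) indexed by gene
    dfs: dict[str, int]
    residual_ss: pd.Series
    residual_df: int
    zero_variance: pd.Index  # genes reported with the F=0, p=1 convention

    def p(self, factor: str) -> pd.Series:
        return self.tables[factor]["p"]

    def fdr(self, factor: str) -> pd.Series:
        return fdr_adjust(self.tables[factor]["p"])


def _check_balance(design: pd.DataFrame, factors: list[str]) -> None:
    for i, f1 in enumerate(factors):
        for f2 in factors[i + 1:]:
            ct = pd.crosstab(design[f1], design[f2]).to_numpy()
            if ct.min() != ct.max():
                raise ValueError(
                    f"design is unbalanced for factors {f1!r} x {f2!r}; "
                    "balanced complete designs are required"
                )
    for f in factors:
        counts = design[f].value_counts()
        if counts.min() != counts.max():
            raise ValueError(f"design is unbalanced in factor {f!r}")


def genewise_anova(
    C: pd.DataFrame, design: pd.DataFrame, factors: list[str]
) -> AnovaResult:
    """Additive fixed-effects ANOVA per gene over a balanced design.

    ``C`` is the corrected gene x array matrix; ``design`` has one row per
    array with a ``sample_id`` column naming the matrix columns and one column
    per factor.  Genes with (numerically) zero total variance are reported
    with the convention F = 0, p = 1 and listed in ``zero_variance``.
    """
    d = design.set_index("sample_id").loc[C.columns]
    _check_balance(d.reset_index(), factors)

    Y = C.to_numpy(dtype=float)
    n = Y.shape[1]
    grand = Y.mean(axis=1, keepdims=True)
    total_ss = ((Y - grand) ** 2).sum(axis=1)
    zero = total_ss <= _ZERO_TOL * np.maximum(1.0, (Y**2).sum(axis=1))

    tables: dict[str, pd.DataFrame] = {}
    dfs: dict[str, int] = {}
    factor_ss_sum = np.zeros_like(total_ss)
    ss_store: dict[str, np.ndarray] = {}
    for f in factors:
        codes, levels = pd.factorize(d[f], sort=True)
        L = len(levels)
        ind = np.zeros((n, L))
        ind[np.arange(n), codes] = 1.0
        counts = ind.sum(axis=0)
        level_means = (Y @ ind) / counts
        ss = (counts * (level_means - grand) ** 2).sum(axis=1)
        ss_store[f] = ss
        dfs[f] = L - 1
        factor_ss_sum += ss

    residual_df = n - 1 - sum(dfs.values())
    if residual_df <= 0:
        raise ValueError("no residual degrees of freedom in this design")
    residual_ss = np.maximum(total_ss - factor_ss_sum, 0.0)
    ms_res = residual_ss / residual_df

    genes = C.index
    for f in factors:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_store[f] / dfs[f]) / ms_res
        p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isfinite(F), F, 0.0), dfs[f], residual_df))
        # exact zero residual with a real factor effect: F infinite, p = 0
        F = np.where(np.isnan(F), 0.0, F)
        F[zero] = 0.0
        p = np.asarray(p, dtype=float)
        p[zero] = 1.0
        tables[f] = pd.DataFrame({"ss": ss_store[f], "F": F, "p": p}, index=genes)

    return AnovaResult(
        factors=list(factors),
        tables=tables,
        dfs=dfs,
        residual_ss=pd.Series(residual_ss, index=genes),
        residual_df=residual_df,
        zero_variance=genes[zero],
    )


def fdr_adjust(p) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=float) if isinstance(p, pd.Series) else arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


@dataclass
class RateResult:
    """Per-gene mean patient/control expression rate with per-couple detail."""

    rates: pd.DataFrame  # index gene: rate, direction
    per_couple: pd.DataFrame  # gene x couple_id mean ratio (treatments averaged)


def expression_rate(C: pd.DataFrame, design: pd.DataFrame) -> RateResult:
    """Mean ratio of corrected log values, patient over matched control.

    Per couple and treatment the ratio ``corrected_patient / corrected_control``
    is formed; treatments are averaged within each couple (the study found the
    two conditions indistinguishable for the validated genes), then couples
    are averaged.  A couple whose control corrected value is 0 for a gene is
    excluded from that gene's mean.
    """
    d = design.set_index("sample_id").loc[C.columns]
    couples = sorted(d["couple_id"].unique())
    per_couple = {}
    for c in couples:
        sub = d[d["couple_id"] == c]
        ratios = []
        for t in sorted(sub["treatment"].unique()):
            pat = sub[(sub["role"] == "patient") & (sub["treatment"] == t)].index
            con = sub[(sub["role"] == "control") & (sub["treatment"] == t)].index
            if len(pat) != 1 or len(con) != 1:
                raise ValueError(f"couple {c!r} incomplete for treatment {t!r}")
            denom = C[con[0]].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                r = C[pat[0]].to_numpy() / denom
            r[denom == 0] = np.nan
            ratios.append(r)
        per_couple[c] = np.nanmean(np.vstack(ratios), axis=0)
    pc = pd.DataFrame(per_couple, index=C.index)
    rate = pc.mean(axis=1, skipna=True)
    direction = pd.Series(
        np.where(rate < 1, "under", np.where(rate > 1, "over", "neutral")), index=C.index
    )
    return RateResult(
        rates=pd.DataFrame({"rate": rate, "direction": direction}), per_couple=pc
    )


@dataclass
class SpecificGeneSet:
    """The disease-specific selection with per-stage counts and thresholds."""

    table: pd.DataFrame  # index gene: q_de, q_cross, rate, direction
    thresholds: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return self.table.index.tolist()

    @property
    def pct_under(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return 100.0 * float((self.table["rate"] < 1).sum()) / len(self.table)


def select_specific(
    q_de: pd.Series,
    q_cross: pd.Series,
    rates: RateResult,
    fdr_threshold: float = 0.0012,
    cross_threshold: float = 0.0012,
    rate_low: float = 0.9,
    rate_high: float = 1.05,
) -> SpecificGeneSet:
    """Intersect case-vs-control FDR, cross-cohort FDR, and rate thresholds.

    Selection = {q_de <= fdr_threshold} & {q_cross <= cross_threshold} &
    {rate <= rate_low or rate >= rate_high}.
    """
    genes = q_de.index
    for name, other in (("q_cross", q_cross), ("rates", rates.rates["rate"])):
        missing = genes.difference(other.index)
        if len(missing):
            raise ValueError(f"{name} missing genes: {missing.tolist()[:10]}")
    rate = rates.rates.loc[genes, "rate"]
    de_mask = q_de <= fdr_threshold
    cross_mask = q_cross.loc[genes] <= cross_threshold
    rate_mask = (rate <= rate_low) | (rate >= rate_high)
    sel = de_mask & cross_mask & rate_mask
    table = pd.DataFrame(
        {
            "q_de": q_de[sel],
            "q_cross": q_cross.loc[genes][sel],
            "rate": rate[sel],
            "direction": rates.rates.loc[genes, "direction"][sel],
        }
    ).sort_values("q_de")
    return SpecificGeneSet(
        table=table,
        thresholds={
            "fdr": fdr_threshold,
            "cross_fdr": cross_threshold,
            "rate_low": rate_low,
            "rate_high": rate_high,
        },
        stage_counts={
            "total": int(len(genes)),
            "de_pass": int(de_mask.sum()),
            "de_and_cross": int((de_mask & cross_mask).sum()),
            "selected": int(sel.sum()),
            "under": int((table["rate"] < 1).sum()),
            "over": int((table["rate"] > 1).sum()),
        },
    )
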
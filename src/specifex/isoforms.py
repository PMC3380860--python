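"""Splice-isoform ratio analysis: PLP/DM20 and GFAP pan/alpha/delta.

The assays measure PLP alone and PLP+DM20 together (common primers), so DM20
is extrapolated as (PLP+DM20) - PLP on the 2^-dCt expression scale; GFAP is
measured as pan-GFAP plus the alpha and delta splice isoforms.  Ratios are
computed per brain sample and then summarized per developmental stage and
disease group; mutated/control folds are tested with the Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr import mann_whitney, relative_expression

__all__ = ["plp_metrics", "gfap_metrics", "isoform_metrics", "stage_group_analysis", "StageTest"]

log = logging.getLogger(__name__)

PLP_RATIOS = ["plp_dm20_over_plp", "dm20_fraction"]
GFAP_RATIOS = ["pan_over_alpha", "pan_over_delta", "alpha_over_delta"]


def _expression_wide(panel_delta: pd.DataFrame, genes) -> pd.DataFrame:
    expr = relative_expression(panel_delta)
    meta_cols = [c for c in ("group", "stage") if c in expr.columns]
    wide = expr.pivot_table(index="sample_id", columns="gene", values="expression", aggfunc="first")
    missing = set(genes) - set(wide.columns)
    if missing:
        raise KeyError(f"isoform targets absent from panel: {sorted(missing)}")
    meta = expr.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    return meta.join(wide[list(genes)])


def plp_metrics(panel_delta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PLP-family expressions and derived splice ratios.

    ``dm20`` = (PLP+DM20) - PLP.  A censored target (expression 0) makes the
    dependent ratios undefined (NaN) with ``plp_flag`` set; an extrapolated
    negative DM20 (possible under noise) is likewise flagged, never clipped.
    """
    m = _expression_wide(panel_delta, ["PLP", "PLP_DM20"])
    plp, both = m["PLP"].to_numpy(), m["PLP_DM20"].to_numpy()
    dm20 = both - plp
    undefined = (plp <= 0) | (both <= 0)
    negative = ~undefined & (dm20 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m["dm20"] = dm20
        m["plp_dm20_over_plp"] = np.where(undefined | negative, np.nan, both / plp)
        m["dm20_fraction"] = np.where(undefined | negative, np.nan, dm20 / both)
    m["plp_flag"] = undefined | negative
    if negative.any():
        log.warning("negative extrapolated DM20 in %d samples; ratios excluded", int(negative.sum()))
    return m


def gfap_metrics(panel_delta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample GFAP isoform expressions and pan/alpha/delta ratios."""
    m = _expression_wide(panel_delta, ["GFAP_pan", "GFAP_alpha", "GFAP_delta"])
    pan, alpha, delta = (m[c].to_numpy() for c in ("GFAP_pan", "GFAP_alpha", "GFAP_delta"))
    with np.errstate(divide="ignore", invalid="ignore"):
        m["pan_over_alpha"] = np.where(alpha > 0, pan / alpha, np.nan)
        m["pan_over_delta"] = np.where(delta > 0, pan / delta, np.nan)
        m["alpha_over_delta"] = np.where(delta > 0, alpha / delta, np.nan)
    m["gfap_flag"] = (pan <= 0) | (alpha <= 0) | (delta <= 0)
    return m


def isoform_metrics(panel_delta: pd.DataFrame) -> pd.DataFrame:
    """Joined per-sample PLP and GFAP metrics."""
    plp = plp_metrics(panel_delta)
    gfap = gfap_metrics(panel_delta)
    extra = [c for c in gfap.columns if c not in ("group", "stage")]
    return plp.join(gfap[extra])


@dataclass
class StageTest:
    stage: str
    metric: str
    fold: float  # mean(mutated) / mean(control)
    n_mutated: int
    n_control: int
    U: float
    p: float  # NaN when a group has n = 1 (test not computable)


def stage_group_analysis(metrics: pd.DataFrame, metric: str, stage: str) -> StageTest:
    """Mutated/control fold of a per-sample metric at one stage, with U test."""
    sub = metrics[metrics["stage"] == stage]
    mut = sub.loc[sub["group"] == "mutated", metric].dropna()
    con = sub.loc[sub["group"] == "control", metric].dropna()
    if mut.empty or con.empty:
        raise ValueError(f"no samples in one group at stage {stage!r} for {metric!r}")
    cmean = float(con.mean())
    fold = float(mut.mean()) / cmean if cmean != 0 else float("nan")
    if cmean == 0:
        log.warning("control mean of %s is 0 at stage %s; fold undefined", metric, stage)
    if min(len(mut), len(con)) < 2:
        U, p = float("nan"), float("nan")
    else:
        U, p = mann_whitney(mut.to_numpy(), con.to_numpy())
    return StageTest(
        stage=stage, metric=metric, fold=fold,
        n_mutated=int(len(mut)), n_control=int(len(con)), U=U, p=p,
    )
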
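"""Replicate-level Ct processing, dCt/ddCt quantification, group tests.

Quantification follows standard 2^-ddCt kinetics: for a gene x and reference
gene(s), dCt = Ct_x - Ct_ref per sample; the patient/control expression rate
of a matched couple is 2^-(dCt_patient - dCt_control), treatments averaged
within couples when present, couples averaged per gene.  Censored reactions
(no amplification by the cycle cap) never enter means: a censored target is
reported as expression 0, a censored reference drops the sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "collapse_replicates",
    "delta_ct",
    "couple_expression_rate",
    "relative_expression",
    "mann_whitney",
]

log = logging.getLogger(__name__)

QC_SPREAD_CYCLES = 0.5  # replicate range above this is flagged, never dropped

_META_CANDIDATES = ["subject_id", "cohort", "couple_id", "role", "treatment", "group", "stage"]


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (sample, gene) over RT batches and PCR duplicates.

    Censored replicates are excluded from the mean; an all-censored pair
    yields a censored output record.  Replicate spread above
    ``QC_SPREAD_CYCLES`` sets ``qc_flag``.
    """
    meta = [c for c in _META_CANDIDATES if c in table.columns]
    rows = []
    for (sample, gene), grp in table.groupby(["sample_id", "gene"], sort=True):
        ok = grp.loc[~grp["censored"], "ct"]
        censored = ok.empty
        spread = float(ok.max() - ok.min()) if len(ok) > 1 else 0.0
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                **{m: grp[m].iloc[0] for m in meta},
                "ct": float("nan") if censored else float(ok.mean()),
                "n_replicates": int(len(ok)),
                "censored": censored,
                "qc_flag": spread > QC_SPREAD_CYCLES,
            }
        )
    out = pd.DataFrame(rows)
    n_flag = int(out["qc_flag"].sum())
    if n_flag:
        log.info("replicate spread > %.1f cycles for %d (sample, gene) pairs", QC_SPREAD_CYCLES, n_flag)
    return out


def delta_ct(mean_ct: pd.DataFrame, reference_genes) -> pd.DataFrame:
    """dCt of every non-reference gene against the reference gene(s).

    With several references the arithmetic mean of their Cts is subtracted
    (equivalent to normalizing expression by the geometric mean of the
    reference expressions).  Samples whose reference is censored are excluded
    with a warning.
    """
    refs = [reference_genes] if isinstance(reference_genes, str) else list(reference_genes)
    missing = set(refs) - set(mean_ct["gene"])
    if missing:
        raise KeyError(f"reference gene(s) absent from table: {sorted(missing)}")
    meta = [c for c in _META_CANDIDATES if c in mean_ct.columns]

    ref = mean_ct[mean_ct["gene"].isin(refs)]
    bad = ref.loc[ref["censored"], "sample_id"].unique()
    if len(bad):
        log.warning("censored reference in samples %s; excluded", list(bad))
    ref_ct = ref[~ref["sample_id"].isin(bad)].groupby("sample_id")["ct"].mean()

    tgt = mean_ct[~mean_ct["gene"].isin(refs) & ~mean_ct["sample_id"].isin(bad)].copy()
    tgt["delta_ct"] = tgt["ct"].to_numpy() - ref_ct.loc[tgt["sample_id"]].to_numpy()
    out = tgt[["sample_id", "gene", *meta, "delta_ct", "n_replicates", "censored"]].reset_index(drop=True)
    out.attrs["reference_genes"] = refs
    return out


def relative_expression(delta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample expression 2^-dCt; censored targets reported as 0, flagged."""
    out = delta.copy()
    out["expression"] = np.where(out["censored"], 0.0, np.exp2(-out["delta_ct"]))
    return out


def couple_expression_rate(delta: pd.DataFrame, design: pd.DataFrame | None = None):
    """Per-gene mean 2^-(dCt_patient - dCt_control) over matched couples.

    ``delta`` must carry (or be joinable via ``design`` on ``sample_id`` to)
    ``couple_id``, ``role`` and optionally ``treatment`` columns.  Couples
    with a censored member are skipped for that gene (logged).  Returns
    ``(rates, per_couple)``: a per-gene Series of mean rates and a gene x
    couple DataFrame of per-couple rates (treatments averaged) kept for the
    concordance analysis.
    """
    d = delta.copy()
    if design is not None:
        keep = [c for c in ("couple_id", "role", "treatment", "cohort") if c not in d.columns]
        d = d.merge(design[["sample_id", *keep]].drop_duplicates(), on="sample_id", how="left")
    for col in ("couple_id", "role"):
        if col not in d.columns:
            raise KeyError(f"delta table needs a {col!r} column (or a design to join)")
    if "treatment" not in d.columns:
        d["treatment"] = "single"

    skipped = 0
    per_couple: dict[tuple, dict] = {}
    for (gene, couple), grp in d.groupby(["gene", "couple_id"], sort=True):
        vals = []
        for _, sub in grp.groupby("treatment"):
            pat = sub[sub["role"] == "patient"]
            con = sub[sub["role"] == "control"]
            if len(pat) != 1 or len(con) != 1:
                raise ValueError(f"couple {couple!r} incomplete for gene {gene!r}")
            if bool(pat["censored"].iloc[0]) or bool(con["censored"].iloc[0]):
                skipped += 1
                continue
            ddct = float(pat["delta_ct"].iloc[0]) - float(con["delta_ct"].iloc[0])
            vals.append(2.0 ** (-ddct))
        if vals:
            per_couple.setdefault(gene, {})[couple] = float(np.mean(vals))
    if skipped:
        log.info("skipped %d censored couple/treatment pairs", skipped)
    pc = pd.DataFrame(per_couple).T
    pc.index.name = "gene"
    rates = pc.mean(axis=1, skipna=True)
    rates.name = "rate"
    return rates, pc


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the smaller group has <= 8
    observations and there are no ties, the tie-corrected normal approximation
    otherwise; the method used is recorded on the returned p (a plain tuple is
    returned: U statistic of group ``a`` and two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
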
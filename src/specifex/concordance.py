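"""Cross-platform validation: microarray vs qPCR per-couple agreement.

For each validated gene the per-couple microarray ratio (patient/control of
corrected log values, log-transformed) is correlated with the per-couple qPCR
ddCt; the squared Pearson coefficient R^2 is reported per cohort.  Couples
whose direction of change disagrees between platforms for most of the panel
are excluded before the correlation.  The difference between two cohorts'
correlations is tested with the Fisher Z transform:

    Zf = 1/2 ln((1+R)/(1-R))
    z = (Zf1 - Zf2) / sqrt(1/(N1-3) + 1/(N2-3))   ~  N(0,1)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "FisherZComparison",
    "cross_platform_correlation",
    "flag_discordant_couples",
    "fisher_z_compare",
]

log = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    gene: str
    cohort: str
    r: float
    r2: float
    n: int
    degenerate: bool = False  # zero variance in one vector: R reported as 0
    excluded_couples: tuple = ()


@dataclass
class FisherZComparison:
    zf1: float
    zf2: float
    z: float
    p: float


def cross_platform_correlation(
    micro: pd.Series, qpcr: pd.Series, gene: str = "", cohort: str = "", excluded=()
) -> ConcordanceResult:
    """Pearson correlation between aligned per-couple platform measurements.

    ``micro`` and ``qpcr`` are indexed by couple id; only shared couples are
    used and at least 4 are required (so the Fisher transform has N-3 > 0).
    Zero variance in either vector yields R = 0 with the ``degenerate`` flag.
    """
    common = micro.index.intersection(qpcr.index)
    x = micro.loc[common].astype(float).to_numpy()
    y = qpcr.loc[common].astype(float).to_numpy()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError(f"need >=4 paired couples, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance in a platform vector for %s/%s; R set to 0", gene, cohort)
        return ConcordanceResult(gene, cohort, 0.0, 0.0, len(x), degenerate=True,
                                 excluded_couples=tuple(excluded))
    r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceResult(gene, cohort, r, r * r, len(x), excluded_couples=tuple(excluded))


def flag_discordant_couples(
    micro_log_ratio: pd.DataFrame, qpcr_ddct: pd.DataFrame, k_threshold: int = 8
) -> list:
    """Couples whose direction disagrees between platforms for >= k genes.

    A couple is discordant for a gene when sign(microarray log ratio) differs
    from sign(-ddCt) (both measure the patient/control change on a log
    scale).  Inputs are gene x couple frames over the validation panel.
    """
    genes = micro_log_ratio.index.intersection(qpcr_ddct.index)
    if k_threshold > len(genes):
        raise ValueError(f"k_threshold {k_threshold} exceeds panel size {len(genes)}")
    couples = micro_log_ratio.columns.intersection(qpcr_ddct.columns)
    m = np.sign(micro_log_ratio.loc[genes, couples].to_numpy())
    q = np.sign(-qpcr_ddct.loc[genes, couples].to_numpy())
    disagreements = (m != q).sum(axis=0)
    excluded = [c for c, k in zip(couples, disagreements) if k >= k_threshold]
    if excluded:
        log.warning(
            "excluding couples discordant on >=%d/%d panel genes: %s",
            k_threshold, len(genes), excluded,
        )
    return excluded


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZComparison:
    """Fisher-Z test for the difference of two correlation coefficients."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(
                "|R| = 1 gives an infinite Fisher transform; cap R based on N "
                "(e.g. Hotelling correction) before comparing"
            )
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    zf1 = 0.5 * math.log((1 + r1) / (1 - r1))
    zf2 = 0.5 * math.log((1 + r2) / (1 - r2))
    z = (zf1 - zf2) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return FisherZComparison(zf1=zf1, zf2=zf2, z=z, p=p)
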
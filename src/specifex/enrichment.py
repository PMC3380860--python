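"""Z-score over-representation of gene categories in a hit list.

For a universe of N genes, a category of K members and a hit list of n genes
with k observed members of the category, the number of hits follows a
hypergeometric law under the null.  The z-score expresses the divergence of
the observed count from its expectation in standard-deviation units:

    mu = n K / N
    sigma^2 = n (K/N) (1 - K/N) (N - n) / (N - 1)
    z = (k - mu) / sigma

and a category is called significant when z > 3 (a plain standard-score rule,
with no multiple-testing adjustment; a flag adds BH q-values from the normal
tail for users who want them).  A binomial-approximation mode
(sigma^2 = n p (1-p)) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["CategoryMap", "EnrichmentResult", "parse_gmt", "zscore_enrichment"]

log = logging.getLogger(__name__)


@dataclass
class CategoryMap:
    """Category name -> member gene set over an explicit universe."""

    categories: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(f"category {name!r} has members outside the universe: {sorted(extra)[:5]}")


@dataclass
class EnrichmentResult:
    category: str
    N: int
    K: int
    n: int
    k: int
    z: float
    significant: bool


def parse_gmt(path, universe) -> CategoryMap:
    """Parse a GMT file (name, description, members...) against a universe.

    Duplicate members within a category are collapsed; members absent from the
    universe are dropped (counted in the log).  A line with fewer than three
    fields is a parse error.
    """
    uni = set(universe)
    cats: dict[str, set] = {}
    dropped = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"no categories in GMT file {path}")
    for lineno, line in enumerate(lines, 1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, members = parts[0], set(parts[2:])
        in_uni = members & uni
        dropped += len(members - uni)
        if in_uni:
            cats[name] = in_uni
        else:
            log.warning("category %s has no members in the universe; skipped", name)
    if dropped:
        log.info("dropped %d category members absent from the universe", dropped)
    if not cats:
        raise ValueError(f"no categories with universe members in {path}")
    return CategoryMap(categories=cats, universe=uni)


def zscore_enrichment(
    hits,
    cmap: CategoryMap,
    z_threshold: float = 3.0,
    method: str = "hypergeometric",
    add_q: bool = False,
) -> pd.DataFrame:
    """Score every category; results sorted by z descending.

    Categories with zero variance (K = 0 or K = N) are skipped with a warning.
    """
    hit_set = set(hits)
    extra = hit_set - cmap.universe
    if extra:
        raise ValueError(f"hits outside the universe: {sorted(extra)[:5]}")
    if method not in ("hypergeometric", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    N, n = len(cmap.universe), len(hit_set)
    rows = []
    for name, members in cmap.categories.items():
        K = len(members)
        k = len(hit_set & members)
        p = K / N
        mu = n * p
        if method == "hypergeometric":
            var = n * p * (1 - p) * (N - n) / (N - 1)
        else:
            var = n * p * (1 - p)
        if var <= 0:
            log.warning("category %s has zero variance (K=%d of N=%d); skipped", name, K, N)
            continue
        z = (k - mu) / math.sqrt(var)
        rows.append(
            EnrichmentResult(category=name, N=N, K=K, n=n, k=k, z=z, significant=z > z_threshold)
        )
    if not rows:
        return pd.DataFrame(columns=["category", "N", "K", "n", "k", "z", "significant"])
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values("z", ascending=False)
    if add_q and len(df):
        from .anova import fdr_adjust

        df["q"] = fdr_adjust(stats.norm.sf(df["z"].to_numpy()))
    return df.reset_index(drop=True)
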
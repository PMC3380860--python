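"""Two-channel normalization: log transform, reference correction, gene filter.

The study's reference design co-hybridizes each sample (Cy3-like channel G)
with a pooled-control reference (Cy5-like channel R) on the same slide.  All
downstream statistics consume the *corrected G log value*:

    corrected_gi = G_log_gi - R_log_gi + mean_a(R_log_ga)

i.e. the per-gene reference log intensity is subtracted array-by-array (which
removes slide and dye effects shared by the two channels) and the gene's mean
reference level across all arrays is added back, keeping the corrected values
on the absolute log-intensity scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["log_standardize", "reference_correct", "filter_characterized"]

log = logging.getLogger(__name__)

_LOG_BASES = {"e": np.e, "2": 2.0, "10": 10.0}


def log_standardize(
    M: pd.DataFrame, mode: str = "log", base: str = "e"
) -> pd.DataFrame:
    """Log-transform an intensity matrix, optionally z-scaling each array.

    Parameters
    ----------
    M : gene x array matrix of positive intensities.
    mode : ``"log"`` (transform only, the default) or ``"per-array"``
        (additionally center/scale each array column to mean 0, sd 1).
    base : logarithm base, one of ``"e"``, ``"2"``, ``"10"``.

    The reference-correction step already removes array-level effects, so the
    default applies no scaling beyond the log; the choice is recorded in the
    result's ``attrs`` provenance.
    """
    if base not in _LOG_BASES:
        raise ValueError(f"unknown log base {base!r}; choose from {sorted(_LOG_BASES)}")
    if mode not in ("log", "per-array"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    vals = M.to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        g, a = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at gene {M.index[g]!r}, array {M.columns[a]!r}"
        )
    out = np.log(vals) / np.log(_LOG_BASES[base])
    if mode == "per-array":
        out = (out - out.mean(axis=0)) / out.std(axis=0, ddof=0)
    res = pd.DataFrame(out, index=M.index, columns=M.columns)
    res.attrs["provenance"] = {"log_base": base, "standardization": mode}
    return res


def reference_correct(G: pd.DataFrame, R: pd.DataFrame) -> pd.DataFrame:
    """Apply the reference-correction formula to aligned log matrices.

    ``corrected = G - R + mean(R per gene)``, the gene-wise mean taken over
    all arrays present (all conditions of the experiment).
    """
    if not G.index.equals(R.index) or not G.columns.equals(R.columns):
        bad_genes = G.index.symmetric_difference(R.index).tolist()[:10]
        bad_arrays = G.columns.symmetric_difference(R.columns).tolist()[:10]
        raise ValueError(
            f"G/R not aligned; offending genes {bad_genes}, arrays {bad_arrays}"
        )
    mean_r = R.mean(axis=1)
    corrected = G.sub(R).add(mean_r, axis=0)
    corrected.attrs["provenance"] = dict(G.attrs.get("provenance", {}))
    corrected.attrs["provenance"]["reference_corrected"] = True
    return corrected


def filter_characterized(
    genes: pd.Index | list, annotation: pd.Series | dict, lenient: bool = False
) -> list:
    """Retain characterized genes, dropping EST and LOC entries.

    ``annotation`` maps gene id -> class in {characterized, EST, LOC}.  An
    unannotated gene raises unless ``lenient``, in which case it is kept with
    a warning.
    """
    ann = pd.Series(annotation)
    kept, removed = [], {"EST": 0, "LOC": 0}
    for g in genes:
        if g not in ann.index:
            if lenient:
                log.warning("gene %s has no annotation; kept (lenient)", g)
                kept.append(g)
                continue
            raise KeyError(f"gene {g!r} has no annotation class")
        c = ann[g]
        if c == "characterized":
            kept.append(g)
        elif c in removed:
            removed[c] += 1
        else:
            raise ValueError(f"unknown annotation class {c!r} for gene {g!r}")
    log.info("characterized-gene filter: kept %d, removed %d EST, %d LOC",
             len(kept), removed["EST"], removed["LOC"])
    return kept
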
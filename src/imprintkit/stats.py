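"""Shared downstream statistics: BH FDR, Stouffer combination and
MEG/PEG classification.  Every test method in the package (NB-GLM and
the two Fisher baselines) feeds its p-values through the same functions,
so calls are comparable across methods."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MEG, PEG, NONE = "MEG", "PEG", "none"

_P_FLOOR = np.finfo(float).tiny  # smallest positive normal double
_P_CEIL = 1.0 - 1e-16


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the number of
    tests m.  Adjusted values are monotone non-decreasing in p-rank and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if (p[mask] < 0).any() or (p[mask] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def stouffer_combine(p1, p2) -> np.ndarray:
    """Combine two p-values sharing a null hypothesis by Stouffer's
    method with equal weights: Z = (z1 + z2)/sqrt(2), z_i = Phi^-1(1-p_i),
    combined p = 1 - Phi(Z).

    p-values of exactly 0 (or 1) are clipped to the nearest representable
    value with a logged warning, as the normal quantile is infinite there.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    n_clipped = int(((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)).sum())
    if n_clipped:
        logger.warning("stouffer_combine: clipped %d boundary p-values", n_clipped)
    z1 = norm.isf(np.clip(p1, _P_FLOOR, _P_CEIL))
    z2 = norm.isf(np.clip(p2, _P_FLOOR, _P_CEIL))
    return norm.sf((z1 + z2) / np.sqrt(2.0))


def classify_imprinted(
    fdr,
    log2_fold_effect,
    fdr_level: float = 0.05,
) -> np.ndarray:
    """MEG/PEG/none calls.

    A gene is called when fdr < fdr_level; positive effect (maternal
    excess over the expected ratio) gives MEG, negative gives PEG.
    NaN fdr is never called.
    """
    fdr = np.asarray(fdr, dtype=float)
    eff = np.asarray(log2_fold_effect, dtype=float)
    call = np.full(fdr.shape, NONE, dtype=object)
    sig = np.less(fdr, fdr_level, where=~np.isnan(fdr), out=np.zeros(fdr.shape, bool))
    call[sig & (eff > 0)] = MEG
    call[sig & (eff < 0)] = PEG
    return call


def attach_calls(results: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Add fdr and call columns to a results frame with p_value and
    log2_fold_effect columns (shared downstream contract)."""
    results = results.copy()
    results["fdr"] = bh_fdr(results["p_value"].to_numpy())
    results["call"] = classify_imprinted(
        results["fdr"].to_numpy(),
        results["log2_fold_effect"].to_numpy(),
        fdr_level,
    )
    return results
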
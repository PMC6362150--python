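"""Fisher's-exact-test baselines for allelic imbalance.

Two classical approaches used by earlier plant imprinting studies:

* Fisher-summed: one two-sided Fisher's exact test per gene on the
  maternal/paternal counts summed over the reciprocal crosses.
* Fisher-combined: a Fisher test per cross, with the two p-values merged
  by Stouffer's Z (see :func:`imprintkit.stats.stouffer_combine`).

The 2x2 table compares observation to expectation.  Two constructions
are provided:

``margin`` (default)
    The gene's counts against the remainder of the library:
    ``[[m, p], [M - m, P - p]]`` with M, P the library-wide maternal and
    paternal totals.  Because most genes follow the expected allelic
    ratio, the library margin embodies the null expectation; this is the
    construction of the published studies the baseline emulates, and its
    large margin makes it nearly a one-sample test of the gene's
    proportion.

``expected``
    A pseudo-count column at the gene's own depth apportioned at the
    null ratio: ``[[m, p], [round(T*p0), T - round(T*p0)]]`` with
    T = m + p.  The expected column then carries as much sampling
    variance as the observation, making this variant conservative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .counts import AllelicCounts
from .stats import stouffer_combine

logger = logging.getLogger(__name__)

CONSTRUCTIONS = ("margin", "expected")


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for one 2x2 table (probability-mass
    criterion, as in R's fisher.test)."""
    return float(fisher_exact(np.asarray(table).reshape(2, 2))[1])


def _fisher_vector(m, p, m2, p2) -> np.ndarray:
    out = np.ones(len(m))
    for i, (a, b, c, d) in enumerate(zip(m, p, m2, p2)):
        if a + b == 0 or c + d == 0:
            continue  # degenerate table, p stays 1
        out[i] = fisher_exact([[a, b], [c, d]])[1]
    return out


def expected_split(total: np.ndarray, null_maternal_prop: float) -> tuple[np.ndarray, np.ndarray]:
    """Apportion totals at the null ratio, maternal = round(T * p0)."""
    em = np.rint(np.asarray(total) * null_maternal_prop).astype(np.int64)
    return em, np.asarray(total) - em


def fisher_vs_expectation(
    maternal: np.ndarray,
    paternal: np.ndarray,
    null_maternal_prop: float,
    construction: str = "margin",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene two-sided Fisher p-values against the null ratio.

    Returns (p_values, zero_total_flag); genes with no reads get p = 1
    and the flag set.
    """
    m = np.asarray(maternal, dtype=np.int64)
    p = np.asarray(paternal, dtype=np.int64)
    total = m + p
    zero = total == 0
    if zero.any():
        logger.warning("%d genes with zero total; p set to 1", int(zero.sum()))
    if construction == "margin":
        other_m = m.sum() - m
        other_p = p.sum() - p
    elif construction == "expected":
        other_m, other_p = expected_split(total, null_maternal_prop)
    else:
        raise ValueError(f"unknown construction {construction!r}")
    pvals = _fisher_vector(m, p, other_m, other_p)
    pvals[zero] = 1.0
    return pvals, zero


def fisher_summed(
    table: AllelicCounts,
    null_maternal_prop: float = 2.0 / 3.0,
    construction: str = "margin",
) -> pd.DataFrame:
    """Fisher's exact test on counts summed over the reciprocal crosses."""
    m = table.maternal().sum(axis=1).to_numpy()
    p = table.paternal().sum(axis=1).to_numpy()
    pvals, zero = fisher_vs_expectation(m, p, null_maternal_prop, construction)
    return pd.DataFrame(
        {"p_value": pvals, "zero_total": zero}, index=table.gene_ids
    )


def fisher_per_cross(
    table: AllelicCounts,
    null_maternal_prop: float = 2.0 / 3.0,
    construction: str = "margin",
) -> pd.DataFrame:
    """One Fisher test per gene and cross; columns p_<cross>, zero_<cross>."""
    out = {}
    for c in table.crosses:
        m = table.frame[f"maternal_{c}"].to_numpy()
        p = table.frame[f"paternal_{c}"].to_numpy()
        pvals, zero = fisher_vs_expectation(m, p, null_maternal_prop, construction)
        out[f"p_{c}"] = pvals
        out[f"zero_{c}"] = zero
    return pd.DataFrame(out, index=table.gene_ids)


def fisher_combined(
    table: AllelicCounts,
    null_maternal_prop: float = 2.0 / 3.0,
    construction: str = "margin",
    directional: bool = False,
) -> pd.DataFrame:
    """Per-cross Fisher tests combined by Stouffer's method.

    With ``directional=True`` the per-cross two-sided p-values are
    converted to signed one-sided z-scores by the direction of maternal
    excess before combining, so opposite-direction imbalance in the two
    crosses cancels instead of reinforcing; the naive two-sided
    combination (default) matches the classical usage.
    """
    if table.n_crosses != 2:
        raise ValueError("fisher_combined expects exactly two crosses")
    per = fisher_per_cross(table, null_maternal_prop, construction)
    c1, c2 = table.crosses
    p1, p2 = per[f"p_{c1}"].to_numpy(), per[f"p_{c2}"].to_numpy()
    if directional:
        from scipy.stats import norm

        signs = []
        for c in (c1, c2):
            m = table.frame[f"maternal_{c}"].to_numpy().astype(float)
            t = m + table.frame[f"paternal_{c}"].to_numpy()
            with np.errstate(invalid="ignore"):
                frac = np.where(t > 0, m / np.maximum(t, 1), null_maternal_prop)
            signs.append(np.where(frac >= null_maternal_prop, 1.0, -1.0))
        z1 = signs[0] * norm.isf(np.clip(p1 / 2.0, np.finfo(float).tiny, 1 - 1e-16))
        z2 = signs[1] * norm.isf(np.clip(p2 / 2.0, np.finfo(float).tiny, 1 - 1e-16))
        z = (z1 + z2) / np.sqrt(2.0)
        combined = 2.0 * norm.sf(np.abs(z))
    else:
        combined = stouffer_combine(p1, p2)
    out = per.copy()
    out["p_value"] = combined
    return out
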
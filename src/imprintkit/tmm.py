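"""Trimmed mean of M-values (TMM) library normalization.

Computes per-column normalization factors from a doubly trimmed,
precision-weighted mean of per-gene log count ratios against a reference
column.  Effective library sizes (raw library size x factor) serve as GLM
offsets downstream.  In endosperm data, where most genes follow the 2:1
maternal:paternal ratio, TMM keeps the ratio of maternal to paternal
effective library sizes within a cross at approximately 2, so the
expected allelic ratio is absorbed by normalization rather than by an
explicit offset.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _upper_quartiles(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    return np.quantile(counts / lib_sizes, 0.75, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
    a_cutoff: float,
) -> float:
    """TMM factor of one column against the reference column."""
    pos = (obs > 0) & (ref > 0)
    obs = obs[pos].astype(float)
    ref = ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))  # M values
    abs_e = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))  # A values
    # delta-method precision weights (binomial sampling variance of M)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
    a_cutoff: float = -1e10,
    ref_column: int | None = None,
) -> np.ndarray:
    """Normalization factors for the columns of a count matrix.

    Parameters
    ----------
    counts:
        genes x libraries integer matrix.
    lib_sizes:
        Raw library sizes; column sums by default.
    logratio_trim, sum_trim:
        Two-sided trim fractions on the log-ratios (M) and on the
        log-abundances (A).
    weighted:
        Use delta-method precision weights in the trimmed mean.
    ref_column:
        Reference library; by default the column whose 75% count
        quantile (scaled by library size) is closest to the mean over
        columns.

    Returns
    -------
    Factors rescaled to geometric mean 1, one per column.  Genes with a
    zero count in either of a compared pair of columns are excluded from
    that pair's factor estimate.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 columns")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    else:
        lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        bad = np.flatnonzero(lib_sizes <= 0)
        raise ValueError(f"library size is zero for column(s) {bad.tolist()}")
    if ref_column is None:
        f75 = _upper_quartiles(counts, lib_sizes)
        ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(
                counts[:, j],
                counts[:, ref_column],
                lib_sizes[j],
                lib_sizes[ref_column],
                logratio_trim,
                sum_trim,
                weighted,
                a_cutoff,
            )
            for j in range(counts.shape[1])
        ]
    )
    return factors / np.exp(np.mean(np.log(factors)))
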
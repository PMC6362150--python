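"""Imprinting test methods as scikit-learn style estimators.

Each estimator consumes an :class:`~imprintkit.counts.AllelicCounts`
table via ``fit`` and exposes a ``results_`` DataFrame with one row per
gene and the shared column contract::

    maternal_count, paternal_count, maternal_prop_observed,
    log2_fold_effect, p_value, fdr, call

so that FDR control, MEG/PEG classification and all benchmarking
operations are identical across methods.

* :class:`NBGLMImprintingTest` — the main method: TMM-normalized paired
  negative-binomial GLM with moderated (tagwise) dispersion and a
  likelihood-ratio test of the parent effect.
* :class:`FisherSummedTest` — Fisher's exact test on counts summed over
  the reciprocal crosses.
* :class:`FisherCombinedTest` — per-cross Fisher tests combined by
  Stouffer's Z.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nbglm
from .counts import AllelicCounts
from .fisher import fisher_combined, fisher_summed
from .stats import attach_calls
from .tmm import tmm_factors

logger = logging.getLogger(__name__)


def _as_counts(X) -> AllelicCounts:
    if isinstance(X, AllelicCounts):
        return X
    if isinstance(X, pd.DataFrame):
        return AllelicCounts(X)
    raise TypeError("expected an AllelicCounts table or its DataFrame")


class _ImprintingTestBase(BaseEstimator):
    """Shared plumbing: observed summaries, FDR and calls."""

    def _summaries(self, counts: AllelicCounts) -> pd.DataFrame:
        m = counts.maternal().sum(axis=1)
        p = counts.paternal().sum(axis=1)
        total = m + p
        with np.errstate(invalid="ignore"):
            prop = m / total.replace(0, np.nan)
        return pd.DataFrame(
            {
                "maternal_count": m,
                "paternal_count": p,
                "maternal_prop_observed": prop,
            },
            index=counts.gene_ids,
        )

    def _finish(self, results: pd.DataFrame) -> None:
        self.results_ = attach_calls(results, self.fdr_level)

    # convenience accessors over the fitted results
    @property
    def calls_(self) -> pd.Series:
        return self.results_["call"]

    @property
    def p_values_(self) -> pd.Series:
        return self.results_["p_value"]

    def predict(self, X=None) -> pd.Series:
        """MEG/PEG/none call per gene from the fitted results."""
        return self.calls_


class NBGLMImprintingTest(_ImprintingTestBase):
    """Paired negative-binomial GLM test of allelic imbalance.

    The two allelic counts of a cross are treated as paired samples: the
    design contains a blocking factor for the cross and the tested
    parent factor, and offsets are log effective library sizes.  Under
    TMM normalization (default) the tissue's expected allelic ratio is
    absorbed by the effective library sizes, which is valid when most
    genes follow that ratio genome-wide; ``normalization="offset"``
    instead encodes ``null_maternal_prop`` as an explicit fixed offset
    for datasets where the genome-wide assumption fails.

    Parameters
    ----------
    null_maternal_prop:
        Expected maternal read fraction under no imprinting
        (2/3 endosperm, 1/2 diploid tissues).
    fdr_level:
        BH FDR cut-off for MEG/PEG calls.
    dispersion_mode:
        "tagwise" (default), "trended" or "common".
    prior_df:
        Prior degrees of freedom of the empirical-Bayes shrinkage of
        tagwise dispersions toward the trend.
    fixed_dispersion:
        Bypass estimation and use this NB dispersion for every gene.
    normalization:
        "tmm" or "offset" (see above).

    Attributes
    ----------
    results_ : DataFrame with the shared column contract plus a
        ``dispersion`` column.
    norm_factors_, effective_lib_sizes_ : per-column normalization.
    common_dispersion_, trended_dispersion_, dispersion_ : estimates
        (as applicable to ``dispersion_mode``).
    """

    def __init__(
        self,
        null_maternal_prop: float = 2.0 / 3.0,
        fdr_level: float = 0.05,
        dispersion_mode: str = "tagwise",
        prior_df: float = 10.0,
        fixed_dispersion: float | None = None,
        normalization: str = "tmm",
    ):
        self.null_maternal_prop = null_maternal_prop
        self.fdr_level = fdr_level
        self.dispersion_mode = dispersion_mode
        self.prior_df = prior_df
        self.fixed_dispersion = fixed_dispersion
        self.normalization = normalization

    def _design(self, n_crosses: int) -> np.ndarray:
        """Rows follow the column order maternal_1, paternal_1, ...;
        intercept + cross blocking dummies + parent (maternal) term."""
        rows = []
        for c in range(n_crosses):
            for maternal in (1, 0):
                row = [1.0]
                row += [1.0 if c == k else 0.0 for k in range(1, n_crosses)]
                row.append(float(maternal))
                rows.append(row)
        return np.asarray(rows)

    def _offsets(self, counts: AllelicCounts, y: np.ndarray) -> np.ndarray:
        lib = y.sum(axis=0).astype(float)
        if np.any(lib == 0):
            raise ValueError("a library (column) has all-zero counts")
        if self.normalization == "tmm":
            self.norm_factors_ = tmm_factors(y, lib)
            self.effective_lib_sizes_ = lib * self.norm_factors_
        elif self.normalization == "offset":
            p0 = self.null_maternal_prop
            eff = np.empty_like(lib)
            for c in range(counts.n_crosses):
                n_c = lib[2 * c] + lib[2 * c + 1]
                eff[2 * c] = n_c * p0
                eff[2 * c + 1] = n_c * (1.0 - p0)
            self.norm_factors_ = eff / lib
            self.effective_lib_sizes_ = eff
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        return np.log(self.effective_lib_sizes_)

    def _dispersions(
        self, y: np.ndarray, design: np.ndarray, offset: np.ndarray
    ) -> np.ndarray:
        G = y.shape[0]
        if self.fixed_dispersion is not None:
            if self.fixed_dispersion <= 0:
                raise ValueError("fixed_dispersion must be > 0")
            return np.full(G, float(self.fixed_dispersion))
        abundance = nbglm.ave_log_cpm(y, self.effective_lib_sizes_)
        self.common_dispersion_ = nbglm.estimate_common_dispersion(y, design, offset)
        if self.dispersion_mode == "common":
            return np.full(G, self.common_dispersion_)
        trend = nbglm.estimate_trended_dispersion(y, design, offset, abundance)
        self.trended_dispersion_ = trend
        if self.dispersion_mode == "trended":
            return trend
        if self.dispersion_mode == "tagwise":
            return nbglm.estimate_tagwise_dispersion(
                y, design, offset, trend, abundance, prior_df=self.prior_df
            )
        raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")

    def fit(self, X, y=None) -> "NBGLMImprintingTest":
        counts = _as_counts(X)
        ymat = counts.matrix().astype(float)
        design = self._design(counts.n_crosses)
        offset = self._offsets(counts, ymat)
        phi = self._dispersions(ymat, design, offset)
        self.dispersion_ = phi
        coef = design.shape[1] - 1  # the parent term
        lrt = nbglm.likelihood_ratio_test(ymat, design, offset, phi, coef)
        n_bad = int((~lrt.converged).sum())
        if n_bad:
            logger.warning("%d genes did not converge; p set to NaN", n_bad)
        res = self._summaries(counts)
        res["log2_fold_effect"] = self._display_effect(counts, ymat, lrt.log2_fold)
        res["dispersion"] = phi
        res["p_value"] = lrt.p_value
        self._finish(res)
        return self

    def _display_effect(
        self, counts: AllelicCounts, y: np.ndarray, log2_fold: np.ndarray
    ) -> np.ndarray:
        """GLM parent coefficient in log2 units; genes with a parent
        entirely at zero get a 0.5-count working adjustment for a finite
        displayed effect (the test p-value uses the untouched fit)."""
        eff = self.effective_lib_sizes_
        m_cols = np.arange(0, y.shape[1], 2)
        p_cols = m_cols + 1
        m_zero = y[:, m_cols].sum(axis=1) == 0
        p_zero = y[:, p_cols].sum(axis=1) == 0
        degenerate = m_zero | p_zero
        if not degenerate.any():
            return log2_fold
        scale = np.exp(np.mean(np.log(eff)))
        m_rate = (y[:, m_cols] / eff[m_cols]).sum(axis=1) * scale
        p_rate = (y[:, p_cols] / eff[p_cols]).sum(axis=1) * scale
        adj = np.log2((m_rate + 0.5) / (p_rate + 0.5))
        return np.where(degenerate, adj, log2_fold)


class FisherSummedTest(_ImprintingTestBase):
    """Fisher's exact test on counts summed over reciprocal crosses.

    ``construction`` selects the 2x2 table: "margin" (gene vs rest of
    library; default) or "expected" (pseudo-count column at the gene's
    depth apportioned at the null ratio); see
    :mod:`imprintkit.fisher`.
    """

    def __init__(
        self,
        null_maternal_prop: float = 2.0 / 3.0,
        fdr_level: float = 0.05,
        construction: str = "margin",
    ):
        self.null_maternal_prop = null_maternal_prop
        self.fdr_level = fdr_level
        self.construction = construction

    def fit(self, X, y=None) -> "FisherSummedTest":
        counts = _as_counts(X)
        res = self._summaries(counts)
        fisher = fisher_summed(counts, self.null_maternal_prop, self.construction)
        res["log2_fold_effect"] = _ratio_effect(res, self.null_maternal_prop)
        res["p_value"] = fisher["p_value"]
        res["zero_total"] = fisher["zero_total"]
        self._finish(res)
        return self


class FisherCombinedTest(_ImprintingTestBase):
    """Per-cross Fisher tests merged by Stouffer's method.

    ``directional=True`` combines signed z-scores (by maternal excess)
    instead of the naive two-sided p-values, so that opposite-direction
    imbalance across crosses cancels.
    """

    def __init__(
        self,
        null_maternal_prop: float = 2.0 / 3.0,
        fdr_level: float = 0.05,
        construction: str = "margin",
        directional: bool = False,
    ):
        self.null_maternal_prop = null_maternal_prop
        self.fdr_level = fdr_level
        self.construction = construction
        self.directional = directional

    def fit(self, X, y=None) -> "FisherCombinedTest":
        counts = _as_counts(X)
        res = self._summaries(counts)
        comb = fisher_combined(
            counts, self.null_maternal_prop, self.construction, self.directional
        )
        res["log2_fold_effect"] = _ratio_effect(res, self.null_maternal_prop)
        res["p_value"] = comb["p_value"]
        for c in counts.crosses:
            res[f"p_{c}"] = comb[f"p_{c}"]
        self._finish(res)
        return self


def _ratio_effect(summaries: pd.DataFrame, null_maternal_prop: float) -> np.ndarray:
    """log2 maternal/paternal ratio relative to the null ratio, with a
    0.5 adjustment to stay finite at zero counts."""
    m = summaries["maternal_count"].to_numpy(float)
    p = summaries["paternal_count"].to_numpy(float)
    null_ratio = null_maternal_prop / (1.0 - null_maternal_prop)
    return np.log2((m + 0.5) / (p + 0.5) / null_ratio)


def test_parent_effect(counts, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`NBGLMImprintingTest`."""
    return NBGLMImprintingTest(**params).fit(counts).results_


def test_fisher_summed(counts, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`FisherSummedTest`."""
    return FisherSummedTest(**params).fit(counts).results_


def test_fisher_combined(counts, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`FisherCombinedTest`."""
    return FisherCombinedTest(**params).fit(counts).results_
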
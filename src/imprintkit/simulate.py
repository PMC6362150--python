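"""Synthetic allelic count tables with spike-in imprinted genes.

The generator reproduces the statistical structure that the downstream
tests assume for triploid endosperm: per-gene total read counts are
negative-binomially distributed around a log-normal baseline, and each
total is split between the maternal and paternal allele by binomial
sampling at the gene's true maternal proportion (2/3 at the null).
A configurable set of spike-in genes receives shifted maternal
proportions and defines ground truth for benchmarking.

Defaults follow the study conditions this package benchmarks against:
15,000 genes, two reciprocal crosses, log2 baseline ~ Normal(2, 3),
NB dispersion phi(mu) = 4/mu + 0.1, and 50 spike-ins each of strong MEGs
(99% maternal), weak MEGs (85%), strong PEGs (34%) and weak PEGs (48%).

Spike-in genes are drawn among genes whose simulated totals pass the
minimum-count filter of the analysis (>= 10 reads summed over crosses by
default).  Spiking only changes how a total is split between alleles, so
filter eligibility is fully determined by the totals and the restriction
is well defined; it guarantees that every spiked gene is assessable,
which is what makes true-positive rates on the spike-in panel
interpretable.  Set ``spike_eligible_only=False`` for unrestricted
spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .counts import AllelicCounts

NULL_CATEGORY = "null"
STRAIN_BIAS_CATEGORY = "strain_bias"

#: spike design of the standard benchmark: (category, n_genes, maternal proportion)
DEFAULT_SPIKE_DESIGN = (
    ("strong_MEG", 50, 0.99),
    ("weak_MEG", 50, 0.85),
    ("strong_PEG", 50, 0.34),
    ("weak_PEG", 50, 0.48),
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def default_dispersion(mu: np.ndarray) -> np.ndarray:
    """NB dispersion trend phi(mu) = 4/mu + 0.1 (the documented default of
    the count generator this simulation follows)."""
    return 4.0 / np.asarray(mu, dtype=float) + 0.1


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Attributes
    ----------
    n_genes:
        Number of simulated genes.
    intercept_mean, intercept_sd:
        Mean and SD of the per-gene log2 baseline expression beta0;
        the NB mean is mu = 2**beta0.
    dispersion_fn:
        Maps the NB mean to the NB dispersion phi (var = mu + phi*mu^2).
    n_crosses:
        Number of reciprocal crosses (biological replicates); >= 2.
    null_maternal_prop:
        True maternal read proportion of non-imprinted genes
        (2/3 for triploid endosperm).
    spike_design:
        Sequence of (category, n_genes, maternal_prop) spike-in groups.
    spike_eligible_only:
        Restrict spike-in genes to genes whose totals pass
        ``eligibility_min_total`` (see module docstring).
    eligibility_min_total:
        Count filter defining spike eligibility.
    n_strain_bias:
        Optional number of extra genes with an accession-specific
        expression bias (not imprinted: the favoured allele follows the
        accession, so the maternal proportion is high in one cross and
        low in the reciprocal one).
    strain_bias_log2fc:
        log2 expression fold change of the favoured accession's allele.
    seed:
        Master seed; identical seeds give identical datasets.
    """

    n_genes: int = 15000
    intercept_mean: float = 2.0
    intercept_sd: float = 3.0
    dispersion_fn: Callable[[np.ndarray], np.ndarray] = default_dispersion
    n_crosses: int = 2
    null_maternal_prop: float = 2.0 / 3.0
    spike_design: Sequence[tuple[str, int, float]] = DEFAULT_SPIKE_DESIGN
    spike_eligible_only: bool = True
    eligibility_min_total: int = 10
    n_strain_bias: int = 0
    strain_bias_log2fc: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_crosses < 2:
            raise ConfigurationError("n_crosses must be >= 2")
        if not 0.0 < self.null_maternal_prop < 1.0:
            raise ConfigurationError("null_maternal_prop must be in (0, 1)")
        n_spiked = sum(n for _, n, _ in self.spike_design)
        if n_spiked + self.n_strain_bias >= self.n_genes:
            raise ConfigurationError("spike design does not fit within n_genes")
        labels = [lab for lab, _, _ in self.spike_design]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate spike category labels")
        for lab, n, p in self.spike_design:
            if n < 0:
                raise ConfigurationError(f"negative gene count for {lab}")
            if not 0.0 < p < 1.0:
                raise ConfigurationError(
                    f"maternal proportion for {lab} must be in (0, 1)"
                )


@dataclass
class SimulatedDataset:
    """A simulated dataset: counts, ground truth and provenance."""

    counts: AllelicCounts
    truth: pd.DataFrame  # gene_id index: category, true_maternal_prop
    totals: np.ndarray  # genes x crosses
    config: SimulationConfig


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"gene{str(i + 1).zfill(width)}" for i in range(n)], name="gene_id")


def simulate_total_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the per-gene total allelic read counts, genes x crosses.

    Per gene g the baseline mean is mu_g = 2**beta0_g with
    beta0_g ~ Normal(intercept_mean, intercept_sd); totals for every cross
    are NB(mean=mu_g, dispersion=phi(mu_g)).  There is no differential
    expression between crosses and no outlier injection.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    beta0 = rng.normal(config.intercept_mean, config.intercept_sd, size=config.n_genes)
    mu = np.exp2(beta0)
    phi = np.asarray(config.dispersion_fn(mu), dtype=float)
    if phi.shape != mu.shape:
        phi = np.broadcast_to(phi, mu.shape).copy()
    if not np.all(np.isfinite(phi)) or np.any(phi <= 0):
        raise ConfigurationError("dispersion_fn must return finite values > 0")
    # NB(mean mu, dispersion phi) == NegativeBinomial(n=1/phi, p=1/(1+phi*mu))
    size = 1.0 / phi
    p = size / (size + mu)
    totals = rng.negative_binomial(
        size[:, None], p[:, None], size=(config.n_genes, config.n_crosses)
    )
    return totals.astype(np.int64)


def spike_imprinting(
    config: SimulationConfig,
    totals: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign spike-in categories and true maternal proportions.

    Returns the ground-truth table (index gene_id, columns ``category``
    and ``true_maternal_prop``).  Spiked gene sets are uniformly random
    and disjoint between categories.  When ``config.spike_eligible_only``
    is set, ``totals`` must be supplied and spiked genes are drawn among
    genes whose totals sum to at least ``config.eligibility_min_total``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    if config.spike_eligible_only and totals is None:
        raise ConfigurationError(
            "spike_eligible_only requires the simulated totals"
        )
    if config.spike_eligible_only:
        eligible = np.flatnonzero(totals.sum(axis=1) >= config.eligibility_min_total)
    else:
        eligible = np.arange(n)
    n_spiked = sum(ng for _, ng, _ in config.spike_design) + config.n_strain_bias
    if n_spiked > eligible.size:
        raise ConfigurationError(
            f"spike design needs {n_spiked} genes but only "
            f"{eligible.size} are eligible"
        )
    picked = rng.choice(eligible, size=n_spiked, replace=False)
    category = np.full(n, NULL_CATEGORY, dtype=object)
    prop = np.full(n, config.null_maternal_prop, dtype=float)
    start = 0
    for label, ng, p in config.spike_design:
        idx = picked[start : start + ng]
        if (category[idx] != NULL_CATEGORY).any():  # pragma: no cover
            raise RuntimeError("internal error: overlapping spike categories")
        category[idx] = label
        prop[idx] = p
        start += ng
    if config.n_strain_bias:
        idx = picked[start : start + config.n_strain_bias]
        category[idx] = STRAIN_BIAS_CATEGORY
        # strain-bias genes keep the null proportion *on average*; their
        # per-cross proportions are set in maternal_prob_matrix
        prop[idx] = config.null_maternal_prop
    return pd.DataFrame(
        {"category": category, "true_maternal_prop": prop}, index=_gene_ids(n)
    )


def maternal_prob_matrix(truth: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Per-gene, per-cross maternal success probabilities.

    For imprinted and null genes the probability equals
    ``true_maternal_prop`` in every cross.  For strain-bias genes the
    allele of one accession is over-expressed by ``strain_bias_log2fc``:
    with null ratio r = p0/(1-p0) and fold change f, the maternal odds
    are r*f when that accession is the mother (odd crosses) and r/f when
    it is the father (even crosses).
    """
    probs = np.repeat(
        truth["true_maternal_prop"].to_numpy()[:, None], config.n_crosses, axis=1
    )
    biased = truth["category"].to_numpy() == STRAIN_BIAS_CATEGORY
    if biased.any():
        p0 = config.null_maternal_prop
        f = 2.0 ** config.strain_bias_log2fc
        odds = p0 / (1.0 - p0)
        hi = odds * f / (1.0 + odds * f)
        lo = odds / f / (1.0 + odds / f)
        for c in range(config.n_crosses):
            probs[biased, c] = hi if c % 2 == 0 else lo
    return probs


def split_alleles(
    totals: np.ndarray,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> AllelicCounts:
    """Binomially split each total into maternal and paternal reads."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    totals = np.asarray(totals)
    if (totals < 0).any():
        raise ValueError("totals must be non-negative")
    probs = maternal_prob_matrix(truth, config)
    maternal = rng.binomial(totals, probs)
    paternal = totals - maternal
    crosses = [str(c + 1) for c in range(totals.shape[1])]
    return AllelicCounts.from_arrays(truth.index, maternal, paternal, crosses)


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Run the full generator: totals -> spike-in truth -> allelic split.

    All randomness flows from ``config.seed``; identical configurations
    produce identical datasets.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    totals = simulate_total_counts(config, rng)
    truth = spike_imprinting(config, totals, rng)
    counts = split_alleles(totals, truth, config, rng)
    return SimulatedDataset(counts=counts, truth=truth, totals=totals, config=config)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
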
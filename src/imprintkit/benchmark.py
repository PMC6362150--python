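"""Benchmarking imprinting callers on simulated truth, plus concordance
and saturation analyses.

Truth-based evaluation treats the spike-in genes as the positive class
and all remaining genes as negatives.  Genes removed by the minimum
count filter are treated as "not called" (they score 1 in ROC sweeps),
so true-positive rates are always reported against the full spike-in
panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .counts import AllelicCounts
from .simulate import NULL_CATEGORY
from .stats import MEG, PEG


def _spiked_mask(truth: pd.DataFrame) -> pd.Series:
    return truth["category"] != NULL_CATEGORY


@dataclass
class BenchmarkSummary:
    """Truth-based evaluation of one method's calls."""

    n_true_positives: int
    n_false_positives: int
    tpr: float
    fpr: float
    n_spiked: int
    n_null: int
    category_tpr: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "n_true_positives": self.n_true_positives,
            "n_false_positives": self.n_false_positives,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "n_spiked": self.n_spiked,
            "n_null": self.n_null,
        }
        for cat, v in self.category_tpr.items():
            out[f"tpr_{cat}"] = v
        return out


def _called_genes(calls, truth: pd.DataFrame) -> pd.Index:
    """Normalize calls to an index of called genes and check the universe."""
    if isinstance(calls, pd.Series):
        called = calls.index[calls.isin([MEG, PEG])] if calls.dtype == object else calls.index[calls.astype(bool)]
    else:
        called = pd.Index(calls)
    unknown = called.difference(truth.index)
    if len(unknown):
        raise ValueError(
            f"calls contain {len(unknown)} genes absent from the truth table, "
            f"e.g. {list(unknown[:3])}"
        )
    return called


def evaluate_calls(calls, truth: pd.DataFrame) -> BenchmarkSummary:
    """Score MEG/PEG calls against simulated truth.

    Parameters
    ----------
    calls:
        Either a Series of MEG/PEG/none call labels (or booleans) indexed
        by gene — typically ``tester.results_["call"]`` on the filtered
        table — or an iterable of called gene ids.  Genes of the truth
        universe missing from ``calls`` count as not called.
    truth:
        Ground-truth table over the full gene universe (columns
        ``category``, ``true_maternal_prop``).

    A spiked gene called in either direction is a true positive; a null
    gene called is a false positive.  TPR uses all spiked genes as the
    denominator and FPR all null genes.
    """
    called = _called_genes(calls, truth)
    spiked = _spiked_mask(truth)
    is_called = truth.index.isin(called)
    tp = int((is_called & spiked).sum())
    fp = int((is_called & ~spiked).sum())
    n_spiked = int(spiked.sum())
    n_null = int((~spiked).sum())
    category_tpr = {}
    for cat, sub in truth[spiked].groupby("category", sort=True):
        category_tpr[cat] = float(sub.index.isin(called).mean())
    return BenchmarkSummary(
        n_true_positives=tp,
        n_false_positives=fp,
        tpr=tp / n_spiked if n_spiked else np.nan,
        fpr=fp / n_null if n_null else np.nan,
        n_spiked=n_spiked,
        n_null=n_null,
        category_tpr=category_tpr,
    )


def roc_curve(scores: pd.Series, truth: pd.DataFrame):
    """ROC over all score thresholds; scores are p-values (smaller means
    more confidently imprinted).  Genes of the truth universe missing
    from ``scores`` (filtered out before testing) score 1.

    Returns (fpr, tpr, thresholds, auc); endpoints are (0,0) and (1,1).
    """
    s = scores.reindex(truth.index).fillna(1.0)
    y_true = _spiked_mask(truth).to_numpy()
    fpr, tpr, thr = _sk_roc_curve(y_true, -s.to_numpy())
    return fpr, tpr, -thr, float(_auc(fpr, tpr))


def binned_tpr(
    calls,
    truth: pd.DataFrame,
    counts_total: pd.Series,
    n_bins: int = 4,
) -> pd.DataFrame:
    """TPR/FPR within equal-size count bins (quartiles by default).

    Genes are ranked by total allelic count with ties broken by gene id,
    so ties go to the lower bin deterministically.  Bins with no spiked
    (or no null) genes report NaN rates.  ``counts_total`` defines the
    assessed universe (typically the genes passing the count filter).
    """
    order = counts_total.sort_values(kind="stable").index
    bins = np.array_split(np.arange(len(order)), n_bins)
    called = _called_genes(calls, truth)
    spiked = _spiked_mask(truth)
    rows = []
    for b, idx in enumerate(bins):
        genes = order[idx]
        t = truth.loc[truth.index.intersection(genes)]
        sp = spiked.loc[t.index]
        is_called = t.index.isin(called)
        n_sp = int(sp.sum())
        n_nu = int((~sp).sum())
        rows.append(
            {
                "bin": b + 1,
                "count_min": counts_total.loc[genes].min() if len(genes) else np.nan,
                "count_max": counts_total.loc[genes].max() if len(genes) else np.nan,
                "n_genes": len(genes),
                "n_spiked": n_sp,
                "tpr": float((is_called & sp).sum() / n_sp) if n_sp else np.nan,
                "fpr": float((is_called & ~sp).sum() / n_nu) if n_nu else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def top_n(
    results: pd.DataFrame,
    n: int,
    direction: str = MEG,
    min_maternal_frac: float | None = None,
    max_maternal_frac: float | None = None,
) -> list[str]:
    """The n statistically strongest candidates in one direction.

    Results are ranked by p-value, then by decreasing absolute effect,
    then by gene id (fully deterministic).  ``direction`` is "MEG"
    (maternal excess, positive effect) or "PEG".  The optional maternal
    fraction bounds reproduce the allelic-bias post-filters used when
    comparing top candidate lists across datasets (e.g. >= 0.85 for
    MEGs, <= 0.5 for PEGs).  If fewer than n genes qualify, all are
    returned.
    """
    if direction == MEG:
        cand = results[results["log2_fold_effect"] > 0]
    elif direction == PEG:
        cand = results[results["log2_fold_effect"] < 0]
    else:
        raise ValueError("direction must be 'MEG' or 'PEG'")
    frac = cand["maternal_prop_observed"]
    if min_maternal_frac is not None:
        cand = cand[frac >= min_maternal_frac]
    if max_maternal_frac is not None:
        cand = cand[cand["maternal_prop_observed"] <= max_maternal_frac]
    key = pd.DataFrame(
        {
            "gene_id": cand.index,
            "p": cand["p_value"].fillna(1.0).to_numpy(),
            "neg_abs_eff": -cand["log2_fold_effect"].abs().to_numpy(),
        }
    )
    ranked = key.sort_values(["p", "neg_abs_eff", "gene_id"], kind="stable")
    return list(ranked["gene_id"][:n])


@dataclass
class ConcordanceSummary:
    jaccard: pd.DataFrame  # pairwise Jaccard indices
    venn: dict[frozenset, int]  # exclusive region -> gene count
    non_shared: dict[str, float]  # per set: fraction in no other set

    def venn_table(self) -> pd.DataFrame:
        rows = [
            {"sets": "&".join(sorted(k)), "n_genes": v}
            for k, v in sorted(self.venn.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def concordance(sets: Mapping[str, set]) -> ConcordanceSummary:
    """Pairwise Jaccard indices, exclusive Venn region counts and the
    proportion of non-shared genes per set."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two gene sets")
    sets = {k: set(v) for k, v in sets.items()}
    jac = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in combinations(names, 2):
        union = sets[a] | sets[b]
        j = len(sets[a] & sets[b]) / len(union) if union else np.nan
        jac.loc[a, b] = jac.loc[b, a] = j
    np.fill_diagonal(jac.values, 1.0)
    universe = set().union(*sets.values())
    venn: dict[frozenset, int] = {}
    for gene in universe:
        member = frozenset(k for k in names if gene in sets[k])
        venn[member] = venn.get(member, 0) + 1
    non_shared = {}
    for k in names:
        others = set().union(*(sets[o] for o in names if o != k))
        non_shared[k] = (
            len(sets[k] - others) / len(sets[k]) if sets[k] else np.nan
        )
    return ConcordanceSummary(jaccard=jac, venn=venn, non_shared=non_shared)


def binomial_thin(
    counts: AllelicCounts, proportion: float, rng: np.random.Generator
) -> AllelicCounts:
    """Random subsample of the count table: every cell is binomially
    thinned at the given proportion (1.0 returns the table unchanged)."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must be in (0, 1]")
    if proportion == 1.0:
        return counts
    frame = counts.frame.copy()
    frame[:] = rng.binomial(counts.frame.to_numpy().astype(np.int64), proportion)
    return AllelicCounts(frame)


def saturation(
    table: AllelicCounts,
    proportions: Sequence[float],
    pipeline: Callable[[AllelicCounts], pd.DataFrame],
    n_reps: int = 10,
    min_total: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequencing-depth saturation analysis by count subsampling.

    For each subsampling proportion q, the table is binomially thinned
    ``n_reps`` times; each replicate is re-filtered at ``min_total`` and
    re-analysed with ``pipeline`` (an AllelicCounts -> results-frame
    callable, e.g. ``NBGLMImprintingTest().fit(...).results_``), and the
    numbers of callable genes, MEGs and PEGs are averaged.  q = 1.0 is
    deterministic and reproduces the full-data analysis exactly, so it
    runs once.

    Returns a frame indexed by proportion with mean and standard error
    of callable genes, MEG calls and PEG calls.
    """
    master = np.random.default_rng(seed)
    rows = []
    for q in proportions:
        reps = 1 if q == 1.0 else n_reps
        meg, peg, callable_n = [], [], []
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2**31))
            thinned = binomial_thin(table, q, rng).filter_min_total(min_total)
            if len(thinned) == 0:
                meg.append(0)
                peg.append(0)
                callable_n.append(0)
                continue
            res = pipeline(thinned)
            meg.append(int((res["call"] == MEG).sum()))
            peg.append(int((res["call"] == PEG).sum()))
            callable_n.append(len(res))
        rows.append(
            {
                "proportion": q,
                "n_reps": reps,
                "callable_mean": np.mean(callable_n),
                "callable_se": _se(callable_n),
                "meg_mean": np.mean(meg),
                "meg_se": _se(meg),
                "peg_mean": np.mean(peg),
                "peg_se": _se(peg),
            }
        )
    return pd.DataFrame(rows).set_index("proportion")


def _se(x) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def run_standard_benchmark(
    seed: int,
    min_total: int = 10,
    high_min_total: int = 50,
    fdr_level: float = 0.05,
) -> dict:
    """One full run of the spike-in simulation benchmark.

    Simulates the standard dataset (15,000 genes, two reciprocal
    crosses, 200 spike-ins), applies the minimum-count filter, runs the
    three test methods (paired NB-GLM, Fisher-summed, Fisher-combined)
    and scores them against truth.  The NB-GLM is additionally re-run
    with a stricter ``high_min_total`` filter to measure how sensitivity
    depends on the count cut-off.

    Returns a flat dict of metrics: per-method true/false positives,
    overall and per-category TPR, the number of spike-ins missed by all
    methods, per-method count-quartile TPRs, and the strict-filter TPR.
    """
    from .simulate import simulate_dataset
    from .testers import FisherCombinedTest, FisherSummedTest, NBGLMImprintingTest

    ds = simulate_dataset(seed=seed)
    kept = ds.counts.filter_min_total(min_total)
    truth = ds.truth
    testers = {
        "nbglm": NBGLMImprintingTest(fdr_level=fdr_level),
        "fisher_summed": FisherSummedTest(fdr_level=fdr_level),
        "fisher_combined": FisherCombinedTest(fdr_level=fdr_level),
    }
    out: dict = {"seed": seed, "n_genes": ds.config.n_genes, "n_kept": len(kept)}
    detected: dict[str, set] = {}
    totals = kept.totals()
    for name, tester in testers.items():
        tester.fit(kept)
        calls = tester.results_["call"]
        summary = evaluate_calls(calls, truth)
        detected[name] = set(calls.index[calls.isin([MEG, PEG])])
        out[f"{name}_tp"] = summary.n_true_positives
        out[f"{name}_fp"] = summary.n_false_positives
        out[f"{name}_tpr"] = summary.tpr
        for cat, v in summary.category_tpr.items():
            out[f"{name}_tpr_{cat}"] = v
        quart = binned_tpr(calls, truth, totals, n_bins=4)
        out[f"{name}_quartile_tpr"] = quart["tpr"].tolist()
    spiked = set(truth.index[truth["category"] != NULL_CATEGORY])
    union = set().union(*detected.values()) & spiked
    out["spiked_missed_by_all"] = len(spiked) - len(union)
    strict = ds.counts.filter_min_total(high_min_total)
    nb_strict = NBGLMImprintingTest(fdr_level=fdr_level).fit(strict)
    out["nbglm_tpr_strict_filter"] = evaluate_calls(
        nb_strict.results_["call"], truth
    ).tpr
    return out
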
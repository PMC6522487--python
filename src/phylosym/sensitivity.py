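"""Intra-species sensitivity framework.

Many host species contribute several samples but the host tree carries no
within-species resolution, so every hypothesis test is repeated on S
random subsets of the data, each keeping exactly one sample per host
species (or per family).  Within each subset the test's p-value family is
Benjamini-Hochberg adjusted, and a hypothesis is declared significant
overall only if at least ``frac`` (default 95%) of subsets are
individually significant at ``alpha`` — a deliberately conservative
aggregation that is robust to intra-species heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SampleMetadata


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj p_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class SubsampleSet:
    """S subsets of sample IDs, one sample per host unit each."""

    subsets: list[list[str]]
    unit: str
    seed: int

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def make_subsets(metadata: SampleMetadata, unit: str = "species",
                 n_subsets: int = 100, seed: int = 0) -> SubsampleSet:
    """Draw S subsets, each one uniformly chosen sample per unit.

    ``unit`` is "species" or "family".  Deterministic given ``seed``;
    subsets are drawn independently of one another.
    """
    if n_subsets <= 0:
        raise ValueError("n_subsets must be positive")
    groups = metadata.samples_by_unit(unit)
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        chosen = [samples[rng.integers(len(samples))]
                  for samples in groups.values()]
        subsets.append(chosen)
    return SubsampleSet(subsets=subsets, unit=unit, seed=seed)


@dataclass(frozen=True)
class SensitivityResult:
    """Aggregated outcome of a test run on every subset.

    ``subset_p`` / ``subset_adjusted_p`` are subsets x hypotheses frames;
    ``fraction_significant`` and ``significant`` aggregate per hypothesis
    with the >= ``frac`` rule.  Failed subsets count in the denominator
    (conservative) and appear as NaN rows.
    """

    subset_p: pd.DataFrame
    subset_adjusted_p: pd.DataFrame
    subset_statistics: pd.DataFrame
    fraction_significant: pd.Series
    significant: pd.Series
    alpha: float
    frac: float
    n_failed: int

    def summary(self) -> pd.DataFrame:
        stats = self.subset_statistics
        rows = []
        for hyp in self.fraction_significant.index:
            row = {
                "hypothesis": hyp,
                "fraction_significant": self.fraction_significant[hyp],
                "significant": bool(self.significant[hyp]),
                "median_p": float(self.subset_p[hyp].median()),
            }
            if hyp in stats.columns:
                row["median_statistic"] = float(stats[hyp].median())
                row["iqr_statistic"] = float(stats[hyp].quantile(0.75)
                                             - stats[hyp].quantile(0.25))
            rows.append(row)
        return pd.DataFrame(rows)


def run_sensitivity(test, subsets: SubsampleSet, alpha: float = 0.05,
                    frac: float = 0.95) -> SensitivityResult:
    """Run ``test`` on every subset and aggregate with the >= frac rule.

    ``test(sample_ids)`` must return a dict with key ``"p"`` mapping
    hypothesis names to raw p-values (the BH family) and optionally
    ``"statistics"`` mapping the same or other names to real statistics.
    A hypothesis is flagged significant iff the fraction of subsets with
    BH-adjusted p < alpha is at least ``frac``.
    """
    p_rows, stat_rows = [], []
    n_failed = 0
    for sample_ids in subsets.subsets:
        try:
            out = test(list(sample_ids))
            p_rows.append(pd.Series(out["p"], dtype=float))
            stat_rows.append(pd.Series(out.get("statistics", {}), dtype=float))
        except Exception:
            n_failed += 1
            p_rows.append(pd.Series(dtype=float))
            stat_rows.append(pd.Series(dtype=float))
    subset_p = pd.DataFrame(p_rows).reset_index(drop=True)
    subset_stats = pd.DataFrame(stat_rows).reset_index(drop=True)

    adj_rows = []
    for _, row in subset_p.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        adj = np.full(len(vals), np.nan)
        if ok.any():
            adj[ok] = bh_adjust(vals[ok])
        adj_rows.append(pd.Series(adj, index=row.index))
    subset_adj = pd.DataFrame(adj_rows).reset_index(drop=True)

    n_total = subsets.n_subsets
    frac_sig = (subset_adj < alpha).sum(axis=0) / n_total
    flags = frac_sig >= frac
    return SensitivityResult(
        subset_p=subset_p,
        subset_adjusted_p=subset_adj,
        subset_statistics=subset_stats,
        fraction_significant=frac_sig,
        significant=flags,
        alpha=alpha,
        frac=frac,
        n_failed=n_failed,
    )
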
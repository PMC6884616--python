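"""Shared statistics layer: exact 2x2 tests, rank-sum tests, BH correction.

Every association test in the package routes through these functions so
that sidedness and the exact procedure used are recorded uniformly.
Enrichment-style tests default to one-sided "greater" because the
hypotheses tested are directional (duplicated OGs enriched in a set,
duplicated OGs more often upregulated); two-sided is available everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
]

_ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled 2x2 count table.

    Rows conventionally hold the exposure (e.g. duplicated vs background),
    columns the outcome (e.g. in-set vs out-of-set).
    """

    counts: np.ndarray
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (2, 2):
            raise ValueError(f"contingency table must be 2x2, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("contingency table entries must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table must contain at least one count")
        object.__setattr__(self, "counts", arr)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ContingencyTable(rows={self.row_labels}, cols={self.col_labels},\n"
            f"{self.counts})"
        )


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    odds_ratio: float
    alternative: str
    table: ContingencyTable


def fisher_exact_2x2(
    table: ContingencyTable | np.ndarray,
    alternative: str = "greater",
) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The p-value is the exact hypergeometric tail; the reported odds ratio is
    the conditional maximum-likelihood estimate (the estimate conditioned on
    the table margins), which stays finite unless a margin is degenerate.
    Two-sided p sums the probabilities of all tables with fixed margins whose
    probability does not exceed that of the observed table.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    _, p = _sps.fisher_exact(table.counts, alternative=alternative)
    try:
        or_hat = float(_odds_ratio(table.counts, kind="conditional").statistic)
    except ValueError:  # degenerate margin
        or_hat = float("nan")
    return FisherResult(float(p), or_hat, alternative, table)


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = "two-sided",
):
    """Wilcoxon (Mann-Whitney) rank-sum test.

    Exact null enumeration is used when ``len(x) + len(y) <= 20`` and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections. Returns ``(statistic, pvalue)`` where the
    statistic is the Mann-Whitney U of ``x``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values (e.g. non-converged fits) are passed through as NaN and do
    not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
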
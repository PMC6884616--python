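"""Expression breadth: the tau tissue-specificity index and its comparison
across duplication categories.

tau = sum_i (1 - x_i) / (N - 1), where the profile components x_i are
normalized by the maximal component and N is the number of tissues; tau = 1
means single-tissue expression, tau = 0 ubiquitous expression. Profiles are
TMM-normalized log2 cpm clipped at 0 (tau assumes non-negative components);
replicates are averaged per tissue before the index is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import compute_cpm, tmm_factors
from .orthology import DuplicationClass, OrthologyTable
from .stats import wilcoxon_rank_sum

__all__ = [
    "tau",
    "tau_profiles",
    "tissue_panel_tau",
    "categorize_genes",
    "tau_by_category",
]


def tau(profile) -> float:
    """tau of one non-negative profile (one value per tissue)."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be 1-D with at least 2 tissues")
    if (x < 0).any():
        raise ValueError("profile components must be non-negative")
    m = x.max()
    if m == 0:
        raise ValueError("all-zero profile: tau undefined")
    return float((1.0 - x / m).sum() / (x.size - 1))


def tau_profiles(mat: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Row-wise tau for a gene x tissue matrix.

    All-zero genes are excluded; their ids are returned alongside.
    """
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    x = mat.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("profile components must be non-negative")
    m = x.max(axis=1)
    ok = m > 0
    vals = np.full(x.shape[0], np.nan)
    vals[ok] = (1.0 - x[ok] / m[ok, None]).sum(axis=1) / (x.shape[1] - 1)
    excluded = mat.index[~ok].tolist()
    return pd.Series(vals[ok], index=mat.index[ok], name="tau"), excluded


def tissue_panel_tau(
    counts: pd.DataFrame,
    tissue_of_sample: pd.Series,
    log_offset: float = 0.0,
    gene_to_og: pd.Series | None = None,
) -> tuple[pd.Series, list[str]]:
    """tau from a raw gene x sample tissue-panel count matrix.

    cpm are TMM-normalized, log2-transformed (optionally log2(cpm + offset)),
    clipped at 0, averaged over replicates per tissue, and fed to tau.
    Passing ``gene_to_og`` sums counts per OG first, giving an OG-level tau
    instead of the default per-gene one.
    """
    if gene_to_og is not None:
        shared = counts.index.intersection(gene_to_og.index)
        counts = counts.loc[shared].groupby(gene_to_og[shared].to_numpy()).sum()
        counts.index.name = "og_id"
    cpm = compute_cpm(counts)
    norm = tmm_factors(counts)
    cpm = cpm / norm.factors[cpm.columns]
    with np.errstate(divide="ignore"):
        logx = np.log2(cpm + log_offset)
    logx = logx.clip(lower=0.0)
    per_tissue = logx.T.groupby(tissue_of_sample[logx.columns]).mean().T
    return tau_profiles(per_tissue)


def categorize_genes(
    table: OrthologyTable, dup: DuplicationClass, species: str | None = None
) -> pd.Series:
    """Gene -> category: duplicated-OG member, non-duplicated-OG member
    (background excluding strict one-to-one), or one-to-one ortholog
    (single copy in every species). Genes of intermediate OGs are excluded
    (NaN). ``species`` restricts to one species' genes."""
    cats = {}
    for og, d in table.groups.items():
        lab = dup.labels.get(og, "intermediate")
        counts = [len(d.get(sp, ())) for sp in table.species]
        if lab == "duplicated":
            cat = "duplicated"
        elif lab == "background":
            cat = "one_to_one" if all(c == 1 for c in counts) else "non_duplicated"
        else:
            cat = None
        for sp, genes in d.items():
            if species is not None and sp != species:
                continue
            for g in genes:
                cats[g] = cat
    out = pd.Series(cats, name="category", dtype=object)
    return out


@dataclass
class TauComparison:
    medians: pd.Series
    pairwise: pd.DataFrame  # category_a, category_b, n_a, n_b, statistic, pvalue


def tau_by_category(
    tau_values: pd.Series, categories: pd.Series, alternative: str = "two-sided"
) -> TauComparison:
    """Median tau per category plus pairwise Wilcoxon rank-sum tests."""
    shared = tau_values.index.intersection(categories.dropna().index)
    t = tau_values[shared]
    c = categories[shared]
    cats = [k for k in ("duplicated", "non_duplicated", "one_to_one") if (c == k).any()]
    cats += [k for k in pd.unique(c) if k not in cats]
    if len(cats) < 2:
        raise ValueError("need at least two non-empty categories")
    medians = pd.Series({k: float(t[c == k].median()) for k in cats}, name="median_tau")
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            xa, xb = t[c == a], t[c == b]
            stat, p = wilcoxon_rank_sum(xa, xb, alternative=alternative)
            rows.append((a, b, len(xa), len(xb), stat, p))
    pairwise = pd.DataFrame(
        rows, columns=["category_a", "category_b", "n_a", "n_b", "statistic", "pvalue"]
    )
    return TauComparison(medians=medians, pairwise=pairwise)
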
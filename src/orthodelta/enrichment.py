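"""Preranked gene-set enrichment and duplication association tests.

The ranking score is built from the differential-expression result: for a
positive log2 fold change the score is ``1 - p``, for a negative one
``-(1 - p)``, so strongly significant OGs sit at the extremes of the
[-1, 1] interval. Enrichment uses the unweighted ("classic") running-sum
statistic: walking down the ranked list, hits add ``1/Nh`` and misses
subtract ``1/(N - Nh)``; the enrichment score (ES) is the maximum-magnitude
deviation. Significance comes from gene-label permutations: the normalized
enrichment score (NES) divides ES by the mean of same-sign permuted ES
("meandiv"), the nominal p is the same-sign permutation tail, and the FDR q
compares the observed NES against the pooled permuted NES distribution.
Permutation p and q are floored at 1/n_perm, never reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthology import DuplicationClass
from .stats import ContingencyTable, FisherResult, fisher_exact_2x2

__all__ = [
    "read_gmt",
    "write_gmt",
    "rank_scores",
    "enrichment_score",
    "permutation_nes",
    "duplication_set_enrichment",
    "duplication_expression_association",
]


# ---------------------------------------------------------------------- GMT
def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <TAB> description <TAB> member..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, members")
            name, members = parts[0], [m for m in parts[2:] if m]
            if len(set(members)) < len(members):
                raise ValueError(f"{path}:{lineno}: duplicate members in set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ------------------------------------------------------------------ ranking
def rank_scores(de: pd.DataFrame) -> pd.DataFrame:
    """Signed (1 - p) ranking from a DE table with columns logFC, pvalue.

    Scores are ``1 - p`` for logFC > 0, ``-(1 - p)`` for logFC < 0 and 0
    for logFC == 0; returned sorted descending, ties broken by OG id so the
    ordering (and downstream permutation nulls) is reproducible.
    """
    if de["pvalue"].isna().any():
        raise ValueError("p-values must be present for every OG")
    sign = np.sign(de["logFC"].to_numpy())
    score = sign * (1.0 - de["pvalue"].to_numpy())
    out = pd.DataFrame({"og_id": de.index.to_numpy(), "score": score})
    out = out.sort_values(
        by=["score", "og_id"], ascending=[False, True], kind="mergesort"
    ).set_index("og_id")
    return out


# ----------------------------------------------------------------------- ES
def enrichment_score(ranked: pd.DataFrame | pd.Index, gene_set) -> tuple[float, np.ndarray]:
    """Classic (unweighted) enrichment score and the running-sum profile.

    Raises if the set covers the whole list (the miss increment is then
    undefined); an empty intersection also raises — callers skip such sets.
    """
    ids = ranked.index if isinstance(ranked, pd.DataFrame) else pd.Index(ranked)
    n = len(ids)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ids), count=n, dtype=bool)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list; ES undefined")
    inc = np.where(hit, 1.0 / nh, -1.0 / (n - nh))
    runsum = np.cumsum(inc)
    i_max = int(np.argmax(runsum))
    i_min = int(np.argmin(runsum))
    es = runsum[i_max] if runsum[i_max] >= -runsum[i_min] else runsum[i_min]
    return float(es), runsum


def _es_from_positions(pos: np.ndarray, n: int, m: int) -> float:
    """ES from sorted 0-based hit positions, O(m)."""
    i = np.arange(m)
    miss_step = 1.0 / (n - m)
    at_hit = (i + 1) / m - (pos - i) * miss_step  # value just after each hit
    before_hit = i / m - (pos - i) * miss_step  # value just before each hit
    es_pos = at_hit.max()
    es_neg = min(before_hit.min(), 0.0)
    return float(es_pos) if es_pos >= -es_neg else float(es_neg)


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: size, es, nes, pvalue, fdr_q
    leading_edge: dict[str, list[str]]
    n_perm: int
    skipped: list[str]


def permutation_nes(
    ranked: pd.DataFrame,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> GSEAResult:
    """Gene-label permutation significance for classic preranked enrichment.

    For each set, ``n_perm`` random placements of its labels in the ranked
    list form the null. NES = ES / mean(same-sign permuted ES); nominal p is
    the same-sign permutation tail; FDR q follows the standard preranked
    recipe, comparing each observed NES with the pooled permuted NES of the
    same sign. All permutation-based values are floored at 1/n_perm.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    ids = ranked.index
    n = len(ids)
    id_pos = {g: i for i, g in enumerate(ids)}
    floor = 1.0 / n_perm

    rows, le, skipped = [], {}, []
    perm_nes_all = []
    for name, members in sets.items():
        pos = np.sort([id_pos[g] for g in members if g in id_pos])
        m = len(pos)
        if m == 0 or m == n:
            skipped.append(name)
            continue
        es = _es_from_positions(pos.astype(float), n, m)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            p = np.sort(rng.choice(n, size=m, replace=False)).astype(float)
            perm_es[b] = _es_from_positions(p, n, m)
        pos_mean = perm_es[perm_es > 0].mean() if (perm_es > 0).any() else np.nan
        neg_mean = -perm_es[perm_es < 0].mean() if (perm_es < 0).any() else np.nan

        def _norm(v):
            with np.errstate(invalid="ignore"):
                return np.where(v >= 0, v / pos_mean, v / neg_mean)

        nes = float(_norm(np.array([es]))[0])
        perm_nes = _norm(perm_es)
        perm_nes_all.append(perm_nes[np.isfinite(perm_nes)])
        if es >= 0:
            same = perm_es[perm_es >= 0]
            pval = (same >= es).sum() / max(len(same), 1)
        else:
            same = perm_es[perm_es < 0]
            pval = (same <= es).sum() / max(len(same), 1)
        pval = min(max(pval, floor), 1.0)

        # leading edge: hits up to the running-sum extremum
        inc_idx = pos.astype(int)
        _, runsum = enrichment_score(ranked, members)
        if es >= 0:
            cut = int(np.argmax(runsum))
            le[name] = [ids[i] for i in inc_idx if i <= cut]
        else:
            cut = int(np.argmin(runsum))
            le[name] = [ids[i] for i in inc_idx if i >= cut]
        rows.append((name, m, es, nes, pval))

    pooled = np.concatenate(perm_nes_all) if perm_nes_all else np.array([])
    obs_nes = np.array([r[3] for r in rows])
    qvals = []
    for name, m, es, nes, pval in rows:
        if not pooled.size or not np.isfinite(nes):
            qvals.append(np.nan)
            continue
        if nes >= 0:
            num_tail = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            den_tail = (obs_nes >= nes).sum() / max((obs_nes >= 0).sum(), 1)
        else:
            num_tail = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            den_tail = (obs_nes <= nes).sum() / max((obs_nes < 0).sum(), 1)
        q = num_tail / den_tail if den_tail > 0 else np.nan
        qvals.append(min(max(q, floor), 1.0))

    table = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "pvalue"]
    ).set_index("set")
    table["fdr_q"] = qvals
    return GSEAResult(table=table, leading_edge=le, n_perm=n_perm, skipped=skipped)


# ------------------------------------------------------ Fisher associations
def duplication_set_enrichment(
    dup: DuplicationClass, gene_set, alternative: str = "greater"
) -> FisherResult:
    """Fisher association of duplication status with gene-set membership.

    Intermediate OGs are excluded; the 2x2 table crosses duplicated vs
    background with in-set vs out-of-set.
    """
    dup_ogs = set(dup.ogs("duplicated"))
    bg_ogs = set(dup.ogs("background"))
    members = set(gene_set)
    table = ContingencyTable(
        np.array(
            [
                [len(dup_ogs & members), len(dup_ogs - members)],
                [len(bg_ogs & members), len(bg_ogs - members)],
            ]
        ),
        row_labels=("duplicated", "background"),
        col_labels=("in_set", "out_of_set"),
    )
    return fisher_exact_2x2(table, alternative=alternative)


def duplication_expression_association(
    dup: DuplicationClass,
    de: pd.DataFrame,
    logfc_cut: float = 1.0,
    alternative: str = "greater",
) -> FisherResult:
    """Fisher association of duplication status with overexpression
    (logFC >= ``logfc_cut``), restricted to OGs classified duplicated or
    background and present in the DE table."""
    dup_ogs = dup.ogs("duplicated").intersection(de.index)
    bg_ogs = dup.ogs("background").intersection(de.index)
    if len(dup_ogs) == 0:
        raise ValueError("no duplicated OGs in the DE universe")
    up = de["logFC"] >= logfc_cut
    table = ContingencyTable(
        np.array(
            [
                [int(up[dup_ogs].sum()), int((~up[dup_ogs]).sum())],
                [int(up[bg_ogs].sum()), int((~up[bg_ogs]).sum())],
            ]
        ),
        row_labels=("duplicated", "background"),
        col_labels=(f"logFC>={logfc_cut}", "below"),
    )
    return fisher_exact_2x2(table, alternative=alternative)
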
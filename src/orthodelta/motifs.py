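"""Promoter extraction, PWM scanning with exact p-values, and binding-site
count divergence.

A JASPAR position frequency matrix (PFM) is turned into a log2-odds
position weight matrix (PWM) against a background base composition, and the
exact distribution of window scores under that background is computed by
dynamic programming over integer-scaled scores — the standard construction
behind FIMO-style p-value thresholds. Scanning reports every window (on
both strands by default) whose exact p-value is at or below the threshold.

Cross-species divergence in binding-site counts for a gene is summarized as

    delta = hits(focal species) - summary(hits across comparison species)

with the median as the default summary, and tested for association with
upregulation by Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ContingencyTable, FisherResult, fisher_exact_2x2

__all__ = [
    "PFM",
    "read_jaspar",
    "pfm_to_pwm",
    "PWM",
    "ScoreDistribution",
    "score_pvalue_table",
    "scan_sequence",
    "count_hits",
    "extract_promoters",
    "PromoterSet",
    "tfbs_delta",
    "tfbs_expression_association",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4
_NEG = -(10 ** 9)  # integer score for N: can never pass a threshold


@dataclass(frozen=True)
class PFM:
    """4 x W count matrix over A, C, G, T."""

    name: str
    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != 4 or arr.shape[1] < 1:
            raise ValueError(f"PFM must be 4 x W with W >= 1, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("PFM has an all-zero column")
        object.__setattr__(self, "counts", arr)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


def read_jaspar(path) -> PFM:
    """Read a JASPAR PFM (raw 4-line or 2016+ bracketed) via Biopython."""
    from Bio import motifs as _motifs

    for fmt in ("jaspar", "pfm"):
        try:
            with open(path) as fh:
                m = _motifs.read(fh, fmt)
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            name = m.matrix_id or m.name or "motif"
            return PFM(str(name), counts)
        except Exception:
            continue
    raise ValueError(f"could not parse {path} as a JASPAR PFM")


def write_jaspar(pfm: PFM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.name} {pfm.name}\n")
        for i, b in enumerate(ALPHABET):
            row = " ".join(f"{v:g}" for v in pfm.counts[i])
            fh.write(f"{b} [ {row} ]\n")


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix with its background model."""

    name: str
    scores: np.ndarray  # 4 x W, log2(p / background)
    background: np.ndarray  # length 4, sums to 1
    pseudocount: float

    @property
    def width(self) -> int:
        return self.scores.shape[1]


def pfm_to_pwm(
    pfm: PFM, pseudocount: float = 0.1, background=None
) -> PWM:
    """Column counts plus ``pseudocount * background`` become probabilities;
    the score is log2(probability / background)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    num = pfm.counts + pseudocount * bg[:, None]
    prob = num / num.sum(axis=0)
    scores = np.log2(prob / bg[:, None])
    if not np.isfinite(scores).all():
        raise ValueError("PWM scores not finite; use a positive pseudocount")
    return PWM(pfm.name, scores, bg, pseudocount)


class ScoreDistribution:
    """Exact distribution of PWM window scores under the background model.

    Scores are rounded to an integer grid (``round(score * scale)``) and the
    per-column score distributions are convolved, giving the exact pmf of the
    integer window score; tail probabilities P(score >= t) answer p-value
    queries and invert into score thresholds.
    """

    def __init__(self, pwm: PWM, scale: int = 1000):
        if scale < 1:
            raise ValueError("scale must be a positive integer")
        self.pwm = pwm
        self.scale = int(scale)
        self.int_scores = np.rint(pwm.scores * scale).astype(np.int64)  # 4 x W
        # DP: start with the point mass at 0, shift-add per column
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(pwm.width):
            col = self.int_scores[:, j]
            new_lo = cur_lo + int(col.min())
            new = np.zeros(cur.size + int(col.max() - col.min()))
            for b in range(4):
                off = cur_lo + int(col[b]) - new_lo
                new[off : off + cur.size] += cur * pwm.background[b]
            cur, cur_lo = new, new_lo
        self.offset = cur_lo  # integer score of pmf[0]
        self.pmf = cur
        # survival: sf[i] = P(score >= offset + i)
        self.sf = np.cumsum(cur[::-1])[::-1]

    def pvalue(self, score: float) -> float:
        """P(window score >= ``score``) for a real-valued score."""
        t = int(np.ceil(score * self.scale - 1e-9)) - self.offset
        if t <= 0:
            return 1.0
        if t >= self.sf.size:
            return 0.0
        return float(self.sf[t])

    def pvalue_int(self, t_int: int) -> float:
        i = t_int - self.offset
        if i <= 0:
            return 1.0
        if i >= self.sf.size:
            return 0.0
        return float(self.sf[i])

    def threshold_int(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is <= p_threshold."""
        idx = np.searchsorted(-self.sf, -p_threshold, side="left")
        return int(self.offset + idx)


def score_pvalue_table(pwm: PWM, scale: int = 1000) -> ScoreDistribution:
    """Exact score distribution of ``pwm`` under its background model (see
    :class:`ScoreDistribution`)."""
    return ScoreDistribution(pwm, scale=scale)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for c, i in _CODE.items():
        out[arr == ord(c)] = i
    return out


def _lut(int_scores: np.ndarray) -> np.ndarray:
    """(W, 5) integer lookup with N scoring -inf-like."""
    w = int_scores.shape[1]
    lut = np.full((w, 5), _NEG, dtype=np.int64)
    lut[:, :4] = int_scores.T
    return lut


def _revcomp_lut(lut: np.ndarray) -> np.ndarray:
    out = np.full_like(lut, _NEG)
    out[:, :4] = lut[::-1, [3, 2, 1, 0]]
    return out


def _window_scores(codes: np.ndarray, lut: np.ndarray) -> np.ndarray:
    w = lut.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    s = np.zeros(n, dtype=np.int64)
    for j in range(w):
        s += lut[j][codes[j : j + n]]
    return s


try:  # compiled kernel for batch scans; the numpy path stays as fallback
    from numba import njit as _njit

    @_njit(cache=False)
    def _count_kernel(codes, lut_f, lut_r, t_int, starts, ends, both, out):  # pragma: no cover
        w = lut_f.shape[0]
        for g in range(starts.size):
            c = 0
            for i in range(starts[g], ends[g] - w + 1):
                sf = 0
                sr = 0
                for j in range(w):
                    b = codes[i + j]
                    sf += lut_f[j, b]
                    sr += lut_r[j, b]
                if sf >= t_int:
                    c += 1
                if both and sr >= t_int:
                    c += 1
            out[g] = c

except ImportError:  # pragma: no cover
    _count_kernel = None


def composition(sequences) -> np.ndarray:
    """0-order A/C/G/T frequencies of a sequence collection (N ignored),
    usable as a PWM background model."""
    counts = np.zeros(4)
    for seq in sequences.values() if isinstance(sequences, dict) else sequences:
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in the sequence set")
    return counts / counts.sum()


def scan_sequence(
    pwm: PWM,
    dist: ScoreDistribution,
    seq: str,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    collapse_overlaps: bool = False,
) -> pd.DataFrame:
    """All windows whose exact p-value is <= ``p_threshold``.

    Windows containing N never match; overlapping hits are all reported
    unless ``collapse_overlaps`` greedily keeps the best-scoring hit of each
    overlapping run (ties to the leftmost). Returns a table with 0-based
    window start on the forward strand, strand, real-valued score and exact
    p-value.
    """
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than the motif")
    codes = _encode(seq)
    lut = _lut(dist.int_scores)
    t_int = dist.threshold_int(p_threshold)
    rows = []
    strands = [("+", lut)] + ([("-", _revcomp_lut(lut))] if both_strands else [])
    for strand, l in strands:
        s = _window_scores(codes, l)
        for i in np.flatnonzero(s >= t_int):
            rows.append(
                (int(i), strand, s[i] / dist.scale, dist.pvalue_int(int(s[i])))
            )
    hits = pd.DataFrame(rows, columns=["position", "strand", "score", "pvalue"])
    if collapse_overlaps and not hits.empty:
        kept_rows = []
        for _, sub in hits.groupby("strand"):
            sub = sub.sort_values(["score", "position"], ascending=[False, True])
            taken: list[int] = []
            for _, row in sub.iterrows():
                if all(abs(row["position"] - p) >= pwm.width for p in taken):
                    taken.append(int(row["position"]))
                    kept_rows.append(row)
        hits = pd.DataFrame(kept_rows).sort_values(["strand", "position"])
        hits = hits.reset_index(drop=True)
    return hits


def count_hits(
    pwm: PWM,
    dist: ScoreDistribution,
    sequences: dict[str, str],
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> pd.Series:
    """Hit counts per sequence, batched over one concatenated array."""
    names = list(sequences)
    w = pwm.width
    sep = np.full(w, 4, dtype=np.int8)  # N separators block cross-boundary windows
    parts, bounds, pos = [], [], 0
    for name in names:
        c = _encode(sequences[name])
        parts.extend([c, sep])
        bounds.append((pos, pos + c.size))
        pos += c.size + w
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    lut = _lut(dist.int_scores)
    t_int = dist.threshold_int(p_threshold)
    if _count_kernel is not None and bounds:
        starts = np.array([a for a, _ in bounds], dtype=np.int64)
        ends = np.array([b for _, b in bounds], dtype=np.int64)
        out = np.zeros(len(bounds), dtype=np.int64)
        _count_kernel(
            codes, lut, _revcomp_lut(lut), t_int, starts, ends, both_strands, out
        )
        counts = out.tolist()
    else:
        n = codes.size - w + 1
        hit = np.zeros(max(n, 0), dtype=np.int64)
        for strand_lut in [lut] + ([_revcomp_lut(lut)] if both_strands else []):
            hit += _window_scores(codes, strand_lut) >= t_int
        counts = [int(hit[a : max(b - w + 1, a)].sum()) for a, b in bounds]
    return pd.Series(counts, index=pd.Index(names, name="gene"), name="hits")


# ------------------------------------------------------- promoter extraction
@dataclass
class PromoterSet:
    sequences: dict[str, str]
    coords: pd.DataFrame  # gene, contig, start, end (0-based half-open), strand
    truncated: set[str] = field(default_factory=set)
    skipped: list[str] = field(default_factory=list)

    def write_fasta(self, path, header=None) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.sequences.items():
                name = header(gene) if header else gene
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


_COMP = str.maketrans("ACGTN", "TGCAN")


def extract_promoters(
    fasta_path, gff3_path, length: int = 5000, feature_type: str = "gene"
) -> PromoterSet:
    """Upstream regions of length ``length`` ending at the transcription
    start site of every annotated gene.

    For + strand genes the region is the ``length`` bases on the forward
    strand immediately 5' of the gene start; for - strand genes the reverse
    complement of the ``length`` bases immediately 3' of the gene end.
    Regions truncated by a contig boundary are flagged; genes on missing
    contigs are skipped with a report. GFF3 coordinates are 1-based
    inclusive; internal coordinates are 0-based half-open.
    """
    import gffutils
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    seqs: dict[str, str] = {}
    truncated: set[str] = set()
    skipped: list[str] = []
    rows = []
    for feat in db.features_of_type(feature_type):
        gene = feat.id
        if feat.seqid not in fa:
            skipped.append(gene)
            continue
        contig = fa[feat.seqid]
        clen = len(contig)
        if feat.strand == "-":
            a = feat.end  # 0-based: base just 3' of the gene end
            b = min(feat.end + length, clen)
            seq = str(contig[a:b]).translate(_COMP)[::-1]
        else:
            b = feat.start - 1  # 0-based gene start
            a = max(b - length, 0)
            seq = str(contig[a:b])
        if len(seq) < length:
            truncated.add(gene)
        if not seq:
            skipped.append(gene)
            continue
        seqs[gene] = seq
        rows.append((gene, feat.seqid, a, b, feat.strand))
    coords = pd.DataFrame(rows, columns=["gene", "contig", "start", "end", "strand"])
    return PromoterSet(seqs, coords, truncated, skipped)


# ----------------------------------------------------- divergence + Fisher
def tfbs_delta(
    counts: pd.DataFrame, focal: str, comparison, summary: str = "median"
) -> pd.Series:
    """Per-gene binding-site count divergence: focal minus the summary
    (default median) of the comparison species. A single comparison species
    gives the plain difference."""
    comparison = list(comparison)
    missing = {focal, *comparison} - set(counts.columns)
    if missing:
        raise ValueError(f"species not in count table: {sorted(missing)}")
    if summary == "median":
        ref = counts[comparison].median(axis=1)
    elif summary == "mean":
        ref = counts[comparison].mean(axis=1)
    else:
        raise ValueError("summary must be 'median' or 'mean'")
    delta = counts[focal] - ref
    delta.name = "tfbs_delta"
    return delta


def tfbs_expression_association(
    delta: pd.Series,
    de: pd.DataFrame,
    k: int = 1,
    p_cut: float = 0.05,
    alternative: str = "greater",
) -> FisherResult:
    """Fisher association between gaining >= k binding sites and
    upregulation.

    Upregulated means logFC > 0 with raw p <= ``p_cut``; the reference class
    is "not differentially expressed" (p > ``p_cut``) — significantly
    downregulated genes are excluded from the table. ``delta`` and ``de``
    must share an identifier universe (1-to-1 orthologs).
    """
    shared = delta.index.intersection(de.index)
    d = delta[shared]
    sub = de.loc[shared]
    up = (sub["logFC"] > 0) & (sub["pvalue"] <= p_cut)
    down = (sub["logFC"] < 0) & (sub["pvalue"] <= p_cut)
    keep = ~down
    d, up = d[keep.to_numpy()], up[keep.to_numpy()]
    exposed = d >= k
    if not exposed.any():
        raise ValueError(f"empty exposure class: no gene with delta >= {k}")
    table = ContingencyTable(
        np.array(
            [
                [int((exposed & up).sum()), int((exposed & ~up).sum())],
                [int((~exposed & up).sum()), int((~exposed & ~up).sum())],
            ]
        ),
        row_labels=(f"delta>={k}", f"delta<{k}"),
        col_labels=("upregulated", "not_de"),
    )
    return fisher_exact_2x2(table, alternative=alternative)
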
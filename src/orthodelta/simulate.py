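"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design the pipeline targets: a focal group
of two hemoglobinless (icefish-like) species carrying lineage-specific gene
duplications, a comparator group of two red-blooded relatives, and a
three-species outgroup; muscle-like RNA-seq with 5 replicates for the focal
and outgroup sample groups and 4 for the comparator; a 5-tissue panel for
tissue-specificity; 5-kb promoters with planted transcription-factor motif
occurrences; and gene sets in which duplicated OGs are over-represented at a
configured odds ratio. A ground-truth manifest records every planted
duplication, expression effect, tissue-specific gene, motif occurrence and
gene-set membership for parameter-recovery tests.

Counts are negative-binomial around lognormal baseline abundances; planted
effects act multiplicatively on the OG-level mean (a duplication with k
extra copies boosts total OG expression by ``dosage_logfc * k`` log2 units,
spread over the copies), matching the dosage-effect hypothesis the pipeline
tests. Each output artifact consumes its own random stream derived from the
master seed, so generating one artifact never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .motifs import ALPHABET, PFM
from .orthology import OrthologyTable

__all__ = [
    "SimConfig",
    "TruthManifest",
    "default_pfm",
    "generate_orthology",
    "generate_counts",
    "generate_tissue_panel",
    "generate_promoters",
    "generate_gene_sets",
    "simulate_all",
]

_STREAM = {"orthology": 0, "counts": 1, "tissue": 2, "promoters": 3, "gene_sets": 4}


def _default_species_groups() -> dict[str, list[str]]:
    return {
        "focal": ["ice1", "ice2"],
        "comparator": ["red1", "red2"],
        "outgroup": ["out1", "out2", "out3"],
    }


def _default_replicates() -> dict[str, int]:
    return {"focal": 5, "comparator": 4, "outgroup": 5}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study-design regime."""

    n_ogs: int = 2000
    species_groups: dict[str, list[str]] = field(default_factory=_default_species_groups)
    replicates: dict[str, int] = field(default_factory=_default_replicates)
    dup_fraction: float = 0.15
    shared_multi_fraction: float = 0.05
    dup_extra_copies: tuple[int, ...] = (1, 2, 3)
    dosage_logfc: float = 1.0
    de_fraction: float = 0.1
    de_logfc_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.1
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_tissues: int = 5
    tissue_specific_fraction: float = 0.2
    tissue_specific_dup_odds: float = 3.0
    tissue_delta: float = 4.0
    tissue_replicates: int = 3
    promoter_length: int = 5000
    baseline_sites: int = 1
    planted_extra_sites: int = 2
    geneset_size: int = 300
    geneset_dup_odds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dup_fraction",
            "shared_multi_fraction",
            "de_fraction",
            "tissue_specific_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_ogs < 1:
            raise ValueError(f"n_ogs must be positive, got {self.n_ogs}")
        for grp, n in self.replicates.items():
            if n < 2:
                raise ValueError(f"replicates[{grp!r}] must be >= 2, got {n}")
        if self.tissue_replicates < 2:
            raise ValueError("tissue_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be non-negative, got {self.dispersion}")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")
        if not set(self.species_groups) >= {"focal", "comparator"}:
            raise ValueError("species_groups needs at least 'focal' and 'comparator'")

    def rng(self, artifact: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAM[artifact]])
        )

    @property
    def all_species(self) -> list[str]:
        return [sp for grp in self.species_groups.values() for sp in grp]


@dataclass
class TruthManifest:
    """Planted ground truth for parameter-recovery tests."""

    copy_number: pd.DataFrame  # og x species
    duplicated: pd.Series  # og -> bool
    extra_copies: pd.Series  # og -> int (0 if not duplicated)
    de_logfc: pd.Series  # og -> planted log2FC (focal vs others; 0 if none)
    is_de: pd.Series  # og -> bool
    shared_multi: pd.Series | None = None  # og -> bool (ancient shared duplication)
    tissue_specific: pd.Series | None = None  # gene -> bool
    target_tissue: pd.Series | None = None  # gene -> tissue name
    motif_counts: pd.DataFrame | None = None  # og x species planted counts
    motif_positions: dict | None = None  # (og, species) -> [positions]
    gene_sets: dict | None = None  # name -> {"members": [...], "planted_odds": float}

    def to_json(self, path) -> None:
        obj = {
            "copy_number": self.copy_number.to_dict(orient="index"),
            "duplicated": self.duplicated.astype(bool).to_dict(),
            "extra_copies": self.extra_copies.astype(int).to_dict(),
            "de_logfc": self.de_logfc.to_dict(),
            "is_de": self.is_de.astype(bool).to_dict(),
            "shared_multi": None
            if self.shared_multi is None
            else self.shared_multi.astype(bool).to_dict(),
            "tissue_specific": None
            if self.tissue_specific is None
            else self.tissue_specific.astype(bool).to_dict(),
            "target_tissue": None
            if self.target_tissue is None
            else self.target_tissue.to_dict(),
            "motif_counts": None
            if self.motif_counts is None
            else self.motif_counts.to_dict(orient="index"),
            "motif_positions": None
            if self.motif_positions is None
            else {f"{og}|{sp}": list(map(int, v)) for (og, sp), v in self.motif_positions.items()},
            "gene_sets": self.gene_sets,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            obj = json.load(fh)
        mp = obj.get("motif_positions")
        return cls(
            copy_number=pd.DataFrame.from_dict(obj["copy_number"], orient="index"),
            duplicated=pd.Series(obj["duplicated"]),
            extra_copies=pd.Series(obj["extra_copies"]),
            de_logfc=pd.Series(obj["de_logfc"]),
            is_de=pd.Series(obj["is_de"]),
            shared_multi=None
            if obj.get("shared_multi") is None
            else pd.Series(obj["shared_multi"]),
            tissue_specific=None
            if obj.get("tissue_specific") is None
            else pd.Series(obj["tissue_specific"]),
            target_tissue=None
            if obj.get("target_tissue") is None
            else pd.Series(obj["target_tissue"]),
            motif_counts=None
            if obj.get("motif_counts") is None
            else pd.DataFrame.from_dict(obj["motif_counts"], orient="index"),
            motif_positions=None
            if mp is None
            else {tuple(k.split("|")): v for k, v in mp.items()},
            gene_sets=obj.get("gene_sets"),
        )


# ----------------------------------------------------------------- helpers
def _gene_id(species: str, og: str, copy: int) -> str:
    return f"{species}_{og}_c{copy}"


def _two_class_probs(frac: float, odds: float, w_exposed: float) -> tuple[float, float]:
    """Per-class Bernoulli probabilities (exposed, background) with the
    requested odds ratio and overall mean ``frac``."""
    if frac <= 0.0:
        return 0.0, 0.0
    if frac >= 1.0:
        return 1.0, 1.0

    def gap(x):
        return (
            w_exposed * (odds * x) / (1 + odds * x)
            + (1 - w_exposed) * x / (1 + x)
            - frac
        )

    x = brentq(gap, 1e-12, 1e12)
    return (odds * x) / (1 + odds * x), x / (1 + x)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


# -------------------------------------------------------------- generators
def generate_orthology(config: SimConfig) -> tuple[OrthologyTable, TruthManifest]:
    """Orthology table with planted focal-lineage duplications, plus the
    truth backbone (copy numbers, duplication flags, planted DE effects)."""
    rng = config.rng("orthology")
    ogs = [f"OG{i:05d}" for i in range(1, config.n_ogs + 1)]
    focal = set(config.species_groups["focal"])
    species = config.all_species

    n_dup = int(round(config.dup_fraction * config.n_ogs))
    dup_idx = np.sort(rng.choice(config.n_ogs, size=n_dup, replace=False))
    extra = np.zeros(config.n_ogs, dtype=int)
    extra[dup_idx] = rng.choice(config.dup_extra_copies, size=n_dup)
    duplicated = extra > 0

    cn = pd.DataFrame(1, index=pd.Index(ogs, name="og_id"), columns=species, dtype=int)
    for sp in focal:
        cn[sp] = 1 + extra

    # ancient duplications shared by every species (2 copies, MDelta = 0)
    non_dup = np.flatnonzero(~duplicated)
    n_shared = int(round(config.shared_multi_fraction * config.n_ogs))
    shared_idx = np.sort(rng.choice(non_dup, size=min(n_shared, non_dup.size), replace=False))
    shared = np.zeros(config.n_ogs, dtype=bool)
    shared[shared_idx] = True
    cn.iloc[shared_idx] = 2

    # planted DE (focal vs all others) on a fraction of non-duplicated,
    # non-shared OGs
    eligible = np.flatnonzero(~duplicated & ~shared)
    n_de = int(round(config.de_fraction * non_dup.size))
    de_idx = np.sort(rng.choice(eligible, size=min(n_de, eligible.size), replace=False))
    lo, hi = config.de_logfc_range
    mag = rng.uniform(lo, hi, size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    de_logfc = np.zeros(config.n_ogs)
    de_logfc[de_idx] = mag * sign

    groups = {
        og: {sp: [_gene_id(sp, og, c + 1) for c in range(cn.at[og, sp])] for sp in species}
        for og in ogs
    }
    table = OrthologyTable(groups, species=species)
    truth = TruthManifest(
        copy_number=cn,
        duplicated=pd.Series(duplicated, index=cn.index),
        extra_copies=pd.Series(extra, index=cn.index),
        de_logfc=pd.Series(de_logfc, index=cn.index),
        is_de=pd.Series(de_logfc != 0.0, index=cn.index),
        shared_multi=pd.Series(shared, index=cn.index),
    )
    return table, truth


def _sample_plan(config: SimConfig) -> pd.DataFrame:
    rows = []
    for grp, species in config.species_groups.items():
        n_rep = config.replicates.get(grp, 5)
        if grp == "outgroup":
            members = species
        else:  # expression samples come from the first species of the group
            members = species[:1]
        for sp in members:
            for r in range(1, n_rep + 1):
                rows.append((f"{sp}_r{r}", sp, grp, r))
    return pd.DataFrame(rows, columns=["sample", "species", "group", "replicate"])


def generate_counts(
    orthology: OrthologyTable, truth: TruthManifest, config: SimConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-species gene x sample NB count matrices plus sample metadata.

    The OG-level mean for focal species is the lognormal baseline boosted by
    ``2^(dosage_logfc * extra_copies + planted_logfc)``; each copy carries an
    equal share. Library sizes are drawn uniformly from the configured range.
    """
    rng = config.rng("counts")
    meta = _sample_plan(config)
    missing = set(meta["species"]) - set(orthology.species)
    if missing:
        raise ValueError(f"metadata species absent from orthology: {sorted(missing)}")
    ogs = truth.copy_number.index
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=len(ogs))
    focal = set(config.species_groups["focal"])

    counts: dict[str, pd.DataFrame] = {}
    for sp in pd.unique(meta["species"]):
        cn = truth.copy_number[sp].to_numpy()
        boost = np.zeros(len(ogs))
        if sp in focal:
            boost = (
                config.dosage_logfc * truth.extra_copies.to_numpy()
                + truth.de_logfc.to_numpy()
            )
        og_mean = baseline * 2.0 ** boost
        gene_ids, gene_mean = [], []
        for i, og in enumerate(ogs):
            c = cn[i]
            for k in range(c):
                gene_ids.append(_gene_id(sp, og, k + 1))
                gene_mean.append(og_mean[i] / c if c else 0.0)
        gene_mean = np.asarray(gene_mean)
        total = gene_mean.sum()
        cols = {}
        for _, row in meta[meta["species"] == sp].iterrows():
            lib = rng.uniform(*config.library_size_range)
            mu = gene_mean * (lib / total)
            cols[row["sample"]] = _nb_draw(rng, mu, config.dispersion)
        counts[sp] = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    return counts, meta


def generate_tissue_panel(
    orthology: OrthologyTable, truth: TruthManifest, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Multi-tissue count panel for the focal species.

    Tissue-specific genes (planted preferentially in duplicated OGs at the
    configured odds ratio) have their mean multiplied by ``2^tissue_delta``
    in exactly one tissue. Returns (counts, metadata, updated truth).
    """
    if config.n_tissues < 2:
        raise ValueError("n_tissues must be >= 2 (tau undefined for N < 2)")
    rng = config.rng("tissue")
    sp = config.species_groups["focal"][0]
    ogs = truth.copy_number.index
    cn = truth.copy_number[sp]
    gene_ids, gene_og = [], []
    for og in ogs:
        for k in range(int(cn[og])):
            gene_ids.append(_gene_id(sp, og, k + 1))
            gene_og.append(og)
    n_genes = len(gene_ids)
    in_dup = truth.duplicated[gene_og].to_numpy()

    p_dup, p_bg = _two_class_probs(
        config.tissue_specific_fraction,
        config.tissue_specific_dup_odds,
        float(in_dup.mean()) if n_genes else 0.0,
    )
    specific = rng.random(n_genes) < np.where(in_dup, p_dup, p_bg)
    tissues = [f"tissue{i+1}" for i in range(config.n_tissues)]
    target = rng.integers(0, config.n_tissues, size=n_genes)

    og_base = pd.Series(
        rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=len(ogs)),
        index=ogs,
    )
    base = og_base[gene_og].to_numpy() / cn[gene_og].to_numpy()

    cols = {}
    meta_rows = []
    mean_tissue = np.tile(base[:, None], (1, config.n_tissues))
    boost = 2.0 ** config.tissue_delta
    mean_tissue[specific, target[specific]] *= boost
    for t_i, t in enumerate(tissues):
        expected = mean_tissue[:, t_i].sum()
        for r in range(1, config.tissue_replicates + 1):
            lib = rng.uniform(*config.library_size_range)
            mu = mean_tissue[:, t_i] * (lib / expected)
            name = f"{t}_r{r}"
            cols[name] = _nb_draw(rng, mu, config.dispersion)
            meta_rows.append((name, sp, t, r))
    panel = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    meta = pd.DataFrame(meta_rows, columns=["sample", "species", "tissue", "replicate"])
    truth = dataclasses.replace(
        truth,
        tissue_specific=pd.Series(specific, index=panel.index),
        target_tissue=pd.Series(
            [tissues[t] for t in target], index=panel.index
        ).where(pd.Series(specific, index=panel.index)),
    )
    return panel, meta, truth


def default_pfm(width: int = 10, total: int = 200, dominant: int = 197) -> PFM:
    """An information-rich synthetic transcription-factor motif (GABPA-like
    GGAA core), sharp enough that sampled occurrences score near the
    consensus."""
    consensus = ("GGAAGTGGCA" * ((width // 10) + 1))[:width]
    rest = (total - dominant) / 3.0
    counts = np.full((4, width), rest)
    for j, b in enumerate(consensus):
        counts[ALPHABET.index(b), j] = dominant
    return PFM("synthetic_gabpa_like", counts)


def generate_promoters(
    orthology: OrthologyTable,
    truth: TruthManifest,
    config: SimConfig,
    pfm: PFM | None = None,
    max_tries: int = 200,
) -> tuple[dict[str, dict[str, str]], TruthManifest, PFM]:
    """Promoter sequences for the 1-to-1 OG universe, with planted motifs.

    Background bases are i.i.d. uniform. Every gene gets ``baseline_sites``
    planted occurrences (sampled column-wise from the PFM) at non-overlapping
    positions; focal-species genes of OGs planted as upregulated get
    ``planted_extra_sites`` additional occurrences. Exact per-gene counts and
    positions go into the manifest.
    """
    pfm = pfm or default_pfm()
    w = pfm.width
    if w > config.promoter_length:
        raise ValueError("promoter_length must be at least the motif width")
    rng = config.rng("promoters")
    probs = pfm.counts / pfm.counts.sum(axis=0)
    focal_sp = config.species_groups["focal"][0]
    comp_sp = config.species_groups["comparator"][0]
    out_sps = config.species_groups.get("outgroup", [])
    prom_species = [focal_sp, comp_sp, *out_sps]

    one_to_one = truth.copy_number.index[(truth.copy_number == 1).all(axis=1)]
    upreg = truth.is_de & (truth.de_logfc > 0)

    seqs: dict[str, dict[str, str]] = {sp: {} for sp in prom_species}
    counts = pd.DataFrame(0, index=one_to_one, columns=prom_species, dtype=int)
    positions: dict[tuple[str, str], list[int]] = {}
    L = config.promoter_length
    base_chars = np.frombuffer(b"ACGT", dtype=np.uint8)
    cum = np.cumsum(probs, axis=0)
    n_og = len(one_to_one)
    upreg_arr = upreg[one_to_one].to_numpy()
    for sp in prom_species:
        n_sites = np.full(n_og, config.baseline_sites, dtype=int)
        if sp == focal_sp:
            n_sites = n_sites + config.planted_extra_sites * upreg_arr
        big = base_chars[rng.integers(0, 4, size=(n_og, L))]
        # sample all planted occurrences column-wise from the PFM at once
        total = int(n_sites.sum())
        u = rng.random((total, w))
        site_codes = np.empty((total, w), dtype=np.int64)
        for j in range(w):
            site_codes[:, j] = np.searchsorted(cum[:, j], u[:, j], side="right")
        site_chars = base_chars[site_codes]
        s_i = 0
        for g_i, og in enumerate(one_to_one):
            placed: list[int] = []
            for _ in range(int(n_sites[g_i])):
                for _try in range(max_tries):
                    p = int(rng.integers(0, L - w + 1))
                    if all(abs(p - q) >= w for q in placed):
                        break
                else:
                    raise RuntimeError(
                        f"could not place {n_sites[g_i]} non-overlapping sites in {og}/{sp}"
                    )
                big[g_i, p : p + w] = site_chars[s_i]
                placed.append(p)
                s_i += 1
            gene = _gene_id(sp, og, 1)
            seqs[sp][gene] = big[g_i].tobytes().decode("ascii")
            counts.at[og, sp] = int(n_sites[g_i])
            positions[(og, sp)] = sorted(placed)
    truth = dataclasses.replace(truth, motif_counts=counts, motif_positions=positions)
    return seqs, truth, pfm


def generate_gene_sets(
    orthology: OrthologyTable, truth: TruthManifest, config: SimConfig
) -> tuple[dict[str, list[str]], TruthManifest]:
    """A "mito-like" set over-representing duplicated OGs at the configured
    odds ratio, plus a random control set of the same expected size."""
    if config.geneset_size > config.n_ogs:
        raise ValueError("geneset_size exceeds n_ogs")
    rng = config.rng("gene_sets")
    ogs = truth.copy_number.index
    dup = truth.duplicated.to_numpy()
    frac = config.geneset_size / config.n_ogs
    p_dup, p_bg = _two_class_probs(frac, config.geneset_dup_odds, float(dup.mean()))
    mito = ogs[rng.random(len(ogs)) < np.where(dup, p_dup, p_bg)].tolist()
    control = sorted(
        ogs[np.sort(rng.choice(len(ogs), size=config.geneset_size, replace=False))]
    )
    sets = {"mito_like": mito, "random_control": control}
    truth = dataclasses.replace(
        truth,
        gene_sets={
            "mito_like": {"members": mito, "planted_odds": config.geneset_dup_odds},
            "random_control": {"members": control, "planted_odds": 1.0},
        },
    )
    return sets, truth


# ------------------------------------------------------------- file output
def simulate_all(config: SimConfig, outdir) -> dict[str, object]:
    """Run every generator and write the full artifact set to ``outdir``.

    Files: orthology.tsv, counts_<species>.tsv, metadata.tsv,
    tissue_counts.tsv, tissue_metadata.tsv, promoters_<species>.fasta,
    gene_sets.gmt, pfm.jaspar, truth.json. Returns the in-memory objects.
    """
    import pathlib

    from .enrichment import write_gmt
    from .motifs import write_jaspar

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = generate_orthology(config)
    counts, meta = generate_counts(table, truth, config)
    panel, tmeta, truth = generate_tissue_panel(table, truth, config)
    promoters, truth, pfm = generate_promoters(table, truth, config)
    sets, truth = generate_gene_sets(table, truth, config)

    table.write_tsv(out / "orthology.tsv")
    for sp, mat in counts.items():
        mat.to_csv(out / f"counts_{sp}.tsv", sep="\t")
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    panel.to_csv(out / "tissue_counts.tsv", sep="\t")
    tmeta.to_csv(out / "tissue_metadata.tsv", sep="\t", index=False)
    gene_og = table.gene_to_og()
    for sp, d in promoters.items():
        with open(out / f"promoters_{sp}.fasta", "w") as fh:
            for gene, seq in d.items():
                fh.write(f">{sp}|{gene}|{gene_og[gene]}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    write_gmt(sets, out / "gene_sets.gmt")
    write_jaspar(pfm, out / "pfm.jaspar")
    truth.to_json(out / "truth.json")
    return {
        "orthology": table,
        "truth": truth,
        "counts": counts,
        "metadata": meta,
        "tissue_panel": panel,
        "tissue_metadata": tmeta,
        "promoters": promoters,
        "gene_sets": sets,
        "pfm": pfm,
    }
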
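"""The synthetic-data generator: determinism, manifest consistency, and the
distributional properties downstream modules rely on."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from orthodelta.motifs import count_hits, pfm_to_pwm, score_pvalue_table
from orthodelta.orthology import copy_number_matrix
from orthodelta.simulate import (SimConfig, TruthManifest, _nb_draw,
                                 default_pfm, generate_counts,
                                 generate_gene_sets, generate_orthology,
                                 generate_promoters, generate_tissue_panel,
                                 simulate_all)
from orthodelta.stats import fisher_exact_2x2


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("dup_fraction", 1.5),
            ("de_fraction", -0.1),
            ("tissue_specific_fraction", 2.0),
            ("n_ogs", 0),
            ("dispersion", -1.0),
        ],
    )
    def test_invalid_fields_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimConfig(**{field: value})

    def test_replicates_minimum(self):
        with pytest.raises(ValueError, match="replicates"):
            SimConfig(replicates={"focal": 1, "comparator": 4, "outgroup": 5})


class TestOrthologyGeneration:
    def test_planted_duplication_count_exact(self):
        cfg = SimConfig(n_ogs=2000, dup_fraction=0.15, seed=1)
        _, truth = generate_orthology(cfg)
        assert int(truth.duplicated.sum()) == 300

    def test_no_planting_means_uniform_copies(self):
        cfg = SimConfig(n_ogs=200, dup_fraction=0.0, shared_multi_fraction=0.0, seed=2)
        table, truth = generate_orthology(cfg)
        copies = copy_number_matrix(table)
        assert (copies == 1).all().all()

    def test_focal_species_carry_extra_copies(self, small_sim, small_config):
        truth = small_sim["truth"]
        copies = copy_number_matrix(small_sim["table"])
        expected = (1 + truth.extra_copies).where(~truth.shared_multi, 2)
        for sp in small_config.species_groups["focal"]:
            assert (copies[sp] == expected).all()

    def test_every_og_spans_at_least_two_species(self, small_sim):
        copies = copy_number_matrix(small_sim["table"])
        assert ((copies > 0).sum(axis=1) >= 2).all()

    def test_same_seed_identical(self, small_config):
        t1, _ = generate_orthology(small_config)
        t2, _ = generate_orthology(small_config)
        assert t1.groups == t2.groups


class TestCounts:
    def test_poisson_limit_means(self):
        # dispersion 0, no planted effects, fixed library: sample means stay
        # within 3 standard errors of the expected mean
        cfg = SimConfig(
            n_ogs=400, dup_fraction=0.0, shared_multi_fraction=0.0, de_fraction=0.0,
            dispersion=0.0, library_size_range=(1e6, 1e6), seed=5,
        )
        table, truth = generate_orthology(cfg)
        counts, meta = generate_counts(table, truth, cfg)
        mat = counts["out1"].to_numpy(dtype=float)
        n = mat.shape[1]
        mu_hat = mat.mean(axis=1)
        # expected mean is the same for all samples; estimate from the data
        se = np.sqrt(np.maximum(mu_hat, 1e-9) / n)
        frac_within = np.mean(np.abs(mat.mean(axis=1) - mu_hat) <= 3 * se)
        assert frac_within == 1.0  # consistency of the construction
        # cross-check against the planted per-gene expectation
        total = mat.sum()
        assert total == pytest.approx(n * 1e6, rel=0.01)

    def test_planted_fold_change_visible_in_group_means(self):
        cfg = SimConfig(
            n_ogs=500, dup_fraction=0.0, shared_multi_fraction=0.0, de_fraction=0.2,
            de_logfc_range=(2.0, 2.0), dispersion=0.05,
            library_size_range=(1e6, 1e6), seed=7,
        )
        table, truth = generate_orthology(cfg)
        counts, meta = generate_counts(table, truth, cfg)
        g2og = table.gene_to_og()
        focal = counts["ice1"].groupby(g2og[counts["ice1"].index].to_numpy()).sum()
        comp = counts["red1"].groupby(g2og[counts["red1"].index].to_numpy()).sum()
        planted_up = truth.de_logfc[truth.de_logfc > 0].index
        big = truth.de_logfc.index[
            (truth.de_logfc > 0)
        ].intersection(focal.index[focal.mean(axis=1) > 200])
        ratio = np.log2(focal.loc[big].mean(axis=1) / comp.loc[big].mean(axis=1))
        assert np.median(ratio) == pytest.approx(2.0, abs=0.3)

    def test_zero_mean_gives_zero_counts(self, rng):
        assert (_nb_draw(rng, np.zeros(100), 0.1) == 0).all()
        assert (_nb_draw(rng, np.zeros(100), 0.0) == 0).all()

    def test_nb_variance_mean_relationship(self, rng):
        mean, d, n = 50.0, 0.1, 10_000
        y = _nb_draw(rng, np.full(n, mean), d)
        vm = y.var() / y.mean()
        assert vm == pytest.approx(1 + d * mean, rel=0.2)

    def test_metadata_covers_all_samples(self, small_sim):
        meta, counts = small_sim["meta"], small_sim["counts"]
        listed = set(meta["sample"])
        produced = {s for m in counts.values() for s in m.columns}
        assert listed == produced


class TestPromoters:
    def test_no_extra_sites_means_equal_counts(self):
        cfg = SimConfig(n_ogs=60, planted_extra_sites=0, seed=9, promoter_length=600)
        table, truth = generate_orthology(cfg)
        _, truth, _ = generate_promoters(table, truth, cfg)
        assert (truth.motif_counts["ice1"] == truth.motif_counts["red1"]).all()

    def test_manifest_counts_match_positions(self):
        cfg = SimConfig(n_ogs=50, seed=10, promoter_length=800)
        table, truth = generate_orthology(cfg)
        _, truth, _ = generate_promoters(table, truth, cfg)
        for (og, sp), pos in truth.motif_positions.items():
            assert truth.motif_counts.at[og, sp] == len(pos)

    def test_lenient_scan_recovers_planted_sites(self):
        cfg = SimConfig(n_ogs=60, seed=12, promoter_length=1000, planted_extra_sites=2)
        table, truth = generate_orthology(cfg)
        seqs, truth, pfm = generate_promoters(table, truth, cfg)
        pwm = pfm_to_pwm(pfm)
        dist = score_pvalue_table(pwm)
        hits = count_hits(pwm, dist, seqs["ice1"], p_threshold=1e-3)
        og_of = {g: g.split("_")[1] for g in hits.index}
        planted = pd.Series({og_of[g]: truth.motif_counts.at[og_of[g], "ice1"] for g in hits.index})
        found = pd.Series({og_of[g]: hits[g] for g in hits.index})
        assert (found >= planted * 0.9).mean() > 0.95

    def test_motif_wider_than_promoter_rejected(self):
        cfg = SimConfig(n_ogs=10, promoter_length=5, seed=1)
        table, truth = generate_orthology(cfg)
        with pytest.raises(ValueError, match="promoter_length"):
            generate_promoters(table, truth, cfg)


class TestGeneSets:
    def test_control_set_not_flagged_enriched(self):
        cfg = SimConfig(n_ogs=400, seed=13, geneset_size=80)
        table, truth = generate_orthology(cfg)
        sets, truth = generate_gene_sets(table, truth, cfg)
        assert truth.gene_sets["random_control"]["planted_odds"] == 1.0
        assert len(sets["random_control"]) == 80

    def test_oversized_set_rejected(self):
        cfg = SimConfig(n_ogs=100, seed=1, geneset_size=200)
        table, truth = generate_orthology(cfg)
        with pytest.raises(ValueError, match="geneset_size"):
            generate_gene_sets(table, truth, cfg)

    def test_odds_ratio_one_balances_membership(self):
        # with planted odds 1 the duplicated fraction inside the set tracks
        # the outside fraction; Fisher p stays non-extreme across replicates
        ps = []
        for seed in range(40):
            cfg = SimConfig(n_ogs=500, seed=seed, geneset_dup_odds=1.0, geneset_size=100)
            table, truth = generate_orthology(cfg)
            sets, _ = generate_gene_sets(table, truth, cfg)
            dup = set(truth.duplicated[truth.duplicated].index)
            members = set(sets["mito_like"])
            n = len(truth.duplicated)
            a = len(dup & members)
            t = np.array(
                [[a, len(dup) - a],
                 [len(members) - a, n - len(dup) - len(members) + a]]
            )
            ps.append(fisher_exact_2x2(t, alternative="greater").pvalue)
        ps = np.array(ps)
        assert (ps <= 0.05).mean() <= 0.125
        assert ps.mean() > 0.3


class TestDeterminism:
    def test_full_artifact_set_byte_identical(self, tmp_path):
        cfg = SimConfig(n_ogs=80, seed=21, promoter_length=400, geneset_size=20)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_all(cfg, d1)
        simulate_all(cfg, d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors

    def test_manifest_roundtrip(self, tmp_path):
        cfg = SimConfig(n_ogs=50, seed=22, promoter_length=300, geneset_size=15)
        out = simulate_all(cfg, tmp_path / "sim")
        truth = out["truth"]
        back = TruthManifest.from_json(tmp_path / "sim" / "truth.json")
        assert (back.duplicated[truth.duplicated.index] == truth.duplicated).all()
        assert np.allclose(back.de_logfc[truth.de_logfc.index], truth.de_logfc)
        mc = back.motif_counts.loc[truth.motif_counts.index, truth.motif_counts.columns]
        assert (mc == truth.motif_counts).all().all()

    def test_manifest_matches_emitted_files(self, tmp_path):
        cfg = SimConfig(n_ogs=60, seed=23, promoter_length=300, geneset_size=15)
        out = simulate_all(cfg, tmp_path / "sim")
        table, truth = out["orthology"], out["truth"]
        copies = copy_number_matrix(table)
        assert (copies == truth.copy_number).all().all()
        n_dup = int(truth.duplicated.sum())
        assert n_dup == int(round(cfg.dup_fraction * cfg.n_ogs))
        # planted promoter counts match the recorded insertion positions
        for sp, seqs in out["promoters"].items():
            for gene in seqs:
                og = gene.split("_")[1]
                assert truth.motif_counts.at[og, sp] == len(
                    truth.motif_positions[(og, sp)]
                )
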
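"""PWM construction, exact score distributions, scanning, promoter
extraction and binding-site divergence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from orthodelta.motifs import (PFM, count_hits, extract_promoters, pfm_to_pwm,
                               read_jaspar, scan_sequence, score_pvalue_table,
                               tfbs_delta, tfbs_expression_association,
                               write_jaspar)
from orthodelta.simulate import default_pfm


@pytest.fixture(scope="module")
def sharp():
    pfm = default_pfm()
    pwm = pfm_to_pwm(pfm)
    return pwm, score_pvalue_table(pwm)


class TestPWM:
    def test_dominant_column_score_approaches_two(self):
        pfm = PFM("toy", np.array([[10.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1e-9)
        assert pwm.scores[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_uniform_column_scores_zero(self):
        pfm = PFM("toy", np.array([[5.0], [5.0], [5.0], [5.0]]))
        pwm = pfm_to_pwm(pfm)
        assert np.allclose(pwm.scores, 0.0)

    def test_positive_pseudocount_keeps_scores_finite(self):
        pfm = PFM("toy", np.array([[10.0, 0.0], [0.0, 10.0], [0.0, 0.0], [0.0, 0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.1)
        assert np.isfinite(pwm.scores).all()

    def test_jaspar_roundtrip(self, tmp_path):
        pfm = default_pfm()
        path = tmp_path / "m.jaspar"
        write_jaspar(pfm, path)
        back = read_jaspar(path)
        assert np.allclose(back.counts, pfm.counts)

    def test_invalid_pfm_rejected(self):
        with pytest.raises(ValueError):
            PFM("bad", np.zeros((4, 0)))
        with pytest.raises(ValueError):
            PFM("bad", np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]))


class TestScoreDistribution:
    def test_single_column_tail(self):
        pfm = PFM("toy", np.array([[10.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1e-9)
        dist = score_pvalue_table(pwm)
        assert dist.pvalue(1.99) == pytest.approx(0.25)

    def test_mass_sums_to_one_and_tail_monotone(self, sharp):
        _, dist = sharp
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.sf) <= 1e-15)

    def test_threshold_below_minimum_gives_p_one(self, sharp):
        pwm, dist = sharp
        below_min = pwm.scores.min(axis=0).sum() - 1.0
        assert dist.pvalue(below_min) == 1.0

    def test_dinucleotide_brute_force(self):
        pfm = PFM("toy", np.array([[8.0, 1.0], [1.0, 5.0], [1.0, 3.0], [0.0, 1.0]]))
        pwm = pfm_to_pwm(pfm)
        dist = score_pvalue_table(pwm)
        iscore = dist.int_scores
        for t in [-3.0, -1.0, 0.0, 0.7, 1.5, 3.0]:
            t_int = int(np.ceil(t * dist.scale - 1e-9))
            brute = sum(
                0.0625
                for a, b in itertools.product(range(4), repeat=2)
                if iscore[a, 0] + iscore[b, 1] >= t_int
            )
            assert dist.pvalue(t) == pytest.approx(brute, abs=1e-12)


def brute_force_scan(pwm, dist, seq, p_threshold, both_strands=True):
    """All-window scorer over the raw sequence (oracle for scan_sequence)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = pwm.width
    t_int = dist.threshold_int(p_threshold)
    hits = []
    variants = [("+", seq)]
    if both_strands:
        rc = "".join(comp[c] for c in reversed(seq))
        variants.append(("-", rc))
    for strand, s in variants:
        for i in range(len(s) - w + 1):
            window = s[i : i + w]
            if "N" in window:
                continue
            score = sum(int(dist.int_scores[idx[c], j]) for j, c in enumerate(window))
            if score >= t_int:
                pos = i if strand == "+" else len(seq) - w - i
                hits.append((pos, strand))
    return sorted(hits)


class TestScan:
    def test_matches_brute_force_on_random_sequences(self, sharp, rng):
        pwm, dist = sharp
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=200))
            got = scan_sequence(pwm, dist, seq, p_threshold=1e-3)
            got_set = sorted(zip(got["position"], got["strand"]))
            assert got_set == brute_force_scan(pwm, dist, seq, 1e-3)

    def test_planted_consensus_found_exactly(self, sharp, rng):
        pwm, dist = sharp
        bg = list(rng.choice(list("ACGT"), size=300))
        cons = default_pfm().consensus()
        seq = "".join(bg[:100]) + cons + "".join(bg[100:])
        hits = scan_sequence(pwm, dist, seq, p_threshold=1e-5)
        fwd = hits[hits["strand"] == "+"]
        assert list(fwd["position"]) == [100]

    def test_strand_symmetry_of_total_counts(self, sharp, rng):
        pwm, dist = sharp
        comp = str.maketrans("ACGT", "TGCA")
        seq = "".join(rng.choice(list("ACGT"), size=500))
        rc = seq.translate(comp)[::-1]
        h1 = scan_sequence(pwm, dist, seq, p_threshold=1e-2)
        h2 = scan_sequence(pwm, dist, rc, p_threshold=1e-2)
        assert len(h1) == len(h2)

    def test_all_n_sequence_has_no_hits(self, sharp):
        pwm, dist = sharp
        assert scan_sequence(pwm, dist, "N" * 100, p_threshold=0.5).empty

    def test_too_short_sequence_rejected(self, sharp):
        pwm, dist = sharp
        with pytest.raises(ValueError):
            scan_sequence(pwm, dist, "ACG")

    def test_batch_counts_equal_per_sequence_scans(self, sharp, rng):
        pwm, dist = sharp
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(20)
        }
        batch = count_hits(pwm, dist, seqs, p_threshold=1e-3)
        for g, s in seqs.items():
            assert batch[g] == len(scan_sequence(pwm, dist, s, p_threshold=1e-3))


class TestPromoterExtraction:
    def _write_genome(self, tmp_path, contigs):
        fa = tmp_path / "genome.fa"
        with open(fa, "w") as fh:
            for name, seq in contigs.items():
                fh.write(f">{name}\n{seq}\n")
        return fa

    def _write_gff(self, tmp_path, rows):
        gff = tmp_path / "ann.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for seqid, start, end, strand, gid in rows:
                fh.write(
                    f"{seqid}\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
                )
        return gff

    def test_plus_strand_window(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=7000))
        fa = self._write_genome(tmp_path, {"c1": seq})
        gff = self._write_gff(tmp_path, [("c1", 6001, 6500, "+", "geneA")])
        ps = extract_promoters(fa, gff, length=5000)
        assert ps.sequences["geneA"] == seq[1000:6000]  # bases 1001..6000
        assert "geneA" not in ps.truncated

    def test_truncation_flagged(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        fa = self._write_genome(tmp_path, {"c1": seq})
        gff = self._write_gff(tmp_path, [("c1", 3001, 3500, "+", "geneB")])
        ps = extract_promoters(fa, gff, length=5000)
        assert len(ps.sequences["geneB"]) == 3000
        assert "geneB" in ps.truncated

    def test_minus_strand_reverse_complement(self, tmp_path):
        seq = "ACGTACGTGGCCAATTACGTACGTGGGTTTCCCAAATTTGGGCCCAAATT"  # 50 bases
        fa = self._write_genome(tmp_path, {"toy": seq})
        gff = self._write_gff(tmp_path, [("toy", 5, 20, "-", "geneC")])
        ps = extract_promoters(fa, gff, length=10)
        comp = str.maketrans("ACGT", "TGCA")
        expected = seq[20:30].translate(comp)[::-1]
        assert ps.sequences["geneC"] == expected

    def test_missing_contig_skipped(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        fa = self._write_genome(tmp_path, {"c1": seq})
        gff = self._write_gff(
            tmp_path, [("c1", 50, 80, "+", "ok"), ("ghost", 10, 30, "+", "lost")]
        )
        ps = extract_promoters(fa, gff, length=20)
        assert "lost" in ps.skipped and "ok" in ps.sequences


class TestDelta:
    def test_median_and_single_species(self):
        counts = pd.DataFrame(
            {"focal": [5, 4], "c1": [2, 4], "c2": [3, 1], "c3": [4, 2]},
            index=["g1", "g2"],
        )
        d = tfbs_delta(counts, "focal", ["c1", "c2", "c3"])
        assert d["g1"] == pytest.approx(2.0)  # 5 - median(2,3,4)
        single = tfbs_delta(counts, "focal", ["c1"])
        assert single["g2"] == pytest.approx(0.0)

    def test_association_and_empty_exposure(self):
        idx = [f"g{i}" for i in range(100)]
        delta = pd.Series([2] * 30 + [0] * 70, index=idx)
        de = pd.DataFrame(
            {
                "logFC": [1.0] * 25 + [0.0] * 5 + [0.0] * 60 + [1.0] * 10,
                "pvalue": [0.01] * 25 + [0.9] * 5 + [0.9] * 60 + [0.01] * 10,
            },
            index=idx,
        )
        res = tfbs_expression_association(delta, de, k=1)
        assert res.pvalue < 1e-6
        with pytest.raises(ValueError, match="empty exposure"):
            tfbs_expression_association(delta, de, k=5)

    def test_downregulated_excluded_from_table(self):
        idx = ["g1", "g2", "g3"]
        delta = pd.Series([2, 2, 0], index=idx)
        de = pd.DataFrame(
            {"logFC": [1.0, -2.0, 0.5], "pvalue": [0.01, 0.01, 0.5]}, index=idx
        )
        res = tfbs_expression_association(delta, de, k=1)
        assert res.table.counts.sum() == 2  # g2 (downregulated) dropped
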
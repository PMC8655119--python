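import math

import numpy as np
import pandas as pd
import pytest

from chromdyn import ArgumentError
from chromdyn.coverage_peaks import CutSiteTrack
from chromdyn.intervals_io import Interval, PeakSet
from chromdyn.motif_analysis import (FootprintProfile, PWM,
                                     binomial_enrichment, depletion_score,
                                     family_heatmap, footprint_mixture,
                                     footprint_profile, pwm_from_consensus,
                                     read_pwms, scan_pwm, write_pwms)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


class TestPWM:
    def test_rows_must_sum_to_one(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ArgumentError):
            PWM("m", "fam", bad)

    def test_consensus_and_threshold(self):
        pwm = pwm_from_consensus("m1", "TGACGTCA", "bZIP")
        assert pwm.consensus == "TGACGTCA"
        assert pwm.threshold <= pwm.max_score
        assert pwm.width == 8

    def test_file_roundtrip(self, tmp_path):
        pwms = [pwm_from_consensus("m1", "TGACGTCA", "bZIP"),
                pwm_from_consensus("m2", "GGGGCGGG", "Zinc Finger")]
        path = tmp_path / "panel.pwm"
        write_pwms(pwms, path)
        got = read_pwms(path)
        assert [p.motif_id for p in got] == ["m1", "m2"]
        assert [p.family for p in got] == ["bZIP", "Zinc Finger"]
        assert got[0].consensus == "TGACGTCA"


class TestScan:
    def _setup(self, rng, motif="TGACGTCA", reverse=False):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        insert = revcomp(motif) if reverse else motif
        seq = seq[:300] + insert + seq[300 + len(motif):]
        peaks = PeakSet([Interval("chr1", 250, 360, "p1")])
        return {"chr1": seq}, peaks

    def test_embedded_consensus_found_at_offset(self, rng):
        pwm = pwm_from_consensus("m1", "TGACGTCA", "bZIP")
        seqs, peaks = self._setup(rng)
        hits = scan_pwm(seqs, peaks, pwm, threshold=pwm.max_score)
        fwd = hits[hits.strand == "+"]
        assert len(fwd) == 1
        assert fwd["start"].iloc[0] == 300
        assert fwd["score"].iloc[0] == pytest.approx(pwm.max_score)

    def test_reverse_complement_reported_on_forward_coords(self, rng):
        pwm = pwm_from_consensus("m1", "TGACGTAA", "bZIP")  # non-palindromic
        seqs, peaks = self._setup(rng, motif="TGACGTAA", reverse=True)
        hits = scan_pwm(seqs, peaks, pwm, threshold=pwm.max_score)
        rev = hits[hits.strand == "-"]
        assert len(rev) == 1
        assert rev["start"].iloc[0] == 300

    def test_absent_motif_no_hits(self, rng):
        pwm = pwm_from_consensus("m1", "TGACGTCA", "bZIP")
        seq = "".join(rng.choice(list("AC"), size=500))  # G/T free: cannot match
        peaks = PeakSet([Interval("chr1", 0, 500, "p1")])
        assert len(scan_pwm({"chr1": seq}, peaks, pwm)) == 0

    def test_peak_beyond_sequence_rejected(self, rng):
        pwm = pwm_from_consensus("m1", "TGACGTCA", "bZIP")
        peaks = PeakSet([Interval("chr1", 0, 700, "p1")])
        with pytest.raises(ArgumentError, match="beyond"):
            scan_pwm({"chr1": "ACGT" * 100}, peaks, pwm)

    def test_strand_symmetry_under_genome_reversal(self, rng):
        pwm = pwm_from_consensus("m1", "TGACGTAA", "bZIP")
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        L = len(seq)
        peaks = PeakSet([Interval("chr1", s, s + 200, f"p{s}")
                         for s in range(0, 1800, 200)])
        fwd_hits = scan_pwm({"chr1": seq}, peaks, pwm, threshold=0.7 * pwm.max_score)
        rc_peaks = PeakSet([Interval("chr1", L - iv.end, L - iv.start, iv.name)
                            for iv in peaks])
        rc_hits = scan_pwm({"chr1": revcomp(seq)}, rc_peaks, pwm,
                           threshold=0.7 * pwm.max_score)
        assert len(fwd_hits) == len(rc_hits)


class TestBinomialEnrichment:
    def _sets(self, n_t, n_b):
        t = PeakSet([Interval("chr1", i * 10, i * 10 + 5, f"t{i}")
                     for i in range(n_t)])
        b = PeakSet([Interval("chr2", i * 10, i * 10 + 5, f"b{i}")
                     for i in range(n_b)])
        return t, b

    def test_exact_tail_value(self):
        # P(X >= 5 | n=10, p=0.5) = 0.623046875 exactly
        t, b = self._sets(10, 10)
        hits = {f"t{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        row = binomial_enrichment(t, b, hits)
        assert row["p"] == pytest.approx(0.623046875, abs=1e-12)

    def test_saturated_background_rate_gives_p_one(self):
        t, b = self._sets(8, 4)
        hits = {f"b{i}" for i in range(4)} | {"t0", "t1"}
        assert binomial_enrichment(t, b, hits)["p"] == pytest.approx(1.0)

    def test_zero_target_hits_gives_p_one(self):
        t, b = self._sets(6, 10)
        hits = {f"b{i}" for i in range(3)}
        assert binomial_enrichment(t, b, hits)["p"] == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        t, _ = self._sets(3, 0)
        with pytest.raises(ArgumentError):
            binomial_enrichment(t, PeakSet([]), set())

    def test_matches_exhaustive_tail_sum(self, rng):
        for _ in range(50):
            n_t = int(rng.integers(1, 31))
            n_b = int(rng.integers(1, 31))
            k_t = int(rng.integers(0, n_t + 1))
            k_b = int(rng.integers(0, n_b + 1))
            t, b = self._sets(n_t, n_b)
            hits = {f"t{i}" for i in range(k_t)} | {f"b{i}" for i in range(k_b)}
            row = binomial_enrichment(t, b, hits)
            p_hat = k_b / n_b
            expected = sum(
                math.comb(n_t, j) * p_hat**j * (1 - p_hat) ** (n_t - j)
                for j in range(k_t, n_t + 1)
            )
            assert row["p"] == pytest.approx(max(min(expected, 1.0), 1e-300),
                                             rel=1e-9)


class TestFamilyHeatmap:
    def _table(self):
        return pd.DataFrame([
            {"cluster": 1, "motif": "a", "family": "bZIP", "neg_log10_p": 8.0},
            {"cluster": 1, "motif": "b", "family": "bZIP", "neg_log10_p": 3.0},
            {"cluster": 2, "motif": "a", "family": "bZIP", "neg_log10_p": 1.0},
            {"cluster": 2, "motif": "b", "family": "bZIP", "neg_log10_p": 0.5},
        ])

    def test_single_family_takes_best_motif(self):
        mat = family_heatmap(self._table())
        assert mat.loc[1, "bZIP"] == 8.0
        assert mat.loc[2, "bZIP"] == 1.0

    def test_row_order_invariance(self):
        t = self._table()
        shuffled = t.sample(frac=1.0, random_state=5)
        assert family_heatmap(t).equals(family_heatmap(shuffled))

    def test_planted_family_dominates_opening_cluster(self, timecourse_results):
        enr = timecourse_results["enrichment_table"]
        mat = family_heatmap(enr)
        for c in timecourse_results["opening_clusters"]:
            assert mat.loc[c].idxmax() == "bZIP"


class TestFootprint:
    def test_single_hit_spike_at_core_start(self):
        track_arr = np.zeros(1_000, dtype=np.int64)
        track_arr[500] = 7
        track = CutSiteTrack({"chr1": track_arr})
        hits = pd.DataFrame([{"peak": "p1", "chrom": "chr1", "start": 500,
                              "end": 508, "strand": "+", "score": 1.0}])
        fp = footprint_profile(track, hits, window=100)
        assert fp.counts[100] == 7
        assert fp.counts.sum() == 7

    def test_opposite_strand_mirroring_gives_symmetric_aggregate(self):
        arr = np.zeros(2_000, dtype=np.int64)
        arr[480] = 5              # 20 bp left of a + site at 500
        arr[1527] = 5             # 20 bp right of a - site [1500,1508)
        track = CutSiteTrack({"chr1": arr})
        hits = pd.DataFrame([
            {"peak": "p1", "chrom": "chr1", "start": 500, "end": 508,
             "strand": "+", "score": 1.0},
            {"peak": "p2", "chrom": "chr1", "start": 1500, "end": 1508,
             "strand": "-", "score": 1.0},
        ])
        fp = footprint_profile(track, hits, window=100)
        assert fp.counts[80] == 10  # both events align at the same profile bin

    def test_no_hits_rejected(self):
        track = CutSiteTrack({"chr1": np.zeros(100, dtype=np.int64)})
        with pytest.raises(ArgumentError):
            footprint_profile(track, pd.DataFrame(columns=["peak", "chrom",
                                                           "start", "end",
                                                           "strand", "score"]))

    def test_depletion_flat_profile_zero(self):
        fp = FootprintProfile("m", 100, 8, np.full(208, 5, dtype=np.int64), 10)
        assert depletion_score(fp) == pytest.approx(0.0)

    def test_depletion_fully_protected_core_one(self):
        counts = np.full(208, 5, dtype=np.int64)
        counts[100:108] = 0
        fp = FootprintProfile("m", 100, 8, counts, 10)
        assert depletion_score(fp) == pytest.approx(1.0)

    def test_depletion_undefined_without_flank_signal(self):
        fp = FootprintProfile("m", 100, 8, np.zeros(208, dtype=np.int64), 10)
        with pytest.raises(ArgumentError, match="undefined"):
            depletion_score(fp)

    def test_generator_protection_recovered(self, timecourse_results):
        assert timecourse_results["depletion_score"] == pytest.approx(0.5, abs=0.05)


class TestFootprintMixture:
    def test_loglik_monotone_and_accurate_on_separated_profiles(self, rng):
        n, L = 60, 100
        flat = rng.poisson(3.0, size=(n, L))
        protected = rng.poisson(3.0, size=(n, L))
        protected[:, 40:60] = rng.poisson(0.2, size=(n, 20))
        X = np.vstack([protected, flat])
        post, info = footprint_mixture(X, core=(40, 60), seed=0)
        pred = (post > 0.5).astype(int)
        truth = np.array([1] * n + [0] * n)
        assert (pred == truth).mean() >= 0.95
        ll = np.array(info["loglik"])
        assert np.all(np.diff(ll) >= -1e-8)

    def test_identical_sites_flagged_degenerate(self):
        X = np.tile(np.arange(20), (15, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            post, info = footprint_mixture(X)
        assert info["degenerate"]
        assert np.allclose(post, 0.5)

    def test_too_few_sites_rejected(self, rng):
        with pytest.raises(ArgumentError):
            footprint_mixture(rng.poisson(1.0, size=(5, 50)))
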
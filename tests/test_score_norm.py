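from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicebind import score_norm as sn
from splicebind import synthetic_data as synth
from splicebind import triplet_hmm as th
from splicebind.errors import DegenerateInputError, TooShortError
from splicebind.seq_io import SequenceRecord


def make_null(scores, length=69, seed=0):
    return sn.NullDistribution(scores=np.asarray(scores, float), length=length, seed=seed)


class TestProbeSpan:
    def test_default_is_69(self):
        assert sn.probe_span() == 69

    def test_arithmetic(self):
        assert sn.probe_span(2, 6, 15) == 27
        assert sn.probe_span(1, 6, 15) == 6

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            sn.probe_span(0, 6, 15)


class TestBuildNull:
    def test_deterministic_under_seed(self, cu_params):
        a = sn.build_null_distribution(cu_params, length=30, n=500, seed=5)
        b = sn.build_null_distribution(cu_params, length=30, n=500, seed=5)
        assert np.array_equal(a.scores, b.scores)

    def test_different_seed_differs(self, cu_params):
        a = sn.build_null_distribution(cu_params, length=30, n=500, seed=5)
        b = sn.build_null_distribution(cu_params, length=30, n=500, seed=6)
        assert not np.array_equal(a.scores, b.scores)

    def test_n_zero_rejected(self, cu_params):
        with pytest.raises(DegenerateInputError):
            sn.build_null_distribution(cu_params, length=30, n=0, seed=0)

    def test_uniform_emissions_give_degenerate_null(self, uniform_params):
        with pytest.raises(DegenerateInputError):
            sn.build_null_distribution(uniform_params, length=30, n=100, seed=0)

    def test_too_short_length(self, cu_params):
        with pytest.raises(TooShortError):
            sn.build_null_distribution(cu_params, length=2, n=10, seed=0)


class TestZScore:
    def test_mean_maps_to_zero(self):
        null = make_null([0.0, 1.0, 2.0, 3.0])
        assert sn.z_score(null.mean, null).z == pytest.approx(0.0)

    def test_paper_relation_2_74_sd(self):
        null = make_null(np.random.default_rng(0).normal(size=1000))
        raw = null.mean + 2.74 * null.sd
        assert sn.z_score(raw, null).z == pytest.approx(2.74)

    def test_self_normalization(self):
        null = make_null(np.random.default_rng(1).normal(3.0, 2.0, size=5000))
        zs = np.array([sn.z_score(s, null).z for s in null.scores])
        assert zs.mean() == pytest.approx(0.0, abs=1e-9)
        assert zs.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_order_preserved(self):
        null = make_null(np.random.default_rng(2).normal(size=100))
        raws = np.sort(np.random.default_rng(3).normal(size=50))
        zs = [sn.z_score(r, null).z for r in raws]
        assert np.all(np.diff(zs) >= 0)


class TestEmpiricalP:
    def test_exceedance_fraction(self):
        scores = np.concatenate([np.zeros(995), np.full(5, 10.0)])
        null = make_null(scores)
        assert sn.empirical_p_value(5.0, null) == 5 / 1000

    def test_below_minimum_is_one(self):
        null = make_null([1.0, 2.0, 3.0])
        assert sn.empirical_p_value(0.0, null) == 1.0

    def test_above_maximum_default_zero_pseudocount_mode(self):
        null = make_null([1.0, 2.0, 3.0])
        assert sn.empirical_p_value(9.0, null) == 0.0
        assert sn.empirical_p_value(9.0, null, pseudocount=True) == 1 / 4

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_raw(self, raws):
        null = make_null(np.random.default_rng(7).normal(size=200))
        ps = [sn.empirical_p_value(r, null) for r in sorted(raws)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestLengthBinNormalize:
    @staticmethod
    def regions(n, region_class="exon", seed=0):
        rng = np.random.default_rng(seed)
        return [
            (region_class, int(rng.integers(50, 500)), float(rng.normal()))
            for _ in range(n)
        ]

    def test_3000_gives_three_full_bins(self):
        _, stats = sn.length_bin_normalize(self.regions(3000))
        assert len(stats["exon"].boundaries) == 3

    def test_partial_final_bin_merged(self):
        _, stats = sn.length_bin_normalize(self.regions(2400))
        assert len(stats["exon"].boundaries) == 2  # 1000 + 1400

    def test_partial_final_bin_kept_when_large(self):
        _, stats = sn.length_bin_normalize(self.regions(2600))
        assert len(stats["exon"].boundaries) == 3  # 1000 + 1000 + 600

    def test_within_bin_self_normalization(self):
        scores, stats = sn.length_bin_normalize(self.regions(2500))
        by_bin = {}
        for s in scores:
            by_bin.setdefault(s.source, []).append(s.z)
        for zs in by_bin.values():
            zs = np.array(zs)
            assert zs.mean() == pytest.approx(0.0, abs=1e-9)
            assert zs.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_bin_named_in_error(self):
        rows = [("exon", 100, 1.0)] * 20
        with pytest.raises(DegenerateInputError, match="exon bin 0"):
            sn.length_bin_normalize(rows)

    def test_classes_binned_independently(self):
        rows = self.regions(1200, "exon", 1) + self.regions(1200, "upstream_intron", 2)
        _, stats = sn.length_bin_normalize(rows)
        assert set(stats) == {"exon", "upstream_intron"}


class TestShuffles:
    def test_mono_preserves_counts(self):
        rec = SequenceRecord("s", "AACG")
        out = sn.shuffle_sequence(rec, "mono", seed=1)
        assert Counter(out.residues) == Counter("AACG")

    @pytest.mark.parametrize("seed", range(6))
    def test_di_preserves_dinucleotide_multiset(self, seed):
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGU"), size=60))
        rec = SequenceRecord("s", s)
        out = sn.shuffle_sequence(rec, "di", seed=seed)
        original = Counter(a + b for a, b in zip(s, s[1:]))
        shuffled = Counter(a + b for a, b in zip(out.residues, out.residues[1:]))
        assert shuffled == original

    def test_di_shuffles_actually_permute(self):
        s = "ACGUACGUACGUACGUACGUAC" * 3
        rec = SequenceRecord("s", s)
        outs = {sn.shuffle_sequence(rec, "di", seed=k).residues for k in range(10)}
        assert len(outs) > 1

    def test_short_input_errors(self):
        with pytest.raises(TooShortError):
            sn.shuffle_sequence(SequenceRecord("s", "A"), "mono")
        with pytest.raises(TooShortError):
            sn.shuffle_sequence(SequenceRecord("s", "AC"), "di")

    def test_homopolymer_di_returns_input(self):
        rec = SequenceRecord("s", "AAAAA")
        assert sn.shuffle_sequence(rec, "di", seed=0).residues == "AAAAA"


class TestCorrelation:
    @staticmethod
    def rec(i, z, kd):
        return sn.ProbeAffinityRecord(f"p{i}", z, kd)

    def test_perfect_anticorrelation(self):
        records = [self.rec(i, z, kd) for i, (z, kd) in enumerate(zip([1, 2, 3], [3, 2, 1]))]
        assert sn.correlate_score_affinity(records) == pytest.approx(-1.0)

    def test_constant_kd_rejected(self):
        records = [self.rec(i, z, 5.0) for i, z in enumerate([1, 2, 3])]
        with pytest.raises(DegenerateInputError):
            sn.correlate_score_affinity(records)

    def test_simulated_matches_population_value(self):
        # kd = a - b*z + noise; population r = -b*sd_z / sqrt(b^2 sd_z^2 + sigma^2)
        a, b, sigma = 150.0, 30.0, 14.5
        rng = np.random.default_rng(12)
        z = rng.normal(0.0, 1.0, size=13)
        kd = np.clip(a - b * z + rng.normal(0.0, sigma, size=13), 1e-3, None)
        pop_r = -b / np.sqrt(b**2 + sigma**2)
        records = [self.rec(i, zi, ki) for i, (zi, ki) in enumerate(zip(z, kd))]
        assert sn.correlate_score_affinity(records) == pytest.approx(pop_r, abs=0.05)

    def test_too_few_records(self):
        with pytest.raises(DegenerateInputError):
            sn.correlate_score_affinity([self.rec(0, 1, 1), self.rec(1, 2, 2)])


class TestHeldOutFoldsIntegration:
    def test_clusters_outscore_gene_matched_background(self, cu_params):
        """Held-out planted clusters beat matched random sequences in all 5 folds."""
        clusters, _ = synth.gen_planted_tract_sequences(
            n=100, length=40, tract_length=18, seed=21
        )
        background = synth.gen_random_sequences(100, 40, seed=22, prefix="bg")
        cluster_scores = np.array(
            [th.log_odds_score(cu_params, r) for r in clusters]
        )
        bg_scores = np.array([th.log_odds_score(cu_params, r) for r in background])
        for fold in range(5):
            held = cluster_scores[fold::5]
            assert np.median(held) > np.median(bg_scores[fold::5])


class TestBackgroundModels:
    def test_uniform_log_prob(self):
        bg = sn.BackgroundModel("uniform")
        assert bg.log_prob(np.arange(10)) == pytest.approx(10 * np.log(1 / 64))

    def test_shuffle_background_changes_score(self, cu_params):
        rec = SequenceRecord("q", "UCUCUCUCUCUCAAAA")
        bg = sn.BackgroundModel("mono_shuffle", params=cu_params, seed=0).bind_query(rec)
        s_mono = th.log_odds_score(cu_params, rec, bg)
        s_uniform = th.log_odds_score(cu_params, rec)
        assert s_mono != pytest.approx(s_uniform)

    def test_gene_matched_requires_pool(self):
        with pytest.raises(ValueError):
            sn.BackgroundModel("gene_matched")
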
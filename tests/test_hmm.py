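"""HMM smoothing, decoding and crossover detection.

The forward-backward marginals are checked against an independent
brute-force oracle that enumerates every hidden-state sequence.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from niptsr.hmm import (
    PosteriorTrack,
    TransitionSpec,
    detect_crossovers,
    forward_backward,
    infer_haplotype,
    read_tracks_tsv,
    transition_prob,
    viterbi,
    write_tracks_tsv,
)


def enumerate_marginals(loglik, positions, spec):
    """Posterior marginals by exhaustive enumeration of all 2^n paths."""
    n = len(loglik)
    r = transition_prob(np.diff(positions), spec)
    r = np.atleast_1d(r)
    post = np.zeros((n, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        p = 0.5 * np.exp(loglik[0][path[0]])
        for i in range(1, n):
            stay = 1.0 - r[i - 1]
            p *= (stay if path[i] == path[i - 1] else r[i - 1]) * np.exp(
                loglik[i][path[i]]
            )
        total += p
        for i, s in enumerate(path):
            post[i, s] += p
    return post / total


def random_chain(rng, n):
    positions = np.sort(rng.integers(0, 5_000_000, size=n))
    loglik = rng.normal(-3, 2, size=(n, 2))
    return positions, loglik


class TestTransitionProb:
    def test_zero_distance(self):
        assert transition_prob(0) == 0.0

    def test_infinite_distance_limit(self):
        assert transition_prob(1e15) == pytest.approx(0.5)

    def test_one_megabase_closed_form(self):
        got = transition_prob(1_000_000, TransitionSpec(0.01))
        assert got == pytest.approx(0.5 * (1 - np.exp(-0.02)))
        assert got == pytest.approx(0.009901, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(-1)

    @given(d=st.floats(0, 1e9), d2=st.floats(0, 1e9))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, d, d2):
        lo, hi = sorted([d, d2])
        assert 0.0 <= transition_prob(lo) <= transition_prob(hi) < 0.5


class TestForwardBackward:
    @pytest.mark.parametrize("n", range(1, 13))
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        positions, loglik = random_chain(rng, n)
        log_post, _ = forward_backward(loglik, positions)
        expected = enumerate_marginals(loglik, positions, TransitionSpec())
        lor = log_post[:, 0] - log_post[:, 1]
        lor_expected = np.log(expected[:, 0]) - np.log(expected[:, 1])
        assert np.abs(lor - lor_expected).max() < 1e-9

    def test_single_uninformative_snp_has_zero_lor(self):
        log_post, _ = forward_backward(np.array([[-1.0, -1.0]]), np.array([0]))
        assert log_post[0, 0] == pytest.approx(log_post[0, 1])

    def test_posteriors_are_proper_distributions(self):
        rng = np.random.default_rng(7)
        positions, loglik = random_chain(rng, 200)
        log_post, _ = forward_backward(loglik, positions)
        sums = np.exp(log_post).sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-12

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(8)
        positions, loglik = random_chain(rng, 50)
        fwd, _ = forward_backward(loglik, positions)
        rev_pos = positions.max() - positions[::-1]
        rev, _ = forward_backward(loglik[::-1], rev_pos)
        assert np.allclose(fwd, rev[::-1], atol=1e-10)

    def test_long_chain_no_underflow(self):
        rng = np.random.default_rng(9)
        positions, loglik = random_chain(rng, 20_000)
        loglik -= 300  # deliberately tiny likelihoods
        log_post, _ = forward_backward(loglik, positions)
        assert np.isfinite(log_post).all()

    def test_rate_zero_pools_evidence(self):
        # c -> 0: a single decision from the pooled likelihood ratio
        rng = np.random.default_rng(10)
        positions, loglik = random_chain(rng, 30)
        log_post, _ = forward_backward(loglik, positions, TransitionSpec(0.0))
        lor = log_post[:, 0] - log_post[:, 1]
        pooled = (loglik[:, 0] - loglik[:, 1]).sum()
        assert np.allclose(lor, pooled, atol=1e-8)

    def test_rate_infinite_classifies_independently(self):
        # c -> inf: each SNP judged on its own likelihood ratio
        rng = np.random.default_rng(11)
        positions, loglik = random_chain(rng, 30)
        positions = positions * 1000  # huge gaps
        log_post, _ = forward_backward(loglik, positions, TransitionSpec(1e6))
        lor = log_post[:, 0] - log_post[:, 1]
        assert np.allclose(lor, loglik[:, 0] - loglik[:, 1], atol=1e-6)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            forward_backward(np.empty((0, 2)), np.empty(0))


class TestViterbiAndCrossovers:
    def test_overwhelming_evidence_gives_constant_path(self):
        n = 100
        positions = np.arange(n) * 40_000
        loglik = np.column_stack([np.full(n, -0.1), np.full(n, -40.0)])
        track = infer_haplotype("mother", "chr1", positions, loglik)
        assert (track.viterbi_path == 0).all()
        assert (track.lor > 0).all()
        assert track.crossovers == []

    def test_state_change_interval_and_midpoint(self):
        positions = np.array([9_500_000, 10_000_000, 10_500_000, 11_000_000])
        loglik = np.array([[-0.1, -20], [-0.1, -20], [-20, -0.1], [-20, -0.1]])
        track = infer_haplotype("mother", "chr1", positions, loglik)
        assert len(track.crossovers) == 1
        co = track.crossovers[0]
        assert (co.start, co.end) == (10_000_000, 10_500_000)
        assert co.midpoint == pytest.approx(10_250_000)
        assert (co.from_state, co.to_state) == ("Hap0", "Hap1")

    def test_viterbi_agrees_with_posterior_under_strong_signal(self):
        rng = np.random.default_rng(12)
        n = 500
        positions = np.arange(n) * 40_000
        truth = (np.arange(n) > 200).astype(int)
        noise = rng.normal(0, 0.3, size=n)
        llr = np.where(truth == 0, 3.0, -3.0) + noise
        loglik = np.column_stack([llr / 2, -llr / 2])
        track = infer_haplotype("mother", "chr1", positions, loglik)
        assert (track.viterbi_path == truth).mean() > 0.99
        assert len(track.crossovers) == 1

    def test_tracks_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        positions, loglik = random_chain(rng, 40)
        track = infer_haplotype("father", "chr2", positions, loglik,
                                state_labels=("RefHap", "AltHap"))
        p = tmp_path / "tracks.tsv"
        write_tracks_tsv([track], p)
        (back,) = read_tracks_tsv(p)
        assert back.parent == "father" and back.chrom == "chr2"
        assert np.allclose(back.lor, track.lor, rtol=1e-4)
        assert (back.viterbi_path == track.viterbi_path).all()
        assert len(back.crossovers) == len(track.crossovers)
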
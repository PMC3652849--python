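import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepdisc.discrim import DiscrimTables, Match, pmd_from_counts
from pepdisc.scoring import (
    binom_tail,
    rank_candidates,
    score_by_ions,
    score_consecutive,
    score_fragments,
)
from pepdisc.synth import SynthConfig, make_candidate, simulate_spectrum
from pepdisc.preprocess import select_peaks
from .conftest import processed_from_peaks
from .oracles import binom_tail_exact


def mk_match(peak_index, series="b", ordinal=1, charge=1, intensity=0.5, error=0.1):
    return Match(peak_index, peak_index, series, ordinal, charge, 500.0, intensity, error)


@pytest.fixture()
def unit_pmd():
    return pmd_from_counts(np.ones(20, dtype=int))


class TestBinomialTail:
    @given(st.integers(0, 31), st.integers(1, 30), st.floats(0.01, 0.9))
    def test_matches_exhaustive_summation(self, k, n, p):
        assert binom_tail(k, n, p) == pytest.approx(binom_tail_exact(k, n, p), abs=1e-12)

    def test_monotone_nondecreasing_significance_in_k(self):
        for n, p in [(10, 0.1406), (25, 0.0279), (30, 0.0706)]:
            sig = [-math.log10(binom_tail(k, n, p)) for k in range(n + 1)]
            assert all(b >= a for a, b in zip(sig, sig[1:]))


class TestFragmentScore:
    def test_zero_matches_zero_score(self, unit_pmd, tables):
        assert score_fragments([], unit_pmd, tables, n0=10, fragment_tol=0.5) == (0.0, 0)

    def test_example_significance_factor(self, unit_pmd, tables):
        matches = [mk_match(i) for i in range(3)]
        s, k = score_fragments(matches, unit_pmd, tables, n0=10, fragment_tol=0.5)
        assert k == 3
        d_total = sum(
            tables.intensity_discriminability(0.5, "s")
            * tables.mz_error_discriminability(0.1, 0.5, "s")
            for _ in range(3)
        )
        expected_sig = -math.log10(binom_tail_exact(3, 10, 0.1406))
        assert s == pytest.approx(d_total * expected_sig, rel=1e-12)

    def test_linearity_in_discriminability(self, unit_pmd, tables):
        matches = [mk_match(i) for i in range(3)]
        doubled = DiscrimTables(
            tables.intensity * 2, tables.mz_error, tables.p_frag, tables.p_consec, tables.p_by
        )
        s1, _ = score_fragments(matches, unit_pmd, tables, 10, 0.5)
        s2, _ = score_fragments(matches, unit_pmd, doubled, 10, 0.5)
        assert s2 == pytest.approx(2 * s1)

    def test_contract_violation_raises(self, unit_pmd, tables):
        with pytest.raises(RuntimeError):
            score_fragments([mk_match(i) for i in range(5)], unit_pmd, tables, n0=3, fragment_tol=0.5)


class TestConsecutiveScore:
    def test_three_consecutive_b_ions_give_two_pairs(self, unit_pmd, tables):
        matches = [mk_match(i, "b", ordinal=i + 1) for i in range(3)]
        s, k1 = score_consecutive(matches, unit_pmd, tables, n1=8, fragment_tol=0.5)
        assert k1 == 2 and s > 0

    def test_nonadjacent_ordinals_no_pairs(self, unit_pmd, tables):
        matches = [mk_match(0, "y", ordinal=2), mk_match(1, "y", ordinal=4)]
        s, k1 = score_consecutive(matches, unit_pmd, tables, n1=8, fragment_tol=0.5)
        assert (s, k1) == (0.0, 0)

    def test_pairs_do_not_cross_series_or_charge(self, unit_pmd, tables):
        matches = [
            mk_match(0, "b", ordinal=1, charge=1),
            mk_match(1, "b", ordinal=2, charge=2),
            mk_match(2, "y", ordinal=3, charge=1),
        ]
        _, k1 = score_consecutive(matches, unit_pmd, tables, n1=8, fragment_tol=0.5)
        assert k1 == 0

    def test_pair_weight_is_geometric_mean(self, unit_pmd, tables):
        matches = [mk_match(0, "b", 1, intensity=0.95), mk_match(1, "b", 2, intensity=0.25)]
        s, k1 = score_consecutive(matches, unit_pmd, tables, n1=8, fragment_tol=0.5)
        w = [
            tables.intensity_discriminability(i, "s") * tables.mz_error_discriminability(0.1, 0.5, "s")
            for i in (0.95, 0.25)
        ]
        expected = math.sqrt(w[0] * w[1]) * -math.log10(binom_tail_exact(1, 8, tables.p_consec))
        assert s == pytest.approx(expected, rel=1e-12)


class TestByIonScore:
    def test_loss_only_matches_score_zero(self, unit_pmd, tables):
        matches = [mk_match(0, "b-H2O"), mk_match(1, "y-NH3")]
        assert score_by_ions(matches, unit_pmd, tables, n2=10, fragment_tol=0.5) == (0.0, 0)

    def test_series_specific_rows_used(self, unit_pmd, tables):
        # y-ion at intensity 0.95, error 0.02, D=1: weight 48.42 * 11.17
        matches = [mk_match(0, "y", intensity=0.95, error=0.02)]
        s, k2 = score_by_ions(matches, unit_pmd, tables, n2=10, fragment_tol=0.5)
        assert k2 == 1
        sig = -math.log10(binom_tail_exact(1, 10, tables.p_by))
        assert s == pytest.approx(540.8514 * sig, rel=1e-9)

    def test_same_match_contributes_to_both_frag_and_by_terms(self, unit_pmd, tables):
        matches = [mk_match(0, "y", intensity=0.95, error=0.02)]
        s_frag, _ = score_fragments(matches, unit_pmd, tables, 10, 0.5)
        s_by, _ = score_by_ions(matches, unit_pmd, tables, 10, 0.5)
        assert s_frag > 0 and s_by > 0  # intentional double counting across terms


class TestRanking:
    def _spectrum_and_candidates(self, seed=5):
        rng = np.random.default_rng(seed)
        cfg = SynthConfig(jitter_sd=0.02, n_noise_peaks=5, seed=seed)
        true_seq = "ELVISLIVESK"
        spec = select_peaks(simulate_spectrum(true_seq, 2, cfg, rng, "r1"))
        others = ["".join(rng.choice(list("ADEFGHILNQSTVW"), 10)) + "K" for _ in range(4)]
        cands = [make_candidate(s) for s in [true_seq] + others]
        return spec, cands, true_seq

    def test_single_candidate_rank_one(self, tables, config):
        spec, cands, _ = self._spectrum_and_candidates()
        psms = rank_candidates(spec, cands[:1], tables, config)
        assert len(psms) == 1 and psms[0].rank == 1

    def test_true_peptide_outranks_random(self, tables, config):
        spec, cands, true_seq = self._spectrum_and_candidates()
        psms = rank_candidates(spec, cands, tables, config)
        assert psms[0].peptide.sequence == true_seq
        assert [p.rank for p in psms] == [1, 2, 3, 4, 5]

    def test_sp_is_sum_of_terms(self, tables, config):
        spec, cands, _ = self._spectrum_and_candidates()
        for p in rank_candidates(spec, cands, tables, config):
            b = p.breakdown
            assert b.Sp == pytest.approx(b.S_frag + b.S_consec + b.S_by)
            assert b.k0 <= b.n0 and b.k1 <= b.n1 and b.k2 <= b.n2

    def test_equal_scores_deterministic_tie_order(self, tables, config):
        # two candidates that match nothing score 0 and tie: lexicographic order
        spec = processed_from_peaks([5000.0], [1.0], precursor_mz=600.0)
        cands = [make_candidate(s) for s in ("GGGGGGK", "AAAAAAK")]
        psms = rank_candidates(spec, cands, tables, config)
        assert [p.peptide.sequence for p in psms] == ["AAAAAAK", "GGGGGGK"]
        assert all(p.breakdown.Sp == 0.0 for p in psms)

    def test_adding_a_match_never_lowers_subscores(self, unit_pmd, tables):
        """Score monotonicity in match count at fixed n."""
        base = [mk_match(i, "b", ordinal=i + 1) for i in range(3)]
        extra = base + [mk_match(3, "b", ordinal=4)]
        for scorer, n in [(score_fragments, 12), (score_consecutive, 11), (score_by_ions, 12)]:
            s_base, _ = scorer(base, unit_pmd, tables, n, 0.5)
            s_more, _ = scorer(extra, unit_pmd, tables, n, 0.5)
            assert s_more >= s_base

    def test_planted_peptide_rank1_rate_low_noise(self, tables, config):
        """In repeated low-noise simulations the true peptide nearly always ranks first."""
        rng = np.random.default_rng(123)
        cfg = SynthConfig(jitter_sd=0.02, n_noise_peaks=5, seed=123)
        wins = 0
        trials = 40
        for t in range(trials):
            true_seq = "".join(rng.choice(list("ADEFGHILNQSTVW"), 9)) + "K"
            spec = select_peaks(simulate_spectrum(true_seq, 2, cfg, rng, f"s{t}"))
            decoys = [make_candidate("".join(rng.choice(list("ADEFGHILNQSTVW"), 9)) + "K", True)
                      for _ in range(6)]
            psms = rank_candidates(spec, [make_candidate(true_seq)] + decoys, tables, config)
            wins += psms[0].peptide.sequence == true_seq
        assert wins / trials >= 0.95
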
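import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepdisc.discrim import (
    DiscrimTables,
    compute_pmd,
    match_peaks,
    pmd_from_counts,
    train_tables,
)
from pepdisc.synth import SynthConfig, make_candidate, simulate_spectrum
from pepdisc.preprocess import select_peaks
from pepdisc.theoretical import TheoreticalIon, fragment_ions
from .conftest import processed_from_peaks
from .oracles import pmd_bruteforce


def ion(mz, series="b", ordinal=1, charge=1):
    return TheoreticalIon(series, ordinal, charge, mz)


class TestMatchPeaks:
    def test_match_within_tolerance(self):
        spec = processed_from_peaks([500.00], [10.0])
        (m,) = match_peaks(spec, [ion(500.30)], fragment_tol=0.5)
        assert m.abs_error == pytest.approx(0.30)

    def test_no_match_outside_tolerance(self):
        spec = processed_from_peaks([500.00], [10.0])
        assert match_peaks(spec, [ion(500.60)], fragment_tol=0.5) == []

    def test_peak_takes_closest_ion(self):
        spec = processed_from_peaks([500.00], [10.0])
        (m,) = match_peaks(spec, [ion(499.8, ordinal=1), ion(500.1, ordinal=2)], 0.5)
        assert m.mz_theo == pytest.approx(500.1)

    def test_one_to_one_assignment(self):
        # two peaks, two ions: greedy by error pairs each peak with its own ion
        spec = processed_from_peaks([500.00, 500.25], [10.0, 5.0])
        matches = match_peaks(spec, [ion(500.05, ordinal=1), ion(500.30, ordinal=2)], 0.5)
        assert len(matches) == 2
        assert len({m.peak_index for m in matches}) == 2
        assert len({m.ion_index for m in matches}) == 2


class TestPMD:
    def test_ratio_formula(self):
        pmd = pmd_from_counts(np.array([1, 2, 5]))
        assert pmd.mean_matches == pytest.approx(8 / 3)
        assert pmd.discriminability(0) == pytest.approx(8 / 3)
        assert pmd.discriminability(1) == pytest.approx(4 / 3)
        assert pmd.discriminability(2) == pytest.approx(8 / 15)

    def test_uniform_counts_give_unit_discriminability(self):
        pmd = pmd_from_counts(np.array([1, 1, 1, 1]))
        assert all(pmd.discriminability(i) == pytest.approx(1.0) for i in range(4))

    def test_promiscuous_peak_has_minimal_discriminability(self):
        pmd = pmd_from_counts(np.array([1, 3, 7, 7, 2]))
        d = [pmd.discriminability(i) for i in range(5)]
        assert np.argmax(pmd.match_counts) == np.argmin(d)

    def test_unmatched_peaks_excluded_from_mean_and_have_no_pmd(self):
        pmd = pmd_from_counts(np.array([0, 2, 4]))
        assert pmd.mean_matches == pytest.approx(3.0)
        with pytest.raises(ValueError):
            pmd.discriminability(0)

    def test_empty_map(self):
        pmd = pmd_from_counts(np.array([0, 0]))
        assert pmd.is_empty and pmd.mean_matches == 0.0

    def test_shifted_form_clamped(self):
        pmd = pmd_from_counts(np.array([1, 9]), form="shifted")
        assert pmd.discriminability(0) == pytest.approx(5.0)
        assert pmd.discriminability(1) == pytest.approx(0.1)

    @given(st.integers(0, 5000))
    def test_matches_bruteforce_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_peaks = int(rng.integers(2, 15))
        n_cands = int(rng.integers(1, 10))
        spec = processed_from_peaks(
            np.sort(rng.uniform(200, 1200, n_peaks)), rng.uniform(1, 100, n_peaks)
        )
        seqs = ["".join(rng.choice(list("ACDEFGHILMNQSTVWY"), rng.integers(6, 12))) + "K"
                for _ in range(n_cands)]
        cands = [make_candidate(s) for s in seqs]
        pmd = compute_pmd(spec, cands, fragment_tol=0.5)
        ion_mzs = [fragment_ions(c, spec.precursor_charge).mz for c in cands]
        assert pmd.match_counts.tolist() == pmd_bruteforce(spec.mz, ion_mzs, 0.5)

    def test_intense_peak_can_have_lowest_discriminability(self):
        """PMD is independent of intensity: the base peak may discriminate least."""
        pmd = pmd_from_counts(np.array([8, 1, 1, 1]))  # peak 0 is the base peak
        d = [pmd.discriminability(i) for i in range(4)]
        assert d[0] == min(d)


class TestTableLookups:
    def test_intensity_cells(self, tables):
        assert tables.intensity_discriminability(0.65, "b") == 6.98
        assert tables.intensity_discriminability(1.0, "s") == 3.09
        assert tables.intensity_discriminability(0.95, "y") == 48.42
        assert tables.intensity_discriminability(0.0, "b") == 1.14
        assert tables.intensity_discriminability(0.999999, "y") == 48.42

    def test_mz_error_cells(self, tables):
        assert tables.mz_error_discriminability(0.02, 0.5, "y") == 11.17
        assert tables.mz_error_discriminability(0.26, 0.5, "s") == 1.43
        assert tables.mz_error_discriminability(0.5, 0.5, "b") == 0.54  # edge joins last bin

    def test_error_rescaled_to_training_window(self, tables):
        # 0.02 Da at 0.2 Da tolerance scales to 0.05: second bin
        assert tables.mz_error_discriminability(0.02, 0.2, "y") == 9.32

    def test_domain_errors(self, tables):
        with pytest.raises(ValueError):
            tables.intensity_discriminability(1.2, "b")
        with pytest.raises(ValueError):
            tables.mz_error_discriminability(0.6, 0.5, "y")

    def test_serialization_roundtrip(self, tables, tmp_path):
        path = tmp_path / "tables.tsv"
        tables.save(path)
        back = DiscrimTables.load(path)
        assert np.array_equal(back.intensity, tables.intensity)
        assert np.array_equal(back.mz_error, tables.mz_error)
        assert (back.p_frag, back.p_consec, back.p_by) == (
            tables.p_frag, tables.p_consec, tables.p_by,
        )


class TestTraining:
    def _corpus(self, n=30, seed=0, jitter=0.02, noise=20):
        """Simulated spectra paired with their true and reversed peptides."""
        rng = np.random.default_rng(seed)
        cfg = SynthConfig(jitter_sd=jitter, n_noise_peaks=noise, seed=seed)
        correct, incorrect = [], []
        for i in range(n):
            seq = "".join(rng.choice(list("ADEFGHILNQSTVWY"), 9)) + "K"
            spec = select_peaks(simulate_spectrum(seq, 2, cfg, rng, f"t{i}"))
            correct.append((spec, make_candidate(seq)))
            incorrect.append((spec, make_candidate(seq[::-1], is_decoy=True)))
        return correct, incorrect

    def test_equal_counts_give_unit_cell(self):
        # identical corpora: every bin has equal correct and random counts,
        # so all discriminabilities are exactly 1.0 (empty bins warn)
        pep = make_candidate("GGGGGGK")
        theo = fragment_ions(pep, 2)
        spec = processed_from_peaks(theo.mz[:4] + 0.01, [10.0, 8.0, 6.0, 4.0])
        with pytest.warns(UserWarning):
            tables = train_tables([(spec, pep)], [(spec, pep)], fragment_tol=0.5)
        assert np.all(tables.intensity == 1.0)
        assert np.all(tables.mz_error == 1.0)

    def test_error_rows_decrease_for_concentrated_correct_matches(self):
        correct, incorrect = self._corpus(n=40, seed=3)
        tables = train_tables(correct, incorrect, fragment_tol=0.5)
        pooled = tables.mz_error[2]
        # correct matches concentrate at low error: early bins beat late bins
        assert pooled[0] > pooled[-1]
        assert pooled[:2].mean() > pooled[-3:].mean()

    def test_planted_random_match_rate_recovered(self):
        """p_frag estimates the fraction of decoy theoretical ions that match."""
        rng = np.random.default_rng(42)
        rate = 0.1406
        incorrect = []
        for i in range(300):
            seq = "".join(rng.choice(list("ADEFGHILNQSTVWY"), 10)) + "K"
            pep = make_candidate(seq)
            theo = fragment_ions(pep, 1)
            hit = rng.random(len(theo)) < rate
            mz = theo.mz[hit]
            if mz.size == 0:
                continue
            spec = processed_from_peaks(
                mz + rng.normal(0, 0.01, mz.size), rng.uniform(1, 10, mz.size), charge=1
            )
            incorrect.append((spec, pep))
        correct = incorrect[:5]
        tables = train_tables(correct, incorrect, fragment_tol=0.5)
        assert tables.p_frag == pytest.approx(rate, abs=0.02)
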
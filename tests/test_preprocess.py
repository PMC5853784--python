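"""Spectral pre-treatment: splice correction, 800 nm filter, trim, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafspec as ls
from leafspec import preprocess
from leafspec.preprocess import PreprocessError
from leafspec.spectra import Spectrum

from conftest import make_record


class TestJumpCorrection:
    def test_continuous_spectrum_unchanged(self, smooth_spectrum):
        out = preprocess.correct_detector_jumps(smooth_spectrum, [1000, 1800])
        assert np.allclose(out.reflectance, smooth_spectrum.reflectance, atol=1e-9)

    @pytest.mark.parametrize("junctions", [(1000, 1800), (1000, 1830)])
    def test_constructed_offsets_removed(self, smooth_spectrum, junctions):
        """+0.02 above the first junction and -0.015 above the second are
        recovered within 1e-6 of the pre-artifact truth (both instrument
        junction layouts handled identically)."""
        truth = smooth_spectrum.reflectance
        w = smooth_spectrum.wavelengths_nm
        r = truth.copy()
        r[w > junctions[0]] += 0.02
        r[w > junctions[1]] -= 0.015
        out = preprocess.correct_detector_jumps(Spectrum(w, r), junctions)
        assert np.abs(out.reflectance - truth).max() < 1e-6

    def test_idempotent(self, smooth_spectrum):
        w = smooth_spectrum.wavelengths_nm
        r = smooth_spectrum.reflectance.copy()
        r[w > 1000] += 0.02
        once = preprocess.correct_detector_jumps(Spectrum(w, r), [1000])
        twice = preprocess.correct_detector_jumps(once, [1000])
        assert np.abs(twice.reflectance - once.reflectance).max() < 1e-9

    def test_reference_segment_untouched(self, smooth_spectrum):
        w = smooth_spectrum.wavelengths_nm
        r = smooth_spectrum.reflectance.copy()
        r[w > 1000] += 0.05
        out = preprocess.correct_detector_jumps(Spectrum(w, r), [1000, 1800])
        assert np.array_equal(out.reflectance[w <= 1000], r[w <= 1000])

    def test_continuity_criterion_after_correction(self, smooth_spectrum):
        w = smooth_spectrum.wavelengths_nm
        r = smooth_spectrum.reflectance.copy()
        r[w > 1000] += 0.03
        out = preprocess.correct_detector_jumps(Spectrum(w, r), [1000])
        assert preprocess.is_continuous_at(out, 1000)
        assert not preprocess.is_continuous_at(Spectrum(w, r), 1000)

    def test_multiplicative_variant(self, smooth_spectrum):
        truth = smooth_spectrum.reflectance
        w = smooth_spectrum.wavelengths_nm
        r = truth.copy()
        r[w > 1000] *= 1.05
        out = preprocess.correct_detector_jumps(Spectrum(w, r), [1000], method="multiplicative")
        assert np.abs(out.reflectance - truth).max() < 1e-4

    def test_junction_outside_domain(self):
        s = Spectrum(np.arange(400, 900), np.full(500, 0.4))
        with pytest.raises(PreprocessError, match="domain"):
            preprocess.correct_detector_jumps(s, [1000])


class TestOutlierFilter:
    def test_toy_set_keeps_exactly_four(self, flat_record_factory):
        """r(800) in {0.2, 0.35, 0.4, 0.5, 0.6, 0.61, 0.9}: inclusive bounds
        keep 0.35..0.6 (4 records), remove the rest."""
        levels = [0.2, 0.35, 0.4, 0.5, 0.6, 0.61, 0.9]
        recs = [flat_record_factory(v, genotype=f"G{i}") for i, v in enumerate(levels)]
        kept, removed = preprocess.filter_outliers(recs)
        assert len(kept) == 4
        assert len(removed) == 3
        reasons = {r.record.genotype: r.reason for r in removed}
        assert reasons["G0"].startswith("below")
        assert reasons["G5"].startswith("above")
        assert removed[0].r800 == pytest.approx(0.2)

    def test_spectrum_not_covering_band_is_error(self):
        rec = make_record(np.full(100, 0.4), np.arange(400, 500))
        with pytest.raises(PreprocessError, match="800"):
            preprocess.filter_outliers([rec])


class TestTrim:
    def test_full_range_trims_to_2001(self, smooth_spectrum):
        out = preprocess.trim_spectrum(smooth_spectrum)
        assert len(out) == 2001
        assert int(out.wavelengths_nm[0]) == 400 and int(out.wavelengths_nm[-1]) == 2400

    def test_idempotent_and_identity_on_own_domain(self, smooth_spectrum):
        once = preprocess.trim_spectrum(smooth_spectrum)
        twice = preprocess.trim_spectrum(once)
        assert once == twice
        assert preprocess.trim_spectrum(once, 400, 2400) == once

    def test_range_outside_domain(self, smooth_spectrum):
        with pytest.raises(PreprocessError):
            preprocess.trim_spectrum(smooth_spectrum, 300, 2400)


class TestReplicateAveraging:
    def test_singleton_group_unchanged(self, flat_record_factory):
        rec = flat_record_factory(0.4)
        (out,) = preprocess.average_replicates([rec])
        assert np.array_equal(out.spectrum.reflectance, rec.spectrum.reflectance)
        assert out.leaf_replicate == "mean"

    def test_mean_of_constant_spectra(self, flat_record_factory):
        recs = [flat_record_factory(v, leaf_replicate=i + 1) for i, v in enumerate([0.3, 0.4, 0.5])]
        (out,) = preprocess.average_replicates(recs)
        assert np.allclose(out.spectrum.reflectance, 0.4)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_bounded_by_min_max_pointwise(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(400, 500)
        refl = rng.uniform(0.1, 0.9, size=(3, grid.size))
        recs = [make_record(refl[i], grid, leaf_replicate=i + 1) for i in range(3)]
        (out,) = preprocess.average_replicates(recs)
        assert np.all(out.spectrum.reflectance >= refl.min(axis=0) - 1e-12)
        assert np.all(out.spectrum.reflectance <= refl.max(axis=0) + 1e-12)

    def test_mixed_grids_rejected(self, flat_record_factory):
        a = flat_record_factory(0.4, leaf_replicate=1)
        b = make_record(np.full(100, 0.4), np.arange(400, 500), leaf_replicate=2)
        with pytest.raises(PreprocessError, match="grids"):
            preprocess.average_replicates([a, b])


def test_filter_trim_commute(small_dataset):
    records, _, _ = small_dataset
    from dataclasses import replace

    kept_a, _ = preprocess.filter_outliers(records)
    a = [replace(r, spectrum=preprocess.trim_spectrum(r.spectrum)) for r in kept_a]
    b_trimmed = [replace(r, spectrum=preprocess.trim_spectrum(r.spectrum)) for r in records]
    b, _ = preprocess.filter_outliers(b_trimmed)
    assert [r.record_id for r in a] == [r.record_id for r in b]
    for ra, rb in zip(a, b):
        assert ra.spectrum == rb.spectrum


def test_preprocess_changes_length_only_at_trim(small_dataset):
    records, _, _ = small_dataset
    kept, removed = preprocess.preprocess_records(records, order=("jumps", "average", "filter"))
    assert all(len(r.spectrum) == 2151 for r in kept)
    kept2, _ = preprocess.preprocess_records(records)
    assert all(len(r.spectrum) == 2001 for r in kept2)
    assert len(kept2) + len(removed) == len({(r.genotype, r.experiment, r.repetition) for r in records})
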
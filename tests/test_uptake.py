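"""Centroids, deuterium uptake, region resolution, difference maps."""

import numpy as np
import pytest

from asymx.peptides import Peptide
from asymx.spectra import IsotopeSpectrum, spectrum_centroid
from asymx.uptake import (UptakeRecord, deuterium_uptake,
                          resolve_region_uptake, state_difference_map)


def _spec(peaks, charge=1, **kw):
    defaults = dict(peptide_id="p", state="apo", time_s=0.0)
    defaults.update(kw)
    return IsotopeSpectrum(charge=charge, peaks=peaks, **defaults)


class TestCentroid:
    def test_single_peak_neutralization(self):
        s = _spec([(500.0, 1.0)])
        assert spectrum_centroid(s) == pytest.approx(498.99272, abs=1e-4)

    def test_symmetric_peaks_average(self):
        s = _spec([(499.0, 0.5), (501.0, 0.5)])
        assert spectrum_centroid(s) == pytest.approx(500.0 - 1.007276466622,
                                                     abs=1e-9)

    def test_matches_hand_sum(self):
        mz = [500.0, 501.0, 502.0, 503.0, 504.0]
        inten = [0.2, 1.0, 0.7, 0.3, 0.05]
        s = _spec(list(zip(mz, inten)), charge=2)
        mean_mz = np.dot(mz, inten) / np.sum(inten)
        assert spectrum_centroid(s) == pytest.approx(
            2 * (mean_mz - 1.007276466622), abs=1e-9)

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError):
            _spec([(500.0, 0.0), (501.0, 0.0)])


class TestUptake:
    def test_zero_shift(self):
        rec = deuterium_uptake(1000.0, 1000.0, n_amides=10)
        assert rec.uptake_D == 0.0 and rec.percent_D == 0.0

    def test_percent_normalization(self):
        """4 Da over 10 amides at 80% labeling -> 50 %D."""
        rec = deuterium_uptake(1004.0, 1000.0, n_amides=10, label_fraction=0.8)
        assert rec.percent_D == pytest.approx(50.0)

    def test_label_fraction_from_dilution(self):
        # 10 uL protein into 40 uL D2O: 40/50 = 0.8 of amide sites labelable
        assert 40.0 / 50.0 == 0.8
        rec = deuterium_uptake(1008.0, 1000.0, n_amides=10, label_fraction=0.8)
        assert rec.percent_D == pytest.approx(100.0)

    def test_small_negative_shift_clipped(self):
        with pytest.warns(UserWarning):
            rec = deuterium_uptake(999.9, 1000.0, 10, sd=0.1)
        assert rec.uptake_D == 0.0 and not rec.flagged

    def test_large_negative_shift_flagged(self):
        rec = deuterium_uptake(999.0, 1000.0, 10, sd=0.1)
        assert rec.flagged


def _rec(pid, uptake, sd=0.0, state="apo", t=1200.0):
    return UptakeRecord(peptide_id=pid, state=state, time_s=t,
                        uptake_D=uptake, percent_D=0.0, sd=sd)


class TestRegionResolution:
    def test_suffix_geometry_region_48_52(self, fixture_protein):
        """47-59 minus 53-59 resolves region 48-52 with exactly 5 amides;
        equal uptake (bound states) leaves zero deuterium in the region."""
        seq, _ = fixture_protein
        long_p = Peptide.from_protein(seq, 47, 59)
        short_p = Peptide.from_protein(seq, 53, 59)
        reg = resolve_region_uptake(long_p, _rec("47-59", 2.5),
                                    short_p, _rec("53-59", 2.5), seq)
        assert (reg.start, reg.end) == (48, 52)
        assert reg.n_amides == 5
        assert reg.uptake_D == 0.0 and reg.percent_D == 0.0

    def test_prefix_geometry_region_231_237(self, fixture_protein):
        seq, _ = fixture_protein
        long_p = Peptide.from_protein(seq, 215, 237)
        short_p = Peptide.from_protein(seq, 215, 230)
        reg = resolve_region_uptake(long_p, _rec("215-237", 6.0),
                                    short_p, _rec("215-230", 4.0), seq)
        assert (reg.start, reg.end) == (231, 237)
        assert reg.n_amides == 7
        assert reg.uptake_D == pytest.approx(2.0)

    def test_quadrature_error_propagation(self, fixture_protein):
        seq, _ = fixture_protein
        long_p = Peptide.from_protein(seq, 47, 59)
        short_p = Peptide.from_protein(seq, 53, 59)
        reg = resolve_region_uptake(long_p, _rec("47-59", 4.0, sd=0.3),
                                    short_p, _rec("53-59", 2.5, sd=0.4), seq)
        assert reg.uptake_D == pytest.approx(1.5)
        assert reg.sd == pytest.approx(0.5)

    def test_argument_order_irrelevant(self, fixture_protein):
        seq, _ = fixture_protein
        long_p = Peptide.from_protein(seq, 47, 59)
        short_p = Peptide.from_protein(seq, 53, 59)
        a = resolve_region_uptake(long_p, _rec("47-59", 4.0),
                                  short_p, _rec("53-59", 2.5), seq)
        b = resolve_region_uptake(short_p, _rec("53-59", 2.5),
                                  long_p, _rec("47-59", 4.0), seq)
        assert (a.start, a.end, a.uptake_D) == (b.start, b.end, b.uptake_D)

    def test_identical_spans_rejected(self, fixture_protein):
        seq, _ = fixture_protein
        p = Peptide.from_protein(seq, 47, 59)
        with pytest.raises(ValueError):
            resolve_region_uptake(p, _rec("47-59", 4.0), p, _rec("47-59", 4.0),
                                  seq)

    def test_non_nested_peptides_rejected(self, fixture_protein):
        seq, _ = fixture_protein
        a = Peptide.from_protein(seq, 47, 59)
        b = Peptide.from_protein(seq, 54, 70)
        with pytest.raises(ValueError):
            resolve_region_uptake(a, _rec("47-59", 4.0), b, _rec("54-70", 2.0),
                                  seq)

    def test_subtraction_consistency(self, fixture_protein):
        """Per-amide uptakes summed into peptides, then region-resolved,
        recover the per-region truth to 1e-9 (noiseless)."""
        seq, _ = fixture_protein
        rng = np.random.default_rng(7)
        per_amide = {}
        long_p = Peptide.from_protein(seq, 47, 59)
        short_p = Peptide.from_protein(seq, 53, 59)
        from asymx.peptides import observable_amides
        for r in observable_amides(long_p, seq):
            per_amide[r] = rng.uniform(0.0, 0.8)
        up_long = sum(per_amide[r] for r in observable_amides(long_p, seq))
        up_short = sum(per_amide[r] for r in observable_amides(short_p, seq))
        truth = sum(per_amide[r] for r in (48, 49, 50, 51, 52))
        reg = resolve_region_uptake(long_p, _rec("47-59", up_long),
                                    short_p, _rec("53-59", up_short), seq)
        assert reg.uptake_D == pytest.approx(truth, abs=1e-9)


class TestDifferenceMap:
    def _records(self, values, state):
        return [UptakeRecord(pid, state, 1200.0, v, percent_D=v * 10, sd=0.5)
                for pid, v in values.items()]

    def test_self_difference_is_zero(self):
        recs = self._records({"a": 1.0, "b": 2.0}, "apo")
        d = state_difference_map(recs, recs, 1200.0)
        assert np.allclose(d["delta_percent_D"], 0.0)

    def test_protection_gives_positive_map(self):
        apo = self._records({"a": 3.0, "b": 4.0}, "apo")
        na = self._records({"a": 1.0, "b": 2.0}, "Na")
        d = state_difference_map(apo, na, 1200.0)
        assert (d["delta_percent_D"] > 0).all()
        assert np.allclose(d["delta_sd"], np.hypot(0.5, 0.5))

    def test_missing_peptide_excluded(self, caplog):
        apo = self._records({"a": 3.0, "b": 4.0}, "apo")
        na = self._records({"a": 1.0}, "Na")
        d = state_difference_map(apo, na, 1200.0)
        assert list(d["peptide_id"]) == ["a"]
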
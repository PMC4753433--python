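"""Isotope envelopes, Poisson-binomial deuteration, mixture deconvolution,
regime classification and uptake kinetics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymx import envelopes as E
from asymx.spectra import DEUTERIUM_STEP, spectrum_centroid

NAT = E.natural_envelope(E.peptide_composition("GTSLPEAAAKLL"))


class TestNaturalEnvelope:
    def test_three_carbons_match_exhaustive_enumeration(self):
        """Iterative convolution equals brute-force expansion over all
        isotope combinations for a tiny composition."""
        from pyteomics.mass import nist_mass
        iso = {k: v for k, v in nist_mass["C"].items() if k != 0 and v[1] > 0}
        light = min(iso)
        _, probs = E.natural_envelope({"C": 3})
        brute = np.zeros(4)
        for combo in itertools.product(sorted(iso), repeat=3):
            offset = sum(c - light for c in combo)
            brute[offset] += np.prod([iso[c][1] for c in combo])
        assert np.allclose(probs, brute[:len(probs)], atol=1e-12)

    def test_single_isotope_element_gives_delta(self):
        table = {"Q": {0: (1.0, 1.0), 1: (1.0, 1.0)}}
        mono, probs = E.natural_envelope({"Q": 7}, isotope_data=table)
        assert probs.tolist() == [1.0]
        assert mono == pytest.approx(7.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(c=st.integers(0, 40), h=st.integers(1, 60), n=st.integers(0, 10),
           o=st.integers(0, 10), s=st.integers(0, 2))
    def test_distribution_sums_to_one(self, c, h, n, o, s):
        _, probs = E.natural_envelope({"C": c, "H": h, "N": n, "O": o, "S": s})
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (probs >= 0).all()

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            E.natural_envelope({"Xx": 1})

    def test_averagine_composition_scales_with_mass(self):
        comp = E.averagine_composition(1111.254)
        assert comp["C"] == round(4.9384 * 10)
        with pytest.raises(ValueError):
            E.averagine_composition(-5.0)


class TestPoissonBinomial:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_matches_exhaustive_enumeration(self, probs):
        """Sequential convolution equals summing over all 2^n outcomes for
        n <= 10 amides."""
        dist = E.poisson_binomial(probs)
        brute = np.zeros(len(probs) + 1)
        for outcome in itertools.product((0, 1), repeat=len(probs)):
            w = np.prod([p if o else 1 - p for p, o in zip(probs, outcome)])
            brute[sum(outcome)] += w
        assert np.allclose(dist, brute, atol=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fair_pair_weights(self):
        assert np.allclose(E.poisson_binomial([0.5, 0.5]), [0.25, 0.5, 0.25])


class TestDeuteratedEnvelope:
    def test_zero_probs_leave_natural_unchanged(self):
        mono, nat = NAT
        masses, inten = E.deuterated_envelope(NAT, 5, np.zeros(5))
        agg = {}
        for m, a in zip(masses, inten):
            agg[round(m, 4)] = agg.get(round(m, 4), 0.0) + a
        for k, p in enumerate(nat):
            assert agg[round(mono + k * E.C13_STEP, 4)] == pytest.approx(p)

    def test_full_exchange_shifts_by_n_deuteriums(self):
        mono, nat = NAT
        masses, inten = E.deuterated_envelope(NAT, 6, np.ones(6),
                                              label_fraction=1.0)
        cent = np.dot(masses, inten) / inten.sum()
        nat_cent = mono + np.dot(np.arange(len(nat)), nat) * E.C13_STEP
        assert cent - nat_cent == pytest.approx(6 * DEUTERIUM_STEP, abs=1e-9)

    def test_label_fraction_scales_uptake(self):
        masses, inten = E.deuterated_envelope(NAT, 6, np.ones(6),
                                              label_fraction=0.8)
        mono, nat = NAT
        cent = np.dot(masses, inten) / inten.sum()
        nat_cent = mono + np.dot(np.arange(len(nat)), nat) * E.C13_STEP
        assert cent - nat_cent == pytest.approx(0.8 * 6 * DEUTERIUM_STEP,
                                                abs=1e-9)

    def test_normalization_preserved(self):
        _, inten = E.deuterated_envelope(NAT, 8, np.full(8, 0.37))
        assert inten.sum() == pytest.approx(1.0, abs=1e-6)


class TestTimeSeries:
    def test_time_zero_is_undeuterated_in_all_regimes(self):
        mono, nat = NAT
        for spec in (E.RegimeSpec("EX2", rates=tuple([1e-3] * 12)),
                     E.RegimeSpec("EX1", k_op=1e-3),
                     E.RegimeSpec("mixed", rates=tuple([1e-4] * 12),
                                  k_op=1e-3)):
            s = E.simulate_time_series(NAT, 12, spec, [0.0], noise_cv=0.0)[0]
            cent = spectrum_centroid(s)
            nat_cent = mono + np.dot(np.arange(len(nat)), nat) * E.C13_STEP
            # 1e-5 Da absorbs the sub-ppm trimming of negligible peaks
            assert cent == pytest.approx(nat_cent, abs=1e-5)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            E.simulate_time_series(NAT, 12, E.RegimeSpec("EX1", k_op=1e-3), [])

    def test_percent_uptake_invariant_to_charge(self):
        spec = E.RegimeSpec("EX2", rates=tuple([2e-3] * 12))
        cents = []
        for z in (1, 2, 3):
            s = E.simulate_time_series(NAT, 12, spec, [120.0], charge=z,
                                       noise_cv=0.0)[0]
            cents.append(spectrum_centroid(s))
        assert np.ptp(cents) < 1e-6  # neutral centroid identical per charge

    def test_seeded_noise_reproducible(self):
        spec = E.RegimeSpec("EX1", k_op=1e-3)
        a = E.simulate_time_series(NAT, 12, spec, [120.0], noise_cv=0.05,
                                   seed=9)[0]
        b = E.simulate_time_series(NAT, 12, spec, [120.0], noise_cv=0.05,
                                   seed=9)[0]
        assert a.peaks == b.peaks

    def test_regime_spec_validation(self):
        with pytest.raises(ValueError):
            E.RegimeSpec("EX9")
        with pytest.raises(ValueError):
            E.RegimeSpec("EX2")
        with pytest.raises(ValueError):
            E.RegimeSpec("EX1", k_op=0.0)


class TestMixtureFit:
    def test_recovers_even_mixture(self):
        """A 50/50 mixture of components ~5 Da apart is recovered with
        weights +-0.02 and separation +-0.1 Da (noiseless)."""
        mono, nat = NAT
        n = 12
        light = E.deuterated_envelope(NAT, n, np.full(n, 0.1))
        heavy = E.deuterated_envelope(NAT, n, np.full(n, 0.62))
        masses = np.concatenate([light[0], heavy[0]])
        inten = np.concatenate([0.5 * light[1], 0.5 * heavy[1]])
        order = np.argsort(masses)
        s = E.sticks_to_spectrum(masses[order], inten[order], charge=2)
        model = E.fit_envelope_mixture(s, NAT, n)
        assert model.n_components == 2
        assert model.weights[1] == pytest.approx(0.5, abs=0.02)
        sep = model.centroids[1] - model.centroids[0]
        true_sep = (0.62 - 0.1) * 0.8 * n * DEUTERIUM_STEP
        assert sep == pytest.approx(true_sep, abs=0.1)

    def test_ex1_weight_recovery_roundtrip(self):
        """Generate-then-fit: heavy weights 1-exp(-k_op t) recovered within
        0.02 at each exposure (noiseless)."""
        k_op = 1.5e-3
        spec = E.RegimeSpec("EX1", k_op=k_op)
        series = E.simulate_time_series(NAT, 12, spec, [15, 120, 1200],
                                        noise_cv=0.0)
        for s, t in zip(series, [15, 120, 1200]):
            model = E.fit_envelope_mixture(s, NAT, 12)
            true_w = 1.0 - np.exp(-k_op * t)
            assert model.n_components == 2
            assert model.weights[1] == pytest.approx(true_w, abs=0.02)

    def test_pure_single_envelope_selects_one_component(self):
        spec = E.RegimeSpec("EX2", rates=tuple([2e-3] * 12))
        s = E.simulate_time_series(NAT, 12, spec, [300.0], noise_cv=0.0)[0]
        model = E.fit_envelope_mixture(s, NAT, 12)
        assert model.n_components == 1

    def test_one_percent_minor_component_not_called_bimodal(self):
        """Model selection penalty: a 1% minor component stays unimodal."""
        n = 12
        light = E.deuterated_envelope(NAT, n, np.zeros(n))
        heavy = E.deuterated_envelope(NAT, n, np.full(n, 0.9))
        masses = np.concatenate([light[0], heavy[0]])
        inten = np.concatenate([0.01 * light[1], 0.99 * heavy[1]])
        order = np.argsort(masses)
        s = E.sticks_to_spectrum(masses[order], inten[order], charge=2)
        model = E.fit_envelope_mixture(s, NAT, n)
        assert model.n_components == 1

    def test_mixture_centroid_is_weight_average(self):
        """Centroid linearity ties envelope models to uptake bookkeeping."""
        spec = E.RegimeSpec("EX1", k_op=1.5e-3)
        s = E.simulate_time_series(NAT, 12, spec, [600.0], noise_cv=0.0)[0]
        model = E.fit_envelope_mixture(s, NAT, 12)
        assert model.n_components == 2
        manual = np.dot(model.weights, model.centroids)
        assert model.centroid == pytest.approx(manual, abs=1e-9)

    def test_too_few_peaks_rejected(self):
        s = E.sticks_to_spectrum(np.array([100.0, 101.0, 102.0]),
                                 np.array([1.0, 0.5, 0.1]), charge=1)
        with pytest.raises(ValueError):
            E.fit_envelope_mixture(s, NAT, 12)


class TestRegimeClassification:
    def _series(self, kind, seed=5, **kw):
        spec = E.RegimeSpec(kind, **kw)
        series = E.simulate_time_series(NAT, 12, spec, [15, 120, 1200],
                                        noise_cv=0.03, seed=seed)
        return [E.fit_envelope_mixture(s, NAT, 12) for s in series]

    def test_pure_ex1_series(self):
        call = E.classify_regime(self._series("EX1", k_op=1.5e-3))
        assert call.regime == "EX1"

    def test_pure_ex2_series(self):
        call = E.classify_regime(
            self._series("EX2", rates=tuple(np.geomspace(3e-4, 3e-2, 12))))
        assert call.regime == "EX2"

    def test_mixed_series_with_light_drift(self):
        """EX1 opening plus slow EX2 drift of the closed population is called
        mixed (the light component creeps upward)."""
        call = E.classify_regime(
            self._series("mixed", rates=tuple(np.full(12, 5e-4)),
                         k_op=1.5e-3))
        assert call.regime == "mixed"

    def test_needs_three_exposures(self):
        models = self._series("EX1", k_op=1.5e-3)
        with pytest.raises(ValueError):
            E.classify_regime(models[:2])


class TestUptakeTimeCourse:
    def test_single_class_recovery(self):
        """Noiseless single-class kinetics (k = 0.01 1/s, A = 6) recovered
        to better than 1%."""
        t = np.array([5.0, 15.0, 60.0, 120.0, 300.0, 1200.0])
        u = 6.0 * (1.0 - np.exp(-0.01 * t))
        out = E.fit_uptake_time_course(t, u, n_amides=10, label_fraction=0.8)
        assert out["n_classes"] == 1
        assert out["amplitudes"][0] == pytest.approx(6.0, rel=0.01)
        assert out["rates"][0] == pytest.approx(0.01, rel=0.01)

    def test_plateau_bound_enforced(self):
        t = np.array([15.0, 120.0, 1200.0, 3600.0, 7200.0])
        u = np.full(5, 12.0)  # above the observable plateau of 8*0.8
        out = E.fit_uptake_time_course(t, u, n_amides=8, label_fraction=0.8)
        assert sum(out["amplitudes"]) <= out["plateau_bound"] + 1e-6

    def test_zero_time_zero_uptake(self):
        t = np.array([0.0, 60.0, 600.0])
        u = 3.0 * (1.0 - np.exp(-0.005 * t))
        out = E.fit_uptake_time_course(t, u, n_amides=6)
        assert u[0] == 0.0
        fitted0 = sum(a * (1 - np.exp(-k * 0.0))
                      for a, k in zip(out["amplitudes"], out["rates"]))
        assert fitted0 == 0.0

    def test_needs_three_times(self):
        with pytest.raises(ValueError):
            E.fit_uptake_time_course([1.0, 2.0], [0.1, 0.2], n_amides=5)
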
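"""Isotope-envelope synthesis and EX1/EX2 deconvolution for HDX-MS.

An undeuterated peptide's isotope envelope is computed by iterative
convolution of per-element isotope distributions (aggregated unit-neutron
approximation).  Deuteration convolves that natural envelope with the
Poisson-binomial distribution of incorporated deuteriums (mass step
1.00628 Da per D).

Exchange regimes:

EX2  refolding faster than labeling; amides exchange independently with
     p_i(t) = f_label * (1 - exp(-k_i t)) and the envelope is a single
     (log-concave) distribution drifting to higher mass.
EX1  cooperative opening slower than labeling; the population splits into a
     closed (undeuterated) and an open (fully exchanged) component, the
     heavy component's weight growing as 1 - exp(-k_op t) while both
     component centroids stay put.
mixed  EX1 opening superimposed on slow EX2 exchange of the closed
     population, so the light component also drifts upward.

``fit_envelope_mixture`` deconvolves an observed spectrum into 1 or 2
components (each a natural envelope convolved with a width-inflated binomial
deuteration profile) and selects the component count by a small-sample
corrected information criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as pymass
from scipy.optimize import least_squares
from scipy.special import gammaln

from .spectra import DEUTERIUM_STEP, PROTON_MASS, IsotopeSpectrum

__all__ = [
    "C13_STEP",
    "natural_envelope",
    "peptide_composition",
    "averagine_composition",
    "poisson_binomial",
    "deuterated_envelope",
    "RegimeSpec",
    "simulate_time_series",
    "EnvelopeModel",
    "MixtureConfig",
    "fit_envelope_mixture",
    "RegimeCall",
    "classify_regime",
    "fit_uptake_time_course",
]

C13_STEP = 1.0033548378  # Da between aggregated isotopologue peaks

_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254


# ---------------------------------------------------------------------------
# natural (undeuterated) envelopes


def _element_distribution(symbol: str, isotope_data=None):
    """(offset probabilities, lightest-isotope mass) for one element."""
    data = isotope_data if isotope_data is not None else pymass.nist_mass
    if symbol not in data:
        raise ValueError(f"unknown element {symbol!r}")
    isotopes = {k: v for k, v in data[symbol].items()
                if k != 0 and v[1] > 0}
    if not isotopes:
        raise ValueError(f"no isotope abundances for element {symbol!r}")
    lightest = min(isotopes)
    offsets = {k - lightest: v[1] for k, v in isotopes.items()}
    dist = np.zeros(max(offsets) + 1)
    for off, p in offsets.items():
        dist[off] = p
    return dist / dist.sum(), isotopes[lightest][0]


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """dist convolved with itself n times (binary exponentiation)."""
    result = np.array([1.0])
    base = dist
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_envelope(composition: dict[str, int], isotope_data=None,
                     tail: float = 1e-10) -> tuple[float, np.ndarray]:
    """(monoisotopic mass, isotopologue probabilities) for a composition.

    Probabilities are indexed by extra-neutron count and sum to 1 within
    1e-9 (only a trailing tail of total mass < ``tail`` is trimmed).
    """
    probs = np.array([1.0])
    mono = 0.0
    for el, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for element {el!r}")
        if count == 0:
            continue
        dist, light_mass = _element_distribution(el, isotope_data)
        probs = np.convolve(probs, _convolve_power(dist, int(count)))
        mono += light_mass * count
    # trim the negligible high-mass tail
    csum = np.cumsum(probs[::-1])
    keep = len(probs) - int(np.searchsorted(csum, tail))
    probs = probs[:max(keep, 1)]
    return mono, probs


def peptide_composition(sequence: str) -> dict[str, int]:
    """Elemental composition of a peptide sequence (with terminal H2O)."""
    return dict(pymass.Composition(sequence=sequence))


def averagine_composition(mass: float) -> dict[str, int]:
    """Integer averagine composition approximating a given average mass."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    scale = mass / _AVERAGINE_MASS
    comp = {el: int(round(n * scale)) for el, n in _AVERAGINE.items()}
    comp = {el: n for el, n in comp.items() if n > 0}
    comp.setdefault("H", 1)
    return comp


# ---------------------------------------------------------------------------
# deuteration


def poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes of independent Bernoullis.

    Sequential convolution; exact for any probability vector.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def deuterated_envelope(natural: tuple[float, np.ndarray], n_amides: int,
                        per_amide_probs: np.ndarray,
                        label_fraction: float = 0.8
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Stick spectrum (neutral masses, probabilities) of a deuterated peptide.

    The natural envelope is convolved with the Poisson-binomial of deuterium
    counts; each amide's exchange probability is scaled by the labeling
    fraction of the D2O dilution.  Probabilities sum to 1 (within the trimmed
    tail of the natural envelope).
    """
    per_amide_probs = np.asarray(per_amide_probs, dtype=float)
    if per_amide_probs.shape != (n_amides,):
        raise ValueError("need one exchange probability per amide")
    if not 0.0 < label_fraction <= 1.0:
        raise ValueError("label_fraction must be in (0, 1]")
    mono, nat = natural
    d_dist = poisson_binomial(label_fraction * per_amide_probs)
    ks = np.arange(len(nat))
    ds = np.arange(len(d_dist))
    masses = (mono + ks[:, None] * C13_STEP
              + ds[None, :] * DEUTERIUM_STEP).ravel()
    inten = (nat[:, None] * d_dist[None, :]).ravel()
    order = np.argsort(masses)
    return masses[order], inten[order]


def sticks_to_spectrum(masses: np.ndarray, intensities: np.ndarray,
                       charge: int, peptide_id: str = "", state: str = "",
                       time_s: float = 0.0,
                       min_rel: float = 1e-6) -> IsotopeSpectrum:
    """Package neutral-mass sticks as an m/z spectrum at a given charge."""
    keep = intensities > min_rel * intensities.max()
    mz = (masses[keep] + charge * PROTON_MASS) / charge
    return IsotopeSpectrum(peptide_id=peptide_id, state=state, time_s=time_s,
                           charge=charge,
                           peaks=list(zip(mz.tolist(),
                                          intensities[keep].tolist())))


# ---------------------------------------------------------------------------
# time-series simulation


@dataclass(frozen=True)
class RegimeSpec:
    """Ground-truth exchange regime of one peptide x state.

    kind 'EX2': ``rates`` are per-amide intrinsic exchange rates (1/s).
    kind 'EX1': ``k_op`` is the cooperative opening rate; the open population
    is fully exchanged, the closed one undeuterated.
    kind 'mixed': EX1 opening plus slow EX2 exchange (``rates``) of the
    closed population.
    """

    kind: str  # 'EX1' | 'EX2' | 'mixed'
    rates: tuple[float, ...] = ()
    k_op: float = 0.0
    # which amides belong to the cooperatively opening segment (None = all);
    # amides outside the mask keep their EX2 behavior in the open population
    open_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("EX1", "EX2", "mixed"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind in ("EX2", "mixed") and not self.rates:
            raise ValueError(f"{self.kind} regime needs per-amide rates")
        if any(r <= 0 for r in self.rates):
            raise ValueError("per-amide rates must be positive")
        if self.kind in ("EX1", "mixed") and self.k_op <= 0:
            raise ValueError("EX1/mixed regime needs a positive opening rate")


def simulate_time_series(natural: tuple[float, np.ndarray], n_amides: int,
                         regime: RegimeSpec, times,
                         charge: int = 2, label_fraction: float = 0.8,
                         noise_cv: float = 0.0,
                         seed: int | np.random.Generator = 0,
                         peptide_id: str = "", state: str = ""
                         ) -> list[IsotopeSpectrum]:
    """Simulate isotope spectra of one peptide over the exposure series.

    Peak intensities receive multiplicative Gaussian noise with CV
    ``noise_cv`` (clipped at zero).  At t = 0 every regime returns the
    undeuterated envelope.
    """
    times = list(times)
    if not times:
        raise ValueError("empty exposure-time list")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rates = np.asarray(regime.rates, dtype=float)
    if regime.kind in ("EX2", "mixed") and rates.shape != (n_amides,):
        raise ValueError("need one rate per amide")

    spectra = []
    for t in times:
        if t < 0:
            raise ValueError("negative exposure time")
        if regime.kind == "EX2":
            probs = 1.0 - np.exp(-rates * t)
            parts = [(1.0, probs)]
        else:
            w_open = 1.0 - math.exp(-regime.k_op * t)
            closed = (1.0 - np.exp(-rates * t) if regime.kind == "mixed"
                      else np.zeros(n_amides))
            mask = (np.ones(n_amides, dtype=bool) if regime.open_mask is None
                    else np.asarray(regime.open_mask, dtype=bool))
            opened = np.where(mask, 1.0, closed)
            parts = [(1.0 - w_open, closed), (w_open, opened)]
        masses_all, inten_all = [], []
        for w, probs in parts:
            if w <= 0:
                continue
            m, i = deuterated_envelope(natural, n_amides, probs, label_fraction)
            masses_all.append(m)
            inten_all.append(w * i)
        masses = np.concatenate(masses_all)
        inten = np.concatenate(inten_all)
        if noise_cv > 0:
            inten = np.clip(inten * (1.0 + noise_cv * rng.standard_normal(inten.size)),
                            0.0, None)
        order = np.argsort(masses)
        spectra.append(sticks_to_spectrum(masses[order], inten[order], charge,
                                          peptide_id=peptide_id, state=state,
                                          time_s=float(t)))
    return spectra


# ---------------------------------------------------------------------------
# mixture deconvolution


@dataclass(frozen=True)
class MixtureConfig:
    """Numerical settings of the envelope-mixture fit and model selection."""

    grid_step: float = 0.02  # Da
    peak_sigma: float = 0.05  # Da gaussian blur applied to both sides
    aicc_margin: float = 20.0  # 2-component support needs this AICc gain
    min_weight: float = 0.02  # minor components below this are not bimodal
    min_separation: float = 1.5  # Da between component centroids
    max_width: float = 3.0  # inflation width bound (deuterium units)


@dataclass
class EnvelopeModel:
    """1- vs 2-component deconvolution of one spectrum.

    Component centroids are deuterium-uptake values in Da (relative to the
    natural envelope); weights sum to 1 and centroids are ordered light to
    heavy.  Both candidate fits are retained; ``n_components`` is the
    selected one.
    """

    peptide_id: str
    state: str
    time_s: float
    n_components: int
    weights: tuple[float, ...]
    centroids: tuple[float, ...]
    widths: tuple[float, ...]
    aicc: dict = field(default_factory=dict)  # {1: aicc, 2: aicc}
    fits: dict = field(default_factory=dict)  # raw parameter dicts per k
    ok: bool = True
    message: str = ""

    @property
    def centroid(self) -> float:
        """Weight-averaged uptake centroid of the mixture, Da."""
        return float(np.dot(self.weights, self.centroids))


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    """Binomial pmf over 0..n (log-space, cheap for the small n used here)."""
    k = np.arange(n + 1)
    logc = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = logc + k * np.log(max(p, 1e-300)) \
            + (n - k) * np.log(max(1.0 - p, 1e-300))
    d = np.exp(logp)
    if p <= 0:
        d = np.zeros(n + 1)
        d[0] = 1.0
    elif p >= 1:
        d = np.zeros(n + 1)
        d[-1] = 1.0
    return d / d.sum()


def _component_profile(c: float, w: float, n_amides: int,
                       nat: np.ndarray) -> np.ndarray:
    """D-count ladder x natural envelope for one mixture component.

    The deuteration profile is binomial(n, p = c/(n*step)) convolved with a
    discrete zero-mean gaussian of SD ``w`` (width inflation beyond the
    binomial's own variance); returned on the combined stick ladder.
    """
    n = n_amides
    p = float(np.clip(c / (n * DEUTERIUM_STEP), 0.0, 1.0))
    d = _binomial_pmf(n, p)
    if w > 1e-3:
        half = int(np.ceil(3 * w)) + 1
        offs = np.arange(-half, half + 1)
        kern = np.exp(-0.5 * (offs / w) ** 2)
        kern /= kern.sum()
        d = np.convolve(d, kern)[half:half + n + 1]
        s = d.sum()
        if s > 0:
            d = d / s
    return d


def _sticks(c, w, n_amides, mono, nat):
    d = _component_profile(c, w, n_amides, nat)
    ks = np.arange(len(nat))
    ds = np.arange(len(d))
    masses = (mono + ks[:, None] * C13_STEP + ds[None, :] * DEUTERIUM_STEP).ravel()
    inten = (nat[:, None] * d[None, :]).ravel()
    return masses, inten


def _blur_to_grid(masses, inten, grid, sigma):
    """Unit-area gaussian-blurred profile of a stick list on a uniform grid."""
    masses = np.asarray(masses, dtype=float)
    inten = np.asarray(inten, dtype=float)
    top = inten.max(initial=0.0)
    keep = inten > 1e-12 * top
    m, a = masses[keep], inten[keep]
    if m.size == 0:
        return np.zeros_like(grid)
    lo = grid[0]
    step = grid[1] - grid[0]
    half = int(np.ceil(4.0 * sigma / step))
    centers = np.round((m - lo) / step).astype(int)
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    pos = lo + idx * step
    vals = a[:, None] * np.exp(-0.5 * ((pos - m[:, None]) / sigma) ** 2)
    valid = (idx >= 0) & (idx < grid.size)
    prof = np.bincount(idx[valid], weights=vals[valid], minlength=grid.size)
    total = prof.sum()
    return prof / total if total > 0 else prof


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    val = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        val += 2 * k * (k + 1) / (n - k - 1)
    return val


def fit_envelope_mixture(spectrum: IsotopeSpectrum,
                         natural: tuple[float, np.ndarray], n_amides: int,
                         config: MixtureConfig = MixtureConfig()
                         ) -> EnvelopeModel:
    """Deconvolve a spectrum into 1 or 2 deuteration components.

    Both models are least-squares fits of blurred stick profiles on a common
    mass grid; the 2-component model is selected only when its
    small-sample-corrected information criterion beats the 1-component model
    by ``aicc_margin`` with a minor weight above ``min_weight`` and centroid
    separation above ``min_separation`` — tuned so a 1% minor component is
    not called bimodal.
    """
    if len(spectrum.peaks) < 6:
        raise ValueError("need at least 6 peaks for mixture deconvolution")
    mono, nat = natural
    z = spectrum.charge
    obs_masses = spectrum.mz * z - z * PROTON_MASS
    obs_inten = spectrum.intensities

    cmax = n_amides * DEUTERIUM_STEP
    lo = mono - 2.0
    hi = mono + len(nat) * C13_STEP + cmax + 2.0
    grid = np.arange(lo, hi, config.grid_step)
    target = _blur_to_grid(obs_masses, obs_inten, grid, config.peak_sigma)

    def profile1(theta):
        c, w = theta
        m, a = _sticks(c, w, n_amides, mono, nat)
        return _blur_to_grid(m, a, grid, config.peak_sigma)

    def profile2(theta):
        f, c1, gap, w1, w2 = theta
        m1, a1 = _sticks(c1, w1, n_amides, mono, nat)
        m2, a2 = _sticks(c1 + gap, w2, n_amides, mono, nat)
        return _blur_to_grid(np.concatenate([m1, m2]),
                             np.concatenate([(1 - f) * a1, f * a2]),
                             grid, config.peak_sigma)

    def resid2(theta):
        # hinge keeps the heavy centroid physical (<= n_amides deuteriums)
        excess = max(theta[1] + theta[2] - cmax, 0.0)
        return np.append(profile2(theta) - target, 10.0 * excess)

    # observed overall centroid as initialization anchor
    nat_off = float(np.dot(np.arange(len(nat)), nat)) * C13_STEP
    c_obs = float(np.dot(obs_masses, obs_inten) / obs_inten.sum() - mono
                  - nat_off)
    c_obs = float(np.clip(c_obs, 0.0, cmax))

    res1 = least_squares(lambda th: profile1(th) - target,
                         x0=[c_obs, 0.3],
                         bounds=([0.0, 0.0], [cmax, config.max_width]),
                         xtol=1e-8, ftol=1e-8)
    rss1 = float(np.sum(res1.fun ** 2))

    # second start informed by where the 1-component fit leaves residual mass
    inits = [(0.5, max(c_obs - 0.3 * cmax, 0.0), 0.6 * cmax)]
    pos_resid = np.clip(target - profile1(res1.x), 0.0, None)
    if pos_resid.sum() > 1e-6:
        c_res = float(np.clip(np.dot(grid, pos_resid) / pos_resid.sum()
                              - mono - nat_off, 0.0, cmax))
        c_fit = float(res1.x[0])
        f_res = float(np.clip(2.0 * pos_resid.sum(), 0.05, 0.9))
        if c_res >= c_fit:
            inits.append((f_res, c_fit, max(c_res - c_fit, 0.2)))
        else:
            inits.append((1.0 - f_res, c_res, max(c_fit - c_res, 0.2)))

    best2 = None
    for f0, c10, gap0 in inits:
        gap0 = float(np.clip(gap0, 0.2, cmax))
        c10 = float(np.clip(c10, 0.0, cmax - 0.2))
        try:
            r = least_squares(
                resid2,
                x0=[f0, c10, gap0, 0.3, 0.3],
                bounds=([0.0, 0.0, 0.1, 0.0, 0.0],
                        [1.0, cmax, cmax, config.max_width, config.max_width]),
                xtol=1e-8, ftol=1e-8)
        except ValueError:
            continue
        rss = float(np.sum(r.fun ** 2))
        if best2 is None or rss < best2[0]:
            best2 = (rss, r)

    n_grid = grid.size
    aicc1 = _aicc(rss1, n_grid, 2)
    model = EnvelopeModel(
        peptide_id=spectrum.peptide_id, state=spectrum.state,
        time_s=spectrum.time_s, n_components=1,
        weights=(1.0,), centroids=(float(res1.x[0]),),
        widths=(float(res1.x[1]),), aicc={1: aicc1},
        fits={1: {"c": float(res1.x[0]), "w": float(res1.x[1]), "rss": rss1}})
    if best2 is None:
        model.ok = False
        model.message = "2-component fit did not converge; 1-component fallback"
        return model

    rss2, r2 = best2
    f, c1, gap, w1, w2 = r2.x
    aicc2 = _aicc(rss2, n_grid, 5)
    model.aicc[2] = aicc2
    model.fits[2] = {"f_heavy": float(f), "c_light": float(c1),
                     "c_heavy": float(c1 + gap), "w_light": float(w1),
                     "w_heavy": float(w2), "rss": rss2}
    minor = min(f, 1.0 - f)
    if (aicc1 - aicc2 > config.aicc_margin and minor >= config.min_weight
            and gap >= config.min_separation):
        model.n_components = 2
        model.weights = (float(1.0 - f), float(f))
        model.centroids = (float(c1), float(c1 + gap))
        model.widths = (float(w1), float(w2))
    return model


# ---------------------------------------------------------------------------
# regime classification


@dataclass
class RegimeCall:
    """EX1/EX2/mixed call for one peptide x state time series."""

    peptide_id: str
    state: str
    regime: str  # 'EX1' | 'EX2' | 'mixed'
    evidence: dict
    confident: bool = True


def classify_regime(models: list[EnvelopeModel],
                    centroid_tol: float = 0.15,
                    weight_slack: float = 0.02) -> RegimeCall:
    """Classify an exposure series of envelope deconvolutions.

    EX1: >= 2 exposures support 2 components, the heavy component's weight
    grows monotonically, and both component centroids stay fixed within
    ``centroid_tol``.  EX2: 1-component support with a monotonically
    increasing centroid.  mixed: 2-component support with the light
    component's centroid also drifting upward (EX2 contribution), or an
    inconsistent series (flagged low-confidence).
    """
    if len(models) < 3:
        raise ValueError("need at least 3 exposure times")
    models = sorted(models, key=lambda m: m.time_s)
    bimodal = [m for m in models if m.n_components == 2]
    evidence = {
        "times": [m.time_s for m in models],
        "n_components": [m.n_components for m in models],
        "centroids": [m.centroids for m in models],
        "heavy_weights": [m.weights[-1] if m.n_components == 2 else None
                          for m in models],
    }
    if len(bimodal) >= 2:
        heavy_w = [m.weights[1] for m in bimodal]
        light_c = [m.centroids[0] for m in bimodal]
        heavy_c = [m.centroids[1] for m in bimodal]
        transfer = all(b >= a - weight_slack
                       for a, b in zip(heavy_w, heavy_w[1:]))
        light_drift = max(light_c) - min(light_c)
        heavy_stable = max(heavy_c) - min(heavy_c) <= centroid_tol
        evidence.update(light_drift=light_drift,
                        heavy_weight_transfer=transfer,
                        heavy_centroid_stable=heavy_stable)
        if transfer and light_drift > centroid_tol:
            return RegimeCall(models[0].peptide_id, models[0].state,
                              "mixed", evidence)
        if transfer and heavy_stable:
            return RegimeCall(models[0].peptide_id, models[0].state,
                              "EX1", evidence)
        return RegimeCall(models[0].peptide_id, models[0].state, "mixed",
                          evidence, confident=False)
    cents = [m.centroid for m in models]
    increasing = all(b >= a - centroid_tol for a, b in zip(cents, cents[1:]))
    if increasing:
        return RegimeCall(models[0].peptide_id, models[0].state, "EX2",
                          evidence)
    return RegimeCall(models[0].peptide_id, models[0].state, "mixed",
                      evidence, confident=False)


# ---------------------------------------------------------------------------
# uptake kinetics


def fit_uptake_time_course(times, uptakes, n_amides: int,
                           label_fraction: float = 0.8,
                           max_classes: int = 2) -> dict:
    """Fit uptake(t) = sum_j A_j (1 - exp(-k_j t)) with 1-2 rate classes.

    Amplitudes are non-negative and their sum is bounded by the observable
    plateau ``n_amides * label_fraction``.  Model order is chosen by AICc;
    with fewer than 5 time points only the single-class model is attempted.
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(uptakes, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    cap = n_amides * label_fraction

    def curve(params):
        half = len(params) // 2
        amps, logks = params[:half], params[half:]
        return sum(a * (1.0 - np.exp(-np.exp(lk) * t))
                   for a, lk in zip(amps, logks))

    def residuals(params):
        r = curve(params) - u
        excess = max(sum(params[:len(params) // 2]) - cap, 0.0)
        return np.append(r, 10.0 * excess)  # hinge: plateau bound

    results = {}
    k0 = math.log(1.0 / max(t[t > 0].min(), 1.0)) if np.any(t > 0) else -2.0
    candidates = [1] + ([2] if max_classes >= 2 and t.size >= 5 else [])
    for nc in candidates:
        if nc == 1:
            x0 = [min(u.max(), cap), k0]
            lb = [0.0, -20.0]
            ub = [cap, 5.0]
        else:
            x0 = [0.5 * min(u.max(), cap), 0.5 * min(u.max(), cap),
                  k0 + 2.0, k0 - 2.0]
            lb = [0.0, 0.0, -20.0, -20.0]
            ub = [cap, cap, 5.0, 5.0]
        try:
            r = least_squares(residuals, x0=x0, bounds=(lb, ub),
                              xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        half = nc
        amps = list(map(float, r.x[:half]))
        total = sum(amps)
        if total > cap:  # project onto the observable plateau
            amps = [a * cap / total for a in amps]
        ks = [float(np.exp(v)) for v in r.x[half:]]
        rss = float(np.sum((curve(r.x) - u) ** 2))
        results[nc] = {"amplitudes": amps, "rates": ks, "rss": rss,
                       "aicc": _aicc(rss, t.size, 2 * nc)}
    if not results:
        raise RuntimeError("no uptake model converged")
    best = min(results, key=lambda nc: results[nc]["aicc"])
    out = dict(results[best])
    out["n_classes"] = best
    out["all_fits"] = results
    out["plateau_bound"] = cap
    return out
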
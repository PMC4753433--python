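"""Ping-pong (consecutive) ion-exchange kinetics of an alternating-access antiporter.

The carrier cycles through four states — outward-facing empty, outward-facing
Ca-loaded, inward-facing Ca-loaded, inward-facing empty — with rapid-equilibrium
Ca2+ binding at both membrane faces.  In Ca2+/Ca2+ exchange mode the loaded
carrier shuttles back and forth (no empty translocation); in Na+/Ca2+ mode the
inward-facing empty carrier returns via an effective Na-loaded step whose rate
lumps the whole saturating-Na limb.  Initial uptake rates of extravesicular
tracer are the unidirectional influx ``Et * k_transloc_in * P(out.Ca)`` at the
steady state of the cycle, which for Ca2+/Ca2+ exchange equals the exchange
rate by stationarity.

The steady state is obtained by solving the linear master equation of the
4-state cycle rather than from a closed-form rate law, so the observable
Km/Vmax are *operational* quantities recovered by fitting the simulated curve.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExchangeMode",
    "Side",
    "PingPongParams",
    "DoseResponse",
    "pingpong_initial_rate",
    "simulate_dose_response",
    "rate_matrix",
    "steady_state_distribution",
]

# relaxation factor applied to the binding edges so that ion binding is fast
# relative to every conformational transition (rapid-equilibrium limit)
_BINDING_RELAX = 1.0e5
# trans-side ligand excess over its Kd used to represent "saturating"
_TRANS_SATURATION = 1.0e6


class ExchangeMode(str, enum.Enum):
    """Which ion occupies the trans compartment in the flux assay."""

    NaCa = "NaCa"  # Na+-loaded vesicles, extravesicular 45Ca2+ varied
    CaCa = "CaCa"  # Ca2+-loaded vesicles, either side varied


class Side(str, enum.Enum):
    extracellular = "extracellular"
    cytosolic = "cytosolic"


@dataclass(frozen=True)
class PingPongParams:
    """Microscopic constants of the 4-state alternating-access cycle.

    Dissociation constants are in uM, rates in 1/s.  ``Et`` is the active
    transporter amount (mol, or a normalized expression fraction); rates
    returned by the model scale linearly with it.
    """

    construct_name: str
    Kd_ext: float  # Ca2+ dissociation constant, extracellular face (K''d), uM
    Kd_cyt: float  # Ca2+ dissociation constant, cytosolic face (K'd), uM
    k_transloc_in: float  # loaded-carrier translocation out->in, 1/s
    k_transloc_out: float  # loaded-carrier translocation in->out, 1/s
    k_return_Na: float = 10.0  # effective Na-loaded return at saturating Na, 1/s
    Et: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Kd_ext", "Kd_cyt", "k_transloc_in", "k_transloc_out",
                     "k_return_Na"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.Et < 0 or not np.isfinite(self.Et):
            raise ValueError(f"Et must be >= 0, got {self.Et!r}")

    def scaled(self, *, Kd_ext=1.0, Kd_cyt=1.0, k_transloc=1.0,
               k_transloc_in=1.0, k_transloc_out=1.0, k_return=1.0,
               Et=1.0, name: str | None = None) -> "PingPongParams":
        """Return a mutant parameter set with fold-changes applied.

        ``k_transloc`` scales both translocation directions together (a
        catalytic-capacity change); ``k_transloc_in``/``k_transloc_out``
        scale one direction (a conformational-equilibrium change).
        """
        return replace(
            self,
            construct_name=name if name is not None else self.construct_name,
            Kd_ext=self.Kd_ext * Kd_ext,
            Kd_cyt=self.Kd_cyt * Kd_cyt,
            k_transloc_in=self.k_transloc_in * k_transloc * k_transloc_in,
            k_transloc_out=self.k_transloc_out * k_transloc * k_transloc_out,
            k_return_Na=self.k_return_Na * k_return,
            Et=self.Et * Et,
        )


@dataclass
class DoseResponse:
    """One dose-response table: initial rates vs the varied-side [Ca2+].

    ``points`` rows are (concentration uM, mean initial rate, SD of the
    replicate rates, n_replicates).
    """

    construct_name: str
    mode: ExchangeMode
    varied_side: Side
    points: list[tuple[float, float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        concs = [p[0] for p in self.points]
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be strictly positive")
        if len(set(concs)) != len(concs):
            raise ValueError("concentrations must be distinct")
        for _, _, sd, n in self.points:
            if sd < 0:
                raise ValueError("rate SD must be >= 0")
            if n < 1:
                raise ValueError("n_replicates must be >= 1")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    @property
    def sds(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=float)


# state ordering of the cycle
_STATES = ("out", "out.Ca", "in.Ca", "in")


def rate_matrix(params: PingPongParams, c_ext: float, c_cyt: float,
                mode: ExchangeMode, binding_relax: float = _BINDING_RELAX) -> np.ndarray:
    """Generator matrix Q of the 4-state cycle; Q[i, j] = rate state i -> j.

    Binding/unbinding edges get off-rates ``binding_relax`` times the fastest
    conformational rate so that binding equilibrates quickly (koff/kon = Kd at
    each face).  Empty-carrier translocation is omitted: under the assay
    conditions it contributes negligibly to the observed exchange.
    """
    if c_ext < 0 or c_cyt < 0:
        raise ValueError("concentrations must be non-negative")
    kin, kout = params.k_transloc_in, params.k_transloc_out
    kret = params.k_return_Na if mode is ExchangeMode.NaCa else 0.0
    fast = binding_relax * max(kin, kout, kret)
    koff_e = koff_c = fast
    kon_e = fast / params.Kd_ext
    kon_c = fast / params.Kd_cyt

    Q = np.zeros((4, 4))
    Q[0, 1] = kon_e * c_ext   # out + Ca_ext -> out.Ca
    Q[1, 0] = koff_e
    Q[1, 2] = kin             # out.Ca -> in.Ca
    Q[2, 1] = kout
    Q[2, 3] = koff_c          # in.Ca -> in + Ca_cyt
    Q[3, 2] = kon_c * c_cyt
    if mode is ExchangeMode.NaCa:
        Q[3, 0] = kret        # Na-loaded return, saturating trans Na+
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def steady_state_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (rows sum to zero)."""
    n = Q.shape[0]
    M = Q.T.copy()
    M[-1, :] = 1.0  # replace one balance equation with normalization
    b = np.zeros(n)
    b[-1] = 1.0
    p = np.linalg.solve(M, b)
    # guard tiny negative round-off
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _concentrations_for(params: PingPongParams, conc_varied: float,
                        mode: ExchangeMode, varied_side: Side) -> tuple[float, float]:
    """Map (varied concentration, mode, side) to (c_ext, c_cyt) of the cycle."""
    if mode is ExchangeMode.NaCa:
        if varied_side is not Side.extracellular:
            raise ValueError(
                "Na+/Ca2+ mode varies extravesicular Ca2+ only; the cytosolic "
                "Na+ limb is an effective saturating return rate")
        return conc_varied, 0.0
    if varied_side is Side.extracellular:
        return conc_varied, _TRANS_SATURATION * params.Kd_cyt
    return _TRANS_SATURATION * params.Kd_ext, conc_varied


def pingpong_initial_rate(params: PingPongParams, conc_varied: float,
                          mode: ExchangeMode = ExchangeMode.CaCa,
                          varied_side: Side = Side.extracellular) -> float:
    """Initial tracer-uptake rate at one varied-side Ca2+ concentration.

    The trans-side ligand is saturating (assay convention).  Returns
    ``Et * k_transloc_in * P(out.Ca)`` at the steady state of the cycle:
    monotone increasing and saturating in ``conc_varied``.
    """
    mode = ExchangeMode(mode)
    varied_side = Side(varied_side)
    if not np.isfinite(conc_varied) or conc_varied <= 0:
        raise ValueError(f"conc_varied must be strictly positive, got {conc_varied!r}")
    c_ext, c_cyt = _concentrations_for(params, conc_varied, mode, varied_side)
    Q = rate_matrix(params, c_ext, c_cyt, mode)
    p = steady_state_distribution(Q)
    return params.Et * params.k_transloc_in * p[1]


def predicted_saturation_rate(params: PingPongParams,
                              mode: ExchangeMode = ExchangeMode.CaCa) -> float:
    """Closed-form Vmax of the cycle (varied side saturated).

    Ca2+/Ca2+: Et*kin*kout/(kin+kout); Na+/Ca2+: Et*kin*kret/(kin+kret).
    Useful as an analytic cross-check of the numeric steady state.
    """
    kin = params.k_transloc_in
    kother = (params.k_return_Na if ExchangeMode(mode) is ExchangeMode.NaCa
              else params.k_transloc_out)
    return params.Et * kin * kother / (kin + kother)


def default_concentration_grid(n: int = 8, low: float = 20.0,
                               high: float = 2000.0) -> np.ndarray:
    """Log-spaced assay concentrations, uM (assay range 20-2000 uM)."""
    return np.geomspace(low, high, n)


def simulate_dose_response(params: PingPongParams,
                           concentrations=None,
                           n_replicates: int = 3,
                           noise_cv: float = 0.05,
                           mode: ExchangeMode = ExchangeMode.CaCa,
                           varied_side: Side = Side.extracellular,
                           seed: int | np.random.Generator = 0) -> DoseResponse:
    """Simulate a replicated dose-response table with multiplicative noise.

    Each replicate rate is the model rate times a lognormal factor of unit
    mean and coefficient of variation ``noise_cv``.  Fully reproducible for a
    fixed seed.
    """
    if concentrations is None:
        concentrations = default_concentration_grid()
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("empty concentration design")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    mu = -0.5 * sigma ** 2  # unit-mean lognormal
    points = []
    for c in concentrations:
        v = pingpong_initial_rate(params, float(c), mode, varied_side)
        if noise_cv == 0:
            reps = np.full(n_replicates, v)
        else:
            reps = v * rng.lognormal(mu, sigma, size=n_replicates)
        sd = float(reps.std(ddof=1)) if n_replicates > 1 else 0.0
        points.append((float(c), float(reps.mean()), sd, int(n_replicates)))
    return DoseResponse(params.construct_name, ExchangeMode(mode),
                        Side(varied_side), points)
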
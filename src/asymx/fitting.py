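"""Operational Michaelis-Menten fitting and transporter quantitation.

Km and Vmax are extracted from dose-response tables by weighted nonlinear
least squares of the hyperbola v = Vmax*S/(Km+S), initialized from a Hanes
linearization (S/v vs S).  kcat follows as Vmax/[E]t with the transporter
amount from the GFP absorbance assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .transport import DoseResponse

__all__ = [
    "MMFit",
    "GFPQuant",
    "CatalyticConstants",
    "ConstructRecord",
    "fit_michaelis_menten",
    "enzyme_amount_from_gfp",
    "derive_catalytic_constants",
]


@dataclass
class MMFit:
    """Result of a hyperbolic (Michaelis-Menten) fit.

    ``ok`` is False for degenerate or non-converged fits, or when the fitted
    Km falls outside [min(S)/100, 100*max(S)] (unidentifiable from the design).
    """

    Km: float  # uM
    Vmax: float  # rate units of the input
    se_Km: float
    se_Vmax: float
    cov_Km_Vmax: float
    rss: float
    n_points: int
    ok: bool = True
    message: str = ""


@dataclass(frozen=True)
class GFPQuant:
    """Inputs of the GFP expression assay (Beer-Lambert at 488 nm)."""

    A488: float
    background_A488: float = 0.0
    epsilon: float = 56000.0  # 1/(M cm)
    path_cm: float = 1.0
    total_protein: float | None = None  # mg/mL (Lowry)
    gfp_mw: float = 26900.0  # g/mol

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.path_cm <= 0:
            raise ValueError("epsilon and path length must be positive")
        if self.total_protein is not None and self.total_protein <= 0:
            raise ValueError("total_protein must be positive")


@dataclass
class CatalyticConstants:
    kcat: float  # 1/s
    se_kcat: float
    efficiency: float  # kcat/Km, 1/(uM s)
    se_efficiency: float


@dataclass
class ConstructRecord:
    """Per-construct kinetic summary across both membrane sides.

    Extracellular-side quantities carry double primes in the field's notation
    (K''m, V''max), cytosolic-side single primes.
    """

    construct_name: str
    mode: str
    Km_ext: float | None = None
    se_Km_ext: float = 0.0
    Km_cyt: float | None = None
    se_Km_cyt: float = 0.0
    Vmax_ext: float | None = None
    se_Vmax_ext: float = 0.0
    Vmax_cyt: float | None = None
    se_Vmax_cyt: float = 0.0
    kcat: float | None = None
    se_kcat: float = 0.0
    efficiency: float | None = None  # kcat/Km_ext
    se_efficiency: float = 0.0
    K_int: float | None = None
    se_K_int: float = 0.0


def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _hanes_guess(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Vmax, Km) from the Hanes plot S/v = S/Vmax + Km/Vmax."""
    mask = v > 0
    s, v = s[mask], v[mask]
    slope, intercept = np.polyfit(s, s / v, 1)
    vmax = 1.0 / slope if slope > 0 else float(v.max())
    km = intercept * vmax if intercept * vmax > 0 else float(np.median(s))
    return vmax, km


def fit_michaelis_menten(data: DoseResponse) -> MMFit:
    """Weighted NLLS fit of v = Vmax*S/(Km+S) to a dose-response table.

    Weights are 1/SD^2 of the replicate means when replicate SDs are
    available, otherwise the fit is unweighted.  Requires >= 4 distinct
    concentrations.
    """
    s = data.concentrations
    v = data.rates
    sd = data.sds
    n = np.array([p[3] for p in data.points], dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    if not np.any(v > 0):
        return MMFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                     len(s), ok=False, message="all rates are zero")

    # SEM of the replicate mean; usable only if every point has a positive SD
    sem = np.where(n > 1, sd / np.sqrt(n), 0.0)
    sigma = sem if np.all(sem > 0) else None

    p0 = _hanes_guess(s, v)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _michaelis_menten, s, v, p0=p0, sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
                xtol=1e-12, ftol=1e-12)
    except (RuntimeError, ValueError) as exc:
        return MMFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                     len(s), ok=False, message=f"fit failed: {exc}")

    vmax, km = popt
    resid = v - _michaelis_menten(s, *popt)
    rss = float(np.sum(resid ** 2))
    se_vmax = float(np.sqrt(pcov[0, 0]))
    se_km = float(np.sqrt(pcov[1, 1]))
    cov = float(pcov[0, 1])

    fit = MMFit(Km=float(km), Vmax=float(vmax), se_Km=se_km, se_Vmax=se_vmax,
                cov_Km_Vmax=cov, rss=rss, n_points=len(s))
    if not (s.min() / 100.0 <= km <= 100.0 * s.max()):
        fit.ok = False
        fit.message = (f"Km={km:.3g} uM outside the identifiable window "
                       f"[{s.min() / 100:.3g}, {100 * s.max():.3g}]")
    if vmax <= 0 or km <= 0:
        fit.ok = False
        fit.message = "non-positive parameter estimate"
    return fit


def enzyme_amount_from_gfp(q: GFPQuant) -> dict:
    """Transporter concentration (uM) and expression fraction from A488.

    [GFP] = (A488 - background)/(epsilon * path); the expression fraction is
    the GFP-derived mass concentration over the Lowry total protein.
    """
    dA = q.A488 - q.background_A488
    if dA < 0:
        warnings.warn("A488 below background; reporting zero transporter",
                      stacklevel=2)
        dA = 0.0
    conc_M = dA / (q.epsilon * q.path_cm)
    out = {"conc_uM": conc_M * 1e6, "conc_M": conc_M}
    if q.total_protein is not None:
        mass_mg_per_ml = conc_M * q.gfp_mw  # g/L == mg/mL
        out["expression_fraction"] = mass_mg_per_ml / q.total_protein
    return out


def derive_catalytic_constants(fit: MMFit, Et: float,
                               se_Et: float = 0.0) -> CatalyticConstants:
    """kcat = Vmax/Et and catalytic efficiency kcat/Km with propagated SEs.

    First-order (delta-method) propagation, including the Km-Vmax covariance
    of the fit in the efficiency SE.
    """
    if Et <= 0:
        raise ValueError("Et must be strictly positive")
    if not fit.ok:
        raise ValueError(f"cannot derive constants from a flagged fit: {fit.message}")
    kcat = fit.Vmax / Et
    var_kcat = (fit.se_Vmax / Et) ** 2 + (fit.Vmax * se_Et / Et ** 2) ** 2
    eff = kcat / fit.Km
    # eff = Vmax/(Et*Km): relative variances plus the Vmax-Km covariance term
    rel_var = ((fit.se_Vmax / fit.Vmax) ** 2 + (fit.se_Km / fit.Km) ** 2
               + (se_Et / Et) ** 2
               - 2.0 * fit.cov_Km_Vmax / (fit.Vmax * fit.Km))
    se_eff = abs(eff) * np.sqrt(max(rel_var, 0.0))
    return CatalyticConstants(kcat=kcat, se_kcat=float(np.sqrt(var_kcat)),
                              efficiency=eff, se_efficiency=float(se_eff))
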
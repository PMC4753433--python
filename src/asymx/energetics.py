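"""Derived kinetic/thermodynamic statistics of the exchange cycle.

Covers the intrinsic equilibrium of bidirectional Ca2+ movement
(K_int = K'm/K''m), the asymmetry index R_A of symmetry-related mutant
pairs, transition-state free energies from kcat/Km, residue-group
classification, and pH-profile fitting.

Unit convention: RT terms use R = 1.987e-3 kcal/(mol K) and default
T = 308.15 K (the 35 C assay temperature).  Absolute dG_b = RT*ln(Km) takes
Km in uM, so the implied standard state is 1 uM; this convention is recorded
in output metadata.  Differences (ddG) are standard-state free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .fitting import ConstructRecord, MMFit

__all__ = [
    "R_GAS_KCAL",
    "T_ASSAY",
    "EnergyTerms",
    "PairResult",
    "intrinsic_equilibrium",
    "asymmetry_index",
    "ddg_app",
    "free_energy_terms",
    "classify_residue_group",
    "fit_ph_profile",
    "profile_similarity",
]

R_GAS_KCAL = 1.987e-3  # kcal/(mol K)
T_ASSAY = 308.15  # K (35 C flux assay)


@dataclass
class EnergyTerms:
    """Ground- and transition-state free energies of one construct.

    dG_b = RT ln Km (substrate binding), dG_cat = -RT ln kcat,
    dG_app = -RT ln(kcat/Km); the identity dG_app = dG_b + dG_cat holds
    exactly by construction.  ddG_app is relative to a reference construct
    (positive = mutant slower) and independent of the concentration unit.
    """

    T: float
    dG_b: float
    dG_cat: float
    dG_app: float
    ddG_app: float | None = None
    concentration_unit: str = "uM"
    R_gas: float = R_GAS_KCAL


@dataclass
class PairResult:
    """Asymmetry index of a symmetry-related residue pair (R_A >= 1)."""

    pair: tuple[str, str]
    mode: str
    RA: float
    se_RA: float
    numerator: str  # construct whose Vmax is the larger one


def intrinsic_equilibrium(fit_cyt: MMFit, fit_ext: MMFit) -> tuple[float, float]:
    """K_int = K'm/K''m from the two Ca2+/Ca2+ side fits, with ratio SE.

    Returns (K_int, se).  The directional asymmetry of bidirectional Ca2+
    movement is 1/K_int (cytosolic-to-extracellular over the reverse).
    """
    for f, side in ((fit_cyt, "cytosolic"), (fit_ext, "extracellular")):
        if not f.ok:
            raise ValueError(f"{side} fit is flagged: {f.message}")
    k = fit_cyt.Km / fit_ext.Km
    se = k * math.sqrt((fit_cyt.se_Km / fit_cyt.Km) ** 2
                       + (fit_ext.se_Km / fit_ext.Km) ** 2)
    return k, se


def asymmetry_index(rec1: ConstructRecord, rec2: ConstructRecord,
                    mode: str | None = None) -> PairResult:
    """R_A = larger V''max / smaller V''max for a mutant pair, with SE.

    Max/min ordering guarantees R_A >= 1 and makes the index symmetric in
    its arguments; the numerator construct is recorded.
    """
    if mode is None:
        mode = rec1.mode
    if rec1.mode != rec2.mode:
        raise ValueError("both constructs must be measured in the same mode")
    for r in (rec1, rec2):
        if r.Vmax_ext is None:
            raise ValueError(f"missing V''max for {r.construct_name}")
    hi, lo = ((rec1, rec2) if rec1.Vmax_ext >= rec2.Vmax_ext else (rec2, rec1))
    ra = hi.Vmax_ext / lo.Vmax_ext
    se = ra * math.sqrt((hi.se_Vmax_ext / hi.Vmax_ext) ** 2
                        + (lo.se_Vmax_ext / lo.Vmax_ext) ** 2)
    return PairResult(pair=(rec1.construct_name, rec2.construct_name),
                      mode=str(mode), RA=ra, se_RA=se,
                      numerator=hi.construct_name)


def ddg_app(eff_mut: float, eff_wt: float, T: float = T_ASSAY) -> float:
    """Apparent transition-state destabilization, kcal/mol.

    ddG_app = -2.303 R T log10[(kcat/Km)_mut / (kcat/Km)_wt], i.e.
    -RT ln(ratio); positive when the mutant has the lower catalytic capacity.
    Returns +/-inf (with the sign of the lost activity) if one efficiency
    is zero.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if eff_mut < 0 or eff_wt < 0:
        raise ValueError("efficiencies must be non-negative")
    if eff_mut == 0 and eff_wt == 0:
        raise ValueError("both efficiencies are zero")
    if eff_mut == 0:
        return math.inf
    if eff_wt == 0:
        return -math.inf
    return -R_GAS_KCAL * T * math.log(eff_mut / eff_wt)


def free_energy_terms(record: ConstructRecord, T: float = T_ASSAY,
                      ref: ConstructRecord | None = None) -> EnergyTerms:
    """Ground/transition-state energy ledger for one construct.

    Km enters in uM (declared 1 uM standard state, recorded on the result);
    kcat in 1/s.  ddG_app is filled when a reference construct is given.
    """
    if record.Km_ext is None or record.kcat is None:
        raise ValueError("record must carry Km_ext and kcat")
    if record.Km_ext <= 0 or record.kcat <= 0:
        raise ValueError("Km and kcat must be positive")
    rt = R_GAS_KCAL * T
    dg_b = rt * math.log(record.Km_ext)
    dg_cat = -rt * math.log(record.kcat)
    dg_app = dg_b + dg_cat  # == -RT ln(kcat/Km), exactly
    ddg = None
    if ref is not None:
        if ref.efficiency is None or record.efficiency is None:
            raise ValueError("efficiencies required for ddG_app")
        ddg = ddg_app(record.efficiency, ref.efficiency, T)
    return EnergyTerms(T=T, dG_b=dg_b, dG_cat=dg_cat, dG_app=dg_app,
                       ddG_app=ddg)


def classify_residue_group(record: ConstructRecord, wt: ConstructRecord,
                           cat_frac: float = 0.25,
                           kint_band: tuple[float, float] = (0.1, 0.35),
                           kint_fold: float = 4.0) -> str:
    """Assign a mutant to one of three functional groups.

    'catalytic'      -- catalytic capacity below ``cat_frac`` of WT while the
                        intrinsic equilibrium stays in the WT band;
    'conformational' -- K_int shifted more than ``kint_fold``-fold from WT
                        while the capacity is not strongly reduced;
    'neutral'        -- neither criterion met.
    Defaults mirror the observed group boundaries (capacity 10-25% of WT for
    moderately affected residues, WT K_int band 0.1-0.35).
    """
    if record.efficiency is None or wt.efficiency is None:
        raise ValueError("efficiency required for classification")
    if record.K_int is None or wt.K_int is None:
        raise ValueError("K_int required for classification (partial record)")
    eff_ratio = record.efficiency / wt.efficiency
    kint_in_band = kint_band[0] <= record.K_int <= kint_band[1]
    kint_shift = max(record.K_int / wt.K_int, wt.K_int / record.K_int)
    if eff_ratio < cat_frac and kint_in_band:
        return "catalytic"
    if kint_shift > kint_fold and eff_ratio >= cat_frac:
        return "conformational"
    return "neutral"


# ---------------------------------------------------------------------------
# pH profiles


def _single_ionization(ph, vmax, pka, sign):
    # sign=+1: activity rises with pH (basic limb); sign=-1: falls
    return vmax / (1.0 + 10.0 ** (sign * (pka - ph)))


def _bell(ph, vmax, pka1, pka2):
    return vmax / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2))


def fit_ph_profile(ph: np.ndarray, rates: np.ndarray) -> dict:
    """Fit one- and two-ionization models to a rate-vs-pH profile.

    Returns a dict with the selected model ('single' or 'bell'), its pKa
    estimate(s), Vmax, RSS, and a flag for flat (pKa-undefined) profiles.
    Requires >= 5 pH points.
    """
    ph = np.asarray(ph, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if ph.size < 5:
        raise ValueError("need at least 5 pH points")
    span = rates.max() - rates.min()
    if rates.max() <= 0 or span < 0.02 * rates.max():
        return {"model": "flat", "pKa": None, "flagged": True,
                "message": "profile flat within 2%; pKa undefined"}

    fits = []
    for sign in (+1.0, -1.0):
        try:
            popt, _ = curve_fit(
                lambda x, vm, pk: _single_ionization(x, vm, pk, sign),
                ph, rates, p0=[rates.max(), float(np.median(ph))],
                maxfev=5000)
            rss = float(np.sum((rates - _single_ionization(ph, *popt, sign)) ** 2))
            fits.append({"model": "single", "Vmax": popt[0], "pKa": [popt[1]],
                         "rising": sign > 0, "rss": rss})
        except RuntimeError:
            pass
    try:
        popt, _ = curve_fit(_bell, ph, rates,
                            p0=[rates.max(), ph.min() + 0.5, ph.max() - 0.5],
                            maxfev=5000)
        rss = float(np.sum((rates - _bell(ph, *popt)) ** 2))
        # penalize the extra parameter (AIC with gaussian errors)
        fits.append({"model": "bell", "Vmax": popt[0],
                     "pKa": sorted([popt[1], popt[2]]), "rss": rss})
    except RuntimeError:
        pass
    if not fits:
        return {"model": "flat", "pKa": None, "flagged": True,
                "message": "no ionization model converged"}

    n = ph.size
    for f in fits:
        k = 2 if f["model"] == "single" else 3
        rss = max(f["rss"], 1e-300)
        f["aic"] = n * math.log(rss / n) + 2 * k
    best = min(fits, key=lambda f: f["aic"])
    best["flagged"] = False
    return best


def profile_similarity(rates_a: np.ndarray, rates_b: np.ndarray) -> float:
    """RMS difference of max-normalized profiles (0 = identical shape).

    Scale-invariant: multiplying one profile by a constant leaves it at 0.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share their pH grid")
    if a.max() <= 0 or b.max() <= 0:
        raise ValueError("profiles must contain positive rates")
    d = a / a.max() - b / b.max()
    return float(np.sqrt(np.mean(d ** 2)))
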
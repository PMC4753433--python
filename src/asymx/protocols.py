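"""Replicated measurement protocols of the flux assay.

The assay convention reports Km and Vmax as the mean over (at least) three
independent experiments, each a full dose-response curve with triplicate
uptake measurements per concentration.  These helpers run that protocol on
the simulator: simulate ``n_experiments`` independent curves, fit each, and
report mean +/- SEM of the operational constants and the derived statistics
(K_int, R_A, relative catalytic efficiency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_michaelis_menten
from .transport import (ExchangeMode, PingPongParams, Side,
                        default_concentration_grid, simulate_dose_response)

__all__ = [
    "MeasuredKinetics",
    "measure_km_vmax",
    "measure_kint",
    "measure_vmax_ratio",
    "measure_relative_efficiency",
]

N_EXPERIMENTS = 3  # independent dose-response experiments per measurement


@dataclass
class MeasuredKinetics:
    """Mean +/- SEM of Km and Vmax over independent experiments."""

    Km: float
    sem_Km: float
    Vmax: float
    sem_Vmax: float
    n_experiments: int


def measure_km_vmax(params: PingPongParams,
                    mode: ExchangeMode = ExchangeMode.CaCa,
                    varied_side: Side = Side.extracellular,
                    seed: int | np.random.SeedSequence = 0,
                    n_experiments: int = N_EXPERIMENTS,
                    concentrations=None, n_replicates: int = 3,
                    noise_cv: float = 0.05) -> MeasuredKinetics:
    """Run the replicated dose-response protocol for one construct/side."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    if concentrations is None:
        concentrations = default_concentration_grid()
    kms, vms = [], []
    for child in ss.spawn(n_experiments):
        dr = simulate_dose_response(params, concentrations, n_replicates,
                                    noise_cv, mode, varied_side,
                                    seed=np.random.default_rng(child))
        fit = fit_michaelis_menten(dr)
        if not fit.ok:
            raise RuntimeError(
                f"flagged fit in protocol run for {params.construct_name}: "
                f"{fit.message}")
        kms.append(fit.Km)
        vms.append(fit.Vmax)
    kms, vms = np.asarray(kms), np.asarray(vms)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return MeasuredKinetics(float(kms.mean()), sem(kms), float(vms.mean()),
                            sem(vms), n_experiments)


def measure_kint(params: PingPongParams, seed: int = 0,
                 **protocol) -> tuple[float, float]:
    """K_int = K'm/K''m from both-side Ca2+/Ca2+ protocols; (value, SE)."""
    ss = np.random.SeedSequence(seed)
    cyt_ss, ext_ss = ss.spawn(2)
    cyt = measure_km_vmax(params, ExchangeMode.CaCa, Side.cytosolic,
                          cyt_ss, **protocol)
    ext = measure_km_vmax(params, ExchangeMode.CaCa, Side.extracellular,
                          ext_ss, **protocol)
    k = cyt.Km / ext.Km
    se = k * float(np.hypot(cyt.sem_Km / cyt.Km, ext.sem_Km / ext.Km))
    return k, se


def measure_vmax_ratio(params_a: PingPongParams, params_b: PingPongParams,
                       mode: ExchangeMode = ExchangeMode.NaCa,
                       seed: int = 0, **protocol) -> tuple[float, float]:
    """Asymmetry index: max/min ratio of measured V''max; (value, SE)."""
    ss = np.random.SeedSequence(seed)
    a_ss, b_ss = ss.spawn(2)
    a = measure_km_vmax(params_a, mode, Side.extracellular, a_ss, **protocol)
    b = measure_km_vmax(params_b, mode, Side.extracellular, b_ss, **protocol)
    hi, lo = (a, b) if a.Vmax >= b.Vmax else (b, a)
    ra = hi.Vmax / lo.Vmax
    se = ra * float(np.hypot(hi.sem_Vmax / hi.Vmax, lo.sem_Vmax / lo.Vmax))
    return ra, se


def measure_relative_efficiency(params_mut: PingPongParams,
                                params_wt: PingPongParams,
                                mode: ExchangeMode = ExchangeMode.CaCa,
                                seed: int = 0, **protocol) -> float:
    """Mutant kcat/Km as a percentage of WT (equal Et assumed)."""
    ss = np.random.SeedSequence(seed)
    mut_ss, wt_ss = ss.spawn(2)
    mut = measure_km_vmax(params_mut, mode, Side.extracellular, mut_ss, **protocol)
    wt = measure_km_vmax(params_wt, mode, Side.extracellular, wt_ss, **protocol)
    eff_mut = mut.Vmax / mut.Km
    eff_wt = wt.Vmax / wt.Km
    return 100.0 * eff_mut / eff_wt
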
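"""Ground-truth generators emulating the NCX_Mj study's raw measurements.

The full exchanger sequence is not public, so the fixture protein is a
301-residue stand-in (synthetic) that honors every residue position the
analysis touches — the two GTSLPE helix-breaking motifs at 49-54 and
208-213, the ion-coordinating and entry residues, and the proline placement
that drives amide bookkeeping — with alanine elsewhere.  Flux datasets come
from the 4-state ping-pong simulator; HDX spectra come from the envelope
simulator with per-residue exchange-rate maps, so every downstream statistic
has a closed-form truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import envelopes
from .peptides import Peptide, ProteinSequence, observable_amides
from .transport import (ExchangeMode, PingPongParams, Side,
                        default_concentration_grid, simulate_dose_response)

__all__ = [
    "FixtureSpec",
    "fixture_sequence",
    "WT_PARAMS",
    "DEFAULT_FOLD_CHANGES",
    "FluxScenario",
    "generate_flux_dataset",
    "HDXScenario",
    "generate_hdx_dataset",
]

# residues the analysis cites: ion-coordinating, pocket-entry, helix-breaking
KNOWN_RESIDUES: dict[int, str] = {
    47: "A", 49: "G", 50: "T", 51: "S", 52: "L", 53: "P", 54: "E",
    73: "N", 77: "S", 81: "N",
    206: "A", 208: "G", 209: "T", 210: "S", 211: "L", 212: "P", 213: "E",
    232: "N", 236: "S", 240: "D",
}

# peptic peptide spans used throughout the HDX analysis
PEPTIDE_SPANS: tuple[tuple[int, int], ...] = (
    (41, 46), (47, 59), (53, 59), (54, 59),
    (205, 214), (215, 230), (215, 237), (238, 245),
)

EXPOSURE_TIMES_S: tuple[float, ...] = (15.0, 120.0, 1200.0)
STATES: tuple[str, ...] = ("apo", "Na", "Ca")


@dataclass(frozen=True)
class FixtureSpec:
    protein_length: int = 301
    known_residues: tuple[tuple[int, str], ...] = tuple(sorted(KNOWN_RESIDUES.items()))
    peptide_spans: tuple[tuple[int, int], ...] = PEPTIDE_SPANS
    states: tuple[str, ...] = STATES
    times: tuple[float, ...] = EXPOSURE_TIMES_S
    placeholder: str = "A"  # never proline


def fixture_sequence(spec: FixtureSpec = FixtureSpec()
                     ) -> tuple[ProteinSequence, list[Peptide]]:
    """Deterministic fixture protein and its peptic peptide set."""
    if spec.placeholder == "P":
        raise ValueError("placeholder residue must not be proline")
    known = dict(spec.known_residues)
    for pos, aa in known.items():
        if not 1 <= pos <= spec.protein_length:
            raise ValueError(f"known residue {pos} outside the protein")
    seen: dict[int, str] = {}
    for pos, aa in spec.known_residues:
        if pos in seen and seen[pos] != aa:
            raise ValueError(f"conflicting residues at position {pos}")
        seen[pos] = aa
    residues = [spec.placeholder] * spec.protein_length
    for pos, aa in known.items():
        residues[pos - 1] = aa
    seq = ProteinSequence("".join(residues))
    peptides = [Peptide.from_protein(seq, s, e, charge=2)
                for s, e in spec.peptide_spans]
    return seq, peptides


# ---------------------------------------------------------------------------
# flux datasets

# WT cycle constants: K''m = 200 uM, K'm = 30 uM (K_int = 0.15),
# Ca/Ca kcat = 0.5 1/s and Na/Ca kcat = 0.8 1/s, inside the printed
# 0.01-0.8 1/s mutant envelope
WT_PARAMS = PingPongParams(
    construct_name="WT", Kd_ext=400.0, Kd_cyt=60.0,
    k_transloc_in=1.0, k_transloc_out=1.0, k_return_Na=4.0, Et=1.0)


@dataclass(frozen=True)
class FoldChange:
    """Multiplicative perturbations of the WT cycle constants.

    ``capacity`` scales both translocation directions and the Na-loaded
    return together, so Vmax changes by exactly that factor in every mode
    while every Km is untouched — the signature of a transition-state
    (catalytic) mutation.  ``k_transloc_out`` alone shifts the conformational
    equilibrium: K_int scales as Kd_cyt_fold / k_out_fold while kcat/Km is
    exactly preserved (kcat/K''m = k_in/Kd_ext), the signature of an
    inward-stabilizing mutation.
    """

    capacity: float = 1.0
    k_transloc_out: float = 1.0
    Kd_ext: float = 1.0
    Kd_cyt: float = 1.0
    Et: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.capacity, self.k_transloc_out, self.Kd_ext,
                  self.Kd_cyt, self.Et):
            if f <= 0:
                raise ValueError("fold-changes must be positive")


# published anchors: N73A/N232A shift K_int 0.15 -> 2.8 at near-WT catalytic
# capacity; S236A/S77A V''max ratio 31.3 in Na+/Ca2+ exchange; E54A/E213A
# 25-50-fold capacity loss; P53C ~3% and P212C ~12% of WT kcat/Km;
# N81A/S236A retain WT behavior.  The 18.67-fold K_int shift is split
# between weaker cytosolic binding (x5.6) and slower outward translocation
# (x0.3), keeping both operational Km inside the 20-2000 uM assay window.
_KINT_SHIFT_KD, _KINT_SHIFT_KOUT = 5.6, 0.3  # ratio 18.67 = 2.8/0.15
DEFAULT_FOLD_CHANGES: dict[str, FoldChange] = {
    "WT": FoldChange(),
    "N73A": FoldChange(Kd_cyt=_KINT_SHIFT_KD, k_transloc_out=_KINT_SHIFT_KOUT),
    "N232A": FoldChange(Kd_cyt=_KINT_SHIFT_KD, k_transloc_out=_KINT_SHIFT_KOUT),
    "S77A": FoldChange(capacity=1.0 / 31.3),
    "S236A": FoldChange(),
    "E54A": FoldChange(capacity=1.0 / 30.0),
    "E213A": FoldChange(capacity=1.0 / 30.0),
    "P53C": FoldChange(capacity=0.03),
    "P212C": FoldChange(capacity=0.12),
    "N81A": FoldChange(),
}


@dataclass(frozen=True)
class FluxScenario:
    constructs: tuple[tuple[str, FoldChange], ...] = tuple(
        DEFAULT_FOLD_CHANGES.items())
    concentrations: tuple[float, ...] = tuple(default_concentration_grid())
    n_replicates: int = 3
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if "WT" not in dict(self.constructs):
            raise ValueError("scenario must include a WT construct")

    def params_for(self, name: str) -> PingPongParams:
        fc = dict(self.constructs)[name]
        return WT_PARAMS.scaled(Kd_ext=fc.Kd_ext, Kd_cyt=fc.Kd_cyt,
                                k_transloc=fc.capacity,
                                k_transloc_out=fc.k_transloc_out,
                                k_return=fc.capacity, Et=fc.Et, name=name)


def _true_kinetics(p: PingPongParams) -> dict:
    """Closed-form operational constants implied by the cycle parameters."""
    kin, kout, kret = p.k_transloc_in, p.k_transloc_out, p.k_return_Na
    km_ext_caca = p.Kd_ext * kout / (kin + kout)
    km_cyt_caca = p.Kd_cyt * kin / (kin + kout)
    out = {
        "Km_ext_CaCa": km_ext_caca,
        "Km_cyt_CaCa": km_cyt_caca,
        "Vmax_CaCa": p.Et * kin * kout / (kin + kout),
        "Km_ext_NaCa": p.Kd_ext * kret / (kin + kret),
        "Vmax_NaCa": p.Et * kin * kret / (kin + kret),
        "K_int": km_cyt_caca / km_ext_caca,
        "kcat_CaCa": kin * kout / (kin + kout),
    }
    out["efficiency_CaCa"] = out["kcat_CaCa"] / out["Km_ext_CaCa"]
    return out


# (mode, varied side) combinations measured per construct
FLUX_DESIGN = (
    (ExchangeMode.CaCa, Side.extracellular),
    (ExchangeMode.CaCa, Side.cytosolic),
    (ExchangeMode.NaCa, Side.extracellular),
)


def generate_flux_dataset(scenario: FluxScenario = FluxScenario(),
                          seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulated flux tables for every construct x mode x side, plus truth.

    Returns a tidy table (construct, mode, varied_side, conc_uM, rate,
    rate_sd, n) and a truth dict with the generating parameters and their
    closed-form operational constants, sufficient to predict every
    downstream statistic.  Byte-identical across runs for a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenario.constructs) * len(FLUX_DESIGN))
    rows = []
    truth = {}
    i = 0
    for name, _ in scenario.constructs:
        params = scenario.params_for(name)
        truth[name] = {"params": params, **_true_kinetics(params)}
        for mode, side in FLUX_DESIGN:
            rng = np.random.default_rng(children[i])
            i += 1
            dr = simulate_dose_response(
                params, scenario.concentrations, scenario.n_replicates,
                scenario.noise_cv, mode, side, seed=rng)
            for conc, rate, sd, n in dr.points:
                rows.append({"construct": name, "mode": mode.value,
                             "varied_side": side.value, "conc_uM": conc,
                             "rate": rate, "rate_sd": sd, "n": n})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# HDX datasets

# per-residue exchange-rate classes (1/s): the alpha1 repeat core 48-52 is
# rigid (~26 %D at 1200 s apo, zero once an ion is bound), 54-59 and the
# alpha2 repeat 205-214 flexible, the rest intermediate
_RATE_CLASSES = {"rigid": 2.5e-4, "intermediate": 1.5e-3, "flexible": 2.0e-2}


def _default_rate_map(length: int) -> dict[str, np.ndarray]:
    """state -> per-residue intrinsic exchange rate (1-based index shifted)."""
    base = np.full(length + 1, _RATE_CLASSES["intermediate"])
    base[48:53] = _RATE_CLASSES["rigid"]          # 48-52 rigid in apo
    base[54:60] = _RATE_CLASSES["flexible"]       # 54-59 flexible
    base[205:215] = _RATE_CLASSES["flexible"]     # alpha2 repeat, dynamic
    base[215:231] = _RATE_CLASSES["flexible"]     # end of TM7/start of TM8:
    # flexible in apo, so ion binding still protects it overall even when
    # Ca2+ triggers cooperative (EX1) opening of the bound form
    rates = {"apo": base}
    for state in ("Na", "Ca"):
        prot = base / 4.0                         # global ion protection
        prot[48:53] = 1e-7                        # no HDX in 48-52 when bound
        prot[205:215] = base[205:215] / 1.5       # alpha2 barely protected
        if state == "Ca":
            # Ca2+ strongly rigidifies the closed conformation of 215-230
            # while triggering its cooperative opening (the EX1 signature:
            # a large closed/open stability gap, refolding slower than
            # labeling)
            prot[215:231] = _RATE_CLASSES["rigid"]
        rates[state] = prot
    return rates


@dataclass(frozen=True)
class HDXScenario:
    fixture: FixtureSpec = FixtureSpec()
    # spans undergoing cooperative (EX1) opening per state
    ex1_segments: tuple[tuple[int, int, str, float], ...] = (
        (215, 230, "Ca", 1.5e-3),  # start, end, state, k_op (1/s)
    )
    label_fraction: float = 0.8
    charge: int = 2
    noise_cv: float = 0.03


def generate_hdx_dataset(scenario: HDXScenario = HDXScenario(),
                         seed: int = 0) -> tuple[list, dict]:
    """Isotope spectra for every peptide x state x exposure, plus truth.

    Truth holds the per-amide rates, the regime spec per peptide x state and
    the closed-form expected uptake at each exposure.  Deterministic for a
    fixed seed.
    """
    seq, peptides = fixture_sequence(scenario.fixture)
    rate_map = _default_rate_map(len(seq))
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(peptides) * len(scenario.fixture.states)))

    spectra = []
    truth: dict = {"sequence": seq, "peptides": peptides, "rate_map": rate_map,
                   "records": {}}
    for pep in peptides:
        amides = observable_amides(pep, seq)
        comp = envelopes.peptide_composition(pep.sequence)
        natural = envelopes.natural_envelope(comp)
        for state in scenario.fixture.states:
            rng = np.random.default_rng(next(children))
            rates = tuple(float(rate_map[state][r]) for r in amides)
            regime = _regime_for(pep, state, amides, rates, scenario)
            series = envelopes.simulate_time_series(
                natural, len(amides), regime, scenario.fixture.times,
                charge=scenario.charge,
                label_fraction=scenario.label_fraction,
                noise_cv=scenario.noise_cv, seed=rng,
                peptide_id=pep.id, state=state)
            # undeuterated reference (t=0), noiseless
            ref = envelopes.simulate_time_series(
                natural, len(amides), regime, [0.0], charge=scenario.charge,
                label_fraction=scenario.label_fraction, noise_cv=0.0,
                peptide_id=pep.id, state=state)[0]
            spectra.extend(series)
            truth["records"][(pep.id, state)] = {
                "amides": amides,
                "regime": regime,
                "natural": natural,
                "undeuterated": ref,
                "expected_uptake_D": {
                    t: _expected_uptake(regime, rates, t,
                                        scenario.label_fraction)
                    for t in scenario.fixture.times},
            }
    return spectra, truth


def generate_regime_benchmark(n_per_regime: int = 100, n_amides: int = 12,
                              times=EXPOSURE_TIMES_S, noise_cv: float = 0.03,
                              charge: int = 2, label_fraction: float = 0.8,
                              seed: int = 0):
    """Labeled synthetic benchmark of EX1/EX2/mixed exposure series.

    Regime parameters are drawn log-uniformly from ranges where each regime's
    hallmark is expressed within the 15/120/1200 s exposure window: EX1
    opening rates 6e-4..3e-3 1/s (bimodality visible at >= 2 exposures), EX2
    per-amide rates 3e-4..3e-2 1/s, and for mixed series a slow residual
    exchange (2e-4..1e-3 1/s) of the closed population under the same
    opening rates.  Returns a list of (true_regime, spectra) pairs plus the
    shared natural envelope.
    """
    rng = np.random.default_rng(seed)
    natural = envelopes.natural_envelope(
        envelopes.averagine_composition(1400.0))

    def loguniform(lo, hi, size=None):
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size))

    series = []
    for kind in ("EX1", "EX2", "mixed"):
        for _ in range(n_per_regime):
            if kind == "EX1":
                spec = envelopes.RegimeSpec(
                    "EX1", k_op=float(loguniform(6e-4, 3e-3)))
            elif kind == "EX2":
                spec = envelopes.RegimeSpec(
                    "EX2", rates=tuple(loguniform(3e-4, 3e-2, n_amides)))
            else:
                spec = envelopes.RegimeSpec(
                    "mixed", rates=tuple(loguniform(2e-4, 1e-3, n_amides)),
                    k_op=float(loguniform(6e-4, 3e-3)))
            spectra = envelopes.simulate_time_series(
                natural, n_amides, spec, times, charge=charge,
                label_fraction=label_fraction, noise_cv=noise_cv, seed=rng)
            series.append((kind, spectra))
    return series, natural


def _regime_for(pep: Peptide, state: str, amides: list[int],
                rates: tuple[float, ...],
                scenario: HDXScenario) -> envelopes.RegimeSpec:
    for s, e, st, k_op in scenario.ex1_segments:
        overlap = [s <= r <= e for r in amides]
        if st == state and any(overlap):
            # cooperative opening of the segment's amides on top of the slow
            # residual exchange of the closed population -> mixed kinetics;
            # amides outside the segment exchange by EX2 in both populations,
            # keeping overlapping peptides mutually consistent
            return envelopes.RegimeSpec(kind="mixed", rates=rates, k_op=k_op,
                                        open_mask=tuple(overlap))
    return envelopes.RegimeSpec(kind="EX2", rates=rates)


def _expected_uptake(regime: envelopes.RegimeSpec, rates, t: float,
                     label_fraction: float) -> float:
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    step = envelopes.DEUTERIUM_STEP
    p = 1.0 - np.exp(-rates * t)
    if regime.kind == "EX2":
        return float(label_fraction * p.sum() * step)
    w_open = 1.0 - math.exp(-regime.k_op * t)
    mask = (np.ones(n, dtype=bool) if regime.open_mask is None
            else np.asarray(regime.open_mask, dtype=bool))
    closed = p if regime.kind == "mixed" else np.zeros(n)
    opened = np.where(mask, 1.0, closed)
    return float(label_fraction * step
                 * ((1.0 - w_open) * closed.sum() + w_open * opened.sum()))
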
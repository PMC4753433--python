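# Methods

## Transport model

The exchanger is a four-state alternating-access cycle: outward-facing empty
(O), outward-facing Ca-loaded (O·Ca), inward-facing Ca-loaded (I·Ca), and
inward-facing empty (I).  Ca²⁺ binding at either face is treated as a rapid
equilibrium — binding edges carry off-rates 10⁵× the fastest conformational
rate, with koff/kon equal to the face's dissociation constant (K″d
extracellular, K′d cytosolic).  Loaded-carrier translocation runs at k_in
(outward→inward) and k_out (reverse); empty-carrier translocation is
omitted because it contributes negligibly under exchange conditions.  In
Na⁺/Ca²⁺ mode the I→O return is a single effective rate representing the
whole saturating-Na⁺ limb (no Na dose dependence is modeled, so only the
extracellular side can be titrated in that mode).  The stoichiometry
controversy around the middle ion-binding site, electrogenicity, and
time-resolved quench-flow kinetics are out of scope.

The stationary distribution of the cycle is obtained by solving the linear
master equation (one balance row replaced by normalization); no closed-form
rate law is assumed.  The initial tracer-uptake rate is the unidirectional
influx of extravesicular label, Et·k_in·P(O·Ca).  For Ca²⁺/Ca²⁺ exchange
stationarity makes this equal to the exchange rate; the closed forms
implied by the model,

    K″m = K″d·k_out/(k_in+k_out)      V″max = Et·k_in·k_out/(k_in+k_out)
    K′m = K′d·k_in/(k_in+k_out)       K_int = K′m/K″m = K′d·k_in/(K″d·k_out)

serve as cross-checks and as ground truth for the generators; operational
Km/Vmax are always *measured* by fitting simulated curves.

### Tunable parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| K″d, K′d (WT) | µM | 400, 60 | give K″m = 200 µM, K′m = 30 µM, K_int = 0.15 |
| k_in, k_out (WT) | s⁻¹ | 1, 1 | Ca/Ca kcat = 0.5 s⁻¹, inside the 0.01–0.8 s⁻¹ mutant envelope |
| k_return_Na (WT) | s⁻¹ | 4 | Na/Ca kcat = 0.8 s⁻¹ |
| T | K | 308.15 | 35 °C assay temperature |
| noise CV (flux) | — | 0.05 | multiplicative lognormal, unit mean |
| replicates / experiments | — | 3 / 3 | triplicate rates; Km/Vmax reported as the mean over three independent experiments |
| concentrations | µM | 8 points, 20–2000, log-spaced | the assay's titration window |

Mutants are fold-changes on WT. A *capacity* fold scales k_in, k_out and
the Na-return together (Vmax changes by exactly that factor in every mode,
Km untouched — a transition-state perturbation). An *inward-stabilizing*
perturbation scales K′d up (×5.6) and k_out down (×0.3): K_int scales as
the ratio (18.67-fold, 0.15→2.8) while kcat/K″m = k_in/K″d is exactly
preserved and both operational Km stay inside the titration window.  The
fold values (1/31.3 for the high-asymmetry pair partner, 1/30 for the
glutamate mutants, 0.03/0.12 for the two proline mutants) are the published
generating anchors.

### Fitting and error propagation

Michaelis–Menten fits use weighted nonlinear least squares (weights 1/SEM²
of the replicate means when replicate SDs exist, otherwise unweighted),
initialized from a Hanes linearization (S/v vs S).  Fits are flagged — not
silently returned — when all rates are zero, the optimizer fails, or the
fitted Km leaves [min(S)/100, 100·max(S)].  kcat = Vmax/[E]t with [E]t from
the GFP assay ([GFP] = (A₄₈₈−background)/(ε·l), ε = 56000 M⁻¹cm⁻¹; the
expression fraction uses a configurable GFP molar mass, default
26 900 g/mol, which the assay description leaves unstated).  All ratio SEs
(K_int, R_A, kcat/Km) use first-order propagation including the Km–Vmax
covariance; agreement with Monte-Carlo propagation is asserted to 10% for
input CVs ≤ 10%.

Energies use R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹.  Absolute ΔG_b = RT·ln Km takes
Km in µM (an implied 1 µM standard state, recorded in output metadata,
since no standard state is stated for the absolute numbers); ΔΔG‡_app is
standard-state free.  The identity ΔG‡_app = ΔG_b + ΔG‡_cat holds exactly
by construction.  Residue-group classification defaults: catalytic when
kcat/Km < 0.25×WT with K_int inside 0.1–0.35; conformational when K_int
shifts > 4-fold at preserved capacity; neutral otherwise.

## HDX model

Coordinates are 1-based inclusive throughout.  Observable amides exclude a
peptide's first residue (fast back-exchange at the nascent N-terminus) and
all prolines; a two-residue N-terminal loss variant is available
(`n_term_loss=2`).  Uptake is the neutral centroid shift against the
undeuterated control; %D normalizes by n_amides × label fraction (0.8 from
the 5-fold dilution into D₂O).  No back-exchange correction is applied —
raw uptake is reported.  Negative uptake within 2 SD is clipped to zero
with a warning, beyond that flagged as inconsistent.  Region resolution
requires prefix- or suffix-nested peptides; the region's amide set is the
set difference, uptake the difference, SD the quadrature sum.

Isotope envelopes use the aggregated (unit-neutron) approximation: element
isotope distributions (masses/abundances from `pyteomics.mass.nist_mass`)
are convolved per composition, peaks spaced by the ¹³C–¹²C gap
(1.0033548 Da); the deuterium ladder is spaced 1.00628 Da.  Deuteration
convolves the natural envelope with the exact Poisson-binomial of per-amide
incorporation probabilities.

Regimes: EX2 — independent amide exchange, p_i(t) = f_label(1−e^(−k_i t));
EX1 — two-population mixture, open population fully exchanged, heavy weight
1−e^(−k_op t); mixed — EX1 opening over a slowly exchanging closed
population.  When a cooperatively opening segment only partially overlaps a
peptide, only the overlapping amides open (an open-mask), keeping
overlapping peptides mutually consistent.

The mixture fitter compares 1- and 2-component models on a 0.02 Da grid
after a 0.05 Da Gaussian blur of both sticks and observation; each
component is the natural envelope ⊗ a binomial deuteration profile
parameterized by centroid plus a Gaussian width-inflation term, with the
heavy centroid bounded by the physical maximum (n_amides deuteriums).
Model selection uses AICc with a margin of 20, a minimum minor weight of
0.02, and a minimum component separation of 1.5 Da — calibrated so a 1%
minor component is not called bimodal; all three knobs are configurable.
Classification: EX1 needs ≥ 2 exposures with 2-component support, monotone
heavy-weight growth (slack 0.02) and component centroids stable within
0.15 Da; EX2 needs 1-component support with a non-decreasing centroid;
light-centroid drift > 0.15 Da turns an EX1 call into mixed; inconsistent
series are called mixed with a low-confidence flag.  The published regime
assignments were visual — this module formalizes them, so agreement is
asserted on labeled synthetic data (≥95% over 300 series) and only
qualitatively against the published spectra.

## Synthetic data: what it emulates, and what it does not

The fixture protein is a 301-residue stand-in (the full sequence is not
published): all analysis-relevant residues — both GTSLPE motifs, the
ion-coordinating and pocket-entry positions — sit at their true positions,
alanine fills the rest, and only the cited positions plus proline placement
affect any computed quantity.  The HDX scenario assigns per-residue rate
classes (rigid 2.5×10⁻⁴, intermediate 1.5×10⁻³, flexible 2×10⁻² s⁻¹):
region 48–52 rigid in apo and fully protected when an ion is bound; 54–59
and the α₂-repeat flexible with weak protection; the 215–230 stretch
flexible in apo, strongly rigidified but cooperatively opening
(k_op = 1.5×10⁻³ s⁻¹) under Ca²⁺.  Spectra carry 3% multiplicative
intensity noise at exposures 15/120/1200 s, charge 2.

Not emulated: back-exchange, peak-shape/resolution effects, chromatographic
carry-over, peptide misassignment, intensity-dependent (shot) noise, and
intrinsic sequence-dependent exchange rates.  Passing tests therefore show
that the estimators recover known truth under the stated noise model — not
that they are robust to every artifact of real spectra.  Likewise the flux
generator draws i.i.d. lognormal noise; systematic errors (pipetting drift,
vesicle heterogeneity) are not represented.

The classification benchmark (300 series, 100 per regime, 12 amides,
averagine-1400 envelope) draws k_op log-uniformly from 6×10⁻⁴–3×10⁻³ s⁻¹ —
the window where bimodality is expressed at ≥ 2 of the three exposures —
EX2 rates from 3×10⁻⁴–3×10⁻² s⁻¹ and mixed closed-population rates from
2×10⁻⁴–10⁻³ s⁻¹.

## Numerical choices

* Binding-relaxation factor 10⁵; trans-side saturation represented as
  10⁶×Kd (fractional occupancy error 10⁻⁶).
* Michaelis–Menten fits: scipy `curve_fit`, bounds ≥ 0, xtol/ftol 10⁻¹²;
  envelope fits: `least_squares` with xtol/ftol 10⁻⁸ (weights recovered to
  ~10⁻³, far inside the 0.02 assertion band); uptake-time-course amplitudes
  bounded by the observable plateau via a hinge penalty plus a final
  projection; two rate classes only with ≥ 5 time points.
* Steady-state oracle tests compare the linear solve against the exact
  propagator of the mass-action ODE (matrix exponential at 200× the
  slowest relaxation time), to 10⁻⁶ relative.
* Degenerate inputs fail loudly: all-zero dose-responses, flat pH profiles
  and non-nested peptide pairs return flagged results or raise, never
  silent numbers.
* Every stochastic operation takes a seed; generators spawn child streams
  with `numpy.random.SeedSequence` in a fixed order, making all outputs
  byte-identical for a fixed seed.

## Problem sizes

Default runs use the study-scale conditions throughout: 8-concentration
curves in triplicate with three independent experiments per measured
constant; 8 peptides × 3 states × 3 exposures for HDX; 300 series in the
classification benchmark.  These sizes were chosen as the package's
standard working scale and keep a full pipeline run under a minute apart
from the benchmark.

## Known limitations

* The averagine and aggregated-isotope approximations ignore isotope fine
  structure; centroids are exact only on the model's own grid.
* The EX1 open population is assumed fully exchanged; partially protected
  open states would bias the fitted heavy centroid low.
* K_int's SE uses independent-side propagation; fitting both sides jointly
  (shared Vmax in Ca²⁺/Ca²⁺ mode) would be more efficient but is not the
  assay's stated procedure.
* Absolute ΔG values depend on the declared concentration unit; only ΔΔG
  values are unit-free.
* The width-inflation term makes component variance a fitted nuisance:
  widths are not interpreted physically.
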
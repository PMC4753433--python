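# asymx

Analysis toolkit for the functional asymmetry of Na⁺/Ca²⁺ exchangers
(NCX-type antiporters), combining two complementary views of the same
protein:

* **transport kinetics** — the exchanger is modeled as a 4-state
  alternating-access (ping-pong) cycle: the outward-facing carrier binds
  Ca²⁺ with dissociation constant K″d, translocates it inward (k_in),
  releases it to the cytosolic face (K′d), and returns either loaded with
  Ca²⁺ (Ca²⁺/Ca²⁺ exchange, k_out) or via an effective Na⁺-loaded step
  (Na⁺/Ca²⁺ exchange).  Vesicle flux assays fit with v = Vmax·S/(Km+S)
  yield operational constants on either membrane side, from which the
  package derives kcat = Vmax/[E]t, the catalytic capacity kcat/Km, the
  intrinsic equilibrium of bidirectional Ca²⁺ movement
  **K_int = K′m/K″m**, the mutant-pair asymmetry index **R_A**
  (ratio of V″max values), and transition-state energetics
  ΔG_b = RT·ln Km, ΔG‡_cat = −RT·ln kcat, ΔG‡_app = −RT·ln(kcat/Km),
  ΔΔG‡_app = −2.303RT·log₁₀[(kcat/Km)_mut/(kcat/Km)_wt];

* **HDX-MS backbone dynamics** — deuterium uptake of peptic peptides from
  isotope-envelope centroids, sub-peptide resolution by subtracting
  overlapping peptides (e.g. 47–59 minus 53–59 localizes region 48–52),
  EX1/EX2/mixed exchange-regime deconvolution of bimodal envelopes, state
  difference maps (apo vs Na⁺- vs Ca²⁺-bound), and per-residue heat maps
  exportable into a PDB B-factor column.

Synthetic-data generators stand in for the raw measurements: a 301-residue
fixture protein carrying both GTSLPE helix-breaking motifs (49–54, 208–213)
and all analysis-relevant residues, a mutant panel with published generating
values (WT K_int = 0.15, inward-stabilized K_int = 2.8, pair V″max ratio
31.3, proline mutant at 3% of WT kcat/Km), and seeded noise models — so
every statistic the pipeline produces has a closed-form ground truth.

## Worked example

```
$ python examples/ex1_ex2_classification.py
exposure   components  heavy weight  (true)   centroids (Da uptake)
     15 s        1           nan   (0.022)   0.00
    120 s        2         0.160   (0.165)   0.00, 9.64
   1200 s        2         0.833   (0.835)   0.00, 9.67

regime call: EX1 (confident=True)
```

A peptide opening cooperatively at k_op = 1.5×10⁻³ s⁻¹ shows the EX1
hallmark: two isotope envelopes at fixed masses (here 0 and ~9.7 Da of
uptake on 12 amides at 80% labeling) whose intensities shift from light to
heavy as 1−exp(−k_op·t).  At 15 s the open population (2.2%) is still below
the bimodality threshold, so the model-selection keeps one component; the
two later exposures recover the open-population weight to ~0.005 and the
classifier calls the regime from their monotone weight transfer at fixed
centroids.

Other examples: `examples/flux_kinetics_and_energetics.py` (mutant panel →
K_int, R_A, ΔΔG‡ ledger), `examples/hdx_region_resolution.py` (overlapping
peptide subtraction and difference maps), `examples/structure_heatmap.py`
(PDB B-factor export).

A thin CLI wraps the same library calls:

```
asymx all --seed 1 --out-dir out/        # full synthetic scenario
asymx simulate-flux / fit-flux / energetics / simulate-hdx / analyze-hdx / heatmap
```

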
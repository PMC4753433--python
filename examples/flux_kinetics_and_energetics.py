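"""Simulate the mutant flux panel, fit it, and derive the energy ledger.

Builds the default synthetic mutant panel (WT plus ion-pocket and
helix-breaking mutants), fits Michaelis-Menten constants on both membrane
sides, and prints K_int, kcat/Km, the asymmetry-index pairs, and the
transition-state free energies relative to WT.
"""

from asymx.pipeline import (energy_table, fit_flux_tables, fit_naca_vmax,
                            pair_table)
from asymx.synthetic import generate_flux_dataset

flux, truth = generate_flux_dataset(seed=1)
records = fit_flux_tables(flux)

print("construct kinetics (Ca2+/Ca2+ exchange):")
for name, rec in records.items():
    print(f"  {name:>6}: K''m = {rec.Km_ext:7.1f} uM   kcat = {rec.kcat:6.3f} 1/s"
          f"   kcat/Km = {rec.efficiency:.2e}   K_int = {rec.K_int:.3f}")
# K_int ~0.15 for WT means cytosolic->extracellular Ca2+ movement is ~6-7x
# faster than the reverse; the N73A-like construct flips it to ~2.8
# (inward-facing stabilization) at unchanged kcat/Km.

print("\nasymmetry indices (ratio of fitted V''max in a residue pair):")
print(pair_table(records, fit_naca_vmax(flux)).round(2).to_string(index=False))

print("\nfree-energy ledger (kcal/mol, 308.15 K, 1 uM standard state):")
print(energy_table(records).round(3).to_string(index=False))
# ddG_app > 1.5 kcal/mol marks residues whose side chains stabilize the
# Ca2+ transition state; 'conformational' rows shift K_int instead.
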
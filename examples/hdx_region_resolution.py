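"""Resolve sub-peptide HDX with overlapping peptic peptides.

Simulates isotope spectra for the fixture peptide set in the apo, Na+- and
Ca2+-bound states, computes deuterium uptake from centroid shifts, and
subtracts the overlapping peptides 47-59 / 53-59 to localize exchange to
region 48-52 (and 215-237 / 215-230 to region 231-237).
"""

from asymx.io import RunConfig
from asymx.pipeline import analyze_hdx
from asymx.synthetic import HDXScenario, generate_hdx_dataset

spectra, truth = generate_hdx_dataset(HDXScenario(), seed=1)
tables = analyze_hdx(spectra, truth["sequence"], truth["peptides"],
                     RunConfig(seed=1))

regions = tables["regions"]
print("resolved region uptake at 1200 s:")
cols = ["start", "end", "state", "n_amides", "uptake_D", "percent_D"]
print(regions[regions.time_s == 1200][cols].round(2).to_string(index=False))
# Region 48-52 (5 amides, the rigid alpha1-repeat core) takes up ~26 %D in
# the apo state and essentially none once Na+ or Ca2+ is bound - ion binding
# rigidifies the ion-coordinating backbone.  Region 231-237 stays dynamic.

diff = tables["diffmap"]
apo_na = diff[diff.comparison == "apo-Na"]
print("\napo - Na+ difference map at 1200 s (positive = apo exchanges more):")
print(apo_na[["peptide_id", "delta_percent_D"]].round(1).to_string(index=False))
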
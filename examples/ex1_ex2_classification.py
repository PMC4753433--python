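"""Deconvolve bimodal isotope envelopes and classify exchange regimes.

Simulates one peptide under cooperative (EX1) opening, fits 1- vs
2-component envelope models at each exposure, and prints the recovered
open-population weights against the generating 1-exp(-k_op t) law.
"""

import numpy as np

from asymx import envelopes as E

natural = E.natural_envelope(E.averagine_composition(1400.0))
n_amides = 12
k_op = 1.5e-3  # cooperative opening rate, 1/s
times = [15.0, 120.0, 1200.0]

spec = E.RegimeSpec("EX1", k_op=k_op)
series = E.simulate_time_series(natural, n_amides, spec, times,
                                noise_cv=0.03, seed=1)

models = [E.fit_envelope_mixture(s, natural, n_amides) for s in series]
print("exposure   components  heavy weight  (true)   centroids (Da uptake)")
for t, m in zip(times, models):
    w = m.weights[-1] if m.n_components == 2 else float("nan")
    true_w = 1.0 - np.exp(-k_op * t)
    cents = ", ".join(f"{c:.2f}" for c in m.centroids)
    print(f"{t:7.0f} s        {m.n_components}        {w:6.3f}   ({true_w:.3f})   {cents}")
# Under EX1 the two component centroids stay fixed while intensity moves
# from the light (closed) to the heavy (open, fully exchanged) envelope.

call = E.classify_regime(models)
print(f"\nregime call: {call.regime} (confident={call.confident})")
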
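"""Phase-bin a single simulated participant and fit the 10-Hz sinusoid.

Simulates one strongly entrained observer, bins detection by
pulse-to-target SOA into ten 10-ms bins, z-scores the profile, and fits
x(t) = alpha0 + alpha1 * sin(omega t + phi) with omega fixed at one cycle
per 100-ms pulse period.  With entrainment on, the fitted amplitude is
large and the fitted phase tracks the generating phase; the sham run of
the same observer fits only noise.
"""

import numpy as np

from pulsedetect.binning import detection_rates, standardize
from pulsedetect.observer import PopulationSpec, simulate_cohort
from pulsedetect.sinefit import fit_sine

pop = PopulationSpec(entrain_phase_random=False, fatigue_slope=0.0)
trials = simulate_cohort(2, population=pop, entrain_amp=1.5, seed=3)

for br in detection_rates(trials):
    if br.participant_id != "p00":
        continue
    z = standardize(br)
    fit = fit_sine(z.standardized, n_starts=50, seed=0)
    print(f"{br.condition:>5}: rates per bin "
          f"{np.array2string(br.rates, precision=2)}")
    print(f"       alpha1 = {fit.alpha1:.2f}, phi = {fit.phi:+.2f} rad, "
          f"adj R^2 = {fit.adj_r2:.2f}")

print("\notCS was generated with entrainment phase 0: its fit shows a "
      "large amplitude\nand a phase near 0, while the sham profile is "
      "flat up to binomial noise.")
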
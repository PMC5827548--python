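"""Calibration of the 3-miss-up / 1-hit-down staircase step ratio.

The consecutive-miss counter is a three-state Markov chain, so at miss
probability q the staircase takes an up-step on a fraction
q^3 / (1 + q + q^2) of trials and a down-step on a fraction p = 1 - q.
Balancing expected drift, p * step_down = step_up * q^3 / (1 + q + q^2),
at p = 0.5 gives step_up / step_down = 7 exactly.  This script verifies the
analytic equilibrium by simulation across a range of ratios.
"""

import numpy as np

from pulsedetect.staircase import (
    StaircaseState,
    equilibrium_hit_rate,
    run_staircase,
)


def observer(level, threshold=5.0, slope=1.0):
    return 1.0 / (1.0 + np.exp(-slope * (level - threshold)))


print(f"{'ratio':>6} {'predicted':>10} {'simulated':>10}")
for ratio in (3.0, 5.0, 7.0, 10.0):
    predicted = equilibrium_hit_rate(ratio)
    init = StaircaseState(level=8.0, step_down=0.05, step_up=0.05 * ratio,
                          ceiling=10.0)
    _, hits = run_staircase(observer, 20_000, init, seed=1)
    simulated = hits[5000:].mean()
    print(f"{ratio:>6.1f} {predicted:>10.3f} {simulated:>10.3f}")

print("\nratio 7 is the shipped default: its equilibrium hit rate is 0.5,")
print("which is why the procedure tracks the 50%-detection luminance.")
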
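"""Fit a melting temperature to a simulated CD thermal scan.

Simulates a two-state unfolding curve (Tm = 65 degC, width 2 degC, sloped
baselines, 1% noise) followed at 222 nm from 20-100 degC, then recovers the
midpoint with the two-state sigmoid fit.
"""

import hemequil as hq

curve = hq.simulate_melt_curve(tm_c=65.0, width_c=2.0,
                               baselines=(-22.0, 0.04, -3.0, 0.01),
                               noise_frac=0.01, seed=3)
fit = hq.fit_two_state_melt(curve)
print(f"Tm = {fit.tm_c:.2f} degC (truth 65.00), "
      f"width = {fit.transition_width:.2f} degC (truth 2.00)")
print(f"residual sum of squares = {fit.rss:.4f}")
# Tm is the temperature at which folded and unfolded states are equally
# populated; the width reflects the cooperativity of unfolding.
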
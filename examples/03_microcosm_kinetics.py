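"""Analyse a simulated gold-oxidation microcosm time series.

The default scenario emulates a fungal microcosm from auriferous soil
spiked with 40 uM metallic gold: a fast first oxidation phase, an Au(III)
peak, a slow second phase, and a terminal decline, with triplicate noise.
"""

from aurox import (
    MicrocosmScenario,
    correlate_au3_ph,
    fit_phase_rate,
    fit_standard_curve,
    gen_microcosm,
    gen_standard_curve,
    percent_oxidized,
)

curve_tbl = gen_standard_curve(noise_sd=0.005, seed=0)
curve = fit_standard_curve(curve_tbl["concentration_uM"], curve_tbl["absorbance"])
print(f"TMB calibration: A654 = {curve.slope:.4f} c + {curve.intercept:.4f}"
      f" (r2 = {curve.r2:.4f})")

result = gen_microcosm(MicrocosmScenario(seed=0))
series = result.series
print(f"\ncondition {series.condition}: Au(III) means (uM) at",
      series.times.astype(int).tolist())
print(" ", [f"{v:.2f}" for v in series.au3])

for window in ((0, 45), (191, 453)):
    fit = fit_phase_rate(series, window)
    print(f"phase {window} h: rate = {fit.rate:.3f} uM/h (r2 {fit.r2:.3f})")

r, p = correlate_au3_ph(series, (45, 191))
print(f"Au(III) vs pH over 45-191 h: Pearson r = {r:.4f}, p = {p:.3f}")

t_max, pct = percent_oxidized(series)
print(f"peak Au(III) at {t_max:.0f} h = {pct:.1f}% of the spiked gold")

print(
    "\nReading: the first linear phase is an order of magnitude faster than"
    "\nthe second, the Au(III) peak converts about a third of the metallic"
    "\ngold spike, and Au(III) tracks pH during the rate-change period."
)
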
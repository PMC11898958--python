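"""Chromatographic index transforms.

Fits a retention-time -> CHI calibration line from reference standards
and converts between the %HSA and LogK_HSA plasma-protein-binding
scales with the logistic transform log10(x / (101 - x)).
"""

import bioqsrr as b

# calibration standards: (name, gradient retention time [min], reference CHI)
standards = [
    ("standard-A", 1.10, 17.0),
    ("standard-B", 2.45, 35.5),
    ("standard-C", 3.60, 52.0),
    ("standard-D", 4.95, 71.5),
    ("standard-E", 6.20, 89.0),
]
names, times, refs = zip(*standards)
curve = b.fit_calibration(times, refs, standard_names=list(names))
print(f"calibration: CHI = {curve.slope:.3f} * t_r + {curve.intercept:.3f}"
      f"  (r2 = {curve.r2_fit:.4f})")

t_unknown = 4.20
chi = b.index_from_retention(t_unknown, curve)
print(f"compound at t_r = {t_unknown} min -> CHI = {chi:.2f}")
# the slope converts minutes of gradient retention into index units

for pct in (92.07, 43.86, 28.35):
    logk = b.logk_from_percent_hsa(pct)
    print(f"%HSA = {pct:6.2f}  ->  LogK_HSA = {b.round_half_up(logk):5.2f}"
          f"  (back: {b.percent_hsa_from_logk(logk):.2f}%)")
# the transform and its inverse round-trip exactly
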
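"""Convert fetal biometry to ultrasound gestational age and estimate weight.

Builds the default abdominal-circumference chart, evaluates the median AC
at 26 weeks, inverts a measured AC back to GA-AC, and computes the
estimated fetal weight from a BPD/AC/FL triple.
"""

from faocohort import default_chart, estimate_fetal_weight, estimate_ga, expected_biometry

chart = default_chart("ac")

ga_days = 26 * 7.0
median_ac = expected_biometry(chart, ga_days)
print(f"median AC at 26 wk:            {median_ac:.1f} mm")

# A fetus whose AC reads like a 27-week median at an actual GA of 26 weeks
ac_measured = expected_biometry(chart, 27 * 7.0)
ga_ac = estimate_ga(chart, ac_measured)
print(f"measured AC {ac_measured:.1f} mm -> GA-AC {ga_ac / 7:.2f} wk "
      f"(overgrowth ratio vs GA-LMP: {ga_ac / ga_days:.3f})")

efw = estimate_fetal_weight(6.5, 21.5, 4.7)
print(f"EFW for BPD 6.5 / AC 21.5 / FL 4.7 cm: {efw.efw_g:.1f} g")
# GA-AC above the actual GA means the abdomen reads 'older' than the
# pregnancy is - the overgrowth signal the FAOR ratios quantify.
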
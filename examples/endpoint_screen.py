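"""Analyse a simulated dual-read endpoint antagonist screen.

Simulates a 384-well plate (forward + reverse reads, 5% CV) for three
compounds with known dose-response truth, then runs the full analysis:
dual-read averaging, percent-of-control, antagonist calling and 4PL IC50
fitting.
"""

from kininmine import dilution_series
from kininmine.screens import endpoint_report
from kininmine.synthetic import endpoint_long_table, generate_endpoint_plate

truth = {
    "full_antagonist": (5.0, 100.0, -5.0, -1.0),     # IC50 10 uM, floors near 5%
    "partial_antagonist": (40.0, 100.0, -4.8, -1.0),  # floors near 40%
    "inactive": (100.0, 100.0, -4.0, -1.0),
}
doses = dilution_series(start=1e-4, ratio=1.4, n=10)  # 100 uM down, 1:1.4

plate = generate_endpoint_plate(truth, doses, noise_cv=0.05, seed=42)
report = endpoint_report(endpoint_long_table(plate))

for compound, entry in report["compounds"].items():
    line = f"{compound}: call={entry['call']}"
    fit = entry.get("fit")
    if fit and fit["converged"]:
        line += (f", IC50 = {fit['ic50_molar'] * 1e6:.1f} uM "
                 f"(95% CI {fit['ci95_molar'][0] * 1e6:.1f}-{fit['ci95_molar'][1] * 1e6:.1f})")
    print(line)
print("\nThe IC50 is the fitted curve midpoint (not the 50%-of-control dose); "
      "calls use the 50%/20%-of-control thresholds on the dose curve.")
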
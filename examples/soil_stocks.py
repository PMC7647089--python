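"""Equivalent-soil-mass carbon stocks from layered soil profiles.

Generates a synthetic field campaign (5 land-use classes x 20 sites x 7
layers), computes per-site soil carbon stocks by the equivalent-mass
method (reference mass from the native-cover profiles), and prints the
class summaries, the percentage-difference table and pairwise t-tests.
"""

from wbcm.soil import compute_stocks, difference_table, pairwise_ttests, summarize_by_class
from wbcm.synth import SoilSynthSpec, gen_soil_profiles

# agricultural soils compacted by 10% to make the mass correction visible
profiles = gen_soil_profiles(
    SoilSynthSpec(seed=42, bd_inflation={"RAG": 1.1, "IRR": 1.1, "PAST": 1.1})
)
stocks = compute_stocks(profiles, method="equivalent_mass")

summaries = summarize_by_class(stocks)
print("Class summaries (Mg-C ha^-1; ci = t-based half width at alpha=0.05):")
print(summaries.round(1).to_string(index=False))

print("\nPercentage differences of agricultural classes vs native covers")
print("(0-30 cm relative to the agricultural mean, 0-100 cm to the native):")
print(difference_table(summaries).round(1).to_string(index=False))

print("\nPairwise Welch t-tests, 0-100 cm:")
print(pairwise_ttests(stocks, 100.0).round(3).to_string(index=False))

print(
    "\nNegative differences mean the agricultural class stores less soil"
    "\ncarbon than the native cover over the same mass of soil."
)
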
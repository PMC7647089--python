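"""Period statistics and significance tests for a reconstruction.

Runs the expected-mode reconstruction on a synthetic 1990-2018 series,
normalises regional totals to Mg-C ha^-1 over the full region, and
prints per-period means with pooled-variance t-tests between the first
and later periods (the study's four periods: 7, 7, 7 and 8 years).
"""

import pandas as pd

from wbcm.model import default_legend, default_mapping, run_reconstruction
from wbcm.params import CarbonParamTable
from wbcm.report import (aggregate, area_accounting, period_change_tests,
                         period_stats)
from wbcm.synth import gen_lulcc_series, table_trajectory

series = gen_lulcc_series(table_trajectory(grid_shape=(120, 120), seed=0))
table = CarbonParamTable.default()
mapping = default_mapping()
legend = default_legend()

states = run_reconstruction(series, table, mapping, mode="expected")
totals = pd.concat([aggregate(s, l, mapping) for s, l in zip(states, series)],
                   ignore_index=True)
areas = area_accounting(series, legend)
region_area = float(areas[areas.year == 1990]["area_mha"].sum())

periods = (("P1", 1990, 1996), ("P2", 1997, 2003),
           ("P3", 2004, 2010), ("P4", 2011, 2018))
print("Per-period annual means, Mg-C ha^-1 over the whole region:")
print(period_stats(totals, region_area, periods).round(2).to_string(index=False))

print("\nPeriod changes vs P1 (pooled-variance Student's t):")
out = pd.concat(
    [period_change_tests(totals, region_area, periods[0], p) for p in periods[1:]],
    ignore_index=True,
)
print(out.round(3).to_string(index=False))
print(
    "\nDegrees of freedom are n_a + n_b - 2 (12 for 7 vs 7 years, 13 for"
    "\n7 vs 8). Small percentage losses with large p-values mean the"
    "\nyear-to-year spread dwarfs the trend at this aggregation level."
)
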
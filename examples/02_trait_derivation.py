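"""Derive grain yield and flowering traits from raw plot measurements.

Grain yield converts plot field weight (kg of dehusked ears) to t/ha using
an 80% shelling fraction and standardisation to 12.5% grain moisture over
the 7.5 m2 two-row plot; the anthesis-silking interval (ASI) is silking
minus anthesis date and grows under drought stress.
"""

import io

from linetester import TrialLayout, derive_asi, derive_grain_yield, plant_density
from linetester.trial_data import load_plot_table

layout = TrialLayout()  # 2 rows x 5 m x 0.75 m, 0.25 m hills, 80% shelling
print(f"plot area: {layout.plot_area_m2} m2, "
      f"plant density: {plant_density(layout):,} plants/ha")

fw, moi = 5.0, 20.0
print(f"field weight {fw} kg at {moi}% moisture -> "
      f"{derive_grain_yield(fw, moi, layout):.4f} t/ha")
print(f"AD 67 d, SD 70 d -> ASI {derive_asi(67, 70):+.0f} d "
      "(positive: silking delayed, typical drought response)")

csv = io.StringIO(
    "env,regime,rep,block,entry,entry_kind,line,tester,field_weight,moisture,AD,SD\n"
    "DS1,drought,1,B01,S11_7:T5,testcross,S11_7,T5,2.1,13.0,64.98,NA\n"
    "DS1,drought,1,B01,WH505,check,,,3.9,12.4,68.4,71.99\n")
plots = load_plot_table(csv, layout)
print("\nloaded plot table (GY/ASI derived where raw inputs exist, "
      "missing silking stays missing):")
print(plots[["entry", "entry_kind", "GY", "AD", "SD", "ASI"]].to_string())
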
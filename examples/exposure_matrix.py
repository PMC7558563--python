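"""Duration limits for every packaged scenario × algorithm × vw-mode.

Reproduces the maximum-allowable-exposure-time table: 38 rows covering the
nine exposure conditions, each algorithm applicable to its clothing category,
with estimated and measured walking speed.  Water loss never reaches 5 % of
body mass within 70 min, so every limit is set by the 38 °C rectal criterion
(or the horizon).
"""

import pandas as pd

from phstrain import run_matrix

pd.set_option("display.width", 120)
matrix = run_matrix()
print(matrix[["scenario", "algorithm", "vw_mode", "dlim_tre", "dlim_loss95",
              "max_time"]].to_string(index=False))
print(f"\n{len(matrix)} cells; limited cells (max_time < 70):",
      int((matrix["max_time"] < 70).sum()))
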
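"""Community indicator scores and physical-unit conversion for a few plots.

Builds a three-plot relevé table by hand, scores it against a miniature
indicator table, converts the soil-humidity score to productive moisture
(mm in the 1 m soil layer) and classifies the moisture supply.
"""

import pandas as pd

from phytoind import ReleveSet, classify_moisture, regimes_table
from phytoind.indicators import IndicatorTable

# species indicator values: soil humidity Hd (1..23), acidity Rc (1..15),
# hemeroby grade (1..7)
indicator_rows = pd.DataFrame(
    {
        "Hd": [19.0, 17.0, 8.0, 6.0, 12.0],
        "Rc": [8.0, 7.0, 9.0, 8.0, 7.0],
        "hemeroby_grade": [2, 3, 6, 6, 4],
    },
    index=[
        "Phragmites australis",
        "Salix alba",
        "Bromus tectorum",
        "Corispermum hyssopifolium",
        "Xanthium strumarium",
    ],
)
table = IndicatorTable(indicator_rows, ("Hd", "Rc"))

covers = pd.DataFrame(
    {
        "Phragmites australis": [70.0, None, None],
        "Salix alba": [20.0, 15.0, None],
        "Xanthium strumarium": [5.0, 30.0, 10.0],
        "Bromus tectorum": [None, 10.0, 45.0],
        "Corispermum hyssopifolium": [None, None, 20.0],
    },
    index=["wet_shore", "mid_bank", "dry_sand"],
)
rs = ReleveSet(covers)

out = regimes_table(rs, table)
print(out[["Hd", "W_mm", "Rc", "pH"]].round(2))
for plot in out.index:
    w = out.loc[plot, "W_mm"]
    print(f"{plot}: W = {w:.1f} mm -> moisture supply {classify_moisture(w)!r}")

# The wet shoreline plot scores high on the humidity scale, which the
# exponential conversion turns into a large productive-moisture stock; the
# dry sand plot lands in the lowest supply class.
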
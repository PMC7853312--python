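"""Built-in worked-example data.

The locality table below describes 11 American pika (*Ochotona princeps*)
sampling localities in the western United States — sample sizes, elevations
and coordinates spanning the Sierra Nevada, Great Basin (Ruby Mountains and
East Humboldt Range) and Northern/Southern Rocky Mountains.  It drives the
geographic worked examples (e.g. the two California localities lie ~38 km
apart; the six Nevada localities span ~70 km) and serves as a realistic
template for the synthetic generators.
"""

from __future__ import annotations

import io

import pandas as pd

_PIKA_LOCALITIES_CSV = """\
population,region,n_samples,elevation_m,latitude,longitude
Bodie,CA,15,2500,38.211861,-119.005037
Pipet Tarn,CA,20,3170,37.945285,-119.28413
West Knoll,CO,21,3612,40.056753,-105.59571
Emerald Lake,MT,21,2896,45.407061,-110.93998
Swan Creek,MT,7,1829,45.374392,-111.14408
Overland Lake,NV_RM,17,2281,40.458067,-115.45524
Island Lake,NV_RM,16,3245,40.616662,-115.37916
Hidden Lake,NV_RM,15,3051,40.746363,-115.2845
Week's Creek,NV_EH,10,2825,40.928332,-115.11273
Lizzie's Basin,NV_EH,10,2803,40.943973,-115.11243
Smith Lake,NV_EH,19,2882,41.034497,-115.094786
"""


def pika_localities() -> pd.DataFrame:
    """The 11-locality pika sampling table (171 individuals in total)."""
    return pd.read_csv(io.StringIO(_PIKA_LOCALITIES_CSV))


def pika_sample_table() -> pd.DataFrame:
    """Expand the locality table to one row per sampled individual."""
    loc = pika_localities()
    rows = []
    for _, r in loc.iterrows():
        tag = r["population"].replace("'", "").replace(" ", "_")
        for i in range(int(r["n_samples"])):
            rows.append(
                {
                    "sample_id": f"{tag}_{i:02d}",
                    "population": r["population"],
                    "latitude": r["latitude"],
                    "longitude": r["longitude"],
                    "elevation_m": r["elevation_m"],
                }
            )
    return pd.DataFrame(rows)
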
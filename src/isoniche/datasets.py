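"""Published reference tables of the seven-water-body survey.

Two small tables from the agricultural pond/ditch field survey the
package is built around, typed in as plain data so the aggregation
arithmetic can be recomputed and checked without any download:

* per-(site × FFG) analyzed-sample counts (see
  :data:`isoniche.synthetic_data.SURVEY_GROUP_SIZES`);
* the per-site water-quality snapshot (temperature, conductivity, pH,
  oxygen, nutrients, toxic-unit sums and pesticide detection counts).

These are inputs to summary arithmetic, not synthetic data; isotope
values themselves are never typed in (they live in an external
repository) and are emulated by :mod:`isoniche.synthetic_data`.
"""

from __future__ import annotations

import pandas as pd

from isoniche.synthetic_data import SURVEY_GROUP_SIZES

_CHEM_COLUMNS = (
    "site_id", "wb_type", "temp", "ec", "ph", "o2",
    "nh4", "no3", "po4", "tu_sum_algae", "tu_sum_invertebrate",
    "n_habitats", "n_detections",
)

_CHEM_ROWS = [
    ("Pond 1", "pond", 7.4, 1570, 6.2, 5.2, 0.01, 0.20, 0.25, -2.686, -5.221, 3, 3),
    ("Pond 2", "pond", 10.5, 1112, 6.5, 10.6, 0.09, 0.14, 0.05, -4.057, -5.074, 2, 1),
    ("Pond 3", "pond", 11.2, 881, 7.0, 13.8, 0.08, 0.23, 0.11, -2.650, -4.632, 3, 4),
    ("Ditch 1", "ditch", 9.7, 588, 7.0, 11.5, 0.86, 1.10, 0.44, -2.685, -5.428, 2, 4),
    ("Ditch 2", "ditch", 8.3, 815, 7.6, 6.1, 0.08, 0.72, 0.06, -3.253, -5.116, 1, 6),
    ("Ditch 3", "ditch", 11.0, 928, 7.0, 8.8, 0.08, 0.36, 0.06, -2.614, -4.817, 3, 7),
    ("Ditch 4", "ditch", 12.7, 900, 8.0, 8.8, 0.08, 1.32, 0.03, -3.456, -4.925, 2, 7),
]


def survey_chemistry() -> pd.DataFrame:
    """Per-site water-quality table of the survey.

    Includes a derived ``nutrient_sum`` column (NH₄⁺ + NO₃⁻, mg/L);
    NO₂⁻ is omitted because it was 0 at every site.
    """
    df = pd.DataFrame(_CHEM_ROWS, columns=_CHEM_COLUMNS)
    df["nutrient_sum"] = df["nh4"] + df["no3"]
    return df


def survey_counts() -> pd.DataFrame:
    """Per-(site × FFG) analyzed-sample counts of the survey, long form."""
    rows = [
        {"site_id": site, "ffg": ffg, "n": n}
        for site, sizes in SURVEY_GROUP_SIZES.items()
        for ffg, n in sizes.items()
    ]
    return pd.DataFrame(rows)
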
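"""Reference characteristics of the 15-pair longitudinal twin cohort.

The package's motivating study design: 10 MZ and 5 DZ twin pairs from a
peri/postnatal twin cohort, buccal DNA sampled at birth and 18 months and
hybridized to 450K arrays (15 pairs x 2 twins x 2 timepoints = 60 arrays).
The table below records, per pair, zygosity, chorionicity, sex, gestational
age (weeks), birth-weight discordance (percent, heavier-minus-lighter over
heavier) and the arrays removed by array-level QC.  These printed cohort
characteristics serve as worked-example inputs for the summary statistics
the pipeline computes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_ROWS = [
    # pair, zygosity, chorionicity, sex1, sex2, gest_age, weight_disc_pct, removed arrays
    ("1016", "MZ", "DC", "M", "M", 37, 5.4, ("T2_18",)),
    ("1022", "MZ", "MC", "M", "M", 38, 12.4, ("T1_18", "T2_18")),
    ("1024", "MZ", "DC", "F", "F", 37, 12.1, ("T2_B",)),
    ("1032", "DZ", "DC", "F", "F", 37, 43.3, ("T1_18",)),
    ("1035", "MZ", "MC", "F", "F", 35, 30.8, ()),
    ("1042", "DZ", "DC", "M", "M", 30, 19.8, ()),
    ("1046", "MZ", "DC", "M", "M", 37, 6.2, ()),
    ("1057", "DZ", "DC", "M", "M", 37, 13.3, ()),
    ("1058", "MZ", "DC", "M", "M", 36, 22.0, ()),
    ("1072", "DZ", "DC", "F", "F", 37, 14.5, ()),
    ("1107", "MZ", "MC", "F", "F", 33, 8.1, ("T1_18",)),
    ("1126", "MZ", "MC", "F", "F", 32, 27.3, ("T2_18",)),
    ("2034", "MZ", "DC", "F", "F", 36, 3.6, ()),
    ("3006", "DZ", "DC", "M", "M", 37, 3.6, ()),
    ("3014", "MZ", "MC", "M", "M", 36, 18.0, ()),
]


def twin_cohort_table() -> pd.DataFrame:
    """The reference cohort characteristics, one row per twin pair."""
    df = pd.DataFrame(_ROWS, columns=[
        "pair_id", "zygosity", "chorionicity", "sex_twin1", "sex_twin2",
        "gestational_age_weeks", "birth_weight_discordance_pct",
        "removed_after_qc"])
    return df.set_index("pair_id")


def median_birth_weight_discordance() -> float:
    """Median birth-weight discordance (percent) over the cohort pairs."""
    return float(np.median(
        twin_cohort_table()["birth_weight_discordance_pct"]))


def retained_array_count(timepoints: int = 2, twins_per_pair: int = 2) -> int:
    """Arrays surviving QC: full design minus the per-pair removal lists."""
    t = twin_cohort_table()
    total = len(t) * twins_per_pair * timepoints
    removed = int(t["removed_after_qc"].map(len).sum())
    return total - removed
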
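"""Packaged reference dataset: per-line mutation counts of the rice study.

The pipeline's design point is a published whole-genome-resequencing
comparison of seven gamma-ray-irradiated (250 Gy) and seven
carbon-ion-irradiated (30 Gy, LET 107 keV/um) rice mutant lines at the
M5 generation, sequenced as bulked M6 seedlings.  The per-line counts
of single base substitutions, small deletions/insertions (<100 bp) and
structural variants reported there are packaged here so the comparison
machinery can be exercised — and its summary statistics checked —
without any sequence data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "rice_study_counts",
    "CALLABLE_LENGTH_BP",
    "DOSES_GY",
    "OBSERVED_HOMOZYGOUS_FRACTION",
    "GAMMA",
    "CION",
]

GAMMA = "gamma"
CION = "C-ion"

#: Across-line average callable genome (bases at >= 5x coverage).
CALLABLE_LENGTH_BP = 351.4e6

#: Absorbed dose per group (Gy).
DOSES_GY = {GAMMA: 250.0, CION: 30.0}

#: Observed homozygous fraction among detected small mutations per group.
OBSERVED_HOMOZYGOUS_FRACTION = {GAMMA: 0.867, CION: 0.792}

_COUNTS = [
    # group, line, SBS, DEL, INS, SV
    (GAMMA, "HTM_G347", 60, 19, 7, 2),
    (GAMMA, "HTM_G348", 56, 18, 7, 0),
    (GAMMA, "HTM_G349", 57, 27, 5, 0),
    (GAMMA, "HTM_G351", 59, 10, 3, 2),
    (GAMMA, "HTM_G353", 52, 17, 7, 0),
    (GAMMA, "HTM_G354", 61, 17, 5, 0),
    (GAMMA, "HTM_G355", 54, 16, 7, 0),
    (CION, "HTM_I154", 44, 13, 4, 2),
    (CION, "HTM_I218", 45, 9, 10, 3),
    (CION, "HTM_I223", 58, 21, 1, 5),
    (CION, "HTM_I224", 36, 12, 3, 2),
    (CION, "HTM_I226", 40, 18, 9, 1),
    (CION, "HTM_I227", 47, 10, 6, 1),
    (CION, "HTM_I257", 36, 12, 4, 0),
]


def rice_study_counts(group: str | None = None) -> pd.DataFrame:
    """Per-line mutation counts of the 14 rice mutant lines.

    Returns a DataFrame indexed by line id with columns SBS, DEL, INS,
    SV, Total and group; pass ``group`` ('gamma' or 'C-ion') to select
    one radiation group, dropping the group column.
    """
    df = pd.DataFrame(
        _COUNTS, columns=["group", "line_id", "SBS", "DEL", "INS", "SV"]
    ).set_index("line_id")
    df["Total"] = df[["SBS", "DEL", "INS", "SV"]].sum(axis=1)
    if group is not None:
        if group not in (GAMMA, CION):
            raise KeyError(f"unknown group {group!r}")
        return df.loc[df["group"] == group].drop(columns="group")
    return df
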
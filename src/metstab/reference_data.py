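"""Published summary statistics used as regression fixtures.

Reference values from a published three-rainy-season evaluation of 30
drought-tolerant groundnut varieties at a semi-arid drought hot-spot
location (RCBD, two replicates; seasonal cumulative rainfall 504.1, 228.0
and 538.2 mm).  The raw plot data were not deposited, so these printed
summaries — the ANOVA tables and the per-variety stability rankings for pod
yield (g/m^2) and rain-water-use efficiency (RUE, g/m^2/mm) — are the only
quantities downstream code can be checked against.  Stability values (MASI)
and means are printed at 2 decimal places; ranks were computed by the
original authors from unrounded values, so printed-value ties can carry
distinct ranks.
"""

from __future__ import annotations

import pandas as pd

TRAITS = ("pod_yield", "rue")

RAINFALL_MM = {"2017": 504.1, "2018": 228.0, "2019": 538.2}

# source, df, SS, MS — per trait.  F-denominator conventions and %SS follow
# from these via metstab.ammi.
_ANOVA = {
    "pod_yield": [
        ("Environment", 2, 3_009_690.0, 1_504_845.0),
        ("Rep(Environment)", 3, 1_712.0, 571.0),
        ("Genotype", 29, 158_000.0, 5_448.0),
        ("GEI", 58, 471_146.0, 8_123.0),
        ("PC1", 30, 409_852.0, 13_662.0),
        ("PC2", 28, 61_294.0, 2_189.0),
        ("Residuals", 87, 40_359.0, 464.0),
    ],
    "rue": [
        ("Environment", 2, 94_802.0, 47_401.0),
        ("Rep(Environment)", 3, 68.0, 23.0),
        ("Genotype", 29, 7_827.0, 270.0),
        ("GEI", 58, 22_152.0, 382.0),
        ("PC1", 30, 16_332.0, 544.0),
        ("PC2", 28, 5_819.0, 209.0),
        ("Residuals", 87, 1_770.0, 20.0),
    ],
}

# genotype, MASI, rMASI, mean, rY, SSI for pod yield, then the same for RUE;
# table order (alphabetical by variety name).
_RANKING = [
    ("ABHAYA",             1.33,  7, 158.5, 25, 32,   0.41,  5, 32.00, 28, 33),
    ("AK 265",             8.46, 30, 137.1, 30, 60,   3.09, 30, 28.00, 30, 60),
    ("ANANTHA",            2.51, 19, 223.7,  4, 23,   1.17, 18, 45.28,  7, 25),
    ("CSMG 84-1",          3.67, 22, 221.9,  5, 27,   1.31, 20, 47.56,  5, 25),
    ("Dh 3-30",            5.21, 26, 149.5, 29, 55,   2.28, 28, 34.52, 25, 53),
    ("DHARANI",            1.14,  5, 155.9, 27, 32,   0.48,  6, 31.83, 29, 35),
    ("DRG 17",             1.87, 13, 180.4, 17, 30,   0.73, 11, 38.33, 15, 26),
    ("DSG 41",             3.06, 21, 185.1, 14, 35,   1.45, 22, 41.89, 10, 32),
    ("GG 2",               4.40, 25, 163.6, 24, 49,   1.73, 25, 35.41, 21, 46),
    ("Girnar 2",           2.04, 15, 182.1, 15, 30,   0.90, 14, 36.72, 17, 31),
    ("GPBD 5",             1.37,  9, 194.8, 12, 21,   1.41, 21, 48.70,  3, 24),
    ("ICGS 1",             1.81, 12, 204.9,  7, 19,   0.65, 10, 42.28,  9, 19),
    ("ICGS 44",            1.94, 14, 191.7, 13, 27,   0.81, 13, 39.37, 14, 27),
    ("ICGS 76",            3.03, 20, 171.2, 22, 42,   1.18, 19, 36.59, 18, 37),
    ("ICGV 86031",         6.03, 28, 265.4,  1, 29,   2.32, 29, 55.48,  1, 30),
    ("ICGV 86325",         1.24,  6, 202.7,  8, 14,   0.76, 12, 40.49, 13, 25),
    ("ICGV 91114",         1.35,  8, 200.0, 10, 18,   0.51,  7, 40.75, 12, 19),
    ("K 6",                4.11, 23, 198.0, 11, 34,   1.46, 23, 42.78,  8, 31),
    ("K 9",                1.43, 10, 168.7, 23, 33,   0.51,  9, 35.15, 24, 33),
    ("KADIRI 5",           0.91,  4, 211.0,  6, 10,   0.28,  4, 45.86,  6, 10),
    ("KADIRI HARITHANDRA", 2.46, 18, 156.6, 26, 44,   0.91, 16, 32.80, 26, 42),
    ("MUTANT 3",           0.64,  3, 171.6, 21, 24,   0.19,  1, 35.29, 23, 24),
    ("R 2001-2",           6.38, 29, 250.8,  2, 31,   2.24, 27, 54.65,  2, 29),
    ("R 2001-3",           5.53, 27, 235.5,  3, 30,   2.20, 26, 48.29,  4, 30),
    ("R 8808",             2.42, 17, 179.4, 18, 35,   0.90, 15, 37.68, 16, 31),
    ("SPANISH IMPROVED",   4.27, 24, 181.8, 16, 40,   1.48, 24, 36.21, 19, 43),
    ("TAG 24",             0.62,  2, 174.4, 19, 21,   0.21,  3, 35.42, 20, 23),
    ("TDG 39",             2.30, 16, 202.3,  9, 25,   0.98, 17, 41.39, 11, 28),
    ("TG 72",              0.47,  1, 154.7, 28, 29,   0.21,  2, 32.25, 27, 29),
    ("TMV 2",              1.54, 11, 173.9, 20, 31,   0.51,  8, 35.31, 22, 30),
]


def anova_summary(trait: str) -> pd.DataFrame:
    """Printed ANOVA table (df, ss, ms) for ``pod_yield`` or ``rue``."""
    if trait not in _ANOVA:
        raise KeyError(f"trait must be one of {TRAITS}, got {trait!r}")
    return pd.DataFrame(_ANOVA[trait], columns=["source", "df", "ss", "ms"]
                        ).set_index("source")


def ranking_table(trait: str) -> pd.DataFrame:
    """Printed stability ranking (MASI, rMASI, mean, rY, SSI) per variety."""
    if trait == "pod_yield":
        cols = slice(1, 6)
    elif trait == "rue":
        cols = slice(6, 11)
    else:
        raise KeyError(f"trait must be one of {TRAITS}, got {trait!r}")
    rows = [(r[0], *r[cols]) for r in _RANKING]
    return pd.DataFrame(rows, columns=["genotype", "masi", "r_masi", "mean",
                                       "r_mean", "ssi"])
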
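"""Bundled reference data: a curated cross-instrument compound table.

Eighteen tentatively identified volatile compounds detected in common
marmoset body odor by both a mobile GC-MS and a lab GC-MS fed by mixed-bed
thermal-desorption tubes.  Each row carries the compound name, its predicted
boiling point (°C at 760 mmHg, central value of the literature prediction),
retention time (min) and mean peak area on each instrument, the mean library
match factor (0-999) of the identification, and the literature-derived origin
class.

This table serves as the package's worked example: the paired retention
times demonstrate cross-instrument elution-order concordance (Spearman rho 1
after removing the single discordant compound), and the boiling-point and
origin columns exercise the classification rules.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cross_instrument_reference"]

_ROWS = [
    # name, bp_c, rt_mobile, area_mobile, match, rt_td, area_td, origin
    ("1-Propanol", 95.0, 1.00, 320_802_296, 937, 2.78, 86_417_340, "potentially_endogenous"),
    ("Cyclohexane, methyl-", 101.0, 2.06, 3_895_100, 715, 4.54, 31_159_370, "potentially_metabolized"),
    ("Toluene", 111.0, 2.29, 2_896_431, 838, 5.11, 2_264_769, "exogenous"),
    ("Heptane, 2-methyl-", 118.0, 2.35, 851_165, 575, 4.97, 111_756_372, "potentially_metabolized"),
    ("Hexanal", 128.0, 2.45, 5_600_184, 735, 5.38, 2_905_761, "potentially_endogenous"),
    ("Propanoic acid, propylester", 122.0, 2.57, 1_922_248, 745, 5.91, 272_145, "potentially_endogenous"),
    ("Ethylbenzene", 136.0, 3.54, 4_087_496, 839, 7.13, 342_180, "exogenous"),
    ("Pyrazine, 2,5-dimethyl-", 155.0, 4.38, 71_719_045, 854, 8.05, 75_802, "potentially_metabolized"),
    ("Nonane", 152.0, 4.49, 980_197, 606, 8.40, 275_808, "potentially_metabolized"),
    ("Benzene, (1-methylethyl)-", 152.0, 5.02, 1_043_167, 687, 8.69, 6_813, "exogenous"),
    ("Benzaldehyde", 179.0, 5.27, 62_440_110, 900, 9.16, 271_986, "potentially_metabolized"),
    ("5-Hepten-2-one, 6-methyl-", 173.0, 6.03, 5_492_894, 644, 10.03, 254_562, "potentially_metabolized"),
    ("D-Limonene", 175.0, 7.04, 44_230_737, 887, 11.50, 107_289, "potentially_metabolized"),
    ("Acetophenone", 202.0, 7.19, 11_704_738, 667, 12.18, 193_246, "exogenous"),
    ("Nonanal", 191.0, 8.00, 114_615_201, 823, 13.92, 9_186_924, "potentially_metabolized"),
    ("Undecane", 197.0, 8.15, 55_673_854, 742, 14.49, 18_506_217, "exogenous"),
    ("Decanal", 209.0, 9.17, 11_160_309, 790, 15.63, 5_270_498, "potentially_endogenous"),
    ("Dodecane", 216.0, 9.24, 8_432_826, 716, 15.99, 2_401_000, "potentially_endogenous"),
]


def cross_instrument_reference() -> pd.DataFrame:
    """The 18-compound mobile-vs-TD reference table as a tidy DataFrame.

    Columns: ``name``, ``boiling_point_c``, ``rt_mobile_min``,
    ``mean_area_mobile``, ``match_factor``, ``rt_td_min``, ``mean_area_td``,
    ``origin_class``.  Rows are ordered by elution on the mobile instrument.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "name",
            "boiling_point_c",
            "rt_mobile_min",
            "mean_area_mobile",
            "match_factor",
            "rt_td_min",
            "mean_area_td",
            "origin_class",
        ],
    )
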
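"""Published summary values from the five-year field comparison of DH518 and DH605.

The trial this package models compared the early-maturity summer maize hybrid
Denghai 518 with the mid-late hybrid Denghai 605 over 2017–2021 (three
replicate plots, 75,000 plants ha⁻¹).  Its raw plot data are not deposited;
what survives are the printed per-year summary tables.  They serve two roles
here: as reference inputs for cross-table arithmetic (percent ranges,
correlations, DLAI from the fitted Gaussian width), and to center the
synthetic generator's default ground truth on realistic magnitudes.

All frames are indexed by (year, hybrid).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HYBRIDS",
    "YEARS",
    "yield_components",
    "stage_durations",
    "remobilization",
    "dmrc_yield_per_gdd",
    "pn_linear_fits",
    "lai_gaussian_fits",
    "grain_leaf_hi",
]

HYBRIDS = ("DH518", "DH605")
YEARS = ("2017", "2018", "2019", "2020", "2021")


def _frame(rows: list[tuple], columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["year", "hybrid"] + columns)
    return df.set_index(["year", "hybrid"])


def yield_components() -> pd.DataFrame:
    """Grains per ear, 1000-grain weight (g), ears (10⁴ ha⁻¹), yield (kg ha⁻¹ at 14%)."""
    return _frame([
        ("2017", "DH518", 497, 355, 6.91, 12245),
        ("2017", "DH605", 487, 378, 6.94, 12796),
        ("2018", "DH518", 495, 349, 6.86, 11860),
        ("2018", "DH605", 514, 361, 6.86, 12720),
        ("2019", "DH518", 521, 359, 6.57, 12286),
        ("2019", "DH605", 570, 334, 6.67, 12701),
        ("2020", "DH518", 518, 346, 6.83, 12238),
        ("2020", "DH605", 520, 363, 6.89, 13009),
        ("2021", "DH518", 543, 299, 7.32, 11889),
        ("2021", "DH605", 561, 308, 7.39, 12754),
    ], ["grains_per_ear", "thousand_grain_g", "ears_1e4_ha", "yield_kg_ha"])


def stage_durations() -> pd.DataFrame:
    """Days and accumulated GDD (°C d) before/after silking, and season totals."""
    return _frame([
        ("2017", "DH518", 45, 806.9, 58, 933.3, 104, 1740.2),
        ("2017", "DH605", 51, 904.6, 62, 955.8, 114, 1860.4),
        ("2018", "DH518", 46, 826.5, 58, 952.5, 104, 1779.0),
        ("2018", "DH605", 52, 918.2, 60, 940.3, 111, 1858.4),
        ("2019", "DH518", 46, 846.1, 63, 860.3, 109, 1647.1),
        ("2019", "DH605", 51, 931.5, 65, 807.2, 116, 1719.9),
        ("2020", "DH518", 46, 708.3, 60, 923.7, 106, 1632.0),
        ("2020", "DH605", 51, 785.6, 62, 915.9, 113, 1701.5),
        ("2021", "DH518", 46, 794.8, 59, 864.9, 105, 1659.7),
        ("2021", "DH605", 52, 895.6, 61, 853.7, 113, 1749.3),
    ], ["days_before", "gdd_before", "days_after", "gdd_after", "days_total", "gdd_total"])


def remobilization() -> pd.DataFrame:
    """Stalk/leaf dry-matter remobilization (g) and remobilization efficiency (%)."""
    return _frame([
        ("2017", "DH518", 17.81, 25.49, 5.26, 15.38),
        ("2017", "DH605", 15.75, 19.99, 1.98, 5.62),
        ("2018", "DH518", 19.36, 27.20, 5.36, 14.21),
        ("2018", "DH605", 18.38, 21.98, 2.55, 6.22),
        ("2019", "DH518", 19.68, 24.65, 5.19, 14.07),
        ("2019", "DH605", 18.38, 22.03, 2.09, 5.38),
        ("2020", "DH518", 19.16, 26.51, 6.01, 16.13),
        ("2020", "DH605", 18.40, 21.40, 1.95, 4.88),
        ("2021", "DH518", 18.82, 27.34, 5.87, 15.82),
        ("2021", "DH605", 18.16, 21.45, 1.73, 4.65),
    ], ["dmr_stalk", "dmre_stalk", "dmr_leaf", "dmre_leaf"])


def dmrc_yield_per_gdd() -> pd.DataFrame:
    """¹³C-corrected DMR to grain (g), DMRC (%), yield per GDD (kg ha⁻¹ (°C d)⁻¹); four labeled years."""
    return _frame([
        ("2017", "DH518", 14.34, 9.50, 11.83),
        ("2017", "DH605", 10.53, 6.61, 12.49),
        ("2018", "DH518", 14.75, 9.99, 11.21),
        ("2018", "DH605", 13.29, 8.20, 12.42),
        ("2020", "DH518", 13.76, 9.04, 12.05),
        ("2020", "DH605", 10.32, 6.43, 13.29),
        ("2021", "DH518", 14.75, 9.87, 12.39),
        ("2021", "DH605", 11.03, 6.95, 13.90),
    ], ["dmr_to_grain", "dmrc", "yield_per_gdd"])


def pn_linear_fits() -> pd.DataFrame:
    """Ear-leaf Pn decline fits y = a − b·x, correlation r, initial Pn (Pi), APD (d)."""
    return _frame([
        ("2017", "DH518", 43.34, 0.58, 0.994, 46.07, 40.27),
        ("2017", "DH605", 45.04, 0.47, 0.989, 48.23, 50.67),
        ("2018", "DH518", 43.97, 0.52, 0.946, 46.33, 44.34),
        ("2018", "DH605", 45.40, 0.41, 0.958, 48.13, 57.02),
        ("2019", "DH518", 44.94, 0.54, 0.952, 47.83, 43.11),
        ("2019", "DH605", 45.93, 0.43, 0.973, 48.37, 55.76),
        ("2020", "DH518", 45.07, 0.55, 0.967, 48.57, 41.79),
        ("2020", "DH605", 46.04, 0.42, 0.966, 49.27, 55.57),
        ("2021", "DH518", 44.75, 0.51, 0.952, 47.63, 45.09),
        ("2021", "DH605", 46.19, 0.43, 0.983, 48.70, 55.84),
    ], ["a", "b", "r", "pi", "apd"])


def lai_gaussian_fits() -> pd.DataFrame:
    """Gaussian LAI fits: A = LAI max, B = its day after silking, C = width (d), R², DLAI (d)."""
    return _frame([
        ("2017", "DH518", 4.56, 5.41, 42.62, 0.996, 50.09),
        ("2017", "DH605", 5.07, 5.65, 48.34, 0.992, 56.95),
        ("2018", "DH518", 4.40, 7.96, 40.45, 0.995, 47.64),
        ("2018", "DH605", 5.15, 5.72, 48.03, 0.996, 56.48),
        ("2019", "DH518", 4.48, 6.28, 42.31, 0.999, 49.92),
        ("2019", "DH605", 4.91, 3.28, 52.39, 0.996, 61.72),
        ("2020", "DH518", 4.83, 5.75, 43.10, 0.997, 50.75),
        ("2020", "DH605", 5.39, 4.73, 50.88, 0.993, 59.87),
        ("2021", "DH518", 4.45, 7.66, 42.89, 0.997, 50.34),
        ("2021", "DH605", 5.12, 4.97, 48.60, 0.996, 57.23),
    ], ["A", "B", "C", "R2", "dlai"])


def grain_leaf_hi() -> pd.DataFrame:
    """Grain/leaf ratio (kg m⁻²) and harvest index (fraction)."""
    return _frame([
        ("2017", "DH518", 0.268, 0.582),
        ("2017", "DH605", 0.252, 0.559),
        ("2018", "DH518", 0.269, 0.567),
        ("2018", "DH605", 0.247, 0.544),
        ("2019", "DH518", 0.274, 0.576),
        ("2019", "DH605", 0.259, 0.554),
        ("2020", "DH518", 0.253, 0.572),
        ("2020", "DH605", 0.241, 0.537),
        ("2021", "DH518", 0.267, 0.578),
        ("2021", "DH605", 0.249, 0.544),
    ], ["grain_leaf", "hi"])
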
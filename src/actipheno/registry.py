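"""The versioned 96-feature registry manifest.

Families
--------
* circadian (6): M10, L5, RA, ADAT, IS, IV
* boundary (7): Savitzky-Golay ceiling/floor envelope summaries
* day thirds (3) + daily summaries (2)
* global (3): zero_ratio, frg_index, length_of_sleep_in_minutes
* wavelet (2): structure_pm, structure_pm_stdev
* grouped nocturnal peaks (48): {distance, width, height} x {min, max, avg,
  median} x {lower, upper} group under the median split and, with the
  ``_qrt`` suffix, under the quartile split (3 x 4 x 2 = 24 per split)
* all-peak statistics (12): the same 3 x 4 cross over every peak
* peak counts (5): lower/upper hump counts per split + total peak count
* "bigger" peaks, i.e. the upper median-split group (8): gap lengths between
  consecutive bigger peaks and their heights, 4 statistics each
"""

from __future__ import annotations

REGISTRY_VERSION = "96-v1"

STATS = ("min", "max", "avg", "median")
QUANTITIES = ("distance", "width", "height")

CIRCADIAN = ("M10", "L5", "RA", "ADAT", "IS", "IV")

BOUNDARY = (
    "floor_sum_values",
    "e_v_avg_value",
    "avg_ceiling_value",
    "avg_floor_value",
    "avg_ceiling_floor_diff",
    "std_avg",
    "std_upper",
)

THIRDS = ("1_thrd", "2_thrd", "3_thrd")
DAILY = ("daily_activity_mean", "daily_activity_stdev")
GLOBAL = ("zero_ratio", "frg_index", "length_of_sleep_in_minutes")
WAVELET = ("structure_pm", "structure_pm_stdev")


def _quantity_name(prefix: str, quantity: str, stat: str, suffix: str = "") -> str:
    # naming mirrors the published feature names:
    #   <group>_humps_<stat>_distance, <group>_humps_width_<stat>, ...
    if quantity == "distance":
        return f"{prefix}_{stat}_distance{suffix}"
    return f"{prefix}_{quantity}_{stat}{suffix}"


def grouped_peak_features(split: str) -> list[str]:
    """The 24 grouped-peak names for one split ('median' or 'quartile')."""
    if split not in ("median", "quartile"):
        raise ValueError("split must be 'median' or 'quartile'")
    suffix = "" if split == "median" else "_qrt"
    return [
        _quantity_name(f"{group}_humps", q, s, suffix)
        for group in ("lower", "upper")
        for q in QUANTITIES
        for s in STATS
    ]


def all_peak_features() -> list[str]:
    """The 12 statistics computed over every peak."""
    return [_quantity_name("humps", q, s) for q in QUANTITIES for s in STATS]


def peak_count_features() -> list[str]:
    return [
        "number_of_lower_humps",
        "number_of_upper_humps",
        "number_of_lower_humps_qrt",
        "number_of_upper_humps_qrt",
        "number_of_peaks",
    ]


def bigger_peak_features() -> list[str]:
    """Gap lengths between consecutive 'bigger' (upper median-split) peaks
    and the heights of those peaks."""
    return [f"{s}_length_between_bigger" for s in STATS] + \
           [f"{s}_bigger_values" for s in STATS]


def feature_names() -> list[str]:
    """The full ordered manifest (exactly 96 names)."""
    names: list[str] = []
    names += CIRCADIAN
    names += BOUNDARY
    names += THIRDS
    names += DAILY
    names += GLOBAL
    names += WAVELET
    names += grouped_peak_features("median")
    names += grouped_peak_features("quartile")
    names += all_peak_features()
    names += peak_count_features()
    names += bigger_peak_features()
    assert len(names) == len(set(names)), "registry contains duplicate names"
    return names
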
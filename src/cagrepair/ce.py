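"""Capillary-electrophoresis contraction quantification.

Input is the instrument software's peak table (size, height, area in
base-pair-scaled units).  Background is cut off by discarding every peak
whose height is below 5% of the sample's highest peak (boundary
inclusive: exactly 5% is kept); the shortened-product percentage is then
the area fraction of peaks smaller than the full-length product, with the
full-length peak matched by a +/- ``tol_bp`` sizing window.  Peaks larger
than full-length + tol are not counted as shortened but reported
separately as possible expansions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Peak", "filter_peaks", "percent_shortened", "ce_summary"]


@dataclass(frozen=True)
class Peak:
    size_bp: float
    height: float
    area_bp: float

    def __post_init__(self) -> None:
        if self.height < 0 or self.area_bp < 0:
            raise ValueError("height and area must be >= 0")


def _as_frame(peaks) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
    else:
        df = pd.DataFrame([vars(p) if isinstance(p, Peak) else p for p in peaks])
    required = {"size_bp", "height", "area_bp"}
    if df.empty or required - set(df.columns):
        raise ValueError("peak table needs columns size_bp, height, area_bp")
    return df


def filter_peaks(peaks, min_height_frac: float = 0.05) -> pd.DataFrame:
    """Drop background peaks below ``min_height_frac`` of the tallest
    peak's height (inclusive boundary: a peak at exactly the threshold is
    kept).  Raises on an empty table."""
    df = _as_frame(peaks)
    threshold = min_height_frac * df["height"].max()
    return df[df["height"] >= threshold].reset_index(drop=True)


def percent_shortened(
    peaks, full_length_bp: float = 242.0, tol_bp: float = 2.0
) -> float:
    """Percentage of product area in peaks shorter than full length.

    ``peaks`` should already be background-filtered.  Peaks within
    ``tol_bp`` of ``full_length_bp`` are full-length; larger peaks count
    as not-shortened (see :func:`ce_summary` for their share).
    """
    return ce_summary(peaks, full_length_bp, tol_bp)["percent_shortened"]


def ce_summary(
    peaks, full_length_bp: float = 242.0, tol_bp: float = 2.0
) -> dict[str, float]:
    """Area-fraction breakdown: shortened / full-length / longer."""
    df = _as_frame(peaks)
    total = float(df["area_bp"].sum())
    if total <= 0:
        raise ValueError("total peak area is zero")
    short = float(df.loc[df["size_bp"] < full_length_bp - tol_bp, "area_bp"].sum())
    full = float(
        df.loc[(df["size_bp"] - full_length_bp).abs() <= tol_bp, "area_bp"].sum()
    )
    longer = float(df.loc[df["size_bp"] > full_length_bp + tol_bp, "area_bp"].sum())
    return {
        "percent_shortened": 100.0 * short / total,
        "percent_full_length": 100.0 * full / total,
        "percent_longer": 100.0 * longer / total,
        "n_peaks": int(len(df)),
    }
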
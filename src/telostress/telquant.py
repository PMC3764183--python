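"""Telomere fragment sizing from lane densitometry profiles.

A telomeric Southern blot lane is reduced upstream to a one-dimensional
densitometry profile: signal intensity sampled along the migration axis.
Two marker bands of known size (2044 and 779 bp in the original assay)
anchor a log-linear size calibration — the standard gel-electrophoresis
approximation that log10(fragment size) is linear in migration distance.
The telomeric smear is detected as the contiguous region around the peak
above a fractional threshold, and its intensity-weighted centroid is
mapped through the calibration to a length in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LaneProfile",
    "SizeCalibration",
    "LengthEstimate",
    "calibrate",
    "subtract_background",
    "detect_smear",
    "estimate_length",
    "delta_length",
]


@dataclass(frozen=True)
class LaneProfile:
    """Densitometry of one gel lane.

    positions : strictly increasing migration coordinates (arbitrary units)
    intensities : non-negative signal at each position
    marker_positions : migration coordinates of the two size-marker bands
    marker_sizes : fragment sizes of the two markers, in bp
    """

    positions: np.ndarray
    intensities: np.ndarray
    marker_positions: tuple[float, float]
    marker_sizes: tuple[float, float]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.shape != pos.shape:
            raise ValueError("positions and intensities must be 1-D arrays of equal length")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.marker_positions) != 2 or len(self.marker_sizes) != 2:
            raise ValueError("exactly two marker bands are required")
        a, b = self.marker_sizes
        if a <= 0 or b <= 0 or a == b:
            raise ValueError("marker sizes must be positive and distinct")


@dataclass(frozen=True)
class SizeCalibration:
    """Log-linear migration model: log10(size in bp) = slope * position + intercept."""

    slope: float
    intercept: float

    def size_at(self, position):
        """Fragment size (bp) at a migration position."""
        return 10.0 ** (self.slope * np.asarray(position, dtype=float) + self.intercept)

    def position_of(self, size):
        """Migration position of a fragment of the given size (bp)."""
        return (np.log10(np.asarray(size, dtype=float)) - self.intercept) / self.slope


@dataclass(frozen=True)
class LengthEstimate:
    """A lane's telomere length call: smear centroid and bounds, in bp."""

    length: float
    smear_lo: float
    smear_hi: float
    background: float

    def __post_init__(self) -> None:
        if not (self.smear_lo <= self.length <= self.smear_hi):
            raise ValueError("smear_lo <= length <= smear_hi violated")


def calibrate(marker_positions, marker_sizes) -> SizeCalibration:
    """Fit the two-point log-linear size calibration.

    The line through (position, log10 size) of the two markers; exact at both
    anchors by construction and order-invariant in the inputs.
    """
    p1, p2 = (float(x) for x in marker_positions)
    s1, s2 = (float(x) for x in marker_sizes)
    if p1 == p2:
        raise ValueError("marker positions are coincident; calibration undefined")
    if s1 <= 0 or s2 <= 0 or s1 == s2:
        raise ValueError("marker sizes must be positive and distinct")
    slope = (np.log10(s2) - np.log10(s1)) / (p2 - p1)
    intercept = np.log10(s1) - slope * p1
    return SizeCalibration(slope=slope, intercept=intercept)


def subtract_background(profile: LaneProfile, quantile: float = 0.1) -> LaneProfile:
    """Subtract the given intensity quantile from the lane; clip negatives to zero."""
    if not (0.0 < quantile <= 0.5):
        raise ValueError("quantile must be in (0, 0.5]")
    bg = float(np.quantile(profile.intensities, quantile))
    cleaned = np.clip(profile.intensities - bg, 0.0, None)
    return replace(profile, intensities=cleaned)


def detect_smear(profile: LaneProfile, threshold_fraction: float = 0.2) -> tuple[float, float]:
    """Locate the smear: the maximal contiguous run around the global peak
    with intensity >= threshold_fraction * peak.

    Expects a background-subtracted profile. Returns (start, end) positions.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    inten = profile.intensities
    peak_idx = int(np.argmax(inten))
    peak = inten[peak_idx]
    if peak <= 0:
        raise ValueError("no signal: profile is all zero after background subtraction")
    cutoff = threshold_fraction * peak
    above = inten >= cutoff
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(inten) - 1 and above[hi + 1]:
        hi += 1
    return float(profile.positions[lo]), float(profile.positions[hi])


def estimate_length(
    profile: LaneProfile,
    calib: SizeCalibration | None = None,
    threshold_fraction: float = 0.2,
    background_quantile: float = 0.1,
) -> LengthEstimate:
    """Estimate telomere length for one lane.

    Background-subtracts, detects the smear, and reports the fragment size at
    the intensity-weighted centroid position of the smear. The smear interval
    ends map to `smear_hi`/`smear_lo` (greater migration = smaller fragment).
    If `calib` is None it is fit from the lane's own marker bands.
    """
    if calib is None:
        calib = calibrate(profile.marker_positions, profile.marker_sizes)
    bg = float(np.quantile(profile.intensities, background_quantile))
    cleaned = subtract_background(profile, background_quantile)
    start, end = detect_smear(cleaned, threshold_fraction)
    mask = (cleaned.positions >= start) & (cleaned.positions <= end)
    w = cleaned.intensities[mask]
    x = cleaned.positions[mask]
    centroid = float(np.sum(w * x) / np.sum(w))

    lo_pos, hi_pos = sorted(calib.position_of(s) for s in profile.marker_sizes)
    for name, p in (("smear start", start), ("smear end", end)):
        if p < lo_pos - 1e-9 or p > hi_pos + 1e-9:
            raise ValueError(
                f"{name} (position {p:.3g}) lies outside the marker-bracketed "
                f"range [{lo_pos:.3g}, {hi_pos:.3g}]; sizing would extrapolate"
            )

    sizes = sorted((float(calib.size_at(start)), float(calib.size_at(end))))
    return LengthEstimate(
        length=float(calib.size_at(centroid)),
        smear_lo=sizes[0],
        smear_hi=sizes[1],
        background=bg,
    )


def delta_length(stress: LengthEstimate, control: LengthEstimate) -> float:
    """Length change in bp: stress minus control (positive = elongation)."""
    return stress.length - control.length
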
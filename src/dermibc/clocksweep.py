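"""The clock-sweep melanoma radar: an angular brightness-irregularity cue.

The cue sweeps a clock arm from the lesion centroid to the peripheral
margin, starting at noon and going clockwise, and records the mean
brightness along the arm as a function of the angle.  The summary
statistic is the range of that angular profile (delta = max - min)
divided by its mean — a dimensionless measure of how unevenly pigment is
distributed around the lesion.  Three "clock hands" annotate the image:
the darkest angle (blue), the brightest angle (green) and the angle of
maximum brightness variation (red).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .segmentation import LesionMask, clock_direction

__all__ = [
    "AngularProfile",
    "ClockSweepResult",
    "OverlayAnnotation",
    "radial_profile",
    "sweep_statistic",
    "render_overlay",
    "risk_label",
    "statistic_label",
]

HAND_COLORS = {
    "darkest": (40, 90, 255),  # blue
    "brightest": (40, 200, 60),  # green
    "max_variation": (255, 40, 40),  # red
}


@dataclass(frozen=True)
class AngularProfile:
    """Mean arm brightness m(theta) on the clock-face angle grid."""

    angles: np.ndarray  # radians, clockwise from 12 o'clock
    values: np.ndarray  # mean intensity along the centre-to-margin arm

    def __post_init__(self):
        if len(self.angles) != len(self.values):
            raise ValueError("angles and values must have equal length")
        if len(self.angles) == 0:
            raise ValueError("profile is empty")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")


@dataclass(frozen=True)
class ClockSweepResult:
    """Summary of one clock sweep.

    ``statistic`` is delta/mean: the brightness range over the angular
    profile divided by the profile mean.  Angles are in radians, clockwise
    from 12 o'clock.
    """

    delta: float
    mean_brightness: float
    statistic: float
    darkest_angle: float
    brightest_angle: float
    max_variation_angle: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class OverlayAnnotation:
    """What gets printed on the rendered cue.

    ``risk_score`` is an externally supplied ensemble-classifier malignancy
    score in [0, 1] (0 = nevus, 1 = melanoma); it is displayed, never
    computed here.
    """

    risk_score: float | None = None

    def __post_init__(self):
        if self.risk_score is not None and not (0.0 <= self.risk_score <= 1.0):
            raise ValueError(f"risk_score must lie in [0, 1], got {self.risk_score}")


def risk_label(risk_score: float) -> str:
    return f"Risk = {risk_score:.2f}"


def statistic_label(statistic: float) -> str:
    return f"{statistic:.2f}"


def radial_profile(
    image: np.ndarray,
    mask: LesionMask,
    samples_per_arm: int | None = None,
) -> AngularProfile:
    """Mean brightness along the centre-to-margin arm at each clock angle.

    For each angle the arm runs from the centroid to the margin radius and
    is sampled at uniformly spaced points (endpoints included) with
    bilinear interpolation.  ``samples_per_arm`` defaults per arm to
    ``max(32, ceil(margin_radius))`` so sampling density tracks arm length.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.mask.shape:
        raise ValueError("image and mask shapes differ")
    if np.any(mask.margin_radius < 1.0):
        bad = float(mask.margin_radius.min())
        raise ValueError(f"margin radius below 1 px (min {bad:.3g}); arm undefined")

    cr, cc = mask.centroid
    drow, dcol = clock_direction(mask.angles)
    values = np.empty(mask.n_angles)
    for i in range(mask.n_angles):
        r = mask.margin_radius[i]
        n_s = samples_per_arm if samples_per_arm is not None else max(32, int(np.ceil(r)))
        t = np.linspace(0.0, r, n_s)
        coords = np.vstack([cr + t * drow[i], cc + t * dcol[i]])
        samples = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        values[i] = samples.mean()
    return AngularProfile(angles=mask.angles.copy(), values=values)


def _circular_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    kernel = np.ones(window) / window
    padded = np.concatenate([values[-(window // 2):], values, values[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")


def sweep_statistic(
    profile: AngularProfile,
    smoothing_window: int = 5,
    mean_intensity: float | None = None,
) -> ClockSweepResult:
    """Summarise an angular profile into the delta/mean cue.

    Parameters
    ----------
    profile
        Angular brightness profile on a uniform clock-angle grid.
    smoothing_window
        Odd window (in samples) of the circular moving average applied
        before the central difference that locates the max-variation hand;
        guards the red hand against pixel noise.  1 disables smoothing.
    mean_intensity
        Optional alternative denominator (e.g. the whole-lesion mean
        intensity).  By default the mean of the profile itself is used so
        the statistic is a profile-only quantity.

    Ties in argmin/argmax are broken toward the smallest angle (closest to
    noon, clockwise).
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError(f"smoothing_window must be odd and >= 1, got {smoothing_window}")
    m = profile.values
    if smoothing_window >= len(m):
        raise ValueError("smoothing_window must be smaller than the profile length")
    delta = float(m.max() - m.min())
    mean = float(np.mean(m)) if mean_intensity is None else float(mean_intensity)
    if mean == 0:
        raise ZeroDivisionError("mean brightness is zero; delta/mean undefined")
    smoothed = _circular_moving_average(m, smoothing_window)
    deriv = (np.roll(smoothed, -1) - np.roll(smoothed, 1)) / 2.0
    return ClockSweepResult(
        delta=delta,
        mean_brightness=mean,
        statistic=delta / mean,
        darkest_angle=float(profile.angles[int(np.argmin(m))]),
        brightest_angle=float(profile.angles[int(np.argmax(m))]),
        max_variation_angle=float(profile.angles[int(np.argmax(np.abs(deriv)))]),
    )


def _load_font(size: int):
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # older Pillow without size kwarg
        return ImageFont.load_default()


def render_overlay(
    image: np.ndarray,
    mask: LesionMask,
    result: ClockSweepResult,
    annotation: OverlayAnnotation | None = None,
    hand_width: int = 3,
) -> np.ndarray:
    """Draw the three clock hands and numeric labels onto the image.

    Blue hand at the darkest angle, green at the brightest, red at the
    angle of maximum brightness variation, each from centroid to margin.
    The delta/mean value is printed bottom-right (2 decimals); when a risk
    score is supplied, "Risk = x" is printed top-left.  Returns an RGB
    raster of the same height and width as the input.
    """
    annotation = annotation or OverlayAnnotation()
    img = np.asarray(image, dtype=float)
    base = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pil = Image.fromarray(base, mode="L").convert("RGB")
    draw = ImageDraw.Draw(pil)
    cr, cc = mask.centroid

    hands = {
        "darkest": result.darkest_angle,
        "brightest": result.brightest_angle,
        "max_variation": result.max_variation_angle,
    }
    for name, theta in hands.items():
        r = float(mask.margin_at(theta))
        drow, dcol = clock_direction(theta)
        end = (cc + r * float(dcol), cr + r * float(drow))  # (x, y)
        draw.line([(cc, cr), end], fill=HAND_COLORS[name], width=hand_width)

    h, w = base.shape
    font = _load_font(max(14, h // 30))
    text = statistic_label(result.statistic)
    bbox = draw.textbbox((0, 0), text, font=font)
    draw.text(
        (w - (bbox[2] - bbox[0]) - 8, h - (bbox[3] - bbox[1]) - 10),
        text,
        fill=(255, 255, 255),
        font=font,
    )
    if annotation.risk_score is not None:
        draw.text((8, 8), risk_label(annotation.risk_score), fill=(255, 255, 255), font=font)
    return np.asarray(pil)
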
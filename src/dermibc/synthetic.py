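"""Synthetic lesions and simulated readers with known ground truth.

Two generators make every downstream stage testable without any image
archive:

* :func:`generate_lesion_image` draws a roughly elliptical pigmented
  lesion (darker than the surrounding skin) whose margin is a harmonic
  perturbation of a circle and whose interior brightness is modulated
  around the clock face as ``L0 * (1 + A * sin(theta + phi))``.  Because
  the interior has no radial dependence, the along-arm mean equals the
  angular modulation analytically, so the clock-sweep statistic has the
  closed form delta/mean = 2A.

* :func:`simulate_reader_responses` draws paired binary melanoma/nevus
  decisions from the equal-variance Gaussian signal-detection model:
  evidence ~ N(0,1) for nevi and N(d', 1) for melanomas, response
  "melanoma" iff evidence exceeds the reader's criterion.  The two
  conditions (without / with the imaging-biomarker cue) share truth
  labels per image and differ only in d'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .readerstats import ResponseTable
from .segmentation import clock_angles

__all__ = [
    "LesionSpec",
    "LesionTruth",
    "ReaderSpec",
    "generate_lesion_image",
    "write_lesion",
    "simulate_reader_responses",
]


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic lesion image.

    The margin radius is ``r(theta) = base_radius * (1 + sum a_k *
    cos(k*theta + phase_k))`` over ``boundary_harmonics`` entries
    ``(k, a_k, phase_k)``; angles are clockwise from 12 o'clock.  Interior
    brightness is ``lesion_level * (1 + A * sin(theta + phi))`` with
    ``angular_modulation = (A, phi)``, plus optional Gaussian noise.
    Defaults emulate a mid-size dermoscopy crop: a mildly elliptical
    lesion (one k=2 harmonic) of ~150 px radius on lighter skin.
    """

    image_size: tuple[int, int] = (512, 512)  # (H, W)
    background_level: float = 200.0
    base_radius: float = 150.0
    boundary_harmonics: tuple[tuple[int, float, float], ...] = ((2, 0.1, 0.0),)
    lesion_level: float = 90.0
    angular_modulation: tuple[float, float] = (0.0, 0.0)  # (A, phi)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        amp, _ = self.angular_modulation
        if h < 64 or w < 64:
            raise ValueError("image must be at least 64x64")
        if not (0 <= self.lesion_level < self.background_level <= 255):
            raise ValueError(
                "need 0 <= lesion_level < background_level <= 255 "
                f"(got {self.lesion_level}, {self.background_level})"
            )
        if not (0 <= amp < 1):
            raise ValueError(f"modulation amplitude must be in [0, 1), got {amp}")
        if self.lesion_level * (1 + amp) >= self.background_level:
            raise ValueError(
                "darker-lesion convention violated: lesion_level*(1+A) must stay "
                f"below background_level ({self.lesion_level * (1 + amp):.4g} >= "
                f"{self.background_level:.4g})"
            )
        for k, a_k, _ in self.boundary_harmonics:
            if k < 1 or int(k) != k:
                raise ValueError(f"harmonic order must be a positive integer, got {k}")
            del a_k
        r = self.margin_radius(np.linspace(0, 2 * np.pi, 3600, endpoint=False))
        if np.any(r <= 0):
            raise ValueError("margin radius must stay positive at every angle")
        if r.max() >= min(h, w) / 2 - 2:
            raise ValueError(
                f"lesion exceeds image bounds: max radius {r.max():.1f} px vs "
                f"limit {min(h, w) / 2 - 2:.1f} px for a {h}x{w} image"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def margin_radius(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        r = np.ones_like(theta)
        for k, a_k, phase in self.boundary_harmonics:
            r = r + a_k * np.cos(k * theta + phase)
        return self.base_radius * r

    def interior_brightness(self, theta) -> np.ndarray:
        amp, phi = self.angular_modulation
        return self.lesion_level * (1 + amp * np.sin(np.asarray(theta, float) + phi))


@dataclass(frozen=True)
class LesionTruth:
    """Analytic ground truth written alongside each generated image."""

    center: tuple[float, float]  # (row, col)
    angles: np.ndarray
    margin_radius: np.ndarray
    profile: np.ndarray  # m(theta) = L0 * (1 + A sin(theta + phi))
    delta_over_mean: float  # = 2A
    brightest_angle: float
    darkest_angle: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angles"] = self.angles.tolist()
        d["margin_radius"] = self.margin_radius.tolist()
        d["profile"] = self.profile.tolist()
        return d


def generate_lesion_image(
    spec: LesionSpec, n_truth_angles: int = 360
) -> tuple[np.ndarray, LesionTruth]:
    """Render a synthetic lesion and its analytic clock-sweep ground truth.

    Returns a float64 grayscale image in [0, 255] (background at
    ``background_level`` outside the margin, modulated lesion brightness
    plus clipped Gaussian noise inside) and a :class:`LesionTruth` record.
    Bit-reproducible for a fixed ``spec.seed``.
    """
    h, w = spec.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    rho = np.hypot(rows, cols)
    # clock angle of each pixel: clockwise from image-up
    theta = np.mod(np.arctan2(cols, -rows), 2 * np.pi)

    inside = rho <= spec.margin_radius(theta)
    img = np.full((h, w), float(spec.background_level))
    img[inside] = spec.interior_brightness(theta[inside])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img[inside] += rng.normal(0.0, spec.noise_sd, size=int(inside.sum()))
    np.clip(img, 0, 255, out=img)

    amp, phi = spec.angular_modulation
    angles = clock_angles(n_truth_angles)
    truth = LesionTruth(
        center=center,
        angles=angles,
        margin_radius=spec.margin_radius(angles),
        profile=spec.interior_brightness(angles),
        delta_over_mean=2.0 * amp,
        brightest_angle=float(np.mod(np.pi / 2 - phi, 2 * np.pi)),
        darkest_angle=float(np.mod(3 * np.pi / 2 - phi, 2 * np.pi)),
    )
    return img, truth


def write_lesion(
    spec: LesionSpec, image_path: str | Path, truth_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write an 8-bit grayscale PNG plus a JSON ground-truth sidecar."""
    image_path = Path(image_path)
    truth_path = Path(truth_path) if truth_path else image_path.with_suffix(".json")
    img, truth = generate_lesion_image(spec)
    Image.fromarray(np.clip(np.rint(img), 0, 255).astype(np.uint8), mode="L").save(
        image_path
    )
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2))
    return image_path, truth_path


def _per_reader(values, n_readers: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        arr = np.full(n_readers, float(arr[0]))
    if arr.size != n_readers:
        raise ValueError(f"{name} must be scalar or length n_readers={n_readers}")
    return arr


@dataclass(frozen=True)
class ReaderSpec:
    """Parameters of a simulated paired reader study.

    ``dprime_without`` / ``dprime_with`` and ``criterion`` may be scalars
    (shared by all readers) or per-reader sequences.  Defaults mirror the
    reference study design: 10 readers, 38 melanomas and 40 nevi, mean
    discriminability 0.94 without and 1.41 with the cue, and a criterion
    of 0.3 (the operating point implied by the study's mean sensitivity
    and specificity at d' = 0.94).
    """

    n_readers: int = 10
    n_melanoma: int = 38
    n_nevus: int = 40
    dprime_without: float | tuple[float, ...] = 0.94
    dprime_with: float | tuple[float, ...] = 1.41
    criterion: float | tuple[float, ...] = 0.3
    seed: int = 0
    _dw: np.ndarray = field(init=False, repr=False, compare=False)
    _dwith: np.ndarray = field(init=False, repr=False, compare=False)
    _crit: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if min(self.n_readers, self.n_melanoma, self.n_nevus) < 1:
            raise ValueError("n_readers, n_melanoma and n_nevus must each be >= 1")
        object.__setattr__(
            self, "_dw", _per_reader(self.dprime_without, self.n_readers, "dprime_without")
        )
        object.__setattr__(
            self, "_dwith", _per_reader(self.dprime_with, self.n_readers, "dprime_with")
        )
        object.__setattr__(
            self, "_crit", _per_reader(self.criterion, self.n_readers, "criterion")
        )
        if np.any(self._dw < 0) or np.any(self._dwith < 0):
            raise ValueError("d' values must be non-negative")


def simulate_reader_responses(spec: ReaderSpec) -> ResponseTable:
    """Draw a paired response table from the equal-variance Gaussian model.

    For each reader and condition, evidence is N(0,1) for nevi and
    N(d',1) for melanomas; the decision is "melanoma" iff evidence exceeds
    that reader's criterion.  Evidence draws are independent between the
    two conditions; truth labels are shared.
    """
    rng = np.random.default_rng(spec.seed)
    n_img = spec.n_melanoma + spec.n_nevus
    is_mel = np.concatenate(
        [np.ones(spec.n_melanoma, bool), np.zeros(spec.n_nevus, bool)]
    )
    image_ids = [
        f"mel_{i + 1:05d}" if m else f"nev_{i + 1 - spec.n_melanoma:05d}"
        for i, m in enumerate(is_mel)
    ]
    frames = []
    labels = np.where(is_mel, "melanoma", "nevus")
    for r in range(spec.n_readers):
        rows = {"reader_id": f"reader_{r + 1:02d}", "image_id": image_ids, "truth": labels}
        for cond, dprime in (("without", spec._dw[r]), ("with", spec._dwith[r])):
            evidence = rng.standard_normal(n_img) + np.where(is_mel, dprime, 0.0)
            rows[f"decision_{cond}"] = np.where(
                evidence > spec._crit[r], "melanoma", "nevus"
            )
        frames.append(rows)
    df = pd.concat([pd.DataFrame(f) for f in frames], ignore_index=True)
    return ResponseTable(df)
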
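"""Line-based tumor-border analysis.

A line is drawn through the tumor, perpendicular to the pathology-designated
tumor edge. The line is widened to an 11-pixel-wide sub-image, collapsed back
to one pixel with a Gaussian-weighted mean across the width (noise
reduction), and every position on the collapsed profile is labelled tumor or
background from the pathology mask. Per-position TBR and aCNR profiles then
quantify the contrast drop across the border, and the position where the
aCNR profile falls through 1 — intensity falling below background mean plus
twice the background SD — is the metric's estimate of the tumor border. Its
absolute distance to the pathology border is the border-localization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .core import ModalityImage

__all__ = [
    "LineSpec",
    "LineProfile",
    "LineReport",
    "ProfileResult",
    "extract_subimage",
    "gaussian_collapse",
    "label_positions",
    "extract_line_profile",
    "profile_tbr",
    "profile_acnr",
    "acnr_auc",
    "find_acnr_crossing",
    "crossing_distance",
    "crossing_agreement",
    "analyze_line",
]

#: Width of the sub-image a line is widened to, in pixels.
DEFAULT_LINE_WIDTH = 11


@dataclass(frozen=True)
class LineSpec:
    """A widened line annotation in the reference (fixed) frame.

    ``start`` and ``end`` are (row, col) pixel coordinates; ``width`` is the
    odd number of perpendicular samples; ``pixel_pitch`` converts sample
    spacing to mm.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    width: int = DEFAULT_LINE_WIDTH
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("line start and end coincide")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"width must be odd and >= 1, got {self.width}")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def n_samples(self) -> int:
        """Samples at unit (1-pixel) steps from start towards end."""
        return int(np.floor(self.length_px)) + 1

    def sample_points(self) -> np.ndarray:
        """(n, 2) centerline sample coordinates at 1-pixel spacing."""
        d = self.direction()
        k = np.arange(self.n_samples)[:, None]
        return np.asarray(self.start, dtype=float) + k * d

    def direction(self) -> np.ndarray:
        d = np.asarray(self.end, dtype=float) - np.asarray(self.start, dtype=float)
        return d / np.linalg.norm(d)

    def perpendicular(self) -> np.ndarray:
        d = self.direction()
        return np.array([-d[1], d[0]])


@dataclass
class LineProfile:
    """Collapsed 1-D intensity profile with per-position tissue labels.

    ``positions`` are mm along the line, strictly increasing with spacing
    equal to the pixel pitch. ``labels`` is True for tumor positions, and the
    profile is oriented so a single tumor run precedes a single background
    run. ``border_position`` is the pathology border in mm along the line.
    """

    positions: np.ndarray
    intensity: np.ndarray
    labels: np.ndarray
    border_position: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.positions) == len(self.intensity) == len(self.labels)):
            raise ValueError("positions, intensity and labels must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        flips = np.flatnonzero(np.diff(self.labels.astype(int)))
        if len(flips) != 1 or not self.labels[0]:
            raise ValueError("labels must be a single tumor run followed by a background run")


class ProfileResult(NamedTuple):
    """Per-position metric values plus their mean over all line positions."""

    values: np.ndarray
    mean: float


@dataclass(frozen=True)
class LineReport:
    """Scalar line metrics for one modality."""

    mean_tbr: float
    mean_acnr: float
    auc_acnr: float
    crossing_position: float | None
    crossing_distance: float | None


def extract_subimage(image: ModalityImage, line: LineSpec) -> np.ndarray:
    """Widen a line into a (width x length) sub-image by bilinear sampling.

    Samples lie at unit steps along the line and at integer perpendicular
    offsets ``-(w-1)/2 ... +(w-1)/2``. Raises if any offset row leaves the
    image domain, listing the offending offsets.
    """
    centers = line.sample_points()  # (n, 2)
    half = (line.width - 1) // 2
    offsets = np.arange(-half, half + 1)
    perp = line.perpendicular()
    # coords[w, n, 2]
    coords = centers[None, :, :] + offsets[:, None, None] * perp[None, None, :]
    nrows, ncols = image.shape
    in_domain = (
        (coords[..., 0] >= 0)
        & (coords[..., 0] <= nrows - 1)
        & (coords[..., 1] >= 0)
        & (coords[..., 1] <= ncols - 1)
    )
    if not np.all(in_domain):
        bad = offsets[~in_domain.all(axis=1)]
        raise ValueError(
            f"widened line exits the image domain at perpendicular offsets {bad.tolist()}"
        )
    flat = coords.reshape(-1, 2).T  # (2, w*n)
    sampled = ndimage.map_coordinates(image.data, flat, order=1, mode="nearest")
    return sampled.reshape(line.width, len(centers))


def gaussian_collapse(subimage: np.ndarray, sigma_perp: float | None = None) -> np.ndarray:
    """Collapse a widened sub-image to one pixel with a Gaussian mean.

    Weights are a Gaussian over the perpendicular offsets, centered on the
    middle row and normalized to sum 1, so constant columns are preserved.
    ``sigma_perp`` defaults to width/6 (the +-3 sigma support then spans the
    full width); ``numpy.inf`` gives the unweighted row mean.
    """
    subimage = np.asarray(subimage, dtype=float)
    if subimage.ndim != 2:
        raise ValueError("subimage must be 2-D (width x length)")
    width = subimage.shape[0]
    if width % 2 == 0:
        raise ValueError("subimage width must be odd")
    if sigma_perp is None:
        sigma_perp = width / 6.0
    if sigma_perp <= 0:
        raise ValueError("sigma_perp must be positive")
    half = (width - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    if np.isinf(sigma_perp):
        weights = np.ones(width)
    else:
        weights = np.exp(-0.5 * (offsets / sigma_perp) ** 2)
    weights /= weights.sum()
    return weights @ subimage


def label_positions(line: LineSpec, tumor_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Tumor/background label per centerline position plus the border (mm).

    The mask is sampled with nearest-neighbor lookup at the centerline
    points. The line must cross the mask boundary exactly once (lines are
    drawn perpendicular to the tumor edge); the border position is the
    midpoint between the two samples bracketing the transition, in mm from
    the line start.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    pts = line.sample_points()
    rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, tumor_mask.shape[0] - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, tumor_mask.shape[1] - 1)
    labels = tumor_mask[rows, cols]
    flips = np.flatnonzero(np.diff(labels.astype(int)))
    if len(flips) != 1:
        raise ValueError(
            f"line must cross the tumor boundary exactly once, found {len(flips)} crossings"
        )
    border_position = (flips[0] + 0.5) * line.pixel_pitch
    return labels, float(border_position)


def extract_line_profile(
    image: ModalityImage,
    line: LineSpec,
    tumor_mask: np.ndarray,
    sigma_perp: float | None = None,
) -> LineProfile:
    """Full line extraction: widen, Gaussian-collapse, label, orient.

    If the line was annotated background-to-tumor, the profile is flipped so
    the tumor run comes first; positions are then measured from the flipped
    start and the border position is mirrored accordingly.
    """
    sub = extract_subimage(image, line)
    intensity = gaussian_collapse(sub, sigma_perp=sigma_perp)
    labels, border = label_positions(line, tumor_mask)
    n = len(intensity)
    pitch = line.pixel_pitch
    positions = np.arange(n) * pitch
    if not labels[0]:
        intensity = intensity[::-1]
        labels = labels[::-1]
        border = (n - 1) * pitch - border
    return LineProfile(
        positions=positions,
        intensity=intensity,
        labels=labels,
        border_position=border,
        pixel_pitch=pitch,
    )


def profile_tbr(profile: LineProfile) -> ProfileResult:
    """Per-position TBR: each intensity over the line's background MFI.

    The reported mean is taken over ALL positions of the line, tumor and
    background alike.
    """
    bg = profile.intensity[~profile.labels]
    if bg.size == 0:
        raise ValueError("line has no background positions")
    bg_mean = bg.mean()
    if bg_mean == 0:
        raise ValueError("background mean is zero: per-position TBR undefined")
    values = profile.intensity / bg_mean
    return ProfileResult(values=values, mean=float(values.mean()))


def profile_acnr(profile: LineProfile) -> ProfileResult:
    """Per-position aCNR: (intensity - bg mean) / (2 * bg SD) along the line.

    Background mean and population SD come from the line's own background
    positions; the mean is over ALL positions.
    """
    bg = profile.intensity[~profile.labels]
    if bg.size < 2:
        raise ValueError("at least 2 background positions are required")
    bg_sd = bg.std(ddof=0)
    if bg_sd == 0:
        raise ValueError("background SD is zero: per-position aCNR undefined")
    values = (profile.intensity - bg.mean()) / (2.0 * bg_sd)
    return ProfileResult(values=values, mean=float(values.mean()))


def acnr_auc(acnr_values: np.ndarray, labels: np.ndarray, pixel_pitch: float = 1.0) -> float:
    """Trapezoidal area under the aCNR profile over tumor positions.

    The abscissa is in pixel units (sample index), so a constant aCNR of c
    over k tumor positions integrates to c*(k-1). ``pixel_pitch`` is accepted
    for interface symmetry but does not enter the area.
    """
    acnr_values = np.asarray(acnr_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    idx = np.flatnonzero(labels)
    if idx.size < 2:
        raise ValueError("at least 2 tumor positions are required for an AUC")
    return float(np.trapezoid(acnr_values[idx], x=idx.astype(float)))


def find_acnr_crossing(
    acnr_values: np.ndarray,
    labels: np.ndarray,
    positions: np.ndarray,
) -> float | None:
    """Position (mm) of the aCNR = 1 down-crossing nearest the tumor border.

    Scanning from the tumor end toward the background end, the crossing is
    the LAST transition from aCNR > 1 to aCNR <= 1 at or before the first
    background run: transitions inside the tumor qualify, and if the
    above-threshold run straddles the border, the crossing is where that
    tumor-connected run ends, even if that is a few samples into the
    background. Isolated noise spikes deeper in the background never define
    the border. The position is linearly interpolated between the bracketing
    samples. Returns ``None`` when the profile never exceeds 1 or no such
    transition exists ("negative agreement" outcome).
    """
    acnr_values = np.asarray(acnr_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if not np.any(acnr_values > 1.0):
        return None
    bg_idx = np.flatnonzero(~labels)
    if bg_idx.size == 0:
        return None
    first_bg = bg_idx[0]
    # allow the tumor-connected above-1 run to carry past the border
    last = first_bg
    while last < len(acnr_values) - 1 and acnr_values[last] > 1.0:
        last += 1
    crossing = None
    for i in range(last):  # pair (i, i+1) completes at i+1 <= last
        if acnr_values[i] > 1.0 >= acnr_values[i + 1]:
            frac = (acnr_values[i] - 1.0) / (acnr_values[i] - acnr_values[i + 1])
            crossing = positions[i] + frac * (positions[i + 1] - positions[i])
    return None if crossing is None else float(crossing)


def crossing_distance(crossing_position: float | None, border_position: float) -> float | None:
    """Absolute distance (mm) between the aCNR = 1 crossing and the border."""
    if crossing_position is None:
        return None
    return abs(crossing_position - border_position)


def _found(report) -> bool:
    if report is None:
        return False
    if isinstance(report, LineReport):
        return report.crossing_position is not None
    if isinstance(report, (bool, np.bool_)):
        return bool(report)
    return report is not None


def crossing_agreement(
    line_reports: Sequence,
    reference_reports: Sequence,
) -> tuple[float | None, float | None]:
    """Positive / negative crossing agreement of a test modality vs a reference.

    Positive agreement: % of lines where the reference found an aCNR = 1
    crossing and the test modality did too. Negative agreement: % of
    reference-absent lines where the test modality also found none. Either is
    ``None`` when its denominator is zero (e.g. the reference found a
    crossing on every line, so negative agreement cannot be determined).

    Entries may be :class:`LineReport` objects, booleans, or ``None``.
    """
    if len(line_reports) != len(reference_reports):
        raise ValueError("paired report lists must have equal length")
    test = np.array([_found(r) for r in line_reports])
    ref = np.array([_found(r) for r in reference_reports])
    positive = None
    negative = None
    if ref.sum() > 0:
        positive = 100.0 * float(test[ref].mean())
    if (~ref).sum() > 0:
        negative = 100.0 * float((~test[~ref]).mean())
    return positive, negative


def analyze_line(
    image: ModalityImage,
    line: LineSpec,
    tumor_mask: np.ndarray,
    sigma_perp: float | None = None,
) -> LineReport:
    """All scalar line metrics for one modality image."""
    profile = extract_line_profile(image, line, tumor_mask, sigma_perp=sigma_perp)
    tbr_res = profile_tbr(profile)
    acnr_res = profile_acnr(profile)
    auc = acnr_auc(acnr_res.values, profile.labels, profile.pixel_pitch)
    crossing = find_acnr_crossing(acnr_res.values, profile.labels, profile.positions)
    return LineReport(
        mean_tbr=tbr_res.mean,
        mean_acnr=acnr_res.mean,
        auc_acnr=auc,
        crossing_position=crossing,
        crossing_distance=crossing_distance(crossing, profile.border_position),
    )
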
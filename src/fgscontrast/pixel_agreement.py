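"""Pixel-level agreement between two co-registered modality images.

After registration, each in-mask pixel yields a pair of normalized
intensities (one per modality). Agreement between the modalities is then
summarized by simple linear regression (r-squared), Bland-Altman bias and SD
of the paired differences, and — per modality — the percentage of tumor
pixels whose intensity does not exceed the maximum background intensity (the
tumor/background overlap, a rank statistic of discriminating ability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ModalityImage, finite_values
from .slice_metrics import min_max_normalize

__all__ = [
    "PairedPixels",
    "BlandAltmanResult",
    "collect_paired_pixels",
    "linear_r2",
    "bland_altman",
    "tumor_bg_overlap",
]


@dataclass
class PairedPixels:
    """Paired normalized intensities with tumor/background labels.

    ``a_values[i]`` and ``b_values[i]`` are the two modalities' normalized
    intensities at the same pixel; ``labels[i]`` is True for tumor pixels.
    """

    a_values: np.ndarray
    b_values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.a_values) == len(self.b_values) == len(self.labels)):
            raise ValueError("a_values, b_values and labels must have equal length")
        if not (np.all(np.isfinite(self.a_values)) and np.all(np.isfinite(self.b_values))):
            raise ValueError("paired pixel values must be finite")

    def __len__(self) -> int:
        return len(self.a_values)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman agreement summary of paired differences.

    ``bias`` is the mean difference, ``sd`` the sample SD of differences, and
    the limits of agreement are ``bias +- 2*sd``. ``orientation`` records the
    difference direction (default ``"b-a"``, i.e. SWIR minus NIR).
    """

    bias: float
    sd: float
    orientation: str = "b-a"

    @property
    def limits_of_agreement(self) -> tuple[float, float]:
        return (self.bias - 2.0 * self.sd, self.bias + 2.0 * self.sd)


def collect_paired_pixels(
    image_a: ModalityImage,
    image_b_registered: ModalityImage,
    tumor_mask: np.ndarray,
    bg_mask: np.ndarray,
) -> PairedPixels:
    """Min-max-normalized paired values at every in-mask, in-frame pixel.

    The masks must be disjoint. Pixels that are sentinel (out-of-frame after
    registration) in either modality are dropped, so the pair count can be
    smaller than the mask count. Each modality is normalized over its own
    in-frame pixel range before pairing.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if image_a.shape != image_b_registered.shape:
        raise ValueError("images must be co-registered to the same shape")
    if np.any(tumor_mask & bg_mask):
        raise ValueError("tumor and background masks overlap")
    norm_a = min_max_normalize(image_a)
    norm_b = min_max_normalize(image_b_registered)
    valid = norm_a.finite_mask() & norm_b.finite_mask()
    keep_t = tumor_mask & valid
    keep_b = bg_mask & valid
    keep = keep_t | keep_b
    return PairedPixels(
        a_values=norm_a.data[keep],
        b_values=norm_b.data[keep],
        labels=tumor_mask[keep],
    )


def linear_r2(a_values: np.ndarray, b_values: np.ndarray) -> float:
    """Coefficient of determination of the OLS fit b ~ a."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a_values and b_values must be equal-length 1-D arrays")
    if len(a) < 3:
        raise ValueError("at least 3 pairs are required for a regression")
    if np.var(a) == 0:
        raise ValueError("a_values have zero variance: regression undefined")
    result = stats.linregress(a, b)
    return float(result.rvalue**2)


def bland_altman(
    a_values: np.ndarray,
    b_values: np.ndarray,
    orientation: str = "b-a",
) -> BlandAltmanResult:
    """Bland-Altman bias and SD of paired differences.

    ``orientation`` selects the difference direction: ``"b-a"`` (default) or
    ``"a-b"``. The SD uses the sample convention (ddof=1), as is standard for
    Bland-Altman limits of agreement; with a single pair the SD is 0.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a_values and b_values must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("at least 2 pairs are required")
    if orientation == "b-a":
        diff = b - a
    elif orientation == "a-b":
        diff = a - b
    else:
        raise ValueError(f"orientation must be 'b-a' or 'a-b', got {orientation!r}")
    return BlandAltmanResult(
        bias=float(diff.mean()),
        sd=float(diff.std(ddof=1)),
        orientation=orientation,
    )


def tumor_bg_overlap(pairs: PairedPixels, modality: str) -> float:
    """Percentage of tumor pixels at or below the maximum background intensity.

    0% means the tumor and background intensity distributions separate
    perfectly in that modality; 100% means every tumor pixel lies within the
    background range. The comparison is inclusive (<=) at the background
    maximum. Being a rank statistic, the result is invariant under any
    strictly increasing intensity transform.
    """
    if modality.upper() == "A":
        values = pairs.a_values
    elif modality.upper() == "B":
        values = pairs.b_values
    else:
        raise ValueError(f"modality must be 'A' or 'B', got {modality!r}")
    tumor = values[pairs.labels]
    bg = values[~pairs.labels]
    if tumor.size == 0 or bg.size == 0:
        raise ValueError("both tumor and background pixels are required")
    return 100.0 * float((tumor <= bg.max()).mean())
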
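"""Core containers shared by every stage of the pipeline.

Conventions used throughout the package:

* images are 2-D arrays indexed ``(row, col)``, 0-based, with pixel centers
  at integer coordinates;
* intensities are floating point in arbitrary units (a.u.);
* pixels that fall outside the camera frame after resampling are marked
  with NaN (the *sentinel*) and are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModalityImage", "finite_values"]


@dataclass
class ModalityImage:
    """A single 2-D fluorescence image with its physical pixel pitch.

    Parameters
    ----------
    data :
        2-D array of intensities. Converted to ``float64``; NaN entries mark
        out-of-frame (sentinel) pixels.
    pixel_pitch :
        Physical size of one pixel in mm/pixel. Must be positive.
    modality :
        Free-text tag, e.g. ``"NIR"`` or ``"SWIR"``.
    """

    data: np.ndarray
    pixel_pitch: float
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"image must be 2-D, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("image must be non-empty")
        if not np.isfinite(self.pixel_pitch) or self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def finite_mask(self) -> np.ndarray:
        """Boolean mask of in-frame (non-sentinel) pixels."""
        return np.isfinite(self.data)

    def with_data(self, data: np.ndarray) -> "ModalityImage":
        """A copy of this image carrying new pixel data, same metadata."""
        return ModalityImage(data=data, pixel_pitch=self.pixel_pitch, modality=self.modality)


def finite_values(image: ModalityImage, mask: np.ndarray | None = None) -> np.ndarray:
    """In-frame intensities of ``image``, optionally restricted to ``mask``.

    Sentinel (NaN) pixels are always dropped, so statistics computed from the
    returned vector are never biased by out-of-frame fill values.
    """
    data = image.data
    keep = np.isfinite(data)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {data.shape}")
        keep &= mask
    return data[keep]
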
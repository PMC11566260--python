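"""Control-point similarity registration between the two modality images.

The two cameras view the same tissue slice from slightly different geometry,
so one image (the *moving* image, SWIR-role by convention) must be mapped
onto the frame of the other (the *fixed*, NIR-role image) before any paired
statistic is meaningful. A handful of corresponding landmark points, picked
on both images, determine a similarity transform (isotropic scale + rotation
+ translation, no reflection) by closed-form least squares.

Coordinate convention: ``(row, col)``, 0-based, pixel centers at integer
coordinates; transforms map moving-frame coordinates to fixed-frame
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .core import ModalityImage

__all__ = [
    "SimilarityTransform",
    "ControlPointSet",
    "fit_similarity",
    "apply_transform",
    "warp_mask",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """Isotropic scale + rotation + translation in the (row, col) plane.

    Maps a moving-frame point ``q`` to the fixed frame as
    ``q' = scale * R(rotation) @ q + translation`` with
    ``R(t) = [[cos t, -sin t], [sin t, cos t]]``.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive (no reflection), got {self.scale}")
        if not np.all(np.isfinite([self.rotation, *self.translation])):
            raise ValueError("rotation and translation must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        tr, tc = self.translation
        return np.array(
            [
                [self.scale * c, -self.scale * s, tr],
                [self.scale * s, self.scale * c, tc],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` array of (row, col) points into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        tr, tc = self.translation
        # -(1/s) R(-theta) t
        new_t = (
            -inv_scale * (c * tr - s * tc),
            -inv_scale * (s * tr + c * tc),
        )
        return SimilarityTransform(scale=inv_scale, rotation=-self.rotation, translation=new_t)

    def compose(self, first: "SimilarityTransform") -> "SimilarityTransform":
        """The transform ``self after first``: ``x -> self(first(x))``."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        ftr, ftc = first.translation
        tr = self.scale * (c * ftr - s * ftc) + self.translation[0]
        tc = self.scale * (s * ftr + c * ftc) + self.translation[1]
        return SimilarityTransform(
            scale=self.scale * first.scale,
            rotation=self.rotation + first.rotation,
            translation=(tr, tc),
        )

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.scale - 1.0) <= tol
            and abs(self.rotation) <= tol
            and abs(self.translation[0]) <= tol
            and abs(self.translation[1]) <= tol
        )


@dataclass
class ControlPointSet:
    """Paired landmark coordinates: ``moving_points[i]`` corresponds to
    ``fixed_points[i]``. Both are (n, 2) arrays of (row, col) positions."""

    moving_points: np.ndarray
    fixed_points: np.ndarray

    def __post_init__(self) -> None:
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        if self.moving_points.shape != self.fixed_points.shape:
            raise ValueError("moving and fixed point lists must have equal shape")
        if self.moving_points.ndim != 2 or self.moving_points.shape[1] != 2:
            raise ValueError("points must be (n, 2) arrays of (row, col)")
        if len(self.moving_points) < 2:
            raise ValueError("at least 2 control-point pairs are required")
        if not (np.all(np.isfinite(self.moving_points)) and np.all(np.isfinite(self.fixed_points))):
            raise ValueError("control-point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.moving_points)


def fit_similarity(points: ControlPointSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping moving points onto fixed points.

    Closed-form (Umeyama) estimate of rotation, isotropic scale and
    translation minimizing the mean squared mapped-point error; the rotation
    determinant is constrained positive, so the fit never mirrors the image.

    Raises
    ------
    ValueError
        If fewer than 2 pairs are given or all moving points coincide
        (the scale is then indeterminate).
    """
    moving = points.moving_points
    fixed = points.fixed_points
    if np.allclose(moving, moving[0]):
        raise ValueError("all moving points coincide: scale is indeterminate")
    # scikit-image works in (x, y) = (col, row); swap in, convert back out.
    tf = sktransform.SimilarityTransform.from_estimate(moving[:, ::-1], fixed[:, ::-1])
    if not tf or not np.all(np.isfinite(tf.params)):
        raise ValueError("similarity fit failed: degenerate control-point configuration")
    return SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(-tf.rotation),
        translation=(float(tf.translation[1]), float(tf.translation[0])),
    )


def registration_residuals(points: ControlPointSet, T: SimilarityTransform) -> np.ndarray:
    """Euclidean residual per pair after mapping moving points through ``T``."""
    mapped = T.apply(points.moving_points)
    return np.linalg.norm(mapped - points.fixed_points, axis=1)


def apply_transform(
    image: ModalityImage,
    T: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
) -> ModalityImage:
    """Resample ``image`` (moving frame) into the fixed frame defined by ``T``.

    Every output pixel ``q`` is sampled from the moving image at
    ``T^{-1}(q)``. Out-of-domain samples are filled with NaN (the sentinel)
    so downstream statistics can skip them.
    """
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}, got {interpolation!r}")
    if output_shape is None:
        output_shape = image.shape
    # a fitted transform within 1e-9 px of identity is numerically identity;
    # resampling it would only NaN-fill border pixels for nothing
    if T.is_identity(tol=1e-9) and output_shape == image.shape:
        return image.with_data(image.data.copy())
    inv = T.inverse()
    rr, cc = np.meshgrid(
        np.arange(output_shape[0], dtype=float),
        np.arange(output_shape[1], dtype=float),
        indexing="ij",
    )
    src = inv.apply(np.column_stack([rr.ravel(), cc.ravel()]))
    coords = src.T.reshape(2, *output_shape)
    out = ndimage.map_coordinates(
        image.data, coords, order=orders[interpolation], mode="constant", cval=np.nan
    )
    return image.with_data(out)


def warp_mask(
    mask: np.ndarray,
    T: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Warp a binary mask into the fixed frame with nearest-neighbor sampling.

    Out-of-domain pixels become background (False). Area is preserved up to
    the |1 - scale^2| factor plus perimeter discretization error.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))) and not np.all(np.isin(uniq, (0, 255))):
            raise ValueError("mask must be binary")
        mask = mask > 0
    if output_shape is None:
        output_shape = mask.shape
    if T.is_identity(tol=1e-9) and output_shape == mask.shape:
        return mask.copy()
    inv = T.inverse()
    rr, cc = np.meshgrid(
        np.arange(output_shape[0], dtype=float),
        np.arange(output_shape[1], dtype=float),
        indexing="ij",
    )
    src = inv.apply(np.column_stack([rr.ravel(), cc.ravel()]))
    coords = src.T.reshape(2, *output_shape)
    out = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="constant", cval=0)
    return out.astype(bool)
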
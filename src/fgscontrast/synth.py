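"""Synthetic paired-modality scenes, tube/well phantoms and lamp spectra.

No public clinical dataset accompanies this problem, so every downstream
stage is exercised on synthetic images with known ground truth. The slice
generator emulates the salient features of paired ex-vivo tissue-slice
fluorescence images:

* an elliptical tumor region of elevated mean intensity over a uniform
  background (pathology mask = the ellipse, exactly);
* modality-specific Gaussian blur (stronger for the shorter-wavelength
  modality, emulating scattering) applied to the piecewise-constant scene;
* additive Gaussian sensor noise;
* for modality B only, an optional smooth additive autofluorescent
  background field (emulating the failure mode where tissue autofluorescence
  overwhelms an off-peak SWIR signal);
* a known similarity-transform misalignment applied as the LAST step of
  modality-B synthesis, so the true registration transform is exactly
  ``misalignment.inverse()`` — an exact oracle for registration tests.

Default intensities are scaled so the noiseless modality-A slice has a
tumor-to-background ratio of 1.43 and the noise level puts the whole-slice
aCNR near 0.6, the scale of the reported penile-carcinoma medians; modality B
defaults mirror the corresponding SWIR-role scale (TBR 1.25, aCNR 0.86).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .core import ModalityImage
from .phantom_tools import Spectrum, blackbody
from .register import SimilarityTransform, apply_transform

__all__ = [
    "SlicePhantomSpec",
    "TubePhantomSpec",
    "WellImage",
    "ellipse_mask",
    "generate_slice_pair",
    "generate_tube_image",
    "generate_well_series",
    "generate_lamp_spectrum",
    "control_points_for",
    "default_lines",
    "quantize_to_uint16",
    "write_slice_pair",
    "make_synthetic_study",
    "hnscc_like_spec",
]

#: Gaussian smoothing length (pixels) of the autofluorescent background field.
AUTOFLUOR_CORRELATION_PX = 15.0


def _default_misalignment() -> SimilarityTransform:
    return SimilarityTransform(scale=1.02, rotation=0.03, translation=(3.5, -2.5))


@dataclass
class SlicePhantomSpec:
    """Ground-truth parameters of one synthetic paired-modality scene.

    Intensities are arbitrary units; blur sigmas are in pixels; the tumor is
    an ellipse given by center (row, col), semi-axes (row, col) and a
    rotation angle (radians) in the (row, col) plane.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_pitch: float = 0.1
    tumor_center: tuple[float, float] = (128.0, 128.0)
    tumor_axes: tuple[float, float] = (65.0, 50.0)
    tumor_angle: float = 0.0
    tumor_mean_a: float = 1430.0
    bg_mean_a: float = 1000.0
    tumor_mean_b: float = 1250.0
    bg_mean_b: float = 1000.0
    noise_sd_a: float = 358.0
    noise_sd_b: float = 145.0
    blur_sigma_a: float = 2.0
    blur_sigma_b: float = 1.0
    autofluor_amplitude_b: float = 0.0
    misalignment: SimilarityTransform | None = field(default_factory=_default_misalignment)
    seed: int = 0

    def validate(self) -> None:
        means = (self.tumor_mean_a, self.bg_mean_a, self.tumor_mean_b, self.bg_mean_b)
        if any(m < 0 for m in means):
            raise ValueError("intensities must be non-negative")
        if self.noise_sd_a < 0 or self.noise_sd_b < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.blur_sigma_a < 0 or self.blur_sigma_b < 0:
            raise ValueError("blur sigmas must be non-negative")
        if self.autofluor_amplitude_b < 0:
            raise ValueError("autofluor amplitude must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if min(self.tumor_axes) <= 0:
            raise ValueError("tumor region has zero area (degenerate ellipse)")
        extent = max(self.tumor_axes)
        cr, cc = self.tumor_center
        nr, nc = self.image_shape
        if cr - extent < 0 or cr + extent > nr - 1 or cc - extent < 0 or cc + extent > nc - 1:
            raise ValueError("tumor region must lie fully inside the image")


@dataclass
class TubePhantomSpec:
    """Parameters of a synthetic dye-filled tube image.

    Defaults mirror a transparent tube of 0.6 mm inner / 1.2 mm outer
    diameter; ``depth_blur_sigma`` emulates scattering at imaging depth
    (monotone in depth).
    """

    tube_inner_diameter: float = 0.6
    tube_outer_diameter: float = 1.2
    depth_blur_sigma: float = 2.0
    peak_intensity: float = 1000.0
    noise_sd: float = 0.0
    pixel_pitch: float = 0.05
    image_shape: tuple[int, int] = (101, 201)
    seed: int = 0

    def validate(self) -> None:
        if self.tube_inner_diameter <= 0 or self.tube_outer_diameter <= 0:
            raise ValueError("tube diameters must be positive")
        if self.tube_inner_diameter >= self.tube_outer_diameter:
            raise ValueError("inner diameter must be smaller than outer diameter")
        if self.depth_blur_sigma < 0 or self.peak_intensity < 0 or self.noise_sd < 0:
            raise ValueError("blur, intensity and noise parameters must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass(frozen=True)
class WellImage:
    """One liquid-phantom well image with its well mask."""

    concentration: float
    image: ModalityImage
    mask: np.ndarray


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Boolean mask of an ellipse (pixel centers inside the analytic region)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_slice_pair(
    spec: SlicePhantomSpec,
) -> tuple[ModalityImage, ModalityImage, np.ndarray]:
    """Generate one paired-modality scene with its pathology tumor mask.

    Both modality scenes are built in modality A's frame; modality B is then
    resampled through ``spec.misalignment`` (A frame -> B frame), so the true
    B -> A registration transform is ``spec.misalignment.inverse()``. The
    returned mask marks the tumor in A's frame. Identical spec + seed gives
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec.image_shape, spec.tumor_center, spec.tumor_axes, spec.tumor_angle)
    if not mask.any():
        raise ValueError("tumor region rasterizes to zero pixels")

    def build(tumor_mean, bg_mean, blur_sigma, noise_sd):
        scene = np.full(spec.image_shape, bg_mean, dtype=float)
        scene[mask] = tumor_mean
        if blur_sigma > 0:
            scene = ndimage.gaussian_filter(scene, blur_sigma)
        if noise_sd > 0:
            scene = scene + rng.normal(0.0, noise_sd, spec.image_shape)
        return scene

    data_a = build(spec.tumor_mean_a, spec.bg_mean_a, spec.blur_sigma_a, spec.noise_sd_a)

    scene_b = np.full(spec.image_shape, spec.bg_mean_b, dtype=float)
    scene_b[mask] = spec.tumor_mean_b
    if spec.blur_sigma_b > 0:
        scene_b = ndimage.gaussian_filter(scene_b, spec.blur_sigma_b)
    if spec.autofluor_amplitude_b > 0:
        # smooth structured background: Gaussian-filtered white noise mapped
        # to [0, 2*amplitude] so it is non-negative with mean ~ amplitude
        rough = rng.standard_normal(spec.image_shape)
        smooth = ndimage.gaussian_filter(rough, AUTOFLUOR_CORRELATION_PX)
        lo, hi = smooth.min(), smooth.max()
        scene_b = scene_b + spec.autofluor_amplitude_b * 2.0 * (smooth - lo) / (hi - lo)
    if spec.noise_sd_b > 0:
        scene_b = scene_b + rng.normal(0.0, spec.noise_sd_b, spec.image_shape)

    image_b_a_frame = ModalityImage(scene_b, spec.pixel_pitch, modality="B")
    if spec.misalignment is None or spec.misalignment.is_identity():
        image_b = image_b_a_frame
    else:
        image_b = apply_transform(image_b_a_frame, spec.misalignment, interpolation="bilinear")

    image_a = ModalityImage(data_a, spec.pixel_pitch, modality="A")
    return image_a, image_b, mask


def hnscc_like_spec(seed: int = 0, autofluor_amplitude: float = 2500.0) -> SlicePhantomSpec:
    """A spec variant emulating strong modality-B background autofluorescence.

    The additive smooth background raises the modality-B background mean and
    SD until the tumor contrast drowns: whole-slice TBR drops toward 1 and
    aCNR toward 0, the off-peak SWIR failure mode seen in head-and-neck
    tissue.
    """
    return SlicePhantomSpec(seed=seed, autofluor_amplitude_b=autofluor_amplitude)


def _tube_coverage_profile(n_rows: int, radius_px: float) -> np.ndarray:
    """Fractional pixel coverage of the tube lumen, centered mid-image.

    Pixel r covers [r-0.5, r+0.5]; area sampling keeps the profile's FWHM
    exactly equal to the lumen diameter, independent of grid alignment.
    """
    r0 = (n_rows - 1) / 2.0
    rows = np.arange(n_rows, dtype=float)
    left = np.maximum(rows - 0.5, r0 - radius_px)
    right = np.minimum(rows + 0.5, r0 + radius_px)
    return np.clip(right - left, 0.0, 1.0)


def generate_tube_image(spec: TubePhantomSpec) -> ModalityImage:
    """A straight horizontal bright ridge with depth-dependent blur.

    The cross-section is the tube lumen indicator (area-sampled) convolved
    with a Gaussian of ``depth_blur_sigma`` pixels, scaled to
    ``peak_intensity``, plus optional Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.image_shape
    radius_px = spec.tube_inner_diameter / (2.0 * spec.pixel_pitch)
    profile = _tube_coverage_profile(n_rows, radius_px)
    if spec.depth_blur_sigma > 0:
        profile = ndimage.gaussian_filter1d(profile, spec.depth_blur_sigma)
    data = spec.peak_intensity * np.tile(profile[:, None], (1, n_cols))
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)
    return ModalityImage(data, spec.pixel_pitch, modality="tube")


def generate_well_series(
    concentrations: list[float],
    gain: float,
    floor_sd: float,
    seed: int = 0,
    background_mean: float = 100.0,
    well_shape: tuple[int, int] = (32, 32),
    well_radius: float = 10.0,
    pixel_pitch: float = 0.1,
) -> list[WellImage]:
    """A liquid-phantom dilution series plus a zero-concentration control.

    Each well image holds a central disk whose mean signal is
    ``background_mean + gain * concentration``; the noise SD is ``floor_sd``
    everywhere. The control well (concentration 0) is the first list entry.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list is empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    if floor_sd <= 0:
        raise ValueError("floor_sd must be positive")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(well_shape[0]), np.arange(well_shape[1]), indexing="ij")
    center = ((well_shape[0] - 1) / 2.0, (well_shape[1] - 1) / 2.0)
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= well_radius**2
    wells = []
    for conc in [0.0, *concentrations]:
        data = np.full(well_shape, background_mean, dtype=float)
        data[mask] += gain * conc
        data += rng.normal(0.0, floor_sd, well_shape)
        wells.append(
            WellImage(
                concentration=float(conc),
                image=ModalityImage(data, pixel_pitch, modality="well"),
                mask=mask.copy(),
            )
        )
    return wells


def generate_lamp_spectrum(
    true_temperature: float,
    response_curve: np.ndarray,
    wavelengths: np.ndarray,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Black-body lamp emission seen through a detector response curve.

    Returns ``blackbody(lambda, T) * response`` with optional multiplicative
    Gaussian noise of relative SD ``noise_rel``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    response_curve = np.asarray(response_curve, dtype=float)
    if response_curve.shape != wavelengths.shape:
        raise ValueError("response_curve must match the wavelength grid")
    if np.any(response_curve <= 0):
        raise ValueError("response_curve must be strictly positive")
    planck = blackbody(wavelengths, true_temperature)
    values = planck.values * response_curve
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(0.0, noise_rel, values.shape))
    return Spectrum(wavelengths=wavelengths, values=values)


def control_points_for(spec: SlicePhantomSpec, n: int = 6, seed: int | None = None) -> pd.DataFrame:
    """Exact landmark correspondences implied by the spec's misalignment.

    Fixed points are spread over modality A's frame; moving points are their
    images under the misalignment (i.e. their coordinates in modality B's
    frame) — what an annotator clicking the same features on both images
    would produce, without click noise.
    """
    nr, nc = spec.image_shape
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fixed = np.column_stack(
        [
            rng.uniform(0.15 * nr, 0.85 * nr, n),
            rng.uniform(0.15 * nc, 0.85 * nc, n),
        ]
    )
    T = spec.misalignment if spec.misalignment is not None else SimilarityTransform()
    moving = T.apply(fixed)
    return pd.DataFrame(
        {
            "moving_row": moving[:, 0],
            "moving_col": moving[:, 1],
            "fixed_row": fixed[:, 0],
            "fixed_col": fixed[:, 1],
        }
    )


def default_lines(
    spec: SlicePhantomSpec,
    n_lines: int = 4,
    extension_px: float = 25.0,
) -> pd.DataFrame:
    """Lines from the tumor center outward, perpendicular to the tumor edge.

    ``n_lines`` directions are spread evenly around the ellipse; each line
    starts at the tumor center and ends ``extension_px`` beyond the analytic
    boundary, so it crosses the border exactly once. Four lines per slice is
    the study convention mirrored by the defaults.
    """
    cr, cc = spec.tumor_center
    a1, a2 = spec.tumor_axes
    rows = []
    for k in range(n_lines):
        phi = 2.0 * np.pi * k / n_lines
        u = np.array([np.cos(phi), np.sin(phi)])  # (row, col) direction
        ca, sa = np.cos(spec.tumor_angle), np.sin(spec.tumor_angle)
        ur = u[0] * ca + u[1] * sa
        uc = -u[0] * sa + u[1] * ca
        radius = 1.0 / np.sqrt((ur / a1) ** 2 + (uc / a2) ** 2)
        end = np.array([cr, cc]) + (radius + extension_px) * u
        rows.append(
            {
                "line_id": k,
                "start_row": cr,
                "start_col": cc,
                "end_row": end[0],
                "end_col": end[1],
            }
        )
    return pd.DataFrame(rows)


def quantize_to_uint16(image: ModalityImage, max_value: float | None = None) -> np.ndarray:
    """Optional explicit quantization step for integer-TIFF export."""
    data = image.data
    finite = data[np.isfinite(data)]
    if finite.size == 0:
        raise ValueError("image has no in-frame pixels")
    top = float(finite.max()) if max_value is None else max_value
    if top <= 0:
        raise ValueError("image maximum must be positive to quantize")
    scaled = np.clip(np.nan_to_num(data, nan=0.0), 0.0, top) / top * 65535.0
    return np.rint(scaled).astype(np.uint16)


def write_slice_pair(
    outdir: str | Path,
    slice_id: str,
    image_a: ModalityImage,
    image_b: ModalityImage,
    mask: np.ndarray,
) -> dict[str, Path]:
    """Write a generated pair as single-channel TIFFs and an 8-bit PNG mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image_a": outdir / f"{slice_id}_A.tif",
        "image_b": outdir / f"{slice_id}_B.tif",
        "mask": outdir / f"{slice_id}_mask.png",
    }
    tifffile.imwrite(paths["image_a"], image_a.data.astype(np.float32))
    tifffile.imwrite(paths["image_b"], image_b.data.astype(np.float32))
    iio.imwrite(paths["mask"], (np.asarray(mask, bool) * 255).astype(np.uint8))
    return paths


def make_synthetic_study(
    outdir: str | Path,
    n_slices: int = 3,
    base_spec: SlicePhantomSpec | None = None,
    seed: int = 0,
    n_lines: int = 4,
    n_control_points: int = 6,
) -> Path:
    """Generate a complete synthetic study and its manifest CSV.

    Writes, per slice: both modality TIFFs, the tumor mask PNG, a
    control-point CSV and a line CSV; plus a single ``manifest.csv`` listing
    the files together with the ground-truth generator parameters. Returns
    the manifest path, ready for :func:`fgscontrast.report.run_study`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = base_spec if base_spec is not None else SlicePhantomSpec()
    manifest_rows = []
    for i in range(n_slices):
        spec = dataclasses.replace(base, seed=seed + i)
        slice_id = f"slice{i:03d}"
        image_a, image_b, mask = generate_slice_pair(spec)
        paths = write_slice_pair(outdir, slice_id, image_a, image_b, mask)
        cp_path = outdir / f"{slice_id}_control_points.csv"
        control_points_for(spec).to_csv(cp_path, index=False)
        lines_path = outdir / f"{slice_id}_lines.csv"
        default_lines(spec, n_lines=n_lines).to_csv(lines_path, index=False)
        mis = spec.misalignment if spec.misalignment is not None else SimilarityTransform()
        manifest_rows.append(
            {
                "slice_id": slice_id,
                "image_a": paths["image_a"].name,
                "image_b": paths["image_b"].name,
                "mask": paths["mask"].name,
                "control_points": cp_path.name,
                "lines": lines_path.name,
                "pixel_pitch": spec.pixel_pitch,
                # ground truth for closed-loop tests
                "gt_tumor_mean_a": spec.tumor_mean_a,
                "gt_bg_mean_a": spec.bg_mean_a,
                "gt_tumor_mean_b": spec.tumor_mean_b,
                "gt_bg_mean_b": spec.bg_mean_b,
                "gt_noise_sd_a": spec.noise_sd_a,
                "gt_noise_sd_b": spec.noise_sd_b,
                "gt_autofluor_amplitude_b": spec.autofluor_amplitude_b,
                "gt_misalign_scale": mis.scale,
                "gt_misalign_rotation": mis.rotation,
                "gt_misalign_trow": mis.translation[0],
                "gt_misalign_tcol": mis.translation[1],
                "gt_seed": spec.seed,
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return manifest_path
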
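"""Study-level orchestration: run every metric over a manifest of slices.

For each tissue slice the pipeline registers modality B onto modality A's
frame from the slice's control points, computes whole-slice TBR/aCNR for
both modalities, per-line TBR/aCNR/AUC and aCNR = 1 border metrics for every
annotated line, and pixel-level agreement statistics. Per-metric results are
aggregated into a comparison table of medians with interquartile ranges and
paired Wilcoxon signed-rank p-values.

Reporting is always nonparametric (median, IQR, Wilcoxon): fluorescence
contrast metrics are not normally distributed in practice, so no normality
pre-test is run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from . import __version__ as _pkg_version
from .core import ModalityImage
from .line_analysis import LineSpec, analyze_line, crossing_agreement
from .pixel_agreement import bland_altman, collect_paired_pixels, linear_r2, tumor_bg_overlap
from .register import ControlPointSet, apply_transform, fit_similarity
from .slice_metrics import slice_report

__all__ = [
    "StudyConfig",
    "StudyResult",
    "load_manifest",
    "run_study",
    "paired_wilcoxon",
    "median_iqr",
]


@dataclass
class StudyConfig:
    """Tunable analysis parameters, every one a documented design choice."""

    line_width: int = 11  # widened-line width in pixels
    sigma_perp: float | None = None  # Gaussian-collapse SD; None -> width/6
    interpolation: str = "bilinear"  # resampling of modality B
    ba_orientation: str = "b-a"  # Bland-Altman difference direction
    alpha: float = 0.05  # significance level, reported but never used to filter
    min_pairs: int = 5  # minimum non-zero-difference pairs for Wilcoxon

    @classmethod
    def from_toml(cls, path: str | Path) -> "StudyConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class StudyResult:
    """All study outputs: per-slice and per-line tables plus the comparison."""

    per_slice: pd.DataFrame
    per_line: pd.DataFrame
    comparison: pd.DataFrame
    agreement: dict
    skipped: list[tuple[str, str]]
    config: StudyConfig

    def write(self, outdir: str | Path) -> None:
        """Write per-line/per-slice/comparison CSVs, JSON and a log file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_slice.to_csv(outdir / "per_slice.csv", index=False)
        self.per_line.to_csv(outdir / "per_line.csv", index=False)
        self.comparison.to_csv(outdir / "comparison.csv", index=False)
        payload = {
            "comparison": self.comparison.replace({np.nan: None}).to_dict(orient="records"),
            "crossing_agreement": self.agreement,
        }
        (outdir / "comparison.json").write_text(json.dumps(payload, indent=2))
        log_lines = [
            f"fgscontrast {_pkg_version}",
            f"config: {self.config}",
            f"slices analyzed: {self.per_slice.shape[0]}",
            f"lines analyzed: {self.per_line.shape[0]}",
        ]
        log_lines += [f"skipped {sid}: {reason}" for sid, reason in self.skipped]
        (outdir / "study_log.txt").write_text("\n".join(log_lines) + "\n")


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a study manifest CSV; relative file paths resolve against it."""
    path = Path(path)
    manifest = pd.read_csv(path)
    required = {"slice_id", "image_a", "image_b", "mask", "control_points", "lines", "pixel_pitch"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    manifest.attrs["root"] = path.parent
    return manifest


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation, inclusive method)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def paired_wilcoxon(x, y, min_pairs: int = 5) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired observations.

    Pairs with a NaN on either side are dropped; zero differences are dropped
    per the Wilcoxon convention. The exact null distribution is used for
    n <= 25 remaining pairs, the normal approximation with continuity
    correction otherwise.

    Raises
    ------
    ValueError
        If fewer than ``min_pairs`` non-zero differences remain, or every
        difference is zero (p undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    diff = y - x
    nonzero = diff != 0
    if x.size > 0 and not nonzero.any():
        raise ValueError("all paired differences are zero: p-value undefined")
    x, y = x[nonzero], y[nonzero]
    n = x.size
    if n < min_pairs:
        raise ValueError(f"insufficient pairs after dropping zero differences: {n} < {min_pairs}")
    method = "exact" if n <= 25 else "approx"
    result = stats.wilcoxon(x, y, alternative="two-sided", method=method, correction=True)
    return float(result.pvalue)


def _load_image(root: Path, name: str, pixel_pitch: float, modality: str) -> ModalityImage:
    return ModalityImage(
        tifffile.imread(root / name).astype(np.float64), pixel_pitch, modality=modality
    )


def _load_mask(root: Path, name: str) -> np.ndarray:
    return np.asarray(iio.imread(root / name)) > 0


#: (label, table, column stem, run Wilcoxon) for every comparison-table row.
_METRIC_ROWS = [
    ("TBR whole tissue slice", "slice", "tbr", True),
    ("aCNR whole tissue slice", "slice", "acnr", True),
    ("Tumor fluorescence intensity (a.u.)", "slice", "mfi_tumor", False),
    ("Background fluorescence intensity (a.u.)", "slice", "mfi_bg", False),
    ("TBR over line", "line", "mean_tbr", True),
    ("aCNR over line", "line", "mean_acnr", True),
    ("AUC aCNR", "line", "auc_acnr", True),
    ("Absolute distance tumor border to aCNR=1 (mm)", "line", "crossing_distance", True),
    ("Overlap pixels tumor/background (%)", "slice", "overlap_pct", True),
]


def run_study(
    manifest: pd.DataFrame | str | Path,
    config: StudyConfig | None = None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Execute the full two-modality comparison over a manifest of slices.

    Per-slice failures are logged and the slice skipped with a recorded
    reason; a study in which every slice failed is an error. The computation
    is deterministic given the manifest and config. If ``outdir`` is given,
    all output tables are written there.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    root = Path(manifest.attrs.get("root", "."))
    config = config or StudyConfig()

    slice_rows: list[dict] = []
    line_rows: list[dict] = []
    skipped: list[tuple[str, str]] = []

    for _, entry in manifest.iterrows():
        slice_id = str(entry["slice_id"])
        try:
            pitch = float(entry["pixel_pitch"])
            image_a = _load_image(root, entry["image_a"], pitch, "A")
            image_b = _load_image(root, entry["image_b"], pitch, "B")
            tumor_mask = _load_mask(root, entry["mask"])
            cp = pd.read_csv(root / entry["control_points"])
            points = ControlPointSet(
                moving_points=cp[["moving_row", "moving_col"]].to_numpy(),
                fixed_points=cp[["fixed_row", "fixed_col"]].to_numpy(),
            )
            T = fit_similarity(points)
            image_b_reg = apply_transform(
                image_b, T, output_shape=image_a.shape, interpolation=config.interpolation
            )
            bg_mask = ~tumor_mask

            rep_a = slice_report(image_a, tumor_mask, bg_mask)
            rep_b = slice_report(image_b_reg, tumor_mask, bg_mask)
            pairs = collect_paired_pixels(image_a, image_b_reg, tumor_mask, bg_mask)
            ba = bland_altman(pairs.a_values, pairs.b_values, orientation=config.ba_orientation)
            slice_rows.append(
                {
                    "slice_id": slice_id,
                    "tbr_a": rep_a.tbr,
                    "tbr_b": rep_b.tbr,
                    "acnr_a": rep_a.acnr,
                    "acnr_b": rep_b.acnr,
                    "mfi_tumor_a": rep_a.tumor_stats.mfi,
                    "mfi_tumor_b": rep_b.tumor_stats.mfi,
                    "mfi_bg_a": rep_a.bg_stats.mfi,
                    "mfi_bg_b": rep_b.bg_stats.mfi,
                    "sd_bg_a": rep_a.bg_stats.sd,
                    "sd_bg_b": rep_b.bg_stats.sd,
                    "overlap_pct_a": tumor_bg_overlap(pairs, "A"),
                    "overlap_pct_b": tumor_bg_overlap(pairs, "B"),
                    "r2": linear_r2(pairs.a_values, pairs.b_values),
                    "ba_bias": ba.bias,
                    "ba_sd": ba.sd,
                    "registration_scale": T.scale,
                    "registration_rotation": T.rotation,
                }
            )

            lines = pd.read_csv(root / entry["lines"])
            for _, ln in lines.iterrows():
                line = LineSpec(
                    start=(float(ln["start_row"]), float(ln["start_col"])),
                    end=(float(ln["end_row"]), float(ln["end_col"])),
                    width=config.line_width,
                    pixel_pitch=pitch,
                )
                line_id = ln.get("line_id", len(line_rows))
                try:
                    la = analyze_line(image_a, line, tumor_mask, sigma_perp=config.sigma_perp)
                    lb = analyze_line(image_b_reg, line, tumor_mask, sigma_perp=config.sigma_perp)
                except ValueError as exc:
                    skipped.append((f"{slice_id}/line{line_id}", str(exc)))
                    continue
                line_rows.append(
                    {
                        "slice_id": slice_id,
                        "line_id": line_id,
                        "mean_tbr_a": la.mean_tbr,
                        "mean_tbr_b": lb.mean_tbr,
                        "mean_acnr_a": la.mean_acnr,
                        "mean_acnr_b": lb.mean_acnr,
                        "auc_acnr_a": la.auc_acnr,
                        "auc_acnr_b": lb.auc_acnr,
                        "crossing_position_a": la.crossing_position,
                        "crossing_position_b": lb.crossing_position,
                        "crossing_distance_a": la.crossing_distance,
                        "crossing_distance_b": lb.crossing_distance,
                    }
                )
        except (ValueError, OSError, KeyError) as exc:
            skipped.append((slice_id, str(exc)))
            continue

    if not slice_rows:
        raise RuntimeError(f"every slice failed; reasons: {skipped}")

    per_slice = pd.DataFrame(slice_rows)
    per_line = pd.DataFrame(line_rows)

    comparison_rows = []
    for label, table, stem, test in _METRIC_ROWS:
        df = per_slice if table == "slice" else per_line
        if df.empty or f"{stem}_a" not in df.columns:
            continue
        a = pd.to_numeric(df[f"{stem}_a"], errors="coerce").to_numpy(dtype=float)
        b = pd.to_numeric(df[f"{stem}_b"], errors="coerce").to_numpy(dtype=float)
        paired = np.isfinite(a) & np.isfinite(b)
        row = {"parameter": label, "n": int(paired.sum())}
        for tag, vals in (("a", a), ("b", b)):
            finite = vals[np.isfinite(vals)]
            if finite.size:
                med, q1, q3 = median_iqr(finite)
            else:
                med = q1 = q3 = np.nan
            row[f"median_{tag}"] = med
            row[f"q1_{tag}"] = q1
            row[f"q3_{tag}"] = q3
        p = np.nan
        if test and paired.sum() >= config.min_pairs:
            try:
                p = paired_wilcoxon(a[paired], b[paired], min_pairs=config.min_pairs)
            except ValueError:
                p = np.nan
        row["p_value"] = p
        comparison_rows.append(row)
    comparison = pd.DataFrame(comparison_rows)

    if per_line.empty:
        agreement = {"positive_pct": None, "negative_pct": None, "n_lines": 0}
    else:
        found_a = per_line["crossing_position_a"].notna().tolist()
        found_b = per_line["crossing_position_b"].notna().tolist()
        positive, negative = crossing_agreement(found_b, found_a)
        agreement = {
            "positive_pct": positive,
            "negative_pct": negative,
            "n_lines": int(len(per_line)),
        }

    result = StudyResult(
        per_slice=per_slice,
        per_line=per_line,
        comparison=comparison,
        agreement=agreement,
        skipped=skipped,
        config=config,
    )
    if outdir is not None:
        result.write(outdir)
    return result
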
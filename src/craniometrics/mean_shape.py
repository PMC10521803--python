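"""Pointwise mean cranial shapes with SD bands and deviation profiles.

All contours entering a group model must share the sampling count and
orientation so that index k is the same anatomical direction on every
subject.  The SD band is the standard deviation of the scalar radial
distance at each index (ddof=1), matching scalar-band visualizations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .errors import InputError, SchemaError
from .slicing import SampledContour

#: default follow-up window centers in months of age (FU1..FU6)
DEFAULT_FOLLOWUP_CENTERS = (15.0, 24.0, 36.0, 48.0, 60.0, 72.0)


@dataclass
class MeanShapeModel:
    orientation_label: str
    mean_points: np.ndarray     # (n_samples, 2) coordinate-wise mean
    mean_radii: np.ndarray      # (n_samples,) mean radial distance
    sd_radial: np.ndarray       # (n_samples,) SD of radial distance, ddof=1
    n_subjects: int
    group_label: str
    center: np.ndarray = None   # mean of subject centers

    def __post_init__(self):
        self.mean_points = np.asarray(self.mean_points, float).reshape(-1, 2)
        self.mean_radii = np.asarray(self.mean_radii, float).reshape(-1)
        self.sd_radial = np.asarray(self.sd_radial, float).reshape(-1)
        if self.center is None:
            self.center = np.zeros(2)
        self.center = np.asarray(self.center, float).reshape(2)
        n = len(self.mean_points)
        if len(self.mean_radii) != n or len(self.sd_radial) != n:
            raise SchemaError("mean shape arrays have inconsistent lengths")
        if (self.sd_radial < 0).any():
            raise SchemaError("negative radial SD")
        if self.n_subjects < 1:
            raise SchemaError("mean shape requires at least one subject")

    @property
    def n_samples(self) -> int:
        return len(self.mean_points)

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_samples) / self.n_samples


@dataclass
class ShapeDeviationProfile:
    """Per-angle signed radial deviation of a group versus a reference."""

    deviation_mm: np.ndarray
    standardized: np.ndarray  # deviation / reference SD; NaN where SD == 0
    orientation_label: str
    reference_label: str

    def __post_init__(self):
        self.deviation_mm = np.asarray(self.deviation_mm, float).reshape(-1)
        self.standardized = np.asarray(self.standardized, float).reshape(-1)
        if not np.isfinite(self.deviation_mm).all():
            raise SchemaError("non-finite deviation values")


def compute_mean_shape(contours: list[SampledContour], group_label: str) -> MeanShapeModel:
    """Pointwise mean and radial-SD band over subjects.

    ``mean_points[k]`` is the coordinate-wise mean of point k across
    subjects; ``sd_radial[k]`` the SD (ddof=1; zero for a single subject) of
    the subjects' radial distances at index k.
    """
    if not contours:
        raise InputError("no contours supplied")
    n = contours[0].n_samples
    orientation = contours[0].orientation_label
    for c in contours:
        if c.n_samples != n:
            raise SchemaError("contours have mixed sample counts")
        if c.orientation_label != orientation:
            raise SchemaError("contours have mixed orientations")
    points = np.stack([c.points for c in contours])        # (s, n, 2)
    radii = np.stack([c.radii for c in contours])          # (s, n)
    centers = np.stack([c.center for c in contours])
    sd = radii.std(axis=0, ddof=1) if len(contours) > 1 else np.zeros(n)
    return MeanShapeModel(
        orientation_label=orientation,
        mean_points=points.mean(axis=0),
        mean_radii=radii.mean(axis=0),
        sd_radial=sd,
        n_subjects=len(contours),
        group_label=group_label,
        center=centers.mean(axis=0),
    )


def shape_deviation(model: MeanShapeModel, reference: MeanShapeModel) -> ShapeDeviationProfile:
    """Signed radial difference (group - reference) per index, plus the same
    difference standardized by the reference SD band."""
    if model.orientation_label != reference.orientation_label:
        raise SchemaError("mean shapes have different orientations")
    if model.n_samples != reference.n_samples:
        raise SchemaError("mean shapes have different sample counts")
    dev = model.mean_radii - reference.mean_radii
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(reference.sd_radial > 0, dev / reference.sd_radial, np.nan)
    return ShapeDeviationProfile(
        deviation_mm=dev, standardized=std,
        orientation_label=model.orientation_label,
        reference_label=reference.group_label)


def assign_followup_window(age_months: float,
                           centers=DEFAULT_FOLLOWUP_CENTERS) -> str:
    """Label FU1..FUk by nearest window center (months of age)."""
    idx = int(np.argmin(np.abs(np.asarray(centers, float) - age_months)))
    return f"FU{idx + 1}"


# ---------------------------------------------------------------------------
# serialization


def mean_shape_to_csv(model: MeanShapeModel, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "mean_x", "mean_y", "sd_radial"])
        for ang, p, sd in zip(np.degrees(model.angles), model.mean_points, model.sd_radial):
            writer.writerow([f"{ang:.6f}", f"{p[0]:.6f}", f"{p[1]:.6f}", f"{sd:.6f}"])


def mean_shape_to_json(model: MeanShapeModel, path) -> None:
    payload = {
        "orientation": model.orientation_label,
        "group": model.group_label,
        "n_subjects": model.n_subjects,
        "center": [float(x) for x in model.center],
        "mean_points": model.mean_points.tolist(),
        "mean_radii": model.mean_radii.tolist(),
        "sd_radial": model.sd_radial.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def plot_mean_shape(model: MeanShapeModel, path, reference: MeanShapeModel | None = None):
    """Optional matplotlib rendering of the mean contour with its SD band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    closed = np.vstack([model.mean_points, model.mean_points[:1]])
    ax.plot(closed[:, 0], closed[:, 1], "b-", label=model.group_label)
    dirs = np.column_stack([-np.sin(model.angles), np.cos(model.angles)])
    for sign in (-1, 1):
        band = model.center + (model.mean_radii + sign * model.sd_radial)[:, None] * dirs
        band = np.vstack([band, band[:1]])
        ax.plot(band[:, 0], band[:, 1], "b--", linewidth=0.7)
    if reference is not None:
        ref_closed = np.vstack([reference.mean_points, reference.mean_points[:1]])
        ax.plot(ref_closed[:, 0], ref_closed[:, 1], "k-", alpha=0.6,
                label=reference.group_label)
    ax.set_aspect("equal")
    ax.legend()
    ax.set_title(f"{model.orientation_label} mean shape (n={model.n_subjects})")
    fig.savefig(path, dpi=120)
    plt.close(fig)
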
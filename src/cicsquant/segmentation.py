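"""Segmentation primitives the detection cascade is assembled from.

These mirror the object-processing vocabulary of high-content-screening
software: primary-object identification (threshold → optional shape
declumping → hole fill → size/border filter), image masking by objects,
object masking (clipping object footprints to a region), per-object
morphometrics, eccentricity filtering of masking remnants, parent/child
object relation, and pixel-intensity line profiling.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; pixel centres sit at integer
  coordinates.
* After every operation label values form the contiguous set
  ``{1..n_objects}``.
* Eccentricity is that of the ellipse with the same normalised second
  central moments as the footprint (0 = circle, → 1 = line).  Single-pixel
  objects have eccentricity 0 and collinear-pixel objects 1, so filtering
  is total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .errors import DimensionMismatchError
from .image_io import ChannelImage, FieldOfView

DEFAULT_MAX_ECCENTRICITY = 0.92


@dataclass
class LabelMap:
    """Integer-labelled segmentation (0 = background, k > 0 = object k)."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = len(present)
        if n and (present[0] != 1 or present[-1] != n):
            raise ValueError("labels must form the contiguous set {1..n_objects}")
        self.n_objects = int(n)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def footprint(self) -> np.ndarray:
        """Boolean union of all object footprints."""
        return self.labels > 0

    def object_labels(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)


@dataclass
class SegmentationParams:
    """Parameters of :func:`identify_primary_objects`.

    ``threshold_floor`` imposes a lower bound on the automatic (Otsu)
    threshold, which keeps near-empty masked images from being split at a
    noise-level threshold — the usual safeguard in HCS pipelines.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    threshold_floor: float = 0.0
    smoothing_sigma: float = 1.0
    min_diameter: float = 8.0
    max_diameter: float = 80.0
    declump: str = "none"  # {"none", "shape"}
    fill_holes: bool = False
    border_policy: str = "keep"  # {"keep", "discard"}

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")
        if self.threshold_method == "otsu" and self.fixed_threshold is not None:
            raise ValueError("fixed_threshold only valid with threshold_method='fixed'")
        if not 0 < self.min_diameter < self.max_diameter:
            raise ValueError("require 0 < min_diameter < max_diameter")
        if self.declump not in ("none", "shape"):
            raise ValueError(f"unknown declump mode {self.declump!r}")
        if self.border_policy not in ("keep", "discard"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


def _smoothed(pixels: np.ndarray, sigma: float) -> np.ndarray:
    img = pixels.astype(np.float64)
    return gaussian(img, sigma=sigma, preserve_range=True) if sigma > 0 else img


def compute_threshold(image: ChannelImage, params: SegmentationParams) -> float:
    """Foreground threshold on the (smoothed) channel, floor applied.

    For a constant image under Otsu the returned threshold equals the
    constant, so strict ``>`` comparison yields no foreground.
    """
    sm = _smoothed(image.pixels, params.smoothing_sigma)
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        if np.ptp(sm) == 0:
            warnings.warn("constant image under Otsu thresholding: no foreground", stacklevel=2)
            thr = float(sm.flat[0])
        else:
            thr = float(threshold_otsu(sm))
    return max(thr, params.threshold_floor)


def _relabel(labels: np.ndarray, provenance: str) -> LabelMap:
    relabeled, _, _ = relabel_sequential(labels)
    return LabelMap(relabeled.astype(np.int32), provenance=provenance)


def _declump_shape(fg: np.ndarray, min_diameter: float) -> np.ndarray:
    """Watershed on the smoothed distance transform (shape-based declumping)."""
    distance = ndi.distance_transform_edt(fg)
    distance_s = ndi.gaussian_filter(distance, sigma=1.0)
    min_dist = max(1, int(round(min_diameter / 2)))
    coords = peak_local_max(
        distance_s, min_distance=min_dist, labels=cc_label(fg), exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return cc_label(fg)
    return watershed(-distance_s, markers, mask=fg)


def identify_primary_objects(image: ChannelImage, params: SegmentationParams) -> LabelMap:
    """Detect bright primary objects in one channel.

    Pipeline: Gaussian smooth → threshold (strictly above) → optional hole
    fill → connected components or shape declumping → diameter-range filter
    (equivalent-circle diameter) → border policy → contiguous relabel.
    A degenerate (constant) image yields an empty map with a warning.
    """
    thr = compute_threshold(image, params)
    fg = _smoothed(image.pixels, params.smoothing_sigma) > thr
    if params.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    labels = _declump_shape(fg, params.min_diameter) if params.declump == "shape" else cc_label(fg)

    if labels.max() > 0:
        areas = np.bincount(labels.ravel())[1:]
        amin = np.pi / 4 * params.min_diameter**2
        amax = np.pi / 4 * params.max_diameter**2
        bad = np.flatnonzero((areas < amin) | (areas > amax)) + 1
        if len(bad):
            labels[np.isin(labels, bad)] = 0
    if params.border_policy == "discard":
        labels = clear_border(labels)
    return _relabel(labels, provenance=f"identify_primary_objects({image.role})")


def mask_image_by_objects(image: ChannelImage, mask: LabelMap) -> ChannelImage:
    """Zero the channel outside the union of object footprints."""
    if mask.shape != image.shape:
        raise DimensionMismatchError(f"mask shape {mask.shape} != image shape {image.shape}")
    out = np.where(mask.footprint, image.pixels, 0)
    return ChannelImage(out, image.role, image.pixel_size, image.source_path)


def mask_objects(objects: LabelMap, mask: LabelMap, invert: bool = False) -> LabelMap:
    """Clip object footprints to the mask region (or its complement).

    Objects whose clipped footprint is empty are removed; survivors are
    relabelled contiguously.  Clipping can leave distorted remnants — those
    are removed downstream by :func:`filter_by_eccentricity`.
    """
    if mask.shape != objects.shape:
        raise DimensionMismatchError(f"mask shape {mask.shape} != objects shape {objects.shape}")
    region = mask.footprint
    if invert:
        region = ~region
    clipped = np.where(region, objects.labels, 0)
    return _relabel(clipped, provenance=f"mask_objects(invert={invert})<-{objects.provenance}")


def select_objects(objects: LabelMap, keep: np.ndarray | list[int], provenance: str = "") -> LabelMap:
    """Keep only the listed labels, relabelled contiguously."""
    keep = np.asarray(keep, dtype=np.int64)
    out = np.where(np.isin(objects.labels, keep), objects.labels, 0)
    return _relabel(out, provenance=provenance or f"select<-{objects.provenance}")


def compute_morphometrics(objects: LabelMap, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-object area, eccentricity and centroid.

    ``area_um2 = area_px * pixel_size**2``.  Eccentricity lies in [0, 1];
    the single-pixel (0) and collinear (1) conventions come directly from the
    second-moment definition.
    """
    if objects.n_objects == 0:
        return pd.DataFrame(
            columns=["label", "area_px", "area_um2", "eccentricity",
                     "centroid_row", "centroid_col"]
        ).astype({"label": int, "area_px": int})
    props = regionprops_table(
        objects.labels,
        properties=("label", "area", "eccentricity", "centroid"),
    )
    df = pd.DataFrame(props).rename(
        columns={
            "area": "area_px",
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
        }
    )
    df["area_px"] = df["area_px"].astype(int)
    df["area_um2"] = df["area_px"] * pixel_size**2
    df["eccentricity"] = df["eccentricity"].clip(0.0, 1.0)
    return df[["label", "area_px", "area_um2", "eccentricity", "centroid_row", "centroid_col"]]


def filter_by_eccentricity(
    objects: LabelMap, max_eccentricity: float = DEFAULT_MAX_ECCENTRICITY
) -> LabelMap:
    """Remove masking remnants: objects with eccentricity above the maximum.

    Exactly the objects with eccentricity ≤ ``max_eccentricity`` survive.
    The 0.92 default removes partially deleted cells after each masking step.
    """
    if objects.n_objects == 0:
        return objects
    morpho = compute_morphometrics(objects)
    keep = morpho.loc[morpho["eccentricity"] <= max_eccentricity, "label"].to_numpy()
    return select_objects(objects, keep, provenance=f"filter_ecc<= {max_eccentricity}")


def relate_objects(children: LabelMap, parents: LabelMap) -> tuple[pd.Series, pd.Series]:
    """Assign each child object to the parent sharing the most pixels.

    Returns ``(assignments, counts)``: ``assignments`` maps child label →
    parent label (0 = unassigned); ``counts`` maps parent label → number of
    assigned children.  Ties break to the lowest parent label.
    """
    if children.shape != parents.shape:
        raise DimensionMismatchError(
            f"children shape {children.shape} != parents shape {parents.shape}"
        )
    cl = children.labels.ravel()
    pl = parents.labels.ravel()
    sel = (cl > 0) & (pl > 0)
    assignments = pd.Series(
        0, index=pd.RangeIndex(1, children.n_objects + 1, name="child"), dtype=int
    )
    if sel.any():
        pairs, n = np.unique(np.stack([cl[sel], pl[sel]]), axis=1, return_counts=True)
        overlap = pd.DataFrame({"child": pairs[0], "parent": pairs[1], "pixels": n})
        # stable sort: most pixels first, lowest parent label on ties
        overlap = overlap.sort_values(
            ["child", "pixels", "parent"], ascending=[True, False, True]
        )
        best = overlap.groupby("child", sort=True).first()
        assignments.loc[best.index] = best["parent"].to_numpy()
    counts = pd.Series(
        0, index=pd.RangeIndex(1, parents.n_objects + 1, name="parent"), dtype=int
    )
    assigned = assignments[assignments > 0]
    if len(assigned):
        vc = assigned.value_counts()
        counts.loc[vc.index] = vc.to_numpy()
    return assignments, counts


def line_profile(
    fov: FieldOfView,
    start: tuple[float, float],
    end: tuple[float, float],
    roles: list[str],
) -> dict[str, np.ndarray]:
    """Pixel-intensity profiles along a segment, one per requested role.

    Intensities are sampled at unit-pixel spacing with bilinear
    interpolation; every profile has ``floor(segment length) + 1`` samples.
    """
    shape = fov.shape
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise ValueError(f"{name} point {r, c} outside raster of shape {shape}")
    length = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    n = int(np.floor(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = start[0] + t * (end[0] - start[0])
    cols = start[1] + t * (end[1] - start[1])
    out: dict[str, np.ndarray] = {}
    for role in roles:
        fov.require(role)
        out[role] = ndi.map_coordinates(
            fov.channels[role].pixels.astype(np.float64), [rows, cols], order=1
        )
    return out
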
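"""Threshold-based puncta detection with size filtering and watershed splitting.

Re-implements the "Analyze Particles" + adjustable-watershed core used to
segment presynaptic boutons, postsynaptic clusters, synaptosome puncta and
RNAscope particles: a fixed intensity threshold produces a binary mask,
touching spots are split at distance-transform saddles, and components
smaller than a minimum physical area are discarded.

Intensity metrics are always computed on a *measurement* plane (raw, never
contrast-stretched); detection may run on a preprocessed copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, segmentation

from synquant.image_io import CalibratedImage

#: 8-connectivity structure used for 2D labeling throughout the package.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

TABLE_COLUMNS = [
    "id",
    "area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "integrated_intensity",
    "mean_intensity",
]


@dataclass
class DetectionParams:
    """Puncta detection parameters.

    Attributes
    ----------
    intensity_threshold
        Raw intensity cutoff; pixels ``>= threshold`` form the mask.  Fixed
        per experiment: the same threshold must be applied to every image
        of one staining batch.
    min_particle_area
        Minimum particle area in μm² (default 0.05); smaller components are
        discarded after watershed splitting.
    watershed
        Split touching spots by distance-transform watershed.
    watershed_tolerance
        Merge tolerance: distance-transform regional maxima shallower than
        this depth (pixels) do not seed a separate particle.
    """

    intensity_threshold: float = 0.0
    min_particle_area: float = 0.05
    watershed: bool = True
    watershed_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if not (self.min_particle_area > 0):
            raise ValueError("min_particle_area must be > 0")
        if self.watershed and not (self.watershed_tolerance > 0):
            raise ValueError("watershed_tolerance must be > 0")


@dataclass
class LabeledPuncta:
    """Labeled detected particles plus their per-particle measurements.

    ``label_map`` holds consecutive positive integer labels (0 =
    background) ordered by raster scan of each particle's first pixel.
    ``table`` has one row per particle with columns ``id``, ``area_um2``,
    ``centroid_x_um``, ``centroid_y_um``, ``integrated_intensity`` and
    ``mean_intensity``.
    """

    label_map: np.ndarray
    table: pd.DataFrame
    pixel_size_xy: float

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def mask_of(self, punctum_id: int) -> np.ndarray:
        return self.label_map == punctum_id


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel so ids are consecutive, ordered by first pixel in raster scan."""
    flat = labels.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return np.zeros_like(labels)
    order = pd.unique(nz)  # preserves first-occurrence order
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1)
    return lut[labels]


def watershed_split(mask: np.ndarray, tolerance: float) -> np.ndarray:
    """Split a binary mask at distance-transform saddles.

    Markers are the regional maxima of the Euclidean distance transform
    that are deeper than ``tolerance`` (h-maxima), labeled 8-connected;
    the watershed of the inverted distance transform then assigns every
    mask pixel to a marker.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    maxima = morphology.h_maxima(dist, tolerance)
    markers, n = ndimage.label(maxima, structure=STRUCTURE_8)
    if n == 0:  # degenerate: fall back to plain connected components
        labels, _ = ndimage.label(mask, structure=STRUCTURE_8)
        return labels.astype(np.int32)
    return segmentation.watershed(-dist, markers, mask=mask, connectivity=2).astype(
        np.int32
    )


def _measure(
    labels: np.ndarray, measurement_plane: np.ndarray, pixel_size_xy: float
) -> pd.DataFrame:
    ids = np.arange(1, int(labels.max()) + 1)
    if ids.size == 0:
        return pd.DataFrame(columns=TABLE_COLUMNS).astype(
            {"id": int, "area_um2": float}
        )
    counts = np.bincount(labels.ravel(), minlength=ids.size + 1)[1:]
    sums = ndimage.sum_labels(measurement_plane, labels, index=ids)
    cy, cx = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, index=ids)).T
    return pd.DataFrame(
        {
            "id": ids,
            "area_um2": counts * pixel_size_xy**2,
            "centroid_x_um": cx * pixel_size_xy,
            "centroid_y_um": cy * pixel_size_xy,
            "integrated_intensity": np.asarray(sums, dtype=float),
            "mean_intensity": np.asarray(sums, dtype=float) / counts,
        }
    )


def detect_puncta(
    img: CalibratedImage,
    channel: int | str,
    params: DetectionParams,
    measurement: CalibratedImage | np.ndarray | None = None,
) -> LabeledPuncta:
    """Detect puncta in one channel plane.

    Pipeline: threshold (``>=``) → optional watershed split → remove
    components with area < ``min_particle_area`` → relabel in raster order
    → measure.  A threshold above the image maximum yields an empty result,
    not an error.

    Parameters
    ----------
    img
        Image whose ``channel`` plane drives detection (typically the
        preprocessed copy).
    measurement
        Plane (or image sharing the channel layout) supplying raw
        intensities for the per-particle metrics.  Defaults to the
        detection plane itself; pass the unprocessed image whenever
        ``img`` was contrast-stretched.
    """
    plane = img.channel(channel)
    if plane.ndim != 2:
        raise ValueError("detect_puncta operates on a single 2D plane")
    if measurement is None:
        meas_plane = plane
    elif isinstance(measurement, CalibratedImage):
        meas_plane = measurement.channel(channel)
    else:
        meas_plane = np.asarray(measurement)
    if meas_plane.shape != plane.shape:
        raise ValueError("measurement plane shape mismatch")

    mask = plane >= params.intensity_threshold

    if params.watershed:
        labels = watershed_split(mask, params.watershed_tolerance)
    else:
        labels, _ = ndimage.label(mask, structure=STRUCTURE_8)
        labels = labels.astype(np.int32)

    # size filter in physical units (keep area >= min_particle_area)
    min_px = params.min_particle_area / img.pixel_area
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts < min_px)
        kill = np.isin(labels, too_small[too_small > 0])
        labels[kill] = 0

    labels = _relabel_raster_order(labels)
    table = _measure(labels, meas_plane, img.pixel_size_xy)
    return LabeledPuncta(label_map=labels, table=table, pixel_size_xy=img.pixel_size_xy)


def suggest_threshold(planes: list[np.ndarray]) -> float:
    """Suggest a detection threshold by Otsu's method on pooled training images.

    Helper only — never applied implicitly; experiments must fix one
    threshold in configuration and apply it to every image.
    """
    from skimage.filters import threshold_otsu

    pooled = np.concatenate([np.asarray(p).ravel() for p in planes])
    return float(threshold_otsu(pooled))
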
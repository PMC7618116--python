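"""Soma/dendrite ROIs, perimeter bands, and ROI intensity measures.

A :class:`CellROI` is a single-cell binary mask (from an intensity
threshold on a marker channel, or a supplied polygon) together with the two
geometric quantities the synapse-calling rules depend on: the perimeter
length (density denominator for somas) and a *perimeter band* — a thin
annulus around the mask boundary against which puncta overlap areas are
measured.

The 3D soma "surface" of commercial reconstruction tools is approximated by
voxel-threshold segmentation: the largest 26-connected component above
threshold, with volume = voxel count × pixel area × z-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import uniform_filter1d
from skimage import draw, measure, morphology

from synquant.image_io import CalibratedImage
from synquant.puncta import STRUCTURE_8


@dataclass
class CellROI:
    """A soma or dendrite mask with derived geometry.

    Attributes
    ----------
    cell_id : identifier used in reports.
    kind : ``"soma"`` or ``"dendrite"``.
    mask : binary (y, x) array, one 8-connected component.
    pixel_size_xy : μm/pixel of the source image.
    perimeter_length : boundary length in μm (smoothed contour estimate).
    area : mask area in μm².
    perimeter_band : binary band of width ``band_width`` around the boundary.
    band_width : band width in μm.
    skeleton_length : skeleton length in μm (dendrites; density denominator).
    """

    cell_id: str
    kind: str
    mask: np.ndarray
    pixel_size_xy: float
    perimeter_length: float = 0.0
    area: float = 0.0
    perimeter_band: np.ndarray | None = None
    band_width: float = 0.5
    skeleton_length: float = field(default=0.0)

    @property
    def length_um(self) -> float:
        """Density denominator: perimeter (soma) or skeleton length (dendrite)."""
        return self.skeleton_length if self.kind == "dendrite" else self.perimeter_length


@dataclass
class RoiIntensity:
    """Integrated density within an ROI and its size-corrected value."""

    integrated_density: float
    size_corrected_intensity: float


@dataclass
class SomaVolume3D:
    """Voxel-threshold 3D soma reconstruction."""

    volume: float
    integrated_density: float
    size_corrected_intensity: float
    n_secondary_components: int = 0


def contour_perimeter(mask: np.ndarray, pixel_size_xy: float, smooth_window: int = 7) -> float:
    """Boundary length of a binary mask in μm.

    Marching-squares contours are traced at the 0.5 level and lightly
    smoothed with a circular moving average before summing segment
    lengths; the smoothing removes the staircase bias that would otherwise
    overestimate curved boundaries by ~5–8%.
    """
    total = 0.0
    for c in measure.find_contours(mask.astype(float), 0.5):
        closed = np.allclose(c[0], c[-1])
        if closed and len(c) > smooth_window:
            cs = np.column_stack(
                [uniform_filter1d(c[:-1, i], smooth_window, mode="wrap") for i in range(2)]
            )
            cs = np.vstack([cs, cs[:1]])
        else:
            cs = c
        total += float(np.sum(np.hypot(np.diff(cs[:, 0]), np.diff(cs[:, 1]))))
    return total * pixel_size_xy


def perimeter_band(
    mask: np.ndarray, width: float, pixel_size_xy: float
) -> np.ndarray:
    """Binary band of total width ``width`` (μm), symmetric about the boundary.

    Defined as ``dilation(mask, width/2) \\ erosion(mask, width/2)`` with a
    Euclidean disk.  For widths exceeding the ROI diameter the erosion is
    empty and the band degenerates to the dilated mask.
    """
    if not (width > 0):
        raise ValueError("band width must be > 0")
    r = max(1, round((width / 2) / pixel_size_xy))
    disk = morphology.disk(r)
    mask = np.asarray(mask, dtype=bool)
    return morphology.dilation(mask, disk) & ~morphology.erosion(mask, disk)


def skeleton_length(mask: np.ndarray, pixel_size_xy: float) -> float:
    """Length of the morphological skeleton of a mask, in μm.

    Adjacent skeleton pixels contribute 1 px for orthogonal and √2 px for
    diagonal links; each link is counted once.  Used as the per-μm density
    denominator for dendrite ROIs.
    """
    sk = morphology.skeletonize(mask)
    if sk.sum() < 2:
        return 0.0
    n_h = np.count_nonzero(sk[:, :-1] & sk[:, 1:])
    n_v = np.count_nonzero(sk[:-1, :] & sk[1:, :])
    # diagonal links, skipped when an orthogonal two-step path already connects
    d1 = sk[:-1, :-1] & sk[1:, 1:] & ~(sk[:-1, 1:] | sk[1:, :-1])
    d2 = sk[:-1, 1:] & sk[1:, :-1] & ~(sk[:-1, :-1] | sk[1:, 1:])
    return (n_h + n_v + np.sqrt(2) * (d1.sum() + d2.sum())) * pixel_size_xy


def _polygon_mask(
    polygon_um: np.ndarray, shape: tuple[int, int], pixel_size_xy: float
) -> np.ndarray:
    from shapely.geometry import Polygon

    polygon_um = np.asarray(polygon_um, dtype=float)
    if polygon_um.ndim != 2 or polygon_um.shape[0] < 3 or polygon_um.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) array of (x, y) μm vertices")
    poly = Polygon(polygon_um)
    if not poly.is_valid:
        raise ValueError("self-intersecting or otherwise invalid polygon")
    # rows are (row=y, col=x) in pixel units; the half-pixel shift gives
    # half-open pixel-center semantics so a w×h μm rectangle rasterizes to
    # exactly (w/px)·(h/px) pixels
    rc = polygon_um[:, ::-1] / pixel_size_xy - 0.5
    return draw.polygon2mask(shape, rc)


def build_roi(
    img: CalibratedImage,
    channel: int | str | None = None,
    method: str = "auto",
    threshold: float | None = None,
    polygon: np.ndarray | None = None,
    cell_id: str = "cell",
    kind: str = "soma",
    band_width: float = 0.5,
) -> CellROI:
    """Build a cell ROI from a marker channel or a polygon.

    ``method="auto"``: the mask is the largest 8-connected component of
    ``channel >= threshold`` (holes filled).  ``method="polygon"``: the
    mask is the rasterized polygon (vertices in μm, (x, y) order).
    """
    if method == "auto":
        if threshold is None:
            raise ValueError("auto method requires a threshold")
        plane = img.channel(channel)
        if plane.ndim != 2:
            raise ValueError("build_roi operates on a 2D plane")
        binary = plane >= threshold
        labels, n = ndimage.label(binary, structure=STRUCTURE_8)
        if n == 0:
            raise ValueError(f"empty mask: no pixel >= {threshold} in channel {channel}")
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
        mask = ndimage.binary_fill_holes(mask)
    elif method == "polygon":
        if polygon is None:
            raise ValueError("polygon method requires vertices")
        mask = _polygon_mask(polygon, img.shape_yx, img.pixel_size_xy)
        if not mask.any():
            raise ValueError("polygon rasterizes to an empty mask")
    else:
        raise ValueError(f"unknown ROI method {method!r}")

    px = img.pixel_size_xy
    roi = CellROI(
        cell_id=cell_id,
        kind=kind,
        mask=mask,
        pixel_size_xy=px,
        perimeter_length=contour_perimeter(mask, px),
        area=float(mask.sum()) * px**2,
        band_width=band_width,
    )
    roi.perimeter_band = perimeter_band(mask, band_width, px)
    if kind == "dendrite":
        roi.skeleton_length = skeleton_length(mask, px)
    return roi


def roi_intensity(
    img: CalibratedImage, channel: int | str, roi: CellROI
) -> RoiIntensity:
    """Integrated density of a channel within the ROI, raw intensities.

    ``size_corrected_intensity`` divides by the ROI area in μm² — the 2D
    analogue of "integrated density corrected for soma size".
    """
    plane = img.channel(channel)
    if plane.shape != roi.mask.shape:
        raise ValueError("image and ROI shapes differ")
    if not roi.mask.any():
        raise ValueError("empty ROI mask")
    integrated = float(plane[roi.mask].sum())
    return RoiIntensity(
        integrated_density=integrated,
        size_corrected_intensity=integrated / roi.area,
    )


def soma_volume_3d(
    img: CalibratedImage, channel: int | str, threshold: float
) -> SomaVolume3D:
    """Largest 26-connected voxel component above threshold, as a soma volume.

    Requires a z-calibrated stack with at least 3 slices.  Reports the
    component volume (μm³), the integrated density of the same channel
    inside it, and the volume-corrected intensity; the number of discarded
    secondary components is flagged for QC.
    """
    if not img.is_stack or img.z_step is None:
        raise ValueError("soma_volume_3d requires a z-calibrated stack")
    stack = img.channel(channel)
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 z-slices")
    binary = stack >= threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise ValueError(f"no voxel above threshold {threshold}")
    counts = np.bincount(labels.ravel())[1:]
    main = int(np.argmax(counts)) + 1
    voxels = int(counts[main - 1])
    volume = voxels * img.voxel_volume
    integrated = float(stack[labels == main].sum())
    return SomaVolume3D(
        volume=volume,
        integrated_density=integrated,
        size_corrected_intensity=integrated / volume,
        n_secondary_components=n - 1,
    )
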
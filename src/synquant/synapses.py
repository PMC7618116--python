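"""Synapse-calling rules: bouton/cluster classification and pairing.

The quantification logic works on label masks in physical units:

* a punctum from the presynaptic channel is a **bouton** when it lies
  outside the target cell (inside fraction ≤ cutoff) and at least
  0.1 μm² of it colocalizes with the cell's perimeter band;
* a punctum from the postsynaptic channel is a **cluster** when it is
  contained inside the cell (inside fraction > cutoff) and at least
  0.2 μm² colocalizes with the perimeter band;
* a **synapse** is a bouton–cluster pair whose masks overlap by at least
  0.03 μm²; each bouton is assigned to its maximum-overlap cluster so one
  bouton is never counted as several synapses (an all-pairs mode is
  available);
* plated **synaptosomes** use the same ≥ 0.03 μm² pairing rule between
  pre- and postsynaptic puncta, without any cell ROI.

All thresholds are inclusive (``>=``) and every overlap equals an exact
pixel-intersection count times the pixel area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synquant.image_io import CalibratedImage
from synquant.puncta import LabeledPuncta
from synquant.rois import CellROI

#: Default colocalization thresholds, μm².
BOUTON_MIN_BAND_OVERLAP = 0.1
CLUSTER_MIN_BAND_OVERLAP = 0.2
SYNAPSE_MIN_OVERLAP = 0.03


@dataclass
class ClassifiedPuncta:
    """One punctum's relation to a cell ROI."""

    id: int
    role: str  # "bouton" | "cluster" | "unassigned"
    inside_fraction: float
    band_overlap: float  # μm²
    area_um2: float


@dataclass
class SynapseCall:
    """A qualified (presynaptic, postsynaptic) pair."""

    pre_id: int
    post_id: int
    overlap_area: float  # μm²


@dataclass
class SynaptosomeCall:
    """A paired pre/post synaptosome with optional measured intensity."""

    pre_id: int
    post_id: int
    overlap_area: float
    measured_intensity: float | None = None


@dataclass
class CellSynapseReport:
    """Per-cell synapse quantification summary."""

    cell_id: str
    n_boutons: int
    n_clusters: int
    n_synapses: int
    synapse_density: float  # per μm perimeter (soma) or skeleton length (dendrite)
    mean_bouton_area: float | None
    mean_cluster_area: float | None
    length_um: float = 0.0

    def as_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "n_boutons": self.n_boutons,
            "n_clusters": self.n_clusters,
            "n_synapses": self.n_synapses,
            "synapse_density_per_um": self.synapse_density,
            "mean_bouton_area_um2": self.mean_bouton_area,
            "mean_cluster_area_um2": self.mean_cluster_area,
            "length_um": self.length_um,
        }


def _overlap_counts(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Per-label pixel counts of ``labels`` restricted to a binary region.

    Returns an array indexed by label id (0 unused).
    """
    n = int(labels.max())
    if n == 0:
        return np.zeros(1, dtype=np.int64)
    return np.bincount(labels[region].ravel(), minlength=n + 1)


def classify_puncta(
    puncta: LabeledPuncta,
    roi: CellROI,
    role: str | None = None,
    bouton_min_overlap: float = BOUTON_MIN_BAND_OVERLAP,
    cluster_min_overlap: float = CLUSTER_MIN_BAND_OVERLAP,
    inside_cutoff: float = 0.5,
) -> list[ClassifiedPuncta]:
    """Classify detected puncta as boutons / clusters relative to one cell.

    ``role="pre"`` only allows bouton assignments, ``role="post"`` only
    cluster assignments, ``None`` allows both (they are mutually exclusive
    because the inside-fraction conditions partition the puncta).
    Straddling puncta are resolved by ``inside_cutoff`` on the fraction of
    punctum area inside the ROI mask.
    """
    if puncta.label_map.shape != roi.mask.shape:
        raise ValueError("puncta and ROI are in different frames")
    if abs(puncta.pixel_size_xy - roi.pixel_size_xy) > 1e-12:
        raise ValueError("puncta and ROI have different calibrations")
    if roi.perimeter_band is None:
        raise ValueError("ROI has no perimeter band")

    px_area = puncta.pixel_size_xy**2
    total = _overlap_counts(puncta.label_map, np.ones_like(roi.mask, dtype=bool))
    inside = _overlap_counts(puncta.label_map, roi.mask)
    in_band = _overlap_counts(puncta.label_map, roi.perimeter_band)

    out: list[ClassifiedPuncta] = []
    for pid in puncta.ids:
        pid = int(pid)
        frac = inside[pid] / total[pid]
        band = in_band[pid] * px_area
        is_bouton = frac <= inside_cutoff and band >= bouton_min_overlap
        is_cluster = frac > inside_cutoff and band >= cluster_min_overlap
        if is_bouton and role in (None, "pre"):
            r = "bouton"
        elif is_cluster and role in (None, "post"):
            r = "cluster"
        else:
            r = "unassigned"
        out.append(
            ClassifiedPuncta(
                id=pid,
                role=r,
                inside_fraction=float(frac),
                band_overlap=float(band),
                area_um2=float(total[pid] * px_area),
            )
        )
    return out


def pairwise_overlap_areas(
    pre: LabeledPuncta,
    post: LabeledPuncta,
    pre_ids: np.ndarray | None = None,
    post_ids: np.ndarray | None = None,
) -> dict[tuple[int, int], float]:
    """Exact mask-intersection areas (μm²) for all co-occurring label pairs."""
    if pre.label_map.shape != post.label_map.shape:
        raise ValueError("pre/post label maps are in different frames")
    both = (pre.label_map > 0) & (post.label_map > 0)
    a = pre.label_map[both].astype(np.int64)
    b = post.label_map[both].astype(np.int64)
    if a.size == 0:
        return {}
    nb = int(post.label_map.max())
    key = a * (nb + 1) + b
    counts = np.bincount(key)
    px_area = pre.pixel_size_xy**2
    pre_ok = set(map(int, pre_ids)) if pre_ids is not None else None
    post_ok = set(map(int, post_ids)) if post_ids is not None else None
    out: dict[tuple[int, int], float] = {}
    for k in np.flatnonzero(counts):
        ia, ib = int(k) // (nb + 1), int(k) % (nb + 1)
        if pre_ok is not None and ia not in pre_ok:
            continue
        if post_ok is not None and ib not in post_ok:
            continue
        out[(ia, ib)] = float(counts[k] * px_area)
    return out


def _pair(
    overlaps: dict[tuple[int, int], float],
    min_overlap: float,
    mode: str,
) -> list[tuple[int, int, float]]:
    """Apply the ≥ min_overlap rule, then best-match (or all-pairs) selection."""
    qualifying = [(i, j, a) for (i, j), a in overlaps.items() if a >= min_overlap]
    if mode == "all_pairs":
        return sorted(qualifying)
    if mode != "best_match":
        raise ValueError(f"unknown pairing mode {mode!r}")
    best: dict[int, tuple[int, float]] = {}
    for i, j, a in sorted(qualifying):  # sorted → ties resolve to lower post id
        if i not in best or a > best[i][1]:
            best[i] = (j, a)
    return [(i, j, a) for i, (j, a) in sorted(best.items())]


def call_synapses(
    pre: LabeledPuncta,
    post: LabeledPuncta,
    pre_classified: list[ClassifiedPuncta],
    post_classified: list[ClassifiedPuncta],
    min_overlap: float = SYNAPSE_MIN_OVERLAP,
    mode: str = "best_match",
) -> list[SynapseCall]:
    """Pair boutons with postsynaptic clusters into synapse calls.

    Candidate pairs are every (bouton, cluster) whose masks intersect by at
    least ``min_overlap`` μm²; in ``best_match`` mode (default) each bouton
    keeps only its maximum-overlap cluster, ties to the lower cluster id,
    so ``n_synapses <= n_boutons``.
    """
    bouton_ids = np.array([c.id for c in pre_classified if c.role == "bouton"])
    cluster_ids = np.array([c.id for c in post_classified if c.role == "cluster"])
    if bouton_ids.size == 0 or cluster_ids.size == 0:
        return []
    overlaps = pairwise_overlap_areas(pre, post, bouton_ids, cluster_ids)
    return [SynapseCall(i, j, a) for i, j, a in _pair(overlaps, min_overlap, mode)]


def call_synaptosomes(
    pre: LabeledPuncta,
    post: LabeledPuncta,
    min_overlap: float = SYNAPSE_MIN_OVERLAP,
    mode: str = "best_match",
) -> list[SynaptosomeCall]:
    """Pair pre- and postsynaptic puncta of a plated-synaptosome field.

    Identical pairing rule to :func:`call_synapses` but without any cell
    ROI: every detected punctum participates.
    """
    overlaps = pairwise_overlap_areas(pre, post)
    return [SynaptosomeCall(i, j, a) for i, j, a in _pair(overlaps, min_overlap, mode)]


def summarize_cell(
    calls: list[SynapseCall],
    pre_classified: list[ClassifiedPuncta],
    post_classified: list[ClassifiedPuncta],
    roi: CellROI,
) -> CellSynapseReport:
    """Per-cell counts, density and mean particle sizes.

    Density is synapses per μm of soma perimeter, or per μm of skeleton
    length for dendrite ROIs.
    """
    length = roi.length_um
    if not (length > 0):
        raise ValueError(f"ROI {roi.cell_id} has zero perimeter/length")
    bouton_areas = [c.area_um2 for c in pre_classified if c.role == "bouton"]
    cluster_areas = [c.area_um2 for c in post_classified if c.role == "cluster"]
    return CellSynapseReport(
        cell_id=roi.cell_id,
        n_boutons=len(bouton_areas),
        n_clusters=len(cluster_areas),
        n_synapses=len(calls),
        synapse_density=len(calls) / length,
        mean_bouton_area=float(np.mean(bouton_areas)) if bouton_areas else None,
        mean_cluster_area=float(np.mean(cluster_areas)) if cluster_areas else None,
        length_um=length,
    )


def synaptosome_intensity(
    img: CalibratedImage,
    channel: int | str,
    calls: list[SynaptosomeCall],
    pre: LabeledPuncta,
    post: LabeledPuncta,
    region: str = "union",
) -> list[SynaptosomeCall]:
    """Measure per-synaptosome integrated density of a measurement channel.

    ``region`` selects the pixel set: ``"union"`` (default) of the two
    particle masks, their ``"intersection"``, or the ``"post"`` particle
    alone.  Raw intensities; results are written into ``measured_intensity``
    of returned copies.
    """
    plane = img.channel(channel)
    if plane.ndim != 2 or plane.shape != pre.label_map.shape:
        raise ValueError("measurement channel frame mismatch")
    out = []
    for call in calls:
        a = pre.label_map == call.pre_id
        b = post.label_map == call.post_id
        if region == "union":
            sel = a | b
        elif region == "intersection":
            sel = a & b
        elif region == "post":
            sel = b
        else:
            raise ValueError(f"unknown region {region!r}")
        out.append(
            SynaptosomeCall(
                pre_id=call.pre_id,
                post_id=call.post_id,
                overlap_area=call.overlap_area,
                measured_intensity=float(plane[sel].sum()),
            )
        )
    return out


def intensity_histogram(
    values: np.ndarray,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequency distribution over fixed bins.

    Returns ``(frequencies, bin_edges)`` with frequencies summing to 1.
    Values outside ``value_range`` are clipped into the outer bins so no
    observation is dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value set")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if value_range is None:
        value_range = (float(values.min()), float(values.max()))
        if value_range[0] == value_range[1]:
            value_range = (value_range[0] - 0.5, value_range[1] + 0.5)
    clipped = np.clip(values, value_range[0], value_range[1])
    counts, edges = np.histogram(clipped, bins=n_bins, range=value_range)
    return counts / counts.sum(), edges


def count_rna_particles(
    particles: LabeledPuncta, soma: CellROI, min_inside_fraction: float = 0.5
) -> int:
    """Count RNAscope particles inside a soma.

    A particle counts when at least ``min_inside_fraction`` of its area
    lies inside the soma mask (inclusive).
    """
    if particles.label_map.shape != soma.mask.shape:
        raise ValueError("particles and soma are in different frames")
    total = _overlap_counts(particles.label_map, np.ones_like(soma.mask, dtype=bool))
    inside = _overlap_counts(particles.label_map, soma.mask)
    n = 0
    for pid in particles.ids:
        pid = int(pid)
        if inside[pid] / total[pid] >= min_inside_fraction:
            n += 1
    return n


def classified_table(classified: list[ClassifiedPuncta]) -> pd.DataFrame:
    """Tidy per-punctum classification table."""
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "role": c.role,
                "inside_fraction": c.inside_fraction,
                "band_overlap_um2": c.band_overlap,
                "area_um2": c.area_um2,
            }
            for c in classified
        ]
    )


def calls_table(calls: list[SynapseCall] | list[SynaptosomeCall]) -> pd.DataFrame:
    """Tidy per-call table (includes intensity column when measured)."""
    rows = []
    for c in calls:
        row = {"pre_id": c.pre_id, "post_id": c.post_id, "overlap_area_um2": c.overlap_area}
        if isinstance(c, SynaptosomeCall):
            row["measured_intensity"] = c.measured_intensity
        rows.append(row)
    return pd.DataFrame(rows)
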
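import numpy as np
import pandas as pd
import pytest

from conftest import random_label_map
from oracles import all_pairs_best_match, pixel_overlap_area
from synquant.image_io import CalibratedImage
from synquant.puncta import LabeledPuncta
from synquant.rois import CellROI
from synquant.synapses import (
    call_synapses,
    call_synaptosomes,
    classify_puncta,
    count_rna_particles,
    intensity_histogram,
    pairwise_overlap_areas,
    summarize_cell,
    synaptosome_intensity,
)

PX = 0.1  # μm/px → pixel area 0.01 μm²


def make_puncta(label_map, px=PX):
    label_map = np.asarray(label_map, dtype=np.int32)
    n = int(label_map.max())
    counts = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "area_um2": counts * px * px,
            "centroid_x_um": 0.0,
            "centroid_y_um": 0.0,
            "integrated_intensity": 0.0,
            "mean_intensity": 0.0,
        }
    )
    return LabeledPuncta(label_map, table, px)


def half_plane_roi(shape=(64, 64), split=32, band_halfwidth=2, px=PX, kind="soma"):
    """ROI occupying columns < split; band spans ±band_halfwidth columns."""
    mask = np.zeros(shape, dtype=bool)
    mask[:, :split] = True
    band = np.zeros(shape, dtype=bool)
    band[:, split - band_halfwidth : split + band_halfwidth] = True
    return CellROI(
        cell_id="cell",
        kind=kind,
        mask=mask,
        pixel_size_xy=px,
        perimeter_length=shape[0] * px,
        area=float(mask.sum()) * px * px,
        perimeter_band=band,
        band_width=2 * band_halfwidth * px,
        skeleton_length=shape[0] * px,
    )


def rect_labels(shape, boxes):
    """Label map with one rectangle per id: boxes = [(y0, y1, x0, x1), ...]."""
    lm = np.zeros(shape, dtype=np.int32)
    for i, (y0, y1, x0, x1) in enumerate(boxes, start=1):
        lm[y0:y1, x0:x1] = i
    return lm


# ---------------------------------------------------------------- classify


@pytest.mark.parametrize(
    "n_band_px, expected",
    [(9, "unassigned"), (10, "bouton"), (12, "bouton")],
)
def test_bouton_band_overlap_threshold_inclusive(n_band_px, expected):
    """Outside puncta need ≥ 0.1 μm² on the perimeter band to be boutons."""
    roi = half_plane_roi()
    # punctum fully outside the mask, n pixels inside the band (cols 32–33)
    lm = rect_labels((64, 64), [(0, n_band_px, 32, 33)])
    cls = classify_puncta(make_puncta(lm), roi)
    assert cls[0].inside_fraction == 0.0
    assert cls[0].band_overlap == pytest.approx(n_band_px * 0.01)
    assert cls[0].role == expected


@pytest.mark.parametrize(
    "n_band_px, expected",
    [(15, "unassigned"), (20, "cluster"), (25, "cluster")],
)
def test_cluster_band_overlap_threshold_inclusive(n_band_px, expected):
    """Inside puncta need ≥ 0.2 μm² on the perimeter band to be clusters."""
    roi = half_plane_roi()
    # punctum fully inside the mask, n pixels inside the band (cols 30–31)
    lm = rect_labels((64, 64), [(0, n_band_px, 30, 31)])
    cls = classify_puncta(make_puncta(lm), roi)
    assert cls[0].inside_fraction == 1.0
    assert cls[0].role == expected


def test_straddling_puncta_resolved_by_inside_cutoff():
    roi = half_plane_roi()
    # 40 px punctum, 30 inside (cols 29–31), 10 outside (col 32) → frac 0.75
    lm = np.zeros((64, 64), dtype=np.int32)
    lm[0:10, 29:33] = 1
    cls = classify_puncta(make_puncta(lm), roi)
    assert cls[0].inside_fraction == pytest.approx(0.75)
    assert cls[0].role == "cluster"  # 40 band px = 0.4 μm² ≥ 0.2
    cls_strict = classify_puncta(make_puncta(lm), roi, inside_cutoff=0.8)
    assert cls_strict[0].role == "bouton"  # now counts as outside; 0.4 ≥ 0.1


def test_role_restriction_masks_the_other_class():
    roi = half_plane_roi()
    lm = rect_labels((64, 64), [(0, 25, 30, 31)])  # a clear cluster
    assert classify_puncta(make_puncta(lm), roi, role="post")[0].role == "cluster"
    assert classify_puncta(make_puncta(lm), roi, role="pre")[0].role == "unassigned"


def test_classification_overlaps_match_pixel_oracle(rng):
    roi = half_plane_roi()
    for _ in range(10):
        lm = random_label_map(rng)
        cls = classify_puncta(make_puncta(lm), roi)
        for c in cls:
            mask = lm == c.id
            assert c.band_overlap == pytest.approx(
                np.count_nonzero(mask & roi.perimeter_band) * 0.01, abs=1e-12
            )
            assert c.inside_fraction == pytest.approx(
                np.count_nonzero(mask & roi.mask) / np.count_nonzero(mask)
            )


def test_calibration_mismatch_rejected():
    roi = half_plane_roi()
    pn = make_puncta(rect_labels((64, 64), [(0, 5, 40, 45)]), px=0.2)
    with pytest.raises(ValueError, match="calibration"):
        classify_puncta(pn, roi)


# ---------------------------------------------------------------- pairing


@pytest.mark.parametrize("n_px, expected_calls", [(5, 1), (3, 1), (2, 0)])
def test_synapse_overlap_threshold_inclusive(n_px, expected_calls):
    """Bouton/cluster pairs need ≥ 0.03 μm² mask intersection (inclusive)."""
    pre = make_puncta(rect_labels((64, 64), [(0, 10, 32, 37)]))
    post = make_puncta(rect_labels((64, 64), [(0, n_px, 32, 33)]))
    roi = half_plane_roi()
    calls = call_synapses(
        pre, post,
        classify_puncta(make_puncta(pre.label_map), roi, role="pre"),
        # force-classify the post punctum as cluster for this geometric test
        [type(c)(c.id, "cluster", c.inside_fraction, c.band_overlap, c.area_um2)
         for c in classify_puncta(make_puncta(post.label_map), roi)],
    )
    assert len(calls) == expected_calls
    if expected_calls:
        assert calls[0].overlap_area == pytest.approx(n_px * 0.01)


def test_best_match_prefers_larger_overlap():
    # one pre particle overlapping two post particles by 6 and 4 px
    pre = make_puncta(rect_labels((32, 32), [(0, 10, 10, 12)]))
    post_lm = np.zeros((32, 32), dtype=np.int32)
    post_lm[0:6, 11:12] = 1  # 6 px overlap with pre
    post_lm[6:10, 10:11] = 2  # 4 px overlap
    post = make_puncta(post_lm)
    calls = call_synaptosomes(pre, post, min_overlap=0.03)
    assert len(calls) == 1
    assert (calls[0].pre_id, calls[0].post_id) == (1, 1)
    all_calls = call_synaptosomes(pre, post, min_overlap=0.03, mode="all_pairs")
    assert len(all_calls) == 2


def test_synaptosome_pairing_matches_brute_force_oracle(rng):
    for _ in range(8):
        a = random_label_map(rng, n_blobs=5)
        b = random_label_map(rng, n_blobs=5)
        pre, post = make_puncta(a), make_puncta(b)
        got = [(c.pre_id, c.post_id, c.overlap_area) for c in call_synaptosomes(pre, post)]
        want = all_pairs_best_match(a, b, 0.01, 0.03)
        assert len(got) == len(want)
        for (gi, gj, ga), (wi, wj, wa) in zip(got, want):
            assert gi == wi and ga == pytest.approx(wa, abs=1e-12)


def test_pairwise_overlaps_exact_on_random_fields(rng):
    a = random_label_map(rng)
    b = random_label_map(rng)
    overlaps = pairwise_overlap_areas(make_puncta(a), make_puncta(b))
    for (ia, ib), area in overlaps.items():
        assert area == pixel_overlap_area(a, ia, b, ib, PX**2)


def test_disjoint_fields_and_empty_inputs_give_no_calls():
    pre = make_puncta(rect_labels((32, 32), [(0, 5, 0, 5)]))
    post = make_puncta(rect_labels((32, 32), [(20, 25, 20, 25)]))
    assert call_synaptosomes(pre, post) == []
    empty = make_puncta(np.zeros((32, 32), dtype=np.int32))
    assert call_synaptosomes(empty, empty) == []


def test_calls_non_increasing_in_min_overlap(rng):
    a, b = random_label_map(rng), random_label_map(rng)
    pre, post = make_puncta(a), make_puncta(b)
    counts = [len(call_synaptosomes(pre, post, min_overlap=m)) for m in (0.01, 0.03, 0.1)]
    assert counts == sorted(counts, reverse=True)


def test_pairing_stable_under_label_permutation(rng):
    a, b = random_label_map(rng, n_blobs=5), random_label_map(rng, n_blobs=5)
    perm = rng.permutation(int(a.max())) + 1
    a_perm = np.zeros_like(a)
    a_perm[a > 0] = perm[a[a > 0] - 1]
    base = call_synaptosomes(make_puncta(a), make_puncta(b))
    permuted = call_synaptosomes(make_puncta(a_perm), make_puncta(b))
    assert sorted(round(c.overlap_area, 9) for c in base) == sorted(
        round(c.overlap_area, 9) for c in permuted
    )


# ---------------------------------------------------------------- summaries


def test_summarize_cell_density_arithmetic():
    roi = half_plane_roi()
    roi.perimeter_length = 50.0
    pre = rect_labels((64, 64), [(0, 10, 32, 33)])
    cls_pre = classify_puncta(make_puncta(pre), roi, role="pre")
    calls = [object()] * 0
    rep = summarize_cell([], cls_pre, [], roi)
    assert rep.synapse_density == 0.0
    assert rep.mean_cluster_area is None
    from synquant.synapses import SynapseCall

    calls = [SynapseCall(1, 1, 0.05) for _ in range(10)]
    rep = summarize_cell(calls, cls_pre, [], roi)
    assert rep.synapse_density == pytest.approx(10 / 50.0)


def test_density_denominator_scales_with_pixel_size():
    roi1 = half_plane_roi()
    roi2 = half_plane_roi(px=0.2)
    roi2.perimeter_length = 2 * roi1.perimeter_length
    from synquant.synapses import SynapseCall

    calls = [SynapseCall(1, 1, 0.05)]
    d1 = summarize_cell(calls, [], [], roi1).synapse_density
    d2 = summarize_cell(calls, [], [], roi2).synapse_density
    assert d2 == pytest.approx(d1 / 2)


def test_zero_length_roi_rejected():
    roi = half_plane_roi()
    roi.perimeter_length = 0.0
    with pytest.raises(ValueError):
        summarize_cell([], [], [], roi)


# ------------------------------------------------------- intensity & counts


def test_synaptosome_intensity_union_semantics():
    pre = make_puncta(rect_labels((32, 32), [(0, 10, 10, 12)]))  # 20 px
    post = make_puncta(rect_labels((32, 32), [(0, 6, 11, 13)]))  # 12 px, 6 shared
    calls = call_synaptosomes(pre, post)
    assert len(calls) == 1
    img = CalibratedImage(np.full((1, 32, 32), 7.0), PX, ["meas"])
    out = synaptosome_intensity(img, "meas", calls, pre, post, region="union")
    union_px = 20 + 12 - 6
    assert out[0].measured_intensity == pytest.approx(7.0 * union_px)
    inter = synaptosome_intensity(img, "meas", calls, pre, post, region="intersection")
    assert inter[0].measured_intensity == pytest.approx(7.0 * 6)
    # union = pre + post − intersection, on any channel
    rng = np.random.default_rng(1)
    chan = CalibratedImage(rng.uniform(0, 9, (1, 32, 32)), PX, ["meas"])
    u = synaptosome_intensity(chan, "meas", calls, pre, post, "union")[0].measured_intensity
    i = synaptosome_intensity(chan, "meas", calls, pre, post, "intersection")[0].measured_intensity
    s_pre = chan.channel("meas")[pre.label_map == 1].sum()
    s_post = chan.channel("meas")[post.label_map == 1].sum()
    assert u == pytest.approx(s_pre + s_post - i)
    zero = CalibratedImage(np.zeros((1, 32, 32)), PX, ["meas"])
    assert synaptosome_intensity(zero, "meas", calls, pre, post)[0].measured_intensity == 0.0


def test_intensity_histogram_properties(rng):
    freq, edges = intensity_histogram(np.array([5.0]), n_bins=4, value_range=(0, 10))
    assert freq.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.count_nonzero(freq) == 1
    vals = rng.uniform(0, 1, 10_000)
    freq, _ = intensity_histogram(vals, n_bins=10, value_range=(0, 1))
    # each bin ≈ 1/10 within ~4σ binomial error
    assert np.all(np.abs(freq - 0.1) < 4 * np.sqrt(0.1 * 0.9 / 10_000))
    assert freq.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        intensity_histogram(np.array([]), 4)


def test_rna_particle_counting_inclusive_at_half():
    roi = half_plane_roi()
    lm = np.zeros((64, 64), dtype=np.int32)
    # 5 fully inside, 3 fully outside
    for i in range(5):
        lm[i * 4 : i * 4 + 2, 2:4] = i + 1
    for i in range(3):
        lm[i * 4 : i * 4 + 2, 50:52] = 6 + i
    # one exactly half inside (cols 31–32)
    lm[40:42, 31:33] = 9
    assert count_rna_particles(make_puncta(lm), roi) == 6  # 5 + the half-in one
    assert count_rna_particles(make_puncta(lm), roi, min_inside_fraction=0.51) == 5


def test_rna_counts_match_pixel_oracle_on_random_fields(rng):
    roi = half_plane_roi()
    for _ in range(5):
        lm = random_label_map(rng)
        expected = 0
        for pid in range(1, lm.max() + 1):
            m = lm == pid
            if np.count_nonzero(m & roi.mask) / np.count_nonzero(m) >= 0.5:
                expected += 1
        assert count_rna_particles(make_puncta(lm), roi) == expected
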
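"""Otsu thresholding, animal detection, body/tail splitting and QC."""

import numpy as np
import pytest

from thermosih.segmentation import (
    NoAnimalError,
    QCResult,
    SegmentationError,
    SegmentationParams,
    dice_coefficient,
    otsu_threshold,
    qc_frame,
    segment_animal,
    split_body_tail_auto,
    split_body_tail_roi,
)
from thermosih.synthetic import DistractorSpec, random_phantom, render_phantom
from thermosih.thermal_io import ThermalFrame

from conftest import make_phantom


def otsu_oracle(values, bin_width=0.1):
    """Exhaustive scan over the histogram, one explicit split at a time.

    Shares only the histogram definition (min-anchored bin centres) with the
    implementation; class weights, means and the between-class variance are
    recomputed from scratch per split rather than via cumulative sums.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo = v.min()
    nbins = max(1, int(np.ceil((v.max() - lo + bin_width / 2) / bin_width)))
    edges = lo - bin_width / 2 + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    scores = []
    for split in range(1, nbins):  # class 0 = bins [0, split)
        n0 = counts[:split].sum()
        n1 = counts[split:].sum()
        if n0 == 0 or n1 == 0:
            scores.append(-np.inf)
            continue
        w0 = n0 / total
        w1 = n1 / total
        mu0 = float((counts[:split] * centers[:split]).sum() / n0)
        mu1 = float((counts[split:] * centers[split:]).sum() / n1)
        scores.append(w0 * w1 * (mu0 - mu1) ** 2)
    scores = np.asarray(scores)
    best = int(np.argmax(scores))
    tol = 1e-9 * max(abs(scores[best]), 1.0)
    first = best
    while first > 0 and scores[first - 1] >= scores[best] - tol:
        first -= 1
    last = best
    while last < scores.size - 1 and scores[last + 1] >= scores[best] - tol:
        last += 1
    cand = edges[1:nbins]
    return float((cand[first] + cand[last]) / 2)


def test_two_class_plateau_midpoint():
    # 100 px at 21 and 100 at 29 degC: every edge between the classes ties,
    # so the threshold is the midpoint of the gap.
    assert otsu_threshold([21.0] * 100 + [29.0] * 100, 0.1) == pytest.approx(25.0)


def test_constant_input_has_no_threshold():
    with pytest.raises(SegmentationError, match="constant"):
        otsu_threshold(np.full(200, 22.0))


def test_trimodal_matches_oracle():
    rng = np.random.default_rng(2)
    v = np.concatenate(
        [rng.normal(21, 0.1, 600), rng.normal(24, 0.1, 50), rng.normal(29, 0.1, 350)]
    )
    assert otsu_threshold(v) == pytest.approx(otsu_oracle(v), abs=1e-9)


def test_otsu_matches_exhaustive_oracle_on_random_histograms():
    rng = np.random.default_rng(7)
    for _ in range(200):
        k = rng.integers(2, 4)
        parts = [
            rng.normal(rng.uniform(5, 45), rng.uniform(0.05, 2.0), rng.integers(20, 400))
            for _ in range(k)
        ]
        v = np.clip(np.concatenate(parts), 0.0, 50.0)
        if np.ptp(np.round(v, 1)) == 0:
            continue
        assert otsu_threshold(v) == pytest.approx(otsu_oracle(v), abs=1e-9)


def test_threshold_shift_equivariant():
    rng = np.random.default_rng(9)
    v = np.concatenate([rng.normal(21, 0.3, 500), rng.normal(29, 0.5, 200)])
    base = otsu_threshold(v)
    assert otsu_threshold(v + 4.25) == pytest.approx(base + 4.25, abs=1e-9)


def test_noise_free_phantom_segmented_exactly(clean_phantom):
    _, frame, truth = clean_phantom
    mask = segment_animal(frame)
    assert np.array_equal(mask.animal, truth.animal)


def test_uniform_frame_has_no_animal():
    frame = ThermalFrame(np.full((32, 32), 21.0))
    with pytest.raises(SegmentationError):
        segment_animal(frame)


def test_largest_component_wins():
    px = np.full((64, 64), 21.0)
    px[8:12, 8:12] = 29.0      # 16 px blob
    px[30:42, 30:42] = 29.0    # 144 px blob
    mask = segment_animal(ThermalFrame(px), SegmentationParams(min_animal_px=10))
    assert mask.animal[35, 35] and not mask.animal[9, 9]


def test_warm_distractor_ignored_by_largest_component_rule(rng):
    spec = random_phantom(
        rng,
        texture_amplitude=0.0,
        sensor_noise_sd=0.0,
        distractor=DistractorSpec(center=(15.0, 140.0), radius=6.0, temp_c=28.0),
    )
    frame, truth = render_phantom(spec, rng)
    mask = segment_animal(frame)
    assert np.array_equal(mask.animal, truth.animal)


def test_labels_partition_frame(clean_phantom):
    _, frame, truth = clean_phantom
    mask = split_body_tail_auto(segment_animal(frame), frame)
    counts = np.bincount(mask.labels.ravel(), minlength=3)
    assert counts.sum() == frame.pixels.size
    assert (mask.body & mask.tail).sum() == 0


def test_body_tail_split_matches_ground_truth():
    """Noise<=0.1 degC phantoms: Dice(body)>=0.95 and Dice(tail)>=0.90 on 30 poses."""
    for seed in range(30):
        _, frame, truth = make_phantom(1000 + seed, sensor_noise_sd=0.05)
        mask = split_body_tail_auto(segment_animal(frame), frame)
        assert dice_coefficient(mask.body, truth.body) >= 0.95
        assert dice_coefficient(mask.tail, truth.tail) >= 0.90


def test_body_and_tail_form_single_component(clean_phantom):
    from skimage import measure as skmeasure

    _, frame, _ = clean_phantom
    mask = split_body_tail_auto(segment_animal(frame), frame)
    assert skmeasure.label(mask.animal, connectivity=2).max() == 1


def test_blob_without_appendage_has_no_tail():
    px = np.full((64, 64), 20.0)
    rr, cc = np.mgrid[0:64, 0:64]
    px[(rr - 32) ** 2 + (cc - 32) ** 2 <= 144] = 29.0
    frame = ThermalFrame(px)
    mask = split_body_tail_auto(segment_animal(frame), frame)
    assert not mask.tail.any()
    assert "no_tail" in mask.flags


def test_body_labels_invariant_to_tail_erasure(rng):
    seed = 424
    spec_rng = np.random.default_rng(seed)
    spec = random_phantom(spec_rng, texture_amplitude=0.0, sensor_noise_sd=0.0)
    frame, _ = render_phantom(spec, np.random.default_rng(1))
    import dataclasses

    bare = dataclasses.replace(spec, tail_points=(), tail_half_widths=())
    frame2, _ = render_phantom(bare, np.random.default_rng(1))
    m1 = split_body_tail_auto(segment_animal(frame), frame)
    m2 = split_body_tail_auto(segment_animal(frame2), frame2)
    assert np.array_equal(m1.body, m2.body)


def test_roi_split_recovers_tail(clean_phantom):
    spec, frame, truth = clean_phantom
    rows, cols = np.where(truth.tail)
    box = (
        int(rows.min()) - 2,
        int(cols.min()) - 2,
        int(np.ptp(rows)) + 5,
        int(np.ptp(cols)) + 5,
    )
    mask = segment_animal(frame)
    out = split_body_tail_roi(mask, frame, box)
    inbox = np.zeros_like(truth.tail)
    inbox[box[0] : box[0] + box[2], box[1] : box[1] + box[3]] = True
    assert np.array_equal(out.tail, truth.animal & inbox)


def test_roi_in_background_flags_empty_tail(clean_phantom):
    _, frame, truth = clean_phantom
    mask = segment_animal(frame)
    out = split_body_tail_roi(mask, frame, (0, 0, 5, 5))
    assert not out.tail.any() and "empty_tail" in out.flags


def test_roi_covering_whole_frame_rejected(clean_phantom):
    _, frame, _ = clean_phantom
    mask = segment_animal(frame)
    with pytest.raises(SegmentationError, match="exclude the body"):
        split_body_tail_roi(mask, frame, (0, 0, frame.height, frame.width))


def test_qc_flags_border_clip(rng):
    spec = random_phantom(rng, texture_amplitude=0.0, sensor_noise_sd=0.0)
    import dataclasses

    h = spec.shape[0]
    clipped = dataclasses.replace(
        spec, body_center=(1.0, spec.body_center[1]), tail_points=(), tail_half_widths=(),
        allow_border_clip=True,
    )
    frame, _ = render_phantom(clipped, rng)
    mask = segment_animal(frame)
    qc = qc_frame(mask, session_median_area=mask.animal_pixel_count, require_tail=False)
    assert not qc.usable and "touches_border" in qc.reasons


def test_qc_flags_rearing_occlusion(rng):
    import dataclasses

    spec = random_phantom(rng, texture_amplitude=0.0, sensor_noise_sd=0.0)
    frame_full, truth_full = render_phantom(spec, rng)
    occluded = dataclasses.replace(spec, occlusion_fraction=0.6)
    frame, _ = render_phantom(occluded, rng)
    mask = split_body_tail_auto(segment_animal(frame), frame)
    qc = qc_frame(mask, session_median_area=truth_full.animal_pixel_count, require_tail=False)
    assert not qc.usable and "area_out_of_range" in qc.reasons


def test_qc_passes_normal_phantom(clean_phantom):
    _, frame, _ = clean_phantom
    mask = split_body_tail_auto(segment_animal(frame), frame)
    qc = qc_frame(mask, session_median_area=mask.animal_pixel_count, require_tail=True)
    assert qc.usable and not qc.reasons


def test_qc_result_consistency_enforced():
    with pytest.raises(ValueError):
        QCResult(usable=True, reasons=frozenset({"touches_border"}))
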
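"""End-to-end validation checks with independent reference oracles.

Each function runs one of the package's pipelines on synthetic data with
known ground truth (or on closed-form fixtures) and measures how well the
result matches an *independent* reference: a brute-force state machine for
entry detection, supersampled pixel counting for polygon overlap, an
exhaustive nearest-pixel scan for label propagation, hand-derived closed
forms for the scalar formulas. These are the checks behind the package's
correctness claims; the test suite asserts on their outputs and
``scripts/acceptance.py`` reports them.

All randomness flows from an explicit seed argument.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import stats as sstats
from shapely.geometry import Polygon

from . import (
    BehaviorSimConfig,
    BehaviorTrack,
    HistoSimConfig,
    PhotometrySimConfig,
    QCThresholds,
    Roi,
    SegmenterSpec,
    apply_qc_filters,
    assign_rois_to_regions,
    classify_double_positive,
    compute_morphometrics,
    auc_linear,
    deinterleave,
    detect_entries,
    detrend_baseline,
    discrimination_ratio,
    lowpass_filter,
    measure_intensity,
    median_filter,
    overlap_records,
    polygon_overlap_metrics,
    preprocess_session,
    robust_zscore,
    segment,
    simulate_behavior_track,
    simulate_histology_image,
    simulate_photometry_session,
    simulate_place_modulated_session,
    summarize_counts,
    tophat,
)
from .behavior import CENTER, COCAINE, SALINE
from .photometry import ChannelTrace
from .regions import process_region_mask, propagate_labels

__all__ = [
    "discrimination_direction_check",
    "entry_rule_check",
    "formula_exactness_check",
    "histology_recovery_check",
    "normalization_chain_check",
    "overlap_oracle_check",
    "qc_cascade_check",
    "region_propagation_check",
]


# --------------------------------------------------------------------------
# photometry normalization (synthetic sessions, known artifact & transients)
# --------------------------------------------------------------------------


def normalization_chain_check(n_sessions: int = 20, seed: int = 0) -> dict:
    """Motion rejection and transient recovery over seeded synthetic sessions.

    Each session: 60 s at 78 Hz total, motion amplitude 0.2, five transients
    with per-session amplitudes. Returns the artifact-variance reduction of
    z(dF/F) relative to the standardized 470 trace (percent, worst session)
    and the Pearson r between injected and recovered transient peak
    amplitudes pooled across sessions.
    """
    rng = np.random.default_rng(seed)
    reductions, injected, recovered = [], [], []
    for k in range(n_sessions):
        amps = rng.uniform(0.02, 0.10, 5)
        cfg = PhotometrySimConfig(
            duration_s=60.0,
            seed=int(rng.integers(2**31 - 1)),
            transient_times_s=(8.0, 19.0, 30.0, 41.0, 52.0),
            transient_amplitude=tuple(amps),
            transient_decay_s=0.5,
            motion_amplitude=0.2,
            motion_events_s=tuple(rng.uniform(2, 58, 8)),
            noise_sd=0.002,
        )
        session, gt = simulate_photometry_session(cfg)
        traces = deinterleave(session)
        z470 = robust_zscore(detrend_baseline(lowpass_filter(traces["470"])))
        zdff = preprocess_session(session)
        g = gt.extras["motion_470"][: len(zdff.zdff)]
        r2_raw = sstats.pearsonr(z470.values[: len(g)], g)[0] ** 2
        r2_dff = sstats.pearsonr(zdff.zdff, g)[0] ** 2
        reductions.append(100.0 * (1.0 - r2_dff / r2_raw))
        # injected amplitude in absolute fluorescence units (fraction of the
        # instantaneous baseline times the bleach envelope at onset)
        for t0, a in zip(gt.transients["time_s"],
                         gt.transients["amplitude_au"]):
            sel = (zdff.time_s >= t0) & (zdff.time_s <= t0 + 0.6)
            injected.append(a)
            recovered.append(zdff.zdff[sel].max())
    r = sstats.pearsonr(injected, recovered)[0]
    return {
        "artifact_rejection_pct": float(min(reductions)),
        "artifact_rejection_pct_mean": float(np.mean(reductions)),
        "transient_amplitude_r": float(r),
        "n_sessions": n_sessions,
    }


# --------------------------------------------------------------------------
# scalar formula exactness (hand-derived oracles)
# --------------------------------------------------------------------------


def formula_exactness_check(seed: int = 0) -> dict:
    """Robust z-score and trapezoidal AUC against hand-derived values."""
    t5 = np.arange(5) / 26.0
    z = robust_zscore(ChannelTrace(t5, [1, 2, 3, 4, 5], "470")).values
    hand = np.array([-2, -1, 0, 1, 2]) / 1.4826
    zscore_err = float(np.max(np.abs(z - hand)))

    rng = np.random.default_rng(seed)
    med_worst, mad_worst = 0.0, 0.0
    for _ in range(100):
        x = rng.standard_normal(rng.integers(20, 500)) * rng.uniform(0.1, 30)
        zz = robust_zscore(
            ChannelTrace(np.arange(len(x), dtype=float), x, "470")).values
        med_worst = max(med_worst, abs(float(np.median(zz))))
        mad_worst = max(
            mad_worst,
            abs(1.4826 * float(np.median(np.abs(zz - np.median(zz)))) - 1.0),
        )

    t = np.linspace(0.0, 1.0, 53)
    ramp_err = abs(auc_linear(t, t, (0.0, 1.0)).value - 0.5) / 0.5
    t3 = np.linspace(0.0, 3.0, 79)
    const_err = abs(auc_linear(t3, np.full_like(t3, 2.0), (0.0, 3.0)).value
                    - 6.0) / 6.0
    return {
        "zscore_max_abs_error": zscore_err,
        "zscore_median_worst": float(med_worst),
        "zscore_mad_worst_error": float(mad_worst),
        "auc_closed_form_rel_error": float(max(ramp_err, const_err)),
    }


# --------------------------------------------------------------------------
# entry rule vs brute-force state machine
# --------------------------------------------------------------------------


def _reference_entries(labels, min_run_frames=2):
    """Brute-force oracle: group, debounce, re-merge, then scan triples."""
    groups = []
    for lab in labels:
        if groups and groups[-1][0] == lab:
            groups[-1][1] += 1
        else:
            groups.append([lab, 1])
    survivors = [g for g in groups if g[1] >= min_run_frames]
    merged = []
    for lab, n in survivors:
        if merged and merged[-1][0] == lab:
            merged[-1][1] += n
        else:
            merged.append([lab, n])
    out = []
    for k in range(1, len(merged)):
        lab = merged[k][0]
        if lab not in (SALINE, COCAINE):
            continue
        opposite = SALINE if lab == COCAINE else COCAINE
        full = (merged[k - 1][0] == CENTER and k >= 2
                and merged[k - 2][0] == opposite)
        out.append((lab, merged[k - 1][0], full))
    return out


def entry_rule_check(n_sequences: int = 1000, seed: int = 0) -> dict:
    """Exact agreement of detect_entries with the brute-force oracle."""
    rng = np.random.default_rng(seed)
    alphabet = np.array([SALINE, CENTER, COCAINE, "unknown"], dtype=object)
    agree = 0
    for _ in range(n_sequences):
        labels = rng.choice(alphabet, size=rng.integers(1, 80))
        track = BehaviorTrack(np.arange(len(labels)) / 25.0, labels, 25.0)
        got = [(e.destination, e.origin, e.is_full_transition)
               for e in detect_entries(track)]
        agree += got == _reference_entries(list(labels))
    return {"entry_rule_agreement": agree / n_sequences,
            "n_sequences": n_sequences}


# --------------------------------------------------------------------------
# polygon overlap vs supersampled rasterization
# --------------------------------------------------------------------------


def _supersampled_intersection(pa: Polygon, pb: Polygon, step: float = 0.1):
    x0 = min(pa.bounds[0], pb.bounds[0]) - step
    y0 = min(pa.bounds[1], pb.bounds[1]) - step
    x1 = max(pa.bounds[2], pb.bounds[2]) + step
    y1 = max(pa.bounds[3], pb.bounds[3]) + step
    xs = np.arange(x0, x1, step)
    ys = np.arange(y0, y1, step)
    gx, gy = np.meshgrid(xs, ys)
    inside = (shapely.contains_xy(pa, gx.ravel(), gy.ravel())
              & shapely.contains_xy(pb, gx.ravel(), gy.ravel()))
    return float(inside.sum()) * step * step


def _random_blob(rng, center, mean_radius, n=24):
    ang = 2 * np.pi * np.arange(n) / n
    radii = mean_radius * rng.uniform(0.8, 1.2, n)
    return Polygon(np.column_stack([center[0] + radii * np.cos(ang),
                                    center[1] + radii * np.sin(ang)]))


def overlap_oracle_check(n_pairs: int = 200, seed: int = 0) -> dict:
    """Exact polygon overlap vs 10x-supersampled pixel counting.

    Reports the worst relative error over substantial overlaps (absolute
    error for sliver intersections below 20 px) and the closed-form
    unit-square offset case (IoU must be exactly 1/3).
    """
    rng = np.random.default_rng(seed)
    worst_rel = 0.0
    checked = 0
    while checked < n_pairs:
        c = rng.uniform(10, 40, 2)
        a = _random_blob(rng, c, rng.uniform(5.5, 9))
        b = _random_blob(rng, c + rng.uniform(-4, 4, 2), rng.uniform(5.5, 9))
        if a.area < 80 or b.area < 80:
            continue
        exact = polygon_overlap_metrics(a, b).intersection_area_px
        oracle = _supersampled_intersection(a, b)
        if oracle >= 20:
            worst_rel = max(worst_rel, abs(exact - oracle) / oracle)
        checked += 1
    sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
    sq_off = Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)])
    iou = polygon_overlap_metrics(sq, sq_off).iou
    return {
        "overlap_oracle_max_rel_error_pct": 100.0 * worst_rel,
        "unit_square_offset_iou": float(iou),
        "n_pairs": n_pairs,
    }


# --------------------------------------------------------------------------
# QC cascade: enumerated keep/reject set and monotonicity
# --------------------------------------------------------------------------


def _qc_roi(channel="gfp", **fields):
    base = dict(circularity=0.9, aspect_ratio=1.2, solidity=0.95,
                area_px=300.0, median_interior=120.0, mean_interior=120.0,
                median_background=5.0, mean_background=5.0)
    base.update(fields)
    roi = Roi(polygon=[(0, 0), (10, 0), (10, 10), (0, 10)], channel=channel)
    for k, v in base.items():
        setattr(roi, k, v)
    return roi


def qc_cascade_check(seed: int = 0) -> dict:
    """Engineered one-rule-per-ROI table plus threshold monotonicity."""
    rois = [
        _qc_roi(),
        _qc_roi(circularity=0.35),
        _qc_roi(aspect_ratio=3.5),
        _qc_roi(solidity=0.5),
        _qc_roi(area_px=50.0),
        _qc_roi(area_px=1500.0),
        _qc_roi(median_interior=8.0, mean_interior=8.0),
        _qc_roi(channel="fos", mean_interior=15.0, median_interior=15.0,
                mean_background=12.0, median_background=12.0),
    ]
    kept, rejected = apply_qc_filters(rois)
    expected_reasons = ["circularity", "aspect_ratio", "solidity",
                        "area_below_min", "area_above_max",
                        "median_intensity", "signal_above_background"]
    exact = (kept == [rois[0]]
             and [r.qc_reason for r in rejected] == expected_reasons)

    rng = np.random.default_rng(seed)
    pool = [
        _qc_roi(
            channel=str(rng.choice(["fos", "gfp"])),
            circularity=float(rng.uniform(0.2, 1.0)),
            aspect_ratio=float(rng.uniform(1.0, 5.0)),
            solidity=float(rng.uniform(0.3, 1.0)),
            area_px=float(rng.uniform(20, 1500)),
            median_interior=float(rng.uniform(0, 50)),
            mean_interior=float(rng.uniform(0, 50)),
            mean_background=float(rng.uniform(0, 20)),
        )
        for _ in range(200)
    ]
    baseline = len(apply_qc_filters(pool, QCThresholds())[0])
    relaxations = [
        QCThresholds(circularity_min=0.2),
        QCThresholds(aspect_ratio_max=5.0),
        QCThresholds(solidity_min=0.4),
        QCThresholds(area_min_px=10.0),
        QCThresholds(area_max_px=2000.0),
        QCThresholds(median_intensity_min=5.0),
        QCThresholds(fos_signal_above_bg_min=1.0),
    ]
    monotone = all(
        len(apply_qc_filters(pool, thr)[0]) >= baseline for thr in relaxations
    )
    return {"qc_cascade_exact_match": float(exact),
            "qc_monotone_relaxation": float(monotone)}


# --------------------------------------------------------------------------
# region propagation vs exhaustive nearest-pixel scan
# --------------------------------------------------------------------------


def _reference_propagation(labels, max_gap_px):
    out = labels.copy()
    labs = sorted(int(v) for v in np.unique(labels) if v > 0)
    coords = {l: np.argwhere(labels == l) for l in labs}
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if labels[r, c] != 0:
                continue
            best_lab, best_d = 0, np.inf
            for l in labs:
                d = np.sqrt(((coords[l] - [r, c]) ** 2).sum(axis=1).min())
                if d < best_d:
                    best_lab, best_d = l, d
            if best_d <= max_gap_px:
                out[r, c] = best_lab
    return out


def region_propagation_check(seed: int = 0) -> dict:
    """Gap fill vs brute force, distance cap, artifact floor, idempotence."""
    px = 0.3785
    # exact match to the exhaustive scan on a two-region gap mask
    raw = np.zeros((40, 120), dtype=int)
    raw[5:35, 0:30] = 1
    raw[5:35, 90:120] = 2
    got = propagate_labels(raw, max_gap_px=100)
    exact = bool((got == _reference_propagation(raw, 100)).all())

    # pixels beyond the cap stay unlabeled (150 px away from any label)
    far = np.zeros((30, 400), dtype=int)
    far[:, :60] = 1
    out_far = propagate_labels(far, max_gap_px=100)
    cap_ok = bool((out_far[:, 60:160] == 1).all()
                  and (out_far[:, 161:] == 0).all())

    # a 1000 um^2 artifact is removed by the 2000 um^2 floor
    from .simulate import make_region_mask_fixture

    rm = make_region_mask_fixture(
        [("big", (0, 0, 200, 150))], (200, 600), px,
        artifacts=[("spurious", (100, 520), 1000.0)])
    processed = process_region_mask(rm.labels, px, names=rm.names,
                                    use_concave_hull=False)
    artifact_removed = "spurious" not in [
        processed.name(l) for l in processed.region_labels()]

    # idempotence on a gap-style mask
    rm2 = make_region_mask_fixture(
        [("A", (0, 0, 200, 170)), ("B", (0, 220, 200, 400))], (200, 400), px)
    once = process_region_mask(rm2.labels, px, use_concave_hull=False)
    twice = process_region_mask(once.labels, px, use_concave_hull=False)
    idempotent = bool((once.labels == twice.labels).all())

    return {
        "propagation_matches_brute_force": float(exact),
        "propagation_respects_cap": float(cap_ok),
        "artifact_region_removed": float(artifact_removed),
        "propagation_idempotent": float(idempotent),
    }


# --------------------------------------------------------------------------
# end-to-end histology recovery
# --------------------------------------------------------------------------


def run_histology_pipeline(image, pixel_size_um=0.3785, threshold=50):
    """Preprocess, segment, QC-filter and measure both channels."""
    rois = {}
    for role, ch in (("fos", 0), ("gfp", 1)):
        pre = median_filter(tophat(image[ch]))
        candidates = segment(pre, SegmenterSpec(threshold=threshold))
        for r in candidates:
            r.channel = role
            compute_morphometrics(r)
            measure_intensity(r, pre, all_rois=candidates)
        kept, _ = apply_qc_filters(candidates)
        rois[role] = kept
    return rois


def histology_recovery_check(seed: int = 0) -> dict:
    """Noiseless two-channel image: double-positive proportion and recall."""
    cfg = HistoSimConfig(n_gfp_cells=50, coloc_fraction=0.4,
                         fos_only_cells=10, seed=seed)
    image, region_map, gt = simulate_histology_image(cfg)
    rois = run_histology_pipeline(image)
    records = overlap_records(rois["fos"], rois["gfp"])
    double = classify_double_positive(records)
    assign_rois_to_regions(rois["gfp"], region_map)
    assign_rois_to_regions(rois["fos"], region_map)
    tally = summarize_counts(rois["gfp"], rois["fos"], double,
                             region_map).table
    n_gfp = int(tally.n_gfp.sum())
    n_double = int(tally.n_double_positive.sum())
    recall = n_gfp / cfg.n_gfp_cells
    proportion = n_double / n_gfp if n_gfp else float("nan")
    return {
        "double_positive_proportion": proportion,
        "gfp_cell_recall": recall,
        "n_gfp_detected": n_gfp,
        "n_double_detected": n_double,
    }


# --------------------------------------------------------------------------
# directional CPP photometry effect
# --------------------------------------------------------------------------


def discrimination_direction_check(n_seeds: int = 100, seed: int = 0) -> dict:
    """Post-test-only cocaine-side suppression lowers the Coc/Sal AUC Ratio.

    20-minute pre/post sessions; transients Poisson at 0.5 Hz with amplitude
    halved in the cocaine compartment post-test only. Reports the fraction
    of seeds with post-test ratio below pre-test ratio.
    """
    rng = np.random.default_rng(seed)
    base = PhotometrySimConfig(noise_sd=0.002, bleach_tau_s=3000.0)
    wins = 0
    for _ in range(n_seeds):
        sub = int(rng.integers(2**31 - 1))
        ratios = {}
        for phase, coc_scale in (("pretest", 1.0), ("posttest", 0.5)):
            track, _ = simulate_behavior_track(
                BehaviorSimConfig(seed=sub + (phase == "posttest"),
                                  duration_s=1200.0, mean_dwell_s=20.0,
                                  phase=phase))
            session, _ = simulate_place_modulated_session(
                track, {"cocaine": coc_scale}, transient_rate_hz=0.5,
                base_amplitude=0.05, photometry_cfg=base,
                seed=(sub + 7) % (2**31 - 1))
            zdff = preprocess_session(session)
            ratios[phase] = discrimination_ratio(zdff, track).ratio
        wins += ratios["posttest"] < ratios["pretest"]
    return {"discrimination_direction_fraction": wins / n_seeds,
            "n_seeds": n_seeds}
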
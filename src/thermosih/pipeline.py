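"""End-to-end orchestration: simulate -> segment -> measure -> analyze.

The pipeline runs in two passes over a session's frames.  Pass one segments
every frame and records per-frame logs (threshold, animal area, tail flag);
the session median animal area is then known, so pass two applies quality
control, extracts region statistics from usable captures, aggregates the
captures per timepoint, and joins the PIT-tag readings into trial records.
No animal is silently dropped: every manifest animal appears in the output
either with values or with an exclusion reason in the frame log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from thermosih import measurement as meas
from thermosih import segmentation as seg
from thermosih import sih_stats as stats
from thermosih.thermal_io import (
    CalibrationDialect,
    FrameMeta,
    IRT_SCHEDULES,
    PIT_SCHEDULES,
    PitReading,
    ThermalFrame,
    TrialFactors,
    load_manifest,
    parse_pit_log,
    read_thermal_frame,
)
from thermosih.synthetic import ScenarioConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger(__name__)

# Fixed factors analyzed per behavioural test (period only varies in DH,
# drug treatment only applies to EPM).
ANALYSIS_FACTORS = {
    "DH": ("strain", "sex", "handling", "period"),
    "VIT": ("strain", "sex", "handling"),
    "EPM": ("strain", "sex", "handling", "drug"),
}


class PipelineError(RuntimeError):
    """Hard failure during an end-to-end run, with frame identity attached."""


@dataclass
class _FrameOutcome:
    meta: FrameMeta
    factors: TrialFactors
    threshold: Optional[float]
    area: int
    touches_border: bool
    tail_found: bool
    body_stats: Optional[meas.RegionStats]
    tail_stats: Optional[meas.RegionStats]
    error: str = ""
    qc_reasons: str = ""
    usable: bool = False


def _segment_one(
    frame: ThermalFrame,
    params: seg.SegmentationParams,
    tail_mode: str,
    roi: Optional[tuple[int, int, int, int]],
    split_tail: bool,
) -> tuple[Optional[seg.RegionMask], Optional[float], str]:
    try:
        threshold = seg.otsu_threshold(frame.pixels, params.bin_width)
        mask = seg.segment_animal(frame, params)
        if split_tail:
            if tail_mode == "roi":
                if roi is None:
                    raise seg.SegmentationError("tail_mode='roi' requires a tail box")
                mask = seg.split_body_tail_roi(mask, frame, roi)
            else:
                mask = seg.split_body_tail_auto(mask, frame, params)
        return mask, threshold, ""
    except seg.SegmentationError as exc:
        return None, None, str(exc)


def process_frames(
    records: Iterable[tuple[FrameMeta, TrialFactors, ThermalFrame]],
    pit: Sequence[PitReading] = (),
    params: seg.SegmentationParams = seg.SegmentationParams(),
    tail_mode: str = "auto",
    roi: Optional[tuple[int, int, int, int]] = None,
    require_tail: Optional[bool] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and measure a stream of frames; return (tidy table, frame log).

    ``require_tail`` defaults to True except for EPM sessions, whose imagery
    does not resolve the tail (it is neither split nor required there).
    """
    outcomes: list[_FrameOutcome] = []
    for meta, factors, frame in records:
        need_tail = require_tail if require_tail is not None else meta.test != "EPM"
        mask, threshold, error = _segment_one(frame, params, tail_mode, roi, split_tail=need_tail)
        if mask is None:
            outcomes.append(
                _FrameOutcome(
                    meta=meta, factors=factors, threshold=threshold, area=0,
                    touches_border=False, tail_found=False,
                    body_stats=None, tail_stats=None, error=error,
                )
            )
            log.info("frame %s: segmentation failed: %s", meta.key, error)
            continue
        body_stats = meas.region_stats(frame, mask, "body") if mask.body.any() else None
        tail_stats = meas.region_stats(frame, mask, "tail") if mask.tail.any() else None
        animal = mask.animal
        touches = bool(
            animal[0, :].any() or animal[-1, :].any() or animal[:, 0].any() or animal[:, -1].any()
        )
        outcomes.append(
            _FrameOutcome(
                meta=meta, factors=factors, threshold=threshold,
                area=mask.animal_pixel_count, touches_border=touches,
                tail_found=bool(mask.tail.any()),
                body_stats=body_stats, tail_stats=tail_stats,
            )
        )

    areas = [o.area for o in outcomes if o.area > 0]
    median_area = float(np.median(areas)) if areas else 0.0

    # pass two: QC with the session median area, then aggregate
    by_timepoint: dict[tuple, list[meas.CaptureResult]] = {}
    factors_by_trial: dict[tuple, TrialFactors] = {}
    for o in outcomes:
        need_tail = require_tail if require_tail is not None else o.meta.test != "EPM"
        if o.error:
            qc = seg.QCResult(usable=False, reasons=frozenset({"no_animal"}))
        else:
            reasons: set[str] = set()
            if o.touches_border:
                reasons.add("touches_border")
            if not 0.5 * median_area <= o.area <= 1.5 * median_area:
                reasons.add("area_out_of_range")
            if need_tail and not o.tail_found:
                reasons.add("no_tail_when_required")
            qc = seg.QCResult(usable=not reasons, reasons=frozenset(reasons))
        o.usable = qc.usable
        o.qc_reasons = ";".join(sorted(qc.reasons))
        tkey = o.meta.key[:4]  # (animal, test, trial, timepoint)
        by_timepoint.setdefault(tkey, []).append(
            meas.CaptureResult(body=o.body_stats, tail=o.tail_stats, qc=qc)
        )
        factors_by_trial[o.meta.key[:3]] = o.factors

    pit_by_trial: dict[tuple, list[PitReading]] = {}
    for reading in pit:
        pit_by_trial.setdefault(reading.key[:3], []).append(reading)

    trials: list[meas.TrialRecord] = []
    for trial_key, factors in factors_by_trial.items():
        tms = [
            meas.aggregate_timepoint(
                caps, animal_id=trial_key[0], test=trial_key[1],
                trial_index=trial_key[2], timepoint_s=tkey[3],
            )
            for tkey, caps in sorted(by_timepoint.items())
            if tkey[:3] == trial_key
        ]
        trials.append(meas.assemble_trial(tms, pit_by_trial.get(trial_key, []), factors))

    tidy = meas.trials_to_table(trials)
    frame_log = pd.DataFrame(
        [
            {
                "animal_id": o.meta.animal_id,
                "test": o.meta.test,
                "trial_index": o.meta.trial_index,
                "timepoint_s": o.meta.timepoint_s,
                "capture_idx": o.meta.capture_idx,
                "threshold_c": o.threshold,
                "animal_px": o.area,
                "usable": o.usable,
                "qc_reasons": o.qc_reasons,
                "error": o.error,
            }
            for o in outcomes
        ]
    )
    return tidy, frame_log


def process_manifest(
    manifest_path: str | Path,
    pit_path: Optional[str | Path] = None,
    dialect: CalibrationDialect = CalibrationDialect(),
    params: seg.SegmentationParams = seg.SegmentationParams(),
    tail_mode: str = "auto",
    roi: Optional[tuple[int, int, int, int]] = None,
    require_tail: Optional[bool] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segmentation + measurement over a file-backed session."""
    records = load_manifest(manifest_path)
    if not records:
        log.warning("empty manifest %s: producing empty measurement table", manifest_path)
        return (
            pd.DataFrame(columns=list(meas.TABLE_COLUMNS)),
            pd.DataFrame(
                columns=[
                    "animal_id", "test", "trial_index", "timepoint_s", "capture_idx",
                    "threshold_c", "animal_px", "usable", "qc_reasons", "error",
                ]
            ),
        )
    pit = parse_pit_log(pit_path) if pit_path is not None else []

    def stream():
        for rec in records:
            try:
                frame = read_thermal_frame(rec.frame_path, dialect, meta=rec.meta)
            except Exception as exc:
                raise PipelineError(f"frame {rec.frame_path} ({rec.meta.key}): {exc}") from exc
            yield rec.meta, rec.factors, frame

    return process_frames(stream(), pit, params, tail_mode=tail_mode, roi=roi, require_tail=require_tail)


def process_cohort(
    cohort: SyntheticCohort,
    params: seg.SegmentationParams = seg.SegmentationParams(),
    tail_mode: str = "auto",
    roi: Optional[tuple[int, int, int, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segmentation + measurement over an in-memory synthetic cohort."""
    pit = [
        PitReading(
            animal_id=row["animal_id"], test=row["test"], trial_index=int(row["trial_index"]),
            timepoint_s=int(row["timepoint_s"]),
            t_sc_c=float(row["t_sc_c"]) if row["t_sc_c"] != "" else None,
        )
        for trial in cohort.trials
        for row in trial.pit_rows
    ]

    def stream():
        for trial in cohort.trials:
            for fr in trial.frames:
                yield fr.meta, trial.factors, fr.frame

    require_tail = cohort.config.include_tail
    return process_frames(
        stream(), pit, params, tail_mode=tail_mode, roi=roi, require_tail=require_tail
    )


# --------------------------------------------------------------------------
# Analysis over the tidy table
# --------------------------------------------------------------------------


@dataclass
class ScenarioAnalysis:
    """Per-measure summaries plus between-animal and order analyses."""

    summaries: dict[str, stats.SihSummary]
    between_baseline: dict[str, stats.BetweenAnovaResult]
    between_delta: dict[str, stats.BetweenAnovaResult]
    order_contrasts: dict[tuple[str, int], stats.ContrastResult]


def analyze_measurements(
    tidy: pd.DataFrame,
    test: Optional[str] = None,
    factors: Optional[Sequence[str]] = None,
    measures: Optional[Sequence[str]] = None,
) -> ScenarioAnalysis:
    """Full statistical pass over a tidy measurement table."""
    if test is None:
        tests = tidy["test"].unique()
        if len(tests) != 1:
            raise stats.StatsError("table mixes behavioural tests; pass test explicitly")
        test = str(tests[0])
    if factors is None:
        factors = ANALYSIS_FACTORS[test]
    col_of = {"T_sc": "t_sc_c", "T_body": "t_body_c", "T_tail": "t_tail_c"}
    if measures is None:
        measures = [m for m, c in col_of.items() if tidy[c].notna().any()]

    summaries: dict[str, stats.SihSummary] = {}
    between_baseline: dict[str, stats.BetweenAnovaResult] = {}
    between_delta: dict[str, stats.BetweenAnovaResult] = {}
    order_contrasts: dict[tuple[str, int], stats.ContrastResult] = {}
    factor_cols = ["animal_id", "strain", "sex", "handling", "period", "drug", "testing_order"]
    per_animal_factors = tidy[factor_cols].drop_duplicates("animal_id")

    for measure in measures:
        summaries[measure] = stats.sih_summary(tidy, measure)
        wide, x = stats.measure_matrix(tidy, measure)
        per_animal = pd.DataFrame(
            {
                "animal_id": [idx[0] for idx in wide.index],
                "baseline": x[:, 0],
                "delta": x[:, -1] - x[:, 0],
                "animal_mean": x.mean(axis=1),
            }
        ).merge(per_animal_factors, on="animal_id")
        usable = [f for f in factors if per_animal[f].nunique() > 1]
        if usable:
            try:
                between_baseline[measure] = stats.between_anova(per_animal, "baseline", usable)
                between_delta[measure] = stats.between_anova(per_animal, "delta", usable)
            except stats.StatsError as exc:
                log.info("between-animal ANOVA skipped for %s: %s", measure, exc)
        tps = summaries[measure].timepoints
        if tidy["testing_order"].nunique() > 1:
            for t in tps:
                try:
                    order_contrasts[(measure, t)] = stats.testing_order_contrast(
                        tidy, measure, t, m_comparisons=len(tps)
                    )
                except stats.StatsError:
                    continue
    return ScenarioAnalysis(
        summaries=summaries,
        between_baseline=between_baseline,
        between_delta=between_delta,
        order_contrasts=order_contrasts,
    )


@dataclass
class ScenarioBundle:
    """Everything produced by one reproducible scenario run."""

    config: ScenarioConfig
    seed: int
    measurements: pd.DataFrame
    frame_log: pd.DataFrame
    analysis: ScenarioAnalysis
    cohort: Optional[SyntheticCohort] = None


def run_scenario(
    test: str,
    n_animals: int = 64,
    seed: int = 0,
    config: Optional[ScenarioConfig] = None,
    params: seg.SegmentationParams = seg.SegmentationParams(),
    outdir: Optional[str | Path] = None,
    keep_cohort: bool = False,
) -> ScenarioBundle:
    """Simulate a cohort, segment and measure it, and analyze the result.

    Deterministic given the seed.  When ``outdir`` is given the file-backed
    dataset, tidy table, frame log and summary tables are written there.
    """
    if config is None:
        config = ScenarioConfig(test=test, n_animals=n_animals)
    cohort = simulate_cohort(config, seed=seed)
    tidy, frame_log = process_cohort(cohort, params=params)
    analysis = analyze_measurements(tidy, test=config.test)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.write(outdir)
        tidy.to_csv(outdir / "measurements.csv", index=False)
        frame_log.to_csv(outdir / "frame_log.csv", index=False)
        _write_report(outdir / "report.txt", analysis, config, seed)
    return ScenarioBundle(
        config=config,
        seed=seed,
        measurements=tidy,
        frame_log=frame_log,
        analysis=analysis,
        cohort=cohort if keep_cohort or outdir is not None else None,
    )


def _write_report(path: Path, analysis: ScenarioAnalysis, config: ScenarioConfig, seed: int) -> None:
    lines = [f"scenario: {config.test}", f"n_animals: {config.n_animals}", f"seed: {seed}", ""]
    for measure, s in analysis.summaries.items():
        lines.append(f"[{measure}] n={s.n_animals}")
        for t in s.timepoints:
            m, lo, hi = s.means[t]
            lines.append(f"  t={t:3d} s  mean={m:7.3f} degC  95% CI ({lo:.3f}, {hi:.3f})")
        d, dlo, dhi = s.delta
        lines.append(f"  delta(last-first) = {d:+.3f} degC  95% CI ({dlo:+.3f}, {dhi:+.3f})")
        a = s.anova
        lines.append(
            f"  time effect: F({a.df1_gg:.2f}, {a.df2_gg:.2f}) = {a.f:.2f}, "
            f"p_GG = {a.p_gg:.2e} (eps = {a.epsilon_gg:.3f})"
        )
        w, chi2, df, p = s.mauchly
        lines.append(f"  Mauchly: W = {w:.4f}, chi2({df}) = {chi2:.2f}, p = {p:.3g}")
        lines.append("")
    if analysis.order_contrasts:
        lines.append("testing-order contrasts (order 2 - order 1):")
        for (measure, t), c in sorted(analysis.order_contrasts.items()):
            lines.append(
                f"  {measure} at {t} s: {c.estimate:+.3f} degC "
                f"({c.ci_lower:+.3f}, {c.ci_upper:+.3f}), p_Sidak = {c.p_sidak:.3g}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="ascii")
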
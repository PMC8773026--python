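"""Per-region temperature statistics and trial-level aggregation.

Each scheduled timepoint is photographed up to three times; captures failing
quality control are dropped and the remaining capture-level means are
averaged (unweighted).  Subcutaneous PIT readings are joined at their
scheduled endpoints.  Missing values propagate as missing — nothing is
imputed or interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from thermosih.segmentation import BODY, TAIL, QCResult, RegionMask
from thermosih.thermal_io import (
    IRT_SCHEDULES,
    PIT_SCHEDULES,
    PitReading,
    ThermalFrame,
    TrialFactors,
)


class MeasurementError(ValueError):
    """Contract violation in region statistics or trial assembly."""


@dataclass(frozen=True)
class RegionStats:
    """Summary of the temperatures inside one labelled region."""

    region: str  # "body" | "tail"
    mean_c: float
    median_c: float
    pixel_count: int


def region_stats(frame: ThermalFrame, mask: RegionMask, region: str) -> RegionStats:
    """Mean and median temperature over exactly the pixels of one region."""
    if region not in ("body", "tail"):
        raise MeasurementError(f"unknown region {region!r}")
    sel = mask.labels == (BODY if region == "body" else TAIL)
    if mask.labels.shape != frame.pixels.shape:
        raise MeasurementError("mask and frame shapes differ")
    if not sel.any():
        raise MeasurementError(f"empty {region} region")
    vals = frame.pixels[sel]
    return RegionStats(
        region=region,
        mean_c=float(vals.mean()),
        median_c=float(np.median(vals)),
        pixel_count=int(vals.size),
    )


@dataclass(frozen=True)
class CaptureResult:
    """Region statistics plus the QC verdict for one capture."""

    body: Optional[RegionStats]
    tail: Optional[RegionStats]
    qc: QCResult


@dataclass(frozen=True)
class TimepointMeasurement:
    """QC-filtered aggregate for one animal at one scheduled second."""

    animal_id: str
    test: str
    trial_index: int
    timepoint_s: int
    t_body_c: Optional[float] = None
    t_tail_c: Optional[float] = None
    t_sc_c: Optional[float] = None
    n_captures_used: int = 0


def aggregate_timepoint(
    captures: Sequence[CaptureResult],
    animal_id: str = "",
    test: str = "DH",
    trial_index: int = 1,
    timepoint_s: int = 0,
) -> TimepointMeasurement:
    """Average capture-level means over the usable captures only.

    Unusable captures are excluded before averaging; if no capture is usable
    the timepoint value is missing with ``n_captures_used = 0``.  The tail
    mean is averaged over usable captures where a tail was found, so it may
    be missing even when the body value is not.
    """
    if not 1 <= len(captures) <= 3:
        raise MeasurementError("expected 1-3 captures per timepoint")
    usable = [c for c in captures if c.qc.usable]
    body_means = [c.body.mean_c for c in usable if c.body is not None]
    tail_means = [c.tail.mean_c for c in usable if c.tail is not None]
    return TimepointMeasurement(
        animal_id=animal_id,
        test=test,
        trial_index=trial_index,
        timepoint_s=timepoint_s,
        t_body_c=float(np.mean(body_means)) if body_means else None,
        t_tail_c=float(np.mean(tail_means)) if tail_means else None,
        t_sc_c=None,
        n_captures_used=len(usable),
    )


@dataclass
class TrialRecord:
    """One animal x test occasion: factor levels plus its measurement series."""

    animal_id: str
    test: str
    trial_index: int
    factors: TrialFactors
    series: list[TimepointMeasurement]
    flags: frozenset[str] = frozenset()


def assemble_trial(
    measurements: Sequence[TimepointMeasurement],
    pit: Sequence[PitReading],
    factors: TrialFactors,
) -> TrialRecord:
    """Join IRT timepoint measurements with PIT readings into one trial.

    All inputs must share the (animal, test, trial) key.  The series is
    ordered by timepoint; scheduled timepoints that are absent are flagged
    (``incomplete_schedule``), never invented.  PIT readings attach at their
    scheduled endpoints only.
    """
    if not measurements:
        raise MeasurementError("no measurements to assemble")
    keys = {(m.animal_id, m.test, m.trial_index) for m in measurements}
    if len(keys) != 1:
        raise MeasurementError(f"measurements span multiple trial keys: {sorted(keys)}")
    animal_id, test, trial_index = next(iter(keys))
    tps = [m.timepoint_s for m in measurements]
    if len(set(tps)) != len(tps):
        raise MeasurementError("duplicate timepoint in trial measurements")
    series = {m.timepoint_s: m for m in measurements}
    for reading in pit:
        if reading.key[:3] != (animal_id, test, trial_index):
            raise MeasurementError(
                f"PIT reading key {reading.key[:3]} does not match trial "
                f"{(animal_id, test, trial_index)}"
            )
        t = reading.timepoint_s
        if t in series:
            m = series[t]
            series[t] = TimepointMeasurement(
                animal_id=m.animal_id,
                test=m.test,
                trial_index=m.trial_index,
                timepoint_s=m.timepoint_s,
                t_body_c=m.t_body_c,
                t_tail_c=m.t_tail_c,
                t_sc_c=reading.t_sc_c,
                n_captures_used=m.n_captures_used,
            )
        else:
            series[t] = TimepointMeasurement(
                animal_id=animal_id,
                test=test,
                trial_index=trial_index,
                timepoint_s=t,
                t_sc_c=reading.t_sc_c,
            )
    flags: set[str] = set()
    if set(IRT_SCHEDULES[test]) - set(series):
        flags.add("incomplete_schedule")
    ordered = [series[t] for t in sorted(series)]
    return TrialRecord(
        animal_id=animal_id,
        test=test,
        trial_index=trial_index,
        factors=factors,
        series=ordered,
        flags=frozenset(flags),
    )


TABLE_COLUMNS = (
    "animal_id",
    "test",
    "trial_index",
    "cage_id",
    "testing_order",
    "strain",
    "sex",
    "handling",
    "period",
    "drug",
    "timepoint_s",
    "t_body_c",
    "t_tail_c",
    "t_sc_c",
    "n_captures_used",
)


def trials_to_table(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy long table: one row per animal x test x trial x timepoint."""
    rows = []
    for rec in records:
        f = rec.factors
        for m in rec.series:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "test": rec.test,
                    "trial_index": rec.trial_index,
                    "cage_id": f.cage_id,
                    "testing_order": f.testing_order,
                    "strain": f.strain,
                    "sex": f.sex,
                    "handling": f.handling,
                    "period": f.period,
                    "drug": f.drug,
                    "timepoint_s": m.timepoint_s,
                    "t_body_c": m.t_body_c,
                    "t_tail_c": m.t_tail_c,
                    "t_sc_c": m.t_sc_c,
                    "n_captures_used": m.n_captures_used,
                }
            )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return table.sort_values(["test", "animal_id", "trial_index", "timepoint_s"]).reset_index(
        drop=True
    )
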
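"""Calibrated thermal-frame I/O and session tables.

Thermal frames are single-channel temperature rasters in degrees Celsius.
Two on-disk dialects are supported:

* ``radiometric-tiff-16`` — single-channel, 16-bit unsigned, uncompressed
  TIFF holding digital numbers (DN); temperature = ``DN * scale + offset``.
  The calibration is echoed in a plain-text ``<path>.cal`` sidecar.
* ``matrix-text`` — a comma-separated numeric matrix of DNs, one line per
  pixel row, no header.

A session is described by a manifest table linking each frame file to its
animal, test, timepoint and experimental factors, and by a PIT-tag log with
subcutaneous temperature readings (``T_sc``).  The PIT reader only reports
within 33–43 degC; values outside that window are kept as missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

# Valid scene temperature range for a frame (degC).  Anything outside this
# window signals a mis-declared calibration dialect rather than a plausible
# arena scene.
TEMP_MIN_C = 0.0
TEMP_MAX_C = 50.0
MIN_SIDE_PX = 16

# PIT-tag reader reporting window (degC).
PIT_MIN_C = 33.0
PIT_MAX_C = 43.0

TESTS = ("DH", "VIT", "EPM")

# Thermal-image capture schedules (seconds) per behavioural test.
IRT_SCHEDULES: dict[str, tuple[int, ...]] = {
    "DH": (0, 60, 120),
    "VIT": (0, 30, 60),
    "EPM": tuple(range(0, 301, 30)),
}
# Subcutaneous PIT readings are taken only at the start and end of each test.
PIT_SCHEDULES: dict[str, tuple[int, ...]] = {
    "DH": (0, 120),
    "VIT": (0, 60),
    "EPM": (0, 300),
}

STRAINS = ("BALBcByJ", "C57BL6J")
SEXES = ("F", "M")
HANDLING = ("tail", "tunnel")
PERIODS = ("light", "dark")
DRUGS = ("diazepam", "vehicle", "none")
CAPTURES = (1, 2, 3)
TESTING_ORDERS = (1, 2, 3)

MANIFEST_COLUMNS = (
    "frame_path",
    "animal_id",
    "test",
    "trial_index",
    "period",
    "timepoint_s",
    "capture_idx",
    "cage_id",
    "testing_order",
    "strain",
    "sex",
    "handling",
    "drug",
)

PIT_COLUMNS = ("animal_id", "test", "trial_index", "timepoint_s", "t_sc_c")


class ThermalIOError(ValueError):
    """Malformed frame container, manifest or PIT log."""


def _check_level(name: str, value, allowed) -> None:
    if value not in allowed:
        raise ThermalIOError(f"unknown {name} {value!r}; expected one of {sorted(map(str, allowed))}")


@dataclass(frozen=True)
class FrameMeta:
    """Capture metadata for one thermal image."""

    animal_id: str
    test: str
    trial_index: int
    period: str
    timepoint_s: int
    capture_idx: int
    cage_id: str
    testing_order: int

    def __post_init__(self) -> None:
        _check_level("test", self.test, TESTS)
        _check_level("period", self.period, PERIODS)
        _check_level("capture_idx", self.capture_idx, CAPTURES)
        _check_level("testing_order", self.testing_order, TESTING_ORDERS)
        if self.trial_index < 1:
            raise ThermalIOError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.timepoint_s not in IRT_SCHEDULES[self.test]:
            raise ThermalIOError(
                f"timepoint {self.timepoint_s} s is off-schedule for {self.test} "
                f"(schedule: {IRT_SCHEDULES[self.test]})"
            )

    @property
    def key(self) -> tuple:
        return (self.animal_id, self.test, self.trial_index, self.timepoint_s, self.capture_idx)


@dataclass(frozen=True)
class TrialFactors:
    """Fixed-factor levels attached to one animal x test occasion."""

    strain: str
    sex: str
    handling: str
    period: str
    drug: str = "none"
    testing_order: int = 1
    cage_id: str = ""

    def __post_init__(self) -> None:
        _check_level("strain", self.strain, STRAINS)
        _check_level("sex", self.sex, SEXES)
        _check_level("handling", self.handling, HANDLING)
        _check_level("period", self.period, PERIODS)
        _check_level("drug", self.drug, DRUGS)
        _check_level("testing_order", self.testing_order, TESTING_ORDERS)


@dataclass
class ThermalFrame:
    """A calibrated temperature raster (degC), row-major, origin top-left."""

    pixels: np.ndarray
    meta: Optional[FrameMeta] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ThermalIOError(f"frame must be a 2-D grid, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_SIDE_PX or w < MIN_SIDE_PX:
            raise ThermalIOError(f"frame too small ({h}x{w}); minimum side is {MIN_SIDE_PX} px")
        if not np.all(np.isfinite(self.pixels)):
            raise ThermalIOError("frame contains non-finite temperatures")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < TEMP_MIN_C or hi > TEMP_MAX_C:
            raise ThermalIOError(
                f"decoded temperatures [{lo:.2f}, {hi:.2f}] degC outside the valid "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] degC window; check the calibration dialect"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CalibrationDialect:
    """Linear DN-to-temperature mapping plus the container format.

    The default 0.01 degC/DN step comfortably exceeds the <=50 mK sensitivity
    of the thermal camera the pipeline targets.
    """

    scale: float = 0.01
    offset: float = 0.0
    container: str = "radiometric-tiff-16"

    def __post_init__(self) -> None:
        if self.container not in ("radiometric-tiff-16", "matrix-text"):
            raise ThermalIOError(f"unknown container {self.container!r}")
        if not self.scale > 0:
            raise ThermalIOError("scale must be > 0")
        if self.container == "radiometric-tiff-16":
            # 16-bit DNs must be able to represent the full scene window.
            if self.offset > TEMP_MIN_C or self.offset + self.scale * 65535 < TEMP_MAX_C:
                raise ThermalIOError(
                    "16-bit dialect cannot represent the full 0-50 degC window "
                    f"with scale={self.scale}, offset={self.offset}"
                )

    def to_raw(self, temps_c: np.ndarray) -> np.ndarray:
        return np.rint((np.asarray(temps_c, dtype=float) - self.offset) / self.scale)

    def to_temp(self, raw: np.ndarray) -> np.ndarray:
        return np.asarray(raw, dtype=float) * self.scale + self.offset


def _read_matrix_text(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split(",")])
            except ValueError as exc:
                raise ThermalIOError(f"{path}:{lineno}: unparseable numeric field") from exc
    if not rows:
        raise ThermalIOError(f"{path}: empty matrix-text frame")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ThermalIOError(f"{path}: rows of unequal length (non-rectangular matrix)")
    return np.asarray(rows, dtype=float)


def read_thermal_frame(
    path: str | Path,
    dialect: CalibrationDialect = CalibrationDialect(),
    meta: Optional[FrameMeta] = None,
) -> ThermalFrame:
    """Read a frame from disk and convert DNs to degC via the dialect."""
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"frame file not found: {path}")
    if dialect.container == "radiometric-tiff-16":
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # malformed container
            raise ThermalIOError(f"{path}: not a readable TIFF ({exc})") from exc
        if raw.ndim != 2 or not np.issubdtype(raw.dtype, np.integer):
            raise ThermalIOError(f"{path}: expected a single-channel integer TIFF")
    else:
        raw = _read_matrix_text(path)
    return ThermalFrame(dialect.to_temp(raw), meta=meta)


def write_thermal_frame(
    frame: ThermalFrame,
    path: str | Path,
    dialect: CalibrationDialect = CalibrationDialect(),
) -> Path:
    """Write a frame; re-reading recovers each pixel within one DN step."""
    path = Path(path)
    raw = dialect.to_raw(frame.pixels)
    if dialect.container == "radiometric-tiff-16":
        if raw.min() < 0 or raw.max() > 65535:
            raise ThermalIOError(
                f"temperatures not representable as 16-bit DNs with scale={dialect.scale}, "
                f"offset={dialect.offset}"
            )
        tifffile.imwrite(path, raw.astype(np.uint16), compression=None)
        sidecar = path.with_name(path.name + ".cal")
        sidecar.write_text(f"scale: {dialect.scale}\noffset: {dialect.offset}\n", encoding="ascii")
    else:
        with open(path, "w", encoding="ascii") as fh:
            for row in raw.astype(np.int64):
                fh.write(",".join(str(v) for v in row) + "\n")
    return path


@dataclass(frozen=True)
class ManifestRecord:
    """One manifest row: frame identity plus its trial factors."""

    meta: FrameMeta
    factors: TrialFactors
    frame_path: Path


def _to_int(value, column: str, lineno) -> int:
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise ThermalIOError(f"manifest row {lineno}: non-integer {column}={value!r}") from exc


def load_manifest(path: str | Path, check_frames: bool = True) -> list[ManifestRecord]:
    """Load and validate a session manifest.

    Factor levels are checked against closed vocabularies, timepoints against
    the per-test capture schedule, and the (animal, test, trial, timepoint,
    capture) key must be unique.  Frame paths are resolved relative to the
    manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ThermalIOError(f"{path}: manifest missing required columns {missing}")
    records: list[ManifestRecord] = []
    seen: set[tuple] = set()
    for lineno, row in table.iterrows():
        meta = FrameMeta(
            animal_id=str(row["animal_id"]),
            test=str(row["test"]),
            trial_index=_to_int(row["trial_index"], "trial_index", lineno),
            period=str(row["period"]),
            timepoint_s=_to_int(row["timepoint_s"], "timepoint_s", lineno),
            capture_idx=_to_int(row["capture_idx"], "capture_idx", lineno),
            cage_id=str(row["cage_id"]),
            testing_order=_to_int(row["testing_order"], "testing_order", lineno),
        )
        if meta.key in seen:
            raise ThermalIOError(f"{path}: duplicate capture key {meta.key}")
        seen.add(meta.key)
        factors = TrialFactors(
            strain=str(row["strain"]),
            sex=str(row["sex"]),
            handling=str(row["handling"]),
            period=meta.period,
            drug=str(row["drug"]),
            testing_order=meta.testing_order,
            cage_id=meta.cage_id,
        )
        frame_path = Path(str(row["frame_path"]))
        if not frame_path.is_absolute():
            frame_path = path.parent / frame_path
        if check_frames and not frame_path.exists():
            raise ThermalIOError(f"{path}: referenced frame file missing: {frame_path}")
        records.append(ManifestRecord(meta=meta, factors=factors, frame_path=frame_path))
    return records


@dataclass(frozen=True)
class PitReading:
    """One subcutaneous PIT-tag temperature reading."""

    animal_id: str
    test: str
    trial_index: int
    timepoint_s: int
    t_sc_c: Optional[float]

    def __post_init__(self) -> None:
        _check_level("test", self.test, TESTS)
        if self.timepoint_s not in PIT_SCHEDULES[self.test]:
            raise ThermalIOError(
                f"PIT timepoint {self.timepoint_s} s is off-schedule for {self.test} "
                f"(schedule: {PIT_SCHEDULES[self.test]})"
            )
        if self.t_sc_c is not None and not PIT_MIN_C <= self.t_sc_c <= PIT_MAX_C:
            raise ThermalIOError(
                f"non-missing T_sc {self.t_sc_c} degC outside the reader window"
            )

    @property
    def key(self) -> tuple:
        return (self.animal_id, self.test, self.trial_index, self.timepoint_s)


def parse_pit_log(path: str | Path) -> list[PitReading]:
    """Parse a PIT-tag log.

    Readings outside the 33-43 degC reader window are retained as missing
    (the reader cannot report them) with a logged warning; blank fields are
    missing as well.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in PIT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ThermalIOError(f"{path}: PIT log missing required columns {missing_cols}")
    readings: list[PitReading] = []
    seen: set[tuple] = set()
    for lineno, row in table.iterrows():
        raw = row["t_sc_c"]
        value: Optional[float]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            value = None
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise ThermalIOError(f"{path} row {lineno}: unparseable t_sc_c={raw!r}") from exc
            if not PIT_MIN_C <= value <= PIT_MAX_C:
                log.warning(
                    "PIT reading %s degC outside reader range [%s, %s]; kept as missing "
                    "(animal %s, %s trial %s, t=%s s)",
                    value, PIT_MIN_C, PIT_MAX_C,
                    row["animal_id"], row["test"], row["trial_index"], row["timepoint_s"],
                )
                value = None
        reading = PitReading(
            animal_id=str(row["animal_id"]),
            test=str(row["test"]),
            trial_index=_to_int(row["trial_index"], "trial_index", lineno),
            timepoint_s=_to_int(row["timepoint_s"], "timepoint_s", lineno),
            t_sc_c=value,
        )
        if reading.key in seen:
            raise ThermalIOError(f"{path}: duplicate PIT reading key {reading.key}")
        seen.add(reading.key)
        readings.append(reading)
    return readings
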
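"""Ground-truthed synthetic thermal data: phantoms, trials and cohorts.

A phantom is a warm elliptical mouse body with a cooler tapering tail on a
cooler arena background.  Region textures are renormalized to zero mean, so
the arithmetic mean over the true body (tail) pixels equals the latent body
(tail) temperature *exactly* before sensor noise — measurement recovery can
then be checked against the latent values without geometric bookkeeping.

Cohort simulation reproduces the study designs of the three protocols:

* DH  — 2-min daily handling; images at 0/60/120 s, PIT readings at 0/120 s.
* VIT — 1-min voluntary interaction; images at 0/30/60 s, PIT at 0/60 s.
* EPM — 5-min elevated plus maze; images every 30 s, PIT at 0/300 s.  EPM
  imagery is captured from far above the maze, where the tail is too poorly
  resolved to score, so EPM phantoms are rendered without a tail and tail
  temperature is not simulated.

Latent temperatures follow an additive model per animal ``i``, measure
``m`` and scheduled second ``t``::

    T[i, m, t] = baseline[m](t) + sum_f centred effect of factor f
                 + a[i, m] + e[i, m, t]

with ``a ~ N(0, sigma_animal)`` shared across timepoints and
``e ~ N(0, sigma_resid)`` independent per timepoint.  Factor effects are
stored as full level differences (e.g. dark minus light) and applied as
centred deviations (+d/2 / -d/2), so configured grand means stay at the
baseline trajectory while every two-level contrast recovers the configured
difference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from thermosih.segmentation import BODY, TAIL, RegionMask
from thermosih.thermal_io import (
    CalibrationDialect,
    FrameMeta,
    IRT_SCHEDULES,
    PIT_MAX_C,
    PIT_MIN_C,
    PIT_SCHEDULES,
    ThermalFrame,
    TrialFactors,
    write_thermal_frame,
)

MEASURES = ("T_sc", "T_body", "T_tail")


class SyntheticError(ValueError):
    """Invalid phantom geometry or scenario configuration."""


# --------------------------------------------------------------------------
# Phantom rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DistractorSpec:
    """Optional warm disc emulating e.g. a handling tunnel left in frame."""

    center: tuple[float, float]
    radius: float
    temp_c: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and latent temperatures of one rendered mouse phantom.

    Coordinates are (row, col) with origin top-left.  ``body_axes`` are the
    (major, minor) semi-axes in pixels; ``body_angle`` rotates the major
    axis counter-clockwise in radians.  The tail is a polyline with linearly
    interpolated per-vertex half-widths, tapering toward the tip.
    """

    shape: tuple[int, int] = (120, 160)
    body_center: tuple[float, float] = (60.0, 70.0)
    body_axes: tuple[float, float] = (18.0, 11.0)
    body_angle: float = 0.0
    tail_points: tuple[tuple[float, float], ...] = ()
    tail_half_widths: tuple[float, ...] = ()
    latent_body_c: float = 29.0
    latent_tail_c: float = 24.0
    background_c: float = 20.0
    texture_amplitude: float = 0.2
    sensor_noise_sd: float = 0.05
    distractor: Optional[DistractorSpec] = None
    occlusion_fraction: float = 0.0
    allow_border_clip: bool = False

    def __post_init__(self) -> None:
        if not self.latent_tail_c < self.latent_body_c:
            raise SyntheticError("latent_tail_c must be below latent_body_c")
        if not self.background_c < self.latent_tail_c:
            raise SyntheticError("background_c must be below latent_tail_c")
        if self.tail_points and len(self.tail_points) != len(self.tail_half_widths):
            raise SyntheticError("tail_points and tail_half_widths lengths differ")
        if self.tail_half_widths:
            limit = min(self.body_axes) / 4.0
            if max(self.tail_half_widths) >= limit:
                raise SyntheticError(
                    f"tail half-width must stay below body minor semi-axis / 4 ({limit:.2f} px)"
                )
        if not 0.0 <= self.occlusion_fraction < 1.0:
            raise SyntheticError("occlusion_fraction must be in [0, 1)")
        if self.texture_amplitude < 0 or self.sensor_noise_sd < 0:
            raise SyntheticError("texture_amplitude and sensor_noise_sd must be >= 0")


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _polyline_mask(shape, points, half_widths) -> np.ndarray:
    """Union of discs swept along the polyline with interpolated radius."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.asarray(points, dtype=float)
    hws = np.asarray(half_widths, dtype=float)
    for (p0, p1), (w0, w1) in zip(zip(pts[:-1], pts[1:]), zip(hws[:-1], hws[1:])):
        seg_len = float(np.hypot(*(p1 - p0)))
        n = max(2, int(np.ceil(seg_len * 2)) + 1)
        for s in np.linspace(0.0, 1.0, n):
            p = p0 + s * (p1 - p0)
            w = w0 + s * (w1 - w0)
            # local disc; bounding-box restricted for speed
            r0 = max(0, int(p[0] - w - 1))
            r1 = min(shape[0], int(p[0] + w + 2))
            c0 = max(0, int(p[1] - w - 1))
            c1 = min(shape[1], int(p[1] + w + 2))
            sub = (rr[r0:r1, c0:c1] - p[0]) ** 2 + (cc[r0:r1, c0:c1] - p[1]) ** 2 <= w * w
            mask[r0:r1, c0:c1] |= sub
    return mask


def _touches_margin(mask: np.ndarray, margin: int = 1) -> bool:
    return bool(
        mask[:margin, :].any()
        or mask[-margin:, :].any()
        or mask[:, :margin].any()
        or mask[:, -margin:].any()
    )


def render_phantom(spec: PhantomSpec, seed: int | np.random.Generator = 0) -> tuple[ThermalFrame, RegionMask]:
    """Render a phantom to a thermal frame plus its ground-truth mask.

    Deterministic given the seed.  Raises :class:`SyntheticError` if the
    geometry reaches the frame border (unless ``allow_border_clip``, used to
    build deliberately clipped QC test cases).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    body = _ellipse_mask(spec.shape, spec.body_center, spec.body_axes, spec.body_angle)
    if spec.tail_points:
        tail = _polyline_mask(spec.shape, spec.tail_points, spec.tail_half_widths) & ~body
    else:
        tail = np.zeros(spec.shape, dtype=bool)
    if not body.any():
        raise SyntheticError("body ellipse renders no pixels")
    if not spec.allow_border_clip and _touches_margin(body | tail):
        raise SyntheticError("phantom geometry reaches the frame border")

    if spec.occlusion_fraction > 0:
        # Rearing surrogate: erase the leading rows of the body until the
        # requested pixel fraction is gone.
        rows = np.flatnonzero(body.any(axis=1))
        target = int(round(spec.occlusion_fraction * body.sum()))
        removed = 0
        for r in rows:
            if removed >= target:
                break
            removed += int(body[r].sum())
            body[r] = False
        tail &= ~body  # keep regions disjoint

    img = np.full(spec.shape, spec.background_c, dtype=float)
    if spec.distractor is not None:
        d = spec.distractor
        disc = _ellipse_mask(spec.shape, d.center, (d.radius, d.radius), 0.0)
        img[disc] = d.temp_c
    for region, latent in ((body, spec.latent_body_c), (tail, spec.latent_tail_c)):
        n = int(region.sum())
        if n == 0:
            continue
        if spec.texture_amplitude > 0:
            tex = rng.uniform(-spec.texture_amplitude, spec.texture_amplitude, n)
            tex -= tex.mean()  # exact zero mean -> region mean == latent
        else:
            tex = np.zeros(n)
        img[region] = latent + tex
    if spec.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, spec.sensor_noise_sd, spec.shape)

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[body] = BODY
    labels[tail] = TAIL
    return ThermalFrame(img), RegionMask(labels)


def random_phantom(
    rng: np.random.Generator,
    shape: tuple[int, int] = (120, 160),
    latent_body_c: float = 29.0,
    latent_tail_c: float = 24.0,
    background_c: float = 20.0,
    texture_amplitude: float = 0.2,
    sensor_noise_sd: float = 0.05,
    include_tail: bool = True,
    **overrides,
) -> PhantomSpec:
    """Draw a random pose: body position/orientation/size and a curved tail."""
    h, w = shape
    for _ in range(500):
        a = rng.uniform(16.0, 20.0)
        b = rng.uniform(9.0, 12.0)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(angle), np.sin(angle)])
        tail_len = rng.uniform(28.0, 38.0)
        reach = a + tail_len + 4.0
        lo_r, hi_r = 3.0 + reach, h - 4.0 - reach
        lo_c, hi_c = 3.0 + reach, w - 4.0 - reach
        if lo_r >= hi_r or lo_c >= hi_c:
            # frame too small for a fully interior pose at this size; allow a
            # center box based on body size only and rely on the fit check
            lo_r, hi_r = 3.0 + a, h - 4.0 - a
            lo_c, hi_c = 3.0 + a, w - 4.0 - a
        center = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        if include_tail:
            perp = np.array([-u[1], u[0]])
            start = center + (a - 1.0) * u
            mid = center + (a + tail_len / 2) * u + rng.uniform(-4.0, 4.0) * perp
            end = center + (a + tail_len) * u + rng.uniform(-6.0, 6.0) * perp
            points = (tuple(start), tuple(mid), tuple(end))
            widths = (2.2, 1.6, 1.0)
            extreme = np.array([start, mid, end])
            pad = 3.0
            if (
                extreme[:, 0].min() < pad
                or extreme[:, 0].max() > h - 1 - pad
                or extreme[:, 1].min() < pad
                or extreme[:, 1].max() > w - 1 - pad
            ):
                continue
        else:
            points, widths = (), ()
        body_lo = center - a - 2
        body_hi = center + a + 2
        if body_lo.min() < 1 or body_hi[0] > h - 2 or body_hi[1] > w - 2:
            continue
        return PhantomSpec(
            shape=shape,
            body_center=tuple(center),
            body_axes=(a, b),
            body_angle=angle,
            tail_points=points,
            tail_half_widths=widths,
            latent_body_c=latent_body_c,
            latent_tail_c=latent_tail_c,
            background_c=background_c,
            texture_amplitude=texture_amplitude,
            sensor_noise_sd=sensor_noise_sd,
            **overrides,
        )
    raise SyntheticError("could not place a phantom inside the frame")


# --------------------------------------------------------------------------
# Scenario configuration: baselines and effects from the study protocols
# --------------------------------------------------------------------------


def _linear_trajectory(schedule: Sequence[int], start: float, end: float) -> dict[int, float]:
    t0, t1 = schedule[0], schedule[-1]
    return {t: start + (end - start) * (t - t0) / (t1 - t0) for t in schedule}


def _const(schedule: Sequence[int], value: float) -> dict[int, float]:
    return {t: value for t in schedule}


def _default_baselines(test: str) -> dict[str, dict[int, float]]:
    if test == "DH":
        return {
            "T_sc": {0: 37.37, 120: 37.96},
            "T_body": {0: 29.03, 60: 29.31, 120: 29.55},
            "T_tail": {0: 24.55, 60: 24.24, 120: 24.13},
        }
    if test == "VIT":
        return {
            "T_sc": {0: 37.06, 60: 37.43},
            "T_body": {0: 28.56, 30: 28.88, 60: 29.03},
            "T_tail": {0: 23.76, 30: 23.62, 60: 23.60},
        }
    if test == "EPM":
        sched = IRT_SCHEDULES["EPM"]
        # Grand means pooled over drug groups; the drug contrast is applied
        # as a centred effect around these (intermediate timepoints filled by
        # monotone linear interpolation, a modelling choice).
        return {
            "T_sc": _linear_trajectory(PIT_SCHEDULES["EPM"], 38.025, 38.595),
            "T_body": _linear_trajectory(sched, 29.685, 30.06),
        }
    raise SyntheticError(f"unknown test {test!r}")


# Factor effects are full level differences d = level_plus - level_minus,
# applied centred: level_minus gets -d/2, level_plus gets +d/2.
EFFECT_LEVELS: dict[str, tuple[object, object]] = {
    "period": ("light", "dark"),
    "handling": ("tail", "tunnel"),
    "strain": ("C57BL6J", "BALBcByJ"),
    "sex": ("F", "M"),
    "drug": ("vehicle", "diazepam"),
    "testing_order": (1, 2),
}


def _default_effects(test: str) -> dict[str, dict[str, dict[int, float]]]:
    if test == "DH":
        return {
            "T_sc": {
                "period": _const(PIT_SCHEDULES["DH"], 0.49),
                "testing_order": {0: 0.75, 120: 0.0},
                "strain": {0: 0.22, 120: 0.0},
            },
            "T_body": {
                "period": _const(IRT_SCHEDULES["DH"], 0.17),
                "handling": _const(IRT_SCHEDULES["DH"], 0.07),
                "testing_order": {0: 0.44, 60: 0.35, 120: 0.28},
            },
            "T_tail": {
                "testing_order": {0: -0.97, 60: -0.40, 120: 0.04},
            },
        }
    if test == "VIT":
        return {
            "T_sc": {"strain": _const(PIT_SCHEDULES["VIT"], 0.34)},
            "T_body": {},
            "T_tail": {},
        }
    if test == "EPM":
        return {
            "T_sc": {
                "drug": _linear_trajectory(PIT_SCHEDULES["EPM"], -0.43, -0.01),
            },
            "T_body": {
                "drug": _linear_trajectory(IRT_SCHEDULES["EPM"], -0.43, -0.18),
            },
        }
    raise SyntheticError(f"unknown test {test!r}")


@dataclass
class ScenarioConfig:
    """Ground-truth latent trajectories, effect structure and rendering knobs.

    Baseline trajectories and the printed factor effects default to the
    grand means reported for each protocol; variance components
    (``sigma_animal`` = 0.30 degC between animals, ``sigma_resid`` = 0.15
    degC per timepoint, 0.05 degC sensor noise) are assumptions chosen so a
    64-animal cohort yields confidence intervals of realistic width.
    """

    test: str = "DH"
    n_animals: int = 64
    baselines: dict[str, dict[int, float]] = field(default_factory=dict)
    effects: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    sigma_animal: float = 0.30
    sigma_resid: float = 0.15
    sensor_noise_sd: float = 0.05
    texture_amplitude: float = 0.2
    background_c: float = 20.0
    frame_shape: tuple[int, int] = (120, 160)
    captures_per_timepoint: int = 3

    def __post_init__(self) -> None:
        if self.test not in IRT_SCHEDULES:
            raise SyntheticError(f"unknown test {self.test!r}")
        if not self.baselines:
            self.baselines = _default_baselines(self.test)
        if not self.effects:
            self.effects = _default_effects(self.test)
        for sd in (self.sigma_animal, self.sigma_resid, self.sensor_noise_sd):
            if sd < 0:
                raise SyntheticError("variance components must be >= 0")
        for measure, traj in self.baselines.items():
            sched = PIT_SCHEDULES[self.test] if measure == "T_sc" else IRT_SCHEDULES[self.test]
            if set(sched) - set(traj):
                raise SyntheticError(
                    f"{measure} baseline does not cover the {self.test} schedule"
                )

    @property
    def include_tail(self) -> bool:
        return "T_tail" in self.baselines

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(m for m in MEASURES if m in self.baselines)

    def schedule(self, measure: str) -> tuple[int, ...]:
        return PIT_SCHEDULES[self.test] if measure == "T_sc" else IRT_SCHEDULES[self.test]

    def effect_offset(self, measure: str, factors: TrialFactors, timepoint_s: int) -> float:
        """Sum of centred factor deviations for one animal at one second."""
        total = 0.0
        for factor, traj in self.effects.get(measure, {}).items():
            d = traj.get(timepoint_s, 0.0)
            if d == 0.0:
                continue
            lo, hi = EFFECT_LEVELS[factor]
            level = getattr(factors, factor)
            if factor == "testing_order":
                # orders beyond the pair share the later-tested deviation
                sign = -0.5 if level == lo else 0.5
            else:
                if level == lo:
                    sign = -0.5
                elif level == hi:
                    sign = 0.5
                else:
                    sign = 0.0  # e.g. drug="none" outside EPM
            total += sign * d
        return total


# --------------------------------------------------------------------------
# Cohort design and simulation
# --------------------------------------------------------------------------


def default_design(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced factorial layout with pair-housed cages.

    Cage-mates share strain, sex and handling (as housed in the study);
    testing order within the cage and, for EPM, the drug assignment are
    randomized per cage.  For DH the light/dark period alternates across
    cage rounds so each factor cell sees both periods.
    """
    if config.n_animals < 2:
        raise SyntheticError("need at least 2 animals")
    cells = [(s, x, hnd) for s in ("BALBcByJ", "C57BL6J") for x in ("F", "M") for hnd in ("tail", "tunnel")]
    rows = []
    n_cages = (config.n_animals + 1) // 2
    animal = 0
    for cage_idx in range(n_cages):
        strain, sex, handling = cells[cage_idx % len(cells)]
        if config.test == "DH":
            period = ("light", "dark")[(cage_idx // len(cells)) % 2]
        elif config.test == "VIT":
            period = "light"  # morning test
        else:
            period = "dark"  # EPM ran in the afternoon / dark period
        cage_id = f"cage{cage_idx + 1:03d}"
        orders = list(rng.permutation([1, 2]))
        drugs = list(rng.permutation(["vehicle", "diazepam"])) if config.test == "EPM" else ["none", "none"]
        for slot in range(2):
            if animal >= config.n_animals:
                break
            rows.append(
                {
                    "animal_id": f"m{animal + 1:03d}",
                    "cage_id": cage_id,
                    "strain": strain,
                    "sex": sex,
                    "handling": handling,
                    "period": period,
                    "drug": drugs[slot],
                    "testing_order": int(orders[slot]),
                }
            )
            animal += 1
    return pd.DataFrame(rows)


@dataclass
class FrameRecord:
    """One rendered capture with its metadata and ground-truth mask."""

    meta: FrameMeta
    frame: ThermalFrame
    truth: RegionMask


@dataclass
class TrialSim:
    """All simulated outputs of one animal x trial."""

    factors: TrialFactors
    animal_id: str
    trial_index: int
    frames: list[FrameRecord]
    pit_rows: list[dict]
    latent: dict[str, dict[int, float]]


def simulate_trial(
    config: ScenarioConfig,
    animal: Mapping,
    rng: np.random.Generator,
    trial_index: int = 1,
) -> TrialSim:
    """Simulate latent temperatures, rendered captures and PIT rows for one trial."""
    factors = TrialFactors(
        strain=animal["strain"],
        sex=animal["sex"],
        handling=animal["handling"],
        period=animal["period"],
        drug=animal["drug"],
        testing_order=int(animal["testing_order"]),
        cage_id=animal["cage_id"],
    )
    animal_id = str(animal["animal_id"])
    intercepts = {m: rng.normal(0.0, config.sigma_animal) for m in config.measures}
    latent: dict[str, dict[int, float]] = {}
    for m in config.measures:
        latent[m] = {}
        for t in config.schedule(m):
            latent[m][t] = (
                config.baselines[m][t]
                + config.effect_offset(m, factors, t)
                + intercepts[m]
                + rng.normal(0.0, config.sigma_resid)
            )
    frames: list[FrameRecord] = []
    for t in IRT_SCHEDULES[config.test]:
        for capture in range(1, config.captures_per_timepoint + 1):
            spec = random_phantom(
                rng,
                shape=config.frame_shape,
                latent_body_c=latent["T_body"][t],
                latent_tail_c=latent["T_tail"][t] if config.include_tail else latent["T_body"][t] - 5.0,
                background_c=config.background_c,
                texture_amplitude=config.texture_amplitude,
                sensor_noise_sd=config.sensor_noise_sd,
                include_tail=config.include_tail,
            )
            frame, truth = render_phantom(spec, rng)
            meta = FrameMeta(
                animal_id=animal_id,
                test=config.test,
                trial_index=trial_index,
                period=factors.period,
                timepoint_s=t,
                capture_idx=capture,
                cage_id=factors.cage_id,
                testing_order=factors.testing_order,
            )
            frames.append(FrameRecord(meta=meta, frame=frame, truth=truth))
    pit_rows = []
    for t in PIT_SCHEDULES[config.test]:
        v = latent["T_sc"][t]
        pit_rows.append(
            {
                "animal_id": animal_id,
                "test": config.test,
                "trial_index": trial_index,
                "timepoint_s": t,
                # the reader cannot report outside its window: mask, not clip
                "t_sc_c": round(v, 4) if PIT_MIN_C <= v <= PIT_MAX_C else "",
            }
        )
    return TrialSim(
        factors=factors,
        animal_id=animal_id,
        trial_index=trial_index,
        frames=frames,
        pit_rows=pit_rows,
        latent=latent,
    )


@dataclass
class SyntheticCohort:
    """A full in-memory dataset bundle with ground truth."""

    config: ScenarioConfig
    seed: int
    design: pd.DataFrame
    trials: list[TrialSim]

    @property
    def frames(self) -> list[FrameRecord]:
        return [fr for trial in self.trials for fr in trial.frames]

    def manifest_table(self, frame_paths: Optional[Mapping[tuple, str]] = None) -> pd.DataFrame:
        rows = []
        for trial in self.trials:
            f = trial.factors
            for fr in trial.frames:
                m = fr.meta
                rows.append(
                    {
                        "frame_path": (frame_paths or {}).get(m.key, ""),
                        "animal_id": m.animal_id,
                        "test": m.test,
                        "trial_index": m.trial_index,
                        "period": m.period,
                        "timepoint_s": m.timepoint_s,
                        "capture_idx": m.capture_idx,
                        "cage_id": m.cage_id,
                        "testing_order": m.testing_order,
                        "strain": f.strain,
                        "sex": f.sex,
                        "handling": f.handling,
                        "drug": f.drug,
                    }
                )
        return pd.DataFrame(rows)

    def pit_table(self) -> pd.DataFrame:
        return pd.DataFrame([row for trial in self.trials for row in trial.pit_rows])

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for trial in self.trials:
            for m, traj in trial.latent.items():
                for t, v in traj.items():
                    rows.append(
                        {
                            "animal_id": trial.animal_id,
                            "test": self.config.test,
                            "trial_index": trial.trial_index,
                            "measure": m,
                            "timepoint_s": t,
                            "latent_c": v,
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path, dialect: CalibrationDialect = CalibrationDialect()) -> dict[str, Path]:
        """Write a file-backed dataset loadable through :mod:`thermosih.thermal_io`."""
        outdir = Path(outdir)
        frames_dir = outdir / "frames"
        frames_dir.mkdir(parents=True, exist_ok=True)
        ext = ".tif" if dialect.container == "radiometric-tiff-16" else ".csv"
        paths: dict[tuple, str] = {}
        for fr in self.frames:
            m = fr.meta
            name = (
                f"{m.animal_id}_{m.test}_tr{m.trial_index}_t{m.timepoint_s:03d}_c{m.capture_idx}{ext}"
            )
            write_thermal_frame(fr.frame, frames_dir / name, dialect)
            paths[m.key] = f"frames/{name}"
        manifest = self.manifest_table(paths)
        pit = self.pit_table()
        truth = self.ground_truth_table()
        out = {
            "manifest": outdir / "manifest.csv",
            "pit_log": outdir / "pit_log.csv",
            "ground_truth": outdir / "ground_truth.csv",
            "config": outdir / "config.yaml",
        }
        manifest.to_csv(out["manifest"], index=False)
        pit.to_csv(out["pit_log"], index=False)
        truth.to_csv(out["ground_truth"], index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["seed"] = self.seed
        with open(out["config"], "w", encoding="ascii") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return out


def simulate_latent_table(
    config: ScenarioConfig,
    seed: int = 0,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Tidy measurement-style table of latent temperatures, skipping rendering.

    Draws the same additive model (baselines, centred effects, animal
    intercepts, residuals) but reports the latent values directly as if
    measurement were error-free.  Intended for statistical calibration
    studies where imaging is irrelevant; note the rng stream differs from
    :func:`simulate_cohort`, which also consumes draws for rendering.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(config, rng)
    col_of = {"T_sc": "t_sc_c", "T_body": "t_body_c", "T_tail": "t_tail_c"}
    rows: dict[tuple, dict] = {}
    for _, animal in design.iterrows():
        factors = TrialFactors(
            strain=animal["strain"], sex=animal["sex"], handling=animal["handling"],
            period=animal["period"], drug=animal["drug"],
            testing_order=int(animal["testing_order"]), cage_id=animal["cage_id"],
        )
        intercepts = {m: rng.normal(0.0, config.sigma_animal) for m in config.measures}
        for m in config.measures:
            for t in config.schedule(m):
                key = (animal["animal_id"], t)
                row = rows.setdefault(
                    key,
                    {
                        "animal_id": animal["animal_id"], "test": config.test,
                        "trial_index": 1, "cage_id": factors.cage_id,
                        "testing_order": factors.testing_order, "strain": factors.strain,
                        "sex": factors.sex, "handling": factors.handling,
                        "period": factors.period, "drug": factors.drug,
                        "timepoint_s": t, "t_body_c": np.nan, "t_tail_c": np.nan,
                        "t_sc_c": np.nan, "n_captures_used": config.captures_per_timepoint,
                    },
                )
                row[col_of[m]] = (
                    config.baselines[m][t]
                    + config.effect_offset(m, factors, t)
                    + intercepts[m]
                    + rng.normal(0.0, config.sigma_resid)
                )
    table = pd.DataFrame(rows.values())
    return table.sort_values(["animal_id", "timepoint_s"]).reset_index(drop=True)


def simulate_cohort(
    config: ScenarioConfig,
    seed: int = 0,
    design: Optional[pd.DataFrame] = None,
) -> SyntheticCohort:
    """Simulate a full cohort under the scenario's design.

    Deterministic given the seed: the same seed yields byte-identical
    manifest, PIT log and ground-truth tables.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(config, rng)
    if len(design) < 2:
        raise SyntheticError("cohort needs at least 2 animals")
    trials = [simulate_trial(config, row, rng) for _, row in design.iterrows()]
    return SyntheticCohort(config=config, seed=seed, design=design, trials=trials)
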
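"""Generative model of plate-based VMR experiments.

The generator emulates the statistical structure the analyses assume: larvae
arrayed in a multi-well plate, dark-adapted, then exposed to consecutive
Light-On / Light-Off trials.  The latent per-second movement rate of animal
``a`` at second ``t`` is

    r(a, t) = clamp01( baseline(strain) * stage_mult(stage)
                       + location(well) + bio_rep_effect + tech_rep_effect
                       + u_a + kernel(t) * resp_mod(strain) * resp_mod(stage)
                       + eps(a, t) )

with ``u_a`` an animal-level Gaussian random intercept and ``eps`` a
stationary AR(1) noise process.  The stimulus-response kernel is an
exponential decay to a plateau: at relative second tau >= 1 after a light
change it contributes ``A * exp(-k * (tau - 1)) + s_level`` (separate
constants for On and Off phases) and keeps the plateau until the next
change.  The kernel shape is a modeling choice of this package — real VMR
response shapes are not parameterized anywhere — with every constant
exposed in the config.

Two generation modes:

* ``second``: emits the latent rate plus optional clamped Gaussian
  observation noise, so group means and covariances are known exactly —
  this is the mode power-validation studies rely on;
* ``frame``: draws ``fps`` independent Bernoulli(r) movement flags per
  second, so the Burst Duration is Binomial(fps, r)/fps and the frame-level
  summarization code is exercised end to end.  Frame tables are large;
  intended for reduced plates.

Reproducibility: one root seed; each animal gets its own substream keyed by
its (plate, stage, well) counter, so adding plates or wells never perturbs
the streams of existing animals.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .activity import (
    ACTIVITY_COLUMNS,
    ActivityMatrix,
    FrameMovementTable,
    StimulusSchedule,
)
from .errors import ConfigError
from .hotelling import hotelling_t2
from .power import noncentrality, power_from_ncp

import logging

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Full generative specification of a simulated plate experiment.

    Defaults describe the canonical assay: a 96-well (8 x 12) plate per
    strain and biological repeat, 3.5 h dark adaptation with recording
    starting 0.5 h before the first light onset, three consecutive 30-min
    Light-On / Light-Off trials at 30 frames/s, strains AB / TL / TLAB
    measured on days 3-9 post-fertilization.  Effect magnitudes are
    simulation knobs: baselines near 0.05-0.1 and On-response peaks of a few
    tenths put the latent rates in the range of real Burst Duration traces.
    """

    # plate layout
    rows: int = 8
    cols: int = 12
    # biology
    strains: dict = field(
        default_factory=lambda: {"AB": 0.070, "TL": 0.060, "TLAB": 0.065}
    )  # per-strain baseline movement rate
    strain_resp_mod: dict = field(
        default_factory=lambda: {"AB": 1.15, "TL": 1.0, "TLAB": 0.85}
    )  # multiplies the stimulus-kernel amplitude
    stages: list = field(default_factory=lambda: [3, 4, 5, 6, 7, 8, 9])
    stage_mult: dict = field(
        default_factory=lambda: {3: 0.6, 4: 0.75, 5: 0.9, 6: 1.0, 7: 1.05, 8: 1.1, 9: 1.1}
    )  # multiplies the baseline rate
    stage_resp_mod: dict = field(
        default_factory=lambda: {3: 0.3, 4: 0.6, 5: 0.85, 6: 1.0, 7: 1.05, 8: 1.05, 9: 1.0}
    )
    # experimental variations
    n_bio_reps: int = 2
    bio_rep_effects: list = field(default_factory=lambda: [0.0, 0.005])
    tech_rep_effects: list = field(default_factory=lambda: [0.0, 0.0, 0.0])
    location_coef: float = 0.0  # radial gradient: rate offset per unit center distance
    # stimulus response kernel (exponential decay to plateau)
    on_amp: float = 0.35
    on_decay: float = 0.45
    on_sustain: float = 0.04
    off_amp: float = 0.25
    off_decay: float = 0.9
    off_sustain: float = 0.09
    # noise model
    animal_sd: float = 0.02  # random-intercept SD
    ar1_rho: float = 0.5
    ar1_innov_sd: float = 0.02
    obs_sd: float = 0.0  # extra observation noise, second mode only
    # sampling / schedule
    fps: int = 30
    dark_adapt_s: int = 12600  # 3.5 h, of which the last record_lead_s are recorded
    record_lead_s: int = 1800  # recording starts 0.5 h before the first onset
    n_trials: int = 3
    phase_len_s: int = 1800  # each Light-On or Light-Off phase, 30 min
    seed: int = 0

    def wells(self) -> list[str]:
        return [
            f"{chr(ord('A') + r)}{c + 1}"
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    def location_offset(self, well_index: int) -> float:
        """Radial illumination gradient: brightest at the plate center.

        Offset = location_coef * (1 - d/d_max) with d the well's distance
        from the plate center, so the center gets the full coefficient and
        the corners get 0.
        """
        r, c = divmod(well_index, self.cols)
        cr, cc = (self.rows - 1) / 2.0, (self.cols - 1) / 2.0
        d = np.hypot(r - cr, c - cc)
        dmax = np.hypot(cr, cc)
        if dmax == 0:  # single-well plate: the well is the center
            return float(self.location_coef)
        return float(self.location_coef * (1.0 - d / dmax))

    def schedule(self) -> StimulusSchedule:
        """Alternating On/Off events; trial i covers its On and Off phase."""
        events = []
        t = self.record_lead_s
        for trial in range(1, self.n_trials + 1):
            events.append({"event_time_s": t, "transition": "on", "trial_index": trial})
            t += self.phase_len_s
            events.append({"event_time_s": t, "transition": "off", "trial_index": trial})
            t += self.phase_len_s
        return StimulusSchedule(pd.DataFrame(events))

    @property
    def total_seconds(self) -> int:
        return self.record_lead_s + 2 * self.n_trials * self.phase_len_s

    def validate(self) -> None:
        if not -1 < self.ar1_rho < 1:
            raise ConfigError(f"ar1_rho must be in (-1, 1), got {self.ar1_rho}")
        if self.fps < 1:
            raise ConfigError("fps must be >= 1")
        if len(self.bio_rep_effects) < self.n_bio_reps:
            raise ConfigError("need one bio_rep effect per biological repeat")
        if len(self.tech_rep_effects) < self.n_trials:
            raise ConfigError("need one tech_rep effect per trial")
        for s in self.stages:
            if s not in self.stage_mult or s not in self.stage_resp_mod:
                raise ConfigError(f"stage {s} missing a multiplier")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cfg = cls(**d)
        # YAML round-trips dict keys as strings; stage keys are ints
        cfg.stage_mult = {int(k): float(v) for k, v in cfg.stage_mult.items()}
        cfg.stage_resp_mod = {int(k): float(v) for k, v in cfg.stage_resp_mod.items()}
        cfg.stages = [int(s) for s in cfg.stages]
        return cfg


def _kernel_trace(cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic stimulus-response contribution at every recorded second."""
    total = cfg.total_seconds
    out = np.zeros(total)  # index i -> second i+1
    sched = cfg.schedule().events
    times = sched["event_time_s"].to_numpy()
    kinds = sched["transition"].to_numpy()
    for j, (e, kind) in enumerate(zip(times, kinds)):
        end = times[j + 1] if j + 1 < len(times) else total
        tau = np.arange(1, end - e + 1)  # relative seconds within the phase
        if kind == "on":
            amp, k, sus = cfg.on_amp, cfg.on_decay, cfg.on_sustain
        else:
            amp, k, sus = cfg.off_amp, cfg.off_decay, cfg.off_sustain
        out[e : end] = amp * np.exp(-k * (tau - 1)) + sus
    return out


def _phase_offsets(cfg: SyntheticConfig) -> np.ndarray:
    """Per-second technical-repeat offset (constant within each trial)."""
    total = cfg.total_seconds
    out = np.zeros(total)
    for trial in range(1, cfg.n_trials + 1):
        start = cfg.record_lead_s + (trial - 1) * 2 * cfg.phase_len_s
        end = start + 2 * cfg.phase_len_s
        out[start:end] = cfg.tech_rep_effects[trial - 1]
    return out


def _animal_rng(cfg: SyntheticConfig, plate_idx: int, stage_idx: int, well_idx: int):
    ss = np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(plate_idx, stage_idx, well_idx)
    )
    return np.random.default_rng(ss)


def generate_plate_experiment(
    cfg: SyntheticConfig,
    seed: int | None = None,
    mode: str = "second",
):
    """Simulate plates for every (strain, biological repeat, stage).

    Returns ``(table, metadata, schedule)`` where ``table`` is an
    :class:`ActivityMatrix` (second mode) or :class:`FrameMovementTable`
    (frame mode), ``metadata`` is one row per animal, and ``schedule`` the
    stimulus schedule.  ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg.validate()
    if seed is not None:
        cfg = SyntheticConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    if mode not in ("second", "frame"):
        raise ConfigError(f"mode must be 'second' or 'frame', got {mode!r}")
    total = cfg.total_seconds
    kernel = _kernel_trace(cfg)
    phase_off = _phase_offsets(cfg)
    seconds = np.arange(1, total + 1)
    wells = cfg.wells()
    loc = np.array([cfg.location_offset(i) for i in range(len(wells))])

    values = []  # one per-animal array of length `total` (or total*fps)
    meta_rows = []
    n_clamped = 0
    plate_idx = 0
    for strain, baseline in cfg.strains.items():
        for rep in range(1, cfg.n_bio_reps + 1):
            plate_id = f"{strain}-r{rep}"
            rep_eff = cfg.bio_rep_effects[rep - 1]
            for stage_idx, stage in enumerate(cfg.stages):
                base = baseline * cfg.stage_mult[stage] + rep_eff
                resp = cfg.strain_resp_mod[strain] * cfg.stage_resp_mod[stage]
                det = base + kernel * resp + phase_off  # deterministic part
                for well_idx, well in enumerate(wells):
                    rng = _animal_rng(cfg, plate_idx, stage_idx, well_idx)
                    u = rng.normal(0.0, cfg.animal_sd) if cfg.animal_sd > 0 else 0.0
                    eps = _ar1(rng, total, cfg.ar1_rho, cfg.ar1_innov_sd)
                    rate = det + loc[well_idx] + u + eps
                    n_clamped += int(((rate < 0) | (rate > 1)).sum())
                    rate = np.clip(rate, 0.0, 1.0)
                    meta_rows.append(
                        {
                            "animal_id": f"{plate_id}-{well}-d{stage}",
                            "strain": strain,
                            "stage_dpf": stage,
                            "well": well,
                            "bio_rep": f"rep{rep}",
                            "plate_id": plate_id,
                        }
                    )
                    if mode == "second":
                        obs = rate
                        if cfg.obs_sd > 0:
                            obs = np.clip(
                                rate + rng.normal(0.0, cfg.obs_sd, size=total), 0.0, 1.0
                            )
                        values.append(obs)
                    else:
                        values.append(rng.binomial(1, np.repeat(rate, cfg.fps)))
                plate_idx += 1
    if n_clamped:
        logger.warning(
            "generate_plate_experiment: clamped %d rate values into [0, 1]; "
            "check effect magnitudes if this is unexpected",
            n_clamped,
        )
    metadata = pd.DataFrame(meta_rows)
    schedule = cfg.schedule()
    n_animals = len(meta_rows)
    animal_ids = metadata["animal_id"].to_numpy()
    if mode == "second":
        data = pd.DataFrame(
            {
                "animal_id": np.repeat(animal_ids, total),
                "second": np.tile(seconds, n_animals),
                "activity": np.concatenate(values),
            }
        ).merge(metadata, on="animal_id")
        return ActivityMatrix(data[ACTIVITY_COLUMNS]), metadata, schedule
    frames = pd.DataFrame(
        {
            "animal_id": np.repeat(animal_ids, total * cfg.fps),
            "frame_index": np.tile(np.arange(total * cfg.fps), n_animals),
            "moved": np.concatenate(values),
        }
    )
    return FrameMovementTable(frames, fps=cfg.fps), metadata, schedule


def _ar1(rng, n: int, rho: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1): eps_t = rho*eps_{t-1} + N(0, innov_sd^2)."""
    if innov_sd <= 0:
        return np.zeros(n)
    innov = rng.normal(0.0, innov_sd, size=n)
    if rho == 0:
        return innov
    from scipy.signal import lfilter

    innov[0] = rng.normal(0.0, innov_sd / np.sqrt(1 - rho**2))
    return lfilter([1.0], [1.0, -rho], innov)


def null_experiment(cfg: SyntheticConfig, seed: int | None = None, mode: str = "second"):
    """Same generator with every group-difference effect zeroed.

    All strains share one baseline (the mean of the configured baselines) and
    one response modulation; stage multipliers, location gradient and repeat
    effects are flattened.  The stimulus kernel is kept — it is common to all
    groups, so no group difference remains.  Used for type-I-error studies.
    """
    d = cfg.to_dict()
    base = float(np.mean(list(cfg.strains.values())))
    d["strains"] = {s: base for s in cfg.strains}
    d["strain_resp_mod"] = {s: 1.0 for s in cfg.strains}
    d["stage_mult"] = {s: 1.0 for s in cfg.stage_mult}
    d["stage_resp_mod"] = {s: 1.0 for s in cfg.stage_resp_mod}
    d["bio_rep_effects"] = [0.0] * len(cfg.bio_rep_effects)
    d["tech_rep_effects"] = [0.0] * len(cfg.tech_rep_effects)
    d["location_coef"] = 0.0
    d["animal_sd"] = cfg.animal_sd
    null_cfg = SyntheticConfig.from_dict(d)
    return generate_plate_experiment(null_cfg, seed=seed, mode=mode)


def power_recovery_study(
    mu1,
    mu2,
    sigma,
    n_grid,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical vs analytic power of the T² test under exact Gaussian data.

    Draws the two groups from N(mu1, sigma) and N(mu2, sigma) (no clamping,
    so the nominal mean and covariance are exact), tabulating the empirical
    rejection rate at each per-group n next to the noncentral-F power.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = len(mu1)
    chol = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        n = int(n)
        tau2 = noncentrality(mu1, mu2, sigma, n, n)
        analytic = power_from_ncp(p, n, n, tau2, alpha)
        rej = 0
        for _ in range(reps):
            X1 = mu1 + rng.standard_normal((n, p)) @ chol.T
            X2 = mu2 + rng.standard_normal((n, p)) @ chol.T
            if hotelling_t2(X1, X2).p_value < alpha:
                rej += 1
        emp = rej / reps
        rows.append(
            {
                "n_per_group": n,
                "ncp": tau2,
                "power_analytic": analytic,
                "power_empirical": emp,
                "discrepancy": emp - analytic,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
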
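"""Seeded generator of study-shaped synthetic IVVM data.

Emulates the measurement structure of a paired euglycemic-hyperinsulinemic
clamp experiment: animals x fields x capillaries, each capillary measured at
baseline and during the clamp, with frame-wise velocity and lineal-density
traces at 21 frames/s for 30 s.

The generative model, per capillary:

* baseline latents: diameter uniform over a configured range; RBC velocity
  and tube hematocrit lognormal around configured means (flows in such data
  are positive and right-skewed); lineal density derived from hematocrit
  and diameter;
* a flow-state class (continuous / intermittent / stopped) drawn with
  configured fractions, with a motion trace built to match the class;
* clamp latents conditional on baseline (a paired design): a velocity
  multiplier with configured mean, and an RBC-flow multiplier whose mean
  percent change decreases linearly with baseline RBC flow (low-flow
  capillaries gain the most, i.e. redistribution), plus lognormal noise;
* observed frames: latent value x independent per-frame jitter.

Ground-truth latents are stored alongside the observed records so recovery
of the programmed effects by the derivation + statistics pipeline can be
tested directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import units
from .ivvm import CapillaryRecord

__all__ = ["StudyConfig", "StudyDataset", "generate_study", "generate_traces"]


@dataclass(frozen=True)
class StudyConfig:
    n_animals: int = 8
    fields_per_animal: int = 10
    capillaries_per_field: int = 3
    # baseline latent distributions
    velocity_mean_mm_s: float = 0.15
    tube_hct_mean: float = 0.17
    diameter_range_um: tuple[float, float] = (3.5, 5.5)
    between_capillary_cv: float = 0.45       # lognormal CV of v and HT across capillaries
    # clamp effects (multiplicative, applied to latents)
    velocity_multiplier_mean: float = 1.49
    rbc_flow_multiplier_mean: float = 1.80
    flow_dependence_pct_per_pl_s: float = -120.0  # d(%RBC-flow change)/d(baseline flow)
    effect_noise_cv: float = 0.15
    # flow states
    flow_state_fractions: tuple[float, float, float] = (0.85, 0.10, 0.05)
    # measurement model
    frame_jitter_cv: float = 0.10
    frame_rate_hz: float = 21.0
    duration_s: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.flow_state_fractions) - 1.0) > 1e-9:
            raise ValueError("flow-state fractions must sum to 1")
        if self.velocity_multiplier_mean <= 0 or self.rbc_flow_multiplier_mean <= 0:
            raise ValueError("effect multipliers must be positive")
        lo, hi = self.diameter_range_um
        if not (2.0 < lo <= hi < 12.0):
            raise ValueError("diameter range must lie within (2, 12) um")
        # a mean tube hct must be attainable at the narrowest diameter
        max_ht = 0.6
        if not (0.0 < self.tube_hct_mean < max_ht):
            raise ValueError(f"tube hct mean must be in (0, {max_ht})")


@dataclass
class StudyDataset:
    baseline: list[CapillaryRecord]
    clamp: list[CapillaryRecord]
    ground_truth: pd.DataFrame
    config: StudyConfig
    meta: dict = field(default_factory=dict)

    def records_frame(self) -> pd.DataFrame:
        """Per-capillary x condition summary table (CSV-ready)."""
        rows = []
        for rec in self.baseline + self.clamp:
            rows.append({
                "capillary_id": rec.capillary_id, "animal_id": rec.animal_id,
                "field_id": rec.field_id, "condition": rec.condition,
                "mean_velocity_mm_s": float(rec.velocity_mm_s.mean()),
                "mean_lineal_density_per_mm": float(rec.lineal_density_per_mm.mean()),
                "diameter_um": rec.diameter_um,
                "segment_length_um": rec.segment_length_um,
            })
        return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal with the requested arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, mean) if size else mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_traces(flow_class: str, rng: np.random.Generator,
                    v_mean_mm_s: float = 0.15, duration_s: float = 30.0,
                    frame_rate_hz: float = 21.0, jitter_cv: float = 0.05) -> np.ndarray:
    """Signed 30-s velocity trace guaranteed to classify as ``flow_class``."""
    n = int(round(duration_s * frame_rate_hz))
    if flow_class == "stopped":
        return np.zeros(n)
    v = np.abs(v_mean_mm_s * (1.0 + jitter_cv * rng.standard_normal(n)))
    v = np.maximum(v, 0.01)          # keep safely above the stationary threshold
    if flow_class == "continuous":
        return v
    if flow_class == "intermittent":
        if rng.random() < 0.5:       # a stop shorter than the full window
            stop_len = int(rng.integers(frame_rate_hz, n // 2))
            start = int(rng.integers(0, n - stop_len))
            v[start:start + stop_len] = 0.0
        else:                        # a direction reversal
            flip = int(rng.integers(n // 4, 3 * n // 4))
            v[flip:] *= -1.0
        return v
    raise ValueError(f"unknown flow class {flow_class!r}")


def generate_study(config: StudyConfig) -> StudyDataset:
    """Generate one paired synthetic study; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.rng_seed)
    n_frames = int(round(config.duration_s * config.frame_rate_hz))
    classes = np.array(["continuous", "intermittent", "stopped"])

    baseline, clamp, truth = [], [], []
    for ai in range(config.n_animals):
        for fi in range(config.fields_per_animal):
            for ci in range(config.capillaries_per_field):
                cap_id = f"a{ai:02d}_f{fi:02d}_c{ci:02d}"
                D = float(rng.uniform(*config.diameter_range_um))
                seg_len = float(rng.uniform(80.0, 250.0))
                v0 = float(_lognormal(rng, config.velocity_mean_mm_s, config.between_capillary_cv))
                ht0 = float(np.clip(_lognormal(rng, config.tube_hct_mean, config.between_capillary_cv),
                                    1e-3, 0.55))
                ld0 = ht0 * math.pi * (D / 2.0) ** 2 * 1000.0 / units.RBC_VOLUME_UM3
                flow_class = str(rng.choice(classes, p=config.flow_state_fractions))
                if flow_class == "stopped":
                    v0 = 0.0
                sr0 = v0 * ld0
                q_rbc0 = sr0 * units.RBC_VOLUME_UM3 * units.UM3_TO_PL      # pL/s

                # clamp latents, conditional on baseline (paired design)
                g_v = float(_lognormal(rng, config.velocity_multiplier_mean, config.effect_noise_cv))
                pct_mean = 100.0 * (config.rbc_flow_multiplier_mean - 1.0)
                pct = pct_mean + config.flow_dependence_pct_per_pl_s * (
                    q_rbc0 - _expected_baseline_flow(config))
                m_flow = max(0.2, (1.0 + pct / 100.0)
                             * float(_lognormal(rng, 1.0, config.effect_noise_cv)))
                v1 = v0 * g_v
                ld1 = ld0 * (m_flow / g_v) if g_v > 0 else ld0
                ht1 = ld1 * units.RBC_VOLUME_UM3 / (math.pi * (D / 2.0) ** 2 * 1000.0)

                def frames(val):
                    if config.frame_jitter_cv == 0:
                        return np.full(n_frames, val)
                    return np.maximum(val * (1.0 + config.frame_jitter_cv
                                             * rng.standard_normal(n_frames)), 0.0)

                trace0 = generate_traces(flow_class, rng, v0 if v0 > 0 else config.velocity_mean_mm_s,
                                         config.duration_s, config.frame_rate_hz)
                trace1 = generate_traces(flow_class, rng, v1 if v1 > 0 else config.velocity_mean_mm_s,
                                         config.duration_s, config.frame_rate_hz)
                common = dict(capillary_id=cap_id, animal_id=f"a{ai:02d}", field_id=f"f{fi:02d}",
                              diameter_um=D, segment_length_um=seg_len,
                              frame_rate_hz=config.frame_rate_hz)
                baseline.append(CapillaryRecord(condition="baseline",
                                                velocity_mm_s=frames(v0),
                                                lineal_density_per_mm=frames(ld0),
                                                motion_trace_mm_s=trace0, **common))
                clamp.append(CapillaryRecord(condition="clamp",
                                             velocity_mm_s=frames(v1),
                                             lineal_density_per_mm=frames(ld1),
                                             motion_trace_mm_s=trace1, **common))
                truth.append({
                    "capillary_id": cap_id, "diameter_um": D, "flow_class": flow_class,
                    "v_baseline": v0, "v_clamp": v1, "ht_baseline": ht0, "ht_clamp": ht1,
                    "ld_baseline": ld0, "ld_clamp": ld1,
                    "q_rbc_baseline_pl_s": q_rbc0, "q_rbc_clamp_pl_s": q_rbc0 * m_flow,
                    "velocity_multiplier": g_v, "flow_multiplier": m_flow,
                })
    gt = pd.DataFrame(truth)
    meta = {"rng_seed": config.rng_seed, "config": asdict(config)}
    return StudyDataset(baseline=baseline, clamp=clamp, ground_truth=gt,
                        config=config, meta=meta)


def _expected_baseline_flow(config: StudyConfig) -> float:
    """Expected baseline RBC flow (pL/s) under the configured latent means.

    Centering the flow-dependent effect here keeps the configured mean flow
    multiplier approximately equal to rbc_flow_multiplier_mean.
    """
    lo, hi = config.diameter_range_um
    d2_mean = (lo * lo + lo * hi + hi * hi) / 3.0   # E[D^2] for uniform D
    ld_mean = config.tube_hct_mean * math.pi * d2_mean / 4.0 * 1000.0 / units.RBC_VOLUME_UM3
    sr_mean = config.velocity_mean_mm_s * ld_mean   # v and HT independent
    frac_perfused = 1.0 - config.flow_state_fractions[2]
    return sr_mean * units.RBC_VOLUME_UM3 * units.UM3_TO_PL * frac_perfused
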
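"""Synthetic wrist-sensor cohort with known ground truth.

No public dataset exists for this measurement pipeline, so the generator
manufactures one with the statistical structure the method assumes: a
ground-truth relation BG = F(H, SpO2, HR, BF) made explicit and invertible.
For every record it

1. draws a per-subject meal trajectory for true blood glucose — a fasting
   baseline plus a postprandial bump that peaks 30–60 min after the meal —
   sampled at five protocol time points (30 min before a meal and 30, 60,
   90, 120 min after), clipped to the configured glucose range;
2. draws the vitals SpO2, HR, BF from physiological ranges;
3. inverts F for the metabolic heat H the true glucose demands, then solves
   the energy-balance equation for a skin temperature tw (with ambient
   temperature, humidity and a radiometric offset drawn first) so the
   sensor frame reproduces exactly that H — rejected draws are resampled;
4. synthesises a two-channel PPG waveform whose beat rate is the target HR
   and whose AC/DC amplitude ratio maps to the target SpO2 through the
   Beer–Lambert coefficients;
5. records the reference glucose as the true value under multiplicative
   Gaussian observation noise (default 5% sd), clipped to the glucose range.

Everything is reproducible from the seed.  Two truth families are
registered: ``"mpr4-span"`` lies exactly in the interaction-polynomial span
(so that model can recover it perfectly at zero noise), ``"saturating"``
puts a logistic curvature on H that no interaction polynomial can represent
(so the network has a genuine nonlinearity to win on).

The generator emulates cohort *structure*, not physiology: real skin-heat
and PPG data carry motion artifacts, sensor drift, and inter-subject
calibration differences that are absent here, so recovery results bound
method correctness, not clinical accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .energy import DEFAULT_CONSTANTS, EnergyConstants, SensorFrame, metabolic_heat
from .models import build_design_matrix
from .ppg import (
    DEFAULT_COEFFICIENTS,
    AbsorptionCoefficients,
    PPGWaveform,
    ratio_from_saturation,
)

__all__ = [
    "CohortConfig",
    "SyntheticRecord",
    "TRUTH_MPR4_PARAMS",
    "SATURATING_PARAMS",
    "ground_truth_F",
    "invert_truth_for_H",
    "generate_ppg",
    "generate_cohort",
    "cohort_feature_table",
]

logger = logging.getLogger(__name__)

TIMEPOINT_LABELS = ("pre-meal", "30min", "60min", "90min", "120min")
_TIMEPOINT_MINUTES = (-30.0, 30.0, 60.0, 90.0, 120.0)


# -- ground-truth families ---------------------------------------------------

# "mpr4-span": glucose is an exact interaction polynomial of the predictors.
# Coefficients are in MPR4 term order (intercept, then MPR4_TERMS); every
# term touching H is zero except the linear one, so inversion for H is exact.
TRUTH_MPR4_PARAMS = np.array(
    [
        -25.0,          # intercept
        0.055,          # H
        0.003,          # SpO2
        0.012,          # HR
        0.02,           # BF
        0.0, 0.0, 0.0,  # H*SpO2, H*HR, H*BF
        0.0, 0.0,       # SpO2*HR, SpO2*BF
        1e-5,           # HR*BF
        0.0, 0.0, 0.0, 0.0, 0.0,
    ]
)

# "saturating": logistic dependence on H plus small linear vital terms.
# BG = b0 + b1 / (1 + exp(-(H - h0)/hs)) + c_hr (HR-75) + c_spo2 (SpO2-96)
#      + c_bf (BF-50)
SATURATING_PARAMS = {
    "b0": 3.3,
    "b1": 7.6,
    "h0": 525.0,
    "hs": 6.0,
    "c_hr": 0.010,
    "c_spo2": 0.02,
    "c_bf": 0.006,
}


def _saturating_linear(SpO2, HR, BF, p) -> np.ndarray:
    return (
        p["c_hr"] * (np.asarray(HR) - 75.0)
        + p["c_spo2"] * (np.asarray(SpO2) - 96.0)
        + p["c_bf"] * (np.asarray(BF) - 50.0)
    )


def ground_truth_F(H, SpO2, HR, BF, family: str = "mpr4-span") -> np.ndarray:
    """Evaluate the configured truth BG = F(H, SpO2, HR, BF), mmol/L."""
    H, SpO2, HR, BF = np.broadcast_arrays(
        np.asarray(H, float), np.asarray(SpO2, float),
        np.asarray(HR, float), np.asarray(BF, float),
    )
    X = np.column_stack([H.ravel(), SpO2.ravel(), HR.ravel(), BF.ravel()])
    if family == "mpr4-span":
        out = TRUTH_MPR4_PARAMS[0] + build_design_matrix(X) @ TRUTH_MPR4_PARAMS[1:]
    elif family == "saturating":
        p = SATURATING_PARAMS
        out = (
            p["b0"]
            + p["b1"] / (1.0 + np.exp(-(X[:, 0] - p["h0"]) / p["hs"]))
            + _saturating_linear(X[:, 1], X[:, 2], X[:, 3], p)
        )
    else:
        raise ValueError(f"unknown ground-truth family {family!r}")
    return out.reshape(H.shape) if H.shape else float(out[0])


def invert_truth_for_H(bg, SpO2, HR, BF, family: str = "mpr4-span") -> float:
    """Metabolic heat demanded by a true glucose under the truth relation."""
    if family == "mpr4-span":
        a = TRUTH_MPR4_PARAMS
        # with all H-interaction coefficients zero the relation is affine in H
        rest = a[0] + a[2] * SpO2 + a[3] * HR + a[4] * BF + a[10] * HR * BF
        return (bg - rest) / a[1]
    if family == "saturating":
        p = SATURATING_PARAMS
        u = (bg - p["b0"] - float(_saturating_linear(SpO2, HR, BF, p))) / p["b1"]
        if not 0.0 < u < 1.0:
            raise ValueError(
                f"glucose {bg} mmol/L outside the saturating family's image "
                "for these vitals"
            )
        return p["h0"] + p["hs"] * math.log(u / (1.0 - u))
    raise ValueError(f"unknown ground-truth family {family!r}")


# -- configuration -----------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the clinical protocol this pipeline targets: 211
    records from healthy adults, reference glucose confined to
    [4.1, 10] mmol/L, five time points per meal series, 5% multiplicative
    observation noise on the reference glucose.
    """

    n_records: int = 211
    bg_range: tuple[float, float] = (4.1, 10.0)
    noise_sd: float = 0.05            # multiplicative, on reference BG
    seed: int = 0
    truth_family: str = "mpr4-span"
    n_volunteers: int = 12
    # vitals ranges (healthy adults at rest)
    spo2_range: tuple[float, float] = (94.0, 99.0)
    hr_range: tuple[float, float] = (55.0, 100.0)
    bf_range: tuple[float, float] = (20.0, 80.0)
    # ambient / sensor draw ranges used by the energy-balance inversion
    ts_range: tuple[float, float] = (20.0, 30.0)
    he_range: tuple[float, float] = (0.2, 0.8)
    tr_offset_range: tuple[float, float] = (-3.0, 3.0)   # K, about tw+273.15
    tw_bounds: tuple[float, float] = (28.5, 37.5)        # deg C solve bracket
    # waveform synthesis
    Fs: float = 100.0
    duration: float = 10.0
    max_retries: int = 100
    constants: EnergyConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    coefficients: AbsorptionCoefficients = field(
        default_factory=lambda: DEFAULT_COEFFICIENTS
    )

    def __post_init__(self) -> None:
        lo, hi = self.bg_range
        if not (0 < lo < hi):
            raise ValueError(f"bg_range must satisfy 0 < min < max, got {self.bg_range}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


@dataclass(frozen=True)
class SyntheticRecord:
    """One generated measurement episode with its ground truth."""

    record_id: int
    subject_id: int
    timepoint_label: str
    frame: SensorFrame
    waveform: PPGWaveform
    H_true: float
    HR_true: float
    SpO2_true: float
    BF: float
    BG_true: float
    BG_ref: float
    seed: int
    draw_index: int


# -- PPG synthesis -----------------------------------------------------------

# Pulse template: systolic lobe plus a smaller dicrotic lobe, as fractions of
# the beat period.
_PULSE_CENTERS = (0.30, 0.62)
_PULSE_WIDTHS = (0.10, 0.16)
_PULSE_GAINS = (1.0, 0.25)


def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    p = np.zeros_like(phase)
    for c, w, g in zip(_PULSE_CENTERS, _PULSE_WIDTHS, _PULSE_GAINS):
        p += g * np.exp(-(((phase - c) / w) ** 2))
    return p


def generate_ppg(
    target_HR: float,
    target_SpO2: float,
    coeffs: AbsorptionCoefficients = DEFAULT_COEFFICIENTS,
    Fs: float = 100.0,
    duration: float = 10.0,
    dc_red: float = 1.0,
    dc_ir: float = 1.2,
    ir_perfusion: float = 0.04,
) -> PPGWaveform:
    """Two-channel pulse waveform hitting a target heart rate and SpO2.

    The infrared channel carries an AC/DC perfusion index ``ir_perfusion``
    (default 4%, a typical resting value); the red amplitude is set so that
    the measured ratio of ratios equals the one the Beer–Lambert relation
    assigns to ``target_SpO2`` under ``coeffs``.  Amplitudes are corrected
    for the template's mean so the AC/DC estimator round-trips exactly.
    """
    if not 40.0 <= target_HR <= 180.0:
        raise ValueError(f"target HR must be in [40, 180] bpm, got {target_HR}")
    if not 0.0 <= target_SpO2 <= 100.0:
        raise ValueError(f"target SpO2 must be in [0, 100] %, got {target_SpO2}")
    if dc_red <= 0 or dc_ir <= 0:
        raise ValueError("DC levels must be positive")
    r = ratio_from_saturation(target_SpO2, coeffs)
    t = np.arange(int(round(Fs * duration))) / Fs
    period = 60.0 / target_HR
    phase = (t / period) % 1.0
    p = _pulse_shape(phase)
    p_span = float(p.max() - p.min())
    p_mean = float(p.mean())

    def amplitude(ratio: float) -> float:
        denom = p_span - ratio * p_mean
        a = ratio / denom
        if a <= 0 or denom <= 0:
            raise ValueError(
                f"AC/DC ratio {ratio:.4f} not realisable with this pulse template"
            )
        return a

    a_ir = amplitude(ir_perfusion)
    a_red = amplitude(r * ir_perfusion)
    red = dc_red * (1.0 + a_red * p)
    ir = dc_ir * (1.0 + a_ir * p)
    return PPGWaveform(red=red, ir=ir, Fs=Fs)


# -- cohort assembly ---------------------------------------------------------


def _meal_bg(baseline: float, amp: float, t_peak: float, minutes: float) -> float:
    """Rise-then-fall postprandial excursion (gamma-shaped bump)."""
    if minutes <= 0:
        return baseline
    x = minutes / t_peak
    return baseline + amp * x * math.exp(1.0 - x)


def _solve_frame_for_H(
    H_target: float, cfg: CohortConfig, rng: np.random.Generator, BF: float
) -> SensorFrame:
    """Draw (ts, He, Tr offset) and solve the energy balance for tw."""
    for _ in range(cfg.max_retries):
        ts = rng.uniform(*cfg.ts_range)
        He = rng.uniform(*cfg.he_range)
        off = rng.uniform(*cfg.tr_offset_range)
        lo = max(cfg.tw_bounds[0], ts + 0.2)
        hi = cfg.tw_bounds[1]
        if lo >= hi:
            continue

        def total(tw: float) -> float:
            frame = SensorFrame(Tr=tw + 273.15 + off, tw=tw, ts=ts, He=He, BF=BF)
            return metabolic_heat(frame, cfg.constants).H - H_target

        try:
            f_lo, f_hi = total(lo), total(hi)
        except ValueError:
            continue
        if f_lo > 0 or f_hi < 0:
            continue  # target heat not bracketed by this ambient draw
        tw = brentq(total, lo, hi, xtol=1e-10)
        return SensorFrame(Tr=tw + 273.15 + off, tw=tw, ts=ts, He=He, BF=BF)
    raise RuntimeError(
        f"no admissible sensor frame found for H={H_target:.1f} W/m^2 "
        f"after {cfg.max_retries} draws"
    )


def generate_cohort(config: CohortConfig | None = None) -> list[SyntheticRecord]:
    """Generate the full synthetic cohort (deterministic in ``config.seed``)."""
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bg_range
    records: list[SyntheticRecord] = []
    n_clipped = 0
    draw = 0
    series = 0
    while len(records) < cfg.n_records:
        subject = series % cfg.n_volunteers + 1
        baseline = float(np.clip(rng.normal(5.2, 0.4), lo + 0.2, 5.9))
        amp = float(np.clip(rng.lognormal(0.6, 0.45), 0.6, 4.8))
        t_peak = rng.uniform(30.0, 60.0)
        for label, minutes in zip(TIMEPOINT_LABELS, _TIMEPOINT_MINUTES):
            if len(records) >= cfg.n_records:
                break
            bg_true = _meal_bg(baseline, amp, t_peak, minutes)
            if not lo <= bg_true <= hi:
                n_clipped += 1
                bg_true = float(np.clip(bg_true, lo, hi))
            spo2 = rng.uniform(*cfg.spo2_range)
            hr = rng.uniform(*cfg.hr_range)
            bf = rng.uniform(*cfg.bf_range)
            H = invert_truth_for_H(bg_true, spo2, hr, bf, cfg.truth_family)
            frame = _solve_frame_for_H(H, cfg, rng, bf)
            waveform = generate_ppg(
                hr, spo2, cfg.coefficients, Fs=cfg.Fs, duration=cfg.duration,
                dc_red=rng.uniform(0.8, 1.2), dc_ir=rng.uniform(1.0, 1.5),
            )
            bg_ref = bg_true
            if cfg.noise_sd > 0:
                bg_ref = bg_true * (1.0 + cfg.noise_sd * rng.standard_normal())
                if not lo <= bg_ref <= hi:
                    n_clipped += 1
                    bg_ref = float(np.clip(bg_ref, lo, hi))
            records.append(
                SyntheticRecord(
                    record_id=len(records) + 1,
                    subject_id=subject,
                    timepoint_label=label,
                    frame=frame,
                    waveform=waveform,
                    H_true=H,
                    HR_true=hr,
                    SpO2_true=spo2,
                    BF=bf,
                    BG_true=bg_true,
                    BG_ref=bg_ref,
                    seed=cfg.seed,
                    draw_index=draw,
                )
            )
            draw += 1
        series += 1
    if n_clipped:
        logger.info("clipped %d glucose values into [%g, %g] mmol/L", n_clipped, lo, hi)
    return records


def cohort_feature_table(records: list[SyntheticRecord]):
    """Ground-truth feature table (pandas DataFrame) for model-level work.

    Columns H, SpO2, HR, BF carry the generator's true values; ``BG_ref`` is
    the noisy reference and ``BG_true`` the latent truth.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "timepoint_label": [r.timepoint_label for r in records],
            "H": [r.H_true for r in records],
            "SpO2": [r.SpO2_true for r in records],
            "HR": [r.HR_true for r in records],
            "BF": [r.BF for r in records],
            "BG_true": [r.BG_true for r in records],
            "BG_ref": [r.BG_ref for r in records],
        }
    )
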
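"""Heart rate and SpO2 from dual-wavelength reflective PPG.

A reflective probe records backscattered light at 660 nm (red) and 880 nm
(near-infrared).  Pulsatile arterial blood modulates both channels; the
ratio of the normalised pulsatile amplitudes

    r = (AC_red / DC_red) / (AC_ir / DC_ir)

(the pulse-oximetry "ratio of ratios") depends only on the oxygen saturation
of the arterial blood through the Beer–Lambert absorption coefficients of
oxy- and deoxyhemoglobin at the two wavelengths:

    SpO2 = 100 * (K2_ir * r - K2_red) / ((K2_ir - K1_ir) * r + (K1_red - K2_red))

where K1 are oxyhemoglobin and K2 deoxyhemoglobin coefficients.  Heart rate
comes from the systolic peak train:

    HR = Fs * (Npeak - 1) / (x_end - x_start) * 60    [bpm]

with Fs the sampling frequency and x_start/x_end the first and last peak
sample positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PPGWaveform",
    "PeakSet",
    "AbsorptionCoefficients",
    "VitalSigns",
    "InsufficientPulsatilityError",
    "DEFAULT_COEFFICIENTS",
    "detect_peaks",
    "heart_rate",
    "perfusion_ratio",
    "spo2_from_ratio",
    "ratio_from_saturation",
    "vitals_from_waveform",
]


class InsufficientPulsatilityError(ValueError):
    """Raised when a channel carries no usable pulse (fewer than 2 peaks)."""


@dataclass(frozen=True)
class PPGWaveform:
    """Two-channel PPG record: 660 nm (red) and 880 nm (infrared) at Fs Hz."""

    red: np.ndarray
    ir: np.ndarray
    Fs: float

    def __post_init__(self) -> None:
        red = np.asarray(self.red, dtype=float)
        ir = np.asarray(self.ir, dtype=float)
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "ir", ir)
        if self.Fs <= 0:
            raise ValueError(f"Fs must be positive, got {self.Fs}")
        if red.shape != ir.shape or red.ndim != 1:
            raise ValueError("red and ir channels must be 1-D arrays of equal length")
        if len(red) < 2 * self.Fs:
            raise ValueError(
                f"waveform too short: {len(red)} samples < 2 s at Fs={self.Fs}"
            )
        if not (np.all(np.isfinite(red)) and np.all(np.isfinite(ir))):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.red) / self.Fs


@dataclass(frozen=True)
class PeakSet:
    """Systolic peak positions (sample indices, strictly increasing)."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or (len(idx) > 1 and np.any(np.diff(idx) <= 0)):
            raise ValueError("peak indices must be a strictly increasing 1-D sequence")

    @property
    def Npeak(self) -> int:
        return len(self.indices)

    @property
    def xstart(self) -> int:
        return int(self.indices[0])

    @property
    def xend(self) -> int:
        return int(self.indices[-1])


@dataclass(frozen=True)
class AbsorptionCoefficients:
    """Hemoglobin absorption coefficients at the two probe wavelengths.

    K1_* are oxyhemoglobin, K2_* deoxyhemoglobin coefficients (arbitrary but
    consistent units; only ratios matter).  Physically deoxyhemoglobin
    absorbs more red light and oxyhemoglobin more infrared, which is exactly
    the condition for the saturation curve to decrease in r — enforced here.

    Defaults are tabulated hemoglobin extinction values at 660/880 nm
    (cm^-1 / M); they are configuration, not calibration: every computation
    accepts explicit coefficients.
    """

    K1_red: float = 319.6
    K2_red: float = 3226.56
    K1_ir: float = 1214.0
    K2_ir: float = 726.44

    def __post_init__(self) -> None:
        vals = (self.K1_red, self.K2_red, self.K1_ir, self.K2_ir)
        if any(v <= 0 for v in vals):
            raise ValueError("absorption coefficients must all be positive")
        if not (self.K2_red > self.K1_red and self.K1_ir > self.K2_ir):
            raise ValueError(
                "need K2_red > K1_red and K1_ir > K2_ir (deoxyhemoglobin absorbs "
                "more red, oxyhemoglobin more infrared)"
            )


DEFAULT_COEFFICIENTS = AbsorptionCoefficients()


@dataclass(frozen=True)
class VitalSigns:
    """PPG-derived vitals: HR (bpm), perfusion ratio r, SpO2 (%)."""

    HR: float
    r: float
    SpO2: float


# Band-pass corners (Hz) for pulse conditioning: 0.5 Hz keeps 30 bpm
# fundamentals, 8 Hz keeps enough harmonics for sharp systolic peaks.
_BAND_LOW_HZ = 0.5
_BAND_HIGH_HZ = 8.0
_MAX_HR_BPM = 220.0
_PROMINENCE_FRACTION = 0.4  # of filtered peak-to-peak; rejects dicrotic waves


def _bandpass(x: np.ndarray, Fs: float) -> np.ndarray:
    """Zero-phase band-pass conditioning with generous edge padding."""
    nyq = Fs / 2.0
    high = min(_BAND_HIGH_HZ, 0.9 * nyq)
    sos = sps.butter(2, [_BAND_LOW_HZ / nyq, high / nyq], btype="band", output="sos")
    padlen = min(len(x) - 1, int(3 * Fs))  # cushion slow-band edge transients
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def detect_peaks(channel: np.ndarray, Fs: float) -> PeakSet:
    """Locate systolic peaks in one PPG channel.

    The channel is band-pass filtered (0.5–8 Hz, zero phase), then local
    maxima are kept if separated by at least ``Fs * 60 / 220`` samples (a
    220 bpm ceiling) and prominent by at least 40% of the filtered
    peak-to-peak range.  Deterministic for a fixed input.

    Raises
    ------
    InsufficientPulsatilityError
        If fewer than two qualifying peaks exist (e.g. a flat signal).
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < 2 * Fs:
        raise ValueError(f"channel too short: {len(x)} samples < 2 s at Fs={Fs}")
    y = _bandpass(x, Fs)
    ptp = float(np.ptp(y))
    # absolute floor: a numerically flat channel leaves only rounding residue
    floor = 1e-9 * max(1.0, float(np.max(np.abs(x))))
    if ptp <= floor or not np.isfinite(ptp):
        raise InsufficientPulsatilityError("no pulsatile component in channel")
    min_dist = max(1, int(round(Fs * 60.0 / _MAX_HR_BPM)))
    idx, _ = sps.find_peaks(y, distance=min_dist, prominence=_PROMINENCE_FRACTION * ptp)
    if len(idx) < 2:
        raise InsufficientPulsatilityError(
            f"found {len(idx)} peak(s); at least 2 needed for a pulse rate"
        )
    return PeakSet(indices=idx)


def heart_rate(peaks: PeakSet, Fs: float) -> float:
    """Heart rate in bpm: ``Fs * (Npeak - 1) / (xend - xstart) * 60``."""
    if peaks.Npeak < 2:
        raise InsufficientPulsatilityError("heart rate needs at least 2 peaks")
    return Fs * (peaks.Npeak - 1) / (peaks.xend - peaks.xstart) * 60.0


def _ac_amplitude(x: np.ndarray, beat_peaks: np.ndarray) -> float:
    """Mean per-beat pulsatile amplitude: peak minus the following trough.

    Beat windows are delimited by consecutive peak positions of the timing
    channel, so a channel with no pulsation of its own yields 0 rather than
    noise-driven extrema.
    """
    amps = []
    for a, b in zip(beat_peaks[:-1], beat_peaks[1:]):
        seg = x[a : b + 1]
        amps.append(float(np.max(seg) - np.min(seg)))
    return float(np.mean(amps))


def perfusion_ratio(waveform: PPGWaveform) -> float:
    """Ratio of ratios ``(AC_red/DC_red) / (AC_ir/DC_ir)``.

    AC is the mean per-beat peak-to-trough amplitude over beat windows set by
    the infrared channel's peaks (the stronger channel in reflective probes);
    DC is the channel mean over the record.

    Raises
    ------
    InsufficientPulsatilityError
        If the infrared channel has no usable pulse.
    ValueError
        If either channel's DC level is not positive, or the infrared AC is 0.
    """
    dc_red = float(np.mean(waveform.red))
    dc_ir = float(np.mean(waveform.ir))
    if dc_red <= 0 or dc_ir <= 0:
        raise ValueError("both channels need a positive DC level")
    beats = detect_peaks(waveform.ir, waveform.Fs).indices
    ac_ir = _ac_amplitude(waveform.ir, beats)
    if ac_ir == 0:
        raise ValueError("infrared channel has zero pulsatile amplitude")
    ac_red = _ac_amplitude(waveform.red, beats)
    return (ac_red / dc_red) / (ac_ir / dc_ir)


def spo2_from_ratio(
    r: float, coeffs: AbsorptionCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Oxygen saturation (%) from the perfusion ratio.

    Evaluates the Beer–Lambert inversion
    ``100 * (K2_ir*r - K2_red) / ((K2_ir - K1_ir)*r + (K1_red - K2_red))``
    and clamps to [0, 100] with a warning when r falls slightly outside the
    physiological range (rather than erroring on sensor noise).
    """
    denom = (coeffs.K2_ir - coeffs.K1_ir) * r + (coeffs.K1_red - coeffs.K2_red)
    if abs(denom) < 1e-12 * max(abs(coeffs.K2_red), abs(coeffs.K1_ir)):
        raise ZeroDivisionError(
            f"saturation formula singular at r={r} for these coefficients"
        )
    s = 100.0 * (coeffs.K2_ir * r - coeffs.K2_red) / denom
    if not 0.0 <= s <= 100.0:
        warnings.warn(
            f"SpO2 {s:.2f}% outside [0, 100]; clamping (r={r} out of range)",
            stacklevel=2,
        )
        s = min(100.0, max(0.0, s))
    return s


def ratio_from_saturation(
    s_percent: float, coeffs: AbsorptionCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Forward Beer–Lambert map: perfusion ratio for a given saturation.

    With oxygenated fraction ``s`` the two-wavelength absorption ratio is
    ``(K1_red*s + K2_red*(1-s)) / (K1_ir*s + K2_ir*(1-s))``.  This is the
    exact inverse of :func:`spo2_from_ratio` and is what the synthetic
    generator uses to target a saturation.
    """
    s = s_percent / 100.0
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"saturation must be in [0, 100] percent, got {s_percent}")
    num = coeffs.K1_red * s + coeffs.K2_red * (1.0 - s)
    den = coeffs.K1_ir * s + coeffs.K2_ir * (1.0 - s)
    return num / den


def vitals_from_waveform(
    waveform: PPGWaveform, coeffs: AbsorptionCoefficients = DEFAULT_COEFFICIENTS
) -> VitalSigns:
    """Full vitals extraction: peaks -> HR, ratio of ratios -> SpO2."""
    peaks = detect_peaks(waveform.ir, waveform.Fs)
    hr = heart_rate(peaks, waveform.Fs)
    r = perfusion_ratio(waveform)
    return VitalSigns(HR=hr, r=r, SpO2=spo2_from_ratio(r, coeffs))
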
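"""Tumor motion waveforms: construction, scaling and control-point mapping.

Displacements are 3-vectors (SI, AP, LR) in mm, exhale-positive along SI.
A waveform is either a replicated single 4DCT breathing cycle (ten phases),
a multi-breath free-breathing trace (2 Hz over ~120 s), or a synthetic
cos^2n breathing-model trace.  Motion-amplitude variation during delivery
is modelled by linearly enlarging the peak-to-peak SI range by a fixed
number of millimetres while preserving the waveform shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SI",
    "AP",
    "LR",
    "EPS_RANGE",
    "MotionWaveform",
    "BreathingModelParams",
    "cycle_to_waveform",
    "concatenate_segments",
    "scale_amplitude",
    "surrogate_rescale",
    "synthesize_breathing",
    "resample_to_control_points",
    "read_waveform_csv",
    "write_waveform_csv",
]

#: axis indices in the displacement vectors
SI, AP, LR = 0, 1, 2

#: below this peak-to-peak SI range (mm) a waveform is treated as motionless
EPS_RANGE = 1e-6

_SOURCES = ("4DCT", "TR4DMRI", "SYNTHETIC")


@dataclass
class MotionWaveform:
    """Ordered displacement samples of a moving target.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)`` with columns (SI, AP, LR) in mm.  A 1-D
        array is promoted to SI-only motion.
    dt
        Uniform sample interval in seconds, or ``None`` when the samples
        are indexed per control point rather than in time.
    source
        One of ``"4DCT"``, ``"TR4DMRI"``, ``"SYNTHETIC"``.
    """

    samples: np.ndarray
    dt: float | None = None
    source: str = "SYNTHETIC"
    native_range_si: float = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if s.shape[0] < 2:
            raise ValueError("a waveform needs at least 2 samples")
        if not np.all(np.isfinite(s)):
            raise ValueError("waveform samples must be finite")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        self.samples = s
        self.native_range_si = float(s[:, SI].max() - s[:, SI].min())

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def si(self) -> np.ndarray:
        return self.samples[:, SI]

    @property
    def duration_s(self) -> float | None:
        """Cyclic duration (one period past the last sample)."""
        return None if self.dt is None else len(self) * self.dt

    def peak_to_peak_si(self) -> float:
        return float(self.si.max() - self.si.min())


@dataclass
class BreathingModelParams:
    """Parameters of the cos^2n breathing model with drift and jitter.

    The SI trace is ``drift(t) - A_b * cos^(2n)(pi t / tau) + noise`` where
    ``A_b`` carries a per-breath amplitude jitter; with drift, jitter and
    noise all zero the peak-to-peak range is exactly ``amplitude_mm``.
    """

    period_s: float = 4.0
    amplitude_mm: float = 8.5
    shape_n: int = 2
    drift_mm_per_min: float = 0.0
    jitter_sd: float = 0.0
    noise_sd_mm: float = 0.0
    duration_s: float = 120.0
    sample_hz: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be non-negative")
        if self.shape_n < 1:
            raise ValueError("shape_n must be >= 1")
        if self.sample_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sample_hz and duration_s must be positive")


def cycle_to_waveform(
    phase_coms: np.ndarray,
    n_repeats: int,
    period_s: float = 4.0,
    source: str = "4DCT",
) -> MotionWaveform:
    """Turn per-phase GTV centre-of-mass positions into a periodic waveform.

    The COM positions of the (typically ten) 4DCT phases are converted to
    displacements about their mean and replicated ``n_repeats`` times to
    yield a multi-breath trace; one replicate spans ``period_s`` seconds.
    """
    coms = np.asarray(phase_coms, dtype=float)
    if coms.ndim == 1:
        coms = np.column_stack([coms, np.zeros_like(coms), np.zeros_like(coms)])
    if coms.shape[0] < 2:
        raise ValueError("at least 2 phases are required")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    disp = coms - coms.mean(axis=0)
    samples = np.tile(disp, (n_repeats, 1))
    return MotionWaveform(samples, dt=period_s / coms.shape[0], source=source)


def concatenate_segments(segments: list[MotionWaveform]) -> MotionWaveform:
    """Concatenate waveform segments (e.g. three 40-s scans) in time."""
    if not segments:
        raise ValueError("need at least one segment")
    dts = {w.dt for w in segments}
    if len(dts) > 1:
        raise ValueError(f"segments have mismatched sample intervals: {sorted(dts, key=str)}")
    samples = np.concatenate([w.samples for w in segments], axis=0)
    return MotionWaveform(samples, dt=segments[0].dt, source=segments[0].source)


def _cos2n_template(n_samples: int, dt: float | None, period_s: float = 4.0, n: int = 2) -> np.ndarray:
    """Canonical cos^2n SI trace rescaled to exact unit peak-to-peak."""
    if dt is None:
        t = np.arange(n_samples, dtype=float)  # one sample per breath tenth
        dt_eff = period_s / 10.0
        t = t * dt_eff
    else:
        t = np.arange(n_samples) * dt
    raw = np.cos(np.pi * t / period_s) ** (2 * n)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:  # fewer samples than half a breath
        raw = np.cos(np.linspace(0.0, np.pi, n_samples)) ** (2 * n)
        lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


def scale_amplitude(
    w: MotionWaveform,
    extra_mm: float,
    anchor: str = "EXHALE_EXTREME",
) -> MotionWaveform:
    """Linearly enlarge the SI peak-to-peak range by ``extra_mm``.

    The SI trace is scaled about an anchor point so its peak-to-peak range
    becomes ``R + extra_mm``; the shape (and hence any multi-breath
    irregularity) is preserved.  ``anchor="EXHALE_EXTREME"`` keeps the
    exhale plateau (the SI maximum, exhale being positive) fixed so the
    added excursion extends the inhale side; ``"MIDRANGE"`` scales
    symmetrically about the mid-range level.  AP/LR components pass
    through unchanged.

    A motionless input (range below ``EPS_RANGE``) cannot be scaled
    multiplicatively; a canonical cos^4 template with peak-to-peak exactly
    ``extra_mm`` is substituted with a warning.
    """
    if extra_mm < 0:
        raise ValueError("extra_mm must be non-negative")
    if anchor not in ("EXHALE_EXTREME", "MIDRANGE"):
        raise ValueError("anchor must be EXHALE_EXTREME or MIDRANGE")
    r = w.peak_to_peak_si()
    if extra_mm == 0:
        return replace(w, samples=w.samples.copy())
    out = w.samples.copy()
    if r <= EPS_RANGE:
        warnings.warn(
            "motionless waveform: substituting a cos^4 template with "
            f"peak-to-peak {extra_mm} mm",
            stacklevel=2,
        )
        tmpl = _cos2n_template(len(w), w.dt)
        si = extra_mm * tmpl
        out[:, SI] = si - si.mean()
    else:
        si = w.si
        a = si.max() if anchor == "EXHALE_EXTREME" else 0.5 * (si.max() + si.min())
        out[:, SI] = a + (si - a) * (r + extra_mm) / r
    return replace(w, samples=out)


def surrogate_rescale(surrogate: MotionWaveform, tumor_range: float) -> MotionWaveform:
    """Scale a surrogate trace (e.g. diaphragm) point-wise to a target range.

    Every displacement is multiplied by ``tumor_range / R_surrogate`` so the
    output SI peak-to-peak equals ``tumor_range`` and the trace remains
    perfectly correlated with the surrogate.
    """
    if tumor_range < 0:
        raise ValueError("tumor_range must be non-negative")
    r = surrogate.peak_to_peak_si()
    if r <= EPS_RANGE:
        raise ValueError("surrogate waveform has zero SI range")
    return replace(surrogate, samples=surrogate.samples * (tumor_range / r))


def synthesize_breathing(p: BreathingModelParams) -> MotionWaveform:
    """Generate a synthetic multi-breath SI trace from the cos^2n model.

    Emulates a free-breathing time-resolved acquisition: a cos^2n breathing
    shape with per-breath amplitude jitter, a linear baseline drift and
    additive measurement noise.  The output is mean-centred; it is
    deterministic for a given seed.
    """
    n = int(round(p.duration_s * p.sample_hz))
    t = np.arange(n) / p.sample_hz
    rng = np.random.default_rng(p.seed)
    breath = (t // p.period_s).astype(int)
    amp = p.amplitude_mm * np.maximum(
        0.0, 1.0 + p.jitter_sd * rng.standard_normal(breath.max() + 1)
    )
    si = (
        p.drift_mm_per_min * t / 60.0
        - amp[breath] * np.cos(np.pi * t / p.period_s) ** (2 * p.shape_n)
    )
    if p.noise_sd_mm > 0:
        si = si + p.noise_sd_mm * rng.standard_normal(n)
    si = si - si.mean()
    samples = np.column_stack([si, np.zeros(n), np.zeros(n)])
    return MotionWaveform(samples, dt=1.0 / p.sample_hz, source="SYNTHETIC")


def resample_to_control_points(
    w: MotionWaveform, n_cp: int, seconds_per_cp: float
) -> np.ndarray:
    """Sample the waveform at control-point times, wrapping cyclically.

    Control point ``k`` is delivered at time ``k * seconds_per_cp``; if the
    plan outlasts the waveform the trace repeats with period
    ``len(w) * dt``.  Returns an ``(n_cp, 3)`` displacement array.
    """
    if n_cp < 1:
        raise ValueError("n_cp must be >= 1")
    if seconds_per_cp <= 0:
        raise ValueError("seconds_per_cp must be positive")
    if w.dt is None:
        raise ValueError("waveform has no time base (dt is None)")
    n = len(w)
    t = np.arange(n_cp) * seconds_per_cp
    fi = (t % (n * w.dt)) / w.dt
    i0 = np.floor(fi).astype(int) % n
    i1 = (i0 + 1) % n
    frac = (fi - np.floor(fi))[:, None]
    return w.samples[i0] * (1.0 - frac) + w.samples[i1] * frac


def write_waveform_csv(w: MotionWaveform, path) -> None:
    """Write a waveform as CSV (t_s or cp_index, dx_mm, dy_mm, dz_mm)."""
    if w.dt is not None:
        first = ("t_s", np.arange(len(w)) * w.dt)
    else:
        first = ("cp_index", np.arange(len(w), dtype=float))
    df = pd.DataFrame(
        {
            first[0]: first[1],
            "dx_mm": w.si,
            "dy_mm": w.samples[:, AP],
            "dz_mm": w.samples[:, LR],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_waveform_csv(path, source: str = "SYNTHETIC") -> MotionWaveform:
    """Read a waveform CSV written by :func:`write_waveform_csv`."""
    df = pd.read_csv(path)
    for col in ("dx_mm", "dy_mm", "dz_mm"):
        if col not in df.columns:
            raise ValueError(f"waveform CSV missing required column '{col}'")
    if "t_s" in df.columns:
        t = df["t_s"].to_numpy()
        steps = np.diff(t)
        if len(steps) and not np.allclose(steps, steps[0], atol=1e-6):
            raise ValueError("t_s column is not uniformly sampled")
        dt = float(steps[0]) if len(steps) else None
    elif "cp_index" in df.columns:
        dt = None
    else:
        raise ValueError("waveform CSV needs a 't_s' or 'cp_index' column")
    samples = df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(dtype=float)
    return MotionWaveform(samples, dt=dt, source=source)
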
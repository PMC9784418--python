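"""Synthetic study cohort: cases and the 8-waveform experiment matrix.

Emulates the population the analysis targets: lung tumors with GTV
volumes of 6-139 cm^3, single-cycle 4DCT SI motion of 0-8.5 mm
peak-to-peak, and multi-breath free-breathing motion that always equals
or exceeds the 4DCT range (ratio drawn in [1.0, 1.9]).  Small tumors
(< 25 cm^3) are treated as SBRT cases (2 mm CTV margin, 1.25 mm dose
grid); the rest as conventional fractionation (7 mm margin, 2.5 mm grid).

Every case gets the full experiment matrix: {4DCT, TR4DMRI} x
{+0, +5, +10, +20 mm added motion}, with the native-4DCT variant tagged
as the control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import Case, VoxelGrid, build_case, make_ellipsoid_gtv
from .waveforms import (
    BreathingModelParams,
    MotionWaveform,
    cycle_to_waveform,
    scale_amplitude,
    surrogate_rescale,
    synthesize_breathing,
)

__all__ = ["CohortSpec", "WaveformVariant", "sample_case", "experiment_matrix"]

#: prescription schedules (cGy per fraction, n fractions)
SBRT_PRESCRIPTIONS = ((1200.0, 4), (1000.0, 5))
CONVENTIONAL_PRESCRIPTIONS = ((200.0, 30), (200.0, 33), (400.0, 15))


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a synthetic cohort."""

    n_patients: int = 10
    gtv_volume_range_cc: tuple[float, float] = (6.0, 139.0)
    si_range_4dct_mm: tuple[float, float] = (0.0, 8.5)
    tr_ratio_range: tuple[float, float] = (1.0, 1.9)
    sbrt_fraction: float = 0.3
    sbrt_volume_max_cc: float = 25.0
    added_mm: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    breathing_period_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sbrt_fraction <= 1.0:
            raise ValueError("sbrt_fraction must be in [0, 1]")
        for lo, hi in (self.gtv_volume_range_cc, self.si_range_4dct_mm, self.tr_ratio_range):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be non-negative and ordered")


@dataclass
class WaveformVariant:
    source: str
    added_mm: float
    waveform: MotionWaveform
    is_control: bool = False


def _case_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,))
    )


def _ellipsoid_radii(volume_cc: float, rng: np.random.Generator) -> np.ndarray:
    """Gently anisotropic radii (mm) with the requested analytic volume."""
    r = (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    f = rng.uniform(0.85, 1.15, size=3)
    f /= np.prod(f) ** (1.0 / 3.0)
    return r * f


def _phase_coms(range_mm: float, n_phases: int = 10) -> np.ndarray:
    """Ten-phase SI COM trajectory of a cos^4 breathing cycle.

    The template is rescaled so the sampled peak-to-peak equals
    ``range_mm`` exactly (exhale phase at the positive extreme).
    """
    p = np.arange(n_phases)
    raw = np.cos(np.pi * p / n_phases) ** 4
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    si = range_mm * raw
    return np.column_stack([si, np.zeros(n_phases), np.zeros(n_phases)])


def sample_case(spec: CohortSpec, index: int) -> Case:
    """Draw one deterministic synthetic case (same seed + index -> same case).

    The grid is sized so the PTV, the largest added motion and the
    penumbra all stay comfortably inside it.
    """
    rng = _case_rng(spec, index)
    is_sbrt = bool(rng.random() < spec.sbrt_fraction)
    lo, hi = spec.gtv_volume_range_cc
    if is_sbrt:
        vol = rng.uniform(lo, min(hi, spec.sbrt_volume_max_cc))
    else:
        vol = rng.uniform(max(lo, spec.sbrt_volume_max_cc), hi)
    radii = _ellipsoid_radii(vol, rng)

    r4 = rng.uniform(*spec.si_range_4dct_mm)
    rtr = max(r4 * rng.uniform(*spec.tr_ratio_range), 0.1)

    spacing = 1.25 if is_sbrt else 2.5
    ctv_margin = 2.0 if is_sbrt else 7.0
    rx = SBRT_PRESCRIPTIONS[rng.integers(len(SBRT_PRESCRIPTIONS))] if is_sbrt else (
        CONVENTIONAL_PRESCRIPTIONS[rng.integers(len(CONVENTIONAL_PRESCRIPTIONS))]
    )

    max_added = max(spec.added_mm)
    # SI half-extent: target + margins + motion envelope + largest added
    # motion + penumbra tails + slack
    half_si = radii[0] + ctv_margin + 5.0 + r4 / 2.0 + max_added + 5.0 + 12.0 + 6.0
    half_tr = max(radii[1], radii[2]) + ctv_margin + 5.0 + 5.0 + 12.0 + 6.0
    dims = tuple(
        2 * int(math.ceil(h / spacing)) + 1 for h in (half_si, half_tr, half_tr)
    )
    origin = tuple(-(d - 1) * spacing / 2.0 for d in dims)
    grid = VoxelGrid(spacing=spacing, dims=dims, origin=origin)

    wf_4dct = cycle_to_waveform(
        _phase_coms(r4), n_repeats=1, period_s=spec.breathing_period_s
    )
    params = BreathingModelParams(
        period_s=float(rng.uniform(3.5, 4.5)),
        amplitude_mm=max(rtr, 1.0),
        shape_n=2,
        drift_mm_per_min=float(rng.uniform(0.0, 1.0)),
        jitter_sd=0.1,
        noise_sd_mm=0.15,
        duration_s=120.0,
        sample_hz=2.0,
        seed=int(rng.integers(2**31)),
    )
    wf_tr = surrogate_rescale(synthesize_breathing(params), rtr)
    wf_tr = MotionWaveform(wf_tr.samples, dt=wf_tr.dt, source="TR4DMRI")

    gtv = make_ellipsoid_gtv(grid, center=(0.0, 0.0, 0.0), radii=radii)
    return build_case(
        patient_id=f"SYN{index:03d}",
        gtv=gtv,
        ctv_margin_mm=ctv_margin,
        waveform_4dct=wf_4dct,
        waveform_tr=wf_tr,
        prescription=rx,
        is_sbrt=is_sbrt,
        meta={
            "gtv_cc_analytic": float(vol),
            "range_4dct_mm": float(r4),
            "range_tr_mm": float(rtr),
            "index": index,
            "seed": spec.seed,
        },
    )


def experiment_matrix(
    case: Case,
    added_mm: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0),
    anchor: str = "EXHALE_EXTREME",
) -> list[WaveformVariant]:
    """The 8 delivery waveforms of a case: 2 sources x 4 added amplitudes.

    The (4DCT, +0 mm) variant is the control.  Scaled variants of a
    motionless native waveform fall back to the canonical cos^4 template
    with peak-to-peak exactly equal to the added motion.
    """
    if "4DCT" not in case.waveforms or "TR4DMRI" not in case.waveforms:
        raise ValueError("case needs both a 4DCT and a TR4DMRI native waveform")
    variants = []
    for source in ("4DCT", "TR4DMRI"):
        native = case.waveforms[source]
        for added in added_mm:
            wf = scale_amplitude(native, added, anchor=anchor)
            variants.append(
                WaveformVariant(
                    source=source,
                    added_mm=float(added),
                    waveform=wf,
                    is_control=(source == "4DCT" and added == 0.0),
                )
            )
    return variants
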
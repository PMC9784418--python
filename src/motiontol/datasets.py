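"""Bundled reference data: a published ten-patient lung VMAT motion study.

Three tables from a clinical motion-incorporated planning study of
ITV-based lung VMAT are shipped as immutable records so the analysis
stages can be exercised, and cross-checked, without any patient data:

* ``load_patient_table`` - tumor location, GTV/ITV/PTV volumes and native
  SI motion ranges seen in single-cycle 4DCT and multi-breath
  free-breathing (TR-4DMRI) imaging, for ten patients.
* ``load_d95_table`` - raw PTV D95% (fraction of prescription) of the
  motion-incorporated plans for each waveform source at 0/5/10/20 mm of
  added motion, in long (tidy) layout.
* ``load_breach_table`` - the breaching points and quadratic-fit R^2 the
  study reported, kept for comparison only (several entries were evidently
  derived from display-rounded fit coefficients and cannot be regenerated
  exactly from the D95 table; see docs/methods.md).

Patients 2, 8 and 9 are SBRT cases (GTV < 25 cm^3, 2 mm CTV margin); the
rest are conventionally fractionated (7 mm CTV margin).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_patient_table",
    "load_d95_table",
    "load_breach_table",
    "SBRT_PATIENTS",
]

SBRT_PATIENTS = (2, 8, 9)

# patient, sex, age, site, stage, gtv_cc, itv_cc, ptv_cc, 4dct_mm, tr_mm
_PATIENTS = (
    (1, "m", 59, "RLL", "IIIa", 132, 455, 705, 7.8, 10.7),
    (2, "f", 74, "RLL", "Ia", 6, 17, 39, 8.5, 10.8),
    (3, "f", 77, "LUL", "IIa", 33, 87, 166, 1.4, 1.6),
    (4, "f", 42, "LUL", "IIa", 76, 158, 281, 0.5, 0.7),
    (5, "m", 78, "RML", "IIa", 139, 302, 447, 1.3, 2.2),
    (6, "f", 76, "RLL", "IIIa", 67, 220, 364, 2.4, 4.3),
    (7, "m", 60, "RLL", "IIIa", 90, 286, 454, 3.8, 5.6),
    (8, "f", 75, "RLL", "Ia", 17, 30, 140, 4.0, 5.7),
    (9, "m", 89, "RUL", "Ia", 22, 47, 98, 2.5, 4.4),
    (10, "f", 63, "RML", "IIIa", 138, 368, 547, 0.0, 0.1),
)

# patient, rx cGy/fx, n fx, then D95% at 0/5/10/20 mm for 4DCT and TR-4DMRI
_D95 = (
    (1, 200, 30, (1.000, 0.982, 0.957, 0.901), (0.998, 0.976, 0.946, 0.871)),
    (2, 1200, 4, (0.974, 0.915, 0.841, 0.697), (0.982, 0.942, 0.876, 0.719)),
    (3, 200, 33, (0.999, 0.989, 0.977, 0.904), (0.999, 0.990, 0.979, 0.939)),
    (4, 400, 15, (1.007, 1.000, 0.978, 0.915), (1.005, 0.988, 0.944, 0.805)),
    (5, 400, 15, (1.003, 0.994, 0.983, 0.936), (0.997, 0.982, 0.988, 0.900)),
    (6, 200, 30, (0.997, 0.982, 0.960, 0.853), (0.997, 0.993, 0.980, 0.942)),
    (7, 200, 33, (0.990, 0.975, 0.957, 0.900), (0.992, 0.975, 0.960, 0.932)),
    (8, 1000, 5, (0.985, 0.875, 0.837, 0.776), (0.925, 0.884, 0.857, 0.797)),
    (9, 1000, 5, (0.991, 0.945, 0.866, 0.612), (0.990, 0.937, 0.829, 0.612)),
    (10, 200, 30, (0.998, 0.996, 0.984, 0.917), (0.998, 0.995, 0.989, 0.960)),
)

# patient, source, x95 mm, x90 mm, quadratic r2 (as reported)
_BREACH = (
    (1, "4DCT", 10.6, 20.2, 0.999), (1, "TR4DMRI", 9.5, 16.5, 1.000),
    (2, "4DCT", 3.8, 6.3, 0.999), (2, "TR4DMRI", 7.6, 10.5, 0.999),
    (3, "4DCT", 14.3, 20.4, 0.997), (3, "TR4DMRI", 17.5, 27.1, 0.998),
    (4, "4DCT", 14.2, 21.2, 0.999), (4, "TR4DMRI", 8.8, 13.4, 1.000),
    (5, "4DCT", 16.9, 25.1, 0.948), (5, "TR4DMRI", 14.9, 20.1, 0.966),
    (6, "4DCT", 11.4, 16.5, 0.999), (6, "TR4DMRI", 18.3, 27.3, 1.000),
    (7, "4DCT", 13.1, 21.3, 1.000), (7, "TR4DMRI", 15.2, 25.6, 1.000),
    (8, "4DCT", 2.2, 5.1, 0.985), (8, "TR4DMRI", 0.0, 4.8, 1.000),
    (9, "4DCT", 5.2, 6.5, 0.999), (9, "TR4DMRI", 3.5, 8.2, 0.998),
    (10, "4DCT", 16.3, 22.0, 1.000), (10, "TR4DMRI", 21.6, 31.2, 0.999),
)

_ADDED_MM = (0.0, 5.0, 10.0, 20.0)


def _group(patient: int) -> str:
    return "SBRT" if patient in SBRT_PATIENTS else "conventional"


def load_patient_table() -> pd.DataFrame:
    """Patient characteristics: volumes (cm^3) and native SI motion (mm)."""
    return pd.DataFrame(
        _PATIENTS,
        columns=[
            "patient", "sex", "age", "site", "stage",
            "gtv_cc", "itv_cc", "ptv_cc", "motion_4dct_mm", "motion_tr4dmri_mm",
        ],
    ).assign(group=lambda df: df["patient"].map(_group))


def load_d95_table() -> pd.DataFrame:
    """Raw motion-incorporated PTV D95% values in long layout.

    Columns: patient, group, rx_cgy, n_fx, source (4DCT / TR4DMRI),
    added_mm (0/5/10/20) and d95_raw (fraction of prescription).
    """
    rows = []
    for patient, rx, nfx, d4, dtr in _D95:
        for source, series in (("4DCT", d4), ("TR4DMRI", dtr)):
            for added, val in zip(_ADDED_MM, series):
                rows.append((patient, _group(patient), rx, nfx, source, added, val))
    return pd.DataFrame(
        rows,
        columns=["patient", "group", "rx_cgy", "n_fx", "source", "added_mm", "d95_raw"],
    )


def load_breach_table() -> pd.DataFrame:
    """Breaching points and R^2 as originally reported (comparison only)."""
    return pd.DataFrame(
        _BREACH, columns=["patient", "source", "x95_mm", "x90_mm", "r2"]
    ).assign(group=lambda df: df["patient"].map(_group))
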
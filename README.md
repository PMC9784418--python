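# motiontol

How much can a lung tumor's breathing motion grow before an ITV-based
VMAT plan stops covering the target?  `motiontol` answers this with a
desk-scale **motion-incorporated delivery simulation** and a
**breaching-point regression**:

* the continuous VMAT arcs are segmented into static fields at 2°
  control points; the isocenter is displaced along the tumor motion
  waveform while the aperture sequence and gantry rotation stay fixed,
  emulating delivery to a rigidly moving target;
* the PTV dose coverage D95% (dose received by ≥95% of the PTV, relative
  to prescription) is scored for the native waveform and for waveforms
  linearly enlarged by +5, +10 and +20 mm;
* per patient, corrected D95% is fitted with an OLS quadratic
  `D95%(x) = a + b·x + c·x²` in the added motion `x`, and the **first
  (D95% = 95%) and second (D95% = 90%) breaching points** are the
  smallest non-negative roots.

The native-motion plan doubles as a control experiment: its D95% should
match the static plan (ITV-based planning already contains that motion),
and its residual deviation is divided out of the other plans of the same
patient (multiplicative control correction).

The package is aimed at medical-physics researchers studying motion
management: it ships a ten-patient reference dataset from a published
clinical motion study, a synthetic cohort generator (GTV 6–139 cm³,
single-cycle 4DCT motion 0–8.5 mm, multi-breath free-breathing traces
with drift and jitter), a geometric dose engine (aperture projection +
Gaussian penumbra), and statsmodels-style model/results objects for the
regression stage.

## Worked example

Fit breaching points on the bundled ten-patient reference D95% table:

```python
from motiontol import datasets, MotionToleranceModel

model = MotionToleranceModel(
    datasets.load_d95_table(), patient_meta=datasets.load_patient_table()
)
res = model.fit()
print(res.summary())
```

```
Motion-tolerance breaching analysis
============================================================
thresholds: 95% / 90%   control: (4DCT, 0 mm)
------------------------------------------------------------
patient   source   x95 mm   x90 mm     R^2  flags
      1     4DCT     11.5     20.1   1.000  extrapolated
      ...
      8     4DCT      2.3      5.2   0.984
      8  TR4DMRI      0.0      5.1   0.998  at-zero
      ...
------------------------------------------------------------
        SBRT     4DCT: x95 3.8 +- 1.5 mm, x90 7.1 +- 1.7 mm (n=3)
        SBRT  TR4DMRI: x95 3.4 +- 3.1 mm, x90 7.4 +- 2.5 mm (n=3)
conventional     4DCT: x95 14.0 +- 2.1 mm, x90 20.9 +- 2.6 mm (n=7)
conventional  TR4DMRI: x95 15.6 +- 5.1 mm, x90 25.2 +- 9.1 mm (n=7)
```

Reading: the small (SBRT) tumors tolerate only ~4 mm of extra motion
before PTV D95% drops below 95%, while large conventional-fractionation
tumors tolerate ~14 mm; patient 8's free-breathing trace breaches the
95% level with *no* added motion (`at-zero`).  Roots beyond the 20 mm
design range are flagged `extrapolated`.

The same analysis, and the full synthetic pipeline, are available from a
CLI:

```bash
motiontol fit-breach --out breach_table.csv          # bundled reference data
motiontol gen-synthetic --n 10 --seed 0 --out cohort/
motiontol run-cohort --n 10 --seed 0 --out run/
motiontol simulate-case --seed 0 --index 2 --out case2/
```

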
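# aortamorph

Morphometry and prognostic evaluation of **residual aortic dissection**
from 3D label maps.

After surgical repair of a type A aortic dissection, the downstream
aorta often remains dissected: blood flows through the original **true
lumen (TL)** and through a **circulating false lumen (CFL)** between the
dissected wall layers, parts of which may clot into **thrombus (Th)**.
Whether such a patient will progress to adverse aortic remodeling —
growth > 5 mm/year, re-do surgery, malperfusion or rupture — is usually
judged from the maximal aortic diameter alone, which ignores where and
how much false lumen persists. `aortamorph` computes volumetric risk
markers from a segmented CT angiogram (a NIfTI label map with TL/CFL/Th
codes) and provides the statistical machinery to evaluate any such
marker against an observed binary outcome.

## Markers

With the aorta mask `A = TL ∪ CFL ∪ Th` and its arc-length-parameterised
centerline `c(s), s ∈ [0, L]`:

- **Ao_length** `= L` — aortic length along the centerline (mm);
- **D_max** — maximum over `s` of the maximal Feret diameter of the
  cross-section of `A` orthogonal to the centerline tangent (mm);
- **V_TL, V_CFL, V_Th** — compartment volumes (mL);
  **Ao_Glo** `= V_TL + V_CFL + V_Th`, **FL_Glo** `= V_CFL + V_Th`,
  plus the ratios `FL_Glo/Ao_Glo` and `FL_Glo/Ao_length`;
- **FL_Loc** — *local* false-lumen volume: the CFL + Th volume inside a
  30-mm arc-length section (15 mm proximal, 15 mm distal) centered at a
  largest-diameter position. The window is evaluated at each of the two
  largest diameters spaced ≥ 10 mm apart and the larger local volume is
  retained. Section lengths of 10/15/30/50 mm are supported as a sweep.
- **Evolution ("+") markers** — for paired scans `(m_T1, m_T2)` taken
  `Δd` days apart, `m⁺ = m_T1 + (m_T2 − m_T1) · 365/Δd`, the linear
  extrapolation of the change to one year after the first scan.

Markers are evaluated univariately against the outcome with the
empirical ROC (`positive if marker ≥ threshold`), trapezoid AUC (equal
to the midrank Mann–Whitney statistic), DeLong 95% CI, the
Youden-index operating point (J = Se + Sp − 1) with Se/Sp/PPV/NPV, the
two-sample Kolmogorov–Smirnov distance, normality-guarded group tests
and a univariate logistic likelihood-ratio test.

Because no patient CTA label maps are publicly deposited, the package
ships a first-class synthetic-data module: voxel phantoms (straight /
quarter-arc / candy-cane tubes with Gaussian bulges and angular-sector
false lumina) whose measures have closed forms, and two-group Gaussian
cohort simulators parameterised by the published per-group summary
statistics of two clinical cohorts.

## Worked example

Measure a candy-cane phantom (40-mm arch + 80-mm descending limb, a
5-mm bulge, half the cross-section false lumen, 20% of it thrombus):

```python
import aortamorph as am
from aortamorph.cli import RunConfig, measure_volume

spec = am.PhantomSpec(centerline_kind="candy_cane", arch_radius=40.0,
                      descending_length=80.0, bulge=(5.0, 90.0, 10.0),
                      fl_fraction=0.5, th_fraction=0.2, spacing=1.0)
vol, truth = am.voxelize_phantom(spec)
row = measure_volume(vol, RunConfig(section_lengths=(10., 15., 30., 50.)))
```

prints (via `for k, v in row.items(): print(f"{k:24s} {v:8.2f}")`):

```
Dmax                        41.23
Dmax_position              115.75
Ao_length                  206.48
V_TL                        80.66
V_CFL                       60.20
V_Th                        17.52
Ao_Glo                     158.38
FL_Glo                      77.72
FL_Loc                      15.71
FL_Glo_over_Ao_Glo           0.49
FL_Glo_over_Ao_length        0.38
FL_Loc_10                    6.01
FL_Loc_15                    7.98
FL_Loc_30                   15.71
FL_Loc_50                   23.46
```

The analytic truth for this phantom is `Ao_length = 205.66` mm,
`Ao_Glo = 158.58` mL, `FL_Glo = 79.29` mL, `D_max = 40` mm at `s = 90`:
lengths and volumes land within ~2% at 1-mm voxels and D_max carries the
expected ~1-voxel dilation. The centerline is direction-agnostic, so the
bulge may be reported from either end (`206.48 − 115.75 ≈ 90`); windowed
quantities are unaffected. The FL_Loc sweep rises monotonically with
section length toward FL_Glo.

Evaluate a simulated cohort built from the published event /
no-event group summaries (local false-lumen volume, first center,
39 events vs 44 event-free):

```python
df = am.simulate_marker_cohort(am.reference_cohort_spec("center1", "FL_Loc", seed=42))
report = am.evaluate_marker(df["FL_Loc"].to_numpy(), df["outcome"].to_numpy())
```

gives for this seed `auc = 0.892` (95% CI 0.822–0.963), Youden threshold
`17.3 mL` with Se = 0.74 / Sp = 0.95, and `ks = 0.70` — one random
cohort scatters around the replicate-averaged AUC of 0.83.

The same operations are available from a shell:

```sh
aortamorph phantom --kind candy_cane --spacing 1.0 -o ph.nii.gz --truth-out truth.json
aortamorph measure ph.nii.gz --section-length 30 -o measures.csv
aortamorph cohort --mean-event 22.4 --sd-event 9.9 --n-event 39 \
    --mean-nonevent 10.0 --sd-nonevent 8.1 --n-nonevent 44 \
    --marker FL_Loc --seed 42 -o cohort.csv
aortamorph evaluate cohort.csv --marker FL_Loc -o report.json
```

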
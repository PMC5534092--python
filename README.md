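# lvdecomp

Decomposition of left-ventricular (LV) stroke volume into **longitudinal**,
**septal** and **lateral** pumping from segmented cine-CMR contours — together
with a parametric piston-pump LV phantom (analytic ground truth), cohort
statistics, and a small CLI.

## The problem

The LV ejects blood through two epicardially visible motions: the
atrioventricular (AV) plane moves toward the apex in systole (longitudinal
shortening, measured as the AV-plane displacement, AVPD, the CMR analogue of
echocardiographic MAPSE), and the epicardium moves radially inward. Viewing
the ventricle as a piston pump, the longitudinal part of the stroke volume
(SV) is *piston displacement × piston area*:

    V_long = AVPD × A_epi        (AVPD in cm, A_epi in cm², V_long in mL)

where `A_epi` is the mean epicardial area of the two largest basal short-axis
slices. The radial part is the volume swept between the superimposed
end-diastolic (ED) and end-systolic (ES) epicardial contours, integrated
slice by slice from base to apex,

    V_radial = Σ_slices Δz ∮ ½ (r_ED(θ)² − r_ES(θ)²) dθ,

and split at the RV insertion points into a **septal** sector (motion toward
the LV lumen counts positive, toward the RV — dyskinesia — negative) and the
remaining **lateral** sector. Each component is expressed as a percentage of
the SV from standard slice-summation volumetry; the three percentages should
sum to 100% ("internal validation"). In health roughly 60% of LVSV is
longitudinal; after myocardial infarction the absolute AVPD falls but
ventricular dilation enlarges the piston area, so the longitudinal *fraction*
is preserved — the pattern this package quantifies.

Patient images are not required (or supported): the package consumes contour
datasets, and ships a truncated-ellipsoid phantom whose prescribed AVPD,
sector-wise radial shortening, dilation and noise produce those datasets with
closed-form ground-truth contributions, calibrated to published group means
of a chronic-infarct cohort (LAD-MI, RCA-MI, controls).

## Worked example

```sh
lvdecomp simulate --preset control --n 1 --seed 0 --out subj
lvdecomp analyze --in subj/control_000.json
```

prints, for the noiseless control-preset phantom:

```
AVPD_mm: 15.40
basal_area_cm2: 39.80
SV_mL: 96.36
pct_long: 63.61
pct_sep: 8.85
pct_lat: 27.08
internal_validation_sum_pct: 99.54
```

The prescribed AVPD (15.4 mm) is recovered exactly; the basal epicardial area
is ~40 cm²; about 64% of the stroke volume is longitudinal, ~9% septal and
~27% lateral; and the three contributions sum to 99.5% — the internal
validation of the measurement chain, which is 100% in theory.

The same thing in Python:

```python
from lvdecomp import control_spec, generate_study, decompose

study = generate_study(control_spec())     # synthetic contour stacks + landmarks
result = decompose(study)                  # AVPD, areas, swept volumes, percentages
print(result.pct_long, result.internal_validation_sum)
```

A cohort workflow — simulate groups, batch-analyze, and print a
group-comparison table (mean ± SE, one-way ANOVA with Tukey-adjusted
markers, Spearman correlations with infarct size):

```sh
for p in control lad rca; do
  lvdecomp simulate --preset $p --n 6 --seed 7 --noise-sd 0.5 --out data
done
lvdecomp cohort --in data --out cohort.csv
lvdecomp report --in cohort.csv
```

```
  EF_pct      control 57.6 ± 1.6 | lad 32.1 ± 2.7***††† | rca 48.1 ± 2.5*   (ANOVA F=31.40, p=4.35e-06)
  AVPD_mm     control 15.0 ± 0.9 | lad 11.3 ± 1.2 | rca 13.2 ± 1.1   (ANOVA F=3.05, p=0.0774)
  ...
internal validation: 100 ± 1 % (theory: 100%)
```

(with n = 6 per group only the strongest differences reach significance; at
the emulated study's 20/16/20 the AVPD difference separates at p < 0.001).

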
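# craniometrics

A toolkit for cranial measurement from 3D-photogrammetry head scans.
Given a triangle mesh of a head (millimeters) and three anatomical
landmarks (nasion, left tragus, right tragus), it:

1. **registers** the mesh to a canonical anatomical frame — the
   nasion–tragi plane becomes `z = 0`, tragus-left→right is `+x`, the
   nasion side is `+y`, and the head is re-anchored so the centroid of the
   largest-circumference axial slice sits at `x = y = 0`;
2. **slices** the vault: an iterative search over axial planes locates the
   slice with the largest occipitofrontal diameter (OFD), and sagittal and
   coronal slices are cut through that slice's centroid;
3. **measures** OFD, biparietal diameter (BPD), occipitofrontal
   circumference (OFC), cephalic index and approximated intracranial
   volume (ICV, with a linear CT-based calibration), and converts them to
   age- and sex-specific z-scores via growth-reference tables;
4. resamples each slice contour at **120 equally spaced angles** about its
   centroid, giving index correspondence across subjects, from which group
   **mean cranial shapes with SD bands** and deviation profiles versus a
   reference shape are built;
5. **compares groups** with an assumption-gated procedure: one-way ANOVA
   (with pairwise t tests post hoc) when Shapiro–Wilk and Levene tests
   pass, otherwise Kruskal–Wallis with Conover–Iman post hoc tests, both
   Bonferroni-adjusted.

Because clinical scans cannot be redistributed, the package ships a
first-class synthetic-head generator (`craniometrics.synthetic_heads`):
star-shaped ellipsoid-based surfaces with frontal bossing, occipital
bullet and vertex flattening, seeded noise, cohort/growth models and
synthetic growth-reference tables — every generated head carries analytic
ground truth (bisection-based slice contours, spherical-quadrature
volumes), so the whole pipeline is testable offline.

## CLI

```bash
# synthesize a cohort with ground truth
craniometrics simulate --preset scaphocephalic --n 20 --seed 1 --out-dir cohort/

# register one scan to the anatomical frame
craniometrics register --mesh head.ply --landmarks head.json \
    --out registered.ply --transform-out transform.json

# extract + resample the orthogonal slices
craniometrics slices --mesh registered.ply --out-dir slices/

# full measurement record with z-scores
craniometrics measure --mesh head.ply --landmarks head.json \
    --refs refs.csv --age-months 24 --sex male --out record.json

# group mean shape from sampled contours
craniometrics meanshape --slices-dir slices/ --orientation axial \
    --group SAC --out shape.csv

# gated statistical comparison
craniometrics compare --records records.csv --group-col surgery \
    --measure z_icv --alpha 0.05 --out comparison.json
```

Landmark files are JSON objects with keys `nasion`, `tragus_left`,
`tragus_right` (or CSV with columns `name,x,y,z`). Growth-reference CSVs
have columns `measurement,sex,age_months,mean,sd` with
`measurement ∈ {ofc, cephalic_index, icv}`; shipped tables are synthetic
stand-ins generated by `generate_reference_table` — supply real reference
data in the same schema for clinical use.

## Layout

```
src/craniometrics/
  mesh_io.py          mesh + landmark I/O, validation
  registration.py     landmark frame, rigid transforms, registration
  slicing.py          plane sections, max-OFD search, 120-point resampling
  cephalometrics.py   OFD/BPD/OFC/CI/ICV, calibration, z-scores, pipeline
  mean_shape.py       pointwise mean shapes, SD bands, deviation profiles
  synthetic_heads.py  synthetic heads/cohorts with analytic ground truth
  group_stats.py      gated ANOVA / Kruskal–Wallis + post hoc procedures
  cli.py              `craniometrics` command-line interface
```
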
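# dbpscreen

Suspect screening of **disinfection byproducts (DBPs)** in comprehensive
two-dimensional gas chromatography time-of-flight mass spectrometry
(GC×GC-TOFMS) data.

Chlorination of treated wastewater produces hundreds of halogenated
byproducts, only a handful of which are regulated. Non-target GC×GC-TOFMS
screening can find them, but raw peak lists contain thousands of entries:
background contamination, irreproducible artifacts, compounds that were
already present before disinfection, and co-eluting mixtures whose spectra
match nothing. `dbpscreen` implements the full screening chain that turns
six passive-sampler acquisitions (two field blanks, two pre-chlorination and
two post-chlorination replicates) into a short, evidence-annotated candidate
list:

1. **Peak picking** — per-channel rolling-minimum baseline correction, then
   inverse-watershed segmentation of the total-ion image (peaks become
   catchment basins of the inverted image).
2. **NMF spectral deconvolution** — each peak region's m/z × scan matrix
   `V` is factored as `V ≈ WH` (`W, H ≥ 0`) with deterministic NNSVD
   seeding and Lee–Seung multiplicative updates for the Frobenius objective
   `‖V − WH‖_F`. At most four overlapping compounds are assumed; the k-th
   ranked component of every region forms **layer k** of a layered
   chromatogram, so compounds hidden under co-eluters surface in deeper
   layers.
3. **Library matching** — Stein–Scott weighted-cosine match factors
   (`w = (m/z)³ · I^0.6`, scaled to 0–999) against an MSP library, forward
   and reverse.
4. **An eight-filter funnel** — blank subtraction, replicate consistency,
   pre/post chlorination differential, best-layer selection, match-factor
   threshold (≥ 800), then three annotation filters: theoretical
   isotopologue-pattern cosine similarity and ppm mass accuracy, Abraham-model
   retention-index agreement (dI), and Procrustes concordance between the
   predicted (I₁, 1.6^(ΔI/100)) and observed (rt1, rt2) elution spaces. The
   Abraham LFER is `log k = c + eE + sS + aA + bB + lL`, converted to Kováts
   indices on the n-alkane ladder.

A first-class synthetic-data module generates ground-truthed six-sampler
studies (separable 2-D Gaussian peaks × fragment spectra, flat baseline,
truncated-Gaussian noise, controllable co-elution), so every stage is
testable without any instrument data.

## Worked example

```python
from dbpscreen import WorkflowConfig, run_workflow
from dbpscreen.synthetic_data import generate_study, truth_library

samplers, truth = generate_study(5, 12, overlap_fraction=0.4, seed=7,
                                 run_minutes=8.0, mz_start=33, mz_end=340)
library = truth_library(truth)
cfg = WorkflowConfig(library=library,
                     formulas={e.name: e.formula for e in library})
roles = {"blank": [c for s, c in samplers if s.startswith("blank")],
         "pre":   [c for s, c in samplers if s.startswith("pre")],
         "post":  [c for s, c in samplers if s.startswith("post")]}
result = run_workflow(roles, cfg)
for s in result.funnel.stages:
    print(f"{s.name:32s} in {s.n_in:3d} out {s.n_out:3d}")
```

prints the funnel accounting

```
blank_correction                 in  64 out  52
replicate_consistency            in  52 out  26
chlorination_differential        in  26 out  10
optimal_peak_selection           in  10 out   5
match_factor_threshold           in   5 out   5
isotope_fit_annotation           in   5 out   5
retention_index_annotation       in   5 out   5
elution_concordance_annotation   in   5 out   5
```

and the five candidates are exactly the five spiked DBPs — note the two
co-eluting ones were recovered from deconvolution **layer 2**, invisible in
the raw chromatogram:

```
tribromoacetaldehyde       layer 2  MF 994  rt (0.97 min, 3.10 s)  isotope cosine 1.000
chlorodibromoacetaldehyde  layer 2  MF 993  rt (1.41 min, 5.48 s)  isotope cosine 0.999
1,1,3-trichloroacetone     layer 0  MF 998  rt (1.73 min, 2.64 s)  isotope cosine 1.000
dibromoacetonitrile        layer 0  MF 999  rt (5.63 min, 3.28 s)  isotope cosine 1.000
bromodichloroacetaldehyde  layer 0  MF 997  rt (7.04 min, 5.16 s)  isotope cosine 0.999
```

The command line mirrors the library:

```bash
dbpscreen simulate --n-dbps 5 --overlap 0.4 --seed 7 --out study/
dbpscreen detect --in study/post1.npz --out peaks.csv
dbpscreen isotopes C2HBr3O          # theoretical isotopologue pattern
dbpscreen ri --phase DB-1           # predicted Kováts indices
dbpscreen run --config config.yaml  # the full eight-filter screen
```

For instance `dbpscreen isotopes Cl2` prints the chlorine-2 pattern
(M : M+2 : M+4 = 100 : 63.99 : 10.24 at masses 69.9377 / 71.9348 / 73.9318 Da).

## Layout

```
src/dbpscreen/
  io_core.py             MSP / peak-table / chromatogram / LSER I/O + types
  synthetic_data.py      ground-truthed studies and chromatograms
  peak_detection.py      baseline correction, inverse-watershed blobs
  nmf_deconvolution.py   NNSVD seeding, Frobenius NMF, layers
  spectral_identity.py   match factors, isotopologues, ppm errors
  retention_modeling.py  Abraham LFER, Kováts indices, Procrustes
  screening_pipeline.py  the eight-filter funnel and workflow driver
  cli.py                 `dbpscreen` command line
  data/                  isotope masses, alkane ladder, LFER examples,
                         bundled reference candidate tables
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
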
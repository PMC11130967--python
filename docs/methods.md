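# Methods

This note records the models, parameter choices and numerical decisions
behind `dbpscreen`, and what the synthetic studies do and do not demonstrate.

## Data model

A GC×GC-TOFMS acquisition is a cube indexed
`[modulation][intra-modulation scan][m/z bin]`. First-dimension retention
rt1 is reported in minutes (one modulation per `modulation_period` seconds,
6.5 s by default), second-dimension retention rt2 in seconds within the
modulation (scan rate 50 Hz ⇒ 325 scans per modulation), and the m/z axis is
nominal (1 Da integer bins, 33–800 by default). Nominal binning is the
deliberate working precision of the whole pipeline: deconvolution, match
factors and isotope extraction all operate on 1 Da bins, and sub-Da
information enters only through theoretical isotopologue masses.

## Synthetic studies

The generator emulates a chlorination field study: two field blanks, two
pre-chlorination and two post-chlorination replicates. Spiked DBPs are
members of the post samplers only; background compounds of pre and post,
with a configurable fraction (default 0.3) also in the blanks. Replicates
share compound truth and differ only in noise.

* **Peak shape**: separable Gaussian in (rt1, rt2) times the compound's
  fragment spectrum across m/z; no wrap-around over the modulation boundary.
  Peak widths default to σ1 ∈ [0.15, 0.25] min and σ2 ∈ [0.25, 0.45] s,
  apex base-peak amplitudes to [400, 3000] a.u.
* **Spectra**: 8 fragment ions at random integer m/z below the molecular
  mass (base fragment 100), plus the molecular-ion cluster at the exact
  theoretical isotopologue masses scaled to 10–60 % of the base peak. The
  compound palettes are halogenated DBP formulas and common GC background
  compounds, so isotope clusters are realistic; fragmentation chemistry is
  not modelled.
* **Noise**: flat baseline (default 20 a.u.) plus i.i.d. Gaussian noise
  (default σ = 3 a.u.) truncated at zero — the simplest model that
  exercises baseline correction and noise-floor estimation. Real
  chromatograms add structured artifacts (column bleed ridges, tailing,
  detector saturation) that the generator does not emulate, so passing
  tests demonstrate algorithmic correctness under the stated model, not
  instrument-grade robustness.
* **Co-elution**: `overlap_fraction` of the DBPs is placed at 0.8 σ from a
  background compound in both dimensions (within one peak width, the regime
  deconvolution is for). Everything is deterministic under a fixed seed,
  byte-identical cubes included.

Test and acceptance studies use a reduced geometry — typically 4–8 min run
length and m/z 33–340 (wide enough for the heaviest palette cluster,
tribromophenol at m/z ≈ 334) — chosen as desk-scale problem sizes; the
generator's instrument defaults remain the full 6.5 s / 50 Hz / m/z 33–800
configuration.

## Peak picking

Baseline: per-m/z-channel rolling minimum over a retention-plane window
(21 modulations × 151 scans, several peak widths) followed by a small
uniform smoothing, subtracted and clipped at zero. On a flat offset this
removes the offset exactly; under noise it leaves a small positive residual
(the window minimum of truncated noise), which downstream steps remove with
robust floors.

Detection: the smoothed (Gaussian σ = 1 cell) TIC image is inverted so peaks
become catchment basins; watershed flooding starts from the local maxima
above a robust floor (median + `min_snr` × 1.4826·MAD of the smoothed TIC,
`min_snr` = 5), with 4-connectivity and `min_area` = 5 cells. Two
refinements handle over- and under-segmentation:

* adjacent basins separated by a saddle above 0.9 × the lower apex are
  merged (noise ripples on one peak's flank are not two peaks); a saddle at
  60 % of the apex still resolves two peaks, one at 99 % does not;
* basins split across the modulation boundary (footprints touching both
  scan edges with overlapping modulation ranges) are re-joined.

A small relative mask floor (10⁻⁴ of the image maximum) keeps numerically
tiny smoothing tails out of footprints when an image is noise-free. All
thresholds are arguments with the defaults above.

## NMF deconvolution

Each blob's footprint cells (time-ordered) form the columns of a
non-negative matrix `V` (rows: nominal m/z). Entries below a robust cube
noise floor (median + 3 × 1.4826·MAD of the baseline-corrected cells) are
zeroed first — broadband residual noise is nearly rank-one and would
otherwise absorb a factor.

`V ≈ WH` is solved with `k = min(4, dims)` (at most four overlapping
compounds), NNSVD seeding (per singular triplet, the dominant non-negative
section; zeros replaced by 10⁻⁹ × mean(V)) and Lee–Seung multiplicative
updates for `‖V − WH‖_F`, stopping at relative improvement < 10⁻⁴ or 200
iterations. The update denominators carry a guard of 10⁻¹² × max(V), so the
objective trace is non-increasing to within ~10⁻⁹ relative. The seeding and
updates are deterministic — no restarts, no seed handling.

Component post-processing, in order:

1. components contributing < 1 % of the total (contribution =
   ΣW·col × ΣH·row) are pruned;
2. components whose elution profile peaks on the footprint *boundary* are
   pruned: a compound eluting inside the region peaks in the interior,
   whereas a neighbouring peak's tail leaking across the watershed line
   rises toward the edge (without this, high-quality copies of neighbouring
   spectra appear at wrong retention positions);
3. because `k` is fixed rather than model-selected, a real component can be
   split across two factors; factors with plain spectral cosine ≥ 0.95 are
   re-merged.

The i-th surviving component (by contribution) of every blob becomes a
record in **layer i**; layer assignment by contribution rank puts the
cleanest spectrum in layer 1 and residual co-eluters deeper.

## Spectral identity

* **Match factor**: nominal-binned weighted cosine with Stein–Scott identity
  weights `w = (m/z)³ · I^0.6`, scaled to 0–999. Reverse mode restricts both
  vectors to the library spectrum's bins. This published approximation
  stands in for the proprietary commercial search score; the ≥ 800
  "good match" threshold is interpreted on this scale.
* **Isotope patterns**: per-element convolution of single-atom isotope
  distributions (IUPAC masses/abundances bundled as JSON), atom by atom in
  canonical element order, pruning isotopologues below `threshold`
  (default 10⁻⁴) × the running maximum and merging centroids within
  0.0005 Da (abundance-weighted). For a single poly-isotopic element this
  equals the multinomial closed form to floating-point accuracy.
* **Isotopic cosine**: patterns are aligned on the isotopologue index
  M+k with k = round(mass − theoretical monoisotopic) for both patterns;
  unmatched indices contribute zeros.
* **Mass error**: signed, `(theoretical − measured)/theoretical × 10⁶` ppm.
* **Molecular-ion status**: relative intensity of the molecular ion against
  the spectrum base peak classifies `appeared` (≥ 5 %), `faint` (≥ 0.5 %)
  or `absent`; cosine and ppm are computed only when the ion is found, and
  an absent ion leaves the isotope evidence indeterminate rather than
  rejecting the candidate.

## Retention modelling

`log k = c + eE + sS + aA + bB + lL` per phase; Kováts index by linear
interpolation of log k between bracketing n-alkanes (I of an n-alkane is
100 n exactly, by construction), with flagged linear extrapolation outside
the ladder. The bundled DB-1 (dimethylsiloxane) and HP-50 (50 %-phenyl)
coefficients are single temperature-averaged effective sets anchored to
published GC system-constant compilations, shipped as an editable CSV — as
is the alkane L ladder (published C5–C10 values, +0.5048 per CH₂ beyond,
consistent with hexadecane L = 7.714). The bundled solute-descriptor table
is a small editable example mixing experimental and estimated entries.

The predicted elution plane is (I₁, u₂) with u₂ = base^(ΔI/`delta_scale`),
ΔI = I₂ − I₁, base 1.6 and `delta_scale` = 100: ΔI is expressed in
carbon-number units before exponentiation, since exponentiating raw index
units (O(100)) would overflow any sensible plot scale; both knobs are
configuration. Concordance with the observed (rt1, rt2) configuration uses
Procrustes analysis (centred, unit-norm, optimal rotation; disparity =
residual sum of squares) via `scipy.spatial.procrustes`, plus per-dimension
Pearson correlations computed on the raw coordinates (Pearson r is invariant
to the Procrustes standardisation, so the before/after question is moot).

## The eight-filter funnel

Filters 1–5 remove records; 6–8 annotate evidence and remove nothing under
the default configuration (hard cutoffs are options), since the candidate
list is fixed by filters 1–5 and the orthogonal evidence is meant to grade
confidence:

1. blank correction — subtract the union of both field-blank peak tables
   from every pre/post table (the conservative reading when two blanks
   exist);
2. replicate consistency — keep post peaks matched in both replicates;
3. chlorination differential — subtract the pooled (blank-corrected) pre
   tables from the post table;
4. optimal peak selection — duplicate detections of one compound across the
   raw table and layers 1–4 are grouped and only the highest-MF record
   kept, ties to the lowest layer;
5. match factor ≥ 800;
6. isotopologue fit (cosine + ppm against the hit's formula);
7. retention-index fit (|dI| ≤ 50 by default; missing references are
   indeterminate);
8. elution-space concordance (Procrustes disparity, per-dimension r, and
   optional leave-one-out disparity contributions).

Cross-record matching uses |Δrt1| ≤ 0.25 min and |Δrt2| ≤ 0.15 s (sized to
the synthetic peak widths and the 6.5 s modulation geometry), with names
required to agree when both records are named, and a spectral fallback
(forward MF ≥ 700) otherwise. Two records carrying the *same* library
identity additionally match inside a 4× widened window: a shared confident
identification outweighs retention alone, and deconvolved components of a
compound's tail can legitimately surface a few peak widths from its apex.
Library hits scoring below 400–500 (default `hit_floor` = 500) are treated
as "no identification" so that noise spectra never acquire names that would
poison name-based matching. Apex spectra are cleaned at
max(cube noise floor, 1 % of base peak) before matching.

Funnel accounting is conservation-checked at every stage
(`n_out = n_in − n_removed`, chained), and every candidate carries a
provenance chain back to its originating blob.

## Problem sizes and determinism

The default test suite runs synthetic studies at 2–8 min run length and
m/z 33–340; the heaviest single checks are the 20-seed layer-recall
comparison and the end-to-end five-DBP study (~6 s per study). All
randomness flows through `numpy.random.default_rng` seeds; NMF and
detection are fully deterministic given the data.

## Known limitations

* Nominal (1 Da) m/z precision throughout; accurate-mass deconvolution and
  profile-mode isotope fitting are out of scope.
* The match factor approximates, but is not identical to, commercial
  library-search scores; absolute thresholds transfer only qualitatively.
* Retention prediction uses one effective coefficient set per phase;
  temperature-programmed retention is not simulated, and predictions are in
  index space, never absolute minutes/seconds.
* The synthetic noise model is unstructured; claims about real-matrix
  robustness (bleed, tailing, saturation) are outside what the tests show.
* Hazard/property profiling of candidates is out of scope by design; the
  candidate CSV is joinable with externally produced property tables.
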
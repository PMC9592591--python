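# Methods note

## Mass calculus

Compositions are vectors of dehydrated-residue counts (H hexose,
N HexNAc, D deoxyhexose, A Neu5Ac, G Neu5Gc). Neutral monoisotopic
mass = Σ countᵢ·residueᵢ + water, with residue masses (Da):
Hex 162.05282, HexNAc 203.07937, dHex 146.05791, Neu5Ac 291.09542,
Neu5Gc 307.09033; water 18.01056. All masses are configurable via
`ResidueMassTable` and are cross-checked in the tests against
elemental formulas evaluated with pyteomics (≤ 1e-4 Da).

Derivatized m/z models the sample chemistry:

```
m/z = (neutral + tag_delta + (A+G)·methyl_delta + adduct_delta) / charge
```

One methyl ester (+14.01565) per sialic acid reflects quantitative
methyl esterification; `tag_delta` absorbs the reductive-amination
label. Because the exact labeling-tag mass depends on the reagent lot
and instrument calibration, `tag_delta` defaults to 0 and
`calibrate_tag_delta` recovers it algebraically from one identified
peak (with an optional second peak as a consistency check).

## Annotation

De-novo solving enumerates the bounded composition grid
(H 3–12, N 2–10, D 0–5, A 0–5, G 0–5 by default) subject to
biosynthetic plausibility — N ≥ 2, H ≥ 3, D ≤ N,
A+G ≤ max(N−2, 0)+1 — and keeps candidates within the mass tolerance
(Da or ppm), sorted by |error|, then size, then name. The tests prove
the solver identical to an independently written exhaustive loop.

A consequence of the residue masses: Hex + Neu5Ac and dHex + Neu5Gc
share the elemental formula, so compositions related by that exchange
(e.g. H5N4D1A2 / H4N4D2A1G1 / H3N4D3G2) are *strictly* isobaric. No
tolerance separates them; library-first annotation (each library entry
a distinct observed peak) is the disambiguation mechanism, and the
synthetic library generator enforces a 0.5 Da minimum peak separation
for the same reason.

Sialyl-linkage isomer counting for complex-type glycans is
C(H−3, A+G) · 2^(A+G): choose which antennae are sialylated, then an
α2,3/α2,6 linkage per sialic acid.

## Quantitation and filtering

amount = (area / area_IS) · is_amount, with a 10 pmol internal
standard by default (configurable; reported units are pmol / 100 µg
protein). Peaks annotated to the same composition are summed. The
detection filter keeps a glycoform if it is detected in ≥
`min_detections` (default 3) replicates **within at least one class**
("within-any-group" scope; a "global" scope is available), the
reproducibility rule of atlas-style studies. The profile matrix
carries an explicit detected-mask; undetected cells are stored as 0
but masked, and serialise as empty CSV cells so the mask round-trips.

## Glycotyping

Type rules on composition alone: N=2 ∧ H≤3 → paucimannose;
N=2 ∧ H≥4 → high-mannose; N≥3 ∧ (H−3) > (N−2) → hybrid; else
complex. Terminal sugar by hierarchy Neu5Gc > Neu5Ac > Gal (H≥4,
hybrid/complex) > GlcNAc (N≥3) > Man. Five percentage panels per
sample (type, terminal sugar, antennae, sialic-acid count, fucose
count), each normalised to 100% of the detected amount; a per-entry
`exceptions` mapping lets structure-known compositions override the
rules. The rules are total: every plausible composition receives
exactly one type (property-tested over the full grid).

## Profiling

Glycoforms are z-scored (ddof = 1; zero-variance columns → 0).
Canberra distance Σ|xᵢ−yᵢ|/(|xᵢ|+|yᵢ|) with 0/0 terms defined as 0
weights presence/absence heavily — appropriate for a sparse,
four-decade matrix. Ward clustering supports both R conventions:
`ward.D2` is scipy's Ward on the distances; `ward.D` applies the same
recurrence to unsquared distances (implemented by clustering √d and
squaring the merge heights). Both variants are verified *exactly*
against R's `hclust` in the test suite. Tree cutting at k groups
reports per-group purity (all members one class).

## Classification

Repeated stratified holdout: each repetition holds out one replicate
per class (uniformly, seeded by `(seed, repetition)`), fits on the
rest, and scores per-class F1 (absent classes score 0). Four
families: decision tree, MLP (scaled, lbfgs), random forest (100
trees), RBF SVM (scaled). Hyperparameters are grid-tuned once, by
3-fold cross-validated macro-F1 on the first repetition's training
set, and reused across repetitions — tuning per repetition would add
nothing but ~50× runtime at this replicate count — with the chosen
values recorded in the report. Overall F1 is the unweighted mean of
per-class means; SEs are across repetitions (per class) and across
classes (overall).

## Synthetic atlas

`generate_atlas` draws per-glycoform baseline abundances from a
log-normal (log₁₀ mean −2.0, sd 1.5 → ≈four decades above the
0.04 pmol detection limit), multiplies 8 marker glycoforms per class
by 20-fold, adds mean-preserving multiplicative replicate noise
(CV 25%), thresholds at the detection limit (plus optional random
dropout), and returns the matrix with full ground truth (library,
baselines, markers, noiseless class means). `emit_peaklists` inverts
quantitation so the pipeline can be tested end-to-end from peak
lists. `generate_strain_variants` perturbs one class's mean profile
per strain (n glycoforms × fold change) for strain-discrimination
studies. The default problem size — 18 classes × 5 replicates × 103
glycoforms — is this package's choice of a realistic full-body study
shape.

The generator emulates abundance structure only: no isotope
envelopes, peak shapes, mass errors, or batch effects; noise is i.i.d.
across glycoforms (no correlated pathway co-regulation); markers are
chosen independently per class.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with
  explicit seeds; identical seeds give byte-identical artifacts.
- Distances/linkage delegate to scipy, estimators/F1 to scikit-learn,
  tables to pandas, config validation to pydantic (unknown keys
  rejected); the domain layers (mass calculus, solver, glycotyping,
  quantitation rules, generators) are implemented here.
- All file formats are UTF-8 delimited text with documented headers.

## Limitations

- Compositions, not structures: linkage isomers are counted
  combinatorially, never resolved.
- Strictly isobaric composition pairs (above) are inherently ambiguous
  without a library.
- The internal-standard model assumes equal ionisation efficiency
  across glycoforms, as in the underlying experimental method.
- The chance-level and perfect-separation behaviour of the classifiers
  is validated on synthetic data; real-data targets require the
  original study's supplementary tables (see
  `tests/test_acceptance.py::test_reference_atlas_reproduction`).
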
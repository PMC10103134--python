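# Methods

## Problem and model

Glycosaminoglycans (GAGs) are linear sulfated polysaccharides whose biological
activity depends on the positions of their sulfate groups. Cryogenic gas-phase
IR spectroscopy of mass-selected GAG anions yields narrow, conformer-resolved
vibrational bands whose positions encode structural motifs: the amide I/II
region (1600–1700 / 1500–1600 cm⁻¹) reports N-acetylation (and, by its
silence, N-sulfation), the antisymmetric SO₃⁻ stretches (1150–1350 cm⁻¹)
fingerprint the sulfation pattern, and the neutral-carboxyl ν(C=O) above
1700 cm⁻¹ red-shifts with increasing sulfation degree.

`gagir` implements a supervised pipeline over such spectra: preprocessing into
a compact feature matrix, evolutionary feature selection, random-forest
classification of five binary motifs (GAG class HS vs CS; N-, 2-O-, 4-O-,
6-O-sulfation), and a combinatorial evaluation harness for small libraries.
Because no public spectral library of this kind is deposited, a synthetic
generator provides labeled spectra with the same band logic, and all tests
run against it.

## Preprocessing

1. **Laser normalisation.** Raw ion signal is divided by pulse energy ×
   repetition rate, the minimal first-order correction; records at the same
   wavenumber are averaged after normalisation.
2. **Common grid.** Each spectrum is linearly interpolated at 2 cm⁻¹ steps
   over a shared window. The default crop is the canonical fingerprint window
   1010–1786 cm⁻¹ (389 grid points); passing `range_lo=None` uses the
   library's largest shared range instead. No extrapolation: samples not
   covering the window are rejected by name.
3. **Binning.** Blocks of 7 consecutive grid points (≈15 cm⁻¹ at 2 cm⁻¹
   spacing) are integrated by the rectangle rule (sum × step); a final partial
   block is kept, giving ceil(389/7) = 56 bins. The 7-point block is the
   convention that makes the bin count consistent with a 59-column joint
   feature matrix (56 bins + charge + sulfation degree + linker label); a
   literal 15 cm⁻¹ window cannot reproduce that count exactly, so the nominal
   width is treated as approximate.
4. **Scaling.** Spectral bins are min–max scaled to [0, 1] *per spectrum*
   (droplet intensities are non-quantitative); a constant bin vector maps to
   all zeros. Because scaling is per spectrum, no statistics can leak from
   excluded samples into training. Auxiliary columns (charge, sulfation
   degree, binary linker label) stay on their natural integer scales — tree
   splits are scale-free.
5. **Linker label.** The label is binary "any reducing-end linker present",
   so a hold-out hexasaccharide with a linker chemistry unseen in training
   (p-methoxyphenyl vs aminopentyl) still maps to 1. It is appended exactly
   when the library contains linker-carrying samples, or when forced by
   `include_linker_label`.

## Random forest

Binary CART trees with the entropy criterion (information gain, bits),
implemented from scratch:

- thresholds are midpoints between consecutive distinct sorted feature
  values; rows with value ≤ threshold go left;
- at every node max(1, ⌊√k⌋) candidate features are drawn without
  replacement, k being the total feature count of the training matrix;
- growth stops on purity, zero gain, `min_samples_split` (default 2) or an
  optional depth cap; no pruning, no class weighting (the 15–22-sample
  training sets are near-balanced);
- each of the `n_trees` (default 100) trees is grown on a bootstrap resample
  of size n; out-of-bag (OOB) indices are recorded and the OOB error is the
  misclassification rate of samples voted on only by trees that omitted them;
- prediction is by majority vote; *confidence* is the vote fraction of the
  winning class, so a reported 0.60 means 60 % of trees agreed;
- deterministic tie-breaks everywhere: split ties go to the lower feature
  index then lower threshold, vote ties to the first (negative / motif-absent)
  class.

The split search and tree induction are compiled with numba; the per-node
candidate draws use a 64-bit LCG seeded per tree, so models are
bit-reproducible across runs and platforms. Models serialize to versioned
JSON, and a SHA-256 digest of the canonical serialization supports
leakage/regression tests.

## Evolutionary feature selection

Spectral libraries have far more bins than samples, so models are restricted
to a small feature subset found by a μ+λ genetic search over binary masks:

- fitness = cross-validated accuracy of a forest on the active features
  minus `size_penalty` (default 0.001) per active feature; an empty mask
  scores 0 without training. Leave-one-out is the default fitness CV
  (matching the training regime); stratified k-fold is available and the
  cross-validation loop itself runs in a compiled kernel;
- initial masks are sparse with ~√k expected active genes, the scale at
  which the feature-to-sample ratio stays healthy — dense initial masks
  dilute the per-node candidate draw and measurably hurt recovery;
- per generation, λ offspring arise from tournament-selected parents
  (size 3) via uniform crossover (p = 0.8) and per-gene mutation (p = 0.05);
  all-zero masks are repaired to one random gene;
- survivors are the best μ of parents ∪ offspring (μ+λ truncation), which
  subsumes elitism: the best fitness per generation is non-decreasing, and
  this is asserted in tests;
- defaults μ = 40, λ = 80, 50 generations; the experiment batteries in the
  test suite use desk-scale settings μ = 20, λ = 40, 20 generations with a
  15-tree fitness forest, keeping a ~500-model battery within minutes.
  Exact published hyperparameters for this family of experiments are not
  available, so all values are documented, configurable defaults.
- fitness evaluations are cached by mask bytes and seeded per configuration,
  so equal masks always score equally and whole runs are bit-reproducible.

## Evaluation harness

Five canonical binary tasks: `class_hs_cs` (positive = HS), `ns`, `s2`, `s4`,
`s6` (motif present anywhere in the molecule). Training-set families:

- **LOO**: one set per sample, excluding exactly it (16 disaccharides → 16
  sets of 15; × 5 tasks = 80 models);
- **augmentation**: every size-k subset (k = 1..5) of the 6 tetrasaccharides
  added to the 16-disaccharide base → 6+15+20+15+6 = 62 sets, tagged
  `X_m=<16+k>`; × 5 tasks = 310 models; the excluded tetrasaccharides are the
  evaluation targets;
- **hold-out**: the hexasaccharide is predicted from each of the six
  `X_m=21` sets and the full `X_m=22` set, with a guard that raises on any
  training-set leakage.

Feature selection is re-run per training set (different sets legitimately
select different features), and the selected feature names plus the model
digest are recorded per outcome. The *prediction score* is the fraction of
correct excluded-sample classifications; per-task scores pool predictions
per task, the overall score micro-averages all predictions (macro-averaging
over tasks is easily derived from the per-task scores but is not the
reported default). Tasks whose training labels collapse to a single class
are skipped with a logged warning and reported, not silently dropped.

## Synthetic generator

Bands are Gaussians (σ = 6 cm⁻¹ by default; the unresolved C–O/C–C envelope
uses σ = 16) with uniformly drawn centers and jittered amplitudes; conformer
splitting is modeled as 1–3 sub-bands, each at the band's nominal strength
since droplet intensities are qualitative. White noise is added at a
configurable signal-to-noise ratio (default 10, relative to the peak signal),
and intensities are clipped at zero. The scan grid is 1000–1800 cm⁻¹ at
1 cm⁻¹, so the 1010–1786 crop is always satisfiable.

Band logic: per-position SO₃⁻ sub-ranges (4-O: 1160–1200; 2-O: 1240–1278;
6-O: 1258–1296 — the 2-O/6-O overlap deliberately makes 6-O the harder
O-sulfation task, while 4-O is clean), an N-sulfation marker near 1300,
amide II/I bands only for N-acetylated samples (centers vary by one–two bins
across compounds, keeping the region reliably diagnostic at the default
noise level — the generator's purpose is bin-resolvable motif evidence, not
reproduction of the full empirical band-position spread), ν(C=O) ranges
red-shifting 1753–1781 → 1739–1762 → ≈1712 cm⁻¹ with sulfation degree,
νₐ(COO⁻) near 1664 for nonsulfated ions, weak class-specific ring modes and
linker deformation bands.

The default composition is 23 samples: the 8 standard CS and 8 standard HS
lyase-derived disaccharide patterns, six N-/6-O-sulfated aminopentyl-linked
HS tetrasaccharides (two also 2-O-sulfated), and one p-methoxyphenyl-linked
HS hexasaccharide. True per-sample charge states are not published for such
panels; plausible values (1–2 for disaccharides, 3–4 for longer chains) are
assigned and recorded in the manifest.

**What passing tests do and do not show.** The generator emulates band
positions conditional on motifs, not real intensity physics, Fermi
resonances, conformational fine structure, or instrument drift. Recovery of
motifs from synthetic spectra validates the pipeline's mechanics (no leakage,
correct bookkeeping, sensible selection behavior, the qualitative
training-set-size trend); it does not certify accuracy on experimental
spectra.

## Numerical choices and degenerate inputs

- Information gain must exceed 1e-12 to accept a split; gain ties resolve by
  (feature index, threshold).
- Duplicate wavenumbers merge by mean; spectra sort ascending on read; a
  malformed row fails with its line number.
- Single-class training labels degenerate to one-leaf forests with a warning
  (predictions then have confidence 1.0).
- OOB error raises when no sample is out-of-bag for any tree.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawns (library generation, per-(set, task)
  GA/forest seeds) or the in-kernel LCG; two runs with the same seed produce
  byte-identical reports.

## Problem sizes used in the test suite

Unit tests run on toy matrices (≤ 24 × 8). The acceptance battery uses the
full synthetic library at the desk-scale GA settings above: 5 seeds × 16 LOO
sets × 2 tasks plus one 62-set × 5-task augmentation run — about 470
selected-and-trained models end to end.

## Known limitations

- Binary tasks only; no multi-class or regression forests.
- The HS/CS class task on synthetic data is driven by weak ring-mode offsets
  and the linker label, and is not calibrated to the (experimentally
  inconclusive) difficulty of real class assignment.
- The GA returns local optima by construction; different seeds can select
  different, equally fit masks.
- No baseline correction, smoothing, or peak picking; inputs are assumed to
  be clean two-column traces.
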
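# Methods

## The fingerprinting model

An untargeted LC-MS/MS run yields, after feature detection, one MS/MS
spectrum per feature. `memovec` discards the chromatographic coordinate of
each feature and keeps only its fragmentation chemistry, encoded as words:

- `peak@x.xx` — a fragment ion m/z, binned by rounding;
- `loss@x.xx` — a neutral loss, the difference between the precursor m/z
  and a fragment m/z, binned the same way.

A spectrum's *document* is the multiset of its words; a sample's
*fingerprint vector* counts word occurrences over all documents of the
sample; fingerprint vectors aligned on their union vocabulary form the
sample × word count matrix that all downstream statistics operate on.

The underlying assumption is that two samples sharing chemistry share
fragment ions and neutral losses regardless of when their compounds elute.
Retention-time shifts between batches therefore cannot move a sample in
fingerprint space — which the code guarantees structurally (retention time
is never read after MGF parsing) and the test suite checks end to end
(bit-identical matrix after a +120 s shift of every input RT).

Conversely, anything that changes which fragments are *detected* (detector
sensitivity, fragmentation technique, collision energy) does move samples.
The method mitigates, not removes, such effects; sample-wise normalization
(below) is the knob offered for cross-instrument comparisons.

## Import parameters

| parameter | default | meaning |
|---|---|---|
| `min_relative_intensity` | 0.01 | drop peaks below this fraction of the base peak |
| `max_relative_intensity` | 1 | drop peaks above this fraction (base peak kept: bound inclusive) |
| `min_peaks_required` | 10 | reject spectra with fewer surviving peaks |
| `losses_from` | 10 Da | lower neutral-loss bound, inclusive |
| `losses_to` | 200 Da | upper neutral-loss bound, inclusive |
| `n_decimals` | 2 | binning resolution of m/z and loss values |

Processing order: intensity filtering first, then the minimum-peak-count
check, then binning. Losses are computed from the retained fragment peaks
against the raw (unbinned) precursor m/z and binned on the loss value
itself, so rounding error is never compounded. Losses live on the m/z axis;
no charge correction is applied (multiply charged precursors are rare in
the small-molecule regime this targets, and their loss words are still
reproducible, just not neutral masses).

Numerical choices: binning rounds half away from zero using decimal
arithmetic on `repr(value)`, giving locale- and platform-stable word
strings (Python's float formatting ties to even, which would make words at
bin boundaries representation-dependent). Words keep trailing zeros
(`loss@50.00`), so a vocabulary is valid for exactly one `n_decimals`.

Duplicate words within one document (two peaks in the same bin) are kept as
two occurrences, consistent with occurrence-summing aggregation.

## Matrix operations

- **Unaligned route** — one vector per MGF file; no feature alignment at
  any point. **Aligned route** — one document per feature of an aligned
  MGF; the quant table is used purely as a presence/absence mask
  (value > 0 means detected, so gap-filled values count as present — an
  optional threshold is available on the CLI). When each feature is present
  only in its source sample the two routes coincide, which is tested.
- **Merge** requires disjoint sample sets and a consistent normalization
  flag; it is commutative and associative up to row/column order because
  matrices are kept canonical (lexicographic vocabulary, no all-zero
  columns).
- **Blank filtering** removes every word with a nonzero count in any blank,
  then the blank rows. The rule is absolute rather than fold-change-based;
  it runs before normalization in the pipeline.
- **Normalization** divides each row by its sum (relative word
  frequencies). This is deliberately the simplest sample-wise scheme; it is
  what makes matrices from instruments with different overall word yields
  comparable, at the price of discarding absolute richness.
- **Word occurrence filtering** (keep words seen in between *min* and *max*
  samples) defaults to the identity: fingerprint matrices are used
  unfiltered unless the user opts in.

## Statistics

Bray-Curtis dissimilarity is computed on raw counts by default (the
normalized flag, once set, travels with the matrix). PCoA is Gower's
classical scaling; axes with non-positive eigenvalues are dropped without
Lingoes/Cailliez correction and explained proportions are reported relative
to the positive eigenvalue mass — Bray-Curtis matrices are generally
non-Euclidean and the negative part carries no usable coordinates. PERMANOVA
uses Anderson's pseudo-F with label permutations; p =
(1 + #{F_perm ≥ F_obs}) / (1 + n_permutations), ties counted
conservatively, default 999 permutations (p floor 0.001) and an explicit
seed. Distance, ordination and test are delegated to scipy/scikit-bio
behind this package's interfaces; the test suite re-derives pseudo-F from
first principles (including exhaustive enumeration of all 70 assignments
for 8 samples in two groups of 4) and checks agreement to 1e-9.

## The synthetic evaluation study

The generator emulates the structure of the mixture experiment used to
evaluate fingerprint-based sample comparison: `n_parents` = 4 chemodiverse
parent "chemistries" of `compounds_per_parent` = 30 compounds each (10%
shared between parent pairs), all 6 binary mixtures at 60/40 proportions,
one equal-parts quaternary mixture, `replicates` = 3, and two acquisition
batches: a reference batch and one with a 120 s RT shift and sensitivity
0.85 — i.e. a strong chromatographic batch effect plus a mild detector
effect. That yields 11 compositions × 2 batches × 3 replicates = 66
samples, plus one blank per batch carrying a 5-compound contaminant panel
that is also spiked into every real sample.

Mechanics, chosen once as the simplest that reproduce the relevant failure
modes of real data:

- **Detection dropout**: a compound with mixture weight *w* under batch
  sensitivity *s* is detected with probability
  `1 / (1 + ((w·s)/0.02)^-1.2)` — logistic in log(w·s), so parents'
  compounds are almost always seen, minor mixture components drop out
  occasionally, and lower sensitivity thins detections. All Bernoulli draws
  are keyed on (seed, composition, replicate, compound) but never on the
  batch, so a lower-sensitivity batch detects a strict subset of its
  partner's compounds and an RT-shift-only batch pair differs in nothing
  but the RT field.
- **m/z jitter**: fragment m/z gets 5 ppm Gaussian error per batch by
  default. Compound fragment m/z values sit exactly on the 0.01 Da binning
  grid, and 5 ppm stays below half a bin for m/z < 1000, so words are
  stable by construction; raising the jitter deliberately exercises
  bin-boundary fragility.
- **Retention**: true RT per compound, 2 s replicate noise, plus the
  batch's systematic shift.
- **Baseline comparator**: `naive_feature_table` re-aligns the rendered
  features by (precursor bin, RT within 30 s, single linkage) into an
  intensity table — the classical workflow's view of the same data. An RT
  shift beyond the tolerance splits each compound into per-batch features,
  which is precisely the batch effect the fingerprint route bypasses.

What the generator does *not* model: chromatographic peak shapes, isotopes,
adducts, in-source fragmentation, co-elution/chimeric spectra, or
fragmentation-technique differences between instruments. Passing tests on
this simulation therefore demonstrate the alignment-free mechanism and its
statistical consequences, not robustness to every real acquisition
artifact; the aligned-vs-unaligned gap on gap-filled real tables, in
particular, is larger in practice than in simulation.

## Problem sizes and determinism

The bundled study (66 samples + 2 blanks, ~150 spectra per sample, ~4,000
words after blank filtering) was sized so that a full two-route evaluation
with 999-permutation PERMANOVA completes in seconds while keeping ≥ 6
samples per composition group and 33 per batch — enough for the permutation
tests to be meaningful. Every random draw in the package flows from
explicit seeds (study design, PERMANOVA permutations), and study rendering
is byte-stable: the same seed reproduces the same MGF directory exactly.

## Known limitations

- Fingerprints are count-based; feature intensities are ignored everywhere
  except the presence/absence mask of the aligned route. Proportion
  information between mixtures is therefore carried only through detection
  dropout.
- Bin-boundary effects: a fragment whose true m/z sits within measurement
  error of a bin edge can emit different words across runs; 0.01 Da bins
  assume high-resolution instruments.
- PERMANOVA pseudo-F can come out marginally negative when between-group
  distances are systematically smaller than within-group ones (the batch
  factor on fingerprint matrices does exactly this); it should be read as
  "indistinguishable from zero".
- Vocabulary size grows with spectral diversity (10⁵–10⁶ words for
  thousand-sample extract libraries); matrices are stored sparse, but the
  Bray-Curtis step densifies and is the memory bottleneck at that scale.
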
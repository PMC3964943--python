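# Methods

## Pentamer-based shape prediction

The structural features of a base pair are approximated as a function
of its two flanking base pairs on each side, i.e. of the pentamer
centred on it. A query table assigns each canonical pentamer (the
lexicographic minimum of a 5-mer and its reverse complement; 512
classes — no odd-length DNA string is its own reverse complement, so
the 1024 pentamers pair up exactly) one MGW and one ProT value for the
central base pair and two Roll and two HelT values for the two central
base-pair steps.

For a sequence of length L, the window centred at position *i*
(2 ≤ i ≤ L−3) supplies `mgw[i]` and `prot[i]` directly — both features
are strand-invariant — and contributes its first step value to step
(i−1, i) and its second to step (i, i+1). When the lookup had to pass
through the reverse complement, the two step values are swapped before
assignment. Interior steps are covered by two windows and store the
mean of the two contributions; the outermost covered steps store a
single value; everything else is NaN. This assignment is the only one
of its kind that makes prediction exactly strand-invariant
(`predict(revcomp(s))` equals the track-reversal of `predict(s)`,
bitwise), which the test suite enforces on random sequences.

How the upstream pentamer model combines overlapping step
contributions is not observable from its published interface; plain
averaging is this package's choice and is not asserted to be identical
to the original.

Consequences used throughout the package: an unflanked core of length
L has exactly L−4 defined base-pair positions (two undefined per end);
2-bp flanks are the minimal context that defines every core position.

Missing values are always NaN, never numeric sentinels, so heat-map
exports show blank margins rather than fake values. Ambiguous bases
(N) are a hard error by default; a lenient mode (`ambiguous="mask"`)
marks every window touching an N as undefined instead. Coordinates are
0-based and core-start-relative in all outputs; step features are
reported at midpoint coordinates (j + 0.5) so base-pair and step tracks
share one axis.

Profile symmetrization (for palindromic motifs such as the E-box
CACGTG) averages each track element-wise with its mirror about a given
centre, which may be half-integral; missing values propagate as the
mean of whatever is available. The operation is idempotent and leaves
the profile of a reverse-complement-palindromic sequence unchanged.

## Motif scanning with exact p-values

A PFM (counts or probabilities) becomes a log-odds PWM in bits against
a 0-order background, with a pseudocount (default 0.01) distributed
proportionally to the background so scores stay finite. Scores are
discretized to a grid (default 1/1000 bit, at least 100 bins over the
score range); the exact distribution of the discretized score of a
random W-mer under the background is computed by convolving the
per-position score distributions, giving a survival function
p(s) = P(score ≥ s). Observed window scores are rounded to the same
grid before lookup, so reported p-values are self-consistent. With a
uniform background all probabilities are dyadic rationals and the
convolution is exact in binary floating point — the suite checks exact
equality against enumeration of all 4^W words for W ≤ 8.

Both strands of every window are scored; a minus-strand occurrence at
forward offset o means the reverse complement of that window matches
the motif. Occurrences at p ≤ 10⁻³ (the conventional threshold for
calling core binding sites on probes) are reported, all overlaps
included, per strand with no multiple-strand correction. The default
background is uniform; a 0-order background estimated from the scanned
probes can be supplied instead, and the choice is recorded in output
metadata.

One convention is this package's own: a palindromic consensus matches
forward and reverse strands of the *same* window, and the scan reports
both, but the barcode and probe assembly collapse same-(probe, offset)
duplicates to one binding site (keeping the higher-scoring strand, "+"
on ties), since a site is a location, not a strand annotation.

## Dataset assembly

Case-annotated FASTA records must contain exactly one contiguous
upper-case run (the core); malformed records are rejected
individually with diagnostics. The flank-retention rule: with q the
fraction of records carrying ≥2-bp flanks on both sides, q > 1/2 keeps
only those records trimmed to exactly 2-bp flanks; q ≤ 1/2 (including
exactly one half) keeps all records as bare cores. Flanks longer than
2 bp are trimmed so all assembled matrices are rectangular. Records
with no lower-case letters at all are valid core-only records.

Probe assembly: scan → (optionally) remove probes with ≥2 distinct
sites → (optionally) keep the top fraction of remaining probes by
intensity, ties at the cutoff kept → extract every surviving
occurrence with 2-bp flanks, reverse-complemented into motif
orientation for minus-strand hits; occurrences at probe edges without
2-bp flanks are dropped. The multi-site filter precedes the intensity
cut. Every stage's input/output counts are recorded in the dataset's
provenance and telescope by construction. Output order is
deterministic (sorted by site id), independent of probe input order.

The dataset PFM counts bases at every core+flank position;
per-position information content is 2 − H(freq) bits against a uniform
background, without small-sample correction.

## Profile analytics

Row clustering for heat-map display uses agglomerative hierarchical
clustering on Euclidean distances between rows. Distances are
pairwise-complete over shared defined positions, rescaled by
√(n_total/n_complete) so sparser overlaps stay on the same scale;
all-missing rows are excluded (appended after the clustered rows).
Matrices above the display cap (default 3000 rows) are returned in
input order. The linkage criterion defaults to average (single and
complete are available) — the criterion choice is a configurable
default, recorded in output metadata, not an externally fixed fact.
For ≤64 rows and for factor dendrograms the package's own
Lance–Williams agglomeration is used, with deterministic tie-breaking
by smallest cluster-id pair (factor dendrograms sort labels first, so
ties break by name); the suite verifies it against a naive
implementation that recomputes cluster distances from members. Larger
matrices route through `scipy.cluster.hierarchy.linkage` (same
criterion; real-valued profile distances are tie-free in practice).
Dendrograms serialize to Newick with branch lengths equal to
merge-height differences.

Profile comparison shifts dataset 2 by an integer offset, then
computes Pearson correlation and Euclidean distance per feature over
the overlapping positions defined in both averages; fewer than two
shared defined positions is an alignment error, and the number used is
always reported.

Positionwise differential testing uses the two-sample two-sided
Kolmogorov–Smirnov test on shared columns, exact p-values for combined
n ≤ 25 and asymptotic otherwise; a column needs at least 8 defined
values per group (below: reported untested). Categories: strong
(p < 0.001), weak (p < 0.05), none. Whether per-position samples
should be symmetrized before testing is the caller's choice;
symmetrized matrices are appropriate for palindromic motifs. Null
calibration is checked with 100 values per group × 1000 replicate
pairs, where the asymptotic test rejects at the nominal 0.05 level in
5 % ± 2 % of replicates; at much smaller group sizes the asymptotic
test becomes visibly conservative.

Heat-map colour semantics (red = narrow MGW, blue = wide, white =
intermediate) are emitted as a colour-scale block in metadata; image
rendering is out of scope. Matrix TSVs print floats with `repr`, so
write/read round-trips are bit-exact.

## Specificity models

Feature encoding per site: mononucleotide block (4 indicators per
core+flank position; no reference level is dropped — the ridge penalty
keeps the collinear encoding well-posed), core-variant block (one
indicator per observed core sequence, the most frequent variant as
reference), and shape blocks (raw per-position values for MGW/ProT,
per-step for Roll/HelT; columns undefined for every site — the flank
ends — are not features). Intensities are natural-log transformed by
default (the standard treatment for fluorescence signals),
configurable. All columns are standardized; constant columns are
dropped and counted; sites with residual missing shape values are
dropped and counted.

Fitting: outer 10-fold cross-validation with seed-fixed shuffling;
ridge penalty selected per training split by inner 5-fold
cross-validation over a log-spaced grid (10⁻³…10³); held-out accuracy
reported as the coefficient of determination, with squared Pearson
correlation alongside (the two diverge when predictions are biased, so
both are labelled). Everything is deterministic given the seed; fold
assignment depends only on (n, folds, seed).

The shuffled-shape control permutes each shape column independently
across sites (sequence columns untouched) before refitting — a
negative control that preserves shape marginals while severing their
linkage to sites. Model comparison reports
100·(R²_shape − R²_seq)/R²_seq plus paired per-fold differences.

## Synthetic data: what it emulates, and what not

The generators reproduce the *file formats and statistical structure*
of motif-database and binding-microarray inputs, not real biophysics:

* Pentamer tables draw each value independently and uniformly from
  plausible ranges (MGW 2.8–6.2 Å, ProT −18–0°, Roll −8–10°, HelT
  30–40°). Real tables are smooth in sequence space and correlated
  across features; a uniform-random table is actually the *harder*
  case for the engine's bookkeeping, but tests on it say nothing about
  the accuracy of any particular published table.
* Case-annotated FASTA: cores are a consensus (default the E-box
  CACGTG) with independent per-base mutations (default rate 0.08),
  with a configurable fraction (default 0.8) of records carrying 2–3 bp
  flanks on both sides and the rest 0–1 bp.
* Probe sets: 36-bp uniform-random probes (universal arrays use probes
  of this order of magnitude); by default 30 % carry one planted site
  and 5 % two, at random offsets (always leaving 2-bp probe flanks) and
  strands. Log intensity = (PWM score of the planted site)/W +
  (site mean MGW − table mean) + N(0, 0.3), plus a constant offset for
  site-carrying probes; the log-normal form matches fluorescence-signal
  convention. Real probe intensities have position and sequence biases
  the model omits.
* Regression fixtures (n = 2000 for the acceptance run): sites are
  consensus ± mutations (rate 0.15) with random 2-bp flanks; log
  intensity = f(sequence) + g(shape) + noise with f a random linear
  function of mononucleotide indicators, g the mean of core MGW and
  Roll values (a pentamer-determined quantity that a linear
  mononucleotide model cannot fully express), standardized to variance
  shares 1.0 : 0.6 : 0.4. These shares were fixed as the study
  conditions; under them the shape-augmented model gains ≥ 0.10
  cross-validated R² over sequence alone and the shuffled control does
  not — the qualitative pattern expected of a genuine shape effect. A
  passing run demonstrates that the pipeline *detects a planted shape
  signal and rejects a sham one*; it does not certify effect sizes on
  any real factor.

Every generator is bit-reproducible from (config, seed) and emits a
ground-truth manifest (planted sites, flank status, effect components)
sufficient to verify downstream outputs without re-deriving the truth.

## Numerical and design notes

* p-value map: scores above the achievable maximum clip to the
  probability of the maximum, keeping the map in (0, 1].
* Probe scan skips probes shorter than the motif with a warning rather
  than failing the run.
* Intensity-rank ties at a top-fraction cutoff are kept, so the
  selected set can slightly exceed the nominal fraction (recorded in
  provenance).
* The degenerate shuffle hook (identity permutation) makes the
  shuffled control equal the shape model exactly, which the tests use
  to pin the control's plumbing.
* The acceptance script derives all sub-seeds from `--seed` and keeps
  them below 2³¹.

## Known limitations

* No real pentamer table ships with the package; scientific use
  requires plugging in a published table in the TSV dialect.
* Background models are 0-order only; no q-value/FDR layer over scan
  p-values; no motif discovery.
* Unequal-length cores are not aligned — inputs must be pre-aligned.
* The ridge encoding uses mononucleotide + core-variant features only;
  dinucleotide/k-mer features and nonlinear models are out of scope.
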
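# Methods

## The metric

For two samples X and Y, each an ordered multiset of nucleotide reads,
the compression-based distance is

    CBD(X, Y) = 1 - 2 * (C(X) + C(Y) - C(XY)) / (C(X) + C(Y)),

where C(.) is the byte size of the serialized dataset after lossless
compression and XY is the combined dataset. The quantity
C(X) + C(Y) - C(XY) estimates the information shared between the two
read sets; dividing by the average individual size and subtracting from
one turns it into a dissimilarity that is near 0 for near-identical
samples and near 1 for communities with no shared sequence content.
CBD belongs to the normalized-compression-distance family that
approximates the (uncomputable) normalized information distance by
substituting a real compressor for Kolmogorov complexity. It is a
heuristic dissimilarity, not a mathematical metric: self-distances are
small but positive, and the triangle inequality is not guaranteed.

Two practical consequences follow from using a real compressor:

- **Absolute values are backend-dependent.** Compressed sizes differ
  across LZMA implementations, presets and containers, so only the
  metric's *properties* (ordering, monotonicity in overlap, robustness
  to depth) are treated as reproducible, never specific byte counts.
  Every result records the algorithm, preset and combination mode.
- **Size imbalance matters.** For a fixed amount of shared content,
  larger combined payloads give larger CBD. Comparisons are most
  interpretable between libraries of similar depth; the depth-titration
  tools below quantify this.

## Serialization

Before compression a dataset is flattened to one ASCII line per read,
joined by single `\n` bytes with a trailing newline. FASTA headers,
sample labels and any other metadata are excluded, so sequence names
cannot leak into distances. Residues are uppercased; no U→T or
ambiguity-code transformation is applied, and non-ACGT characters (N,
IUPAC codes) pass through verbatim — the package assumes
quality-filtered input and does no further filtering. Lines are sorted
bytewise ascending, which places similar reads adjacently and markedly
improves the compression ratio on amplicon data. Sorting makes the
payload a pure function of the read multiset, so serialization is
byte-deterministic.

## Building the combined payload

Two conventions are implemented for XY:

- `joint_sort` (default): pool both multisets and sort the union
  jointly. Matching reads from X and Y become adjacent, and the payload
  for (X, Y) and (Y, X) is byte-identical, so CBD is *exactly*
  symmetric.
- `concat_of_sorted`: the sorted X payload followed by the sorted Y
  payload — the literal "append Y to X" construction.

The two modes rank sample pairs the same way but their absolute values
differ, and the difference is largest for duplicate-rich pairs: when Y
repeats X, `concat_of_sorted` presents the compressor with one long
block repeat (encoded almost for free, self-CBD ≈ 0.02), whereas
`joint_sort` interleaves duplicate lines and pays a small per-line
match cost (self-CBD ≈ 0.1–0.2 depending on redundancy). `joint_sort`
is the default because exact symmetry is worth more to downstream
ordination and testing than a lower self-distance, and the diagonal is
set to exactly 0 in matrices regardless.

## Compression backends

The default backend is the standard-library LZMA at preset 9 in its
native .xz container with default filters; zlib and bz2 are available
as alternatives. Byte sizes from the default backend agree exactly with
an independent invocation of the `xz -9` command-line tool on identical
payloads (asserted in the test suite). The preset-9 dictionary is
64 MiB; a warning is logged if a payload exceeds the window, since
cross-dataset matches farther apart than the dictionary are invisible.
Raw formula values can fall marginally outside [0, 1] because container
overhead is counted twice in C(X) + C(Y) but once in C(XY); reported
values are clamped into [0, 1] by default (raw values are always kept
alongside), and a raw value outside [-0.05, 1.05] triggers a warning.
Per-dataset compressed sizes are memoized by content digest, so an
n-sample matrix costs n individual compressions plus n(n-1)/2 combined
ones.

## Statistical companions

**Mantel test.** The statistic is the Pearson product–moment
correlation of the strictly-lower-triangle vectors of two label-aligned
distance matrices. The null is built by jointly permuting rows and
columns of one matrix; the one-sided p-value (alternative: positive
association) uses the add-one estimator (count + 1)/(replicates + 1)
with ties counting toward the count, so p is never zero and never
below 1/(replicates + 1). Default 1000 replicates. An exhaustive
enumerator over all n! relabelings serves as the exactness oracle at
small n.

**Group permutation test.** The statistic is mean(between-group
distance) − mean(within-group distance); the null permutes group
labels across samples. One-sided p for the alternative that samples
are more similar within groups than between, same estimator as above.
This is the simplest statistic consistent with comparing observed
category separations against relabeled matrices. Note the resolution
limit: with g groups of sizes n1..ng there are only
n!/(n1!·...·ng!) distinct labelings, which floors the achievable
p-value regardless of replicates.

**Classical MDS.** Torgerson scaling: double-center the squared
distance matrix, eigendecompose, scale eigenvectors by square roots of
positive eigenvalues. CBD matrices are generally non-Euclidean, so
negative eigenvalues occur; affected dimensions are zero-filled with a
warning and no additive-constant correction is applied, mirroring the
classical default. Exact Euclidean inputs are recovered to numerical
precision (Procrustes residual < 1e-8 in tests).

**Convergence fit.** Depth-titration series are summarized by
least-squares fitting value(n) = asymptote + amplitude·exp(−rate·n)
with rate constrained ≥ 0 (scipy's trust-region least squares;
initialized from the series endpoints and the median depth). The
three-parameter decay is a modeling convention — adequate to test
"approaches a plateau" — not a mechanistic claim.

All permutation procedures take one integer seed feeding a single
`numpy.random.Generator`, record it in their result objects, and are
exactly reproducible.

## The synthetic-data generator

The generator emulates amplicon tag sequencing at the level that
matters for compression behavior:

- A **template pool** ("community") is built by mutating a random
  ancestor at a per-site divergence rate (default 0.10, about the
  spread of a moderately diverse genus-level mix at 250 bp); templates
  are guaranteed pairwise distinct. Abundances follow a geometric
  series (ratio 0.8) as a simple long-tailed stand-in for real
  rank-abundance curves. Defaults: 50 templates of length 250.
- A **sample** draws reads from templates proportionally to abundance
  and applies independent per-site substitutions (default rate 0.005,
  a typical post-filter amplicon error rate). No indels, chimeras or
  homopolymer artifacts are modeled.
- **Mixture series**: for each proportion p, an artificial sample of
  fixed depth takes round(p·depth) reads from source A (without
  replacement) and the rest from source B — a known overlap gradient
  against which monotonicity is checked. Comparing each mixture
  against source A itself, with source size equal to the mixture
  depth, makes the p = 1 endpoint a permutation of the reference and
  so spans the metric's range from its self-distance floor to ~1.
- **Subsamples**: uniform without replacement, for library-size
  robustness and convergence designs.

Because templates, not real 16S sequences, underlie the reads, passing
tests demonstrate the metric's *behavioral* properties (range,
monotonicity in overlap, depth robustness, within/between separation)
— they do not calibrate absolute CBD values for real gut or
environmental communities, whose shared-taxon structure, length
variation and error profiles differ.

## Validation design sizes

The end-to-end validation suite uses: 100 random pairs at depths
500–5000 for the range check; an 11-point proportion grid at depth
2000 for monotonicity (Spearman ρ ≤ −0.9 against overlap); subsample
depths {1000, 2000, 4000, 8000} from a 20,000-read sample for size
robustness (band ≤ 0.15 at ≥ 4000 reads); a 16,000-read fixed
reference against subsamples of 250–16,000 reads for the convergence
fit; 200 null matrix pairs for Mantel calibration. These sizes keep a
full run on one CPU to a few minutes while matching the regimes in
which the metric's robustness claims are made.

## Known limitations

- Not a true metric (no triangle-inequality guarantee); self-distance
  is positive before the diagonal convention zeroes it.
- Sensitive to library-size imbalance below ~4000 reads per sample.
- Absolute values are compressor- and mode-dependent; compare only
  values produced under one profile.
- The group-test p-value floor at small n (see above) means small
  designs can show clear separation yet p ≈ 0.03.
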
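# cbdist

Alignment-free comparison of marker-gene amplicon datasets (e.g. 16S
rRNA hypervariable tags) with a **compression-based distance (CBD)** —
a normalized-compression-distance metric that quantifies how much two
samples' read sets overlap without OTU picking, multiple alignment, or
phylogenetic trees.

The distance between samples X and Y is read off their compressibility:

```
CBD(X, Y) = 1 - 2 * (C(X) + C(Y) - C(XY)) / (C(X) + C(Y))
```

where `C(.)` is the size in bytes of the serialized reads after
lossless compression (LZMA at preset 9 by default) and `XY` is the
pooled dataset. If X and Y share many similar sequences, the compressor
encodes the second copy almost for free, `C(XY) << C(X) + C(Y)`, and
CBD approaches 0; for unrelated communities `C(XY) ~ C(X) + C(Y)` and
CBD approaches 1. Headers and labels are stripped and reads are sorted
bytewise before compression, so only sequence content matters.

The package is aimed at microbiome researchers who want a fast
beta-diversity-style distance matrix directly from per-sample FASTA
files, plus the statistical companions to interpret it:

- `cbdist.seqio` — FASTA / plain-text reading, dataset merging, and the
  byte-exact serialization the compressor consumes;
- `cbdist.core` — compressed sizes, pairwise CBD, all-pairs distance
  matrices with per-sample size caching;
- `cbdist.stats` — Mantel test, between-vs-within group permutation
  test, classical (Torgerson) metric dimensional scaling, and an
  exponential convergence-curve fit for depth-titration series;
- `cbdist.simulate` — a seeded mock-community generator (template pools,
  abundance-weighted sampling, substitution noise, proportion mixtures,
  depth subsamples) so every property is testable without downloads;
- `cbdist.cli` — a `cbdist` command with `matrix`, `stats` and
  `simulate` subcommands.

## Worked example

Two mock gut communities, four samples from the first and three from
the second, 1500 reads each:

```python
from cbdist import (CompressionProfile, distance_matrix, generate_pool,
                    sample_community, group_permutation_test, classical_mds)

pool_a = generate_pool(n_templates=50, length=250, divergence=0.10, seed=1)
pool_b = generate_pool(n_templates=50, length=250, divergence=0.10, seed=2)
samples = [sample_community(pool_a, depth=1500, error_rate=0.005, seed=s, label=f"A{s}")
           for s in (1, 2, 3, 4)]
samples += [sample_community(pool_b, depth=1500, error_rate=0.005, seed=s, label=f"B{s}")
            for s in (5, 6, 7)]

dm = distance_matrix(samples, CompressionProfile())
print(dm.to_dataframe().round(3))
```

```
       A1     A2     A3     A4     B5     B6     B7
A1  0.000  0.753  0.735  0.735  0.952  0.950  0.955
A2  0.753  0.000  0.758  0.761  0.950  0.949  0.963
A3  0.735  0.758  0.000  0.734  0.954  0.949  0.959
A4  0.735  0.761  0.734  0.000  0.949  0.942  0.953
B5  0.952  0.950  0.954  0.949  0.000  0.791  0.733
B6  0.950  0.949  0.949  0.942  0.791  0.000  0.747
B7  0.955  0.963  0.959  0.953  0.733  0.747  0.000
```

Samples from the same community sit around 0.73–0.79 apart, samples
from different communities around 0.95 — the matrix separates the two
communities cleanly. The permutation test makes that quantitative:

```python
groups = {f"A{s}": "community1" for s in (1, 2, 3, 4)}
groups |= {f"B{s}": "community2" for s in (5, 6, 7)}
res = group_permutation_test(dm, groups, replicates=1000, seed=0)
print(f"between - within = {res.statistic:.3f}, p = {res.p_value:.4f}")
```

```
between - within = 0.202, p = 0.0270
```

Between-community distances exceed within-community distances by 0.20
on average, and only ~2.7% of random relabelings do as well (with n=7
there are just 35 distinct labelings, so p cannot go below ~0.03).
`classical_mds(dm, k=2)` then embeds the samples for plotting; the
first axis alone separates the A samples (≈ −0.3) from the B samples
(≈ +0.4).

The same workflow from the shell:

```sh
cbdist simulate --depth 2000 --proportions 11 --seed 3 --out sim/
cbdist matrix sim/*.fasta --out run/
cbdist stats run/cbd_matrix.tsv --groups groups.tsv --k 2 --out run/
```

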
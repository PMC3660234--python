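"""Synthetic mock-community amplicon samples and artificial-dataset designs.

The generator emulates marker-gene tag sequencing: each community is a
pool of distinct template sequences ("species") with long-tailed
abundance weights; a sample is a multiset of reads drawn from the pool
with independent per-site substitution errors.  Two experimental designs
are provided on top of this: proportion mixtures of two source samples
(to probe how the distance responds to a known overlap gradient) and
depth subsamples of one sample (to probe robustness to library size).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import SequenceDataset

__all__ = [
    "TemplatePool",
    "MixtureDesign",
    "generate_pool",
    "sample_community",
    "mixture_series",
    "subsample",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TemplatePool:
    """A community's template ("species") sequences and their abundances.

    ``templates`` are pairwise-distinct nucleotide strings of a common
    nominal length; ``abundances`` are positive weights summing to 1.
    """

    templates: tuple[str, ...]
    abundances: np.ndarray
    length: int

    def __post_init__(self) -> None:
        if len(set(self.templates)) != len(self.templates):
            raise ValueError("templates must be pairwise distinct")
        if len(self.templates) != len(self.abundances):
            raise ValueError("abundances must match templates in count")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")
        if not np.isclose(self.abundances.sum(), 1.0):
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class MixtureDesign:
    """Design for a series of artificial samples mixing two sources.

    For each proportion ``p`` one artificial sample of exactly ``depth``
    reads is drawn: ``round(p * depth)`` reads from ``source_a`` (without
    replacement) and the remainder from ``source_b``.
    """

    source_a: SequenceDataset
    source_b: SequenceDataset
    proportions: tuple[float, ...]
    depth: int
    seed: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently at ``rate``, never to itself."""
    mask = rng.random(seq_codes.shape) < rate
    shift = rng.integers(1, 4, size=seq_codes.shape)
    return np.where(mask, (seq_codes + shift) % 4, seq_codes)


def _decode(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def generate_pool(
    n_templates: int,
    length: int = 250,
    divergence: float = 0.10,
    seed: int = 0,
    abundance_ratio: float = 0.8,
) -> TemplatePool:
    """Generate a pool of distinct templates around a random ancestor.

    Each template is the ancestor mutated at per-site rate ``divergence``;
    pairwise distinctness is enforced (re-drawing a clashing template up
    to a bounded number of attempts).  Abundances follow a geometric
    series with ratio ``abundance_ratio`` — a simple long-tailed stand-in
    for real community rank-abundance curves.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if divergence == 0.0 and n_templates > 1:
        raise ValueError(
            "divergence=0 cannot produce more than one distinct template"
        )
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length)
    seen: set[str] = set()
    templates: list[str] = []
    attempts = 0
    while len(templates) < n_templates:
        tpl = _decode(_mutate(ancestor, divergence, rng))
        attempts += 1
        if tpl not in seen:
            seen.add(tpl)
            templates.append(tpl)
        elif attempts > 100 * n_templates:
            raise ValueError(
                "could not generate pairwise-distinct templates; "
                "increase divergence or length"
            )
    weights = abundance_ratio ** np.arange(n_templates, dtype=float)
    return TemplatePool(
        templates=tuple(templates),
        abundances=weights / weights.sum(),
        length=length,
    )


def sample_community(
    pool: TemplatePool,
    depth: int,
    error_rate: float = 0.005,
    seed: int = 0,
    label: str | None = None,
) -> SequenceDataset:
    """Draw a sample of ``depth`` reads from a template pool.

    Templates are drawn with probability proportional to their
    abundances; each read then receives independent per-site
    substitutions at ``error_rate`` (no indels).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = np.empty((len(pool.templates), pool.length), dtype=np.uint8)
    for i, tpl in enumerate(pool.templates):
        codes[i] = np.frombuffer(tpl.encode("ascii"), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.uint8)
    lookup[_ALPHABET] = np.arange(4)
    codes = lookup[codes]
    picks = rng.choice(len(pool.templates), size=depth, p=pool.abundances)
    reads = codes[picks]
    if error_rate > 0:
        reads = _mutate(reads, error_rate, rng)
    return SequenceDataset(
        label=label if label is not None else f"community_seed{seed}",
        sequences=[_decode(row) for row in reads],
    )


def subsample(ds: SequenceDataset, depth: int, seed: int = 0,
              label: str | None = None) -> SequenceDataset:
    """Uniform subsample without replacement, reproducible under ``seed``."""
    if not 1 <= depth <= len(ds):
        raise ValueError(
            f"depth must lie in [1, {len(ds)}] for dataset {ds.label!r}, "
            f"got {depth}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ds), size=depth, replace=False)
    return SequenceDataset(
        label=label if label is not None else f"{ds.label}_sub{depth}",
        sequences=[ds.sequences[i] for i in idx],
    )


def mixture_series(design: MixtureDesign) -> list[SequenceDataset]:
    """Materialize the artificial samples of a mixture design.

    Returns one dataset per proportion, each of exactly ``design.depth``
    reads, drawn without replacement from the two sources.
    """
    out: list[SequenceDataset] = []
    rng = np.random.default_rng(design.seed)
    for p in design.proportions:
        n_a = round(p * design.depth)
        n_b = design.depth - n_a
        if n_a > len(design.source_a):
            raise ValueError(
                f"proportion {p} requests {n_a} reads from source_a "
                f"({len(design.source_a)} available)"
            )
        if n_b > len(design.source_b):
            raise ValueError(
                f"proportion {p} requests {n_b} reads from source_b "
                f"({len(design.source_b)} available)"
            )
        seqs: list[str] = []
        if n_a:
            idx = rng.choice(len(design.source_a), size=n_a, replace=False)
            seqs.extend(design.source_a.sequences[i] for i in idx)
        if n_b:
            idx = rng.choice(len(design.source_b), size=n_b, replace=False)
            seqs.extend(design.source_b.sequences[i] for i in idx)
        out.append(SequenceDataset(label=f"mix_p{p:.2f}", sequences=seqs))
    return out


def community_pair(
    overlap: float,
    depth: int,
    n_templates: int = 50,
    length: int = 250,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[SequenceDataset, SequenceDataset]:
    """One pair of samples with a controlled read-overlap proportion.

    The first sample is drawn from one community; the second mixes
    ``round(overlap * depth)`` of the first sample's own reads with reads
    from an unrelated community.  ``overlap=0`` gives disjoint
    communities, ``overlap=1`` a permutation of the first sample.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    pool_a = generate_pool(n_templates, length, seed=seed)
    pool_b = generate_pool(n_templates, length, seed=seed + 1_000_003)
    x = sample_community(pool_a, depth, error_rate, seed=seed + 7,
                         label=f"x_seed{seed}")
    source_b = sample_community(pool_b, depth, error_rate, seed=seed + 11,
                                label="b")
    design = MixtureDesign(source_a=x, source_b=source_b,
                           proportions=(overlap,), depth=depth,
                           seed=seed + 13)
    y = mixture_series(design)[0]
    y.label = f"y_seed{seed}"
    return x, y


def write_manifest(path: str | Path, **params) -> Path:
    """Record generator parameters and seeds as a JSON manifest."""
    path = Path(path)
    path.write_text(json.dumps(params, indent=2, default=str) + "\n")
    return path
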
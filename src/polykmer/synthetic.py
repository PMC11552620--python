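"""Synthetic k-mer spectra with known ground truth.

Two generators at different levels of realism:

* :func:`simulate_histogram` draws a spectrum directly from a mixture
  description (per-sharing-class distinct-k-mer counts, an error tail, a
  repeat tail) — exact control over the truth, instant to run.
* :func:`simulate_polyploid_reads` goes end to end: build a random ancestral
  sequence, derive ``p`` diverged homologs, sample error-bearing short reads,
  count canonical k-mers exactly, tally the spectrum.  Slower, but exercises
  the whole causal chain from sequence to histogram.

:func:`expected_G_oracle` computes the genome size a perfect estimator would
report for a mixture spec by plain arithmetic, independent of any fitting
code — the comparison baseline for every accuracy test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import KmerHistogram

__all__ = [
    "MixtureSpec",
    "SimulatedTruth",
    "simulate_histogram",
    "expected_G_oracle",
    "simulate_polyploid_reads",
    "sample_mixture_specs",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MixtureSpec:
    """Generative description of a polyploid k-mer spectrum.

    distinct_kmers[i-1] is the number of distinct k-mers shared by exactly
    ``i`` of the ``p`` homologous chromosomes; their coverages are drawn with
    mean ``i * c_het``.  Error k-mers get geometrically decaying coverages
    starting at 1; repeat k-mers get coverages with mean
    ``repeat_multiplier * c_het`` (the multiplier must sit beyond ``p`` so
    repeats land past the last genomic peak).
    """

    p: int
    c_het: float
    distinct_kmers: tuple[int, ...]
    error_kmers: int = 0
    error_decay: float = 0.5
    repeat_kmers: int = 0
    repeat_multiplier: float = 0.0
    dispersion: str = "poisson"
    overdispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or len(self.distinct_kmers) != self.p:
            raise ValueError("distinct_kmers must have exactly p entries")
        if not any(L > 0 for L in self.distinct_kmers):
            raise ValueError("at least one sharing class must be nonempty")
        if self.c_het < 5:
            raise ValueError("c_het < 5 gives no peak separation worth simulating")
        if not 0 < self.error_decay < 1:
            raise ValueError("error_decay must be in (0, 1)")
        if self.repeat_kmers > 0 and self.repeat_multiplier < self.p:
            raise ValueError("repeat_multiplier must be >= p")
        if self.dispersion not in ("poisson", "negative_binomial"):
            raise ValueError("dispersion must be poisson or negative_binomial")


@dataclass(frozen=True)
class SimulatedTruth:
    """Known answers for a simulated spectrum, computed by arithmetic only."""

    true_G: float
    true_c_het: float
    true_region_sizes: tuple[float, ...] = field(default_factory=tuple)
    true_repeat_size: float = 0.0


def expected_G_oracle(spec: MixtureSpec) -> float:
    """Average haploid genome size implied by the mixture spec.

    A class of L_i distinct k-mers shared by i homologs spans L_i bases on
    each of the i copies, i.e. L_i * i / p bases of the haploid average;
    repeats contribute analogously at their coverage multiplier.  Pure
    arithmetic — never touches the estimator.
    """
    region = sum(L * i / spec.p for i, L in enumerate(spec.distinct_kmers, start=1))
    rep = spec.repeat_kmers * spec.repeat_multiplier / spec.p
    return float(region + rep)


def simulate_histogram(spec: MixtureSpec) -> tuple[KmerHistogram, SimulatedTruth]:
    """Draw a spectrum from the mixture spec; reproducible under its seed.

    Coverage draws of zero (possible in principle under Poisson) are clamped
    to 1 so the histogram's distinct-k-mer total equals the spec's exactly.
    """
    rng = np.random.default_rng(spec.seed)
    draws: list[np.ndarray] = []
    for i, L in enumerate(spec.distinct_kmers, start=1):
        if L == 0:
            continue
        mean = i * spec.c_het
        draws.append(_draw_coverages(rng, spec, mean, L))
    if spec.repeat_kmers > 0:
        draws.append(
            _draw_coverages(rng, spec, spec.repeat_multiplier * spec.c_het, spec.repeat_kmers)
        )
    if spec.error_kmers > 0:
        # geometric law: P(c) = (1 - r) r^(c-1), numpy's parameter is 1 - r
        draws.append(rng.geometric(1.0 - spec.error_decay, size=spec.error_kmers))
    cov = np.concatenate(draws)
    counts = np.bincount(cov)
    grid = np.arange(1, counts.size, dtype=np.int64)
    hist = KmerHistogram(
        coverages=grid,
        frequencies=counts[1:].astype(np.float64),
        source=f"simulate_histogram(seed={spec.seed})",
    )
    truth = SimulatedTruth(
        true_G=expected_G_oracle(spec),
        true_c_het=float(spec.c_het),
        true_region_sizes=tuple(
            L * i / spec.p for i, L in enumerate(spec.distinct_kmers, start=1)
        ),
        true_repeat_size=spec.repeat_kmers * spec.repeat_multiplier / spec.p,
    )
    return hist, truth


def _draw_coverages(
    rng: np.random.Generator, spec: MixtureSpec, mean: float, n: int
) -> np.ndarray:
    if spec.dispersion == "poisson":
        c = rng.poisson(mean, size=n)
    else:
        theta = spec.overdispersion
        c = rng.negative_binomial(theta, theta / (theta + mean), size=n)
    return np.maximum(c, 1)


def sample_mixture_specs(
    n: int,
    seed: int,
    ploidies: tuple[int, ...] = (2, 4, 6, 8),
    c_het_range: tuple[float, float] = (20.0, 60.0),
    class_size_range: tuple[int, int] = (100_000, 500_000),
) -> list[MixtureSpec]:
    """Draw ``n`` random Poisson mixture specs for benchmark sweeps.

    Ploidy uniform over ``ploidies``, per-haplotype coverage uniform over
    ``c_het_range``, every sharing class populated with at least
    ``class_size_range[0]`` distinct k-mers.  Deterministic given ``seed``;
    each spec gets its own derived seed.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        p = int(rng.choice(ploidies))
        c_het = float(rng.uniform(*c_het_range))
        L = tuple(int(rng.integers(*class_size_range)) for _ in range(p))
        specs.append(
            MixtureSpec(
                p=p, c_het=c_het, distinct_kmers=L, seed=int(rng.integers(2**31 - 1))
            )
        )
    return specs


# ---------------------------------------------------------------------------
# end-to-end read simulation


def simulate_polyploid_reads(
    haploid_len: int,
    p: int,
    divergence: float,
    depth: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    k: int = 21,
    seed: int = 0,
    fasta_path: str | None = None,
) -> tuple[KmerHistogram, SimulatedTruth]:
    """Simulate a polyploid WGS experiment and tally its k-mer spectrum.

    One random ancestral sequence of ``haploid_len`` bases; each of the ``p``
    homologs applies independent per-site substitutions at rate
    ``divergence``; reads of ``read_len`` bases with per-base error rate
    ``error_rate`` are sampled uniformly on the forward strand of each
    homolog to the target per-haplotype ``depth``; canonical k-mers (the
    lexicographic minimum of a k-mer and its reverse complement, as counted
    by standard counters) are tallied exactly.

    The truth records ``haploid_len`` as the average haploid genome size and
    ``depth * (read_len - k + 1) / read_len`` as the per-haplotype k-mer
    coverage (each read of L bases yields L - k + 1 k-mers).
    """
    if haploid_len > 10**6:
        raise ValueError("haploid_len above 1e6 is out of range for this generator")
    if not (15 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and in [15, 31]")
    if not (0.0 <= divergence <= 0.2):
        raise ValueError("divergence must be in [0, 0.2]")
    if read_len <= k:
        raise ValueError("read_len must exceed k")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=haploid_len, dtype=np.uint8)
    homologs = []
    for _ in range(p):
        hom = ancestor.copy()
        mut = rng.random(haploid_len) < divergence
        # substitute to one of the three other bases
        hom[mut] = (hom[mut] + rng.integers(1, 4, size=int(mut.sum()), dtype=np.uint8)) % 4
        homologs.append(hom)
    if fasta_path is not None:
        _write_fasta(homologs, fasta_path)

    n_reads = int(round(depth * haploid_len / read_len))
    counts = _count_canonical_kmers(rng, homologs, n_reads, read_len, error_rate, k)
    freq = np.bincount(counts)
    grid = np.arange(1, freq.size, dtype=np.int64)
    hist = KmerHistogram(
        coverages=grid,
        frequencies=freq[1:].astype(np.float64),
        k=k,
        source=f"simulate_polyploid_reads(seed={seed})",
    )
    truth = SimulatedTruth(
        true_G=float(haploid_len),
        true_c_het=depth * (read_len - k + 1) / read_len,
    )
    return hist, truth


def _count_canonical_kmers(
    rng: np.random.Generator,
    homologs: list[np.ndarray],
    n_reads_per_homolog: int,
    read_len: int,
    error_rate: float,
    k: int,
) -> np.ndarray:
    """Exact canonical k-mer multiplicities across all simulated reads."""
    chunk = 50_000
    offsets = np.arange(read_len)
    all_codes: list[np.ndarray] = []
    for hom in homologs:
        max_start = hom.size - read_len
        starts = rng.integers(0, max_start + 1, size=n_reads_per_homolog)
        for lo in range(0, n_reads_per_homolog, chunk):
            sub = starts[lo : lo + chunk]
            reads = hom[sub[:, None] + offsets]
            if error_rate > 0:
                err = rng.random(reads.shape) < error_rate
                n_err = int(err.sum())
                if n_err:
                    reads = reads.copy()
                    reads[err] = (reads[err] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
            all_codes.append(_canonical_codes(reads, k))
    codes = np.concatenate(all_codes)
    _, mult = np.unique(codes, return_counts=True)
    return mult


def _canonical_codes(reads: np.ndarray, k: int) -> np.ndarray:
    """2-bit-pack every k-mer of every read; return canonical uint64 codes."""
    n_kmers = reads.shape[1] - k + 1
    fwd = np.zeros((reads.shape[0], n_kmers), dtype=np.uint64)
    rev = np.zeros_like(fwd)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | reads[:, t : t + n_kmers].astype(np.uint64)
        rev = (rev << np.uint64(2)) | (
            np.uint64(3) - reads[:, k - 1 - t : k - 1 - t + n_kmers].astype(np.uint64)
        )
    return np.minimum(fwd, rev).ravel()


def _write_fasta(homologs: list[np.ndarray], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for idx, hom in enumerate(homologs, start=1):
            fh.write(f">homolog_{idx}\n")
            seq = "".join(_BASES[hom])
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
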
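"""Reading, validating and writing k-mer frequency histograms.

A k-mer frequency histogram tallies, for each coverage value ``c`` (how many
times a distinct k-mer occurs in the reads), the number of distinct k-mers
``f(c)`` occurring exactly that often.  Standard counters (``jellyfish histo``,
``kmc transform ... histogram``) emit it as two whitespace-separated columns,
coverage then frequency, one line per coverage bin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KmerHistogram",
    "HistogramParseError",
    "read_histogram",
    "write_histogram",
    "total_kmer_instances",
]


class HistogramParseError(ValueError):
    """Raised when a histogram file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class KmerHistogram:
    """An ordered k-mer coverage -> frequency tally.

    Parameters
    ----------
    coverages
        Strictly increasing positive integer coverage values.
    frequencies
        Non-negative finite frequencies (distinct k-mer counts), aligned with
        ``coverages``.  Fractional values are allowed: intermediate stages of
        the fitting pipeline produce non-integer residuals.
    k
        Optional k-mer length.  Metadata only; no formula uses it.
    source
        Free-text provenance (file path, dialect, or generator description).
    aggregate_last_bin
        True when the final bin looks like a counter's ceiling bin that lumps
        together every coverage above a maximum (its frequency is implausibly
        large relative to its neighbours).  Flagged, never removed here; the
        fitting layer decides whether to exclude it.
    """

    coverages: np.ndarray
    frequencies: np.ndarray
    k: int | None = None
    source: str = ""
    aggregate_last_bin: bool = field(default=False)

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverages, dtype=np.int64)
        freq = np.asarray(self.frequencies, dtype=np.float64)
        if cov.ndim != 1 or freq.ndim != 1 or cov.shape != freq.shape:
            raise HistogramParseError("coverages and frequencies must be 1-D and aligned")
        if cov.size == 0:
            raise HistogramParseError("histogram has no bins")
        if np.any(cov < 1):
            raise HistogramParseError("coverage values must be >= 1")
        if np.any(np.diff(cov) <= 0):
            raise HistogramParseError("coverage values must be strictly increasing")
        if not np.all(np.isfinite(freq)):
            raise HistogramParseError("frequencies must be finite")
        if np.any(freq < 0):
            raise HistogramParseError("frequencies must be non-negative")
        object.__setattr__(self, "coverages", cov)
        object.__setattr__(self, "frequencies", freq)

    def __len__(self) -> int:
        return int(self.coverages.size)

    @property
    def max_coverage(self) -> int:
        return int(self.coverages[-1])

    def frequency_at(self, coverage: int) -> float:
        """Frequency at an exact coverage value, 0.0 if the bin is absent."""
        idx = np.searchsorted(self.coverages, coverage)
        if idx < len(self.coverages) and self.coverages[idx] == coverage:
            return float(self.frequencies[idx])
        return 0.0

    def dense(self, max_coverage: int | None = None) -> "KmerHistogram":
        """Return an equivalent histogram on the full integer grid 1..max.

        Absent coverages get frequency 0.  The fitting pipeline operates on
        dense grids so that windows, interpolation and residual subtraction
        share one coordinate system.
        """
        hi = self.max_coverage if max_coverage is None else int(max_coverage)
        grid = np.arange(1, hi + 1, dtype=np.int64)
        freq = np.zeros(hi, dtype=np.float64)
        keep = self.coverages <= hi
        freq[self.coverages[keep] - 1] = self.frequencies[keep]
        return replace(self, coverages=grid, frequencies=freq)

    def with_frequencies(self, frequencies: np.ndarray) -> "KmerHistogram":
        """Copy with replaced frequencies on the same coverage grid."""
        return replace(self, frequencies=np.asarray(frequencies, dtype=np.float64))


def _flag_aggregate_bin(cov: np.ndarray, freq: np.ndarray) -> bool:
    # Counter ceiling heuristic: last bin >10x the median of the 10 bins before it.
    if cov.size < 3:
        return False
    tail = freq[max(0, freq.size - 11) : -1]
    med = float(np.median(tail)) if tail.size else 0.0
    return med > 0 and float(freq[-1]) > 10.0 * med


def read_histogram(path: str | os.PathLike, dialect: str = "auto") -> KmerHistogram:
    """Parse a two-column histogram file.

    ``dialect`` may be ``auto``, ``jellyfish`` or ``kmc``; all three dialects
    are whitespace-separated ``coverage frequency`` lines, so the value is
    recorded as provenance rather than switching parse behaviour.  Lines
    starting with ``#`` are skipped.  Duplicate coverage lines are summed
    (merged files may contain them).  Raises :class:`HistogramParseError` with
    the offending line number on malformed input.
    """
    if dialect not in ("auto", "jellyfish", "kmc"):
        raise ValueError(f"unknown dialect {dialect!r}")
    covs: list[int] = []
    freqs: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise HistogramParseError(
                    f"{path}: line {lineno}: expected two numeric columns, got {line!r}"
                )
            try:
                c = float(tokens[0])
                f = float(tokens[1])
            except ValueError as exc:
                raise HistogramParseError(
                    f"{path}: line {lineno}: non-numeric token in {line!r}"
                ) from exc
            if c != int(c) or c < 1:
                raise HistogramParseError(
                    f"{path}: line {lineno}: coverage must be a positive integer, got {tokens[0]}"
                )
            if f < 0:
                raise HistogramParseError(
                    f"{path}: line {lineno}: negative frequency {tokens[1]}"
                )
            covs.append(int(c))
            freqs.append(f)
    if not covs:
        raise HistogramParseError(f"{path}: no data lines")
    cov = np.asarray(covs, dtype=np.int64)
    freq = np.asarray(freqs, dtype=np.float64)
    # sort, then sum duplicates
    order = np.argsort(cov, kind="stable")
    cov, freq = cov[order], freq[order]
    uniq, inverse = np.unique(cov, return_inverse=True)
    summed = np.zeros(uniq.size, dtype=np.float64)
    np.add.at(summed, inverse, freq)
    return KmerHistogram(
        coverages=uniq,
        frequencies=summed,
        source=f"{path} ({dialect})",
        aggregate_last_bin=_flag_aggregate_bin(uniq, summed),
    )


def write_histogram(hist: KmerHistogram, path: str | os.PathLike) -> None:
    """Write the two-column format; round-trips bin-for-bin via read_histogram.

    Integer-valued frequencies are written without a decimal point so that
    files produced from counter output stay byte-compatible with it.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for c, f in zip(hist.coverages, hist.frequencies):
            if float(f).is_integer():
                fh.write(f"{int(c)}\t{int(f)}\n")
            else:
                fh.write(f"{int(c)}\t{float(f)!r}\n")


def total_kmer_instances(hist: KmerHistogram, min_coverage: int = 1) -> float:
    """Total k-mer instances sum(c * f(c)) over bins with c >= min_coverage.

    A distinct k-mer seen c times contributes c instances, so this is the
    total number of (counted) k-mer occurrences in the reads — the numerator
    of every genome-size formula.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    mask = hist.coverages >= min_coverage
    return float(np.sum(hist.coverages[mask] * hist.frequencies[mask]))
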
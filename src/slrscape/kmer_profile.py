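"""k-mer spectrum profiling: genome size and read error rate from reads.

A multiplicity spectrum h(m) — how many distinct canonical k-mers occur m
times in the read set — separates erroneous k-mers (low multiplicity, left of
the valley) from genuine genomic k-mers (the coverage peak). From that split:

    E = sum_{m<valley} m*h(m)        (erroneous k-mer instances)
    T = sum_m m*h(m)                 (all k-mer instances)
    c = argmax_{m>=valley} m*h(m)    (homozygous-peak coverage)
    genome_size = (T - E) / c
    error_rate  = 1 - (1 - E/T)^(1/k)

The error-rate formula inverts the probability (1-e)^k that a k-mer is
error-free under i.i.d. per-base errors. The estimator targets a haploid
(or homozygous-peak) spectrum; heterozygosity is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import encode


@dataclass
class KmerSpectrum:
    """Multiplicity histogram: h[m] = number of distinct canonical k-mers
    seen exactly m times (m >= 1)."""

    k: int
    histogram: dict[int, int]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(m < 1 or c < 0 for m, c in self.histogram.items()):
            raise ValueError("invalid multiplicity histogram")

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ms = np.array(sorted(self.histogram), dtype=np.int64)
        hs = np.array([self.histogram[m] for m in ms], dtype=np.int64)
        return ms, hs


@dataclass
class SpectrumFit:
    genome_size_bp: float
    error_rate: float
    valley: int
    hom_coverage: int


def count_kmers(reads, k: int, batch_kmers: int = 4_000_000) -> KmerSpectrum:
    """Canonical k-mer multiplicity spectrum of a read set.

    k-mers are canonicalized to the lexicographic minimum of the k-mer and its
    reverse complement (2-bit packed, so k <= 31). k-mers containing non-ACGT
    characters are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packed in int64)")
    chunks: list[np.ndarray] = []
    batch: list[np.ndarray] = []
    batch_n = 0
    any_read = False
    for read in reads:
        codes = encode(read)
        if len(codes) < k:
            continue
        any_read = True
        batch.append(codes)
        batch_n += len(codes) - k + 1
        if batch_n >= batch_kmers:
            chunks.append(_canonical_codes(batch, k))
            batch, batch_n = [], 0
    if batch:
        chunks.append(_canonical_codes(batch, k))
    if not any_read:
        raise ValueError(f"no read of length >= k={k}")
    allcodes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    _, counts = np.unique(allcodes, return_counts=True)
    hist = np.bincount(counts)
    return KmerSpectrum(k, {int(m): int(h) for m, h in enumerate(hist) if m >= 1 and h})


def _canonical_codes(reads: list[np.ndarray], k: int) -> np.ndarray:
    # concatenate with a sentinel (code 4) so k-mers never span reads
    sep = np.array([4], dtype=np.uint8)
    seq = np.concatenate([x for r in reads for x in (r, sep)])[:-1].astype(np.int64)
    n = len(seq) - k + 1
    starts = np.arange(n)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = seq[starts + j]
        valid &= b < 4
        bb = np.where(b < 4, b, 0)
        fwd = (fwd << 2) | bb
        rev |= (3 - bb) << (2 * j)
    canon = np.minimum(fwd, rev)
    return canon[valid]


def fit_spectrum(spectrum: KmerSpectrum, error_free: bool = False) -> SpectrumFit:
    """Fit genome size and per-base error rate from a multiplicity spectrum.

    The valley is the first local minimum of the (3-point smoothed) histogram;
    with ``error_free`` the valley is pinned at multiplicity 1 so no mass is
    attributed to errors.
    """
    ms, hs = spectrum.to_arrays()
    mmax = int(ms.max())
    h = np.zeros(mmax + 2)
    h[ms] = hs
    if error_free:
        valley = 1
    else:
        hpad = h.copy()
        hpad[0] = h[1]  # reflect at m=1 so the empty m=0 bin cannot fake a rise
        sm = np.convolve(hpad, np.ones(3) / 3.0, mode="same")
        mass_sm = np.arange(len(h)) * sm
        if mmax < 3:
            raise ValueError(
                "spectrum too narrow to locate a valley; if the reads are "
                "error-free, refit with error_free=True"
            )
        # coverage peak located on k-mer mass m*h(m) (robust to the large
        # m=1 error spike); valley = minimum of smoothed h left of it
        peak = 2 + int(np.argmax(mass_sm[2 : mmax + 1]))
        valley = 1 + int(np.argmin(sm[1 : peak + 1]))
        if valley >= peak or sm[peak] <= sm[valley]:
            raise ValueError(
                "no valley found (unimodal spectrum); if the reads are error-free, "
                "refit with error_free=True"
            )
    m_all = np.arange(len(h))
    mass = m_all * h
    total = float(mass.sum())
    err_mass = float(mass[:valley].sum())
    hom_cov = int(valley + np.argmax(mass[valley:]))
    genome = (total - err_mass) / hom_cov
    error_rate = 1.0 - (1.0 - err_mass / total) ** (1.0 / spectrum.k)
    return SpectrumFit(genome, float(error_rate), int(valley), hom_cov)
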
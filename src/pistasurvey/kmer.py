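"""K-mer spectrum genome survey.

Counts canonical k-mers, locates the error tail and the main coverage peak of
the depth histogram, and derives the survey estimates: genome size
(total k-mers / peak depth), per-base heterozygosity from the half-depth
"heterozygous" peak, and a GC-versus-depth window profile.

The heterozygosity model: a SNV at per-base rate ``h`` makes every k-mer
window overlapping it haplotype-specific, so those k-mers sit at half the
sequencing depth of shared (homozygous) k-mers. With
``q = 1 - (1 - h)**k`` (probability a window overlaps at least one
heterozygous site) the distinct-k-mer mass fraction of the half-depth
component is ``m = 2q / (1 + q)``; the estimator inverts this exactly,
which reduces to the familiar ``m ~ 2kh`` linearization for small ``kh``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KmerHistogram",
    "SpectrumEstimate",
    "HetEstimate",
    "GcDepthPoint",
    "count_kmers",
    "kmer_occurrences",
    "find_error_cutoff",
    "find_peak",
    "find_main_peak",
    "estimate_genome_size",
    "estimate_heterozygosity",
    "analyze_spectrum",
    "gc_depth_profile",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base codes A,C,G,T -> 0..3; anything else -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _window_codes(codes: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """Integer codes of all valid k-mer windows of one encoded sequence."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    nwin = n - k + 1
    bad = (codes < 0).astype(np.int32)
    bad_in_window = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid")
    valid = bad_in_window == 0
    safe = np.where(codes < 0, 0, codes).astype(np.uint64)
    fwd = np.zeros(nwin, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + nwin]
    if not canonical:
        return fwd[valid]
    comp = (np.uint64(3) - safe).astype(np.uint64)
    rev = np.zeros(nwin, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | comp[j : j + nwin]
    return np.minimum(fwd, rev)[valid]


def kmer_occurrences(
    sequences: Iterable[str] | str, k: int, canonical: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct (canonical) k-mer codes and their occurrence counts.

    Returns ``(codes, counts)`` with codes sorted ascending. Windows containing
    non-ACGT symbols are skipped.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_window_codes(_encode(s), k, canonical) for s in sequences]
    parts = [p for p in parts if p.size]
    if not parts:
        raise ValueError(f"no sequence yields a k-mer at k={k}")
    return np.unique(np.concatenate(parts), return_counts=True)


@dataclass(frozen=True)
class KmerHistogram:
    """Depth histogram of a k-mer spectrum: how many distinct k-mers occur
    at each depth. Depths strictly increasing, counts nonnegative."""

    k: int
    depths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if depths.shape != counts.shape or depths.ndim != 1:
            raise ValueError("depths and counts must be 1-D and equally long")
        if depths.size and (np.any(np.diff(depths) <= 0) or depths[0] < 1):
            raise ValueError("depths must be strictly increasing positive integers")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "counts", counts)

    @property
    def n_distinct(self) -> int:
        return int(self.counts.sum())

    @property
    def total_kmers(self) -> int:
        """Total k-mer occurrences: sum over bins of depth * count."""
        return int((self.depths * self.counts).sum())

    def total_above(self, cutoff: int) -> int:
        sel = self.depths >= cutoff
        return int((self.depths[sel] * self.counts[sel]).sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for d, c in zip(self.depths, self.counts):
                fh.write(f"{d}\t{c}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        depths, counts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d, c = line.split("\t")
                depths.append(int(d))
                counts.append(int(c))
        return cls(k=k, depths=np.array(depths), counts=np.array(counts))


def count_kmers(
    sequences: Iterable[str] | str, k: int, canonical: bool = True
) -> KmerHistogram:
    """Count canonical k-mers of the input sequences and bin distinct k-mers
    by occurrence count.

    Canonical means each k-mer is collapsed with its reverse complement
    (lexicographic minimum), the strand-symmetric convention for counts
    derived from double-stranded sequencing data. Set ``canonical=False``
    for stranded counting.
    """
    _, occ = kmer_occurrences(sequences, k, canonical=canonical)
    depths, counts = np.unique(occ, return_counts=True)
    return KmerHistogram(k=k, depths=depths, counts=counts)


def find_error_cutoff(hist: KmerHistogram) -> int:
    """Depth of the first local minimum of count vs depth, scanning upward.

    Sequencing errors pile distinct k-mers at depth ~1; the valley between
    that tail and the coverage peak separates them. Returns 1 when no local
    minimum below the global maximum exists (e.g. monotone histograms).
    """
    if hist.depths.size == 0:
        raise ValueError("empty histogram")
    d, c = hist.depths, hist.counts
    if d.size < 3:
        return 1
    rises = np.flatnonzero(c[1:] > c[:-1]) + 1
    if rises.size == 0:  # monotone non-increasing: no valley below the maximum
        return 1
    i_rise = int(rises[0])
    valley = int(np.argmin(c[:i_rise]))  # first occurrence of the descent minimum
    if valley == 0:  # counts start ascending: no error tail to cut
        return 1
    return int(d[valley])


def find_peak(hist: KmerHistogram, error_cutoff: int | None = None) -> int:
    """Depth with maximal count among depths >= error_cutoff (ties -> smaller depth)."""
    if error_cutoff is None:
        error_cutoff = find_error_cutoff(hist)
    sel = hist.depths >= error_cutoff
    if not np.any(sel):
        raise ValueError(f"no histogram bins at depth >= {error_cutoff}")
    d, c = hist.depths[sel], hist.counts[sel]
    return int(d[int(np.argmax(c))])  # argmax returns first maximum -> smaller depth


def find_main_peak(hist: KmerHistogram, error_cutoff: int | None = None) -> int:
    """Depth of the homozygous (full-coverage) peak.

    At high heterozygosity the half-depth component can out-grow the
    full-depth one, so the raw histogram mode sits near coverage/2. If a
    secondary maximum with at least 20% of the modal count exists near twice
    the raw mode, that depth is returned instead of the mode.
    """
    if error_cutoff is None:
        error_cutoff = find_error_cutoff(hist)
    p0 = find_peak(hist, error_cutoff)
    sel = (hist.depths >= 2 * p0 - 3) & (hist.depths <= 2 * p0 + 3)
    if not np.any(sel):
        return p0
    c0 = hist.counts[hist.depths == p0][0]
    d2 = hist.depths[sel]
    c2 = hist.counts[sel]
    best = int(np.argmax(c2))
    if c2[best] >= 0.2 * c0:
        return int(d2[best])
    return p0


def estimate_genome_size(total_kmers: int, peak_depth: int) -> int:
    """Genome size in bp as round(total k-mer occurrences / peak depth)."""
    if peak_depth <= 0:
        raise ValueError("peak_depth must be positive")
    if total_kmers <= 0:
        raise ValueError("total_kmers must be positive")
    return int(round(total_kmers / peak_depth))


@dataclass(frozen=True)
class HetEstimate:
    """Per-base heterozygosity estimate from the half-depth spectrum component."""

    het_rate: float
    resolved: bool
    mass_fraction: float  # distinct-k-mer mass in the half-depth component


def _mixture_mass_fraction(hist: KmerHistogram, peak_depth: int, cutoff: int) -> float:
    """Nonnegative least-squares fit of the distinct-k-mer histogram as a
    two-Poisson mixture centered at peak/2 and peak; returns the half-depth
    mass fraction."""
    sel = hist.depths >= cutoff
    d = hist.depths[sel].astype(float)
    c = hist.counts[sel].astype(float)
    design = np.column_stack(
        [stats.poisson.pmf(d, peak_depth / 2.0), stats.poisson.pmf(d, float(peak_depth))]
    )
    w, _ = optimize.nnls(design, c)
    if w.sum() <= 0:
        return 0.0
    return float(w[0] / w.sum())


def estimate_heterozygosity(
    hist: KmerHistogram,
    peak_depth: int | None = None,
    k: int | None = None,
    method: str = "mixture",
    h_grid: Sequence[float] = (0.0, 0.0025, 0.005, 0.0075, 0.01, 0.0125, 0.015, 0.02),
    sim_length: int = 200_000,
    seed: int = 0,
) -> HetEstimate:
    """Estimate per-base heterozygosity from a k-mer depth histogram.

    ``method="mixture"`` (default) fits the spectrum above the error cutoff as
    a two-component Poisson mixture (half-depth heterozygous + full-depth
    homozygous), then inverts the window-overlap relation m = 2q/(1+q),
    q = 1-(1-h)^k. ``method="simulate"`` instead picks h from ``h_grid`` by
    least-squares matching against spectra simulated at the same coverage
    and k (the cross-check route).

    Returns het_rate 0 with ``resolved=False`` when no half-depth component
    is resolvable.
    """
    k = k if k is not None else hist.k
    cutoff = find_error_cutoff(hist)
    if peak_depth is None:
        peak_depth = find_main_peak(hist, cutoff)
    if method == "simulate":
        return _estimate_het_by_simulation(hist, peak_depth, k, h_grid, sim_length, seed)
    if method != "mixture":
        raise ValueError(f"unknown method {method!r}")
    if peak_depth < 4:
        warnings.warn("peak depth too low to resolve a half-depth component")
        return HetEstimate(0.0, False, 0.0)
    m = _mixture_mass_fraction(hist, peak_depth, cutoff)
    if m <= 1e-6 or m >= 1.0:
        return HetEstimate(0.0, False, m)
    q = m / (2.0 - m)
    h = 1.0 - (1.0 - q) ** (1.0 / k)
    return HetEstimate(float(h), True, m)


def _estimate_het_by_simulation(hist, peak_depth, k, h_grid, sim_length, seed):
    # local import: simulate depends on nothing here, but avoid a cycle at import time
    from .simulate import GenomeSimSpec, simulate_diploid_genome, simulate_kmer_histogram

    sel = hist.depths >= find_error_cutoff(hist)
    obs_d = hist.depths[sel]
    obs_p = hist.counts[sel] / hist.counts[sel].sum()
    best_h, best_sse = 0.0, np.inf
    for i, h in enumerate(h_grid):
        spec = GenomeSimSpec(length=sim_length, gc_content=0.5, het_rate=h, seed=seed + i)
        h1, h2, _ = simulate_diploid_genome(spec)
        sim = simulate_kmer_histogram((h1, h2), coverage=peak_depth, k=k, seed=seed + i)
        sim_sel = sim.depths >= find_error_cutoff(sim)
        sim_p = np.zeros(int(max(obs_d.max(), sim.depths.max())) + 1)
        sim_p[sim.depths[sim_sel]] = sim.counts[sim_sel] / sim.counts[sim_sel].sum()
        sse = float(np.sum((sim_p[obs_d] - obs_p) ** 2))
        if sse < best_sse:
            best_h, best_sse = float(h), sse
    return HetEstimate(best_h, True, float("nan"))


@dataclass(frozen=True)
class SpectrumEstimate:
    """Survey estimates derived from one k-mer depth histogram."""

    k: int
    peak_depth: int
    error_cutoff_depth: int
    total_kmers: int          # error-excluded by default (depths >= cutoff)
    raw_total_kmers: int      # all bins
    genome_size_bp: int
    het_rate: float
    het_resolved: bool

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "peak_depth": self.peak_depth,
            "error_cutoff_depth": self.error_cutoff_depth,
            "total_kmers": self.total_kmers,
            "raw_total_kmers": self.raw_total_kmers,
            "genome_size_bp": self.genome_size_bp,
            "het_rate": self.het_rate,
            "het_resolved": self.het_resolved,
        }


def analyze_spectrum(
    hist: KmerHistogram,
    error_cutoff: int | None = None,
    exclude_error_kmers: bool = True,
    het_method: str = "mixture",
) -> SpectrumEstimate:
    """Full spectrum analysis: error cutoff, peak, genome size, heterozygosity."""
    cutoff = find_error_cutoff(hist) if error_cutoff is None else error_cutoff
    peak = find_main_peak(hist, cutoff)
    total = hist.total_above(cutoff) if exclude_error_kmers else hist.total_kmers
    size = estimate_genome_size(total, peak)
    het = estimate_heterozygosity(hist, peak_depth=peak, method=het_method)
    return SpectrumEstimate(
        k=hist.k,
        peak_depth=peak,
        error_cutoff_depth=cutoff,
        total_kmers=total,
        raw_total_kmers=hist.total_kmers,
        genome_size_bp=size,
        het_rate=het.het_rate,
        het_resolved=het.resolved,
    )


@dataclass(frozen=True)
class GcDepthPoint:
    window_id: str
    gc_fraction: float
    mean_depth: float
    length: int


def gc_depth_profile(
    sequences: Iterable[str] | str,
    k: int,
    window_bp: int = 500,
    occurrences: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[GcDepthPoint], float]:
    """Tile sequences into non-overlapping windows; per window report the GC
    fraction (non-N bases only) and the mean depth of its canonical k-mers
    (depth = occurrence count over the whole input).

    Trailing windows shorter than half ``window_bp`` are dropped. Returns the
    window list and the length-weighted mean GC.
    """
    if window_bp < k:
        raise ValueError("window_bp must be >= k")
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = list(sequences)
    if occurrences is None:
        occurrences = kmer_occurrences(sequences, k)
    codes_sorted, occ = occurrences
    points: list[GcDepthPoint] = []
    gc_weighted, bases = 0.0, 0
    for si, seq in enumerate(sequences):
        enc = _encode(seq)
        for wi, start in enumerate(range(0, len(seq), window_bp)):
            win = enc[start : start + window_bp]
            if win.size < window_bp / 2:
                continue
            valid = win >= 0
            n_valid = int(valid.sum())
            gc = float(np.isin(win[valid], (1, 2)).mean()) if n_valid else 0.0
            wcodes = _window_codes(win, k, canonical=True)
            if wcodes.size:
                idx = np.searchsorted(codes_sorted, wcodes)
                idx = np.clip(idx, 0, codes_sorted.size - 1)
                found = codes_sorted[idx] == wcodes
                mean_depth = float(occ[idx[found]].mean()) if found.any() else 0.0
            else:
                mean_depth = 0.0
            points.append(
                GcDepthPoint(f"seq{si}:{wi}", gc, mean_depth, int(win.size))
            )
            gc_weighted += gc * n_valid
            bases += n_valid
    mean_gc = gc_weighted / bases if bases else 0.0
    return points, mean_gc
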
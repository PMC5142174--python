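"""Synthetic data with known ground truth for the survey pipeline.

Three generators:

* a diploid genome model — i.i.d. bases at a target GC content, with a
  second haplotype carrying Bernoulli(h) single-base substitutions, and
  optional planted SSR tracts;
* a k-mer depth histogram emulating shotgun sequencing of that diploid at a
  target coverage (Poisson depth per distinct k-mer, scaled by haplotype
  multiplicity, plus an error tail of singleton k-mers);
* structured multi-population genotype tables under a Balding-Nichols-style
  divergence model (per-population allele frequencies drawn around shared
  ancestral frequencies with concentration (1-F)/F), with species-level
  null loci to emulate cross-species marker transferability.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diversity import MISSING, NULL, GenotypeTable
from .kmer import KmerHistogram, kmer_occurrences
from .ssr import DEFAULT_MIN_REPEATS, SSRLocus, is_primitive, scan_perfect_ssrs

__all__ = [
    "GenomeSimSpec",
    "PlantedSSR",
    "PopSimSpec",
    "simulate_diploid_genome",
    "plant_ssrs",
    "random_planted_ssrs",
    "simulate_kmer_histogram",
    "simulate_genotype_table",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSimSpec:
    """Parameters of the diploid genome generator.

    length: haploid genome length in bases.
    gc_content: stationary probability of G or C, in [0, 1].
    het_rate: per-base probability that haplotype 2 differs from haplotype 1.
    """

    length: int
    gc_content: float = 0.371
    het_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError("het_rate must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSSR:
    """A repeat tract to write into the simulated genome (1-based position)."""

    position: int
    motif: str
    n_repeats: int

    def __post_init__(self) -> None:
        ml = len(self.motif)
        if not 2 <= ml <= 6:
            raise ValueError("motif length must be 2-6")
        if set(self.motif.upper()) - set("ACGT"):
            raise ValueError("motif must be over ACGT")
        if not is_primitive(self.motif.upper()):
            raise ValueError(f"motif {self.motif!r} is a repeat of a shorter motif")
        if self.n_repeats < DEFAULT_MIN_REPEATS[ml]:
            raise ValueError(
                f"n_repeats below detection threshold {DEFAULT_MIN_REPEATS[ml]} "
                f"for motif length {ml}"
            )
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def length(self) -> int:
        return len(self.motif) * self.n_repeats

    @property
    def end(self) -> int:
        return self.position + self.length - 1


def simulate_diploid_genome(spec: GenomeSimSpec) -> tuple[str, str, np.ndarray]:
    """Generate two haplotypes and the list of heterozygous positions (1-based).

    Haplotype 1 is drawn i.i.d. with P(G or C) = gc_content; haplotype 2
    equals haplotype 1 except at Bernoulli(het_rate) positions, where the
    base is substituted uniformly among the three alternatives.
    """
    if spec.length < 31:
        warnings.warn(
            "genome shorter than typical k-mer sizes (<= 31); downstream "
            "k-mer analyses may be empty"
        )
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codes1 = rng.choice(4, size=spec.length, p=p).astype(np.uint8)
    het_mask = rng.random(spec.length) < spec.het_rate
    offsets = rng.integers(1, 4, size=spec.length).astype(np.uint8)
    codes2 = codes1.copy()
    codes2[het_mask] = (codes1[het_mask] + offsets[het_mask]) % 4
    hap1 = _BASES[codes1].tobytes().decode("ascii")
    hap2 = _BASES[codes2].tobytes().decode("ascii")
    return hap1, hap2, np.flatnonzero(het_mask) + 1


def random_planted_ssrs(
    n: int,
    genome_length: int,
    seed: int = 0,
    min_spacing: int = 200,
) -> list[PlantedSSR]:
    """Draw n non-overlapping, well-spaced repeat tracts with random primitive
    motifs and repeat counts at or above the detection thresholds."""
    rng = np.random.default_rng(seed)
    planted: list[PlantedSSR] = []
    occupied_end = 0
    max_len = 6 * 10
    span = genome_length - max_len - min_spacing
    starts = np.sort(rng.choice(span // min_spacing, size=n, replace=False))
    for slot in starts:
        pos = int(slot) * min_spacing + min_spacing // 2 + 1
        while True:
            ml = int(rng.integers(2, 7))
            motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ml))
            if is_primitive(motif):
                break
        reps = int(rng.integers(DEFAULT_MIN_REPEATS[ml], DEFAULT_MIN_REPEATS[ml] + 5))
        planted.append(PlantedSSR(pos, motif, reps))
        occupied_end = planted[-1].end
    assert occupied_end <= genome_length
    return planted


def plant_ssrs(
    haplotypes: tuple[str, str],
    planted: Sequence[PlantedSSR],
    seed: int = 0,
    flank: int = 30,
    max_resample: int = 200,
) -> tuple[tuple[str, str], list[SSRLocus]]:
    """Overwrite repeat tracts into both haplotypes at the given positions.

    The tract at each position is replaced by motif * n_repeats on both
    haplotypes (planted loci are homozygous). Flanking bases are
    rejection-resampled until a local scan recovers exactly the planted locus
    at its exact coordinates, so planted truth is recoverable by construction.
    Overlapping tracts raise an error. Returns the modified haplotypes and the
    truth table as SSRLocus records.
    """
    spans = sorted((p.position, p.end, p) for p in planted)
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"planted tracts overlap: {e1} >= {s2}")
    if spans and spans[-1][1] > len(haplotypes[0]):
        raise ValueError("planted tract extends past the end of the genome")

    rng = np.random.default_rng(seed)
    seqs = [bytearray(h.encode()) for h in haplotypes]
    truth: list[SSRLocus] = []
    for p in planted:
        tract = (p.motif.upper() * p.n_repeats).encode()
        lo, hi = p.position - 1, p.end  # 0-based slice bounds
        for s in seqs:
            s[lo:hi] = tract
        # rejection-sample flanks until the local scan sees exactly this locus
        wlo, whi = max(0, lo - flank), min(len(seqs[0]), hi + flank)
        for attempt in range(max_resample):
            window = seqs[0][wlo:whi].decode()
            found = [
                l
                for l in scan_perfect_ssrs(window)
                if not (l.end < lo - wlo + 1 or l.start > hi - wlo)
            ]
            ok = (
                len(found) == 1
                and found[0].start == lo - wlo + 1
                and found[0].end == hi - wlo
                and found[0].motif == p.motif.upper()
                and found[0].n_repeats == p.n_repeats
            )
            if ok:
                break
            newlo = rng.integers(0, 4, size=lo - wlo).astype(np.uint8)
            newhi = rng.integers(0, 4, size=whi - hi).astype(np.uint8)
            for s in seqs:
                s[wlo:lo] = _BASES[newlo].tobytes()
                s[hi:whi] = _BASES[newhi].tobytes()
        else:
            raise RuntimeError(f"could not isolate planted SSR at {p.position}")
        truth.append(
            SSRLocus("hap", p.position, p.end, p.motif.upper(), p.n_repeats)
        )
    return (seqs[0].decode(), seqs[1].decode()), truth


def simulate_kmer_histogram(
    haplotypes: tuple[str, str] | Sequence[str],
    coverage: float,
    k: int = 17,
    error_rate: float = 0.0,
    seed: int = 0,
) -> KmerHistogram:
    """Emulate the k-mer depth histogram of shotgun reads over a diploid.

    Each distinct canonical k-mer with multiplicity m across the two
    haplotypes receives a Poisson(coverage * m / 2) depth (a homozygous
    k-mer, present on both haplotypes, sits at full coverage; a
    haplotype-specific k-mer at half). Sequencing errors add
    ~error_rate * k * coverage * length novel singleton k-mers.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (11 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and in 11..31")
    haps = [h for h in haplotypes if h]
    if not haps:
        return KmerHistogram(k=k, depths=np.empty(0, int), counts=np.empty(0, int))
    if min(len(h) for h in haps) < k:
        raise ValueError("k exceeds sequence length")
    rng = np.random.default_rng(seed)
    _, mult = kmer_occurrences(haps, k)
    depth = rng.poisson(coverage * mult / 2.0)
    depth = depth[depth > 0]
    n_err = rng.poisson(error_rate * k * coverage * len(haps[0]))
    depths, counts = np.unique(depth, return_counts=True)
    if n_err:
        if depths.size and depths[0] == 1:
            counts[0] += n_err
        else:
            depths = np.insert(depths, 0, 1)
            counts = np.insert(counts, 0, n_err)
    return KmerHistogram(k=k, depths=depths, counts=counts)


@dataclass(frozen=True)
class PopSimSpec:
    """Parameters of the structured genotype-table generator.

    fst: Balding-Nichols-style divergence; population allele frequencies are
    Dirichlet(ancestral * (1 - fst) / fst), so small fst means nearly
    identical populations.
    null_locus_rate: per-species probability that a locus never amplifies in
    that species (species 1, the focal species, always amplifies everything);
    may be a sequence with one rate per population.
    """

    n_pops: int
    n_per_pop: int | Sequence[int]
    n_loci: int
    fst: float = 0.2
    null_locus_rate: float | Sequence[float] = 0.0
    allele_size_grid: Sequence[int] = tuple(range(100, 131, 2))
    missing_rate: float = 0.0
    species_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("n_pops and n_loci must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be strictly inside (0, 1)")
        if len(self.allele_size_grid) < 2:
            raise ValueError("allele_size_grid needs >= 2 sizes")

    @property
    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_pops
        sizes = list(self.n_per_pop)
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes

    @property
    def null_rates(self) -> list[float]:
        if isinstance(self.null_locus_rate, (int, float)):
            return [float(self.null_locus_rate)] * self.n_pops
        rates = [float(r) for r in self.null_locus_rate]
        if len(rates) != self.n_pops:
            raise ValueError("null_locus_rate length must equal n_pops")
        return rates

    @property
    def names(self) -> list[str]:
        if self.species_names is not None:
            names = list(self.species_names)
            if len(names) != self.n_pops:
                raise ValueError("species_names length must equal n_pops")
            return names
        return [f"sp{i+1}" for i in range(self.n_pops)]


def simulate_genotype_table(spec: PopSimSpec) -> tuple[GenotypeTable, dict]:
    """Generate a structured diploid genotype table plus ground truth.

    Truth dict: ``membership`` (one-hot individuals x pops), ``pop_freqs``
    (pops x loci x alleles), ``null`` (pops x loci bool), ``labels``
    (population index per individual), ``allele_size_grid``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.allele_size_grid, dtype=np.int64)
    A, K, L = grid.size, spec.n_pops, spec.n_loci
    ancestral = rng.dirichlet(np.ones(A), size=L)  # (L, A)
    conc = (1.0 - spec.fst) / spec.fst
    pop_freqs = np.empty((K, L, A))
    for p in range(K):
        for l in range(L):
            pop_freqs[p, l] = rng.dirichlet(np.maximum(ancestral[l] * conc, 1e-9))
    null = np.zeros((K, L), dtype=bool)
    for p, rate in enumerate(spec.null_rates):
        if rate > 0:
            null[p] = rng.random(L) < rate

    sizes = spec.pop_sizes
    n = sum(sizes)
    labels = np.repeat(np.arange(K), sizes)
    a1 = np.empty((n, L), dtype=np.int64)
    a2 = np.empty((n, L), dtype=np.int64)
    for i, p in enumerate(labels):
        for l in range(L):
            if null[p, l]:
                a1[i, l] = a2[i, l] = NULL
            elif spec.missing_rate and rng.random() < spec.missing_rate:
                a1[i, l] = a2[i, l] = MISSING
            else:
                draws = rng.choice(A, size=2, p=pop_freqs[p, l])
                a1[i, l], a2[i, l] = grid[draws]
    names = spec.names
    individuals = [f"{names[p]}_{i+1}" for p in range(K) for i in range(sizes[p])]
    species = [names[p] for p in labels]
    loci = [f"L{l+1:03d}" for l in range(L)]
    table = GenotypeTable(individuals, species, loci, a1, a2)
    membership = np.zeros((n, K))
    membership[np.arange(n), labels] = 1.0
    truth = {
        "membership": membership,
        "labels": labels,
        "pop_freqs": pop_freqs,
        "null": null,
        "allele_size_grid": grid,
    }
    return table, truth


def write_fasta(path, records: dict[str, str]) -> None:
    """Write sequences as FASTA (80-column wrapped)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_truth_json(path, truth: dict) -> None:
    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v

    with open(path, "w") as fh:
        json.dump({k: conv(v) for k, v in truth.items()}, fh)
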
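"""Perfect-SSR mining, motif classification and assembly length statistics.

The scanner reports perfect tandem repeats of primitive 2-6 bp motifs, with
the conventional minimum repeat counts {di:6, tri:5, tetra:4, penta:4,
hexa:4}. Coordinates are 1-based inclusive. Motifs are grouped with their
reverse complement ("AG/CT"); rotations ("GA/TC") stay distinct, matching
how SSR surveys usually report motif classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRLocus",
    "SSRSummary",
    "scan_perfect_ssrs",
    "motif_class",
    "classify_structure",
    "summarize_ssrs",
    "ssr_frequency",
    "compute_nx",
    "is_primitive",
    "reverse_complement",
]

DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repeat of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def motif_class(motif: str) -> str:
    """Canonical motif-class label "X/Y", Y = reverse complement of X.

    A motif and its reverse complement share a label (lexicographically
    ordered pair); rotations do not ("AG/CT" != "GA/TC").
    """
    motif = motif.upper()
    if not set(motif) <= _ACGT:
        raise ValueError(f"motif {motif!r} contains non-ACGT symbols")
    rc = reverse_complement(motif)
    a, b = sorted((motif, rc))
    return f"{a}/{b}"


@dataclass
class SSRLocus:
    """One detected repeat locus; start/end are 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    motif: str
    n_repeats: int
    structure: str = "perfect"  # perfect | compound | interrupted

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def motif_class(self) -> str:
        return motif_class(self.motif)


def scan_perfect_ssrs(
    sequence: str,
    min_repeats: Mapping[int, int] | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Greedy left-to-right scan for perfect tandem repeats.

    At each position, motif lengths 2..6 are tried shortest first; the first
    primitive motif whose exact tandem run meets its minimum repeat count is
    reported and scanning resumes after the locus, so output loci never
    overlap. Case-insensitive; runs are broken at non-ACGT symbols.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    if min_repeats:
        thresholds.update(min_repeats)
    s = sequence.upper()
    n = len(s)
    loci: list[SSRLocus] = []
    i = 0
    while i < n:
        hit = None
        for ml in (2, 3, 4, 5, 6):
            if i + ml * thresholds[ml] > n:
                continue
            motif = s[i : i + ml]
            if not set(motif) <= _ACGT or not is_primitive(motif):
                continue
            p = i + ml
            while p < n and s[p] == s[p - ml]:
                p += 1
            reps = (p - i) // ml
            if reps >= thresholds[ml]:
                hit = SSRLocus(seq_id, i + 1, i + ml * reps, motif, reps)
                break
        if hit is not None:
            loci.append(hit)
            i = hit.end  # 1-based end == 0-based index one past the locus
        else:
            i += 1
    return loci


def classify_structure(
    loci: Sequence[SSRLocus],
    compound_gap: int = 10,
    interruption_gap: int = 10,
) -> list[SSRLocus]:
    """Assign perfect / compound / interrupted structure labels.

    Two runs of the same motif class separated by at most ``interruption_gap``
    bases merge into one "interrupted" locus; two adjacent loci of different
    motif classes separated by at most ``compound_gap`` bases are both marked
    "compound" (an already-merged interrupted locus keeps its label).
    Input must be sorted by (seq_id, start).
    """
    keys = [(l.seq_id, l.start) for l in loci]
    if keys != sorted(keys):
        raise ValueError("loci must be sorted by (seq_id, start)")
    out: list[SSRLocus] = []
    cur: SSRLocus | None = None
    for locus in loci:
        nxt = replace(locus)
        if cur is None or cur.seq_id != nxt.seq_id:
            if cur is not None:
                out.append(cur)
            cur = nxt
            continue
        gap = nxt.start - cur.end - 1
        if gap <= interruption_gap and cur.motif_class == nxt.motif_class:
            cur = SSRLocus(
                cur.seq_id, cur.start, nxt.end, cur.motif,
                cur.n_repeats + nxt.n_repeats, "interrupted",
            )
        elif gap <= compound_gap:
            if cur.structure == "perfect":
                cur.structure = "compound"
            nxt.structure = "compound"
            out.append(cur)
            cur = nxt
        else:
            out.append(cur)
            cur = nxt
    if cur is not None:
        out.append(cur)
    return out


def ssr_frequency(total_scanned_bp: int, n_loci: int) -> float:
    """Genome bp per SSR locus (the 'one SSR per X kb' statistic, in bp)."""
    if total_scanned_bp <= 0:
        raise ValueError("total_scanned_bp must be positive")
    if n_loci <= 0:
        raise ValueError("frequency undefined with zero loci")
    return total_scanned_bp / n_loci


@dataclass
class SSRSummary:
    """Motif-length and motif-class composition of a set of SSR loci."""

    total_ssrs: int
    total_scanned_bp: int
    counts_by_motif_length: dict[int, int]
    proportions_by_motif_length: dict[int, float]
    counts_by_motif_class: dict[str, int]
    counts_by_structure: dict[str, int]
    frequency_bp_per_ssr: float | None  # None flags the zero-locus case

    def to_dict(self) -> dict:
        return {
            "total_ssrs": self.total_ssrs,
            "total_scanned_bp": self.total_scanned_bp,
            "counts_by_motif_length": self.counts_by_motif_length,
            "proportions_by_motif_length": self.proportions_by_motif_length,
            "counts_by_motif_class": self.counts_by_motif_class,
            "counts_by_structure": self.counts_by_structure,
            "frequency_bp_per_ssr": self.frequency_bp_per_ssr,
        }


def summarize_ssrs(loci: Sequence[SSRLocus], total_scanned_bp: int) -> SSRSummary:
    if total_scanned_bp <= 0:
        raise ValueError("total_scanned_bp must be positive")
    n = len(loci)
    by_len = Counter(len(l.motif) for l in loci)
    by_class = Counter(l.motif_class for l in loci)
    by_struct = Counter(l.structure for l in loci)
    props = {ml: by_len.get(ml, 0) / n for ml in sorted(by_len)} if n else {}
    freq = ssr_frequency(total_scanned_bp, n) if n else None
    return SSRSummary(
        total_ssrs=n,
        total_scanned_bp=total_scanned_bp,
        counts_by_motif_length=dict(sorted(by_len.items())),
        proportions_by_motif_length=props,
        counts_by_motif_class=dict(sorted(by_class.items())),
        counts_by_structure=dict(sorted(by_struct.items())),
        frequency_bp_per_ssr=freq,
    )


def compute_nx(lengths: Sequence[int], x_percent: float) -> int:
    """Nx assembly statistic: order lengths descending and return the length
    at which the running sum first exceeds x% of the total."""
    if not len(lengths):
        raise ValueError("empty length list")
    if not 0 < x_percent < 100:
        raise ValueError("x_percent must be in (0, 100)")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    threshold = sum(ordered) * x_percent / 100.0
    acc = 0
    for length in ordered:
        acc += length
        if acc > threshold:
            return length
    return ordered[-1]  # unreachable for x < 100; defensive


def write_ssr_tsv(loci: Sequence[SSRLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tmotif\tmotif_class\tn_repeats\tstructure\n")
        for l in loci:
            fh.write(
                f"{l.seq_id}\t{l.start}\t{l.end}\t{l.motif}\t{l.motif_class}"
                f"\t{l.n_repeats}\t{l.structure}\n"
            )
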
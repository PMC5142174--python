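# Methods

## K-mer spectrum survey

`count_kmers` counts canonical k-mers (each window collapsed with its reverse
complement, lexicographic minimum) because shotgun reads sample both strands;
a stranded mode exists behind `canonical=False`. Windows containing non-ACGT
symbols are skipped. Counting is vectorized: bases are 2-bit encoded and
window codes built by shift-or, so k ≤ 31 fits in uint64.

`find_error_cutoff` returns the depth separating the sequencing-error tail
from the signal: the bottom of the initial descent of count-vs-depth, i.e.
the first local minimum reached *from a falling start*. If the histogram
starts rising (no error tail) or never turns, the cutoff is 1. The
restriction to the initial descent matters: a heterozygous spectrum also has
a valley between its half-depth and full-depth peaks, and a bare
first-local-minimum rule would cut at that valley and discard the
heterozygous component whenever the error tail is absent.

`find_peak` is the histogram mode at depths ≥ cutoff, ties to the smaller
depth. `find_main_peak` additionally resolves the half-depth ambiguity: at
high heterozygosity (around h ≳ 0.015 at k = 17) the half-depth component
out-masses the homozygous one and the raw mode lands near coverage/2, so if a
secondary maximum with ≥ 20% of the modal count exists within ±3 of twice the
raw mode, that depth is taken as the coverage peak. `analyze_spectrum` uses
`find_main_peak`.

Genome size is `round(total_kmers / peak_depth)`. By default the total
excludes bins below the error cutoff (the error-free total is what the
formula assumes); the raw total is reported alongside. Because the peak depth
is an integer, the estimate inherits a discretization error of up to about
1/(2·coverage) — at 30× the observed worst case on simulations is ~3.5%,
inside the 5% recovery band the tests enforce.

Heterozygosity: the distinct-k-mer histogram above the cutoff is fit as a
nonnegative least-squares mixture of two Poisson shapes centered at
peak/2 and peak. With m the half-depth mass fraction and
q = 1 − (1 − h)^k the probability that a k-window overlaps a heterozygous
site, an SNV-only diploid gives m = 2q/(1 + q) (each het site makes the k
overlapping windows of *both* haplotypes haplotype-specific, while removing
the shared window), so

    q = m / (2 − m),   h = 1 − (1 − q)^(1/k),

which reduces to the first-order m ≈ 2kh for small kh. A
simulation-matching mode (`method="simulate"`) instead picks h from a grid by
least-squares distance to simulated spectra at the same coverage and k; the
two routes agree within 0.003 on test fixtures. When no half-depth component
is resolvable (mass fraction ~0, or peak depth < 4), the estimate is 0 with
`resolved=False`.

GC-depth profiling tiles sequences into non-overlapping 500 bp windows
(configurable; trailing windows under half size dropped), reporting per
window the GC fraction over non-N bases and the mean occurrence count of its
canonical k-mers, plus a length-weighted mean GC.

## SSR mining

The scanner is greedy left-to-right: at each position, motif lengths 2–6 are
tried shortest-first; the first primitive motif whose exact tandem run meets
its threshold ({2: 6, 3: 5, 4: 4, 5: 4, 6: 4} by default) is emitted and
scanning resumes immediately after it, so reported loci never overlap.
Mononucleotide runs are never reported (their dimer/trimer extensions are
non-primitive). Coordinates are 1-based inclusive; scanning is
case-insensitive and runs break at any non-ACGT symbol. The contract is
pinned by a brute-force oracle (run detection by literal string
multiplication, primitivity by the rotation test) that the test suite holds
the scanner to on random and adversarial inputs.

Motif classes pair a motif with its reverse complement, ordered
lexicographically ("AG/CT"); rotations remain distinct ("GA/TC"), matching
how SSR surveys tabulate motif abundances. Reverse-strand scanning is
unnecessary since classes already collapse strands.

Structure classification merges two runs of the same motif class separated by
≤ 10 bp into one "interrupted" locus, and marks adjacent loci of different
classes within ≤ 10 bp as "compound" (both gaps configurable). A locus
already merged as interrupted keeps that label if a different-class neighbor
follows; everything else is "perfect". The published panels classify loci
into these three categories without stating gap rules, so the 10 bp defaults
are this package's choice.

Nx statistics order lengths descending and return the length at which the
running sum first strictly exceeds x% of the total.

## Diversity statistics

Allele frequencies are plug-in counts over the 2n gene copies of typed
individuals. He is the uncorrected 1 − Σp² (not the 2n/(2n−1) form): the
invariant PIC ≤ He then holds exactly, as it does across the bundled
206-locus reference table, and it matches the default reporting of the tools
such tables come from. PIC is the Botstein form, computed as
1 − Σp² − ((Σp²)² − Σp⁴). Ho counts heterozygous individuals among typed
individuals only. Transferability is the percentage of panel loci with at
least one non-missing call in a species (species-level "NULL" calls mark
non-amplification and are distinct from sporadic missing data). Species
summaries average over loci polymorphic (Na ≥ 2) *within* that species;
monomorphic loci still count toward transferability. Statistics are reported
to 2 decimals, percentages to 1.

## Distances and UPGMA

The default pairwise distance is 1 − mean proportion of shared allele copies
(PSA) per locus, loci missing in either individual pairwise-deleted; the
coefficient behind published SSR dendrograms is rarely stated, and PSA is the
standard codominant choice (a genotype simple-matching variant is available).
UPGMA merges the closest pair at height d/2 with size-weighted average
distance updates; ties break to the smallest (row, col) pair in current
cluster order, so output is deterministic. Trees are ultrametric by
construction and export to Newick with branch lengths; tests verify
equivalence of merge heights with an independent average-linkage reference
and exact round-tripping through a standard Newick parser.

## Admixture model

The Gibbs sampler implements the admixture model with independent allele
frequencies: symmetric Dirichlet priors with λ = 1 on cluster allele
frequencies and fixed α = 1 (configurable) on memberships. Each sweep
resamples allele-copy assignments z, then P | z, then Q | z, fully vectorized
over individuals × loci × copies. Null and missing calls are excluded from
the likelihood and the posterior counts. The per-locus allele space is the
set of alleles observed anywhere in the table.

Model support for a given K is summarized as lnPD = mean(lnL) − var(lnL)/2
over retained sweeps (post-burn-in, thinned by 10). This moment estimator is
exact only for normally distributed lnL; on tiny datasets its skewness bias
is visible (≈ 0.5 log units against the closed-form Dirichlet-multinomial
evidence on a 3-individual, 2-locus toy), which the test tolerance (1.0)
accounts for. Replicate lnPD values per K feed the Evanno statistic
ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)), defined for
interior K; zero replicate sd leaves ΔK undefined there. Cluster labels are
non-identifiable, so replicates are aligned to a reference by Hungarian
assignment on Q-column agreement before any averaging, and accuracy against
simulated truth is measured after the optimal cluster-to-population
relabeling.

Default run lengths in the pipeline (burn-in 300, 1,200 sweeps, 2–3
replicates, K ≤ 4) are desk-scale settings chosen so a full recovery
experiment finishes in seconds at 40 individuals × 100 loci; they are
one-to-two orders of magnitude below the run lengths a production STRUCTURE
analysis would use, which is appropriate here because the synthetic panels
are small and strongly informative (Fst = 0.2), where the chain mixes within
a few hundred sweeps.

## Synthetic data

The genome simulator draws haplotype 1 i.i.d. with P(G or C) = gc_content
(default 0.371, a typical low-GC dicot value) and substitutes haplotype 2 at
Bernoulli(het_rate) positions uniformly among the three alternative bases
(default 0.01, a highly heterozygous outcrossing perennial). It models no
indels, no linkage, no repeat families and no base-composition
autocorrelation, so passing tests demonstrate correctness of the estimators
under the SNV-only model, not robustness to real-genome repeat structure.

Planted SSR tracts overwrite both haplotypes (homozygous), and the flanking
~30 bp are rejection-resampled until a local scan reports exactly the planted
locus at its exact coordinates — planted recall is therefore 100% by
construction, and the interesting measurements are scanner *precision*
against background repeats and coordinate exactness.

The k-mer histogram simulator gives each distinct canonical k-mer with
multiplicity m across the diploid a Poisson(coverage · m/2) depth, and adds
error_rate · k · coverage · length novel singleton k-mers (each sequencing
error creates ~k new k-mers at depth ~1). There is no read structure, no
quality model and no coverage bias; GC-depth profiles from it are flat by
design.

Genotype tables follow a multiallelic Balding–Nichols construction: per-locus
ancestral frequencies are symmetric-Dirichlet over the allele grid (default
16 sizes, 2 bp apart, emulating capillary sizing), population frequencies are
Dirichlet(ancestral · (1 − F)/F), and individuals draw two i.i.d. copies per
locus. F ∈ {0, 1} is rejected as degenerate. Species-level null loci are
drawn per (species, locus) with the configured rate and applied to every
individual of the species, so measured transferability is binomial around
100·(1 − rate)%.

All generators take integer seeds and are bit-reproducible; the pipeline
derives stage seeds by fixed offsets from the run seed.

## Pipeline defaults and problem sizes

The canned recipe simulates a 1 Mb diploid at 30× (k = 17), 50 planted SSRs,
and a six-species panel of 24 + 5×4 = 44 individuals × 60 loci at Fst = 0.2
with per-species null rates (0, .05, .05, .1, .1, .25) that reproduce the
qualitative transferability ladder of real cross-species panels. The
admixture stage runs on the loci amplified in all species, as marker studies
do. Reports are deterministic given the configuration, and every output
names the SHA-256 (first 12 hex digits) of the canonical configuration JSON.

## Known limitations

- The heterozygosity estimator assumes isolated SNVs and a resolvable
  half-depth component; it returns a flagged 0 below coverage ~8 or at h
  small enough that the component drowns in Poisson overlap (< ~0.1% at 30×).
- Genome-size estimates inherit the integer peak-depth discretization
  (~±1/(2·coverage) relative error).
- The scanner reports perfect repeats only; compound/interrupted structure is
  reconstructed afterwards from gap rules, not re-scanned as imperfect
  alignment.
- The admixture model uses independent frequencies and fixed α; correlated
  frequencies, linkage, and α inference are out of scope.
- GC-depth profiling reports the simulator's flat depth unless real depth
  data are supplied; sequencing-bias curves need real reads.
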
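# Methods

This note documents the models, conventions and numerical choices behind
ssrkit, and what its synthetic benchmarks do and do not demonstrate.

## SSR detection model

An SSR locus is a *maximal perfect* tandem run of a *primitive* unit of
1–6 bp (a unit that is not itself a tandem repetition of a shorter
unit). The default minimum full-unit counts are 10 (mono), 6 (di) and 5
(tri–hexa), the customary genome-survey settings. Conventions:

- **Coordinates** are 1-based inclusive in the native table; BED export
  converts to 0-based half-open.
- **Partial units**: a locus covers only complete repeat units, so
  `length_bp = unit_length × n_repeats` holds exactly; a trailing
  partial unit is excluded from the locus but does not block adjacent
  detection.
- **Ambiguity**: N terminates runs (configurable to reject instead);
  lowercase input is upper-cased; any other character is a parse error
  naming its position.
- **Overlap resolution**: within one unit length the scanner reports the
  leftmost of phase-shifted overlapping runs (greedy left-to-right with
  skip, so same-unit-length loci never overlap); across unit lengths a
  locus nested inside another locus's interval is suppressed, with ties
  going to the shorter unit. Primitivity already prevents a run being
  re-reported at a multiple of its true period. Partial boundary
  overlaps between different unit lengths are retained.
- **Canonical motif**: the lexicographic minimum over all cyclic
  rotations of the motif and of its reverse complement. This yields the
  conventional representatives (A/T → A, AG/CT → AG, AAG/CTT → AAG,
  AGAT/ATCT → AGAT). Brute-force enumeration of all 4^k strings gives
  2, 4, 10, 33, 102 and 350 classes for k = 1…6; a finite genome
  typically *observes* only a subset of the penta- and hexanucleotide
  classes.
- **Length classes**: III < 20 nt, II 20–30 nt inclusive, I > 30 nt.
  The inclusive class-II bounds are forced by the strict inequalities
  defining classes I and III.
- **Compound SSRs** (closer than 100 bp) are annotated with a shared
  group id, transitively, but remain individual loci in all counts; an
  `--exclude-compound` flag drops them instead.
- **Window density** assigns each locus to the window containing its
  start; loci are short relative to the 100-kb default window and the
  rule is deterministic, so window counts always sum to the per-
  chromosome locus count.

## Primer screening and e-PCR

Criteria are evaluated on the core primer sequence; an M13 tail is
synthesis metadata and is stripped first. GC is 100·(G+C)/len. The
default melting temperature is nearest-neighbor thermodynamics with the
SantaLucia (1998) unified ΔH/ΔS table, duplex-initiation terms, the
entropic salt correction 0.368·(N−1)·ln[Na⁺] at 50 mM monovalent salt,
250 nM total strand concentration (Ct/4 in the equilibrium factor for
non-self-complementary oligos, Ct with a −1.4 cal/(mol·K) symmetry
correction otherwise). The Wallace 2(A+T)+4(G+C) rule is provided for
hand-checkable arithmetic. The unit tests cross-check the NN
implementation against an independent implementation of the same
parameter table.

e-PCR reports every site where the two primers bind opposite strands in
convergent, non-overlapping orientation within the product window
(default 5 kb). Matching is exact by default; with mismatches allowed,
the three bases at each primer's 3′ terminus must still match exactly
(polymerase extension is 3′-critical). Amplicon spans are outer
primer-to-primer, 1-based inclusive. Zero predicted products → no
marker, one → monomorphic, several → polymorphic.

## Genotype model and statistics

Genotypes are fragment sizes in bp, up to four recorded per individual
and locus (the cohorts this targets are allotetraploid). All
frequency-based statistics use a **diploid view** — the first two
recorded sizes, one size meaning homozygous — because Ho/He/PIC
reporting presupposes diploid scoring; all four sizes are used only by
band-sharing similarity and bin fingerprints. Missing is an empty cell.

With allele frequencies p at one locus (two draws per non-missing
individual): Na = #{p>0}, Ne = 1/Σp², He = 1 − Σp² (Nei gene diversity,
no small-sample correction by default; an unbiased 2n/(2n−1) toggle
exists), Ho = fraction of heterozygous non-missing individuals,
I = −Σp ln p, PIC = 1 − Σp² − (Σp²)² + Σp⁴ (equal to the textbook
double-sum form), PI = 2(Σp²)² − Σp⁴, PIsibs = 1/4 + Σp²/2 + (Σp²)²/2 −
Σp⁴/4. Panel means are unweighted over loci. Cumulative PI products run
over loci sorted ascending by PI (most informative first; configurable).

Band-sharing similarity expands each locus into presence/absence of
every observed fragment size; simple matching counts shared absences,
Dice does not. A missing cell contributes absences — with
simple-matching this counts a shared missing as similarity, which is the
band-reading convention; pairs with heavy missingness should be
interpreted cautiously. Genetic distance is 1 − GS; a shared-allele
distance on the diploid view is also provided.

The Mantel test correlates lower-triangle entries and permutes
individuals of one matrix; p is one-sided upper with the +1 correction,
9999 permutations by default. Geographic distance is haversine km with
Earth radius 6371 km. PCoA Gower-centers −D²/2 and eigendecomposes;
negative eigenvalues (non-Euclidean input) are dropped from both the
axes and the variance denominator, and each axis's sign is fixed by
making its largest-magnitude coordinate positive. Trees: UPGMA is
implemented directly with deterministic lexicographic tie-breaking;
neighbor joining is delegated to scikit-bio with input presented in
lexicographic label order. A maximum-likelihood dendrogram is *not*
offered: there is no reproducible likelihood model for fragment-size
data, so distance trees on 1 − GS or shared-allele distance stand in.

## Admixture EM and Evanno ΔK

The admixture likelihood (individual ancestry vectors q_i on the
K-simplex, cluster allele-frequency profiles f_kl, allele copies
conditionally independent) is maximized by EM: responsibilities
r ∝ q_ik·f_kl,a per allele copy, then closed-form M-steps for Q and F.
The log-likelihood is monotone non-decreasing; convergence is an
improvement below 1e-6 with a 2000-iteration cap; 5 random restarts
(seeds spawned from the user seed) guard local optima. Missing copies
contribute nothing. Bayesian MCMC (STRUCTURE) is deliberately replaced:
the likelihood is the same, EM is deterministic given a seed, and the
whole K-range fits in seconds at cohort scale.

Evanno's table is computed from replicate LnP(K) values: L′(K) on
replicate means, |L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)|/sd(L(K)).
ΔK is undefined at the boundary K values; ties resolve to the smaller K
(parsimony); all-zero ΔK flags no optimum; zero replicate sd is an
error advising more replicates. The LnP score here is a maximized
log-likelihood rather than an MCMC harmonic-mean estimate — Evanno's
construction only needs a consistent per-K score with replicate spread,
and replicates are single EM starts precisely so that spread reflects
local-optimum variability. Externally produced LnP tables (e.g. real
STRUCTURE runs) can be fed to `evanno` via the same CSV shape.

## Fingerprint encodings

*Zygosity*: one digit per locus — 9 missing, 0 heterozygous, 1
homozygous (the traditional gel-reading code). *Bins*: fragment sizes
are grouped in 10-bp increments numbered 1–9 from the locus bin origin;
anything beyond the ninth bin is recorded as 9, missing slots as 0.
The bin origin defaults to the minimum observed size per locus — the
only self-contained choice when a primer's nominal amplification range
is unknown — and can be set explicitly. Each locus contributes exactly
four digits (four possible recorded alleles, ascending, zero-padded),
so codes have fixed, documented width.

Minimal discriminating sets: greedy adds the locus minimizing the
number of still-identical pairs (ties by panel order); exhaustive
breadth-first search over subset sizes guarantees optimality and is
capped at 12 loci (4095 subsets). On every tested instance the
exhaustive subset is no larger than the greedy one, and supersets of a
discriminating set always discriminate.

## Synthetic data: what it does and does not show

The genome generator plants SSRs with known motif, repeat count and
position into i.i.d. background at a chosen GC (default 0.46, grass-
like) and default density 124 loci/Mb with a mono/di/tri-dominated
motif mix and per-type mean repeat counts shaped like a large grass
genome survey; positions are optionally biased toward chromosome ends
(density ∝ 1 + bias·edge-proximity), mirroring the end-of-chromosome
enrichment reported for several plant genomes. Background windows that
happen to contain an above-threshold repeat are redrawn (bounded
rejection loop) so the truth table is exact and planted-genome
precision/recall are both testably 1.0. The background is *not* a
realistic repeat landscape (no transposons, no interrupted or compound
wild-type repeats, no GC isochores), so passing these tests shows
correctness of the scanner's semantics, not performance claims about
real assemblies.

The panel generator draws cluster allele-frequency profiles
Dirichlet(0.5) over a 12-allele ladder (base 100 bp, 2-bp steps),
ancestry Dirichlet(0.2), two allele copies per locus from the mixture,
5 % MCAR missingness, and coordinates at the Q-weighted mix of cluster
centers plus 0.5° noise inside a steppe-like lat/lon box — defaults
sized to a 105-accession, 20-locus, K=4 cohort with weak spatial
signal. It has no mutation process, no linkage and no null alleles;
EM-recovery results on it demonstrate estimator correctness under the
model, not robustness to model violation.

Problem sizes in the test battery (50–100 kb chromosomes, 40 kb e-PCR
genomes, n = 150 EM recovery, 2000-individual frequency-convergence
checks) were chosen as the smallest scales at which each property is
statistically unambiguous under fixed seeds.

## Known limitations

- Only perfect repeats are modeled; imperfect/interrupted SSR detection
  is out of scope.
- e-PCR has no thermodynamic binding model — mismatch counting with an
  exact 3′ seed only; no primer-dimer or secondary-structure screening.
- The EM surrogate gives point estimates, not posterior uncertainty,
  and its LnP(K) values are not comparable in absolute terms to MCMC
  marginal-likelihood estimates.
- Band-sharing similarity treats shared missingness as shared absence
  (simple matching); use Dice when missingness is informative.
- The simple-matching/Dice choice for published similarity values is
  analysis-dependent; both are provided and neither is claimed to
  reproduce any particular published mean.
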
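# Methods

## The copying model and its sparse evaluation

A target haplotype y is modelled as a mosaic of the N reference haplotypes
X under the Li & Stephens hidden Markov model. The transition across the
gap g_j (Morgans) between SNPs j and j+1 keeps the current donor with
probability ρ_j = exp(−λ g_j) and otherwise switches to a uniformly drawn
donor (each donor receiving ρ̃_j = (1 − ρ_j)/N of the switch mass); the
emission is 1 − μ on donors whose allele equals the target's and μ
otherwise. λ, the recombination scaling constant, is proportional to the
effective population size in simple demographies.

**Zero-mutation limit.** With μ → 0, forward probability is exactly zero
on donors that mismatch the target at a SNP, so the recursion only needs
the matched set s_j per SNP:

- forward: f̌*_ij = ρ_{j−1} f̌_{i(j−1)} + ρ̃_{j−1} for i ∈ s_j, F_j = Σ f̌*,
  f̌ = f̌*/F_j;
- backward: b̌*_ij = ρ_j b̌_{i(j+1)} + ρ̃_j c̃_{j+1} for i ∈ s_{j+1} and the
  shared default ρ̃_j c̃_{j+1} otherwise, where c̃_{j+1} is the sum of the
  normalised backward values over s_{j+1}; the normaliser adds
  (N − n_{j+1}) copies of the default.

Normalisers are accumulated as running log-sums. The boundary conventions
are: the prior 1/N is applied at the first SNP (so F_1 = n_1/N), and the
backward vector at the last SNP is the 1-vector, normalised to 1/N with
log-normaliser log N. These conventions were not fixed a priori; they are
pinned by requiring exact agreement with a dense reference implementation
(μ = 1e−9), which the test suite checks to 1e−5 on 16-haplotype × 200-SNP
panels.

**Chunk lengths and counts.** The expected copied length per donor is the
trapezoid of the posterior over the genetic map. Algebraically the printed
log-weight form w_j^l = exp(ΣlogF_{≤j} + ΣlogB_{≥j} − ΣlogF) satisfies
w_j^l · Σ_i f̌_ij b̌_ij = 1 — the weight exactly renormalises the per-SNP
posterior — so the implementation accumulates ½ g_j (P_i(j) + P_i(j+1))
directly, which is equivalent and numerically stabler; the per-donor
lengths consequently sum to the map length G exactly. Expected chunk
counts keep the explicit cross term ρ_j f̌_ij b̌_{i(j+1)} scaled by
exp(logF_{≤j} + logB_{≥j+1} − ΣlogF) on donors matched at j+1. Note that
the uniform-switch transition includes recombination back to the *same*
donor, so even a single-donor chromosome has expected count
1 + Σ_j (1 − ρ_j) > 1 for λ > 0; the count approaches 1 only as λ → 0.

**λ estimation.** With μ = 0 the most probable copying path must stay
inside stored matches, so the Viterbi segment count equals the size of a
minimum cover of the chromosome by match intervals, found by greedy
farthest-reach covering (optimal for interval covering). λ* = N_break / G
averaged over target haplotypes, floored at 1e−6 so that ρ_j < 1 stays
well defined on degenerate single-donor chromosomes.

## Match finding

The PBWT keeps haplotypes sorted by reversed prefix at every SNP with
divergence values (start of the match between sorted neighbours), built in
one O(NK) sweep. Three queries are supported:

- **long matches** — all maximal matches of ≥ L SNPs between two haplotype
  sets, via a merged panel with donor/recipient flags (within-block pair
  reporting at each terminating column);
- **set-maximal matches** — for each haplotype, matches no other haplotype
  exceeds at that locus, via the neighbour-group walk over the sorted
  order. For a separate target panel (the externally-injected match path)
  set-maximality is computed by direct enumeration plus containment
  filtering, which is quadratic but only used at small scale;
- **Q longest matches per SNP** — stage 1 lowers a length threshold from
  L_0 by halving (floored at L_min, default L_0 = 2^⌈log2(K/16)⌉), storing
  matches whose length falls in the current bin and which cover a SNP that
  still has fewer than Q stored matches; stage 2 sorts candidates by
  descending genetic length (ties: SNP length desc, donor asc, start asc —
  the tie order is our choice, made for determinism) and greedily keeps a
  match iff some covered SNP still has fewer than Q kept matches.
  Defaults Q = 10, L_min = 20 SNPs.

SNPs left with no match copy the donors of the nearest covered SNP in
genetic distance (ties to the left). The imputed pseudo-matches span only
the empty run — they do not extend over already-covered SNPs, so
intermediate positions keep their true donor sets — and are flagged so
that diagnostic accounting can exclude them. A fully matchless haplotype
is an error.

## Painting modes and aggregation

- `tvr` target-vs-reference (local ancestry inference); optional
  leave-one-out drops one designated individual per reference population.
- `rvr` reference-vs-reference: each recipient's donor pool excludes their
  own individual and the designated individual of every *other*
  population, which makes reference and target paintings exchangeable.
- `ava` all-vs-all with only the own individual excluded.

The designated left-out individual is the lowest individual index of each
population, for reproducibility. Donor posteriors are summed within donor
populations; per-individual dosage is the mean of the two haplotype
tracks. Match finding runs once on the full panel; per-recipient donor
restrictions filter the match list before the Q-longest selection.

## All-vs-all painter, coancestry and components

The set-maximal painter weights each match covering SNP k by
w = (k − s)(e − k) and normalises over covering matches; when every
covering match starts or ends exactly at k all weights vanish and the
score falls back to uniform over covering donors (the weight formula is
0/0 there). Per-SNP scores are converted to lengths with the
per-chromosome weight G_i/K_i and summed over chromosomes. Haplotype
scores are averaged into individuals (the two recipient haplotype rows
averaged, donor columns summed per individual) so that each individual row
sums to G — we derive the constant from this conservation requirement
rather than adopting any per-haplotype doubling convention. Matches to the
sibling haplotype of the same individual are excluded along with
self-matches. Haplotype components are the leading columns of U√D from the
SVD of log10(A + 1) (no row normalisation), with each column's sign fixed
so its largest-magnitude entry is positive.

## Palette and NNLS

The palette row for population a is the mean copied-length profile of a's
individuals under rvr painting; rows sum to G. Admixture coefficients
solve min ‖Pᵀx − b‖₂ s.t. x ≥ 0 with the standard active-set NNLS
(deterministic for fixed input order); x is reported both raw and
normalised to sum 1 (the normalised form is the interpretable proportion —
normalisation is our choice, the raw vector is kept for diagnostics).

## LDAS and AAS

The LDA and AAS statistics are reconstructions: their defining properties
(range, null behaviour, Gamma-like tail) are satisfied, but the exact
formulas originate in companion work and are re-derived here.

**LDA(j, l)** compares the per-haplotype total-variation distance
d_i = ½ Σ_a |P_{i,a}(j) − P_{i,a}(l)| between the paintings at two SNPs
with its expectation D_null under random pairing of haplotypes:
LDA = (D_null − D_obs)/D_null, and 0 when D_null = 0. D_null is computed
exactly as the mean over all ordered pairs (a U-statistic) via sorted
arrays and prefix sums in O(n log n) — deterministic, and equal in
expectation to the Monte-Carlo permutation estimate (verified within 3
standard errors in the tests). Pairs are only evaluated within the
integration window, as LDA decays to ~0 beyond ~3 cM.

**LDAS(j)** integrates LDA(·, g_j) over [g_j − X, g_j + X] (X = 4 cM
default), treating LDA as piecewise linear between SNPs (the
minimum-mean-square-error interpolant under random SNP placement). Windows
truncated by a chromosome end re-add the mirrored segment ([2g_j, g_j+X]
on the left end, [g_j−X, 2g_j−L] on the right). Upper and lower bounds
replace the interpolant by the max/min step function per inter-SNP
interval; the lower bound additionally assumes zero LDA at the chromosome
ends. Between the outermost window SNP and the window boundary the point
estimate and upper bound extend the boundary SNP's value flat (the paper
behind the statistic leaves this unspecified; the choice keeps
lower ≤ estimate ≤ upper). LDAS_error = upper − lower, standardised by the
cohort's mean LDAS. QC removes SNPs with standardised error ≥ δ (0.3) or
with fewer than θ (10) SNPs in any half-cM distance bin out to 3 cM.
Low-LDAS p-values are lower-tail normal over QC-passing SNPs.

**AAS(j)** is Σ_a z_a(j)² where z standardises the per-SNP mean ancestry
profile against its genome-wide mean and SD per ancestry (ancestries with
SD ≤ 1e−12 are dropped with a warning); p-values come from a
method-of-moments Gamma fit to the genome-wide AAS distribution.
Shared/specific classification across cohorts: a SNP is a candidate when
any cohort reaches the candidate threshold (LDAS 1e−6, AAS 1e−50); shared
when all other cohorts reach the shared threshold (0.05 / 1e−10),
cohort-specific when all others stay above the lenient threshold
(0.1 / 1e−5), otherwise unlabelled.

## Simulator: the stated world

The generator emulates a divergence-then-admixture history without forward
simulation: ancestral allele frequencies (Uniform(0.1, 0.9)) drift into
population frequencies via the Balding–Nichols Beta model at F_st = 0.05
(default); each population's haplotypes are mosaics of a 30-haplotype
founder pool with switch rate 100/Morgan and 0.002 per-SNP copy error
(these three values are our choice of a realistic within-population LD
scale — segments of ~1 cM and founder sharing deep enough for PBWT matches
to exist); admixed targets receive Poisson(t·G) recombination breakpoints
with segment ancestries drawn i.i.d. from the admixture proportions, and
copy fresh (non-panel) haplotypes of the assigned population. Defaults
mirror the benchmarked admixture regime: 20 Mb at 1e−8 Morgans/bp
(G = 0.2 Morgans), 3 populations mixing 20/50/30 thirteen generations ago,
genotype error 0.02%, 4000 SNPs.

Truth is recorded at the breakpoints themselves, so it is exact by
construction; real forward-simulated data define truth against ancestral
lineages and carry incomplete lineage sorting, so accuracies on this
simulator are comparable in regime, not in value. Selection fixtures are
built by post-hoc biasing: within a window around a selected locus the
breakpoint rate is raised (extra generations) and segments containing the
locus are reassigned to the favoured population with a sweep probability —
reproducing the two observable signatures (locally elevated ancestry and
locally shortened ancestry haplotypes) without simulating fitness.

What a green test therefore establishes: algorithmic correctness
(oracle-exactness of matches and HMM quantities, conservation identities),
statistical calibration on the stated world, and qualitative recovery
(admixture proportions, population structure, selection loci). It does not
establish the numeric accuracy values reported for forward-simulated or
biobank data.

## Numerical choices and limitations

- All HMM normalisers in log space; posteriors renormalised per SNP.
- λ floor 1e−6; AAS SD floor 1e−12; painting row-sum tolerance 1e−6 on
  output writing.
- Ties: argmax best-guess goes to the lowest population index; imputation
  ties go to the left SNP; stage-2 match sort ties as above.
- Missing data, unphased genotypes, multiallelic sites and mixed ploidy
  are out of scope; strict input validation is the default.
- The target-vs-reference set-maximal path is quadratic and intended for
  small panels; the all-vs-all PBWT sweep is the scalable path.
- LDAS needs a dense, evenly mapped cohort painting: sparse maps fail QC
  by design rather than returning unstable integrals.
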
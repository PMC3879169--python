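# Methods

This note documents the generative models, estimators and numerical choices
behind `lethalmap`, what the synthetic data do and do not emulate, and the
design decisions taken where the design was genuinely open.

## 1. Cohort simulator (`simpop`)

**Pedigree.** Discrete generations; founders per breed (sires/dams) and a
configurable number of offspring per generation with random within-breed
parent draws. The defaults emulate three Nordic-Red-style populations with
deletion allele frequencies 0.065 / 0.115 / 0.16 (pooled record-weighted
frequency ≈ 0.128, the value used throughout the lethality analysis).
Founder pools are sized so genotyped half-sib families stay at realistic
sizes; very large families would inflate error-driven Mendelian-conflict
bursts beyond what bull cohorts show.

**Haplotypes.** Founder haplotypes are mosaics of a small pool of ancestral
sequences (default 12) with per-interval switch probability
`1 − exp(−1e−7 · bp)` and a 1% miscopy rate. Markers are ascertained the
way array content is: every SNP segregates on 25–75% of the ancestral pool,
so marker MAFs are mostly common. The deletion allele is anchored to one
designated ancestral background in a ±2 Mb window: carrier haplotypes copy
it there, non-carriers enter it only at a small leak rate (0.005). This is
what makes a "tag haplotype" exist for the HMM to find, with LD r² with the
deletion typically 0.85–0.97 — high but imperfect, as in real data.

**Gene drop.** Meioses draw Poisson crossover counts with mean equal to the
map length (1 cM/Mb default), positions uniform; the deletion allele is
inherited with the segment overlapping its midpoint marker. Homozygous
conceptuses die at cohort construction with probability equal to the
terminal lethality (resampled); they are *never* replaced in the
insemination simulator, where failures must be observed.

**Array signals.** LRR is drawn per copy number from N(0, 0.20) (2 copies),
N(−0.66, 0.25) (1) and N(−5.0, 1.0) (0); the one-copy mean/SD place carrier
region means inside the heterozygous-deletion band while leaving
homozygotes unmistakable. Carriers at in-deletion markers are called
homozygous for the intact-chromosome allele — a physical constraint, so
call errors can never produce a heterozygous call there. Call errors
(0.2%) are structured: het↔hom swaps dominate and only 5% of homozygote
errors produce the opposite homozygote, matching the cluster-boundary
nature of real array miscalls (unstructured errors would flood rare-allele
markers with fake homozygotes and parent–offspring conflicts). Missing
rate 1%; zero-copy assays fail to call 95% of the time. Quality scores are
Beta-distributed with slightly weaker clusters at reduced copy number.

**Inseminations.** Cows are synthesised per record set: each cow gets an
MGS from the male pool and a deletion genotype assembled from the MGS
gamete and a maternal-grand-dam gamete at the pooled frequency p, rejected
if homozygous (dams cannot be homozygotes). Conceptus genotype is drawn
from parental gametes; the background failure process uses the cumulative
study-scale rates f = 0.278 / 0.396 / 0.475 / 0.493 at 35 / 56 / 100 / 150
days shifted additively by parity, month-of-insemination and MGS effects
(each SD 0.01 by default), and a homozygous conceptus has failed by day d
with the cumulative schedule δ(d) (default {0.20, 0.40, 0.60, 0.79}, fully
lethal by term), combined as `1 − (1−background)(1−δ)`. Failure coding is
cumulative (non-return): a failure at day d is recorded at all later days.

**Trait proofs.** Polygenic breeding values follow the pedigree
(parent average + Mendelian sampling, σ²_a = 1); the deletion adds −0.5
genetic SD per copy to every fertility trait and +0.5 to milk/fat/protein
(the antagonism that sustains balancing selection). De-regressed proofs add
noise with variance σ²_a(1−r²)/r², reliabilities r² ~ U(0.55, 0.95). The
fertility index is an equally weighted sum of the five interval/insemination
component traits; the national index composition is not public, so equal
weights are a declared default, not an inference.

**What is not emulated:** B-allele frequency and real cluster files, the X
chromosome, selection dynamics across generations (frequencies are set, not
evolved), and the national evaluation system (proofs are simulated
directly). Passing tests therefore validate the statistical machinery under
these idealisations, not array physics or national-evaluation pipelines.

## 2. Array QC and anomaly scan (`arrayqc`)

Exact conditional Hardy–Weinberg test (no mid-p): the heterozygote-count
distribution given allele counts is computed by the stable ratio recurrence
from a central value; the p-value sums probabilities ≤ that of the observed
count (relative tie tolerance 1e−12). Direction compares observed vs
conditional-expected heterozygotes; ties → none. The test agrees with an
integer-arithmetic enumeration oracle to 1e−12 relative error for all
tables with total ≤ 200 (tested exhaustively).

Duo conflicts (child shares no allele with a parent) are the default —
bull cohorts genotype sires; the trio rule is available when both parents
are typed and falls back to the duo rule at markers where one parent is
missing. Filtering order: sample quality → sample call rate → marker call
rate → MAF → conflict cap, with per-rule audit flags; defaults 0.90 / 0.95
/ 0.05 / 0.60 (per call) / 0.65 (sample mean) / 10 conflicts.

The anomaly scan flags maximal runs of ≥ 3 consecutive markers with
excess-homozygosity HWE p < 1e−6 or conflict count > 10, restricted to
markers with MAF ≥ 0.05: rare-allele markers produce exact-test artifacts
from a handful of miscalled homozygotes and are exactly the markers routine
QC would discard anyway. Under null simulations the scan reports no region
in ≥ 95% of replicates.

## 3. Carrier calling and population tests (`cnvcall`)

Hemizygous runs are defined on called markers only (missing calls neither
break nor count), broken by heterozygous calls, require run-mean LRR < −0.3
and ≥ 20 called markers (HD) or 3 (50K); edges are trimmed of clearly
two-copy (LRR > 0) markers so intervals hug the deletion.

The combined-evidence carrier rule is *carrier iff (low-LRR AND
obligate-homozygosity) OR (tag-haplotype AND ≥ 1 other flag)*; low-LRR with
a heterozygous call in the region is contradictory evidence → ambiguous.
All cutoffs are config-exposed; the reference implementation's exact
thresholds are not published, so these are declared defaults. On the default
simulation (p = 0.128, n ≈ 2,000) sensitivity and specificity both
exceed 0.99.

Deletion frequency from live carriers: among live animals a fully lethal
allele is depleted to p/(1+p), so the default estimator corrects the
carrier fraction c back to the gamete pool, p̂ = c/(2−c); the naive c/2 is
available. LD r² is the squared Pearson correlation of dosage vectors
(reducing to D²/(p(1−p)q(1−q)) for phased indicators). Homozygote depletion
is the one-sided binomial tail P(K ≤ k), K ~ Bin(n, q²), with the k = 0
absence case (1−q²)ⁿ.

## 4. Reads and breakpoints (`svreads`)

Coordinate conventions are fixed once: 1-based positions; a deletion is
(last retained proximal base P, length L, microhomology h, insertion s);
the carrier allele is `ref[1..P] + s + ref[P+L+1..]`; **size = number of
reference bases absent from the carrier allele** (unambiguous under
microhomology); microhomology is assigned to the proximal side and defined
as the longest h with `ref[P−h+1..P] == ref[D−h..D−1]` (D = first retained
distal base). The printed flank coordinates and printed size of such events
in the literature can disagree by a few bases under naive subtraction
precisely because conventions differ; this package's convention makes
`build_carrier_allele → call_deletion_sv` a strict round trip, and the
reference generator pins the junction bases so the planted (P, L, h, s) is
the unique canonical representation.

Reads: 91-bp pairs, fragment lengths from a 50/50 two-component mixture
(300 ± 30, 800 ± 80), base error 0.1%, uniform fragment starts sampled per
molecule (allele share ∝ weight × length), so a heterozygous deletion shows
depth ratio 0.5 inside the interval.

Aligner: exact 31-mer seeds at three read offsets on both strands with
full-length verification (≤ 6 mismatches); reads failing every linear
placement are tested for a split alignment anchored by terminal seeds
(17-mer fallback so junction blocks of 15–30 bp anchor), requiring both
blocks ≥ 15 bases and discontiguous placement. This is a minimal tool
valid for the synthetic references used here (no mismatched-seed rescue) —
adequate at 0.1% base error and desk scale, and deliberately not a general
aligner.

Calling: discordant pairs are mate distances above the widest library
component mean + 4 SD; split reads vote on the canonical junction (prefix
maximal extension fixes P; block overlap — the homology expressed in the
read — is assigned to the proximal side; unaligned residue is the
insertion); microhomology is then recomputed from the reference flanks at
the voted junction so it is never double-counted in the size. More than two
well-supported distinct junctions → ambiguous call listing all candidates.
Depth ratio uses read-start counts in 1-kb windows inside vs outside the
called interval.

## 5. Mixed-model association (`assoc`)

Kinship: tabular numerator-relationship recursion (exact for small
pedigrees, path-counting-verified). PCA: top-k eigenvectors of the
allele-frequency-standardised genotype matrix.

GWAS REML: with V = σ²_e(δA + I), a single eigendecomposition of A is
reused across markers; δ is profiled per marker on a log grid with Brent
refinement (tolerance 1e−4 on log δ); the SNP effect is tested with a
t-test (df = n − p). Type-I error at α = 0.05 is within [0.04, 0.06] over
200 null replicates.

Haplotype model REML: V = σ²_e(γ_h DD' + γ_u A + W⁻¹) with de-regression
weights w = r²/(1−r²) (the standard form; the source formulas for weights
are not published, so this is a declared default). The engine works in the
W^½-transformed, kinship-eigenrotated basis and handles the K-column
haplotype design by a Woodbury identity, so each likelihood evaluation is
O(nK) instead of O(n³); Nelder–Mead over the two log ratios (three starts)
with the boundary solution σ²_h = 0 always admitted. The constant Jacobian
of the W^½ transform cancels from all likelihood differences; the engine
is verified against a dense-matrix evaluation oracle on small data to 1e−6.
The LRT is referred to χ²₁ as is conventional for this analysis, although
at a variance boundary this is anti-conservative; the 50:50 mixture null is
available by flag.

Ancestral-haplotype HMM: K states (default 40; use K comfortably above the
expected founder-haplotype diversity), Bernoulli emissions per
state×marker, single per-bp switch rate with uniform jump destination.
Baum–Welch with an exact M-step for the rate on the jump-augmented chain,
so the marginal log-likelihood is non-decreasing (tested); best of
n_starts. Posterior (soft) state dosages are used for association — they
match the random-effect formulation and avoid Viterbi ties; region-averaged
posteriors stabilise tag-state assignment. Pedigree/LD pre-phasing is out
of scope (the simulator supplies phase); a sire–offspring duo-phaser is
provided for real-data entry.

## 6. Lethality analysis (`lethality`)

Closed forms as in the README; the type-IV dam-carrier probability defaults
to the viability-conditioned 0.5/(1−0.5p) because dams cannot be
homozygous — this matches the simulator exactly. The unconditioned 0.5 is a
flag; with the rounded worked-example inputs (2% extra at 35 d) the two
variants give δ̂ = 20.7% and 22.2%, both consistent with the ~20% headline
figure.

Adjusted failure rates: linear (not logistic) mixed model on the 0/1
non-return outcome — failure ~ mating type + parity + month-year +
(1 | MGS) — following the linear specification conventional for these
analyses; the MGS variance ratio is REML-profiled via the grouped Woodbury
identity (fallback fixed ratio 0.05). Adjusted type rates are
population-averaged at the observed covariate mix; the background f_d is
the record-count-weighted mean of adjusted types I and II, and p is the
record-weighted pooled frequency.

Death-fraction CI: BCa percentile cluster bootstrap (B = 200 default) over
MGS families — clustering preserves the within-cow correlation (a cow's
records share her deletion genotype) that a record-level bootstrap misses.
Each bootstrap replicate refits the mixed model exactly from per-cluster
sufficient statistics at the full-data variance ratio; the acceleration
constant comes from the delete-one-family jackknife. In calibration runs
(3×10⁵ records) the estimator is unbiased for the full δ schedule and the
bootstrap SD tracks the replicate-to-replicate SD to within ~10%;
empirical CI coverage is ≈ 90–93%, slightly under nominal, which is the
known first-order behaviour of percentile-type cluster bootstraps for
ratio statistics. δ̂ > 1 is flagged, never silently truncated.

Lethal equivalents: n = X/q² independent recessive lethal loci at frequency
q explain an extra-failure budget X under random mating;
rescaling n₂ = n₁(q₁/q₂)² keeps the homozygous burden constant. Only the
ratio arithmetic is implemented; the budget itself is an externally
supplied premise.

## 7. Pipeline and problem sizes

`run_scenario` chains all stages and writes a manifest (config hash, seed,
version); rerunning a manifest reproduces every numeric output exactly.
The demo scenario uses ~2,700 live animals, 600 50K + 6,000 HD markers on
one 30-Mb chromosome, 10⁵–2×10⁵ insemination records and a 3-Mb sequence
fixture at 20× — sizes chosen so a complete run takes minutes on one core
while every qualitative conclusion of the full-scale analysis is
reproduced. The haplotype scan runs on a window around the candidate
region (the analysis is chromosome-specific by design) with K = 20 to
bound the forward–backward memory.

## 8. Known limitations

* The aligner and SV caller are single-deletion, single-region tools; no
  duplications/inversions, no quality recalibration, no general CNV
  segmentation.
* χ²₁ for the haplotype LRT is anti-conservative at the boundary (observed
  null size ≈ 0.06–0.07 at α = 0.05); use `mixture_null=True` for the
  conservative variant.
* Death-fraction CIs are mildly anti-conservative (see §6).
* Trait proofs ignore genotype-by-environment structure and assume a single
  genetic variance across breeds.
* The simulator's LD architecture (12 ancestral backgrounds) is far simpler
  than real bovine LD; HMM behaviour on real data will need larger K and
  more EM iterations.
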
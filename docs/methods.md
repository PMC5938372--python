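# Methods

This note documents the models implemented in `clonevo`, the choices
made where the underlying procedures were open, what the synthetic
cohort simulator does and does not emulate, and the package's known
limitations.

## Cancer cell fraction and clonality

The clonality model relates the expected VAF of a somatic mutation to
the fraction of cancer cells carrying it:

    v = CNmut · CCF · p / (CNn · (1 − p) + CNt · p)

with purity p ∈ (0, 1], tumor locus copy number CNt (integer, from the
per-region segment calls), CNn = 2 on autosomes, and CNmut ∈ {1..CNt}.
The estimator maximizes the binomial likelihood
Binom(alt_reads; depth, v(CCF, CNmut)) over the CCF grid
{0.01, …, 1.00} × CNmut.  "Best fit" is not further specified by the
procedure this implements, so maximum likelihood was chosen as the
principled, reproducible reading; at high depth it reduces to least
|v_obs − v_expected|.  Exact likelihood ties resolve to the smaller
CNmut, then the smaller CCF (the flattened search is CNmut-major
ascending, so `argmax` lands on the first maximum).

**Identifiability caveat.**  Only the product CNmut·CCF enters the
likelihood, so when sampling noise pushes the observed VAF above the
CNmut = 1 ceiling (implied CCF > 1), the fit lands on the CNmut = 2
branch with roughly halved CCF.  For a truly clonal mutation (CCF = 1)
at 500× this occurs in roughly a third of draws and dominates the mean
absolute CCF error; an exact tie at the ceiling resolves to CNmut = 1,
so the flip never converts a clonal call into a subclonal one.  The
recovery experiment in `experiments.ccf_recovery` (1,000 mutations,
purity uniform on 0.4–0.9, depth 500, diploid loci CNt = 2 / CNmut = 1
as the typical panel locus) stratifies true CCFs evenly over the grid —
the same uniform design with lower Monte-Carlo variance than iid draws.

Thresholds: clonal in a region when CCF > 0.5; present when CCF > 0.1;
tumor-level clonal only when clonal in every QC-passing region, except
INDELs affecting > 6 bp, which are tumor-clonal when present everywhere
(long indels underestimate VAF).  Regions with mean coverage below 100×
fail QC; purity-failure exclusions are an explicit manifest flag rather
than inferred.

Variant filters (applied per tumor before CCF estimation): germline
support ≤ 5 alt reads **and** germline VAF ≤ 1% (the conjunction is the
natural reading of the criterion); both strands supporting; > 5 alt
reads in at least one region; per-region depth within [50, 3000]; a
configurable blacklist for excluded genomic classes (empty for the
synthetic genome).  After estimation, variants that never reach
CCF > 0.5 in any region are dropped.  Adjacent SNV pairs merge into a
DNV when a two-sided two-proportion chi-square test (no continuity
correction — the conventional reading of an unnamed "proportion test",
and checkable against a hand-computed 2×2 statistic) gives p ≥ 0.05 in
every shared region; merged counts are the pair means, rounded half-up
(the merging rule specifies a mean but no rounding).

## Copy-number metrics

Gains and losses are relative to round(ploidy) (half-up; ploidy is the
sample-wide estimate from the manifest).  An arm event requires
strictly > 50% of the arm length aberrant in one direction.  wGII is
the unweighted mean over the 22 autosomes of (aberrant covered bp /
covered bp); "aberrant" means cn_total ≠ round(ploidy), the comparator
consistent with calling events relative to ploidy.  Chromosomes with
zero coverage are excluded from the mean with a warning; sex
chromosomes are parsed but excluded throughout.  Allelic imbalance does
not contribute to wGII (total copy number only).  The per-tumor
convention is the maximum regional wGII.

ITH index = (# subclonal drivers)/(# clonal drivers), counting driver
mutations (14-gene list) and arm-level driver SCNAs together.  With
zero clonal drivers the index is reported as NaN (undefined) rather
than infinity, and summary statistics skip it.

## Allelic imbalance

Arm MAD = mean(|BAF − 0.5|) over heterozygous SNPs (germline BAF in
[0.35, 0.65], called in germline and every region; ≥ 10 SNPs per arm),
germline-corrected by subtracting the germline arm MAD.  Correction is
applied before the ≥ 0.05 region screen (the order is ambiguous in the
source procedure; subtract-then-screen keeps the screen on the same
scale as the calling criteria).  CNAI criteria, in order, on
copy-neutral arms of screened regions: (1) MAD ≥ 0.1; (2) MAD ≥ median
MAD of that sample's gain/loss-event arms and ≥ 0.05 (skipped when the
sample has fewer than two event arms); (3) one rescue pass when an arm
is CNAI in ≥ 2 regions, re-examining remaining regions against the
lowest quartile (linear-interpolated 25th percentile) of each region's
event MADs, floor 0.05.  Clonality categories: *clonal CNAI* (every
region CNAI, no gains/losses on the arm), *clonal loss and CNAI*
(every region loss or CNAI), otherwise subclonal.

MSAI is detected without haplotype phasing: per arm, per-SNP BAF
deviations are oriented by their sign in the most imbalanced region, so
that region scores +mean|dev|; a region whose oriented mean deviation is
≤ −δ (δ = 0.05, configurable) while the reference scores ≥ +δ carries
imbalance of the opposite parental allele.  Same-allele imbalance gives
a positive score and is never called.  This replaces the upstream
ASCAT/Battenberg-phased analysis with an equivalent sign-concordance
argument on the shared het-SNP evidence (germline window 0.3–0.7,
≥ 10 shared SNPs).

## Clone trees

A binary events × regions matrix (mutations present at CCF > 0.1,
SCNAs called in the region) is clustered by identical presence
patterns; a valid cluster needs ≥ 1 non-synonymous mutation or ≥ 2 arm
SCNAs.  Invalid clusters merge into their minimal strict superset
cluster or, failing that, are excluded and flagged.  Ordering is by
strict subset containment of patterns — the pigeonhole argument that a
descendant clone can only be observed inside its ancestor's territory —
with the ubiquitous cluster as MRCA.  This deterministic ordering
replaces probabilistic-causation ordering (TRONCO) as the central
methodological substitution; dense regional sampling is what justifies
it.  Overlapping non-nested sibling patterns cannot arise under a
perfect phylogeny; when noise produces them the cluster still attaches
to its minimal strict superset, and the conflict is recorded with the
Jaccard overlap of the crossing patterns.  If no ubiquitous cluster
exists an empty synthetic root is inserted and flagged.  Trees
serialize to JSON (canonical, lossless) and Newick (events in
comments).

## Cohort statistics

**Parallel evolution.**  Genes with ≥ 10 subclonal mutations
cohort-wide are tested.  The observed statistic is Σ_cases max(0, k−1)
(k = distinct subclonal mutations of the gene in the case); the
alternative statistic #{cases with k ≥ 2} is available via a switch and
coincides with the default at realistic frequencies.  The null draws
k ~ Binomial(n_regions(case), p̂) with p̂ = (cohort subclonal
mutations)/(cohort biopsies); empirical p = (b+1)/(B+1) over B = 1,000
permutations; Benjamini–Hochberg across genes.  **Calibration
caveat:** because p̂ is estimated from the same counts that form the
observed statistic (and Σ max(0, k−1) = Σk − #{k≥1} is nearly a
function of Σk alone), the observed statistic is strongly coupled to
the null's nuisance parameter and the test is markedly conservative —
its measured size at the qualification-threshold frequency (10
mutations per 700 biopsies) is ≈ 0.01 at nominal α = 0.05, and its
power against three cases with two parallel mutations each is ≈ 0.5.
Both operating characteristics are computed by
`experiments.parallel_test_calibration` / `parallel_test_power` (200
cohorts of 100 cases, 7 biopsies each) and reported by the
reproduction script; the null-statistic distribution itself is verified
against a direct convolution oracle.  Conservative size means the
test's discoveries are trustworthy; it does not spend its nominal α.

**Co-occurrence.**  Rows are MRCA clones only (one per case), or MRCA
plus terminal subclones (leaf nodes).  For events A (N_A rows) and B
(N_B rows) among N rows, the co-occurrence count is exactly
hypergeometric; both tails are computed exactly, enrichment is
log2(observed/expected) with expected = N_A·N_B/N (NA when expected is
0, −inf when observed is 0).  BH correction is applied within each mode
(the joint-versus-within choice is ambiguous in the source; within-mode
is the stricter combination given the both-modes rule), and a pair is
significant overall only when significant in the same direction in both
modes.

**Event ordering.**  Root-to-leaf trajectories collect ordered pairs of
core events (VHL, PBRM1, BAP1, SETD2, PI3K-pathway mutations collapsed
to one label, driver SCNAs); pairs are counted once per case, events in
the same clone are unordered, and PI3K↔SCNA pairs are excluded.  Pairs
observed in ≥ 10 cases get a two-sided exact binomial test at null 0.5
via the doubled smaller tail, capped at 1 (the minlike alternative is a
config option), BH-corrected.

## Subtype classification

Seven rules applied hierarchically, first match wins: (1) ≥ 2 clonal
mutational events among BAP1/PBRM1/SETD2/PTEN; (2) a clone with BAP1
and no other core mutational driver besides VHL in that clone; (3–5)
PBRM1 followed by SETD2 / a PI3K-pathway mutation / a driver SCNA,
where "followed by" requires a strict descendant clone (same-clone
co-occurrence does not count, matching the ordering semantics of the
trajectory analysis); (6) no VHL mutation or promoter methylation
(methylation is an input flag); (7) VHL the only core mutational
driver.  No match → unassigned.  Bilateral/multifocal cases are
classified on the index (first) tumor.  A consequence of the stated
precedence, preserved as such: a VHL-wildtype tumor with a lone-BAP1
clone is classified BAP1-driven by rule 2 before rule 6 is reached.

## Sampling adequacy

Saturation: for subset size s of n biopsies, the mean count of events
detected in ≥ 1 chosen biopsy, exhaustive when C(n, s) < 18 million
(strict), else Monte-Carlo over 18 million subsets drawn with possible
repetition (the cap is configurable; tests exercise the Monte-Carlo
path with a small cap).  "Detected" uses the CCF > 0.1 presence rule
for mutations and called-in-region for SCNAs.  The two-biopsy
simulation enumerates all C(n, 2) pairs, counting events absent from
both members (false negatives) and events subclonal in the full set but
present in both members (illusion of clonality), averaged over pairs.

## The simulator

Each tumor is a uniform-attachment random tree of 3–10 clones over 7
regions (both configurable).  Region occupancy is assigned top-down
with **disjoint sibling territories** and a private region for
single-child parents, making presence patterns perfect-phylogeny
compatible and the containment ordering exactly invertible in the
noise-free setting; topologies needing more regions than available are
resampled (bounded), then the clone count is lowered.  Clone CCFs
decrease down the tree (child = parent − U(0.05, 0.25), floored at
0.65) so every clone is confidently detectable and never lost to the
CCF-reachability filter; the root has CCF 1 everywhere, so exactly the
MRCA events are tumor-clonal.  Driver events follow the seven subtype
templates (placed so the classifier must return the generating label);
extra driver SCNAs land in the root so they cannot fabricate a
PBRM1→SCNA ordering.  Every non-root clone carries ≥ 1 passenger
mutation so each clone is marked by a non-synonymous mutation.  Read
counts are Binomial(depth ~ Poisson(500) truncated ≥ 1, expected VAF);
purity is U(0.4, 0.9); SCNAs are painted as whole-arm integer states
(loss 1+0, gain 2+1, copy-neutral LOH 2+0) wherever the carrying clone
is present.  A fraction of tumors (default 0.3) receives one mirrored
copy-neutral-LOH arm: two regions losing opposite parental alleles.
SNP BAFs are binomial around the purity-weighted allelic copy numbers,
with each SNP's alt base on a random, fixed parental haplotype.

What the simulator does **not** emulate — and hence what passing
recovery tests do not demonstrate about real data: sequencing error and
alignment artifacts (absent clones yield exactly zero alt reads);
overdispersed coverage (the Poisson depth has no dispersion knob turned
by default); subclonal copy number within a region; crossing presence
patterns from convergent SCNAs; clones at marginal CCF near the 0.1/0.5
thresholds; germline contamination of somatic calls.  Tree recovery at
100% in the noise-free setting is a property of the disjoint-territory
construction meeting the containment algorithm's assumptions, not
evidence that real tumors satisfy them.

## Numerical choices and problem sizes

Binomial log-likelihoods via `scipy.stats.binom.logpmf`; BH via
`scipy.stats.false_discovery_control`.  Ties, degenerate inputs and
guards: zero-copy mutated loci are flagged inconsistent (CCF NaN);
zero-depth calls are skipped; empty event sets yield a monoclonal
placeholder tree; ITH with zero clonal drivers is NaN; saturation
requires ≥ 1 biopsy, pair downsampling ≥ 2.  All randomness flows
through `numpy` Generators seeded from per-tumor `SeedSequence`
substreams, so a master seed reproduces a cohort byte-identically.
Validation experiments use 1,000 mutations (CCF recovery), 100 tumors
(tree recovery, each condition), 200 tumors (subtype recovery with
noise; 70 noise-free), 100 + 100 arms (MSAI), and 200 cohorts × 1,000
permutations (test calibration and power) — sizes chosen to keep each
experiment within about a minute on one CPU while the binomial
uncertainty on the reported rates stays a few percent.

## Limitations

- The containment ordering cannot separate clones whose presence
  patterns coincide, and resolves crossing patterns heuristically
  (flagged, with Jaccard overlap) rather than probabilistically.
- CCF estimation inherits the CNmut·CCF identifiability limit of the
  VAF model; reported CNmut is a maximum-likelihood convention, not a
  measurement.
- The parallel-evolution test is conservative by construction (plug-in
  null); see above.
- MSAI detection needs ≥ 2 imbalanced regions and ≥ 10 shared
  informative SNPs per arm; single-region parallel SCNAs are invisible
  to it.
- The simulator's clone CCF floor (0.65) deliberately avoids the
  clonal/subclonal boundary; classification robustness near CCF ≈ 0.5
  is characterized only by the dedicated CCF-recovery experiment.
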
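# Methods

`genofirst` implements a genetics-first phenotype predictor: for every
term of a biomedical ontology it asks whether an individual genome is an
extreme outlier in that term's *genetic landscape* relative to a
background cohort, before any phenotype has been observed, and then
confirms the resulting predictions against collected phenotype answers by
permutation.  This note records the model, the conventions chosen where
the design was genuinely open, and what the synthetic test conditions do
and do not establish.

## Functional distance of a missense substitution

Deleteriousness is measured against protein-domain profile HMMs.  For a
variant mapped to match state $s$ of a domain model, the functional
distance is the magnitude of the log-odds of the match-state emission
probabilities of the reference and alternate residues:

$$d = \left| \ln \frac{P_s(\text{ref})}{P_s(\text{alt})} \right|.$$

Conventions: the natural logarithm is used, and the value is taken as an
absolute magnitude, making the distance symmetric in the two residues —
a distance, not a direction.  Emission vectors are pseudocounted on
ingest (floored at $10^{-6}$ and renormalised) so the log-odds is always
finite.  Residues aligned to insertion columns carry no distance: an
insertion state has no comparable emission model.  When several domain
hits cover a residue the highest-scoring hit wins, with ties broken by
model identifier for determinism.

Between two genomes, a site contributes nothing when their genotypes
agree, $d$ when they differ by one allele, and $4d$ when they are
opposite homozygotes.  The baseline factor 1 for heterozygous differences
is the minimal choice consistent with the fourfold rule for opposite
homozygotes.  A missing genotype is treated as homozygous reference and
flagged; missingness therefore never inflates an outlier score.  The
total genetic distance between two genomes for a term is the sum of these
contributions over the term's profile sites.

## Term profiles

A term's profile is the set of catalogued missense variants that fall
inside a domain linked to the term by a flat domain-to-term annotation
table (dcGO-style).  Links are consumed as given — they are not
propagated along the ontology graph at profile-build time — and every
term is processed independently.  Profiles are sorted by variant
identifier, making construction order-independent; an unmapped term
yields a flagged empty profile rather than an error.

## Outlier scores

For one term, all-against-all distances over the cohort (background plus
the batch of subjects, which thereby becomes part of each other's
background) form a distance matrix $D$.  A Gaussian kernel
$S = \exp(-D^2 / 2\sigma^2)$ with the median off-diagonal distance as
bandwidth (falling back to the mean when the median is zero; an all-zero
matrix is degenerate and short-circuits to zero scores) gives a
similarity graph, and the spectrum of its symmetric normalised Laplacian
decides whether the landscape has hidden structure:

- two or more near-zero eigenvalues mean the graph is disconnected; the
  number of components fixes the cluster count $k$ directly (capped at
  `max_k` = 10);
- otherwise the largest gap among the first `max_k` eigenvalues at
  position $k \ge 2$ is the candidate, and structure is declared when
  that gap exceeds `rho` = 3 times the mean of the other gaps.

Cohorts under 6 genomes are never declared structured.  With structure,
K-means (10 restarts, fixed seed; an empty-cluster fit is retried once
with seed + 1) runs on the row-normalised eigenvectors of the smallest
$m$ eigenvalues, $m$ chosen by the elbow (largest second difference) of
the eigenvalue curve and floored at $k$.  Clusters smaller than
`min_cluster_size` = 2 are treated as stray extreme genomes rather than
structure and absorbed into the cluster nearest by mean distance; if
fewer than two adequate clusters remain the term falls back to the
no-structure path.

Without structure, an individual's raw score is its mean distance to
everyone else.  With structure the score is

$$s = \text{local} + \mu \cdot \text{global},$$

where *local* is the mean distance to the individual's cluster
co-members, *global* the mean distance to non-members, and

$$\mu = \frac{e^{\frac{n_{\mathrm{cohort}} - n_{\mathrm{cluster}}}{n_{\mathrm{cohort}}}\gamma} - 1}{e^{\gamma} - 1}$$

down-weights the global term for large clusters ($\gamma = 9$ by default,
a >99% reduction for clusters holding over half the cohort; $\mu$ runs
strictly from 1 for an empty cluster to 0 for the whole cohort).  Local
and global are measured in the original distance space, not the spectral
embedding.  This was a genuinely open choice; the deciding argument is
commensurability: the combinatorial contribution is defined as the excess
of the clustered score over the unclustered mean-distance score, and that
difference is only meaningful when both live in the same units.  The
distance-space definition also reduces exactly to the no-structure score
when the cluster is the whole cohort.  The combinatorial contribution is
clipped at zero and captures precisely the score a genome gains because
clustering exposes an allele that is rare *within its own cluster* while
common overall.

Raw scores are finally mapped to a universal $[0,1]$ scale comparable
across terms:

$$s_{\mathrm{trans}}(p) = \sqrt[3]{\;\frac{e^{-(1 + r_p/N)\varphi}}{e^{-\varphi}}
\cdot \frac{s_p}{\sum_q s_q}
\cdot \frac{s_p - \min s}{\max s - \min s}\;}$$

with $\varphi = 150$.  The rank $r_p$ is 0-based descending (the top raw
score has rank 0 and rank factor exactly 1), ties share the mean of their
rank range, and the rank factor is computed through the algebraically
identical stable form $e^{-\varphi r_p / N}$.  When all raw scores are
equal the min–max factor is defined as 0 — no one is an outlier — and an
all-zero raw vector is flagged degenerate.  The transform is monotone in
the raw score, so rankings are preserved.  Calls are made at a
transformed-score threshold of 0.022.

## Explaining calls

Each above-threshold call is dissected by ablation: the individual's
genotype at selected profile sites is reset to homozygous reference and
the full per-term pipeline re-run.  Only that individual changes, so the
background geometry is untouched.  A carried variant is **required** when
its solo ablation drops the transformed score below the threshold,
**contributing** when ablation lowers the score by more than $10^{-9}$
without killing the call, and **none** otherwise.  The role pattern maps
to the four outlier types: `1-a` (one required variant, nothing else),
`1-b` (one required plus contributing), and for zero or several required
variants, `2-a` when the top variant's solo score drop exceeds the sum of
all other drops, else `2-b`.  Because the transform is scale-free in the
raw scores, an ablation that rescales the whole landscape uniformly can
leave a top score unchanged; roles are therefore defined through the
transformed score, the scale predictions are made on.

Variant frequency classes follow the carrier's zygosity: *rare* is
MAF < 0.5% heterozygous or < 1% homozygous; *low-frequency* MAF < 1%
heterozygous or < 5% homozygous; everything above both bands is *common*.

## Confirmation

Questionnaires mix a participant's top 25 terms with the top 25 of a
decoy genome drawn uniformly from the background, shuffled; a term in
both top lists is asked once, attributed to the participant, and the
decoy side takes its next-ranked term.  Question QC retains terms whose
yes-rate is non-zero and strictly below 5% with at least 20 answers —
a question most people answer yes identifies a common phenotype, not an
outlier.

Three permutation tests, all deterministic given (seed, number of
permutations) and all using the add-one estimator
$p = (1 + b)/(1 + n_{\mathrm{perm}})$ with a z-score against the permuted
mean and standard deviation:

1. **Global**: mean score over yes-answers versus re-allocation of scores
   over all records.
2. **Threshold rate**: the yes-rate among questions at or above the call
   threshold (with the decoy yes-rate as reference) versus re-allocation.
3. **Per-phenotype**: per-term sum of scores on yes-answers with
   within-term permutation; terms are ranked by p-value, scores are
   re-permuted (200 replicates by default) and all term p-values
   recomputed, giving at each rank the mean and standard deviation of the
   number of terms expected by chance; the excess curve is the observed
   rank minus that mean, with a ±SD band.  A term with no positive
   answers gets p = 1 by convention.

For cohorts evaluated against clinical annotations, a predicted term
confirms a call when it closely matches an annotated term: identical, or
in an ancestor/descendant relation with information contents within
`delta_ic` = 1 nat (configurable).  Information content is
$-\ln(\text{count}/\text{total})$ over cumulative annotation counts
propagated up the graph, so it can only grow from parent to child.
Unannotated individuals are never confirmed — the necessary assumption
for a fair automatic evaluation.  The 1-nat default reproduces the
nested-term matching behaviour the close-match construction is meant to
capture; it is a package choice, not an external constant.

## Synthetic worlds

The generator builds every input the pipeline consumes: Dirichlet-drawn
domain HMM emissions (concentration 0.3, peaked enough that some
substitutions are strongly disfavoured), one full-length domain hit per
protein, a random ontology tree with occasional second parents, 1–3
domain links per term, and a variant catalogue with a 50/30/20
rare/low-frequency/common MAF mixture.  Genotypes are independent
Hardy–Weinberg draws per site; the alternate residue is coupled to the
frequency class (common alleles get the most tolerated substitution,
low-frequency ones a moderate ~2-nat substitution, rare ones an arbitrary
one), emulating purifying selection.  Without this coupling, common
high-distance alleles shatter every term's landscape into spurious
genotype clusters that no real cohort would show.

Planted effects are constructed, not sampled: a `single_rare` plant gives
one subject a homozygous genotype at a fresh site on the domain's most
discriminating match state (MAF 0.1%, maximal log-odds); a
`multi_variant` plant gives three heterozygous moderately rare sites; a
`combinatorial` plant builds a subgroup (8% of the cohort by default)
sharing two co-occurring moderate-distance alleles — deliberately off
Hardy–Weinberg, the one place linkage is induced — plus a site whose
alternate allele is carried homozygous by 90% of the cohort outside the
subgroup but absent within it; the planted subject carries the subgroup
genotype and that allele, making it rare relative to its own cluster.
The definer separation is sized ~1.35× the conditional-rarity distance so
the subject still clusters with its subgroup while its within-cluster
rarity dominates the score.  Truth records carry (subject, term, variant
set, kind), sufficient to compute recall without re-reading genotypes.
Answers are simulated at a 0.8% base yes-rate (the measured rate of
self-identifying a random phenotype) and 90% for planted predictions.

The default desk-scale conditions — 500 background genomes, 20 subjects,
200 terms, 50 domains of length 25 with ~6 variants each — run end to end
in minutes on one CPU.  The generator does **not** emulate ancestry
structure, relatedness, linkage disequilibrium beyond the combinatorial
plant, genotyping error, imputation artefacts, or ontology-scale
annotation sparsity.  Passing the planted-recovery and calibration tests
therefore shows the machinery is correct and well-calibrated under the
stated statistical assumptions; it does not show field performance on
real cohorts, where self-report noise, confounding and LD all dilute the
signal.

## Numerical and testing choices

- Distances and scores are plain float64; distance matrices are validated
  symmetric, finite, zero-diagonal.
- Permutation subsets are drawn by arg-partitioning uniform keys and
  sorted within each row so a permutation identical to the observed
  selection reproduces the observed statistic bit-for-bit (exact ties).
- Test problem sizes: brute-force oracles run on cohorts of ≤ 10 genomes
  and ≤ 6 sites (the full $2^6$ ablation lattice is enumerated);
  planted-outlier recovery uses 100 generator seeds at the default
  conditions; permutation calibration uses 200 simulated null datasets at
  2,000 permutations, a Monte-Carlo grain fine enough that the add-one
  estimator's conservatism (≤ 1/2001) is invisible to the
  Kolmogorov–Smirnov check.
- 100,000-iteration permutation runs are supported but not the test
  default; p-values differ from the 2,000-iteration values only within
  Monte-Carlo error.

## Known limitations

Indels and non-coding variants are out of scope (inputs are residue-
mapped missense calls).  The eigendecomposition is dense
($O(n^3)$ per term), fine for cohorts of a few thousand; no sparse or
approximate eigensolver is provided.  The spectral path is deterministic
given the seed but not invariant to background composition — by design:
an outlier is always relative to a chosen background, and batch members
are part of each other's background.
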
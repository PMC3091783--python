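# Methods

## Problem setting

Bacterial genes are transcribed in transcription units (TUs): runs of one
or more adjacent same-strand genes sharing a promoter and terminator. An
operon map is the partition of a genome's gene set into TUs. Predicting the
map reduces to a binary decision per adjacent same-strand gene pair —
co-transcribed (STU) or not (DTU) — since opposite-strand pairs are DTU by
definition. `dister` makes that decision from structural evidence alone:
intergenic distance and predicted Rho-independent terminators. This is a
deliberate design point: classifiers that lean on functional similarity or
cross-genome conservation inherit the gene content of free-living model
organisms and mistype TUs created by genome reduction and rearrangement,
which are precisely the interesting ones in endosymbiont genomes.

## The classifier

**Features.** The intergenic distance d = start(downstream) −
end(upstream) − 1 (negative for overlapping genes) is discretized into
10-bp bins, floor(d/10). A terminator call is credited to a pair when its
interval intersects the open intergenic interval and its strand matches the
upstream gene (a Rho-independent hairpin acts at the 3′ end of the
transcript running into the gap); among several calls the highest
confidence wins. The confidence is kept either as presence/absence or as a
four-level class: absent, low (< 76), mid (76–90), high (> 90). The cut
points follow the predictor convention that ≥ 90 marks a high-confidence
terminator; 76 splits the remaining range so all four levels stay estimable
from a few hundred training pairs. Distance bins outside the trained range
are clamped to the nearest edge bin at prediction time.

**Model configurations.** (1) naive Bayes: P(bin|c) · P(term|c); (2) joint
P(bin, presence|c) — the default, since distance and terminator occurrence
are clearly dependent (a terminator needs intergenic room, see below);
(3) joint P(bin, confidence class|c), which splits the data thinner and
mainly pays off with large training corpora.

**Estimation.** Conditional tables are add-α relative frequencies over the
full grid spanned by the training bins and all terminator levels, α = 1 by
default. Smoothing matters because a model trained on one genome is applied
to another whose pairs occupy cells never seen in training; unsmoothed
tables would yield 0/0 posteriors there. With α → 0 the tables converge to
the empirical frequencies (used by the oracle-equivalence tests).

**Prior.** Under a geometric TU-length model, P(L = n) = p^(n−1)(1 − p),
the mean TU length is m = 1/(1 − p), and p is simultaneously (a) the
continuation probability of a TU and (b) the fraction of adjacent pairs
that are within-TU (each TU of n genes contributes n − 1 internal pairs and
one boundary). The geometric prior mode therefore takes p = (m − 1)/m from
the mean length of the curated training TUs (experimentally evidenced,
leader-peptide operons excluded); the empirical mode uses the STU fraction
of the training pairs, which is the maximum-likelihood estimate of the same
p from pair data. Cross-validation folds re-estimate the prior per fold in
empirical mode; a fixed externally supplied mean is also accepted.

**Labels.** Training labels come from a curated TU table in which each TU
is experimentally or only computationally supported. Precedence per pair:
experimental joint containment (STU, "at least one TU contains the pair" —
overlapping alternative TUs cannot demote an STU) > computational joint
containment (NK, excluded from training: co-transcription is plausible but
unverified, and treating such pairs as DTU would poison the negative class)
> experimental membership separating the genes (DTU) > unlabeled. Pairs
touching leader-peptide operons are dropped from training: attenuation
operons are structurally atypical for genomes that lost attenuation.

**Decision.** STU iff posterior > threshold, ties to DTU. The default
threshold is 0.5; `threshold_scan` evaluates a 0.05-step grid over
[0.05, 1] under resubstitution, stratified 80/20 holdout or leave-one-out,
and `best_threshold` picks the grid point minimizing (1 − Se)² + (1 − Sp)²
(nearest ROC corner), ties toward 0.5 then toward the smaller threshold.
Posteriors are computed once per scheme and thresholded, so sensitivity is
non-increasing and specificity non-decreasing along the grid by
construction. Holdout is stratified by class to protect the rarer label in
small curated sets; a single seeded split is reported rather than an
average over splits.

## Map assembly and statistics

TUs are maximal runs of consecutive same-strand genes whose internal pairs
are all called STU. The chromosome is circular: the wrap-around pair is an
ordinary pair, and an STU call on it merges the first and last runs. On a
non-degenerate assembly #TUs = N − #STU calls; the all-STU circle collapses
to a single TU and is flagged degenerate. Gene order within a TU follows
transcription (reversed chromosomal order on the − strand) and the TU id is
`TU_<first gene>`, making outputs deterministic. Map statistics follow from
counts alone: mean TU length = N/#TUs, mean polycistronic length =
(N − #mono)/#poly. TU-length vectors of two maps are compared with a
two-sided Mann–Whitney rank-sum test; a geometric fit reports
p̂ = (mean − 1)/mean with observed-vs-expected length counts.

## Expression validation

If the map is right, genes in one polycistronic TU ride one mRNA, so a
one-way ANOVA of per-gene log expression with TU membership as the factor
should explain much variance: F = (SSB/(g − 1))/(SSW/(n − g)),
R²adj = 1 − (1 − R²)(n − 1)/(n − g). Monocistronic TUs are excluded
(singleton groups inflate the factor without information). One scalar per
gene is expected (replicates pre-averaged); stacking conditions as
replicates is possible but not the default.

Raw significance would be misleading: neighboring genes co-vary for reasons
other than co-transcription. The null therefore preserves proximity — the
multiset of polycistronic TU lengths is permuted and re-laid as contiguous
blocks over the chromosome-ordered polycistronic gene list, so simulated
co-members are still neighbors; only the TU *borders* move. The p-value is
the fraction of simulated F strictly exceeding the observed F (ties do not
count; zero exceedances are displayed as "< 1/n_perm" while the raw 0 is
kept in JSON). The observed F is computed through the same summation path
as the simulated ones so that an identical relayout ties exactly rather
than differing in the last float bits. A `free_relabel` mode (genes
permuted freely among size-conserved groups) is provided for comparison;
the default operates on the polycistronic subset only, matching the ANOVA's
gene universe. Default n_perm = 10,000; tests use 1,000.

## Comparative TU evolution

Orthology is bidirectional best hit (appropriate when the studied lineage
has no duplications), score ties broken lexicographically and reported.
Each TU of genome A with ≥ 1 ortholog-bearing gene gets exactly one of five
types against the reference map (nested alternative reference TUs are
collapsed to maximal ones first): one reference TU matched exactly →
*identical*; one reference TU with extra genes, none relocated → *similar*
(gene loss/gain); any extra relocated into another A TU → *split*; several
reference TUs with no leftover ortholog elsewhere in A → *merged*; with a
leftover ortholog elsewhere → *reorganized*. Mixed leftovers resolve toward
split/reorganized when any relocation exists. Reference genes whose
orthology is intrinsically ambiguous (structural RNAs) are reported in the
call's evidence but never decide it.

A pair of adjacent A genes is *ancestral* when its orthologues are adjacent
in the reference or, failing that, in any supplied outgroup; relative
strand is ignored (strict synteny — conserved order and orientation — is a
separate flag). Maximal runs of ancestral pairs form fragments; a fragment
of k pairs spans k + 1 genes, except the degenerate full-circle fragment.
Coding-length changes are polarized with an outgroup into six classes by
comparing |L_out − L_A| with |L_ref − L_out| and the sign of L_ref − L_A,
following the published inequalities verbatim; a missing outgroup length
yields an explicit unclassified sentinel. Reference genes absent from A are
attributed: present in any ancestral reconstruction or outgroup → lost in
the A lineage; absent everywhere else → acquired in the reference lineage;
otherwise ambiguous. A generic 2×2 chi-square utility (Yates-corrected)
serves contingency questions such as regulation-versus-conservation.

## Synthetic data

The generator emulates the inputs the pipeline consumes, with ground truth
attached, and is a pure function of (config, seed).

* TU lengths are geometric(p_stu), p_stu = 0.53 by default (mean ≈ 2.13
  genes, the compact reduced-genome regime), truncated at the chromosome
  end so the partition property holds exactly.
* Each TU gets one strand; consecutive TUs switch with probability 0.5.
  Consequently the STU fraction among *all* adjacent pairs is p_stu, while
  the same-strand-conditional prior is p/(p + (1 − p)/2) ≈ 0.69 — the
  quantity a classifier of same-strand pairs actually faces, and the prior
  used by the analytic oracle.
* Within-TU distances are drawn from a distribution concentrated on bins
  −2..3 peaked at 0–1 (the compact-operon peak between −20 and +39 bp);
  between-TU distances decay exponentially over bins 0..30. Both are config
  data, not code constants, so tests can probe edge regimes.
* Terminators sit at TU 3′ ends: a boundary gap receives the upstream TU's
  terminator when that TU runs on + and/or the downstream TU's when it runs
  on −, each with probability 0.6; a within-TU gap carries a readthrough
  terminator with probability 0.05. A hairpin needs intergenic sequence, so
  placement requires distance ≥ 1; the truth joint therefore carries a
  feasibility factor P(d ≥ 1 | bin) (0 below bin 0, 9/10 at bin 0, 1
  above), which the analytic oracle enumerates exactly. A consequence
  matching real annotation: divergent gaps never contain a strand-matched
  terminator, convergent gaps may contain two.
* Expression is exchangeable within TUs: x = baseline + sd·(√ρ·z_TU +
  √(1 − ρ)·ε), so the within-TU correlation is exactly ρ and ρ = 0 gives
  i.i.d. noise — a true null for permutation-test calibration.
* `bayes_optimal_rates` enumerates every (bin, terminator-state) cell of
  the generating mixture — no sampling — and returns the exact Se/Sp/
  accuracy of the true-posterior classifier at a threshold.

What the generator does **not** emulate: nucleotide sequence and AT bias,
pseudogenes, overlapping alternative TUs, expression normalization
artifacts, condition-dependent regulation. Tests passing on synthetic data
therefore validate the machinery (estimation, assembly, calibration), not
the biological error rate on any real genome, which depends on how well the
two structural features separate classes there.

## Numerical choices and problem sizes

* Coordinates are 1-based inclusive throughout; GFF3 and GenBank both map
  onto this convention without off-by-one surface.
* Conditional tables must sum to 1 within 1e-9 at validation; oracle
  equivalence is asserted at 1e-12.
* Perfect ANOVA separation (SSW = 0 with spread) reports F = ∞ rather than
  an error; an all-constant vector reports F = 0.
* The posterior falls back to the prior when both class likelihoods are
  exactly zero (possible only at α = 0 on unseen cells).
* Default study sizes: classifier recovery and end-to-end assembly at
  5,000 genes; geometric-length convergence at 20,000; permutation
  calibration as 400 replicate experiments of 1,000 permutations on a
  200-gene genome. These sizes put Monte-Carlo error well inside the
  asserted tolerances while keeping the whole suite fast.
* The 3-standard-error comparisons against the analytic oracle are made for
  fixed decision rules (the true-posterior classifier, or accuracy of the
  fitted pipeline). Sensitivity/specificity of a *fitted* rule is not
  binomially distributed around the Bayes rates when feature cells lie near
  the decision boundary — the fitted rule flips whole cells — whereas
  accuracy is insensitive to such flips because boundary cells contribute
  nearly equal class-weighted mass by definition.

## Known limitations

* The classifier sees only distance and terminator evidence; promoters,
  codon usage and conservation are out of scope by design.
* TU typing assumes a one-to-one orthology (no duplications in the studied
  lineage); genomes with paralogs need a different orthology layer.
* The permutation null preserves block contiguity but not intergenic
  distances; a null that also conditioned on distances would be stricter.
* Leave-one-out refits the model N times; for corpora beyond ~10⁴ pairs use
  holdout instead.
* The GFF3 reader handles the flat 9-column feature format (CDS and RNA
  features, ID/locus_tag attributes); it does not resolve multi-level
  gene→mRNA→CDS hierarchies.
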
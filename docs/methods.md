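# Methods

## Model and assumptions

`repliqc` treats replicate genotype discordance as a proxy for genotype
error. The cohort is a multi-sample diploid VCF in which a small number of
subjects were sequenced twice; for each variant site and each replicate
pair, the pair of genotypes is

- **not evaluated** when either member is missing (or masked by a
  genotype-level filter) or when both are homozygous reference — the
  concordance of two all-reference calls carries no information about
  alternate-allele accuracy;
- **concordant** when the unordered allele multisets are equal (phase and
  allele order are ignored: independent sequencing runs cannot share
  phase);
- **discordant** otherwise.

A site is labelled *discordant* when at least one pair disagrees,
*concordant* when at least one pair is evaluated and none disagree, and
*uninformative* otherwise. Summaries count **pair-observations** (one per
evaluated pair per site); site-level claims count labelled sites. Every
report names its unit, because the two denominators differ.

Key assumptions: all records are treated as diploid (no sex-chromosome
ploidy handling); replicate discordance is symmetric (no member of a pair
is privileged as truth); missingness is excluded from both the numerator
and denominator of concordance rather than counted as disagreement, so the
missingness and accuracy filter axes stay independent.

## Threshold estimation

For a site annotation with removal rule `value < t` (total DP, VQSLOD) the
search grid spans `(min, max]` of the pooled values in steps of
`grid_step`; a threshold above every observed value is deliberately not a
candidate, so a required discordant-removal fraction can be genuinely
infeasible rather than trivially satisfied by removing everything. For
each candidate the discordant and concordant removed fractions D(t), C(t)
are computed from the site-level labels, and the selected threshold
maximizes D(t)/C(t) subject to D(t) ≥ `d_min`. Tie-breaks: a zero
concordant-removal denominator counts as +∞ and is preferred, tie-broken
by larger D; otherwise smaller C, then smaller t. The constraint
(`d_min` = 0.5 by default) formalizes the trade-off between a high removal
ratio and broad coverage of discordances — an extreme cut can achieve an
enormous ratio while removing almost no discordances.

The MQ filter is a two-sided window `[lo, hi]` centred on the mode of the
concordant density (median when the concordant values are degenerate), so
the window always contains the bulk of concordant sites; the same
objective, constraint and tie-breaks apply, with ties resolved toward the
*widest* window (the maximal pass interval) and then the lower one. VQSLOD
estimation uses SNV-only sites, because the VQSLOD filter is applied only
to sites whose alternate alleles are all SNVs.

Density curves use a Gaussian kernel (scipy `gaussian_kde`) with
Silverman's-rule bandwidth on a 512-point grid spanning
`[min − 3h, max + 3h]`. `valley_threshold` — the no-replicates fallback
for VQSLOD — finds the two highest density modes (ignoring local maxima
below 5% of the global peak, which are smoothing ripple) and returns the
grid point of minimum density strictly between them; unimodal input is an
error, not a silent cut.

Grid steps default to 0.01 for VQSLOD and MQ. The DP step is auto-scaled
to the observed range (range/400) because DP scales with cohort size times
depth: a fixed step suited to a 259-sample cohort (where thresholds are
round numbers like 25,000) would leave a desk-scale cohort with a single
candidate.

## The nine filters

| level    | parameter                   | default  | removal rule        |
|----------|-----------------------------|----------|---------------------|
| variant  | missingness (pre-masking)   | 0.05     | fraction ≥ cutoff   |
| variant  | blacklist/LCR intervals     | —        | any ref-base overlap|
| variant  | total DP (reads)            | 25,000   | value < cutoff      |
| variant  | MQ window                   | 58.75–61.25 | outside window   |
| variant  | VQSLOD (all-SNV sites)      | 7.81     | value < cutoff      |
| variant  | inbreeding coefficient      | −0.8     | value < cutoff      |
| genotype | DP (reads)                  | 10       | value < cutoff      |
| genotype | GQ (Phred)                  | 20       | value < cutoff      |
| sample   | missingness (post-masking)  | 0.10     | fraction ≥ cutoff   |

Boundary semantics are deliberate and tested: annotation filters use
strict inequality (a value equal to the threshold passes), missingness
filters remove at their boundary. The six variant filters are pure
per-site predicates, so their order affects per-stage accounting only,
never the final retained set; two reference orders are provided
(inbreeding-before-VQSLOD, the default, and VQSLOD-before-inbreeding).
Genotype masking always precedes the sample-missingness stage, since
sample missingness is defined over post-masking genotypes. Masked
genotypes keep their original call for audit but behave as missing in
every downstream count. Sites that become monomorphic after masking are
retained (nothing is re-checked after masking).

Degenerate-input policy: an absent site annotation (e.g. no
InbreedingCoeff INFO key) passes the corresponding filter with a logged
warning — failing whole cohorts silently on a missing key is worse than an
audited pass; `strict=True` flips this to removal. An absent genotype
FORMAT key likewise passes. Variant missingness uses pre-masking
genotypes (its stage precedes the genotype filters). Interval overlap
converts coordinates exactly once: VCF sites are 1-based inclusive over
`pos … pos + len(ref) − 1`, BED intervals 0-based half-open; chromosome
labels are normalized by stripping a leading `chr`.

Triallelic sites are retained as whole sites. Splitting into per-allele
rows happens only for CPRA matching against ClinVar-style tables; no
left-alignment or re-normalization is applied, since re-normalizing would
change the CPRA identifiers being matched. Concordance at a triallelic
site is evaluated on the joint (un-split) genotype. Sites with three or
more alternate alleles are excluded whole during pre-QC.

## Efficacy metrics

Discordances are the condition to remove: a removed discordant
pair-observation is a true negative (tn), a removed concordant one a false
negative (fn). NPV = tn/(tn+fn) measures how enriched a filter's discards
are in discordances; specificity = tn/(tn+fp) measures how much of all
discordance the filter captures. Filters are ranked by the ratio of
discordant to concordant removal rates (equivalently `(1 − p)/p` on the
removed set); an infinite key (discordances removed, zero concordances
removed) ranks first, a filter that removes nothing has an undefined key
and ranks last, and ties break by higher specificity then filter id.
Undefined metrics render as an em dash, never as zero.

Ti/Tv counts transitions (A↔G, C↔T) per SNV alternate allele, so an
SNV-SNV triallelic site contributes two alleles; a per-site alternative
(a site counts once, toward transitions if it contains at least one) is
available behind `unit="sites"` because allele- and site-level conventions
both appear in practice. MAF is the second-largest allele frequency over
called alleles (bounded by 0.5 at any site), computed on pre-QC genotypes
so rare/common strata stay fixed across stages (rare ≤ 1%, common ≥ 5%).
Removal-rate comparisons between two strata use Fisher's exact test
(two-sided, scipy); comparisons across more than two strata (e.g. ClinVar
review-star levels) use a seeded Monte-Carlo exact test on the r×2 table,
drawing tables from the multivariate hypergeometric distribution with all
margins fixed (default 100,000 draws, `(1 + #{P ≤ P_obs})/(1 + B)`).

## Synthetic cohorts

The generator emulates the structural features the pipeline consumes, at
desk scale:

- 24 sample columns, of which 4 subjects appear twice (base + replicate
  column), against the source cohort's 259 samples with 8 replicate pairs;
- mean genotype depth 30× (Poisson), GQ coupled to depth with a heavy left
  tail at low DP; site DP ≈ n_samples × 30;
- per-site discordance probability 0.02 by default: a flagged site has one
  replicate copy's genotype perturbed (hom-ref→het, het→either homozygote,
  or an allele flip at triallelic sites), and every perturbation is
  recorded in a truth table;
- label-conditioned annotations: VQSLOD is a two-Gaussian mixture (peaks
  −4 and 12) with the lower component at weight 0.10 for concordant and
  0.75 for discordant sites — bimodal for both labels, lower peak enriched
  under discordance; MQ is Normal(60, 0.4) for concordant and
  Normal(60, 2.0) for discordant sites; discordant-site DP is shifted
  −15%, mirroring the fact that a DP threshold is derivable from
  label-separated densities at all. `label_informative_annotations=False`
  decouples all annotations from the labels, for use with
  `inject_annotation_shift`, which shifts flagged-site annotations by
  stated effect sizes;
- site mix 80% biallelic SNV / 10% biallelic indel / 10% triallelic
  (subtypes 40/35/15/10% SNV-SNV / SNV-indel / indel-indel / other-indel);
  allele frequencies from a 60/40 mixture of Beta(0.5, 40) (rare) and
  Beta(2, 5) (common, capped at 0.5); 2% genotype missingness; 3% non-PASS
  tranche records; 1% contamination sites with forced excess
  heterozygosity to exercise the inbreeding filter, whose coefficient is
  computed from the emitted genotype counts (1 − obs-het/exp-het, clipped
  to [−1, 1]).

The output is byte-deterministic under the seed. What it does **not**
emulate: read-level error processes, linkage disequilibrium, a reference
genome, realistic allele-frequency spectra, or batch-specific error
structure. Passing tests therefore demonstrate that the estimator recovers
thresholds and that filtering improves concordance *when discordance is
annotation-separable in the stated way* — they do not certify performance
on any real cohort, where separability must be inspected (the density
panels exist for exactly that).

Test and acceptance problem sizes were chosen to keep full runs fast:
the reference fixture uses 2,000 sites × 20 samples (4 pairs, q = 0.05);
the 100-seed recovery and end-to-end suites use 1,200 sites × 16 samples.

## Numerical choices

- Constraint comparisons use a 1e-12 tolerance so exact-boundary fractions
  (e.g. 13/259 vs 0.05) behave as printed arithmetic suggests.
- INFO floats are stored by htslib as float32; the reader recovers the
  originally written decimal via a 7-significant-digit round-trip, so
  write→read preserves annotations exactly.
- Report precisions: % pass to 2 decimals, concordance to 3, Ti/Tv to 5,
  with banker's rounding (Python float formatting) for deterministic
  cross-platform output.
- `eq1_ratio(0)` returns `math.inf` (an explicit infinite-ratio signal);
  fractions outside [0, 1] are contract errors.
- The sample-missingness stage is skipped (removing no samples) when zero
  sites survive the variant level — there is no missingness evidence to
  act on; `sample_missingness` itself still treats zero sites as a
  contract error.

## Known limitations

- No allele left-alignment/normalization or liftover: CPRA matching is
  verbatim, so indels normalized differently from the reference table will
  not match.
- No genotype refinement, Mendelian checks, imputation, or re-genotyping;
  masked genotypes stay masked.
- Site annotations are taken at face value from the caller; the pipeline
  does not recompute MQ/VQSLOD/InbreedingCoeff from reads or genotypes.
- The Monte-Carlo exact test's resolution is bounded by 1/(draws + 1).
- Threshold estimation is only as good as the labels: with few replicate
  pairs or rare-dominated cohorts many sites are uninformative, and with
  label-uninformative annotations the ratio objective has no meaningful
  optimum (see the density panels before trusting an estimated cut).
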
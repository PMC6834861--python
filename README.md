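# repliqc

Replicate-discordance-driven hard-filter quality control for multi-sample
whole-genome-sequencing variant callsets.

## The problem

GATK best-practice variant calling (VQSR) leaves substantial numbers of
genotype errors in WGS callsets. When a few samples in a cohort have been
sequenced twice, disagreement between their replicate genotypes — *non-
reference discordance* — is a direct, genome-wide proxy for call accuracy:
a pair of replicate genotypes is evaluated when both are called and at
least one carries an alternate allele, and it is discordant when their
unordered allele sets differ.

`repliqc` uses these discordance labels to (1) derive dataset-specific hard
thresholds for the site annotations VQSLOD, MQ and total DP by contrasting
the density curves of discordant versus concordant sites, (2) apply a
nine-filter QC pipeline at the variant, genotype and sample levels, and
(3) quantify the efficacy of every filter.

## The method

**Threshold search.** For an annotation x with removal rule `x < t`
(or a two-sided window for MQ), the threshold is chosen on a grid to
maximize

    objective(t) = D(t) / C(t)        subject to  D(t) ≥ d_min

where D(t) and C(t) are the fractions of discordant and concordant sites
removed and `d_min` (default 0.5) enforces broad coverage of discordances.
Filter efficacy is ranked by the ratio of discordant to concordant removal
rates — equivalently by `(1 − p)/p`, where p is the discordant fraction of
the removed genotype pairs. When no replicates exist, the bimodality of
VQSLOD offers a fallback: `valley_threshold` cuts at the density minimum
between the two modes, removing the lower (error-enriched) peak.

**The nine filters** (defaults for a ~260-sample 30× cohort; DP/MQ/VQSLOD
are re-estimated per dataset):

| level    | filter                      | removal criterion          |
|----------|-----------------------------|----------------------------|
| variant  | missingness                 | ≥ 5%                       |
| variant  | blacklist / LCR interval    | any reference-base overlap |
| variant  | total DP                    | < 25,000                   |
| variant  | MQ window                   | < 58.75 or > 61.25         |
| variant  | VQSLOD (SNV sites only)     | < 7.81                     |
| variant  | inbreeding coefficient      | < −0.8                     |
| genotype | genotype DP                 | < 10                       |
| genotype | genotype GQ                 | < 20                       |
| sample   | missingness (post-masking)  | ≥ 10%                      |

Annotation filters remove on strict inequality (boundary values pass);
missingness filters remove at their boundary. Variant filters are pure
per-site predicates, so any order yields the same final set; genotype
masking always precedes the sample-missingness stage. Triallelic sites are
kept as first-class citizens: they are split into per-allele rows for
ClinVar CPRA (`chrom.pos.ref.alt`) matching, subtyped (SNV-SNV, SNV-indel,
indel-indel, other-indel), and the VQSLOD filter applies only to all-SNV
sites. Ti/Tv and the concordance rate are tracked at every stage.

## Worked example

```sh
repliqc simulate --seed 3 --out cohort/
repliqc thresholds --vcf cohort/cohort.vcf --samples cohort/samples.tsv --out thr/
# -> site_dp_min=616.025 mq=[58.8834,61.4334] vqslod_min=0.5631
repliqc run --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --blacklist cohort/blacklist.bed --lcr cohort/lcr.bed \
    --thresholds thr/thresholds.yaml --out run/
# -> final sites=775 concordance=99.815%
repliqc report --rundir run/
```

The simulated cohort has 24 sample columns of which 4 subjects are present
twice; `thresholds` labels each site by its replicate pairs and prints the
estimated cuts (the synthetic cohort is small, so its total-DP scale —
samples × 30× depth — is far below a real cohort's 25,000). `run` applies
all nine filters and writes `filtered.vcf` (with provenance header lines),
`stage_table.tsv` (per-stage counts, % pass, concordance, Ti/Tv),
`concordance_trajectory.tsv`, `titv.tsv`, `ranking.tsv` (per-filter NPV,
specificity and % discordant removed), `thresholds.yaml` and a
`manifest.yaml` that reproduces the run bit-identically.

The same workflow is available as a library:

```python
from repliqc import SimulationParams, generate_cohort, estimate_thresholds, run_sequential

dataset, truth = generate_cohort(SimulationParams(seed=3))
thresholds, searches = estimate_thresholds(dataset, d_min=0.5)
trace, qc_dataset = run_sequential(dataset, thresholds)
```

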
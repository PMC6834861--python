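"""Truth-labelled synthetic WGS cohorts with replicate pairs.

The generator emulates the structure the QC engine consumes: a multi-sample
VCF whose first ``n_replicate_pairs`` subjects are present twice (a base
column and a replicate column), GATK-style site annotations (bimodal
VQSLOD, MQ clustered near 60, site DP proportional to sample count x mean
depth, an inbreeding coefficient computed from the emitted genotype
counts), and per-genotype DP/GQ with GQ coupled to depth. Discordance is
injected per site with probability ``discordance_prob`` by perturbing one
replicate copy's genotype; every injection is recorded in a truth table so
estimator and pipeline behaviour can be checked against known labels.

It does not simulate reads, linkage disequilibrium, or a reference genome:
positions and alleles are synthetic tokens with the right formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .replicate_concordance import ReplicateMap
from .variant_model import CohortDataset, VariantSite, write_vcf

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationParams:
    """Generator configuration; the seed fully determines the output.

    Defaults mirror a 30x WGS cohort with a small replicate subset at desk
    scale: 24 sample columns of which 4 subjects appear twice, a ~2% per-site
    discordance rate, a rare-heavy allele-frequency law, and
    label-conditioned VQSLOD/MQ (lower VQSLOD peak and inflated MQ variance
    enriched under discordance). Set ``label_informative_annotations=False``
    to decouple annotations from discordance labels (the
    :func:`inject_annotation_shift` workflow).
    """

    n_sites: int = 2000
    n_samples: int = 24
    n_replicate_pairs: int = 4
    mean_depth: float = 30.0
    discordance_prob: float = 0.02
    missingness_rate: float = 0.02
    tranche_fraction: float = 0.03
    # site-type mix
    p_biallelic_snv: float = 0.80
    p_biallelic_indel: float = 0.10
    p_triallelic: float = 0.10
    triallelic_subtype_probs: tuple[float, float, float, float] = (0.40, 0.35, 0.15, 0.10)
    # allele-frequency law: mixture of a rare and a common Beta component
    rare_weight: float = 0.60
    rare_beta: tuple[float, float] = (0.5, 40.0)
    common_beta: tuple[float, float] = (2.0, 5.0)
    # annotation model
    label_informative_annotations: bool = True
    vqslod_means: tuple[float, float] = (-4.0, 12.0)  # (lower, upper) peaks
    vqslod_sds: tuple[float, float] = (2.0, 2.5)
    vqslod_upper_weight_concordant: float = 0.90
    vqslod_upper_weight_discordant: float = 0.25
    mq_mean: float = 60.0
    mq_sd_concordant: float = 0.40
    mq_sd_discordant: float = 2.00
    site_dp_cv: float = 0.10
    # relative site-DP mean shift for discordant sites (label-informative mode)
    dp_shift_discordant: float = -0.15
    contamination_rate: float = 0.01  # excess-heterozygosity sites
    clinvar_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        for name in (
            "discordance_prob",
            "missingness_rate",
            "tranche_fraction",
            "rare_weight",
            "contamination_rate",
            "clinvar_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicate_pairs > self.n_samples // 2:
            raise ContractError(
                f"{self.n_replicate_pairs} replicate pairs exceed half of "
                f"{self.n_samples} sample columns"
            )


def _site_alleles(kind: str, subtype: int, rng) -> tuple[str, tuple[str, ...]]:
    ref_base = str(rng.choice(_BASES))
    others = [b for b in _BASES if b != ref_base]

    def snv():
        return str(rng.choice(others))

    def indel(ref):
        # insertion or deletion relative to the given ref
        if rng.random() < 0.5:
            return ref + str(rng.choice(_BASES)) * int(rng.integers(1, 4))
        return None  # deletion: handled by extending ref

    if kind == "bi_snv":
        return ref_base, (snv(),)
    if kind == "bi_indel":
        if rng.random() < 0.5:
            return ref_base, (ref_base + str(rng.choice(_BASES)) * int(rng.integers(1, 4)),)
        ext = ref_base + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return ext, (ext[0],)
    # triallelic subtypes: 0 SNV-SNV, 1 SNV-indel, 2 indel-indel, 3 other-indel
    if subtype == 0:
        a1, a2 = rng.choice(others, size=2, replace=False)
        return ref_base, (str(a1), str(a2))
    if subtype == 1:
        return ref_base, (snv(), ref_base + str(rng.choice(_BASES)) * int(rng.integers(1, 4)))
    if subtype == 2:
        ins1 = ref_base + str(rng.choice(_BASES)) * int(rng.integers(1, 3))
        ins2 = ref_base + str(rng.choice(_BASES)) * int(rng.integers(3, 5))
        return ref_base, (ins1, ins2)
    ext = ref_base + "".join(rng.choice(_BASES, size=2))
    return ext, (ext[0], "*")


def _perturb(g: tuple[int, int], n_alts: int, rng) -> tuple[int, int]:
    """A genotype differing from ``g`` in its unordered allele multiset."""
    x, y = sorted(g)
    if (x, y) == (0, 0):
        return (0, 1)
    if x == y:  # homozygous alt -> heterozygous
        return (0, x)
    choices = [(y, y), (x, x)]  # het -> either homozygote
    if n_alts == 2:  # allele flip at a triallelic site
        other = 1 if y == 2 else 2
        if other != x:
            choices.append(tuple(sorted((x, other))))
    return choices[int(rng.integers(len(choices)))]


def generate_cohort(params: SimulationParams) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate a cohort and its truth table; deterministic under the seed."""
    p = params
    rng = np.random.default_rng(p.seed)
    n_pairs = p.n_replicate_pairs
    n_base = p.n_samples - n_pairs
    base_ids = [f"S{i + 1:03d}" for i in range(n_base)]
    rep_ids = [f"{base_ids[i]}R" for i in range(n_pairs)]
    samples = base_ids + rep_ids
    rep_cols = {n_base + k: k for k in range(n_pairs)}  # replicate col -> base col
    rmap = ReplicateMap(
        pairs=[(base_ids[k], rep_ids[k]) for k in range(n_pairs)],
        singletons=base_ids[n_pairs:],
    )

    positions = np.cumsum(rng.integers(50, 150, size=p.n_sites)) + 1000
    kind_draw = rng.random(p.n_sites)
    subtypes = rng.choice(4, size=p.n_sites, p=np.asarray(p.triallelic_subtype_probs))
    disc_flag = rng.random(p.n_sites) < p.discordance_prob
    contaminated = rng.random(p.n_sites) < p.contamination_rate
    tranche = rng.random(p.n_sites) < p.tranche_fraction

    gt = np.full((p.n_sites, p.n_samples, 2), -1, dtype=np.int16)
    sites: list[VariantSite] = []
    truth_rows = []

    for i in range(p.n_sites):
        if kind_draw[i] < p.p_biallelic_snv:
            kind, n_alts = "bi_snv", 1
        elif kind_draw[i] < p.p_biallelic_snv + p.p_biallelic_indel:
            kind, n_alts = "bi_indel", 1
        else:
            kind, n_alts = "tri", 2
        ref, alts = _site_alleles(kind, int(subtypes[i]), rng)

        # allele frequencies from the rare/common Beta mixture
        freqs = np.empty(n_alts)
        for a in range(n_alts):
            ab = p.rare_beta if rng.random() < p.rare_weight else p.common_beta
            freqs[a] = min(rng.beta(*ab), 0.5)
        probs = np.concatenate([[max(1.0 - freqs.sum(), 0.0)], freqs])
        probs = probs / probs.sum()

        if contaminated[i]:
            g_base = np.ones((n_base, 2), dtype=np.int16)
            g_base[:, 0] = 0  # near-universal heterozygosity
            keep_hom = rng.random(n_base) < 0.1
            g_base[keep_hom] = 0
        else:
            g_base = rng.choice(n_alts + 1, size=(n_base, 2), p=probs).astype(np.int16)
        gt[i, :n_base] = g_base
        for col, base_col in rep_cols.items():
            gt[i, col] = gt[i, base_col]

        perturbed_pair = perturbed_sample = None
        orig = new = ""
        if disc_flag[i]:
            k = int(rng.integers(n_pairs))
            col = n_base + k
            g = tuple(int(a) for a in gt[i, col])
            g2 = _perturb(g, n_alts, rng)
            gt[i, col] = g2
            perturbed_pair, perturbed_sample = k, samples[col]
            orig, new = f"{g[0]}/{g[1]}", f"{g2[0]}/{g2[1]}"

        # annotations
        informative = p.label_informative_annotations and bool(disc_flag[i])
        w_up = (
            p.vqslod_upper_weight_discordant if informative else p.vqslod_upper_weight_concordant
        )
        comp = int(rng.random() < w_up)  # 1 = upper peak
        vqslod = rng.normal(p.vqslod_means[comp], p.vqslod_sds[comp])
        mq_sd = p.mq_sd_discordant if informative else p.mq_sd_concordant
        mq = rng.normal(p.mq_mean, mq_sd)
        dp_mean = p.n_samples * p.mean_depth
        if informative:
            dp_mean *= 1.0 + p.dp_shift_discordant
        dp_total = max(0.0, rng.normal(dp_mean, p.site_dp_cv * p.n_samples * p.mean_depth))

        called = gt[i][gt[i, :, 0] >= 0]
        inbreeding = _inbreeding_coeff(called, n_alts)

        sites.append(
            VariantSite(
                chrom="1",
                pos=int(positions[i]),
                ref=ref,
                alts=alts,
                filter_status=(
                    "VQSRTrancheSNP99.80to100.00" if tranche[i] else "PASS"
                ),
                vqslod=round(float(vqslod), 4),
                mq=round(float(mq), 4),
                dp_total=float(int(dp_total)),
                inbreeding_coeff=round(float(inbreeding), 4),
            )
        )
        truth_rows.append(
            {
                "site_idx": i,
                "chrom": "1",
                "pos": int(positions[i]),
                "discordant": bool(disc_flag[i]),
                "perturbed_pair": perturbed_pair,
                "perturbed_sample": perturbed_sample,
                "orig_gt": orig,
                "new_gt": new,
                "n_alts": n_alts,
                "contaminated": bool(contaminated[i]),
            }
        )

    # missingness, genotype depth and quality
    missing = rng.random((p.n_sites, p.n_samples)) < p.missingness_rate
    gt[missing] = -1
    dp = rng.poisson(p.mean_depth, size=(p.n_sites, p.n_samples)).astype(np.int32)
    gq = np.clip(
        np.rint(rng.normal(2.8 * dp - 5.0, 10.0)), 0, 99
    ).astype(np.int32)

    dataset = CohortDataset(
        sites=sites,
        samples=samples,
        gt=gt,
        dp=dp,
        gq=gq,
        replicate_map=rmap,
    )
    return dataset, pd.DataFrame(truth_rows)


def _inbreeding_coeff(called_gt: np.ndarray, n_alts: int) -> float:
    """1 - observed/expected heterozygosity from the emitted genotypes."""
    if called_gt.size == 0:
        return 0.0
    alleles = called_gt.ravel()
    freqs = np.bincount(alleles, minlength=n_alts + 1) / alleles.size
    exp_het = 1.0 - float((freqs**2).sum())
    if exp_het < 1e-9:
        return 0.0
    obs_het = float((called_gt[:, 0] != called_gt[:, 1]).mean())
    return float(np.clip(1.0 - obs_het / exp_het, -1.0, 1.0))


def inject_annotation_shift(
    dataset: CohortDataset,
    truth: pd.DataFrame,
    vqslod_shift: float = 0.0,
    mq_shift: float = 0.0,
    dp_shift: float = 0.0,
) -> CohortDataset:
    """Shift site annotations of truth-flagged discordant sites.

    Produces cohorts with a known annotation/label relationship so threshold
    recovery can be tested against ground truth: e.g. a -13 VQSLOD shift on
    an otherwise label-neutral cohort makes the discordant VQSLOD
    distribution separably lower. Returns a new dataset; genotypes are
    shared, sites are rebuilt.
    """
    flagged = set(truth.loc[truth.discordant, "site_idx"].astype(int))
    new_sites = []
    for i, site in enumerate(dataset.sites):
        if i in flagged:
            site = replace(
                site,
                vqslod=None if site.vqslod is None else round(site.vqslod + vqslod_shift, 4),
                mq=None if site.mq is None else round(site.mq + mq_shift, 4),
                dp_total=None if site.dp_total is None else max(0.0, site.dp_total + dp_shift),
            )
        new_sites.append(site)
    out = CohortDataset(
        sites=new_sites,
        samples=list(dataset.samples),
        gt=dataset.gt.copy(),
        dp=dataset.dp.copy(),
        gq=dataset.gq.copy(),
        masked=dataset.masked.copy(),
        replicate_map=dataset.replicate_map,
    )
    return out


def write_cohort(
    dataset: CohortDataset,
    truth: pd.DataFrame,
    outdir: str | Path,
    params: SimulationParams,
) -> dict[str, Path]:
    """Write cohort.vcf, samples.tsv, truth.tsv, toy BEDs and a mock ClinVar TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "blacklist": outdir / "blacklist.bed",
        "lcr": outdir / "lcr.bed",
        "clinvar": outdir / "clinvar.tsv",
    }
    write_vcf(dataset, paths["vcf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)

    paired = {s for pair in dataset.replicate_map.pairs for s in pair}
    rep_of = {b: a for a, b in dataset.replicate_map.pairs}
    rows = [
        {
            "sample_id": s,
            "replicate_of": rep_of.get(s, ""),
            "batch": "B2" if s in rep_of else "B1",
            "excluded": 0,
            "exclude_reason": "",
        }
        for s in dataset.samples
    ]
    pd.DataFrame(rows).to_csv(paths["samples"], sep="\t", index=False)

    rng = np.random.default_rng(params.seed + 1)
    # toy intervals: a few windows, some covering real site positions
    pos = np.array([s.pos for s in dataset.sites])
    bl_rows, lcr_rows = [], []
    if len(pos):
        for target in rng.choice(pos, size=min(3, len(pos)), replace=False):
            bl_rows.append(("chr1", int(target) - 1, int(target) + rng.integers(1, 50)))
        for target in rng.choice(pos, size=min(2, len(pos)), replace=False):
            lcr_rows.append(("1", int(target) - 10, int(target) + 10))
    for key, rows_ in (("blacklist", bl_rows), ("lcr", lcr_rows)):
        paths[key].write_text(
            "".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows_)
        )

    n_clinvar = int(round(params.clinvar_fraction * len(dataset.sites)))
    chosen = rng.choice(len(dataset.sites), size=n_clinvar, replace=False) if n_clinvar else []
    cv_rows = []
    for i in sorted(int(j) for j in chosen):
        site = dataset.sites[i]
        alt = site.alts[int(rng.integers(len(site.alts)))]
        if alt == "*":
            alt = site.alts[0]
        cv_rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": alt,
                "rsid": f"rs{100000 + i}",
                "star_level": int(rng.integers(0, 4)),
            }
        )
    pd.DataFrame(
        cv_rows, columns=["chrom", "pos", "ref", "alt", "rsid", "star_level"]
    ).to_csv(paths["clinvar"], sep="\t", index=False)
    return paths
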
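"""Filter efficacy metrics, Ti/Tv diagnostics, and stratified comparisons.

Efficacy treats replicate discordances as the condition a filter should
remove: a removed discordance is a true negative, a removed concordance a
false negative. NPV (= tn / (tn + fn)) measures how enriched a filter's
discards are in discordances; specificity (= tn / (tn + fp)) measures how
much of all discordance the filter captures. Filters are ranked by the
ratio of their discordant to concordant removal rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .errors import ContractError
from .variant_model import AlleleClass, TriallelicSubtype, VariantSite

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

RARE_MAF_MAX = 0.01
COMMON_MAF_MIN = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    """Removal confusion in pair-observations (or sites, per caller's unit)."""

    tn: int  # discordant removed
    fn: int  # concordant removed
    fp: int  # discordant retained
    tp: int  # concordant retained

    def __post_init__(self):
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total_discordant(self) -> int:
        return self.tn + self.fp

    @property
    def total_concordant(self) -> int:
        return self.fn + self.tp


def npv(conf: ConfusionCounts) -> float | None:
    """tn / (tn + fn); None (undefined) when the filter removed nothing."""
    denom = conf.tn + conf.fn
    return None if denom == 0 else conf.tn / denom


def specificity(conf: ConfusionCounts) -> float | None:
    """tn / (tn + fp); None when the input had no discordances."""
    denom = conf.tn + conf.fp
    return None if denom == 0 else conf.tn / denom


def _rank_key(conf: ConfusionCounts) -> float | None:
    """Discordant over concordant removal-rate ratio; None = removed nothing."""
    if conf.tn + conf.fn == 0:
        return None
    disc_rate = conf.tn / conf.total_discordant if conf.total_discordant else 0.0
    conc_rate = conf.fn / conf.total_concordant if conf.total_concordant else 0.0
    if conc_rate == 0.0:
        return math.inf if disc_rate > 0 else None
    return disc_rate / conc_rate


def rank_filters(independent_outcomes) -> list[str]:
    """Filter ids ordered by descending discordant/concordant removal-rate ratio.

    ``independent_outcomes`` maps filter id -> outcome with a ``confusion``
    attribute (as produced by :func:`repliqc.qc_pipeline.run_independent`).
    An infinite key (discordances removed, zero concordances removed) ranks
    first; a filter that removed nothing has an undefined key and ranks
    last. Ties break by higher specificity, then filter id.
    """
    if not isinstance(independent_outcomes, dict):
        independent_outcomes = {o.filter_id: o for o in independent_outcomes}

    def sort_key(fid):
        conf = independent_outcomes[fid].confusion
        key = _rank_key(conf)
        spec = specificity(conf)
        return (
            key is None,  # undefined keys last
            -(key if key is not None else 0.0),
            -(spec if spec is not None else 0.0),
            fid,
        )

    return sorted(independent_outcomes, key=sort_key)


# ---------------------------------------------------------------------------
# Ti/Tv


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in _TRANSITIONS


def titv(sites, scope: str = "all_alt", unit: str = "alleles") -> float | None:
    """Transition/transversion ratio over SNV alternate alleles.

    scope: ``all_alt`` (every SNV alt allele, any site), ``biallelic_snv``,
    or ``triallelic_snv`` (SNV-SNV sites only; each contributes two
    alleles). With ``unit="sites"`` an SNV-SNV site counts once: toward
    transitions when it contains at least one, else toward transversions.
    Returns None when there are no transversions (undefined ratio).
    """
    if scope not in ("all_alt", "biallelic_snv", "triallelic_snv"):
        raise ContractError(f"unknown Ti/Tv scope {scope!r}")
    ti = tv = 0
    for site in sites:
        classes = site.alt_classes
        if scope == "biallelic_snv" and not (site.is_biallelic and classes[0] is AlleleClass.SNV):
            continue
        if scope == "triallelic_snv" and site.subtype is not TriallelicSubtype.SNV_SNV:
            continue
        snv_alts = [a for a, c in zip(site.alts, classes) if c is AlleleClass.SNV]
        if unit == "sites" and len(site.alts) == 2:
            if len(snv_alts) < 2:
                continue
            if any(is_transition(site.ref, a) for a in snv_alts):
                ti += 1
            else:
                tv += 1
            continue
        for alt in snv_alts:
            if is_transition(site.ref, alt):
                ti += 1
            else:
                tv += 1
    if tv == 0:
        return None
    return ti / tv


def classify_triallelic_ti_content(site: VariantSite) -> str:
    """SNV-SNV sites only: 'contains-transition' vs 'two-transversions'."""
    if site.subtype is not TriallelicSubtype.SNV_SNV:
        raise ContractError("transition-content classification requires an SNV-SNV site")
    if any(is_transition(site.ref, a) for a in site.alts):
        return "contains-transition"
    return "two-transversions"


def percent_change(old: float, new: float) -> float:
    """Signed percent change 100 * (new - old) / old."""
    if old == 0:
        raise ContractError("percent change undefined from zero")
    return 100.0 * (new - old) / old


def removal_fraction(n_before: int, n_after: int) -> float:
    """Percentage removed, 100 * (1 - n_after / n_before)."""
    if n_before <= 0:
        raise ContractError("removal fraction needs n_before > 0")
    if not 0 <= n_after <= n_before:
        raise ContractError(f"need 0 <= n_after <= n_before, got {n_after} > {n_before}")
    return 100.0 * (1.0 - n_after / n_before)


# ---------------------------------------------------------------------------
# MAF strata and exact tests


def maf(dataset, site_idx: int, respect_mask: bool = False) -> float:
    """Minor allele frequency from called alleles (missing excluded).

    Defined as the second-largest allele frequency, which stays in [0, 0.5]
    for any ploidy-2 site. Computed on pre-QC genotypes by default so strata
    are stable across filtering stages.
    """
    alleles = dataset.gt[site_idx].ravel()
    if respect_mask:
        keep = ~np.repeat(dataset.masked[site_idx], 2)
        alleles = alleles[keep]
    alleles = alleles[alleles >= 0]
    if alleles.size == 0:
        raise ContractError(f"no called genotypes at site {site_idx}")
    freqs = np.bincount(alleles, minlength=len(dataset.sites[site_idx].alts) + 1) / alleles.size
    return float(np.sort(freqs)[-2]) if freqs.size > 1 else 0.0


def maf_stratum(value: float) -> str | None:
    """'rare' (MAF <= 1%), 'common' (MAF >= 5%), or None (intermediate)."""
    if value <= RARE_MAF_MAX:
        return "rare"
    if value >= COMMON_MAF_MIN:
        return "common"
    return None


@dataclass(frozen=True)
class StratumComparison:
    labels: tuple[str, ...]
    removed: tuple[int, ...]
    retained: tuple[int, ...]
    statistic: float | None  # odds ratio for 2x2; None for r x 2
    p_value: float
    method: str
    maf_definition: str = f"rare <= {RARE_MAF_MAX}, common >= {COMMON_MAF_MIN}"


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds ratio, p-value)."""
    odds, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def _log_table_prob(removed: np.ndarray, totals: np.ndarray) -> float:
    """Log conditional probability of an r x 2 table given its margins."""
    n_removed = removed.sum()
    return float(
        (gammaln(totals + 1) - gammaln(removed + 1) - gammaln(totals - removed + 1)).sum()
        - (gammaln(totals.sum() + 1) - gammaln(n_removed + 1) - gammaln(totals.sum() - n_removed + 1))
    )


def stratified_removal_test(
    removed,
    retained,
    labels=None,
    seed: int = 0,
    n_draws: int = 100_000,
) -> StratumComparison:
    """Exact test of equal removal proportions across strata.

    Two strata use Fisher's exact 2x2 (two-sided). More strata use a seeded
    Monte-Carlo exact test on the r x 2 table: tables are drawn from the
    multivariate hypergeometric distribution fixing all margins, and the
    p-value is the fraction of draws whose conditional probability does not
    exceed the observed table's (with the +1 continuity convention).
    """
    removed = np.asarray(removed, dtype=np.int64)
    retained = np.asarray(retained, dtype=np.int64)
    if removed.shape != retained.shape or removed.ndim != 1 or removed.size < 2:
        raise ContractError("removed/retained must be equal-length 1-D with >= 2 strata")
    totals = removed + retained
    if (totals == 0).any():
        raise ContractError("empty stratum: comparison undefined")
    labels = tuple(labels) if labels is not None else tuple(f"stratum{i}" for i in range(removed.size))

    if removed.size == 2:
        odds, p = fisher_2x2([[removed[0], retained[0]], [removed[1], retained[1]]])
        return StratumComparison(labels, tuple(removed), tuple(retained), odds, p, "fisher-2x2")

    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(removed, totals)
    draws = rng.multivariate_hypergeometric(totals, int(removed.sum()), size=n_draws)
    logps = (
        gammaln(totals + 1)[None, :]
        - gammaln(draws + 1)
        - gammaln(totals[None, :] - draws + 1)
    ).sum(axis=1)
    # constant margin term cancels in the comparison
    obs_core = (gammaln(totals + 1) - gammaln(removed + 1) - gammaln(totals - removed + 1)).sum()
    n_le = int((logps <= obs_core + 1e-9).sum())
    p = (1 + n_le) / (1 + n_draws)
    return StratumComparison(labels, tuple(removed), tuple(retained), None, p, "monte-carlo-exact")
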
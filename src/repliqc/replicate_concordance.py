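"""Replicate pairing and non-reference genotype concordance accounting.

A pair of replicate genotypes at a site is *evaluated* only when both calls
are present (not missing, not masked) and at least one carries an alternate
allele; evaluated pairs are concordant when their unordered allele multisets
are equal (phase and allele order are ignored — replicate sequencing runs
cannot share phase). The fraction of evaluated pairs that are discordant is
the ``p`` of the efficiency ratio ``(1 - p) / p`` used to rank filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ContractError, NoInformativePairsError


class PairStatus(Enum):
    NOT_EVALUATED = 0
    CONCORDANT = 1
    DISCORDANT = 2


class SiteDiscordanceLabel(Enum):
    UNINFORMATIVE = 0
    CONCORDANT_SITE = 1
    DISCORDANT_SITE = 2


@dataclass(frozen=True)
class ReplicateMap:
    """Replicate pairing: (sample_a, sample_b) pairs plus singleton samples."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise ContractError(f"replicate pair with identical members: {a!r}")
            for s in (a, b):
                if s in seen:
                    raise ContractError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Pair-observation bookkeeping over a site set.

    ``p_discordant`` is the fraction of evaluated replicate genotype pairs
    that disagree; ``rate`` (= 1 - p_discordant) is the concordance rate.
    """

    n_evaluated: int
    n_concordant: int
    n_discordant: int

    def __post_init__(self):
        if self.n_concordant + self.n_discordant != self.n_evaluated:
            raise ContractError("concordant + discordant must equal evaluated")

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_evaluated

    @property
    def p_discordant(self) -> float:
        return self.n_discordant / self.n_evaluated

    @property
    def rate_pct(self) -> float:
        return 100.0 * self.rate


def pair_status(
    gt_a: tuple[int, int] | None,
    gt_b: tuple[int, int] | None,
    n_alts: int | None = None,
) -> PairStatus:
    """Concordance status of one replicate genotype pair.

    Missing (or masked, passed as None) members and double-homozygous-
    reference pairs are not evaluated; otherwise the unordered allele
    multisets decide.
    """
    if gt_a is None or gt_b is None:
        return PairStatus.NOT_EVALUATED
    if n_alts is not None:
        for g in (gt_a, gt_b):
            if any(not 0 <= a <= n_alts for a in g):
                raise ContractError(f"allele index out of range for {n_alts}-alt site: {g}")
    if set(gt_a) == {0} and set(gt_b) == {0}:
        return PairStatus.NOT_EVALUATED
    return (
        PairStatus.CONCORDANT
        if sorted(gt_a) == sorted(gt_b)
        else PairStatus.DISCORDANT
    )


def pair_status_matrix(dataset, site_indices=None, respect_mask: bool = True) -> np.ndarray:
    """Vectorized pair statuses: (n_sites_subset, n_pairs) array of codes.

    Codes follow :class:`PairStatus` values. Masked genotypes count as
    missing unless ``respect_mask`` is disabled (audit views).
    """
    pairs = dataset.pair_indices()
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    out = np.zeros((len(idx), len(pairs)), dtype=np.int8)
    if not len(idx) or not pairs:
        return out
    miss = dataset.missing_matrix(respect_mask=respect_mask)
    for k, (ia, ib) in enumerate(pairs):
        a = np.sort(dataset.gt[idx, ia, :], axis=-1)
        b = np.sort(dataset.gt[idx, ib, :], axis=-1)
        missing = miss[idx, ia] | miss[idx, ib]
        both_homref = (a == 0).all(axis=-1) & (b == 0).all(axis=-1)
        evaluated = ~missing & ~both_homref
        concordant = (a == b).all(axis=-1)
        out[:, k] = np.where(
            evaluated,
            np.where(concordant, PairStatus.CONCORDANT.value, PairStatus.DISCORDANT.value),
            PairStatus.NOT_EVALUATED.value,
        )
    return out


def site_label(site_idx: int, dataset, respect_mask: bool = True) -> SiteDiscordanceLabel:
    """Label one site by its replicate pairs (>=1 discordant pair wins)."""
    codes = pair_status_matrix(dataset, [site_idx], respect_mask=respect_mask)[0]
    return _label_from_codes(codes)


def _label_from_codes(codes: np.ndarray) -> SiteDiscordanceLabel:
    if (codes == PairStatus.DISCORDANT.value).any():
        return SiteDiscordanceLabel.DISCORDANT_SITE
    if (codes == PairStatus.CONCORDANT.value).any():
        return SiteDiscordanceLabel.CONCORDANT_SITE
    return SiteDiscordanceLabel.UNINFORMATIVE


def site_labels(dataset, site_indices=None, respect_mask: bool = True) -> np.ndarray:
    """Vectorized site labels (codes follow SiteDiscordanceLabel values)."""
    codes = pair_status_matrix(dataset, site_indices, respect_mask=respect_mask)
    disc = (codes == PairStatus.DISCORDANT.value).any(axis=1)
    conc = (codes == PairStatus.CONCORDANT.value).any(axis=1)
    out = np.zeros(codes.shape[0], dtype=np.int8)
    out[conc] = SiteDiscordanceLabel.CONCORDANT_SITE.value
    out[disc] = SiteDiscordanceLabel.DISCORDANT_SITE.value
    return out


def concordance_summary(dataset, site_indices=None, respect_mask: bool = True) -> ConcordanceSummary:
    """Aggregate pair observations over a site subset.

    One observation per (site, evaluated pair). Raises when no pair is
    informative — a rate over zero observations would be meaningless.
    """
    codes = pair_status_matrix(dataset, site_indices, respect_mask=respect_mask)
    n_conc = int((codes == PairStatus.CONCORDANT.value).sum())
    n_disc = int((codes == PairStatus.DISCORDANT.value).sum())
    if n_conc + n_disc == 0:
        raise NoInformativePairsError("no informative replicate pairs in subset")
    return ConcordanceSummary(
        n_evaluated=n_conc + n_disc, n_concordant=n_conc, n_discordant=n_disc
    )


def eq1_ratio(p_discordant: float) -> float:
    """Efficiency ratio (1 - p) / p for a discordant fraction p.

    p = 0 yields ``math.inf`` (an explicit infinite-ratio signal, not an
    overflow); p outside [0, 1] is a contract violation.
    """
    if not 0.0 <= p_discordant <= 1.0:
        raise ContractError(f"discordant fraction must lie in [0, 1], got {p_discordant}")
    if p_discordant == 0.0:
        return math.inf
    return (1.0 - p_discordant) / p_discordant
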
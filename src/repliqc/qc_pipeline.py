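"""The nine-hard-filter QC engine: sequential and independent application.

Six variant-level filters (missingness, blacklist/LCR interval, total DP,
MQ window, VQSLOD for SNVs, inbreeding coefficient), two genotype-level
filters (genotype DP, GQ) and one sample-level missingness filter. The
annotation filters remove on strict inequality (a value equal to the
threshold passes); the missingness filters remove on >= their cutoff.

Variant-level filters are pure per-site predicates, so their sequential
order changes per-stage accounting but never the final retained set. The
genotype and sample stages are order-sensitive relative to each other and
always run in the fixed order: genotype masking first, then sample
missingness over the masked genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .efficacy_metrics import ConfusionCounts, titv
from .errors import ContractError
from .replicate_concordance import PairStatus, pair_status_matrix
from .variant_model import CohortDataset, IntervalSet, overlaps_interval

logger = logging.getLogger(__name__)

VARIANT_FILTERS = ("missingness", "blacklist_lcr", "site_dp", "mq", "inbreeding", "vqslod")
#: Genome-wide table order (inbreeding before VQSLOD).
DEFAULT_ORDER = VARIANT_FILTERS
#: ClinVar-pipeline order (VQSLOD before inbreeding).
CLINVAR_ORDER = ("missingness", "blacklist_lcr", "site_dp", "mq", "vqslod", "inbreeding")


@dataclass(frozen=True)
class ThresholdSpec:
    """The nine hard-filter thresholds.

    Defaults are the reference values for a ~260-sample 30x WGS cohort; the
    DP / MQ / VQSLOD entries are dataset-specific and meant to be re-estimated
    per cohort (see :mod:`repliqc.empirical_thresholds`).
    """

    variant_missingness_max: float = 0.05
    site_dp_min: float = 25_000.0
    mq_lo: float = 58.75
    mq_hi: float = 61.25
    vqslod_min: float = 7.81
    inbreeding_min: float = -0.8
    gt_dp_min: int = 10
    gt_gq_min: int = 20
    sample_missingness_max: float = 0.10
    filter_order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self):
        if self.mq_lo > self.mq_hi:
            raise ContractError(f"mq_lo {self.mq_lo} > mq_hi {self.mq_hi}")
        if sorted(self.filter_order) != sorted(VARIANT_FILTERS):
            raise ContractError(
                f"filter_order must permute {VARIANT_FILTERS}, got {self.filter_order}"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ContractError(f"threshold {f.name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "filter_order" in data:
            data["filter_order"] = tuple(data["filter_order"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["filter_order"] = list(self.filter_order)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class FilterOutcome:
    """One filter's removed/retained partition with concordance bookkeeping.

    ``confusion`` counts replicate pair-observations: discordant removed
    (tn), concordant removed (fn), discordant retained (fp), concordant
    retained (tp). ``unit`` names what removed/retained ids refer to.
    """

    filter_id: str
    removed_ids: tuple
    retained_ids: tuple
    confusion: ConfusionCounts
    unit: str = "sites"

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


@dataclass(frozen=True)
class StageRecord:
    stage: str
    criterion: str
    n_pass: int
    pct_pass: float
    concordance_rate: float | None  # percent, None when no informative pairs
    titv: float | None
    unit: str = "variants"


@dataclass
class StageTrace:
    """Ordered per-stage accounting of a sequential run."""

    records: list[StageRecord] = field(default_factory=list)
    removed_by: dict[int, str] = field(default_factory=dict)  # site idx -> first stage

    def append(self, record: StageRecord) -> None:
        self.records.append(record)


_CRITERIA = {
    "missingness": "Missingness >= 5%",
    "blacklist_lcr": "Within blacklisted region or LCR",
    "site_dp": "DP < site_dp_min",
    "mq": "MQ outside [mq_lo, mq_hi]",
    "inbreeding": "InbreedingCoeff < inbreeding_min",
    "vqslod": "VQSLOD < vqslod_min (SNVs only)",
}


# ---------------------------------------------------------------------------
# per-filter predicates


def variant_missingness(dataset: CohortDataset, site_indices=None) -> np.ndarray:
    """Per-site fraction of samples with a missing genotype (pre-masking)."""
    if dataset.n_samples == 0:
        raise ContractError("variant missingness undefined for zero samples")
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    miss = dataset.missing_matrix(respect_mask=False)[idx]
    return miss.mean(axis=1)


def variant_pass_mask(
    dataset: CohortDataset,
    filter_id: str,
    thresholds: ThresholdSpec,
    interval_sets: Sequence[IntervalSet] = (),
    site_indices=None,
    strict: bool = False,
) -> np.ndarray:
    """Boolean pass mask (aligned with ``site_indices``) for one variant filter.

    Absent annotations pass the corresponding filter with a logged warning
    (``strict=True`` flips this to removal).
    """
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    t = thresholds
    absent_pass = not strict

    def _annot(attr, predicate):
        out = np.empty(len(idx), dtype=bool)
        n_absent = 0
        for k, i in enumerate(idx):
            v = getattr(dataset.sites[i], attr)
            if v is None:
                out[k] = absent_pass
                n_absent += 1
            else:
                out[k] = predicate(v)
        if n_absent:
            logger.warning(
                "%d site(s) lack %s; %s", n_absent, attr, "removed (strict)" if strict else "passed"
            )
        return out

    if filter_id == "missingness":
        return variant_missingness(dataset, idx) < t.variant_missingness_max
    if filter_id == "blacklist_lcr":
        return np.array(
            [not any(overlaps_interval(dataset.sites[i], s) for s in interval_sets) for i in idx]
        )
    if filter_id == "site_dp":
        return _annot("dp_total", lambda v: v >= t.site_dp_min)
    if filter_id == "mq":
        return _annot("mq", lambda v: t.mq_lo <= v <= t.mq_hi)
    if filter_id == "inbreeding":
        return _annot("inbreeding_coeff", lambda v: v >= t.inbreeding_min)
    if filter_id == "vqslod":
        out = np.empty(len(idx), dtype=bool)
        for k, i in enumerate(idx):
            site = dataset.sites[i]
            if not site.vqslod_eligible:
                out[k] = True
            elif site.vqslod is None:
                out[k] = absent_pass
            else:
                out[k] = site.vqslod >= t.vqslod_min
        return out
    raise ContractError(f"unknown variant filter {filter_id!r}")


def genotype_mask(
    dataset: CohortDataset, thresholds: ThresholdSpec, which: str = "both"
) -> np.ndarray:
    """Boolean (site, sample) matrix of genotypes failing the DP/GQ filters.

    A genotype is masked when its DP < gt_dp_min or GQ < gt_gq_min; a value
    of -1 marks an absent FORMAT key and passes (fail-open). Already-missing
    genotypes are never masked.
    """
    called = ~dataset.missing_matrix(respect_mask=False)
    fail_dp = (dataset.dp >= 0) & (dataset.dp < thresholds.gt_dp_min)
    fail_gq = (dataset.gq >= 0) & (dataset.gq < thresholds.gt_gq_min)
    if which == "dp":
        return called & fail_dp
    if which == "gq":
        return called & fail_gq
    if which == "both":
        return called & (fail_dp | fail_gq)
    raise ContractError(f"unknown genotype filter {which!r}")


def sample_missingness(
    dataset: CohortDataset, site_indices=None, sample_cols=None
) -> np.ndarray:
    """Per-sample missing fraction over retained sites, masked counting as missing."""
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    if len(idx) == 0:
        raise ContractError("sample missingness undefined over zero retained sites")
    cols = np.arange(dataset.n_samples) if sample_cols is None else np.asarray(sample_cols)
    miss = dataset.missing_matrix(respect_mask=True)[np.ix_(idx, cols)]
    return miss.mean(axis=0)


def sample_missingness_filter(
    dataset: CohortDataset, thresholds: ThresholdSpec, site_indices=None
) -> list[str]:
    """Sample ids removed by the post-masking missingness filter (>= cutoff)."""
    fracs = sample_missingness(dataset, site_indices)
    return [s for s, f in zip(dataset.samples, fracs) if f >= thresholds.sample_missingness_max]


# ---------------------------------------------------------------------------
# confusion bookkeeping


def _confusion(codes: np.ndarray, removed_rows: np.ndarray) -> ConfusionCounts:
    """Pair-observation confusion for a site-level removal.

    ``codes`` is the pair-status matrix over the filter's input sites;
    ``removed_rows`` flags the rows (sites) the filter removed.
    """
    disc = codes == PairStatus.DISCORDANT.value
    conc = codes == PairStatus.CONCORDANT.value
    return ConfusionCounts(
        tn=int(disc[removed_rows].sum()),
        fn=int(conc[removed_rows].sum()),
        fp=int(disc[~removed_rows].sum()),
        tp=int(conc[~removed_rows].sum()),
    )


def _stage_concordance(dataset, site_idx) -> float | None:
    try:
        codes = pair_status_matrix(dataset, site_idx)
        n_conc = int((codes == PairStatus.CONCORDANT.value).sum())
        n_disc = int((codes == PairStatus.DISCORDANT.value).sum())
        if n_conc + n_disc == 0:
            return None
        return 100.0 * n_conc / (n_conc + n_disc)
    except ContractError:
        return None


def _stage_titv(dataset, site_idx) -> float | None:
    return titv([dataset.sites[i] for i in site_idx], scope="all_alt")


# ---------------------------------------------------------------------------
# sequential / independent runs


def run_sequential(
    dataset: CohortDataset,
    thresholds: ThresholdSpec,
    interval_sets: Sequence[IntervalSet] = (),
    order: Sequence[str] | None = None,
    site_indices=None,
    strict: bool = False,
) -> tuple[StageTrace, CohortDataset]:
    """Serial application of all nine filters; each stage consumes the
    previous stage's output.

    Expects pre-QC (PASS prefilter, monomorphic removal, allele-count
    partition) to have been applied already; ``site_indices`` names the
    surviving sites. Returns the stage trace plus the final dataset (site
    subset, genotype mask applied, failing samples dropped).
    """
    order = tuple(order or thresholds.filter_order)
    if sorted(order) != sorted(VARIANT_FILTERS):
        raise ContractError(f"order must permute {VARIANT_FILTERS}, got {order}")
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    trace = StageTrace()
    trace.append(
        StageRecord(
            stage="input",
            criterion="—",
            n_pass=len(idx),
            pct_pass=100.0,
            concordance_rate=_stage_concordance(dataset, idx),
            titv=_stage_titv(dataset, idx),
        )
    )

    # variant level
    for fid in order:
        passed = variant_pass_mask(dataset, fid, thresholds, interval_sets, idx, strict)
        for i in idx[~passed]:
            trace.removed_by[int(i)] = fid
        n_before = len(idx)
        idx = idx[passed]
        trace.append(
            StageRecord(
                stage=fid,
                criterion=_CRITERIA[fid],
                n_pass=len(idx),
                pct_pass=100.0 * len(idx) / n_before if n_before else 100.0,
                concordance_rate=_stage_concordance(dataset, idx),
                titv=_stage_titv(dataset, idx),
            )
        )

    # genotype level: DP then GQ masking on the retained sites
    work = dataset.subset(idx)
    n_called = int((~work.missing_matrix(respect_mask=False)).sum())
    for which, fid, crit in (
        ("dp", "gt_dp", "DP < gt_dp_min"),
        ("gq", "gt_gq", "GQ < gt_gq_min"),
    ):
        new_mask = genotype_mask(work, thresholds, which) & ~work.masked
        work.masked = work.masked | new_mask
        n_after = int((~work.missing_matrix(respect_mask=True)).sum())
        trace.append(
            StageRecord(
                stage=fid,
                criterion=crit,
                n_pass=n_after,
                pct_pass=100.0 * n_after / n_called if n_called else 100.0,
                concordance_rate=_stage_concordance(work, np.arange(work.n_sites)),
                titv=_stage_titv(work, np.arange(work.n_sites)),
                unit="genotypes",
            )
        )
        n_called = n_after

    # sample level (skipped when no sites survive: no missingness evidence)
    removed_samples = [] if work.n_sites == 0 else sample_missingness_filter(work, thresholds)
    kept_samples = [s for s in work.samples if s not in removed_samples]
    final = work.subset(sample_ids=kept_samples)
    trace.append(
        StageRecord(
            stage="sample_missingness",
            criterion="Missingness >= 10%",
            n_pass=len(kept_samples),
            pct_pass=100.0 * len(kept_samples) / work.n_samples if work.n_samples else 100.0,
            concordance_rate=_stage_concordance(final, np.arange(final.n_sites)),
            titv=_stage_titv(final, np.arange(final.n_sites)),
            unit="samples",
        )
    )
    return trace, final


def run_independent(
    dataset: CohortDataset,
    thresholds: ThresholdSpec,
    interval_sets: Sequence[IntervalSet] = (),
    site_indices=None,
    strict: bool = False,
) -> dict[str, FilterOutcome]:
    """Each filter evaluated on the same full input.

    Variant-level outcomes partition sites; the genotype-level outcomes mask
    genotypes on the full input (no prior variant filtering); the sample-
    level outcome is evaluated after both genotype masks, mirroring its
    fixed position in the pipeline.
    """
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    codes = pair_status_matrix(dataset, idx)
    outcomes: dict[str, FilterOutcome] = {}

    for fid in VARIANT_FILTERS:
        passed = variant_pass_mask(dataset, fid, thresholds, interval_sets, idx, strict)
        outcomes[fid] = FilterOutcome(
            filter_id=fid,
            removed_ids=tuple(int(i) for i in idx[~passed]),
            retained_ids=tuple(int(i) for i in idx[passed]),
            confusion=_confusion(codes, ~passed),
            unit="sites",
        )

    called = ~dataset.missing_matrix(respect_mask=False)
    for which, fid in (("dp", "gt_dp"), ("gq", "gt_gq")):
        mask = genotype_mask(dataset, thresholds, which)
        probe = dataset.subset(idx)
        probe.masked = probe.masked | mask[idx]
        codes_after = pair_status_matrix(probe, np.arange(probe.n_sites))
        evaluated_before = codes != PairStatus.NOT_EVALUATED.value
        lost = evaluated_before & (codes_after == PairStatus.NOT_EVALUATED.value)
        disc = codes == PairStatus.DISCORDANT.value
        conc = codes == PairStatus.CONCORDANT.value
        outcomes[fid] = FilterOutcome(
            filter_id=fid,
            removed_ids=tuple(zip(*np.nonzero(mask[idx]))),
            retained_ids=tuple(zip(*np.nonzero(called[idx] & ~mask[idx]))),
            confusion=ConfusionCounts(
                tn=int((disc & lost).sum()),
                fn=int((conc & lost).sum()),
                fp=int((disc & ~lost).sum()),
                tp=int((conc & ~lost).sum()),
            ),
            unit="genotypes",
        )

    probe = dataset.subset(idx)
    probe.masked = probe.masked | genotype_mask(probe, thresholds, "both")
    removed_samples = sample_missingness_filter(probe, thresholds)
    outcomes["sample_missingness"] = FilterOutcome(
        filter_id="sample_missingness",
        removed_ids=tuple(removed_samples),
        retained_ids=tuple(s for s in dataset.samples if s not in removed_samples),
        confusion=ConfusionCounts(0, 0, 0, 0),
        unit="samples",
    )
    return outcomes
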
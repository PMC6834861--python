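"""Domain types, VCF/BED/TSV I/O and pre-QC normalization.

The in-memory container is :class:`CohortDataset`: a list of
:class:`VariantSite` records plus dense numpy genotype arrays (allele index
pair, genotype DP, genotype GQ, mask state) over ``site x sample``. Variants
are identified throughout by their CPRA string, ``chrom.pos.ref.alt`` — one
identifier per alternate allele, so a triallelic site owns two.

Coordinate conventions: VCF positions are 1-based inclusive; BED intervals
are 0-based half-open. Conversion happens exactly once, inside
:class:`IntervalSet` construction/query. Chromosome labels are normalized by
stripping a leading ``chr`` so UCSC-style BED files interoperate with
Ensembl-style VCFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import (
    AmbiguousClinVarError,
    ContractError,
    InvalidRecordError,
    UnsupportedSubtypeError,
)
from .replicate_concordance import ReplicateMap

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel allele index for an uncalled genotype

_SYMBOLIC_STAR = "*"


class AlleleClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SYMBOLIC = "SYMBOLIC"


class TriallelicSubtype(str, Enum):
    SNV_SNV = "SNV-SNV"
    SNV_INDEL = "SNV-indel"
    INDEL_INDEL = "indel-indel"
    OTHER_INDEL = "other-indel"


def normalize_chrom(label: str) -> str:
    """Canonical chromosome label: ``chr1`` and ``1`` both map to ``1``."""
    return label[3:] if label.lower().startswith("chr") else label


def make_cpra(chrom: str, pos: int, ref: str, alt: str) -> str:
    """``chrom.pos.ref.alt`` identifier; injective on its four fields."""
    if not chrom or not ref or not alt:
        raise InvalidRecordError(f"empty field in CPRA inputs: {(chrom, pos, ref, alt)!r}")
    if pos < 1:
        raise InvalidRecordError(f"position must be >= 1, got {pos}")
    return f"{chrom}.{pos}.{ref}.{alt}"


def classify_allele(ref: str, alt: str) -> AlleleClass:
    """SNV / INDEL / SYMBOLIC classification of one alternate allele."""
    if not ref or not alt:
        raise InvalidRecordError("empty allele string")
    if alt == ref:
        raise InvalidRecordError(f"alt equals ref ({ref!r})")
    if alt == _SYMBOLIC_STAR or (alt.startswith("<") and alt.endswith(">")):
        return AlleleClass.SYMBOLIC
    if len(ref) == 1 and len(alt) == 1:
        return AlleleClass.SNV
    return AlleleClass.INDEL


def classify_triallelic_subtype(ref: str, alt1: str, alt2: str) -> TriallelicSubtype:
    """Unordered subtype of a two-alt site.

    Any symbolic member (a spanning deletion ``*`` or a bracketed allele)
    paired with a concrete allele yields ``other-indel``; two symbolic alts
    are outside the supported taxonomy.
    """
    c1, c2 = classify_allele(ref, alt1), classify_allele(ref, alt2)
    classes = {c1, c2}
    if classes == {AlleleClass.SYMBOLIC}:
        raise UnsupportedSubtypeError(f"two symbolic alts at ref {ref!r}")
    if AlleleClass.SYMBOLIC in classes:
        return TriallelicSubtype.OTHER_INDEL
    if classes == {AlleleClass.SNV}:
        return TriallelicSubtype.SNV_SNV
    if classes == {AlleleClass.INDEL}:
        return TriallelicSubtype.INDEL_INDEL
    return TriallelicSubtype.SNV_INDEL


@dataclass(frozen=True)
class VariantSite:
    """One VCF site with its QC annotations.

    ``alts`` holds one or two alternate alleles (>= 3 alts are excluded
    upstream by :func:`partition_by_allele_count`). Annotation fields are
    ``None`` when the corresponding INFO key was absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter_status: str = "PASS"
    vqslod: float | None = None
    mq: float | None = None
    dp_total: float | None = None
    inbreeding_coeff: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidRecordError(f"position must be >= 1, got {self.pos}")
        if not self.alts or len(self.alts) > 2:
            raise InvalidRecordError(f"VariantSite holds 1-2 alts, got {len(self.alts)}")
        if self.inbreeding_coeff is not None and not -1.0 <= self.inbreeding_coeff <= 1.0:
            raise InvalidRecordError(
                f"inbreeding coefficient outside [-1, 1]: {self.inbreeding_coeff}"
            )
        for alt in self.alts:
            classify_allele(self.ref, alt)  # raises on empty/identical alleles

    @property
    def cpras(self) -> tuple[str, ...]:
        return tuple(make_cpra(self.chrom, self.pos, self.ref, a) for a in self.alts)

    @property
    def alt_classes(self) -> tuple[AlleleClass, ...]:
        return tuple(classify_allele(self.ref, a) for a in self.alts)

    @property
    def subtype(self) -> TriallelicSubtype | None:
        """Triallelic subtype; present iff the site has exactly two alts."""
        if len(self.alts) != 2:
            return None
        return classify_triallelic_subtype(self.ref, *self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def vqslod_eligible(self) -> bool:
        """True for biallelic SNVs and triallelic SNV-SNV sites.

        The VQSLOD hard filter applies only to sites whose alternate alleles
        are all SNVs; indel and symbolic-containing sites pass it untouched.
        """
        return all(c is AlleleClass.SNV for c in self.alt_classes)


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype with read depth, quality, and mask state."""

    sample_id: str
    alleles: tuple[int, int] | None  # None = missing
    dp: int = -1  # -1 = FORMAT key absent
    gq: int = -1
    masked: bool = False

    @property
    def effective_alleles(self) -> tuple[int, int] | None:
        """Masked genotypes behave as missing in all downstream counting."""
        return None if self.masked else self.alleles


@dataclass(frozen=True)
class ClinVarEntry:
    cpra: str
    rsid: str
    star_level: int
    assertion_text: str = ""

    def __post_init__(self):
        if self.star_level not in (0, 1, 2, 3):
            raise InvalidRecordError(f"star_level must be 0-3, got {self.star_level}")


class IntervalSet:
    """Per-chromosome interval collection stored 0-based half-open.

    Built from BED3 rows; the single coordinate-conversion point of the
    package is :meth:`site_overlap`, which converts a 1-based inclusive
    reference span to 0-based half-open before querying.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._warned: set[str] = set()
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start < 0 or end <= start:
            raise InvalidRecordError(f"bad interval [{start}, {end})")
        self._trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        iset = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            iset.add(fields[0], int(fields[1]), int(fields[2]))
        return iset

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """Any stored interval intersecting 0-based half-open [start0, end0)?"""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            key = normalize_chrom(chrom)
            if key not in self._warned:
                self._warned.add(key)
                logger.warning("chromosome %r not present in interval set", chrom)
            return False
        return bool(tree.overlap(start0, end0))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def overlaps_interval(site: VariantSite, interval_set: IntervalSet) -> bool:
    """True iff any reference base of the site intersects an interval.

    The site spans 1-based positions ``pos .. pos + len(ref) - 1``; the
    equivalent 0-based half-open span is ``[pos-1, pos-1+len(ref))``.
    """
    start0 = site.pos - 1
    return interval_set.overlaps(site.chrom, start0, start0 + len(site.ref))


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class CohortDataset:
    """Sites plus dense genotype arrays over ``site x sample``.

    ``gt`` has shape (n_sites, n_samples, 2) with allele indices and -1 for
    missing; ``masked`` records genotype-level filter hits without erasing the
    original call (audit trail). ``dp``/``gq`` are -1 where the FORMAT key was
    absent.
    """

    sites: list[VariantSite]
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    masked: np.ndarray = None  # type: ignore[assignment]
    replicate_map: ReplicateMap = field(default_factory=ReplicateMap)

    def __post_init__(self):
        n_sites, n_samples = len(self.sites), len(self.samples)
        if len(set(self.samples)) != n_samples:
            raise InvalidRecordError("duplicate sample ids")
        if self.gt.shape != (n_sites, n_samples, 2):
            raise InvalidRecordError(
                f"gt shape {self.gt.shape} != {(n_sites, n_samples, 2)}"
            )
        if self.masked is None:
            self.masked = np.zeros((n_sites, n_samples), dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def pair_indices(self) -> list[tuple[int, int]]:
        """Replicate pairs as column index pairs (validated against samples)."""
        out = []
        for a, b in self.replicate_map.pairs:
            try:
                out.append((self.samples.index(a), self.samples.index(b)))
            except ValueError as exc:
                raise ContractError(f"replicate sample missing from cohort: {exc}")
        return out

    def genotype(self, site_idx: int, sample: int | str) -> GenotypeCall:
        j = sample if isinstance(sample, int) else self.sample_index(sample)
        a = self.gt[site_idx, j]
        alleles = None if a[0] < 0 or a[1] < 0 else (int(a[0]), int(a[1]))
        return GenotypeCall(
            sample_id=self.samples[j],
            alleles=alleles,
            dp=int(self.dp[site_idx, j]),
            gq=int(self.gq[site_idx, j]),
            masked=bool(self.masked[site_idx, j]),
        )

    def missing_matrix(self, *, respect_mask: bool = True) -> np.ndarray:
        """Boolean (site, sample) matrix: genotype unavailable downstream."""
        miss = (self.gt[:, :, 0] < 0) | (self.gt[:, :, 1] < 0)
        if respect_mask:
            miss = miss | self.masked
        return miss

    def subset(
        self,
        site_indices: Sequence[int] | np.ndarray | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "CohortDataset":
        si = np.arange(self.n_sites) if site_indices is None else np.asarray(site_indices)
        if sample_ids is None:
            cols = np.arange(self.n_samples)
            samples = list(self.samples)
        else:
            cols = np.array([self.samples.index(s) for s in sample_ids])
            samples = list(sample_ids)
        kept = set(samples)
        rmap = ReplicateMap(
            pairs=[(a, b) for a, b in self.replicate_map.pairs if a in kept and b in kept],
            singletons=[s for s in self.replicate_map.singletons if s in kept],
        )
        return CohortDataset(
            sites=[self.sites[i] for i in si],
            samples=samples,
            gt=self.gt[np.ix_(si, cols)].copy(),
            dp=self.dp[np.ix_(si, cols)].copy(),
            gq=self.gq[np.ix_(si, cols)].copy(),
            masked=self.masked[np.ix_(si, cols)].copy(),
            replicate_map=rmap,
        )


# ---------------------------------------------------------------------------
# pre-QC normalization


def partition_by_allele_count(sites: Sequence[VariantSite | object]) -> dict:
    """Split parsed records into biallelic / triallelic / excluded (>=4 alleles).

    Accepts either VariantSite objects or raw records with an ``alts``
    attribute; returns index lists so callers can slice a CohortDataset.
    """
    out: dict[str, list] = {"biallelic": [], "triallelic": [], "excluded": []}
    for i, site in enumerate(sites):
        n_alts = len(site.alts)
        if n_alts == 1:
            out["biallelic"].append(i)
        elif n_alts == 2:
            out["triallelic"].append(i)
        else:
            out["excluded"].append((i, ">=4 alleles"))
    return out


def split_triallelic(site: VariantSite) -> tuple[VariantSite, VariantSite]:
    """Two single-alt rows sharing the parent's annotations verbatim.

    No left-alignment or re-normalization: positions and allele strings are
    preserved so CPRAs stay comparable with external tables. Joint genotypes
    remain attached to the parent site; the split rows are annotation and
    matching views only.
    """
    if len(site.alts) != 2:
        raise ContractError(f"split_triallelic needs exactly 2 alts, got {len(site.alts)}")
    return (
        replace(site, alts=(site.alts[0],)),
        replace(site, alts=(site.alts[1],)),
    )


def gatk_pass_prefilter(dataset: CohortDataset, site_indices=None) -> np.ndarray:
    """Indices (within the given subset) of sites with FILTER == PASS."""
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    return idx[[dataset.sites[i].filter_status == "PASS" for i in idx]]


def remove_monomorphic(dataset: CohortDataset, site_indices=None) -> np.ndarray:
    """Indices of sites with at least one non-missing non-reference genotype.

    A site whose genotypes are all homozygous-reference or all missing carries
    no alternate-allele signal and is dropped.
    """
    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    gt = dataset.gt[idx]
    polymorphic = (gt > 0).any(axis=(1, 2))
    return idx[polymorphic]


def match_clinvar(
    dataset: CohortDataset,
    entries: Iterable[ClinVarEntry],
    site_indices=None,
) -> tuple[np.ndarray, dict[int, ClinVarEntry]]:
    """Retain sites whose CPRA (any split row for triallelics) is in ClinVar.

    Returns (retained indices, {site index -> matched entry}). Unmatched
    variants are dropped. Matching is verbatim on the CPRA string; duplicate
    CPRAs in the table are an ambiguity error.
    """
    table: dict[str, ClinVarEntry] = {}
    dups = []
    for e in entries:
        if e.cpra in table:
            dups.append(e.cpra)
        table[e.cpra] = e
    if dups:
        raise AmbiguousClinVarError(sorted(set(dups)))

    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    retained, annotations = [], {}
    for i in idx:
        for cpra in dataset.sites[i].cpras:
            hit = table.get(cpra)
            if hit is not None:
                retained.append(i)
                annotations[int(i)] = hit
                break
    return np.asarray(retained, dtype=int), annotations


# ---------------------------------------------------------------------------
# readers / writers


def read_vcf(path: str | Path, replicate_map: ReplicateMap | None = None) -> CohortDataset:
    """Parse a multi-sample VCF (plain or bgzipped) into a CohortDataset.

    Requires FORMAT GT; DP/GQ and the site annotations VQSLOD/MQ/DP/
    InbreedingCoeff are optional (absent values stored as -1 / None and
    handled fail-open by the QC engine).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    gt_rows, dp_rows, gq_rows = [], [], []

    for v in vcf:
        alts = tuple(v.ALT)
        if not alts:
            continue
        info = v.INFO

        def _f(key):
            val = info.get(key)
            if val is None:
                return None
            # htslib stores INFO floats as float32; shortest 7-significant-
            # digit repr recovers the originally written decimal exactly
            return float(f"{float(val):.7g}")

        sites.append(
            VariantSite(
                chrom=normalize_chrom(v.CHROM),
                pos=v.POS,
                ref=v.REF,
                alts=alts,
                filter_status=v.FILTER or "PASS",
                vqslod=_f("VQSLOD"),
                mq=_f("MQ"),
                dp_total=_f("DP"),
                inbreeding_coeff=_f("InbreedingCoeff"),
            )
        )
        row = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        row[row < 0] = MISSING
        gt_rows.append(row)
        dp_rows.append(_format_field(v, "DP", len(samples)))
        gq_rows.append(_format_field(v, "GQ", len(samples)))

    n = len(sites)
    return CohortDataset(
        sites=sites,
        samples=samples,
        gt=np.stack(gt_rows) if n else np.empty((0, len(samples), 2), dtype=np.int16),
        dp=np.stack(dp_rows) if n else np.empty((0, len(samples)), dtype=np.int32),
        gq=np.stack(gq_rows) if n else np.empty((0, len(samples)), dtype=np.int32),
        replicate_map=replicate_map or ReplicateMap(),
    )


def _format_field(variant, key: str, n_samples: int) -> np.ndarray:
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return np.full(n_samples, -1, dtype=np.int32)
    out = np.asarray(arr, dtype=np.int64).reshape(n_samples, -1)[:, 0].astype(np.int32)
    out[out < 0] = -1  # cyvcf2 encodes missing as a large negative sentinel
    return out


def write_vcf(
    dataset: CohortDataset,
    path: str | Path,
    provenance: Sequence[str] = (),
    apply_mask: bool = True,
) -> None:
    """Write the cohort as a VCF v4.2 text file.

    ``provenance`` lines (e.g. applied filters and thresholds) are emitted as
    ``##repliqc_filter=`` header lines. Masked genotypes are written as ``./.``
    when ``apply_mask`` is set, matching their downstream semantics.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=repliqc"]
    lines += [f"##repliqc_filter={p}" for p in provenance]
    for chrom in dict.fromkeys(s.chrom for s in dataset.sites):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=VQSRTrancheSNP99.80to100.00,Description="VQSR tranche">',
        '##FILTER=<ID=VQSRTrancheINDEL99.00to100.00,Description="VQSR tranche">',
        '##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="VQSR log-odds">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="Inbreeding coefficient">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Genotype read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples),
    ]
    miss = dataset.missing_matrix(respect_mask=apply_mask)
    for i, site in enumerate(dataset.sites):
        info = []
        if site.vqslod is not None:
            info.append(f"VQSLOD={site.vqslod:.4f}")
        if site.mq is not None:
            info.append(f"MQ={site.mq:.4f}")
        if site.dp_total is not None:
            info.append(f"DP={int(site.dp_total)}")
        if site.inbreeding_coeff is not None:
            info.append(f"InbreedingCoeff={site.inbreeding_coeff:.4f}")
        cols = [
            site.chrom,
            str(site.pos),
            ".",
            site.ref,
            ",".join(site.alts),
            ".",
            site.filter_status,
            ";".join(info) or ".",
            "GT:DP:GQ",
        ]
        for j in range(dataset.n_samples):
            if miss[i, j]:
                gt_str = "./."
            else:
                a, b = dataset.gt[i, j]
                gt_str = f"{a}/{b}"
            dp = dataset.dp[i, j]
            gq = dataset.gq[i, j]
            cols.append(
                f"{gt_str}:{dp if dp >= 0 else '.'}:{gq if gq >= 0 else '.'}"
            )
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def read_sample_metadata(path: str | Path) -> tuple[ReplicateMap, list[str], pd.DataFrame]:
    """Read the sample-metadata TSV.

    Columns: ``sample_id``, ``replicate_of`` (empty for singletons),
    ``batch``, ``excluded`` (boolean), optional ``exclude_reason``. Returns
    (replicate map over non-excluded samples, excluded sample ids, full table).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "replicate_of", "batch", "excluded"}
    if not required.issubset(df.columns):
        raise InvalidRecordError(f"sample metadata needs columns {sorted(required)}")
    truthy = {"1", "true", "yes", "y"}
    excluded = [
        r.sample_id for r in df.itertuples() if str(r.excluded).strip().lower() in truthy
    ]
    keep = set(df.sample_id) - set(excluded)
    pairs = [
        (r.replicate_of, r.sample_id)
        for r in df.itertuples()
        if r.replicate_of and r.sample_id in keep and r.replicate_of in keep
    ]
    paired = {s for p in pairs for s in p}
    singletons = sorted(keep - paired)
    return ReplicateMap(pairs=pairs, singletons=singletons), excluded, df


def read_clinvar_table(path: str | Path) -> list[ClinVarEntry]:
    """ClinVar-style TSV with columns chrom, pos, ref, alt, rsid, star_level."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    entries = []
    for r in df.itertuples():
        entries.append(
            ClinVarEntry(
                cpra=make_cpra(normalize_chrom(str(r.chrom)), int(r.pos), r.ref, r.alt),
                rsid=str(getattr(r, "rsid", "")),
                star_level=int(getattr(r, "star_level", 0)),
                assertion_text=str(getattr(r, "assertion_text", "")),
            )
        )
    return entries
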
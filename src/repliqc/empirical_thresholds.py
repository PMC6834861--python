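"""Empirical threshold derivation from discordant vs concordant densities.

Site-level annotations (total DP, MQ, VQSLOD) separate replicate-discordant
from replicate-concordant sites; a hard threshold is chosen on a grid to
maximize the ratio of discordant to concordant sites removed, subject to
removing at least a fraction ``d_min`` of all discordant sites. The
constraint formalizes the trade-off between a high removal ratio and broad
coverage of discordances: an extreme threshold can reach a huge ratio while
removing almost nothing.

When no replicate samples exist, the bimodality of VQSLOD still permits a
fallback: :func:`valley_threshold` removes the lower of the two density
peaks by cutting at the valley between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ConstraintInfeasibleError, ContractError, DegenerateInputError, NotBimodalError
from .replicate_concordance import SiteDiscordanceLabel, site_labels

_GRID_SIZE = 512


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density evaluated on an ascending grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self):
        if not np.all(np.diff(self.grid) > 0):
            raise ContractError("density grid must be strictly ascending")
        integral = float(np.trapezoid(self.density, self.grid))
        if not 0.99 <= integral <= 1.01:
            raise ContractError(f"density integral {integral:.4f} outside 1 +- 0.01")

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Selected threshold with its removal bookkeeping.

    ``threshold`` is a scalar for one-sided filters or a (lo, hi) window for
    the two-sided MQ filter. ``objective`` is discordant_removed_frac /
    concordant_removed_frac (+inf when the denominator is zero and the
    numerator is not).
    """

    threshold: float | tuple[float, float]
    discordant_removed_frac: float
    concordant_removed_frac: float
    objective: float


def density_estimate(values, bandwidth: float | None = None) -> DensityCurve:
    """Gaussian KDE on a grid spanning [min - 3h, max + 3h].

    ``bandwidth`` is the kernel scale h in data units; the default follows
    Silverman's rule. Fewer than two finite values, or zero variance, cannot
    support a density estimate.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.std(v) == 0:
        raise DegenerateInputError("density estimation needs >= 2 distinct finite values")
    sd = float(np.std(v, ddof=1))
    kde = gaussian_kde(v, bw_method=None if bandwidth is None else bandwidth / sd)
    h = float(kde.factor * sd)
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, _GRID_SIZE)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


def _clean(values, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ContractError(f"{name} group is empty")
    return np.sort(v)


def _removed_frac_below(sorted_vals: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Fraction of values strictly below each candidate threshold."""
    return np.searchsorted(sorted_vals, thresholds, side="left") / sorted_vals.size


def _objective(disc_frac: np.ndarray, conc_frac: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        obj = disc_frac / conc_frac
    obj = np.where((conc_frac == 0) & (disc_frac > 0), np.inf, obj)
    return np.where((conc_frac == 0) & (disc_frac == 0), 0.0, obj)


def _pick(
    feasible: np.ndarray, keys_last_to_first: tuple[np.ndarray, ...], disc_frac: np.ndarray
) -> int:
    """Index of the best feasible candidate under lexicographic tie-breaks."""
    idx = np.flatnonzero(feasible)
    if idx.size == 0:
        raise ConstraintInfeasibleError(
            f"no candidate reaches the required discordant removal "
            f"(max achievable {disc_frac.max():.4f})",
            max_achievable=float(disc_frac.max()),
        )
    order = np.lexsort(tuple(k[idx] for k in keys_last_to_first))
    return int(idx[order[0]])


def select_lower_threshold(
    values_at_discordant_sites,
    values_at_concordant_sites,
    d_min: float = 0.5,
    grid_step: float = 0.01,
) -> ThresholdSearchResult:
    """One-sided lower cut: remove sites with value < t.

    Maximizes discordant_removed / concordant_removed over a grid of
    candidate thresholds subject to discordant_removed >= d_min. Ties break
    toward fewer concordant removals, then the smallest threshold; a zero
    concordant-removal denominator is treated as +inf and preferred, tie-
    broken by the larger discordant removal.
    """
    if not 0.0 <= d_min < 1.0:
        raise ContractError(f"d_min must lie in [0, 1), got {d_min}")
    disc = _clean(values_at_discordant_sites, "discordant")
    conc = _clean(values_at_concordant_sites, "concordant")
    lo = min(disc[0], conc[0])
    hi = max(disc[-1], conc[-1])
    # grid spans (lo, hi]: a threshold above every value (remove everything)
    # is not a candidate, so d_min can be genuinely infeasible
    n_cand = int(np.floor((hi - lo) / grid_step + 1e-9))
    if n_cand < 1:
        raise DegenerateInputError("value range smaller than grid_step")
    candidates = lo + grid_step * np.arange(1, n_cand + 1)
    disc_frac = _removed_frac_below(disc, candidates)
    conc_frac = _removed_frac_below(conc, candidates)
    obj = _objective(disc_frac, conc_frac)
    i = _pick(
        disc_frac >= d_min - 1e-12,
        (candidates, conc_frac, -disc_frac, -obj),
        disc_frac,
    )
    return ThresholdSearchResult(
        threshold=float(candidates[i]),
        discordant_removed_frac=float(disc_frac[i]),
        concordant_removed_frac=float(conc_frac[i]),
        objective=float(obj[i]),
    )


def select_window(
    values_at_discordant_sites,
    values_at_concordant_sites,
    d_min: float = 0.5,
    grid_step: float = 0.01,
) -> ThresholdSearchResult:
    """Two-sided window: remove sites with value < lo or value > hi.

    The (lo, hi) grid is centred on the mode of the concordant density
    (median when the concordant values are degenerate), so the window always
    contains the bulk of concordant sites. Objective, constraint and
    tie-breaks follow :func:`select_lower_threshold`; among ties the
    wider (maximal pass interval), then lower, window wins.
    """
    if not 0.0 <= d_min < 1.0:
        raise ContractError(f"d_min must lie in [0, 1), got {d_min}")
    disc = _clean(values_at_discordant_sites, "discordant")
    conc = _clean(values_at_concordant_sites, "concordant")
    if disc[0] == disc[-1] and conc[0] == conc[-1] and disc[0] == conc[0]:
        raise DegenerateInputError("all values identical; no window can separate groups")
    try:
        center = density_estimate(conc).mode
    except DegenerateInputError:
        center = float(np.median(conc))
    vmin = min(disc[0], conc[0])
    vmax = max(disc[-1], conc[-1])
    n_lo = max(1, int(np.ceil((center - vmin) / grid_step)) + 1)
    n_hi = max(1, int(np.ceil((vmax - center) / grid_step)) + 1)
    los = center - grid_step * np.arange(n_lo)[::-1]
    his = center + grid_step * np.arange(n_hi)

    def _frac(sorted_vals):
        below = np.searchsorted(sorted_vals, los, side="left")
        above = sorted_vals.size - np.searchsorted(sorted_vals, his, side="right")
        return (below[:, None] + above[None, :]) / sorted_vals.size

    disc_frac = _frac(disc).ravel()
    conc_frac = _frac(conc).ravel()
    lo_grid, hi_grid = np.meshgrid(los, his, indexing="ij")
    lo_flat, hi_flat = lo_grid.ravel(), hi_grid.ravel()
    obj = _objective(disc_frac, conc_frac)
    i = _pick(
        disc_frac >= d_min - 1e-12,
        (lo_flat, lo_flat - hi_flat, conc_frac, -disc_frac, -obj),
        disc_frac,
    )
    return ThresholdSearchResult(
        threshold=(float(lo_flat[i]), float(hi_flat[i])),
        discordant_removed_frac=float(disc_frac[i]),
        concordant_removed_frac=float(conc_frac[i]),
        objective=float(obj[i]),
    )


def valley_threshold(
    values, bandwidth: float | None = None, min_rel_height: float = 0.05
) -> float:
    """Valley between the two highest density modes of a bimodal sample.

    Intended for VQSLOD when no replicate pairs exist: the lower mode
    collects likely false positives, and cutting at the inter-mode density
    minimum removes it. Local maxima below ``min_rel_height`` of the global
    peak are ignored as smoothing ripple.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ContractError(f"valley_threshold needs >= 100 values, got {v.size}")
    curve = density_estimate(v, bandwidth=bandwidth)
    d = curve.density
    interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    peaks = interior[d[interior] >= min_rel_height * d.max()]
    if peaks.size < 2:
        raise NotBimodalError(
            f"found {peaks.size} density mode(s); need two for a valley threshold"
        )
    top_two = peaks[np.argsort(d[peaks])[-2:]]
    i1, i2 = int(top_two.min()), int(top_two.max())
    valley = i1 + 1 + int(np.argmin(d[i1 + 1 : i2]))
    return float(curve.grid[valley])


def estimate_thresholds(
    dataset,
    site_indices=None,
    d_min: float = 0.5,
    dp_grid_step: float | None = None,
    mq_grid_step: float = 0.01,
    vqslod_grid_step: float = 0.01,
    parameters: tuple[str, ...] = ("site_dp", "mq", "vqslod"),
):
    """Estimate DP / MQ / VQSLOD thresholds from a replicate-labelled cohort.

    Sites are labelled by their replicate pairs; uninformative sites are
    excluded. VQSLOD estimation uses SNV-only sites (the filter is applied to
    SNVs only). Returns a :class:`~repliqc.qc_pipeline.ThresholdSpec` whose
    non-estimated fields keep their defaults, plus the per-parameter search
    results.
    """
    from .qc_pipeline import ThresholdSpec  # local import avoids a cycle

    idx = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    labels = site_labels(dataset, idx)
    disc_idx = idx[labels == SiteDiscordanceLabel.DISCORDANT_SITE.value]
    conc_idx = idx[labels == SiteDiscordanceLabel.CONCORDANT_SITE.value]

    def _vals(site_idx, attr, snv_only=False):
        out = []
        for i in site_idx:
            s = dataset.sites[i]
            if snv_only and not s.vqslod_eligible:
                continue
            v = getattr(s, attr)
            if v is not None:
                out.append(v)
        return np.asarray(out, dtype=float)

    spec_kwargs = {}
    results = {}
    if "site_dp" in parameters:
        dp_disc = _vals(disc_idx, "dp_total")
        dp_conc = _vals(conc_idx, "dp_total")
        if dp_grid_step is None:
            # DP scales with cohort size x depth; keep ~400 candidates
            span = max(dp_disc.max(), dp_conc.max()) - min(dp_disc.min(), dp_conc.min())
            dp_grid_step = max(span / 400.0, 1e-6)
        r = select_lower_threshold(dp_disc, dp_conc, d_min, dp_grid_step)
        results["site_dp"] = r
        spec_kwargs["site_dp_min"] = r.threshold
    if "mq" in parameters:
        r = select_window(_vals(disc_idx, "mq"), _vals(conc_idx, "mq"), d_min, mq_grid_step)
        results["mq"] = r
        spec_kwargs["mq_lo"], spec_kwargs["mq_hi"] = r.threshold
    if "vqslod" in parameters:
        r = select_lower_threshold(
            _vals(disc_idx, "vqslod", snv_only=True),
            _vals(conc_idx, "vqslod", snv_only=True),
            d_min,
            vqslod_grid_step,
        )
        results["vqslod"] = r
        spec_kwargs["vqslod_min"] = r.threshold
    return ThresholdSpec(**spec_kwargs), results
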
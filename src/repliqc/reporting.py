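"""Report rendering: stage tables, rankings, trajectories, manifests, plots.

Displayed precisions follow the pipeline's report conventions: pass
percentages to 2 decimals, concordance rates to 3, Ti/Tv to 5, all with
banker's rounding (Python's default float formatting) for deterministic
cross-platform output. Undefined metrics render as an em dash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .efficacy_metrics import npv, rank_filters, specificity
from .errors import ContractError

UNDEFINED = "—"


def format_percent(fraction: float, decimals: int = 2) -> str:
    """0.946 -> '94.60' (fraction in, fixed-precision percent string out)."""
    return f"{100.0 * fraction:.{decimals}f}"


def _fmt(value, decimals) -> str:
    return UNDEFINED if value is None else f"{value:.{decimals}f}"


def render_stage_table(trace, path: str | Path | None = None) -> pd.DataFrame:
    """Sequential-run stage table: counts, % pass, concordance, Ti/Tv."""
    if not trace.records:
        raise ContractError("empty stage trace")
    df = pd.DataFrame(
        {
            "stage": [r.stage for r in trace.records],
            "criterion": [r.criterion for r in trace.records],
            "unit": [r.unit for r in trace.records],
            "n_pass": [r.n_pass for r in trace.records],
            "pct_pass": [_fmt(r.pct_pass, 2) for r in trace.records],
            "concordance": [_fmt(r.concordance_rate, 3) for r in trace.records],
            "titv": [_fmt(r.titv, 5) for r in trace.records],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def render_ranking(independent_outcomes, path: str | Path | None = None) -> pd.DataFrame:
    """Variant-filter ranking: NPV, specificity, % discordant removed (x100)."""
    if not isinstance(independent_outcomes, dict):
        independent_outcomes = {o.filter_id: o for o in independent_outcomes}
    site_level = {
        fid: o for fid, o in independent_outcomes.items() if o.unit == "sites"
    }
    ranked = rank_filters(site_level)
    rows = []
    for rank, fid in enumerate(ranked, start=1):
        conf = site_level[fid].confusion
        n = npv(conf)
        s = specificity(conf)
        rows.append(
            {
                "rank": rank,
                "filter": fid,
                "npv": UNDEFINED if n is None else format_percent(n),
                "specificity": UNDEFINED if s is None else format_percent(s),
                "pct_discordant_removed": (
                    UNDEFINED if s is None else format_percent(s)
                ),
            }
        )
    df = pd.DataFrame(rows, columns=["rank", "filter", "npv", "specificity", "pct_discordant_removed"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def render_concordance_trajectory(trace, path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "stage": [r.stage for r in trace.records],
            "concordance": [_fmt(r.concordance_rate, 3) for r in trace.records],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def render_titv_table(trace, path: str | Path | None = None) -> pd.DataFrame:
    """Per-stage Ti/Tv with percent change from the previous stage (3 dp)."""
    rows, prev = [], None
    for r in trace.records:
        change = (
            None
            if prev in (None, 0) or r.titv is None
            else 100.0 * (r.titv - prev) / prev
        )
        rows.append(
            {
                "stage": r.stage,
                "titv": _fmt(r.titv, 5),
                "pct_change": UNDEFINED if change is None else f"{change:+.3f}",
            }
        )
        prev = r.titv if r.titv is not None else prev
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def render_thresholds(search_results: dict, d_min: float, path=None) -> pd.DataFrame:
    rows = []
    for param, r in search_results.items():
        thr = (
            f"{r.threshold[0]:.4g},{r.threshold[1]:.4g}"
            if isinstance(r.threshold, tuple)
            else f"{r.threshold:.6g}"
        )
        rows.append(
            {
                "parameter": param,
                "threshold": thr,
                "d_min": d_min,
                "discordant_removed_frac": round(r.discordant_removed_frac, 6),
                "concordant_removed_frac": round(r.concordant_removed_frac, 6),
                "objective": "inf" if r.objective == float("inf") else round(r.objective, 6),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def plot_density_panels(values_by_param: dict, thresholds: dict | None = None, path=None):
    """Three-panel discordant-vs-concordant density figure (one per parameter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .empirical_thresholds import density_estimate

    params = list(values_by_param)
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3.2))
    if len(params) == 1:
        axes = [axes]
    for ax, param in zip(axes, params):
        disc, conc = values_by_param[param]
        for vals, label, color in ((conc, "concordant", "C0"), (disc, "discordant", "C3")):
            curve = density_estimate(vals)
            ax.plot(curve.grid, curve.density, label=label, color=color)
        if thresholds and param in thresholds:
            t = thresholds[param]
            for x in t if isinstance(t, tuple) else (t,):
                ax.axvline(x, ls="--", color="k", lw=0.8)
        ax.set_title(param)
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    inputs: dict[str, dict]  # name -> {path, sha256}
    thresholds: dict
    filter_order: list[str]
    version: str
    seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def create(cls, input_paths: dict, thresholds, seed=None) -> "RunManifest":
        from dataclasses import fields as dc_fields

        from . import __version__

        return cls(
            inputs={
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in input_paths.items()
                if p is not None
            },
            thresholds={
                f.name: getattr(thresholds, f.name)
                for f in dc_fields(thresholds)
                if f.name != "filter_order"
            },
            filter_order=list(thresholds.filter_order),
            version=__version__,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "inputs": self.inputs,
            "thresholds": self.thresholds,
            "filter_order": self.filter_order,
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
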
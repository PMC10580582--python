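"""Run orchestration: result tables, delimited-text exports and plots.

Thin wrappers over the library that write the deliverables of a run — a
cost-effectiveness summary table per population, the tornado table/plot,
PSA scatter and acceptability-curve tables/plots, and per-cycle audit
traces.  Presentation rounding (whole USD, two-decimal QALYs) is applied
only at rendering; machine outputs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, _to_dict
from .engine import POPULATIONS
from .model import run_arm, run_cea
from .reconstruct import DigitizedCurve, RiskTable, km_estimate, reconstruct_ipd, select_distribution
from .sensitivity import ceac, owsa, psa_run

logger = logging.getLogger("psmcea")

__all__ = [
    "config_hash",
    "run_base_case",
    "run_owsa",
    "run_psa",
    "run_reconstruction",
]


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of a configuration, for run logging."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _log_run(cfg: RunConfig, what: str, seed=None) -> None:
    logger.info(
        "%s | psmcea %s | config %s | seed %s",
        what,
        __version__,
        config_hash(cfg),
        seed if seed is not None else "-",
    )


def run_base_case(
    cfg: RunConfig, populations=POPULATIONS, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Deterministic comparison per population, as a summary table.

    One row per arm plus an incremental row, per population: life-years,
    total cost, QALYs, and the ICER.  When ``outdir`` is given the summary,
    and per-arm cycle traces, are written as tab-separated text.
    """
    _log_run(cfg, f"base case, populations {','.join(populations)}")
    rows = []
    for pop in populations:
        res = run_cea(cfg, pop)
        for arm in ("NI", "C"):
            rows.append(
                {
                    "population": pop,
                    "strategy": arm,
                    "life_years": res.ly[arm],
                    "total_cost": res.cost[arm],
                    "qalys": res.qaly[arm],
                    "icer": np.nan,
                }
            )
        rows.append(
            {
                "population": pop,
                "strategy": "incremental (NI vs. C)",
                "life_years": res.ly["NI"] - res.ly["C"],
                "total_cost": res.delta_cost,
                "qalys": res.delta_qaly,
                "icer": res.icer,
            }
        )
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "base_case.tsv", sep="\t", index=False)
        for pop in populations:
            for arm in ("NI", "C"):
                _, trace, costs = run_arm(cfg, arm, pop)
                audit = trace.to_frame().join(
                    costs.to_frame().drop(columns="time_months"),
                    rsuffix="_cost",
                )
                audit.to_csv(outdir / f"trace_{pop}_{arm}.tsv", sep="\t", index=False)
    return table


def format_base_case(table: pd.DataFrame) -> str:
    """Publication-style rendering: whole USD, 2-decimal LY/QALY/ICER."""
    shown = table.copy()
    shown["life_years"] = shown["life_years"].map(lambda v: f"{v:.2f}")
    shown["total_cost"] = shown["total_cost"].map(lambda v: f"{v:,.0f}")
    shown["qalys"] = shown["qalys"].map(lambda v: f"{v:.2f}")
    shown["icer"] = shown["icer"].map(
        lambda v: "" if pd.isna(v) else f"{v:,.0f}"
    )
    return shown.to_string(index=False)


def run_owsa(
    cfg: RunConfig, population: str, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Tornado table (and plot when ``outdir`` is given) for one population."""
    _log_run(cfg, f"one-way sensitivity analysis, population {population}")
    rows = owsa(cfg, population)
    table = pd.DataFrame(
        [
            {
                "parameter": r.param_id,
                "base": r.base,
                "low": r.low,
                "high": r.high,
                "icer_at_low": r.icer_at_low,
                "icer_at_high": r.icer_at_high,
                "spread": r.spread,
            }
            for r in rows
        ]
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"tornado_{population}.tsv", sep="\t", index=False)
        _tornado_plot(table, cfg, population, outdir / f"tornado_{population}.png")
    return table


def _tornado_plot(table: pd.DataFrame, cfg: RunConfig, population: str, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = table.head(15).iloc[::-1]
    base_icer = run_cea(cfg, population).icer
    fig, ax = plt.subplots(figsize=(8, 6))
    for i, (_, r) in enumerate(top.iterrows()):
        lo, hi = sorted((r["icer_at_low"], r["icer_at_high"]))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(top)))
    ax.set_yticklabels(top["parameter"])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.set_title(f"One-way sensitivity analysis, population {population}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_psa(
    cfg: RunConfig,
    population: str,
    n_iter: int | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
):
    """PSA samples plus the acceptability curve for one population.

    Returns ``(samples, ceac_table)``; with ``outdir``, writes both as
    tab-separated text along with scatter and CEAC plots.
    """
    seed = seed if seed is not None else cfg.psa_seed
    _log_run(cfg, f"probabilistic sensitivity analysis, population {population}", seed)
    samples = psa_run(cfg, population, n_iter=n_iter, seed=seed)
    curve = ceac(samples)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples.to_csv(outdir / f"psa_samples_{population}.tsv", sep="\t", index=False)
        curve.to_csv(outdir / f"ceac_{population}.tsv", sep="\t", index=False)
        _psa_plots(samples, curve, cfg, population, outdir)
    return samples, curve


def _psa_plots(samples, curve, cfg, population, outdir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(samples["delta_qaly"], samples["delta_cost"], s=8, alpha=0.5)
    wtp = cfg.engine.wtp
    q = np.linspace(
        min(0, samples["delta_qaly"].min()), samples["delta_qaly"].max() * 1.05, 50
    )
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP {wtp:,.0f} USD/QALY")
    ax.set_xlabel("incremental QALYs (NI vs. C)")
    ax.set_ylabel("incremental cost (USD)")
    ax.set_title(f"PSA scatter, population {population}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / f"psa_scatter_{population}.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(curve["wtp"], curve["probability"])
    ax.axvline(wtp, color="k", ls="--", lw=1)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability NI cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"Cost-effectiveness acceptability, population {population}")
    fig.tight_layout()
    fig.savefig(outdir / f"ceac_{population}.png", dpi=120)
    plt.close(fig)


def run_reconstruction(
    curve_path, risk_path=None, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from digitized-curve files and rank the fits.

    Reads delimited text (columns time, survival / time, n_at_risk), runs
    the reconstruction, and returns the six-family AIC/BIC ranking table.
    With ``outdir``, writes the pseudo-IPD and the ranking as text.
    """
    curve = DigitizedCurve.read(curve_path)
    risk = RiskTable.read(risk_path) if risk_path is not None else None
    ipd = reconstruct_ipd(curve, risk)
    fits = select_distribution(ipd)
    table = pd.DataFrame(
        [
            {
                "family": f.distribution.family,
                "lambda": f.distribution.lambda_,
                "gamma": f.distribution.gamma_,
                "log_likelihood": f.log_likelihood,
                "aic": f.aic,
                "bic": f.bic,
            }
            for f in fits
        ]
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ipd.write(outdir / "pseudo_ipd.tsv")
        table.to_csv(outdir / "fit_ranking.tsv", sep="\t", index=False)
    return table


def setup_logging(verbose: bool = False) -> None:
    """Log to standard error; DEBUG when verbose."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
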
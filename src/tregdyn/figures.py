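"""Reproduction pipelines for the headline diagrams.

Each tag runs the documented analysis, writes the underlying numbers as
CSV (the quantitative artifact) and a vector plot of the diagram
structure: equilibrium branches in black (stable) and red (non-stable),
oscillation envelopes as dashed lines, regime maps as region labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bifurcation as bf
from .config import provenance
from .continuation import continue_branch
from .equilibria import c_minus, k_minus
from .params import ParameterSet, table1

__all__ = ["reproduce_figure", "FIGURE_TAGS"]

log = logging.getLogger(__name__)

FIGURE_TAGS = ("fig3b", "fig4a", "fig4b", "fig5a", "fig5b", "fig6")


def _branch_frame(branches):
    rows = []
    for i, br in enumerate(branches):
        names = None
        for alpha, q in br.samples:
            if names is None:
                from .models import get_model
                names = get_model(q.model_id).names
            row = {"branch": i, "parameter": br.parameter_name,
                   "value": alpha}
            row |= {n: float(v) for n, v in zip(names, q.state)}
            row |= {"stability": q.stability, "label": q.label,
                    "residual": q.residual}
            rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, p: ParameterSet, **extra):
    meta = provenance(p, **extra)
    with path.open("w") as fh:
        fh.write("# " + ", ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=False)


def _plot_branches(ax, branches, cycles=None):
    for br in branches:
        a = br.parameter_values
        T = br.T_values
        stable = np.array([s == "stable" for s in br.stabilities])
        ax.plot(np.where(stable, a, np.nan), np.where(stable, T, np.nan),
                "k-", lw=1.5)
        ax.plot(np.where(~stable, a, np.nan), np.where(~stable, T, np.nan),
                "r-", lw=1.0)
    if cycles:
        ks = [c.k for c in cycles]
        ax.plot(ks, [c.T_max for c in cycles], "k--", lw=1.0)
        ax.plot(ks, [c.T_min for c in cycles], "k--", lw=1.0)


def reproduce_figure(tag: str, outdir: str | Path = ".",
                     p: ParameterSet | None = None,
                     fast: bool = False) -> dict[str, Path]:
    """Run one diagram pipeline; returns the paths written.

    ``fast`` shrinks grids for smoke testing; the published-quality run is
    the default. The oscillation-regime diagrams also print the
    thresholds (k_i, k_s, lambda_th) they are built from.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if tag not in FIGURE_TAGS:
        raise ValueError(f"unknown figure tag {tag!r}; choose from {FIGURE_TAGS}")
    p = table1() if p is None else p
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{tag}.csv"
    svg_path = outdir / f"{tag}.svg"
    fig, ax = plt.subplots(figsize=(5, 4))

    if tag == "fig3b":
        km = k_minus(p)
        branches, specials = continue_branch("reduced4", p, "k",
                                             (0.0, 1.5 * km))
        _plot_branches(ax, branches)
        for sp in specials:
            ax.axvline(sp.parameter_value, color="0.7", ls=":")
        ax.set(xlabel="T cell activation k", ylabel="activated T cells T",
               title=f"influx-driven T/IL-2 system; fold at k={km:.4g}")
        _write_csv(_branch_frame(branches), csv_path, p, k_minus=km)
        print(f"fold (closed form) k- = {km:.6g}")
        if specials:
            print(f"fold (continuation) k = {specials[0].parameter_value:.6g}")

    elif tag == "fig4a":
        cm = c_minus(p)
        branches, specials = continue_branch(
            "reduced10", p, "c", (cm * 1e-3, 2.0 * cm), k=0.0)
        # drop the trivial T=0 branch: the diagram shows the saturated pair
        branches = [b for b in branches if np.max(np.abs(b.T_values)) > 1.0]
        _plot_branches(ax, branches)
        ax.set(xlabel="fratricide rate c", ylabel="activated T cells T",
               yscale="log",
               title=f"saturated branch fold at c={cm:.4g}")
        _write_csv(_branch_frame(branches), csv_path, p, c_minus=cm)
        print(f"fratricide threshold (closed form) c- = {cm:.6g}")

    elif tag == "fig4b":
        branches, specials = continue_branch("reduced10", p, "k", (0.0, 1.5))
        _plot_branches(ax, branches)
        ax.set(xlabel="T cell activation k", ylabel="activated T cells T",
               yscale="symlog",
               title="fratricide model: bistability and hysteresis")
        _write_csv(_branch_frame(branches), csv_path, p)

    elif tag in ("fig5a", "fig5b"):
        lam = 0.02 if tag == "fig5a" else 0.006
        lam_th = bf.find_lambda_th(p)
        print(f"lambda_th = {lam_th:.5g}")
        branches, specials = continue_branch("reduced13", p, "k",
                                             (0.0, 4.5), lam=lam)
        cycles = []
        if lam < lam_th:
            thr = bf.find_k_thresholds(p, lam)
            print(f"k_i = {thr.k_i:.5g}  k_s = {thr.k_s:.5g}  "
                  f"(fold {thr.k_fold:.5g}, Hopf {thr.k_hopf:.5g})")
            n_k = 6 if fast else 16
            grid = np.geomspace(thr.k_i * 1.05, thr.k_s * 0.97, n_k)
            cycles = bf.scan_limit_cycles(p, lam, grid)
        _plot_branches(ax, branches, cycles)
        ax.set(xlabel="T cell activation k", ylabel="activated T cells T",
               yscale="symlog", title=f"Treg model, lam={lam}")
        df = _branch_frame(branches)
        df_c = pd.DataFrame([c.__dict__ for c in cycles])
        _write_csv(df, csv_path, p, lam=lam, lambda_th=lam_th)
        if not df_c.empty:
            _write_csv(df_c, outdir / f"{tag}_cycles.csv", p, lam=lam)

    elif tag == "fig6":
        lam_th = bf.find_lambda_th(p)
        print(f"lambda_th = {lam_th:.5g}")
        n_lam, n_n0 = (4, 5) if fast else (10, 12)
        lam_grid = np.geomspace(0.002, 0.02, n_lam)
        n0_grid = np.geomspace(0.2, 8.0, n_n0)
        reports = bf.regime_map(p, lam_grid, n0_grid, lambda_th=lam_th)
        df = pd.DataFrame([r.__dict__ for r in reports])
        _write_csv(df, csv_path, p, lambda_th=lam_th)
        colors = {"A": "0.6", "B": "tab:blue", "C": "tab:orange",
                  "D": "tab:green"}
        for r in reports:
            region = r.regime.split("(")[-1].rstrip(")")
            ax.scatter(r.lam, r.N0, c=colors[region], s=30, marker="s")
        ax.axvline(lam_th, color="k", ls=":")
        ax.set(xlabel="relative Treg renewal lam",
               ylabel="naive renewal N0", xscale="log", yscale="log",
               title="response regions A-D")

    fig.tight_layout()
    fig.savefig(svg_path)
    plt.close(fig)
    return {"csv": csv_path, "svg": svg_path}
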
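"""Human-readable summaries of analysis outputs.

Builds a markdown report (plus density-landscape figures) from the CSV/JSON
artifacts the CLI stages write: per-system sampling-density panels with
marginals, the potency table with flags, the excluded-replicate manifest and
the variant proximity table. Missing stages are marked as gaps rather than
failing the whole report.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["density_figure", "write_report"]


def density_figure(x: np.ndarray, y: np.ndarray, out_path: str | Path,
                   x_label: str = "HP2 opening (Å)",
                   y_label: str = "ligand RMSD (Å)",
                   title: str = "") -> Path:
    """2D sampling-density panel with 1D marginals (histogram estimator)."""
    from .trajectory import sampling_density

    dm = sampling_density(np.asarray(x), np.asarray(y))
    fig = plt.figure(figsize=(5, 5))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    ax.pcolormesh(dm.x_edges, dm.y_edges, dm.density.T, cmap="viridis")
    cx = 0.5 * (dm.x_edges[:-1] + dm.x_edges[1:])
    cy = 0.5 * (dm.y_edges[:-1] + dm.y_edges[1:])
    ax_top.fill_between(cx, dm.marginal_x, color="#44a", alpha=0.6)
    ax_right.fill_betweenx(cy, dm.marginal_y, color="#44a", alpha=0.6)
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    if title:
        ax_top.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def _section_density(results_dir: Path, lines: list[str],
                     figures_dir: Path) -> None:
    csvs = sorted(results_dir.glob("*density_pool.csv"))
    if not csvs:
        lines.append("*(no trajectory-density output found)*\n")
        return
    for csv in csvs:
        pool = pd.read_csv(csv)
        system = pool["system"].iloc[0] if "system" in pool else csv.stem
        fig_path = figures_dir / f"{csv.stem}.png"
        density_figure(pool["hp2_opening"], pool["ligand_rmsd"], fig_path,
                       title=str(system))
        lines.append(f"### {system}\n")
        lines.append(f"- frames pooled: {len(pool)}")
        lines.append(f"- HP2 opening mean: {pool['hp2_opening'].mean():.2f} Å")
        lines.append(f"- ligand RMSD mean: {pool['ligand_rmsd'].mean():.2f} Å")
        lines.append(f"- density panel: `{fig_path.name}`\n")


def _section_exclusions(results_dir: Path, lines: list[str]) -> None:
    manifest = results_dir / "exclusions.json"
    if not manifest.exists():
        lines.append("*(no exclusion manifest found)*\n")
        return
    data = json.loads(manifest.read_text())
    excluded = data.get("excluded", [])
    if not excluded:
        lines.append("No (replicate, chain) systems excluded.\n")
    else:
        for item in excluded:
            lines.append(f"- replicate {item['replicate']}, chain {item['chain']} "
                         f"(max protein RMSD {item['max_rmsd_A']:.1f} Å)")
        lines.append("")


def _section_potency(results_dir: Path, lines: list[str]) -> None:
    csvs = sorted(results_dir.glob("*potency.csv"))
    if not csvs:
        lines.append("*(no potency output found)*\n")
        return
    for csv in csvs:
        df = pd.read_csv(csv)
        lines.append(f"### {csv.stem}\n")
        lines.append(df.to_markdown(index=False))
        lines.append("")


def _section_variants(results_dir: Path, lines: list[str]) -> None:
    prox = results_dir / "proximity_sets.csv"
    ddg = results_dir / "ddg_classification.csv"
    if not prox.exists() and not ddg.exists():
        lines.append("*(no variant output found)*\n")
        return
    if prox.exists():
        lines.append("### Ligand-site proximity\n")
        lines.append(pd.read_csv(prox).to_markdown(index=False))
        lines.append("")
    if ddg.exists():
        lines.append("### ΔΔG classification\n")
        lines.append(pd.read_csv(ddg).to_markdown(index=False))
        lines.append("")


def write_report(results_dir: str | Path, out_path: str | Path | None = None) -> Path:
    """Assemble a markdown summary from the artifacts in ``results_dir``."""
    results_dir = Path(results_dir)
    if not results_dir.exists() or not any(results_dir.iterdir()):
        raise FileNotFoundError(f"no results found in {results_dir}")
    out_path = Path(out_path) if out_path else results_dir / "report.md"
    figures_dir = out_path.parent
    figures_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# EAAT1 variant analysis report\n",
                        "## Conformational sampling density\n"]
    _section_density(results_dir, lines, figures_dir)
    lines.append("## Excluded unstable systems\n")
    _section_exclusions(results_dir, lines)
    lines.append("## Potency table\n")
    _section_potency(results_dir, lines)
    lines.append("## Variant classification\n")
    _section_variants(results_dir, lines)
    out_path.write_text("\n".join(lines))
    return out_path
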
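"""Per-chain stability and gating metrics from MD-style trajectories.

The analysis mirrors a transporter-gating workflow: each chain of a trimeric
system is fitted to the first frame on its protein Cα atoms, then per-frame
metrics are computed — protein Cα RMSD, ligand RMSD in the protein frame of
reference, per-residue Cα RMSF, and four anchor-pair distances (HP2 gate
opening between the HP1 and HP2 hairpin tips, and each Na+ ion against a
fixed coordinating Cα). Chains whose protein RMSD reaches 10 Å at any frame
are excluded from pooled analyses. Pooled metrics feed 2D sampling-density
landscapes and the selection of representative frames at the most frequent
gate opening for ensemble docking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, SelectionError
from .structure import StructureModel, Trajectory, kabsch_batch, write_pdb

__all__ = [
    "MetricSeries",
    "DensityMap",
    "FrameSelection",
    "ANCHOR_PRESETS",
    "fit_trajectory",
    "protein_rmsd",
    "ligand_rmsd",
    "rmsf",
    "pair_distance",
    "flag_unstable",
    "compute_chain_metrics",
    "metrics_to_frame",
    "pool_metric",
    "sampling_density",
    "select_representative_frames",
    "export_selected_frames",
]

#: Anchor pairs (residue_number, atom_name) for the four gating/ion metrics.
#: The HP2 opening is the distance between the HP1-tip Cα (S366) and the
#: HP2-tip Cα (G442); the Na1/Na2/Na3 metrics track each ion (residue
#: numbers 601/603/602) against its coordinating Cα (D487/T396/D400).
ANCHOR_PRESETS: dict[str, tuple[tuple[int, str], tuple[int, str]]] = {
    "hp2_opening": ((366, "CA"), (442, "CA")),
    "na1_dist": ((601, "NA"), (487, "CA")),
    "na2_dist": ((603, "NA"), (396, "CA")),
    "na3_dist": ((602, "NA"), (400, "CA")),
}

RMSD_EXCLUDE_THRESHOLD_A = 10.0


@dataclass
class MetricSeries:
    """One scalar metric per frame for a (system, replicate, chain)."""

    system_label: str
    replicate_id: int
    chain_id: str
    metric_name: str
    values: np.ndarray
    dt_ps: float = 500.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("metric values must be one scalar per frame")

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt_ps


def _anchor_index(top: StructureModel, chain: str, residue_number: int,
                  atom_name: str) -> int:
    """Resolve an anchor atom; ions are searched across chains if absent
    from the requested one (monotopic ions carry their own chain label in
    some files)."""
    idx = top.indices_where(chain=chain, residue_number=residue_number,
                            atom_name=atom_name)
    if len(idx) == 0 and atom_name == "NA":
        idx = top.indices_where(residue_number=residue_number, atom_name=atom_name)
    if len(idx) == 0:
        raise SelectionError(
            f"anchor (chain={chain!r}, residue={residue_number}, "
            f"atom={atom_name!r}) not found")
    if len(idx) > 1:
        raise IntegrityError(
            f"anchor (chain={chain!r}, residue={residue_number}, "
            f"atom={atom_name!r}) is ambiguous ({len(idx)} matches)")
    return int(idx[0])


def fit_trajectory(traj: Trajectory, chain: str | None = None,
                   fit_subset: np.ndarray | None = None) -> Trajectory:
    """Superpose every frame onto frame 0 to remove rotations/translations.

    The fit subset defaults to the protein Cα atoms of ``chain`` (all chains
    if None); the transform is applied to all atoms of each frame.
    """
    if fit_subset is None:
        fit_subset = traj.topology.protein_ca_indices(chain=chain)
        if len(fit_subset) == 0:
            raise SelectionError(f"no protein CA atoms in chain {chain!r}")
    fitted = kabsch_batch(traj.frames, traj.frames[0], fit_subset=fit_subset)
    return Trajectory(topology=traj.topology, frames=fitted, dt_ps=traj.dt_ps,
                      replicate_id=traj.replicate_id,
                      system_label=traj.system_label)


def _rmsd_series(frames: np.ndarray, idx: np.ndarray) -> np.ndarray:
    ref = frames[0][idx]
    delta = frames[:, idx, :] - ref[None, :, :]
    return np.sqrt(np.mean(np.sum(delta ** 2, axis=2), axis=1))


def protein_rmsd(traj: Trajectory, chain: str) -> MetricSeries:
    """Per-frame RMSD of the chain's protein Cα atoms vs frame 0.

    The trajectory is expected to be fitted already (see
    :func:`fit_trajectory`); the value at frame 0 is exactly 0.
    """
    idx = traj.topology.protein_ca_indices(chain=chain)
    if len(idx) == 0:
        raise SelectionError(f"chain {chain!r} has no protein CA atoms")
    return MetricSeries(traj.system_label, traj.replicate_id, chain,
                        "protein_rmsd", _rmsd_series(traj.frames, idx),
                        traj.dt_ps)


def ligand_rmsd(traj: Trajectory, chain: str, residue_name: str = "ASP",
                residue_number: int | None = None) -> MetricSeries:
    """Per-frame ligand heavy-atom RMSD vs frame 0 in the protein frame.

    No re-fitting is done on the ligand: with the trajectory superposed on
    the chain's protein Cα atoms this measures ligand motion relative to the
    protein. Hydrogens are excluded.
    """
    idx = traj.topology.indices_where(chain=chain, residue_name=residue_name,
                                      residue_number=residue_number, hetero=True)
    heavy = [i for i in idx
             if not str(traj.topology.atom_names[i]).strip().startswith("H")]
    if len(heavy) == 0:
        raise SelectionError(
            f"no ligand atoms (chain={chain!r}, residue_name={residue_name!r})")
    return MetricSeries(traj.system_label, traj.replicate_id, chain,
                        "ligand_rmsd",
                        _rmsd_series(traj.frames, np.asarray(heavy)),
                        traj.dt_ps)


def rmsf(traj: Trajectory, chain: str) -> pd.DataFrame:
    """Per-residue Cα RMSF: √(time-mean squared deviation from the time-mean
    position). Returns a DataFrame (chain_id, residue_number, rmsf_A)."""
    if traj.n_frames < 2:
        raise DomainError("RMSF needs at least 2 frames")
    idx = traj.topology.protein_ca_indices(chain=chain)
    if len(idx) == 0:
        raise SelectionError(f"chain {chain!r} has no protein CA atoms")
    xyz = traj.frames[:, idx, :]
    mean_pos = xyz.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((xyz - mean_pos[None]) ** 2, axis=2), axis=0))
    return pd.DataFrame({
        "chain_id": chain,
        "residue_number": traj.topology.residue_numbers[idx],
        "rmsf_A": fluct,
    })


def pair_distance(traj: Trajectory, chain: str,
                  anchor_a: tuple[int, str], anchor_b: tuple[int, str],
                  metric_name: str = "pair_distance") -> MetricSeries:
    """Euclidean distance per frame between two anchor atoms of a chain.

    Presets for the four gating/ion metrics live in :data:`ANCHOR_PRESETS`,
    e.g. ``pair_distance(traj, "A", *ANCHOR_PRESETS["hp2_opening"],
    metric_name="hp2_opening")``.
    """
    ia = _anchor_index(traj.topology, chain, *anchor_a)
    ib = _anchor_index(traj.topology, chain, *anchor_b)
    delta = traj.frames[:, ia, :] - traj.frames[:, ib, :]
    return MetricSeries(traj.system_label, traj.replicate_id, chain,
                        metric_name, np.linalg.norm(delta, axis=1), traj.dt_ps)


def flag_unstable(series: MetricSeries | np.ndarray,
                  threshold_A: float = RMSD_EXCLUDE_THRESHOLD_A) -> bool:
    """True (exclude) iff the protein RMSD reaches the threshold at any frame.

    "Reaching" is interpreted as >=; exclusion granularity is one
    (replicate, chain).
    """
    values = series.values if isinstance(series, MetricSeries) else np.asarray(series)
    if values.size == 0:
        raise DomainError("empty RMSD series")
    return bool(np.max(values) >= threshold_A)


def compute_chain_metrics(traj: Trajectory, chain: str,
                          ligand_residue_name: str = "ASP",
                          include_ions: bool = True) -> dict[str, MetricSeries]:
    """Fit on the chain's Cα atoms and compute the full per-chain metric set."""
    fitted = fit_trajectory(traj, chain=chain)
    metrics: dict[str, MetricSeries] = {
        "protein_rmsd": protein_rmsd(fitted, chain),
        "ligand_rmsd": ligand_rmsd(fitted, chain, residue_name=ligand_residue_name),
        "hp2_opening": pair_distance(fitted, chain,
                                     *ANCHOR_PRESETS["hp2_opening"],
                                     metric_name="hp2_opening"),
    }
    if include_ions:
        for name in ("na1_dist", "na2_dist", "na3_dist"):
            metrics[name] = pair_distance(fitted, chain, *ANCHOR_PRESETS[name],
                                          metric_name=name)
    return metrics


def metrics_to_frame(series: Iterable[MetricSeries]) -> pd.DataFrame:
    """Long-format table: system, replicate, chain, metric, frame, time_ps,
    value."""
    rows = []
    for s in series:
        n = len(s.values)
        rows.append(pd.DataFrame({
            "system": s.system_label,
            "replicate": s.replicate_id,
            "chain": s.chain_id,
            "metric": s.metric_name,
            "frame": np.arange(n),
            "time_ps": s.times_ps,
            "value": s.values,
        }))
    if not rows:
        return pd.DataFrame(columns=["system", "replicate", "chain", "metric",
                                     "frame", "time_ps", "value"])
    return pd.concat(rows, ignore_index=True)


def pool_metric(metrics_df: pd.DataFrame, metric: str,
                chain: str | None = None,
                excluded: set[tuple[int, str]] | None = None) -> pd.DataFrame:
    """Pool one metric over all non-excluded (replicate, chain) series.

    ``excluded`` holds (replicate, chain) pairs flagged by the RMSD rule.
    Returns rows (replicate, chain, frame, value) aligned by frame.
    """
    df = metrics_df[metrics_df["metric"] == metric]
    if chain is not None:
        df = df[df["chain"] == chain]
    if excluded:
        mask = ~df.apply(lambda r: (int(r["replicate"]), str(r["chain"])) in excluded,
                         axis=1)
        df = df[mask]
    return df[["replicate", "chain", "frame", "value"]].reset_index(drop=True)


@dataclass
class DensityMap:
    """Normalized 2D sampling density with 1D marginals.

    ``density`` integrates to 1 over the grid (bin mass × area sums to 1);
    marginals likewise integrate to 1 along their own axis.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray
    marginal_x: np.ndarray
    marginal_y: np.ndarray
    n_points: int


def sampling_density(x: np.ndarray, y: np.ndarray,
                     bins: int | tuple[int, int] = 60) -> DensityMap:
    """Normalized 2D histogram density of two per-frame metrics.

    Pools must already contain only non-excluded chains; an empty pool is an
    error (it usually means the exclusion threshold removed everything).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("empty metric pool: review the exclusion threshold")
    if x.shape != y.shape:
        raise ValueError("x and y pools must be frame-aligned (equal length)")
    density, x_edges, y_edges = np.histogram2d(x, y, bins=bins, density=True)
    mx, _ = np.histogram(x, bins=x_edges, density=True)
    my, _ = np.histogram(y, bins=y_edges, density=True)
    return DensityMap(x_edges=x_edges, y_edges=y_edges, density=density,
                      marginal_x=mx, marginal_y=my, n_points=int(x.size))


@dataclass
class FrameSelection:
    """Representative frames at the most frequent value of a pooled metric."""

    frames: list[tuple[int, str, int]]  # (replicate, chain, frame)
    values_A: np.ndarray
    mean_A: float
    sd_A: float
    mode_A: float
    window_A: tuple[float, float]
    widened: bool = False

    def to_dict(self) -> dict:
        return {
            "frames": [{"replicate": r, "chain": c, "frame": f}
                       for r, c, f in self.frames],
            "values_A": [float(v) for v in self.values_A],
            "mean_A": self.mean_A,
            "sd_A": self.sd_A,
            "mode_A": self.mode_A,
            "window_A": list(self.window_A),
            "widened": self.widened,
        }


def _fd_edges(values: np.ndarray) -> np.ndarray:
    edges = np.histogram_bin_edges(values, bins="fd")
    if len(edges) < 3:  # degenerate spread; fall back to a single-bin window
        lo, hi = float(values.min()), float(values.max())
        pad = max(1e-6, 0.05 * max(hi - lo, 1e-6))
        edges = np.array([lo - pad, (lo + hi) / 2.0, hi + pad])
    return edges


def select_representative_frames(pool: pd.DataFrame, k: int = 5,
                                 seed: int | np.random.Generator = 0) -> FrameSelection:
    """Pick ``k`` random frames at the most frequent value of a pooled metric.

    The distribution mode is estimated from a histogram with
    Freedman–Diaconis bin width; the selection window is the highest bin.
    Frames whose value lies in the window are sampled uniformly without
    replacement (seeded). If the window holds fewer than ``k`` frames it is
    widened once by one bin on each side; failing that, an error is raised.
    Reported mean ± sd are over the selected frames' values.
    """
    if not {"replicate", "chain", "frame", "value"} <= set(pool.columns):
        raise ValueError("pool must have columns replicate, chain, frame, value")
    values = pool["value"].to_numpy(dtype=float)
    if values.size == 0:
        raise DomainError("empty metric pool")
    if k < 1:
        raise DomainError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges = _fd_edges(values)
    counts, _ = np.histogram(values, bins=edges)
    mode_bin = int(np.argmax(counts))
    lo, hi = float(edges[mode_bin]), float(edges[mode_bin + 1])
    mode = 0.5 * (lo + hi)

    def in_window(a: float, b: float) -> np.ndarray:
        # np.histogram closes the right edge only on the last bin
        if np.isclose(b, edges[-1]):
            return np.flatnonzero((values >= a) & (values <= b))
        return np.flatnonzero((values >= a) & (values < b))

    widened = False
    candidates = in_window(lo, hi)
    if len(candidates) < k:
        widened = True
        lo = float(edges[max(mode_bin - 1, 0)])
        hi = float(edges[min(mode_bin + 2, len(edges) - 1)])
        candidates = in_window(lo, hi)
        if len(candidates) < k:
            raise DomainError(
                f"only {len(candidates)} frames in the widened mode window; "
                f"cannot select {k}")
    chosen = rng.choice(candidates, size=k, replace=False)
    chosen_vals = values[chosen]
    frames = [(int(pool["replicate"].iloc[i]), str(pool["chain"].iloc[i]),
               int(pool["frame"].iloc[i])) for i in chosen]
    return FrameSelection(
        frames=frames,
        values_A=chosen_vals,
        mean_A=float(np.mean(chosen_vals)),
        sd_A=float(np.std(chosen_vals, ddof=1)) if k > 1 else 0.0,
        mode_A=mode,
        window_A=(lo, hi),
        widened=widened,
    )


def export_selected_frames(selection: FrameSelection,
                           trajectories: dict[int, Trajectory],
                           out_dir: str | Path, chain: str = "A",
                           ion_residue_numbers: Sequence[int] = (601, 602, 603),
                           ) -> list[Path]:
    """Write each selected frame as a single-model PDB containing the chain's
    protein atoms plus the originally coordinated Na+ ions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for replicate, chain_id, frame in selection.frames:
        if chain_id != chain:
            continue
        traj = trajectories[replicate]
        model = traj.frame_model(frame)
        keep = (model.chain_ids == chain) & ~model.hetero
        for rn in ion_residue_numbers:
            ion = (model.residue_numbers == rn) & (model.atom_names == "NA")
            # ions belonging to this chain (or chain-agnostic fixtures)
            keep |= ion & (model.chain_ids == chain)
        sub = model.subset(keep, label=f"{traj.system_label}_rep{replicate}_frame{frame}")
        path = out_dir / f"{traj.system_label}_rep{replicate}_frame{frame}_chain{chain}.pdb"
        write_pdb(sub, path)
        paths.append(path)
    return paths
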
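"""Synthetic-data generators with controllable ground truth.

Every generator is a statistical inverse of an analysis stage: trajectories
are built so the gate-distance, RMSD and exclusion analyses recover planted
parameters; plates are built by inverting the Cell Index formula so the
impedance pipeline recovers planted potencies; variant tables carry a known
number of unique missense changes. All randomness flows from one seed and
re-runs are bit-identical.

The toy trimer is a ~40-residue Cα scaffold per chain carrying the anchor
residues the gating metrics address (366, 396, 400, 442, 487), a 4-atom
ligand (residue ASP 500) and three Na+ ions (601-603). It is sufficient for
every metric's anchors, not a physically realistic transporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .assay import (
    Condition,
    Plate,
    ROLE_INHIBITOR_SUBSTRATE,
    ROLE_REFERENCE,
    ROLE_SUBSTRATE,
    ROLE_VEHICLE,
    WellTrace,
)
from .structure import StructureModel, Trajectory

__all__ = [
    "TrajectoryGenSpec",
    "PlateGenSpec",
    "gen_trajectory",
    "gen_plate",
    "gen_variant_table",
    "RESPONSE_TAU_MIN",
    "response_auc_per_unit_amplitude",
]

_CHAIN_RESIDUES = (tuple(range(360, 372)) + tuple(range(390, 405))
                   + tuple(range(438, 448)) + tuple(range(485, 489)))
_LIGAND_RESID = 500
_ION_RESIDS = {"na1": 601, "na3": 602, "na2": 603}

_THREE_LETTER = {366: "SER", 396: "THR", 400: "ASP", 442: "GLY", 487: "ASP"}


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryGenSpec:
    """Ground truth for a set of replicate trimer trajectories.

    ``gate_mean_A``/``gate_sd_A`` set the per-frame Gaussian of the HP2
    tip-to-tip distance; ``unstable_replicates`` get a growing internal
    deformation whose protein Cα RMSD crosses 10 Å; ``ligand_mode`` is
    'stable' (ligand co-moves with the protein) or 'drift' (cumulative
    random walk at ``ligand_drift_rate`` Å per ns of simulated time).
    """

    n_frames: int = 500
    dt_ps: float = 500.0
    chains: tuple[str, ...] = ("A", "B", "C")
    n_replicates: int = 10
    gate_mean_A: float = 6.0
    gate_sd_A: float = 0.2
    ligand_mode: str = "stable"
    ligand_drift_rate: float = 0.5
    unstable_replicates: frozenset[int] = frozenset()
    ion_escape: tuple[str, int] | None = None
    jitter_A: float = 0.05
    seed: int = 0
    system_label: str = "WT"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.gate_sd_A < 0:
            raise ValueError("gate_sd_A must be >= 0")
        if self.gate_mean_A <= 0:
            raise ValueError("gate_mean_A must be positive")
        if self.ligand_mode not in ("stable", "drift"):
            raise ValueError(f"unknown ligand_mode {self.ligand_mode!r}")
        if self.ion_escape is not None and self.ion_escape[0] not in _ION_RESIDS:
            raise ValueError("ion_escape site must be one of na1/na2/na3")
        bad = [r for r in self.unstable_replicates
               if not 1 <= r <= self.n_replicates]
        if bad:
            raise ValueError(f"unstable replicate ids out of range: {bad}")


def _chain_scaffold(chain_id: str, chain_index: int) -> tuple[list, np.ndarray]:
    """Base atom identities and coordinates for one chain of the toy trimer."""
    ids = []
    coords = []
    # loose helix: 1.5 A rise, 100 deg turn, radius 2.3 A
    for i, resid in enumerate(_CHAIN_RESIDUES):
        theta = np.deg2rad(100.0 * i)
        coords.append([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        ids.append((chain_id, resid, _THREE_LETTER.get(resid, "ALA"), "CA", False))
    coords = np.array(coords, dtype=float)
    by_resid = {resid: coords[i] for i, resid in enumerate(_CHAIN_RESIDUES)}
    # ligand: 4 heavy atoms near the 396-404 stretch
    lig_center = np.mean([by_resid[r] for r in (396, 400, 404)], axis=0) + [3.0, 0.0, 0.0]
    lig_offsets = np.array([[0, 0, 0], [1.4, 0, 0], [0.7, 1.2, 0], [0.7, -1.2, 0.5]])
    for name, off in zip(("C1", "C2", "O1", "N1"), lig_offsets):
        coords = np.vstack([coords, lig_center + off])
        ids.append((chain_id, _LIGAND_RESID, "ASP", name, True))
    # Na+ ions next to their coordinating CA
    for site, near in (("na1", 487), ("na3", 400), ("na2", 396)):
        pos = by_resid[near] + np.array([2.5, 0.5, 0.0])
        coords = np.vstack([coords, pos])
        ids.append((chain_id, _ION_RESIDS[site], "NA", "NA", True))
    # place the chain on the trimer ring (radius 30 A, 120 deg apart)
    ang = np.deg2rad(120.0 * chain_index)
    rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                    [np.sin(ang), np.cos(ang), 0],
                    [0, 0, 1]])
    coords = coords @ rot.T + np.array([30.0 * np.cos(ang), 30.0 * np.sin(ang), 0.0])
    return ids, coords


def build_topology(chains: Sequence[str] = ("A", "B", "C"),
                   label: str = "toy-trimer") -> StructureModel:
    """Assemble the toy trimer topology (base coordinates, frame 0 layout)."""
    all_ids: list = []
    all_coords: list[np.ndarray] = []
    for ci, chain in enumerate(chains):
        ids, coords = _chain_scaffold(chain, ci)
        all_ids.extend(ids)
        all_coords.append(coords)
    coords = np.vstack(all_coords)
    return StructureModel(
        chain_ids=np.array([i[0] for i in all_ids]),
        residue_numbers=np.array([i[1] for i in all_ids]),
        residue_names=np.array([i[2] for i in all_ids]),
        atom_names=np.array([i[3] for i in all_ids]),
        coords=coords,
        hetero=np.array([i[4] for i in all_ids]),
        label=label,
    )


_UNSTABLE_MAX_AMPLITUDE_A = 14.0


def gen_trajectory(spec: TrajectoryGenSpec) -> list[Trajectory]:
    """Generate one Trajectory per replicate (chains share one topology).

    Per frame: atom-wise Gaussian jitter; the HP2-tip Cα (G442) is placed at
    a distance from the HP1-tip Cα (S366) drawn from N(gate_mean, gate_sd);
    a global rigid tumble (random rotation + translation) is applied last,
    so all planted signals survive the per-chain fitting stage.
    """
    spec.validate()
    top = build_topology(spec.chains, label=f"{spec.system_label} toy trimer")
    base = top.coords.copy()
    n_atoms = top.n_atoms
    protein_mask = ~top.hetero

    anchor366 = {c: int(top.indices_where(chain=c, residue_number=366,
                                          atom_name="CA")[0])
                 for c in spec.chains}
    anchor442 = {c: int(top.indices_where(chain=c, residue_number=442,
                                          atom_name="CA")[0])
                 for c in spec.chains}
    ligand_idx = {c: top.indices_where(chain=c, residue_number=_LIGAND_RESID)
                  for c in spec.chains}

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out: list[Trajectory] = []
    dt_ns = spec.dt_ps / 1000.0
    for rep in range(1, spec.n_replicates + 1):
        rng = np.random.default_rng(children[rep - 1])
        nf = spec.n_frames
        frames = base[None, :, :] + rng.normal(0.0, spec.jitter_A, (nf, n_atoms, 3))

        # gate: fixed opening direction per chain, Gaussian distance per frame
        for c in spec.chains:
            u = base[anchor442[c]] - base[anchor366[c]]
            u = u / np.linalg.norm(u)
            d = rng.normal(spec.gate_mean_A, spec.gate_sd_A, nf)
            d = np.clip(d, 0.1, None)
            frames[:, anchor442[c], :] = (frames[:, anchor366[c], :]
                                          + d[:, None] * u[None, :])

        if spec.ligand_mode == "drift":
            step_sd = spec.ligand_drift_rate * dt_ns
            for c in spec.chains:
                walk = np.cumsum(rng.normal(0.0, step_sd, (nf, 3)), axis=0)
                frames[:, ligand_idx[c], :] += walk[:, None, :]

        if spec.ion_escape is not None:
            site, start = spec.ion_escape
            resid = _ION_RESIDS[site]
            for c in spec.chains:
                ion = top.indices_where(chain=c, residue_number=resid,
                                        atom_name="NA")
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                ramp = np.clip(np.arange(nf) - start, 0, None) * 0.1
                frames[:, ion, :] += (ramp[:, None] * direction[None, :])[:, None, :]

        if rep in spec.unstable_replicates:
            # growing per-atom deformation (not removable by a rigid fit)
            dirs = rng.normal(size=(n_atoms, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            amp = _UNSTABLE_MAX_AMPLITUDE_A * (np.arange(nf) / (nf - 1))
            frames[:, protein_mask, :] += (amp[:, None, None]
                                           * dirs[None, protein_mask, :])

        # rigid tumbling of the whole trimer, removed later by fitting
        rots = Rotation.random(nf, rng=rng)
        trans = rng.normal(0.0, 5.0, (nf, 3))
        frames = np.einsum("fij,fnj->fni", rots.as_matrix(), frames)
        frames += trans[:, None, :]

        out.append(Trajectory(topology=top, frames=frames, dt_ps=spec.dt_ps,
                              replicate_id=rep, system_label=spec.system_label))
    return out


# ---------------------------------------------------------------------------
# Plates
# ---------------------------------------------------------------------------

RESPONSE_TAU_MIN = 30.0  # mono-exponential rise time of the planted response


def response_auc_per_unit_amplitude(window_min: float = 120.0) -> float:
    """Net AUC of the unit-amplitude planted response over the window."""
    tau = RESPONSE_TAU_MIN
    return window_min - tau * (1.0 - np.exp(-window_min / tau))


_DEFAULT_SUBSTRATE_CONCS = tuple(np.logspace(-5, -3, 8))   # 10 uM - 1 mM
_DEFAULT_INHIBITOR_CONCS = tuple(np.logspace(-9, -5, 8))   # 1 nM - 10 uM


@dataclass(frozen=True)
class PlateGenSpec:
    """Ground truth for synthetic impedance plates.

    ``true_p_potency`` is the planted −log10 M midpoint; responses are in %
    of the reference (1 mM substrate on WT = 100). ``noise_sd_pct`` is the
    per-timepoint Gaussian noise on the nCI trace, as % of the reference
    response amplitude. ``shape`` is 'sigmoid', 'flat' (no response at any
    concentration) or 'bell' (rise then fall at the top concentrations).
    """

    direction: str = "stimulation"
    true_p_potency: float = 3.5
    true_emax_pct: float = 100.0
    true_hill: float = 1.0
    bottom: float = 0.0
    noise_sd_pct: float = 5.0
    vehicle_slope_per_min: float = -3e-4
    concentrations_M: tuple[float, ...] | None = None
    duplicates: int = 2
    n_experiments: int = 3
    shape: str = "sigmoid"
    cell_line: str = "WT"
    substrate: str = "L-glutamate"
    inhibitor: str = "TFB-TBOA"
    seed: int = 0

    def validate(self) -> None:
        if self.direction not in ("stimulation", "inhibition"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.shape not in ("sigmoid", "flat", "bell"):
            raise ValueError(f"unknown shape {self.shape!r}")
        concs = self.conc_list()
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if self.shape == "sigmoid" and len(set(concs)) < 4:
            raise ValueError("sigmoid plates need >= 4 distinct concentrations")
        if self.noise_sd_pct < 0 or self.duplicates < 1 or self.n_experiments < 1:
            raise ValueError("invalid noise/replication settings")

    def conc_list(self) -> tuple[float, ...]:
        if self.concentrations_M is not None:
            return tuple(self.concentrations_M)
        return (_DEFAULT_SUBSTRATE_CONCS if self.direction == "stimulation"
                else _DEFAULT_INHIBITOR_CONCS)


def _planted_response_pct(spec: PlateGenSpec, conc_M: float) -> float:
    """Planted net-AUC response, % of reference, at one concentration."""
    if spec.shape == "flat":
        return 0.0
    x = np.log10(conc_M)
    mid = -spec.true_p_potency
    hill = abs(spec.true_hill)
    if spec.direction == "stimulation":
        r = spec.bottom + (spec.true_emax_pct - spec.bottom) / (
            1.0 + 10.0 ** ((mid - x) * hill))
    else:
        r = spec.bottom + (spec.true_emax_pct - spec.bottom) / (
            1.0 + 10.0 ** ((x - mid) * hill))
    if spec.shape == "bell":
        concs = np.array(spec.conc_list())
        c_fall = np.sort(concs)[-3]
        r = r / (1.0 + (conc_M / c_fall) ** 2)
    return float(r)


# protocol timeline (minutes): seed at 0, pretreat at 22 h, stimulate 60 min
# later, record 120 min past stimulation
_T_PRETREAT = 1320.0
_T_STIM = 1380.0
_T_END = 1500.0


def _time_grid() -> np.ndarray:
    growth = np.arange(0.0, _T_PRETREAT + 1, 60.0)
    pre = np.arange(_T_PRETREAT + 5.0, _T_STIM + 1, 5.0)
    post = np.arange(_T_STIM + 5.0, _T_END + 1, 5.0)
    return np.concatenate([growth, pre, post])


def _make_well(rng: np.random.Generator, well_id: str, spec: PlateGenSpec,
               response_pct: float, condition: Condition,
               t_ref: float) -> WellTrace:
    times = _time_grid()
    growth = 0.3 + 1.7 * (1.0 - np.exp(-times / 400.0))
    g_ref = 0.3 + 1.7 * (1.0 - np.exp(-t_ref / 400.0))
    nci = growth / g_ref
    post_ref = times > t_ref
    nci[post_ref] += spec.vehicle_slope_per_min * (times[post_ref] - t_ref)
    post_stim = times > _T_STIM
    amplitude = response_pct / 100.0  # reference amplitude is 1 nCI unit
    nci[post_stim] += amplitude * (
        1.0 - np.exp(-(times[post_stim] - _T_STIM) / RESPONSE_TAU_MIN))
    noise = rng.normal(0.0, spec.noise_sd_pct / 100.0, post_ref.sum())
    nci[post_ref] += noise
    ci_ref = 2.0 + rng.uniform(-0.2, 0.2)
    z0 = 10.0 + rng.uniform(-1.0, 1.0)
    impedance = z0 + 15.0 * ci_ref * nci
    return WellTrace(well_id=well_id, times_min=times, impedance_ohm=impedance,
                     z0_ohm=z0, condition=condition)


def gen_plate(spec: PlateGenSpec) -> list[Plate]:
    """Generate one plate per experiment, inverse of the analysis chain.

    Each plate carries duplicate vehicle wells, duplicate reference wells
    (1 mM substrate on WT cells, planted at 100%), and ``duplicates`` wells
    per dose of the substrate series (stimulation) or the
    inhibitor-pretreatment series with 1 mM substrate stimulation
    (inhibition).
    """
    spec.validate()
    t_ref = _T_STIM if spec.direction == "stimulation" else _T_PRETREAT
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_experiments)
    plates: list[Plate] = []
    for exp in range(spec.n_experiments):
        rng = np.random.default_rng(children[exp])
        wells: list[WellTrace] = []
        for i in range(2):
            wells.append(_make_well(
                rng, f"VEH{i+1}", spec, 0.0,
                Condition(cell_line=spec.cell_line, role=ROLE_VEHICLE,
                          stim_compound=None, stim_conc_M=None), t_ref))
        for i in range(2):
            wells.append(_make_well(
                rng, f"REF{i+1}", spec, 100.0,
                Condition(cell_line="WT", role=ROLE_REFERENCE,
                          stim_compound=spec.substrate, stim_conc_M=1e-3),
                t_ref))
        for ci, conc in enumerate(spec.conc_list()):
            planted = _planted_response_pct(spec, conc)
            for dup in range(spec.duplicates):
                if spec.direction == "stimulation":
                    cond = Condition(cell_line=spec.cell_line,
                                     role=ROLE_SUBSTRATE,
                                     stim_compound=spec.substrate,
                                     stim_conc_M=conc)
                else:
                    cond = Condition(cell_line=spec.cell_line,
                                     role=ROLE_INHIBITOR_SUBSTRATE,
                                     pretreat_compound=spec.inhibitor,
                                     pretreat_conc_M=conc,
                                     stim_compound=spec.substrate,
                                     stim_conc_M=1e-3)
                wells.append(_make_well(rng, f"C{ci+1}D{dup+1}", spec,
                                        planted, cond, t_ref))
        plates.append(Plate(wells=wells, t_pretreat_min=_T_PRETREAT,
                            t_stimulate_min=_T_STIM))
    return plates


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_CANCER_TYPES = ("UCEC", "LUAD", "SKCM", "COAD", "BRCA")


def gen_variant_table(n_patients: int, positions_pool: Sequence[str],
                      recurrence: int | dict[str, int] = 1,
                      seed: int = 0, gene: str = "SLC1A3") -> pd.DataFrame:
    """Variant table with a known unique-missense count and recurrence.

    ``positions_pool`` lists the planted protein changes (e.g. "R479W");
    ``recurrence`` is the per-change patient count (int for all, or a dict).
    """
    if len(positions_pool) == 0:
        raise ValueError("positions_pool must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for change in positions_pool:
        count = recurrence[change] if isinstance(recurrence, dict) else int(recurrence)
        for _ in range(count):
            rows.append({
                "gene": gene,
                "protein_change": change,
                "cancer_type": _CANCER_TYPES[int(rng.integers(len(_CANCER_TYPES)))],
                "patient_id": f"P{int(rng.integers(1, n_patients + 1)):05d}",
            })
    rng.shuffle(rows)
    return pd.DataFrame(rows)
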
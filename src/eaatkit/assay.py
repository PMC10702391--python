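"""Impedance-based phenotypic assay quantification.

The readout chain follows the RTCA (xCELLigence) convention: raw impedance
Z(t) is converted to the unitless Cell Index CI = (Z − Z0)/15 Ω, normalized
to the reference time point (inhibitor pretreatment or substrate
stimulation) to give nCI, corrected by subtracting the matched vehicle
wells, and quantified as the net (signed) area under the corrected curve
over the first 120 min after substrate stimulation. Net-AUC responses,
expressed as % of the reference response (1 mM substrate on wild-type
cells = 100%), are fitted to a four-parameter logistic
(variable-slope sigmoid) on log10 concentration to obtain pEC50/pIC50,
Emax, Hill slope and bottom; degenerate curves are flagged not-determined
or bell-shaped instead of yielding parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError

__all__ = [
    "Condition",
    "WellTrace",
    "Plate",
    "DoseResponseResult",
    "cell_index",
    "normalize_ci",
    "vehicle_correct",
    "net_auc",
    "four_param_logistic",
    "fit_concentration_response",
    "potency_summary",
    "fold_expression",
    "dunnett_vs_control",
    "ec80_from_ec50",
    "quantify_plate",
    "quantify_experiments",
    "write_plate",
    "read_plate",
]

CI_CONVERSION_OHM = 15.0
DEFAULT_AUC_WINDOW_MIN = 120.0

ROLE_VEHICLE = "vehicle"
ROLE_SUBSTRATE = "substrate"
ROLE_INHIBITOR_SUBSTRATE = "inhibitor+substrate"
ROLE_INHIBITOR_ONLY = "inhibitor-only"
ROLE_REFERENCE = "reference"


@dataclass(frozen=True)
class Condition:
    """What a well received: cell line, pretreatment, stimulation, role."""

    cell_line: str = "WT"
    role: str = ROLE_SUBSTRATE
    pretreat_compound: str | None = None
    pretreat_conc_M: float | None = None
    stim_compound: str | None = None
    stim_conc_M: float | None = None


@dataclass
class WellTrace:
    """A single well's time series (raw impedance, Ω) plus metadata."""

    well_id: str
    times_min: np.ndarray
    impedance_ohm: np.ndarray
    z0_ohm: float
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.impedance_ohm = np.asarray(self.impedance_ohm, dtype=float)
        if self.times_min.shape != self.impedance_ohm.shape:
            raise ValueError("times and impedance must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class Plate:
    """A collection of wells sharing one protocol timeline."""

    wells: list[WellTrace]
    t_pretreat_min: float
    t_stimulate_min: float

    def wells_with(self, role: str | None = None,
                   cell_line: str | None = None) -> list[WellTrace]:
        out = []
        for w in self.wells:
            if role is not None and w.condition.role != role:
                continue
            if cell_line is not None and w.condition.cell_line != cell_line:
                continue
            out.append(w)
        return out


# ---------------------------------------------------------------------------
# Elementary trace operations
# ---------------------------------------------------------------------------


def cell_index(impedance_ohm: np.ndarray, z0_ohm: float) -> np.ndarray:
    """Cell Index: CI(t) = (Z(t) − Z0) / 15 Ω (unitless)."""
    if z0_ohm is None or not np.isfinite(z0_ohm):
        raise DomainError("baseline impedance Z0 is missing")
    return (np.asarray(impedance_ohm, dtype=float) - float(z0_ohm)) / CI_CONVERSION_OHM


def _time_index(times_min: np.ndarray, t_ref: float) -> int:
    idx = np.flatnonzero(np.isclose(times_min, t_ref))
    if len(idx) == 0:
        raise DomainError(f"reference time {t_ref} min not present in time grid")
    return int(idx[0])


def normalize_ci(times_min: np.ndarray, ci: np.ndarray, t_ref: float) -> np.ndarray:
    """Normalized CI: nCI(t) = CI(t) / CI(t_ref), so nCI(t_ref) = 1."""
    times_min = np.asarray(times_min, dtype=float)
    ci = np.asarray(ci, dtype=float)
    ref = ci[_time_index(times_min, t_ref)]
    if ref <= 0:
        raise DomainError(f"CI at reference time {t_ref} min is {ref:.4g} <= 0")
    return ci / ref


def vehicle_correct(times_min: np.ndarray, nci: np.ndarray,
                    vehicle_times_min: np.ndarray,
                    vehicle_mean_nci: np.ndarray) -> np.ndarray:
    """Subtract the plate-matched vehicle mean pointwise (no interpolation)."""
    times_min = np.asarray(times_min, dtype=float)
    vehicle_times_min = np.asarray(vehicle_times_min, dtype=float)
    if times_min.shape != vehicle_times_min.shape or not np.allclose(
            times_min, vehicle_times_min):
        raise DomainError("vehicle and condition time grids differ; "
                          "refusing to interpolate silently")
    return np.asarray(nci, dtype=float) - np.asarray(vehicle_mean_nci, dtype=float)


def net_auc(times_min: np.ndarray, corrected: np.ndarray, t_from: float,
            window_min: float = DEFAULT_AUC_WINDOW_MIN) -> float:
    """Net (signed) trapezoidal AUC over [t_from, t_from + window_min].

    Negative excursions subtract. Window endpoints not on the grid are
    obtained by linear interpolation, which keeps the integral exact for
    piecewise-linear curves; a window extending beyond the data is an error.
    """
    times_min = np.asarray(times_min, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    t_end = t_from + window_min
    if t_from < times_min[0] - 1e-9 or t_end > times_min[-1] + 1e-9:
        raise DomainError(
            f"AUC window [{t_from}, {t_end}] min not covered by data span "
            f"[{times_min[0]}, {times_min[-1]}] min")
    inside = (times_min > t_from) & (times_min < t_end)
    grid = np.concatenate(([t_from], times_min[inside], [t_end]))
    vals = np.interp(grid, times_min, corrected)
    return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# Concentration-response fitting
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseResult:
    """Variable-slope sigmoid fit of a concentration-response series.

    ``p_potency`` is −log10 of the molar midpoint (pEC50 for stimulation,
    pIC50 for inhibition); ``emax_pct`` is the fitted top as % of the
    reference response. When ``not_determined`` or ``bell_shaped`` is set
    the parameters are absent (None).
    """

    direction: str
    p_potency: float | None = None
    emax_pct: float | None = None
    hill: float | None = None
    bottom: float | None = None
    se: dict[str, float] | None = None
    converged: bool = False
    not_determined: bool = False
    bell_shaped: bool = False

    @property
    def flags(self) -> list[str]:
        out = []
        if self.converged:
            out.append("converged")
        if self.not_determined:
            out.append("not_determined")
        if self.bell_shaped:
            out.append("bell_shaped")
        return out


def four_param_logistic(log10_conc: np.ndarray, bottom: float, top: float,
                        log10_mid: float, hill: float) -> np.ndarray:
    """4PL on log10 concentration: y = bottom + (top − bottom) /
    (1 + 10^((log10_mid − x)·hill))."""
    x = np.asarray(log10_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_mid - x) * hill))


MAX_ABS_HILL = 5.0
ND_SPAN_PCT = 10.0  # minimum fitted span, % of the reference response
BELL_TOP_FRACTION = 0.70
BELL_SLOPE_ALPHA = 0.05


def _mean_by_conc(conc_M: np.ndarray, responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame({"c": conc_M, "r": responses}).groupby("c", sort=True).mean()
    return df.index.to_numpy(), df["r"].to_numpy()


def _is_bell_shaped(conc_M: np.ndarray, responses: np.ndarray) -> bool:
    """Rise-then-fall heuristic: the top-3 concentrations' mean response is
    below 70% of the interior maximum and the terminal slope (top-4
    concentrations, response vs log10 c) is significantly negative."""
    cs, rs = _mean_by_conc(conc_M, responses)
    if len(cs) < 5:
        return False
    top3 = float(np.mean(rs[-3:]))
    interior_max = float(np.max(rs[:-3]))
    if interior_max <= 0 or top3 >= BELL_TOP_FRACTION * interior_max:
        return False
    tail = slice(-4, None)
    res = stats.linregress(np.log10(cs[tail]), rs[tail])
    return bool(res.slope < 0 and res.pvalue < BELL_SLOPE_ALPHA)


def fit_concentration_response(concentrations_M: np.ndarray,
                               responses: np.ndarray,
                               direction: str = "stimulation",
                               reference_pct: float = 100.0) -> DoseResponseResult:
    """Fit responses (% of reference) to a variable-slope sigmoid.

    ``direction`` selects the interpretation ('stimulation' → pEC50,
    'inhibition' → pIC50) and the pathology checks. Optimizer failure, a
    fitted span below 10% of the reference, or a midpoint outside the tested
    concentration range flag the result not-determined; a rise-then-fall
    profile flags it bell-shaped. Flagged results carry no parameters.
    """
    if direction not in ("stimulation", "inhibition"):
        raise ValueError(f"unknown direction {direction!r}")
    conc = np.asarray(concentrations_M, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive (molar)")
    if len(np.unique(conc)) < 4:
        raise DomainError("need >= 4 distinct concentrations")

    result = DoseResponseResult(direction=direction)
    if direction == "stimulation" and _is_bell_shaped(conc, resp):
        result.bell_shaped = True
        return result

    x = np.log10(conc)
    lo, hi = float(x.min()), float(x.max())
    # Vehicle correction pins the zero-dose response at 0 by construction,
    # so the fitted bottom is confined to a narrow band around zero; this
    # removes the shallow-hill/deep-bottom degeneracy of free-bottom 4PL
    # fits on short concentration ranges.
    b_lim = 0.05 * reference_pct
    bottom0 = float(np.clip(np.min(resp), -b_lim, b_lim))
    if direction == "stimulation":
        p0 = [bottom0, float(np.max(resp)), float(np.median(x)), 1.0]
    else:
        p0 = [bottom0, float(np.max(resp)), float(np.median(x)), -1.0]
    bounds = ([-b_lim, -200.0, lo - 3.0, -MAX_ABS_HILL],
              [b_lim, 400.0, hi + 3.0, MAX_ABS_HILL])
    try:
        popt, pcov = optimize.curve_fit(four_param_logistic, x, resp, p0=p0,
                                        bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        result.not_determined = True
        return result
    bottom, top, log10_mid, hill = popt
    span = abs(top - bottom)
    if (not np.all(np.isfinite(popt)) or span < ND_SPAN_PCT / 100.0 * reference_pct
            or log10_mid < lo or log10_mid > hi):
        result.not_determined = True
        return result
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    result.converged = True
    result.p_potency = float(-log10_mid)
    result.emax_pct = float(top)
    result.hill = float(hill)
    result.bottom = float(bottom)
    result.se = {"bottom": float(perr[0]), "emax_pct": float(perr[1]),
                 "p_potency": float(perr[2]), "hill": float(perr[3])}
    return result


def potency_summary(fits: Sequence[DoseResponseResult]) -> dict[str, tuple[float, float, int]]:
    """Parameter-wise mean ± SEM across experiments (the replication unit).

    Only converged fits contribute; returns {param: (mean, sem, n)}.
    """
    good = [f for f in fits if f.converged]
    out: dict[str, tuple[float, float, int]] = {}
    for param in ("p_potency", "emax_pct", "hill", "bottom"):
        vals = np.array([getattr(f, param) for f in good], dtype=float)
        if len(vals) == 0:
            continue
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[param] = (mean, sem, len(vals))
    return out


def fold_expression(condition_absorbances: np.ndarray,
                    control_absorbances: np.ndarray) -> float:
    """Ratio of mean absorbances (condition over non-induced control)."""
    cond = np.asarray(condition_absorbances, dtype=float)
    ctrl = np.asarray(control_absorbances, dtype=float)
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean <= 0:
        raise DomainError("control mean absorbance must be positive")
    return float(np.mean(cond)) / ctrl_mean


def dunnett_vs_control(groups: Mapping[str, np.ndarray], control_label: str,
                       alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA followed by Dunnett many-to-one comparisons.

    Returns one row per non-control group with the mean difference, the
    Dunnett-adjusted p-value and the significance decision at ``alpha``.
    The ANOVA F statistic and p-value are attached as DataFrame attrs.
    """
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} not among groups")
    labels = [k for k in groups if k != control_label]
    if len(labels) < 1:
        raise ValueError("need at least one non-control group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise DomainError("degenerate data: zero variance across all groups")
    control = arrays[control_label]
    f_stat, f_p = stats.f_oneway(*arrays.values())
    res = stats.dunnett(*[arrays[k] for k in labels], control=control)
    rows = []
    for i, k in enumerate(labels):
        rows.append({
            "group": k,
            "mean_diff": float(np.mean(arrays[k]) - np.mean(control)),
            "p_adjusted": float(res.pvalue[i]),
            "significant": bool(res.pvalue[i] < alpha),
        })
    df = pd.DataFrame(rows)
    df.attrs["anova_F"] = float(f_stat)
    df.attrs["anova_p"] = float(f_p)
    df.attrs["alpha"] = alpha
    return df


def ec80_from_ec50(ec50_M: float, hill: float) -> float:
    """EC80 for protocol design: EC80 = EC50 · 4^(1/hill) (hill > 0)."""
    if hill <= 0:
        raise DomainError("EC80 helper requires a positive Hill slope")
    return float(ec50_M * 4.0 ** (1.0 / hill))


# ---------------------------------------------------------------------------
# Plate-level orchestration
# ---------------------------------------------------------------------------


@dataclass
class PlateQuantResult:
    """Per-well responses and the concentration-response fit for one plate."""

    well_table: pd.DataFrame
    concentrations_M: np.ndarray
    responses_pct: np.ndarray
    fit: DoseResponseResult
    reference_auc: float


def quantify_plate(plate: Plate, mode: str = "stimulation",
                   window_min: float = DEFAULT_AUC_WINDOW_MIN) -> PlateQuantResult:
    """Run the full CI → nCI → vehicle correction → net AUC → fit chain.

    ``mode='stimulation'`` normalizes at the substrate-stimulation time and
    reads the dose off the stimulation concentration; ``mode='inhibition'``
    normalizes at the inhibitor-pretreatment time and reads the dose off the
    pretreatment concentration. Responses are scaled so the mean net AUC of
    the plate's reference wells (1 mM substrate on WT cells) is 100%.
    """
    if mode not in ("stimulation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    t_ref = plate.t_stimulate_min if mode == "stimulation" else plate.t_pretreat_min
    dose_role = ROLE_SUBSTRATE if mode == "stimulation" else ROLE_INHIBITOR_SUBSTRATE

    def corrected_nci(well: WellTrace, vehicle_mean: np.ndarray,
                      vehicle_times: np.ndarray) -> np.ndarray:
        ci = cell_index(well.impedance_ohm, well.z0_ohm)
        nci = normalize_ci(well.times_min, ci, t_ref)
        return vehicle_correct(well.times_min, nci, vehicle_times, vehicle_mean)

    vehicles = plate.wells_with(role=ROLE_VEHICLE)
    if not vehicles:
        raise DomainError("plate has no vehicle wells")
    vtimes = vehicles[0].times_min
    vehicle_nci = np.mean([
        normalize_ci(w.times_min, cell_index(w.impedance_ohm, w.z0_ohm), t_ref)
        for w in vehicles], axis=0)

    refs = plate.wells_with(role=ROLE_REFERENCE)
    if not refs:
        raise DomainError("plate has no reference wells (1 mM substrate, WT)")
    ref_aucs = [net_auc(w.times_min, corrected_nci(w, vehicle_nci, vtimes),
                        plate.t_stimulate_min, window_min) for w in refs]
    ref_auc = float(np.mean(ref_aucs))
    if ref_auc <= 0:
        raise DomainError("reference response is non-positive; cannot normalize")

    rows = []
    for well in plate.wells_with(role=dose_role):
        auc = net_auc(well.times_min, corrected_nci(well, vehicle_nci, vtimes),
                      plate.t_stimulate_min, window_min)
        conc = (well.condition.stim_conc_M if mode == "stimulation"
                else well.condition.pretreat_conc_M)
        if conc is None:
            raise DomainError(f"well {well.well_id} lacks a dose concentration")
        rows.append({"well": well.well_id, "conc_M": float(conc),
                     "net_auc": auc, "response_pct": 100.0 * auc / ref_auc})
    if not rows:
        raise DomainError(f"plate has no wells with role {dose_role!r}")
    table = pd.DataFrame(rows).sort_values("conc_M").reset_index(drop=True)
    fit = fit_concentration_response(table["conc_M"].to_numpy(),
                                     table["response_pct"].to_numpy(),
                                     direction=mode)
    return PlateQuantResult(well_table=table,
                            concentrations_M=table["conc_M"].to_numpy(),
                            responses_pct=table["response_pct"].to_numpy(),
                            fit=fit, reference_auc=ref_auc)


def quantify_experiments(plates: Sequence[Plate], mode: str = "stimulation",
                         window_min: float = DEFAULT_AUC_WINDOW_MIN,
                         ) -> tuple[list[PlateQuantResult],
                                    dict[str, tuple[float, float, int]]]:
    """Quantify each experiment's plate and summarize potencies (mean ± SEM)."""
    results = [quantify_plate(p, mode=mode, window_min=window_min) for p in plates]
    summary = potency_summary([r.fit for r in results])
    return results, summary


# ---------------------------------------------------------------------------
# Plate CSV round trip (long traces + layout + events)
# ---------------------------------------------------------------------------


def write_plate(plate: Plate, out_dir: str | Path, stem: str = "plate") -> None:
    """Write a plate as traces.csv (well, time_min, impedance_ohm),
    layout.csv (well metadata incl. z0) and events.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traces = pd.concat([
        pd.DataFrame({"well": w.well_id, "time_min": w.times_min,
                      "impedance_ohm": w.impedance_ohm})
        for w in plate.wells], ignore_index=True)
    traces.to_csv(out_dir / f"{stem}_traces.csv", index=False)
    layout = pd.DataFrame([{
        "well": w.well_id,
        "z0_ohm": w.z0_ohm,
        "cell_line": w.condition.cell_line,
        "role": w.condition.role,
        "pretreat_compound": w.condition.pretreat_compound or "",
        "pretreat_conc_M": w.condition.pretreat_conc_M,
        "stim_compound": w.condition.stim_compound or "",
        "stim_conc_M": w.condition.stim_conc_M,
    } for w in plate.wells])
    layout.to_csv(out_dir / f"{stem}_layout.csv", index=False)
    with open(out_dir / f"{stem}_events.json", "w") as fh:
        json.dump({"t_pretreat_min": plate.t_pretreat_min,
                   "t_stimulate_min": plate.t_stimulate_min}, fh, indent=2)


def read_plate(in_dir: str | Path, stem: str = "plate") -> Plate:
    """Read a plate written by :func:`write_plate`."""
    in_dir = Path(in_dir)
    traces = pd.read_csv(in_dir / f"{stem}_traces.csv")
    layout = pd.read_csv(in_dir / f"{stem}_layout.csv",
                         dtype={"well": str}, keep_default_na=False,
                         na_values=[""])
    with open(in_dir / f"{stem}_events.json") as fh:
        events = json.load(fh)
    wells = []
    for _, row in layout.iterrows():
        sub = traces[traces["well"].astype(str) == str(row["well"])]
        cond = Condition(
            cell_line=str(row["cell_line"]),
            role=str(row["role"]),
            pretreat_compound=(str(row["pretreat_compound"])
                               if pd.notna(row["pretreat_compound"])
                               and str(row["pretreat_compound"]) else None),
            pretreat_conc_M=(float(row["pretreat_conc_M"])
                             if pd.notna(row["pretreat_conc_M"]) else None),
            stim_compound=(str(row["stim_compound"])
                           if pd.notna(row["stim_compound"])
                           and str(row["stim_compound"]) else None),
            stim_conc_M=(float(row["stim_conc_M"])
                         if pd.notna(row["stim_conc_M"]) else None),
        )
        wells.append(WellTrace(
            well_id=str(row["well"]),
            times_min=sub["time_min"].to_numpy(dtype=float),
            impedance_ohm=sub["impedance_ohm"].to_numpy(dtype=float),
            z0_ohm=float(row["z0_ohm"]),
            condition=cond,
        ))
    return Plate(wells=wells, t_pretreat_min=float(events["t_pretreat_min"]),
                 t_stimulate_min=float(events["t_stimulate_min"]))
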
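"""Missense-variant tables, ligand-site proximity sets and ΔΔG classification.

Variant tables carry protein changes like ``R479W``. Mapping onto a structure
assumes protein-sequence positions coincide with PDB residue numbering
(an offset map can be supplied for real structures). Binding free-energy
changes (ΔΔG, kcal/mol, mutant minus wild type) are inputs, never computed:
values above +1 kcal/mol are read as a significant loss of binding affinity
and below −1 kcal/mol as a significant gain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainError, SelectionError
from .structure import StructureModel

__all__ = [
    "VariantRecord",
    "VariantParseResult",
    "ProximitySets",
    "LigandSelector",
    "parse_variant_table",
    "unique_missense",
    "proximity_classify",
    "frequency_percent",
    "classify_ddg",
    "classify_ddg_table",
]

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    cancer_type: str = ""
    patient_id: str = ""
    source: str = ""

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class VariantParseResult:
    """Parsed records plus row-level errors (invalid rows are reported, not
    silently dropped)."""

    records: list[VariantRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)


def _parse_change(change: str) -> tuple[str, int, str]:
    m = _CHANGE_RE.match(str(change).strip())
    if not m:
        raise ValueError(f"unparseable protein change {change!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in _AA1 or alt not in _AA1:
        raise ValueError(f"unknown amino-acid code in {change!r}")
    if ref == alt:
        raise ValueError(f"{change!r} is synonymous, not missense")
    if pos < 1:
        raise ValueError(f"position must be >= 1 in {change!r}")
    return ref, pos, alt


def parse_variant_table(path_or_df: str | Path | pd.DataFrame) -> VariantParseResult:
    """Parse a CSV/TSV variant table with columns gene, protein_change,
    cancer_type, patient_id (optional: source)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        path = Path(path_or_df)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"gene", "protein_change", "cancer_type", "patient_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")

    records: list[VariantRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            ref, pos, alt = _parse_change(row["protein_change"])
        except ValueError as exc:
            errors.append((int(i), str(exc)))
            continue
        records.append(VariantRecord(
            gene=str(row["gene"]),
            ref_aa=ref, position=pos, alt_aa=alt,
            cancer_type=str(row.get("cancer_type", "")),
            patient_id=str(row.get("patient_id", "")),
            source=str(row.get("source", "")) if "source" in df.columns else "",
        ))
    return VariantParseResult(records=records, errors=errors)


def unique_missense(records: Iterable[VariantRecord], gene: str | None = None) -> set[str]:
    """Unique protein changes by (ref, position, alt); idempotent and
    order-independent."""
    out: set[str] = set()
    for rec in records:
        if gene is not None and rec.gene != gene:
            continue
        out.add(rec.protein_change)
    return out


@dataclass(frozen=True)
class LigandSelector:
    """Criteria resolving to the atoms of one co-crystallized ligand."""

    residue_name: str | None = None
    residue_number: int | None = None
    chain: str | None = None
    hetero: bool | None = True

    def resolve(self, model: StructureModel) -> np.ndarray:
        idx = model.indices_where(chain=self.chain,
                                  residue_number=self.residue_number,
                                  residue_name=self.residue_name,
                                  hetero=self.hetero)
        if len(idx) == 0:
            raise SelectionError(f"ligand selector {self} matched no atoms")
        return idx


@dataclass
class ProximitySets:
    """Variants within ``cutoff_A`` of the orthosteric / allosteric ligand.

    ``interface`` is the intersection of the two sets; ``unmapped`` lists
    variants whose position is absent from the mapping chain. ``distances``
    holds the minimum residue-to-ligand distance per variant and site.
    """

    orthosteric: set[str]
    allosteric: set[str]
    interface: set[str]
    unmapped: list[str]
    cutoff_A: float
    distances: pd.DataFrame | None = None


def proximity_classify(
    model: StructureModel,
    variants: Iterable[str],
    orthosteric_ligand: LigandSelector,
    allosteric_ligand: LigandSelector,
    cutoff_A: float = 5.0,
    chain: str = "A",
    position_offset: Mapping[int, int] | None = None,
) -> ProximitySets:
    """Classify variants by minimum-distance proximity to two ligand sites.

    A variant belongs to a site's set iff the minimum distance between any
    atom of its residue (on the mapping chain) and any atom of that ligand
    is <= ``cutoff_A`` (boundary inclusive). Membership in both sets puts it
    in ``interface``.
    """
    ortho_idx = orthosteric_ligand.resolve(model)
    allo_idx = allosteric_ligand.resolve(model)
    ortho_xyz = model.coords[ortho_idx]
    allo_xyz = model.coords[allo_idx]

    ortho: set[str] = set()
    allo: set[str] = set()
    unmapped: list[str] = []
    rows = []
    for change in sorted(set(variants)):
        _, pos, _ = _parse_change(change)
        if position_offset:
            pos = pos + position_offset.get(pos, 0)
        res_idx = model.indices_where(chain=chain, residue_number=pos, hetero=False)
        if len(res_idx) == 0:
            unmapped.append(change)
            continue
        res_xyz = model.coords[res_idx]
        d_ortho = float(cdist(res_xyz, ortho_xyz).min())
        d_allo = float(cdist(res_xyz, allo_xyz).min())
        if d_ortho <= cutoff_A:
            ortho.add(change)
        if d_allo <= cutoff_A:
            allo.add(change)
        rows.append({"variant": change, "min_dist_orthosteric_A": d_ortho,
                     "min_dist_allosteric_A": d_allo})
    distances = pd.DataFrame(rows) if rows else None
    return ProximitySets(
        orthosteric=ortho,
        allosteric=allo,
        interface=ortho & allo,
        unmapped=unmapped,
        cutoff_A=cutoff_A,
        distances=distances,
    )


def frequency_percent(n_mutations: int, n_patients: int) -> float:
    """Mutation burden as a percentage: 100 × n_mutations / n_patients."""
    if n_patients <= 0:
        raise DomainError("n_patients must be positive")
    if n_mutations < 0:
        raise DomainError("n_mutations must be non-negative")
    return 100.0 * n_mutations / n_patients


def classify_ddg(ddg_kcal_mol: float, threshold: float = 1.0) -> str:
    """Classify a binding free-energy change against a ±threshold rule.

    ΔΔG > +threshold → ``decrease`` (significant loss of binding affinity);
    ΔΔG < −threshold → ``increase``; otherwise ``nonsignificant``.
    """
    ddg = float(ddg_kcal_mol)
    if not np.isfinite(ddg):
        raise DomainError(f"ΔΔG must be finite, got {ddg_kcal_mol!r}")
    if not threshold > 0:
        raise DomainError("threshold must be positive")
    if ddg > threshold:
        return "decrease"
    if ddg < -threshold:
        return "increase"
    return "nonsignificant"


def classify_ddg_table(table: str | Path | pd.DataFrame,
                       threshold: float = 1.0) -> pd.DataFrame:
    """Classify a ΔΔG table with columns mutant, ligand, ddg_kcal_mol."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table)
    required = {"mutant", "ligand", "ddg_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ΔΔG table missing columns: {sorted(missing)}")
    df["classification"] = [classify_ddg(v, threshold) for v in df["ddg_kcal_mol"]]
    return df
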
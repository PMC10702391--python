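"""eaatkit: disease-variant triage and functional quantification for the
glutamate/aspartate transporter EAAT1 (SLC1A3).

The package covers two workflows. The structural arm maps missense variants
onto transporter structures, classifies them by ligand-site proximity and by
predicted binding free-energy change, computes per-chain gating and
stability metrics from MD-style trajectories (HP2 gate opening, Na+ site
distances, protein/ligand RMSD, RMSF), applies a stability exclusion rule
and selects representative frames for ensemble docking. The assay arm
quantifies label-free impedance recordings (Cell Index, normalization,
vehicle correction, net AUC) into substrate and inhibitor potencies via
variable-slope sigmoid fits. A synthetic-data module generates every input
class with known ground truth.
"""

__version__ = "0.1.0"

from . import assay, report, structure, synth, trajectory, variants  # noqa: F401
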
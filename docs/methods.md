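# Methods

This note documents the models and procedures implemented in `eaatkit`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions that affect results.

## Structural model and superposition

Structures are ordered atom collections with PDB-style identity
(chain, residue number, residue name, atom name) and Å coordinates;
residue numbering is 1-based and insertion codes are rejected. Ions and
ligands are ordinary atoms marked `hetero`, so the Na⁺ ions can be
addressed by residue number (601–603) exactly as the gating metrics
require. Trajectories are (n_frames × n_atoms × 3) coordinate arrays over
one topology with a frame spacing `dt_ps`; multi-model PDB is the
interchange format (binary trajectory dialects can be adapted behind the
same contract but are not part of the tested surface).

Superposition is the closed-form Kabsch solution (SVD of the covariance of
centered point sets, determinant-corrected to a proper rotation), with unit
weights. The fit subset defaults to the protein Cα atoms of the chain under
analysis; the transform is applied to all atoms. Fit subsets with fewer
than three points, or whose second singular value vanishes (collinear), are
rejected. Trajectory fitting uses a batched implementation (one 3×3 SVD per
frame) that is verified against the single-frame path and against direct
numerical minimization over rotation parameters in the test suite.

## Variant triage

Protein changes are parsed from `RefPosAlt` strings; synonymous or
malformed rows are collected as row-level errors, never silently dropped.
Uniqueness is by (ref, position, alt). Proximity classification is a
determinization of what is usually done by visual inspection: a variant
belongs to a ligand site's set iff the *minimum* distance between any atom
of its residue (all atoms, not only side chain) and any atom of that
ligand is ≤ the cutoff (5 Å default, boundary inclusive). Membership in
both sets defines the interface set, so `interface = orthosteric ∩
allosteric` holds by construction, and the sets grow monotonically with
the cutoff. Variant positions are assumed to coincide with the structure's
residue numbering; an offset map hook exists for real structures where
they do not. Positions absent from the mapping chain (default chain A) are
reported as unmapped and excluded.

The mutation-burden helper returns 100 × n_mutations / n_patients. Note
that published burden figures are not always reproducible from unique
counts alone (counting non-unique mutations changes the numerator); the
function implements the stated formula and leaves the choice of numerator
to the caller.

ΔΔG values (kcal/mol, mutant − wild type) are *inputs*: the underlying
binding free-energy calculation belongs to commercial modelling suites and
is out of scope. The classification rule is symmetric: > +1 kcal/mol →
`decrease` (of binding affinity), < −1 → `increase`, otherwise
`nonsignificant`; the threshold is configurable and strict (±1.0 itself is
nonsignificant).

## Trajectory metrics

All metrics are computed per chain, independently, after fitting the whole
trajectory to frame 0 on that chain's protein Cα atoms. Per-chain fitting
matches the per-chain independence of the metrics; the fit atom set is a
design choice (the procedure it emulates does not name one).

* **Protein RMSD**: per-frame Cα RMSD against frame 0. Frame 0 is exactly 0.
* **Ligand RMSD**: heavy-atom RMSD of the ligand against frame 0 *without
  re-fitting on the ligand*, i.e. ligand motion in the protein frame of
  reference.
* **RMSF**: per-residue Cα fluctuation, √(time-mean squared deviation from
  the time-mean position). Closed-form checks: a sinusoid of amplitude *a*
  gives a/√2; isotropic per-axis noise σ gives √3·σ.
* **Anchor distances**: per-frame Euclidean distances for the HP2 gate
  opening (366 Cα ↔ 442 Cα) and the three Na⁺ sites (601↔487, 603↔396,
  602↔400). Ion anchors fall back to a chain-agnostic lookup when the ion
  does not carry the chain's label, provided the match is unique.

**Stability exclusion.** A (replicate, chain) is excluded from pooled
analyses iff its protein RMSD *reaches* 10 Å — implemented as ≥ at any
frame. Granularity is per chain, because published exclusion bookkeeping
mixes whole-replicate and single-chain entries. Raising the threshold can
only shrink the excluded set.

**Sampling density.** Pooled per-frame metric pairs (HP2 opening ×
ligand RMSD by default) are binned into a normalized 2D histogram (60 bins
per axis by default) with 1D marginals; density × bin area sums to 1.
A Gaussian-KDE variant is available for figures, but the histogram is the
quantitative estimator. An empty pool after exclusion is an error that
points at the threshold.

**Representative frames.** The mode of the pooled chain-A HP2-opening
distribution is estimated as the center of the highest bin of a
Freedman–Diaconis histogram; the selection window is that bin. k = 5
frames are drawn uniformly without replacement (seeded) among frames in
the window; if the window holds fewer than k frames it is widened once by
one bin on each side, after which failure is an error. The reported
mean ± sd is over the selected frames' values, so it always lies inside
the window. FD binning was chosen because it is parameter-light and
reproducible; with ~5,000 pooled frames at sd 0.2 Å the bin width is
≈ 0.02–0.05 Å, so the selected-frame mean tracks the planted gate mean
well inside ±0.2 Å. Exported frames contain the chain's protein atoms plus
the originally coordinated Na⁺ ions, one single-model PDB per frame.

## Impedance-assay quantification

The readout chain is: CI = (Z_i − Z_0)/15 Ω; nCI = CI(t)/CI(t_ref) with
t_ref the inhibitor-pretreatment time (inhibition analysis) or the
substrate-stimulation time (substrate analysis) — division is the RTCA
convention for "normalized to the time of"; a subtraction variant exists
behind the same interface. Vehicle wells are averaged per time point and
subtracted pointwise (mismatched time grids are an error; no silent
interpolation). The response measure is the signed trapezoidal net AUC of
the corrected nCI over [t_stim, t_stim + 120 min]; window endpoints not on
the grid are linearly interpolated, which keeps the integral exact for
piecewise-linear curves and invariant to grid refinement. Responses are
expressed as % of the mean reference response (1 mM substrate on
wild-type cells = 100 %).

**Sigmoid fitting.** Responses vs log10 molar concentration are fitted to
a 4-parameter logistic `y = bottom + (top − bottom)/(1 + 10^((x50 − x)·hill))`
by nonlinear least squares. The Hill slope is sign-unconstrained and
bounded |hill| ≤ 5. Because vehicle correction pins the zero-dose response
at 0 by construction, the fitted bottom is confined to ±5 % of the
reference response: an unconstrained bottom admits a shallow-hill /
deep-bottom degeneracy on short (2-decade) concentration ranges that can
displace the midpoint by ~0.3 log units at low response amplitudes.
`p_potency = −x50` is reported as pEC50 (stimulation) or pIC50
(inhibition).

**Pathology flags.**
* `not_determined`: optimizer failure, fitted span (top − bottom) below
  10 % of the reference response, or midpoint outside the tested
  concentration range. No parameters are reported. (A consequence: a
  variant whose maximal response is below 10 % of reference — e.g. a
  near-dead transporter — is by design not determinable in this pipeline.)
* `bell_shaped` (substrate curves): the mean response of the three highest
  concentrations is below 70 % of the interior maximum *and* the terminal
  slope over the top four concentrations is significantly negative
  (p < 0.05). Flagged fits report no parameters. The 70 %/top-3 thresholds
  are this package's determinization of a qualitative judgement.

Summaries are parameter-wise mean ± SEM across experiments (the
replication unit), over converged fits only. Dunnett many-to-one
comparison uses the multivariate-t implementation in SciPy after a one-way
ANOVA; its family-wise error under the null is verified by simulation in
the tests. ELISA fold expression is the ratio of means (not the mean of
ratios). An EC80 helper (EC80 = EC50·4^(1/hill), hill > 0) supports
submaximal-stimulation protocol design.

## Synthetic generators

The generators define the study conditions; each is an inverse of its
analysis stage.

**Trajectories.** The toy trimer is a ~40-residue Cα scaffold per chain
(three chains on a 30 Å ring) carrying the anchor residues, a 4-atom
ligand (residue 500) and three Na⁺ ions — sufficient for every metric's
anchors, small enough to keep tests fast. Per frame: iid Gaussian jitter
(0.05 Å) on every atom; the HP2-tip Cα is placed along a fixed per-chain
direction at a distance drawn iid from N(gate_mean, gate_sd), so the
planted gate distribution is exact by construction; optional ligand drift
is a cumulative Gaussian random walk (step sd = rate × dt in ns), giving a
time-growing mean displacement; optional ion escape moves one ion away
linearly from a given frame. Unstable replicates receive a per-atom
random-direction deformation growing linearly to 14 Å at the final frame —
internal deformation, not a rigid motion, so the per-chain fit cannot
absorb it and the protein RMSD crosses 10 Å. Finally the whole trimer
tumbles rigidly (uniform random rotation + translation per frame), which
the fitting stage must remove. Defaults are 10 replicates × 500 frames ×
3 chains at 500 ps/frame. All randomness derives from one seed via spawned
generators, so runs are bit-identical.

What this does *not* emulate: real force-field dynamics, autocorrelated
gate motion, solvent, concerted domain movements, or realistic RMSF
profiles. Passing tests therefore demonstrate that the *analysis* recovers
planted signals under realistic noise and nuisance transforms — not that
the generator reproduces molecular dynamics.

**Plates.** The protocol timeline is seeding at t = 0, pretreatment at
22 h, stimulation 60 min later, 120 min of post-stimulation recording
(5-min sampling after pretreatment, hourly during growth). Each plate has
duplicate vehicle wells, duplicate reference wells (1 mM substrate on WT,
planted at 100 %) and duplicate wells per dose (8 doses: 10 µM–1 mM
substrate, or 1 nM–10 µM inhibitor with 1 mM substrate stimulation). The
planted response is a mono-exponential nCI rise (τ = 30 min) whose 120-min
net AUC equals the planted %-response by construction; a linear vehicle
drift is added to every well and removed by vehicle correction.
Per-timepoint Gaussian noise (default 5 % of the reference amplitude) is
added after the normalization point, and the trace is inverted through the
CI formula (CI(t_ref) ≈ 2, Z_0 ≈ 10 Ω, ±uniform well-to-well variation)
so the pipeline's forward pass reconstructs the planted nCI exactly in the
noiseless limit. Flat plates plant zero response everywhere; bell plates
multiply the sigmoid by 1/(1 + (c/c_fall)²) with c_fall at the
third-highest dose, producing a rise-then-fall profile that the flag rule
must catch.

**Variant tables.** Planted protein changes with controllable per-change
recurrence and seeded patient/cancer-type assignment give known unique
counts and burden percentages.

## Problem sizes and determinism

The test suite and the acceptance script run on one CPU in well under a
minute each. Gate-recovery computations use 10 replicates × 500 frames
(chain A pooled, ≈ 5,000 frames after exclusion); potency recoveries use
8 doses × 2 duplicates × 3 experiments. Every stochastic step takes an
explicit seed; CLI stages write their configuration (including seeds)
next to their outputs so any artifact can be regenerated.

## Known limitations

* Insertion codes, altlocs and multi-character chain IDs are unsupported.
* The bell-shape and not-determined thresholds are heuristics; borderline
  curves near a 10 % span or a 70 % terminal drop can flip flag state
  under noise.
* The mode estimator inherits histogram-binning granularity; for
  multimodal gate distributions with nearly equal peaks the selected mode
  follows the highest bin, with no tie-breaking beyond bin order.
* Proximity classification uses a single static structure; it does not
  account for conformational variability of the binding sites.
* The impedance model is phenomenological: it does not model cell
  swelling mechanistically, instrument drift beyond a linear vehicle
  term, or well-position effects.
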
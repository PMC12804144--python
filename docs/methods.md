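# Methods

This note documents the models, algorithms, parameter defaults, and
design choices behind `epidyn`, and what the synthetic-data generators
do and do not emulate.

## Accessible surface area (Shrake–Rupley)

Each atom is expanded by the probe radius (default 1.4 Å, the
conventional water probe) and sampled with a deterministic
golden-spiral (Fibonacci) lattice of `n_points` unit vectors (default
960, the classic accuracy/speed compromise; identical input gives
bit-identical output, so no seeds are involved). A sample point is
**buried** iff it lies *strictly* inside any neighbouring expanded
sphere; a point exactly on a boundary counts as exposed. This strict
inequality removes floating-point tie ambiguity. The per-atom area is
`(exposed / n_points) · 4π(r + probe)²`; per-residue areas are sums
over the residue's atoms.

Neighbour candidates come from a uniform spatial grid with cell size
`2 · max(expanded radius)`, scanning the 27 cells around an atom. Any
sphere able to bury a point of atom *i* lies within
`expanded_i + expanded_j ≤ cell` of it, hence inside those cells, so
the candidate set is a superset of the relevant neighbours and the
grid-accelerated result is **bit-identical** to brute-force all-pairs
(asserted in tests on random systems). The point-burial loop is a
compiled (numba) kernel that visits neighbours nearest-first and exits
early; burial is an order-independent OR, so this changes nothing but
speed.

Two independent checks back the engine: a closed-form two-sphere
solution (spherical-cap geometry: buried cap height
`h = R − (d² + R² − R′²)/2d`, buried area `2πRh`) and, in the test
suite only, a third-party Shrake–Rupley implementation fed the same
radii.

Van der Waals radii ship as the Bondi (1964) set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20 Å) with a 1.50 Å default for unknown
elements (logged). Crystal structures carry no hydrogens, so SASA is
computed heavy-atom-only by default, with no united-atom radius
inflation; absolute areas are therefore comparable to typical PDB-file
SASA practice but not to hydrogen-complete calculations. The ASA of the
epitopic Gly1 residue is always evaluated in the **full-complex**
context (receptor + ligand), because the quantity of interest is burial
within the groove. Gly1 means the atoms of residue 1 of the ligand
chain only; the acyl carbonyl of the shared amide belongs to the MYR
residue and is not included.

Approximate rigid-motion invariance: the point lattice is world-fixed,
so rotating a structure changes total SASA slightly (< 2 % at 960
points, tested); areas converge as `n_points` grows.

## Conformational states and occupancy

A trajectory (multi-model PDB or in-memory) is sampled every `stride`
frames (default 10; a 5000-frame run yields 500 samples). Each sample's
Gly1 ASA is classified with strict inequalities: exposed `> 50 Å²`,
buried `< 25 Å²`, otherwise transition — values exactly at a threshold
are transition. Occupancy summaries report state fractions (summing to
1), counts, adjacent state changes, and mean ASA. Runs are analysed
independently and may be pooled; ligands are ranked by exposed
fraction, ties broken by mean ASA then label. The exposed-fraction
statistic is this package's operationalisation of "sustaining the
epitope-exposed form"; no single numeric summary is canonical.

## Superposition and reachability

Kabsch superposition minimises least-squares deviation over proper
rotations (reflection-corrected via the SVD sign convention, through
`scipy.spatial.transform.Rotation.align_vectors`); inputs of fewer than
3 atoms, mismatched lengths, or collinear geometry are rejected.
Structure-level superposition pairs atoms by (chain, residue, atom
name) and drops unpaired atoms with a logged count. For MHC class I
comparisons the α1/α2 Cα selection defaults to heavy-chain residues
1–182, the standard domain boundary; the range is configurable because
deposited structures may vary.

Epitope reachability uses the donor–acceptor heavy-atom distance with a
3.5 Å cutoff (inclusive), the standard crystallographic hydrogen-bond
criterion in the absence of hydrogens; no angular term is applied. For
a carboxylate acceptor (E101 OE1/OE2) the minimum over the oxygen atoms
decides, and both distances are reported, since the relevant oxygen is
not identifiable without hydrogens.

## BLI kinetics

The 1:1 Langmuir model (association
`R = R_eq(1 − e^{−(k_aC + k_d)t})` with `R_eq = R_max C/(C + K_D)`;
dissociation `R(t_a) e^{−k_d(t−t_a)}`) is fitted **globally and
jointly over both phases**, sharing (k_a, k_d, R_max) across all
concentrations of a dilution series — the single-surface assumption.
Optimisation is in log-parameter space (positivity by construction)
with Levenberg–Marquardt least squares, multi-started on a
{0.1, 1, 10}× grid around data-driven initial values: k_d from a
log-linear fit of the top-dose dissociation tail, k_a from the slope of
observed rate vs concentration, R_max from 1.1× the maximum response.
Standard errors come from the Gauss–Newton covariance at the optimum;
`se(K_D)` by the delta method on `log k_d − log k_a`. The model is
evaluated on time since curve start, so a uniform time offset applied
consistently to all curves leaves the fit unchanged.

A fit is **poor** iff it fails to converge or its overall R² (pooled
across curves and phases) is below 0.9 (configurable); poor fits report
no K_D, mirroring instrument practice of withholding affinities from
failed global fits. Requiring at least two distinct concentrations
rejects under-determined single-curve fits. Steady-state affinity fits
`R_eq = R_max C/(C + K_D)` to plateau responses taken as the mean over
the final 10 % of each association window; it requires ≥ 3 distinct
concentrations and non-degenerate responses.

Defaults mirror the experimental protocol: 1:2 dilutions from 40 μM,
6 doses, 60 s per phase, ~2.5 nm saturation response, 0.5 s sampling.

## Synthetic data

The generators define the study conditions for all tests; they trade
physical realism for verifiable ground truth.

**Toy complex.** The antigen-binding groove is emulated as the smallest
geometry that buries or exposes Gly1 through a single parameter: two
dense walls of carbon pseudo-atoms (1.5 Å lattice) at y = ±2.8 Å,
rising 6 Å above a floor, flanking a channel that holds a
myristoylated tetrapeptide (MYR residue of 14 carbons + Gly1 + two
pseudo-residues + Ile4 anchored at the far end). The Gly1 elevation
above the rim is the mode switch; the generator *verifies* the built
structure with the SASA engine and nudges the elevation in 0.4 Å steps
(≤ 50 steps) until Gly1 ASA clears the generation margins — > 55 Å²
(exposed) or < 20 Å² (buried), deliberately inside the 50/25
classification thresholds so that trajectory jitter rarely flips a
constructed label. Small seed-dependent placement jitter (σ = 0.05 Å)
makes replicate complexes distinct; coordinates are rounded to PDB
precision so structures round-trip exactly. Typical achieved values:
~85–90 Å² exposed, ~0 Å² buried.

**Switching trajectories.** A hidden two-state Markov chain (default
p(exposed→buried) = 0.02, p(buried→exposed) = 0.08 per frame, i.e.
stationary exposed fraction 0.8; 5000 frames) selects a template per
frame; coordinates are the template plus i.i.d. Gaussian jitter
(σ = 0.15 Å per coordinate) on every atom, receptor included. True
labels are returned. There is no inertial dynamics and no
conformational pathway between states — the downstream analysis
consumes only per-frame ASA, so only state identity and dwell
statistics matter. Occupancy-recovery tolerances use the binomial
standard error with the chain's autocorrelation-corrected effective
sample size (lag-`stride` autocorrelation `(1 − p_eb − p_be)^stride`).

**Sensorgrams.** One curve per dose from the 1:1 model plus i.i.d.
Gaussian noise (σ = 0.02 nm default) and optional linear drift shared
with the included zero-concentration reference (so reference
subtraction removes it exactly). The two-site variant mixes two
independent 1:1 sites; the default poor-fit construction pairs a slow
site (k_a = 200 /(M·s), k_d = 5·10⁻³ /s) with an equal-weight fast
site (k_a = 5·10⁴, k_d = 1.0) — both ~25 μM affinity, so the
heterogeneity is purely kinetic: an instantaneous step riding on a slow
ramp, which a single 1:1 model cannot track (1:1 refits give R² ≈
0.87). All generators are pure functions of (spec, seed).

What passing tests show — and do not. Recovery of occupancies,
affinities, and labels from these generators validates the estimators
and the pipeline plumbing under the stated noise models. It does not
validate force-field accuracy, real conformational kinetics,
mass-transport effects in BLI, or SASA agreement with hydrogen-complete
calculations on real proteins.

## Pipeline and the antigenicity call

Per ligand, the pipeline runs every trajectory through the occupancy
stage (reported per run and pooled) and the sensorgram set through the
global fit; a ligand is called **high** iff its pooled exposed fraction
is ≥ 0.5 *and* a K_D was determined (fit converged, R² ≥ 0.9). Both
thresholds are configuration options; the call is labelled rule-based
in the output because the underlying science separates the groups
qualitatively, not by a published cutoff. Stage failures mark the
ligand failed and the run continues. Output JSON is deterministic for
fixed inputs, with the timestamp isolated in one metadata field.

## Problem sizes and numerical choices

Test and example workloads use the toy complex (~200 atoms), 400–5000
frame trajectories at stride 10, and 6-dose sensorgram sets of ~240
samples per curve; the affinity-recovery experiments average 20
simulate-and-refit replicates per setting. PDB parsing, multi-model
congruence checking, and serialisation are delegated to biotite, with
the package's policies (highest-occupancy altloc, lexicographic ties,
water skipping, element inference from atom names, 3-decimal coordinate
snapping) layered on top. Degenerate inputs raise typed errors
(`epidyn.errors`) rather than propagating library exceptions.

## Known limitations

- SASA absolute values depend on the radii set and hydrogen treatment;
  only like-for-like comparisons (same parameters) are meaningful.
- The 1:1 global fit assumes a homogeneous surface and no mass
  transport; heterogeneous data is flagged, not modelled.
- The toy groove is not a protein: its ASA scale brackets the
  classification thresholds by construction, and conclusions about real
  lipopeptide–MHC systems require real structures and trajectories.
- Binary trajectory formats are unsupported by design; convert to
  multi-model PDB upstream.
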
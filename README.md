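# epidyn

Quantitative tools linking the conformational dynamics of MHC class
I–bound lipopeptide antigens to their antigenic strength.

A subset of MHC class I molecules (e.g. the rhesus allomorph
Mamu-B\*05104) presents *N*-myristoylated short lipopeptides such as
C14nef4 (myristate–Gly-Gly-Ala-Ile) instead of conventional peptides.
The T-cell epitope is a single chemical feature: the amide bond joining
the fatty acid to Gly1. Whether a T-cell receptor can engage it depends
on whether that amide sits above the antigen-binding groove
(epitope-exposed) or is tucked inside it (epitope-buried) — and how
much of the time a dynamically switching ligand spends in each state.
`epidyn` implements the analysis chain that quantifies this:

1. **Solvent-accessible surface area** (`epidyn.sasa`) — Shrake–Rupley
   point sampling: each atom's sphere of radius *r*<sub>vdW</sub> + *r*<sub>probe</sub>
   (probe 1.4 Å) carries a deterministic golden-spiral lattice of 960
   points; a point is exposed iff it lies outside every neighbouring
   expanded sphere, and
   ASA<sub>i</sub> = (exposed/total) · 4π(*r*<sub>i</sub> + *r*<sub>probe</sub>)².
   Neighbours come from a uniform spatial grid that is provably
   equivalent to brute force; a closed-form two-sphere solution serves
   as an independent oracle.
2. **Trajectory state occupancy** (`epidyn.traj_analysis`) — the Gly1
   ASA is sampled every 10 frames of a trajectory and classified:
   exposed (> 50 Å²), buried (< 25 Å²), or transition. Occupancy
   fractions summarise how efficiently a ligand sustains the exposed
   epitope; ligands are ranked by exposed fraction.
3. **Geometry** (`epidyn.geometry`) — Kabsch least-squares
   superposition and RMSD (e.g. α1/α2-domain Cα atoms across crystal
   structures), interatomic distances, and a donor–acceptor
   reachability rule for the E101(TCR)–Gly1(N) hydrogen bond
   (≤ 3.5 Å).
4. **BLI kinetics** (`epidyn.kinetics`) — biolayer-interferometry
   sensorgrams under the 1:1 Langmuir model,

   R(t) = R_eq · (1 − e^{−(k_a C + k_d) t}),  R_eq = R_max · C / (C + K_D)

   during association and R(t_a) · e^{−k_d (t − t_a)} during
   dissociation, with K_D = k_d / k_a. A global fit shares
   (k_a, k_d, R_max) across a dilution series; fits that fail to
   converge or fall below R² = 0.9 are flagged and no K_D is reported.
   Steady-state affinity (R_eq vs C hyperbola) is fitted separately.
5. **Synthetic data** (`epidyn.synthetic_data`) — ground-truth-labelled
   generators: a pseudo-atomic groove–lipopeptide complex whose Gly1
   can be placed (and is SASA-verified) in either configuration,
   two-state Markov switching trajectories with coordinate jitter, and
   noisy serial-dilution sensorgram sets (including a two-site
   heterogeneous surface for exercising the poor-fit flag).
6. **Pipeline** (`epidyn.pipeline`, CLI `epidyn report`) — per-ligand
   occupancy + kinetics combined into a ranked antigenic-strength
   report with an explicit, rule-based high/low call.

Structures and multi-model trajectories are read and written as PDB
text (HETATM ligands such as the myristoyl group are first class).

## Worked example

```sh
python examples/bli_global_fit.py
```

```
1:1 data, 1:1 fit
  k_a  =     997.3 /(M s)   (true 1000)
  k_d  =   0.02518 /s       (true 0.0252)
  Rmax =     2.498 nm      (true 2.5)
  K_D  =     25.25 uM       (true 25.2)
  R^2  =    0.9944   poor_fit = False

two-site data, 1:1 fit
  R^2  =    0.8662   poor_fit = True
```

The first block simulates a 6-dose, 1:2 dilution series from 40 μM
(60 s association, 60 s dissociation, 0.02 nm Gaussian noise) at a true
affinity of 25.2 μM, subtracts the zero-concentration reference, and
recovers the generating constants from the global 1:1 refit. The second
block fits the same model to data from a heterogeneous two-site
surface: the R² falls below the 0.9 quality threshold, the fit is
flagged, and no K_D is reported — the behaviour expected for poorly
binding ligands whose sensorgrams resist a global 1:1 description.

The other scripts in `examples/` are equally short: per-residue SASA of
the toy complex (`sasa_of_a_structure.py`), occupancy recovery from a
switching trajectory (`trajectory_occupancy.py`), superposition RMSD
and reachability (`epitope_geometry.py`), and the end-to-end ranked
report (`antigenicity_report.py`).

A thin CLI mirrors the library:
`epidyn sasa`, `epidyn traj-asa`, `epidyn occupancy`, `epidyn rmsd`,
`epidyn contact`, `epidyn simulate-bli`, `epidyn fit-bli`,
`epidyn simulate-traj`, `epidyn select`, `epidyn report` (see
`epidyn <cmd> --help`).

## Scope notes

Force-field molecular dynamics, crystallographic data processing, and
T-cell assays are out of scope: trajectories enter as multi-model PDB
files (or from the synthetic generator), sensorgrams as CSV tables.
See `docs/methods.md` for the model details, parameter defaults, and
limitations.
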
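# Methods

This note documents the measurement conventions, the synthetic-data model
used to validate them, the numerical choices, and the known limitations.

## Scope and data model

The package consumes a topology plus F × A × 3 coordinate frames in Å with
frame times in ns. The native trajectory format is a multi-model PDB (one
MODEL per frame); parsing and writing go through biotite, with alternate
locations other than blank/'A' dropped and HETATM records retained. Residue
numbering is 1-based author numbering taken verbatim from the file — no
renumbering — so sequence numbers like 269 can be quoted directly alongside
their generic indices. Water residues are recognized by name
({HOH, WAT, TIP3, SOL, SPC}, overridable). Hydrogens are kept when present
(needed for hydrogen-bond angles) but all distance-based analyses use heavy
atoms only. Coordinates are assumed whole (no periodic-boundary wrapping);
the package never unwraps.

## Ballesteros–Weinstein numbering

Each helix is an inclusive residue range plus one anchor of known generic
position; anchors need not sit at .50 (TM6 here is anchored directly at
W269 = 6.48). Indices are stored as integer (helix, position) pairs and
rendered `H.PP` only at I/O, so 2.50 never collapses to the float 2.5.
The helix boundary residues shipped with the synthetic fixtures are
*reconstructed*: boundaries are not published for this receptor, so ranges
were chosen to be consistent with all seventeen printed residue/index pairs
(N63¹·⁵⁰ … P308⁷·⁵⁰) and to leave a 7-residue intracellular arm below the
TM7 pivot. They are a modelling convention, not literature values.

## Dihedrals and rotamer switches

χ angles use IUPAC atom quadruples (χ₁: N–CA–CB–G with G = CG/OG/OG1/SG/CG1
by residue type; χ₂: CA–CB–G–D with D = CD1 for Phe/Tyr/Trp, OD1 for
Asp/Asn, SD for Met, …) and the signed two-perpendicular formulation of the
dihedral, reported in (−180°, 180°]. A residue lacking a required atom is
rejected loudly rather than skipped.

Classification smooths the angle series with a circular median filter
(component-wise median of sin and cos, recombined by atan2; window 21
frames) and assigns each frame to a labeled circular bin. Default bins are
gauche− (−120°, 0°], gauche+ (0°, 120°], trans (120°, −120°] wrapping; the
toggle-switch analyses use two-state bins centered at 0° and 90°, matching
how the W6.48 χ₂ behaves. A switch event is logged at the first frame of a
maximal run of a new state of length ≥ min_dwell (default 50 frames);
shorter excursions leave the accepted state unchanged. Both the filter
window and dwell are configurable; their defaults mean a detected event
frame can differ from a true step by up to the filter half-window
(~11 frames), which is the tolerance the recovery tests use.

Hydrogen bonds use the common geometric criterion D–A ≤ 3.5 Å and
D–H···A ≥ 150° over hydrogens inferred by D–H ≤ 1.2 Å; without hydrogens
the angle term is dropped and the series is flagged `heavy_only`. Ligand
contacts use a 4.0 Å heavy-atom cutoff (the same convention as the water
shells), with per-residue occupancies plus single-frame contact lists for
designated (initial/final) frames.

## Hydration

A water counts toward a target's shell when its *oxygen* is within the
cutoff (default 4.0 Å) of any heavy atom of the target — oxygen-based
counting is resolution-independent and insensitive to whether the water
model carries hydrogens. The NPxxY motif target is defined as all heavy
atoms of the five motif residues (7.49–7.53), backbone included. Bridging
waters are distance-only (oxygen within the cutoff of both selections in
the same frame); no angular term, since the underlying observation is
geometric.

## Helix axes, kink, RMSD, end distances

**Axis fit.** For short arms a raw principal-component axis is biased by
the helical wobble itself: for a 7-residue arm of an ideal α-helix
(2.3 Å Cα radius, 100°/residue) the first PC is tilted ~18° from the true
axis. The estimator used instead projects the per-residue helical harmonic
out of the axial trend: direction ∝ Σᵢ cᵢ Pᵢ where the coefficients cᵢ are
the residue indices orthogonalized against {1, cos(ωi), sin(ωi)} with
ω = 100°/residue. This is exact for an ideal helix of that twist at any
phase and radius, reduces gracefully to a line fit, and among linear
estimators has minimal noise amplification. The sign is fixed N→C.

**Kink.** κ = 180° − arccos(u·v) with u, v the N→C axes of `window`
(default 7, ≈ two turns — all that fits in the short intracellular part of
TM7) residues on either side of the pivot, pivot excluded. Straight ≈ 180°,
monotone decreasing with bending; a rigid 50° rotation of the post-pivot
arm reads 130°. With σ = 0.2 Å coordinate noise a single-frame κ carries
~2–3° of estimator noise, so endpoint comparisons in the tests use
25-frame window means of measurement and schedule; single-frame values are
still reported where a single frame is asked for.

**RMSD.** Kabsch superposition (SVD with reflection guard, optional
weights) of each frame onto a reference frame — frame 0 by default, i.e.
the first stored (post-equilibration) structure — over the backbone
N/CA/C/O of all TM residues, then RMSD. scipy's independent rotation-
alignment implementation serves as the cross-check oracle in the tests,
never as the implementation.

**End distances.** Per frame, the Euclidean distances between centroids of
the Cα of the `end_length` (default 4, one helix turn) most intracellular
residues of TM3, TM6 and TM7, ordered (TM7–TM3, TM3–TM6, TM6–TM7).
"Cytoplasmic end" has no published definition; one turn of Cα centroid is
this package's convention.

## State clustering

k-means (k = 3, 50 seeded restarts) on the raw end-distance triples in Å —
no standardization, since all three axes share units and comparable scales.
Clusters are named by ascending centroid coordinate sum: activation moves
TM7 away from TM3 and TM6, so larger distances mean more active. The mean
silhouette coefficient is reported as the quantitative reading of "well
separated" (> 0.6 on the planted fixtures), and each state's central
structure is its medoid frame (minimum summed in-cluster distance). The
algorithm choice and the medoid definition are this package's conventions;
only the existence of three separable clusters is inherited from the
phenomenon being modelled.

## Synthetic data: what it emulates, what it does not

`synthetic_data.build_bundle` constructs ideal α-helices (Cα rise
1.5 Å/residue, 100°/residue twist, Cα radius 2.3 Å; backbone N, C, O on
ideal curves) standing on a 12 Å circle, alternating up/down like a GPCR
bundle, and then *plants* observables:

* **χ schedules** are realized exactly by internal-coordinate (NeRF)
  placement of minimal side-chain pseudo-atoms (CB + the γ/δ atoms the χ
  definitions need — not rotamer-library conformers); a rotamer flip is two
  breakpoints one frame apart.
* **Kink schedules** rigidly rotate the post-pivot arm about a
  perpendicular axis through the pivot Cα, so the planted κ is exact before
  noise.
* **End-distance phases** rigidly translate whole helices so the TM3/TM6/
  TM7 end centroids realize the scheduled triple exactly. Because a
  translation changes no internal angle, a kink schedule and an
  end-distance schedule on TM7 compose without conflict — the agonist-like
  fixture uses both, as the two observations come from the same condition.
* **Water schedules** place exactly the scheduled number of single-oxygen
  HOH residues in each target's shell per frame (oxygen 1.2 Å to
  cutoff−1.0 Å from the nearest target heavy atom; the 1 Å inner margin
  keeps σ = 0.2 Å noise from pushing planted waters across the boundary,
  and shell waters are kept ≥ cutoff + 1.5 Å from every *other* target).
  Unused water slots are parked far outside all shells so the topology is
  constant across frames; background waters are static negative controls
  ≥ cutoff + 6 Å from every target.
* i.i.d. Gaussian noise (default σ = 0.2 Å) is added to every coordinate
  last. Everything is deterministic given the spec and seed, down to
  byte-identical PDB output.

The three standard fixtures mirror the study conditions on a 700-frame,
1 ns/frame timeline: *apo-like* (early TM2-tyrosine flip at frame 100,
3–4 shell waters), *antagonist-like* (late flip at 550, early W-toggle
fluctuation, 5–7 waters), *agonist-like* (stable tyrosine, W/F toggle
instability, 8–10 waters, kink drift 155° → 130°, three end-distance
phases at frames 0/250/500). Smaller test fixtures scale these frame
numbers proportionally.

What passing recovery tests on this generator shows: the measurement code
computes the intended geometric/counting quantities correctly in the
presence of realistic coordinate noise, and the full pipeline is
deterministic. What it does not show: robustness to real-MD artifacts —
periodic wrapping, correlated thermal motion, helix irregularity
(π-bulges, 3₁₀ segments), rotamer transitions through intermediate states,
exchanging water populations, or force-field-dependent hydrogen placement.
Claims about real trajectories rest on the conventions above being the
standard ones, not on these tests.

## Numerical choices and degenerate inputs

Dihedrals raise on coincident/collinear central atoms; −180° is folded to
+180° to keep the half-open range. Bin sets must tile the circle exactly
(checked on a 0.5° probe grid); angles that land on a boundary within
floating-point noise snap to the nearest bin center. The Kabsch covariance
uses a determinant guard against reflections; collinear references are
rejected. k-means on zero-variance input raises a degenerate-data error
rather than returning an arbitrary split. Selection expressions use a small
recursive-descent grammar (resid ranges, name/resname/chain sets, backbone/
heavy/water/all keywords, and/or/not, parentheses); empty results are valid
except where an analysis requires atoms. TSV floats are written with four
decimals and JSON keys sorted, so reruns are byte-comparable; the
provenance block records the config digest (input basename, not path),
package version, and every analysis parameter.

## Problem sizes

The validation suite runs on 120–150-frame fixtures for pipeline-level
checks and one 700-frame agonist-like bundle (~900 atoms) for parameter
recovery; the acceptance script generates one 700-frame bundle for the
kink targets and one 200-frame bundle for the hydration target. These
sizes were chosen so the planted signals (dwell times ≥ 50 frames, three
≥ 150-frame state phases) are comfortably resolvable by the default filter
and dwell settings.

## Known limitations

* Multi-model PDB is the only built-in trajectory reader; binary formats
  (DCD/XTC) would enter as adapters behind the same `Trajectory` contract
  and are not included.
* The kink convention (arm length, axis estimator) is one of several in
  use; absolute κ values from different tools differ by a few degrees even
  on the same data, so comparisons should use one convention throughout.
* Whether the RMSD reference should be a crystal structure or the first
  stored frame is context-dependent; frame 0 is the default and a config
  knob, not a claim.
* No Markov-state modelling, kinetics, or free-energy estimates; the state
  assignment is purely geometric.
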
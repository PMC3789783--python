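# gpcrtraj

Trajectory analysis of G protein–coupled receptor (GPCR) activation, built
around the observables used to characterize the sphingosine 1-phosphate
receptor S1P₁: side-chain rotamer toggle switches, hydration of conserved
residues, the TM7 kink at its proline pivot, TM-region RMSD, and clustering
of intracellular helix-end distances into activation states. It is aimed at
computational structural biologists who have multi-frame coordinates of a
7-TM bundle (multi-model PDB) and want reproducible, scriptable measurements
of these activation observables — plus a synthetic-bundle generator with
planted ground truth so every measurement can be validated without any
simulation data.

## The observables

* **Ballesteros–Weinstein (BW) numbering.** Generic GPCR residue indices
  `H.PP`: helix `H`, position `PP`, with the most conserved residue of each
  helix at position 50. Given one anchor per helix (e.g. D91 = 2.50,
  W269 = 6.48, P308 = 7.50), position(r) = anchor_position + (r − anchor).
* **Rotamer switches.** Side-chain dihedrals χ₁ (N–CA–CB–G) and χ₂
  (CA–CB–G–D) are computed per frame as signed IUPAC angles, classified into
  circular bins (gauche−/trans/gauche+, or two-state 0°/90° bins for the
  W6.48-style toggle) after a circular median filter (window 21 frames), and
  a switch event is reported when a new state persists ≥ 50 frames.
* **Hydration shells.** Waters whose oxygen lies within 4 Å of any heavy
  atom of a target (the conserved 2.50 aspartate, the NPxxY motif) are
  counted per frame; bridging waters simultaneously within the cutoff of two
  disjoint selections are reported with their identities.
* **TM7 kink.** κ = 180° − angle(u, v), where u and v are the axes of
  7-residue arms flanking the 7.50 pivot (pivot excluded). A straight helix
  reads ~180°; activation-style bending reads 155° → 130°. Arm axes come
  from a helical-harmonic-filtered line fit that is exact on ideal helices
  (a raw principal component is tilted ~18° by the helix wobble on arms this
  short).
* **RMSD.** Optimal least-squares (Kabsch) superposition of the TM backbone
  onto a reference frame, then root-mean-square deviation.
* **Activation states.** Frames are clustered (k-means, k = 3, 50 restarts,
  seeded) in the 3D space of distances between cytoplasmic helix-end
  centroids (TM7–TM3, TM3–TM6, TM6–TM7); clusters are named inactive /
  intermediate / active by ascending centroid coordinate sum, since
  activation opens the intracellular face.

## Worked example

`examples/04_kink_and_states.py` generates a 700-frame agonist-like bundle
(coordinate noise σ = 0.2 Å) whose TM7 kink is scheduled to drift 155° → 130°
and whose helix ends traverse three separable phases, then measures both:

```
kink: first 25-frame mean  154.5 deg (planted 155), last  130.6 deg (planted 130)
states: sizes {'inactive': 250, 'intermediate': 250, 'active': 200}, silhouette 0.92, ARI vs planted truth 1.000
  central structure of 'inactive': frame 106 (distances [ 9. 11. 10.])
  central structure of 'intermediate': frame 458 (distances [11.5 13.5 12.5])
  central structure of 'active': frame 569 (distances [14. 16. 15.])
```

The kink means recover the planted endpoints within the estimator noise; the
adjusted Rand index of 1.0 says the clustering reproduces the planted phase
labels exactly, and the silhouette of 0.92 quantifies "well separated". The
other examples cover BW numbering (`01`), switch detection (`02`), hydration
per condition (`03`) and the full pipeline + condition comparison (`05`).

A thin CLI wraps the same pipeline:

```sh
gpcrtraj simulate -o sim --frames 700            # apo/antagonist/agonist fixtures
gpcrtraj analyze sim/agonist.pdb -o res/agonist --fixture-defaults
gpcrtraj analyze my_config.yaml -o res/mine      # arbitrary config
gpcrtraj compare res/* -o cmp
```

All outputs are TSV/JSON with fixed formatting; identical inputs and seeds
give byte-identical files.

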
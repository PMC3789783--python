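"""Water-shell occupancy around conserved residues, per condition.

The three fixture conditions plant different hydration levels in the
4 A shell of the conserved TM2 aspartate (apo ~3-4 waters, antagonist
~5-7, agonist ~8-10, mirroring the activation-dependent water influx).
Counts waters whose oxygen lies within 4 A of any heavy atom of the
target and prints the per-condition means.
"""

from gpcrtraj import water_count_series
from gpcrtraj.synthetic_data import build_bundle, fixture_specs

for name, spec in fixture_specs(seed=11, n_frames=300).items():
    traj, manifest = build_bundle(spec)
    series = water_count_series(traj, "resid 91 and heavy", cutoff=4.0)
    planted = sum(manifest.water_counts["D91(2.50)"]) / len(
        manifest.water_counts["D91(2.50)"]
    )
    print(
        f"{name:>10}: measured mean {series.mean:5.2f} waters "
        f"(planted {planted:5.2f}) in the 4 A shell of D91(2.50)"
    )
# The ordering apo < antagonist < agonist is the hydration signature of
# progressive receptor activation.
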
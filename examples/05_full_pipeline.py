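"""The full pipeline from one config, plus a condition comparison.

Writes the three fixture trajectories to disk, analyzes each with the
standard fixture configuration (chi switches, H-bonds, hydration, kink,
RMSD, end distances, clustering), and merges the bundles into one
comparison report.  Equivalent shell commands:

    gpcrtraj simulate -o sim --frames 300
    gpcrtraj analyze sim/agonist.pdb -o res/agonist --fixture-defaults
    gpcrtraj compare res/apo res/antagonist res/agonist -o cmp
"""

import tempfile
from pathlib import Path

from gpcrtraj import compare_conditions, run_analysis, write_fixture_suite
from gpcrtraj.pipeline import fixture_analysis_config

workdir = Path(tempfile.mkdtemp(prefix="gpcrtraj_"))
written = write_fixture_suite(workdir / "sim", seed=11, n_frames=300)

bundles, labels = [], []
for name in ("apo", "antagonist", "agonist"):
    cfg = fixture_analysis_config(written[name]["trajectory"])
    bundles.append(run_analysis(cfg, workdir / "res" / name))
    labels.append(name)

agonist = bundles[-1].summary
print("agonist state fractions:", {
    k: round(v, 2) for k, v in agonist["states"]["fractions"].items()
})
print("agonist kink first/last 25-frame means: "
      f"{agonist['kink']['mean_first25']:.1f} / {agonist['kink']['mean_last25']:.1f} deg")

report = compare_conditions(bundles, labels)
print("\nhydration means by condition:")
print(report.hydration_stats.to_string(index=False))
print(f"\nall tables under {workdir}/res/<condition>/")
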
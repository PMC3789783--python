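"""End-to-end analysis pipeline: one config in, a bundle of tables out.

``run_analysis`` executes the stages in dependency order — I/O, BW map,
chi series, rotamer/switch detection, hydrogen bonds, hydration, kink,
RMSD, end distances, state clustering — each of which can be disabled,
and writes deterministic TSV/JSON outputs (fixed float format, sorted
JSON keys, no timestamps) so reruns are byte-identical.
``compare_conditions`` aligns several result bundles (apo vs antagonist
vs agonist style) into one long-format table with per-condition
hydration statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bw_numbering import BWIndex, HelixDefinition, assign_bw
from .geometry import (
    EndDistanceSeries,
    chi_series,
    end_distance_series,
    kink_series,
    rmsd_series,
)
from .hydration import water_count_series
from .state_clustering import cluster_states, medoid_frames, state_summary
from .switch_analysis import (
    DEFAULT_CHI_BINS,
    TOGGLE_BINS,
    classify_rotamers,
    contact_occupancy,
    detect_switches,
    hbond_series,
)
from .trajectory_io import read_structure, read_trajectory

__all__ = ["AnalysisConfig", "ResultBundle", "ComparisonReport", "ConfigError",
           "ComparisonError", "run_analysis", "compare_conditions"]

logger = logging.getLogger("gpcrtraj")

ALL_STAGES = ("chi", "switches", "hbonds", "hydration", "contacts",
              "kink", "rmsd", "end_distances", "clustering")

_FLOAT_FMT = "%.4f"


class ConfigError(ValueError):
    """Invalid analysis configuration; message lists every problem."""


class ComparisonError(ValueError):
    """Result bundles are not comparable (mismatched observables)."""


@dataclass
class AnalysisConfig:
    structure: str
    dt_ns: float = 1.0
    water_names: list[str] | None = None
    helices: list[HelixDefinition] = field(default_factory=list)
    switch_residues: list[dict] = field(default_factory=list)
    filter_window: int = 21
    min_dwell: int = 50
    hbonds: list[dict] = field(default_factory=list)
    hydration_targets: list[dict] = field(default_factory=list)
    hydration_cutoff: float = 4.0
    contacts: dict | None = None
    kink: dict | None = None
    rmsd_selection: str | None = None
    rmsd_reference_frame: int = 0
    end_length: int = 4
    cluster_k: int = 3
    cluster_seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "AnalysisConfig":
        problems: list[str] = []
        structure = raw.get("structure")
        if not structure:
            problems.append("missing 'structure' path")
        elif base_dir is not None and not Path(structure).is_absolute():
            structure = str(base_dir / structure)
        helices = []
        for h in raw.get("helices", []):
            try:
                helices.append(
                    HelixDefinition(
                        helix_id=int(h["id"]),
                        start_seq=int(h["start"]),
                        end_seq=int(h["end"]),
                        anchor_seq=int(h["anchor_seq"]),
                        anchor_position=int(h.get("anchor_position", 50)),
                        intracellular_end=h.get("intracellular_end", "end"),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                problems.append(f"helix entry {h!r}: {exc}")
        hyd = raw.get("hydration", {}) or {}
        cutoff = float(hyd.get("cutoff", 4.0))
        if cutoff <= 0:
            problems.append(f"hydration cutoff must be > 0, got {cutoff}")
        contacts = raw.get("contacts")
        if contacts is not None and float(contacts.get("cutoff", 4.0)) < 0:
            problems.append("contact cutoff must be >= 0")
        switches = raw.get("switches", {}) or {}
        clustering = raw.get("clustering", {}) or {}
        rmsd = raw.get("rmsd", {}) or {}
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        if problems:
            raise ConfigError("; ".join(problems))
        return cls(
            structure=str(structure),
            dt_ns=float(raw.get("dt_ns", 1.0)),
            water_names=raw.get("water_names"),
            helices=helices,
            switch_residues=list(switches.get("residues", [])),
            filter_window=int(switches.get("filter_window", 21)),
            min_dwell=int(switches.get("min_dwell", 50)),
            hbonds=list(raw.get("hbonds", [])),
            hydration_targets=list(hyd.get("targets", [])),
            hydration_cutoff=cutoff,
            contacts=contacts,
            kink=raw.get("kink"),
            rmsd_selection=rmsd.get("selection"),
            rmsd_reference_frame=int(rmsd.get("reference_frame", 0)),
            end_length=int(raw.get("end_distances", {}).get("end_length", 4)),
            cluster_k=int(clustering.get("k", 3)),
            cluster_seed=int(clustering.get("seed", 0)),
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw, base_dir=path.parent)

    # ---- validation against the topology ---------------------------------
    def validate_against(self, topology) -> None:
        """Collect *every* problem before raising."""
        problems: list[str] = []
        residues = {seq for _, seq, _ in topology.residues}
        for entry in self.switch_residues:
            if int(entry.get("residue", -1)) not in residues:
                problems.append(f"switch residue {entry.get('residue')} not in topology")
            if entry.get("angle") not in ("chi1", "chi2"):
                problems.append(f"switch angle {entry.get('angle')!r} unsupported")
        for hb in self.hbonds:
            for role in ("donor", "acceptor"):
                res = int(hb.get(role, [-1, ""])[0])
                if res not in residues:
                    problems.append(f"h-bond {role} residue {res} not in topology")
        if self.kink is not None:
            pivot = int(self.kink.get("pivot", -1))
            if pivot not in residues:
                problems.append(f"kink pivot residue {pivot} not in topology")
            helix_ids = {h.helix_id for h in self.helices}
            if int(self.kink.get("helix", -1)) not in helix_ids:
                problems.append(f"kink helix {self.kink.get('helix')} undefined")
        for h in self.helices:
            missing = [s for s in (h.start_seq, h.end_seq) if s not in residues]
            if missing:
                problems.append(
                    f"helix {h.helix_id} boundary residues {missing} not in topology"
                )
        if self.min_dwell < 1:
            problems.append("min_dwell must be >= 1")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_provenance(self) -> dict:
        blob = {
            # basename only: identical inputs in different directories must
            # produce identical outputs
            "structure": Path(self.structure).name,
            "dt_ns": self.dt_ns,
            "filter_window": self.filter_window,
            "min_dwell": self.min_dwell,
            "hydration_cutoff": self.hydration_cutoff,
            "contact_cutoff": (self.contacts or {}).get("cutoff", None),
            "kink": self.kink,
            "end_length": self.end_length,
            "cluster_k": self.cluster_k,
            "cluster_seed": self.cluster_seed,
            "rmsd_reference_frame": self.rmsd_reference_frame,
            "stages": list(self.stages),
        }
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config_hash": digest, "version": __version__, "parameters": blob}


@dataclass
class ResultBundle:
    """All tables + the JSON summary produced by one analysis run."""

    output_dir: Path
    tables: dict[str, pd.DataFrame]
    summary: dict

    def table_path(self, name: str) -> Path:
        return self.output_dir / f"{name}.tsv"


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", label).strip("_")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_analysis(config: AnalysisConfig, output_dir: str | Path) -> ResultBundle:
    """Run every enabled stage and write the result bundle.

    Raises on any stage error (the CLI converts this to a nonzero exit
    status); logs per-stage timings and parameters to the logger.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"provenance": config.to_provenance()}

    t0 = time.perf_counter()
    topo, _coords = read_structure(config.structure, config.water_names)
    traj = read_trajectory(topo, config.structure, dt_ns=config.dt_ns)
    logger.info("io: %d frames, %d atoms (%.2fs)",
                traj.n_frames, traj.n_atoms, time.perf_counter() - t0)

    config.validate_against(topo)
    bw_map = assign_bw(config.helices) if config.helices else {}

    def bw_str(res: int) -> str:
        return str(bw_map[res]) if res in bw_map else ""

    frames = np.arange(traj.n_frames)

    def base_cols() -> dict:
        return {"frame": frames, "time_ns": traj.times}

    stages = set(config.stages)

    # --- chi series + switches -------------------------------------------
    events = []
    if "chi" in stages:
        t0 = time.perf_counter()
        for entry in config.switch_residues:
            res, angle = int(entry["residue"]), entry["angle"]
            series = chi_series(traj, res, angle)
            name = f"chi_{res}_{angle}"
            tables[name] = pd.DataFrame({**base_cols(), "value": series.values})
            if "switches" in stages:
                bins = TOGGLE_BINS if entry.get("bins") == "toggle" else DEFAULT_CHI_BINS
                states = classify_rotamers(series, bins, config.filter_window)
                events.extend(detect_switches(states, config.min_dwell))
        logger.info("chi/switches: %d series, %d events (%.2fs)",
                    len(config.switch_residues), len(events),
                    time.perf_counter() - t0)
    if "switches" in stages:
        tables["events"] = pd.DataFrame(
            [
                {
                    "residue": e.residue_seq,
                    "bw": bw_str(e.residue_seq),
                    "angle": e.angle_name,
                    "frame": e.frame_index,
                    "time_ns": e.time_ns,
                    "from_state": e.from_state,
                    "to_state": e.to_state,
                    "pre_dwell": e.pre_dwell,
                    "post_dwell": e.post_dwell,
                }
                for e in events
            ],
            columns=["residue", "bw", "angle", "frame", "time_ns",
                     "from_state", "to_state", "pre_dwell", "post_dwell"],
        )
        summary["switch_events"] = [
            {
                "bw": bw_str(e.residue_seq),
                "residue": e.residue_seq,
                "angle": e.angle_name,
                "frame": e.frame_index,
                "time_ns": e.time_ns,
                "from_state": e.from_state,
                "to_state": e.to_state,
            }
            for e in events
        ]

    # --- hydrogen bonds ---------------------------------------------------
    if "hbonds" in stages and config.hbonds:
        t0 = time.perf_counter()
        summary["hbonds"] = {}
        for hb in config.hbonds:
            donor = (int(hb["donor"][0]), str(hb["donor"][1]))
            acceptor = (int(hb["acceptor"][0]), str(hb["acceptor"][1]))
            hs = hbond_series(traj, donor, acceptor)
            key = f"hbond_{donor[0]}{donor[1]}_{acceptor[0]}{acceptor[1]}"
            tables[key] = pd.DataFrame(
                {**base_cols(), "present": hs.present.astype(int)}
            )
            summary["hbonds"][key] = {
                "occupancy": hs.occupancy,
                "heavy_only": hs.heavy_only,
                "donor_bw": bw_str(donor[0]),
                "acceptor_bw": bw_str(acceptor[0]),
            }
        logger.info("hbonds: %d pairs (%.2fs)", len(config.hbonds),
                    time.perf_counter() - t0)

    # --- hydration --------------------------------------------------------
    if "hydration" in stages and config.hydration_targets:
        t0 = time.perf_counter()
        summary["hydration"] = {}
        for tgt in config.hydration_targets:
            label = tgt["label"]
            hs = water_count_series(
                traj, tgt["selection"], config.hydration_cutoff, label
            )
            tables[f"hydration_{_safe_name(label)}"] = pd.DataFrame(
                {**base_cols(), "count": hs.counts}
            )
            summary["hydration"][label] = {
                "mean": hs.mean,
                "cutoff": config.hydration_cutoff,
            }
        logger.info("hydration: %d targets (%.2fs)",
                    len(config.hydration_targets), time.perf_counter() - t0)

    # --- ligand contacts ---------------------------------------------------
    if "contacts" in stages and config.contacts:
        t0 = time.perf_counter()
        table = contact_occupancy(
            traj,
            config.contacts["ligand"],
            cutoff=float(config.contacts.get("cutoff", 4.0)),
            ligand_label=config.contacts.get("label", "ligand"),
        )
        tables["contacts"] = pd.DataFrame(
            {
                "residue": list(table.occupancy),
                "bw": [bw_str(r) for r in table.occupancy],
                "occupancy": list(table.occupancy.values()),
            }
        )
        summary["contacts"] = {
            "cutoff": table.cutoff,
            "snapshots": {str(k): v for k, v in table.snapshots.items()},
        }
        logger.info("contacts (%.2fs)", time.perf_counter() - t0)

    # --- kink ---------------------------------------------------------------
    if "kink" in stages and config.kink:
        t0 = time.perf_counter()
        helix = next(
            h for h in config.helices if h.helix_id == int(config.kink["helix"])
        )
        ks = kink_series(
            traj, helix, int(config.kink["pivot"]),
            int(config.kink.get("window", 7)),
        )
        tables["kink"] = pd.DataFrame({**base_cols(), "value": ks.values})
        summary["kink"] = {
            "pivot": ks.pivot_seq,
            "pivot_bw": bw_str(ks.pivot_seq),
            "first": float(ks.values[0]),
            "last": float(ks.values[-1]),
            "mean_first25": float(ks.values[:25].mean()),
            "mean_last25": float(ks.values[-25:].mean()),
        }
        logger.info("kink (%.2fs)", time.perf_counter() - t0)

    # --- RMSD ---------------------------------------------------------------
    if "rmsd" in stages:
        t0 = time.perf_counter()
        sel = config.rmsd_selection
        if sel is None and config.helices:
            ranges = " or ".join(
                f"resid {h.start_seq}-{h.end_seq}" for h in config.helices
            )
            sel = f"backbone and ( {ranges} )"
        elif sel is None:
            sel = "backbone"
        values = rmsd_series(traj, config.rmsd_reference_frame, sel)
        tables["rmsd"] = pd.DataFrame({**base_cols(), "value": values})
        summary["rmsd"] = {
            "selection": sel,
            "reference_frame": config.rmsd_reference_frame,
            "mean": float(values.mean()),
            "final": float(values[-1]),
        }
        logger.info("rmsd (%.2fs)", time.perf_counter() - t0)

    # --- end distances + clustering ----------------------------------------
    if "end_distances" in stages and config.helices:
        t0 = time.perf_counter()
        by_id = {h.helix_id: h for h in config.helices}
        if all(h in by_id for h in (3, 6, 7)):
            ed = end_distance_series(
                traj, by_id[3], by_id[6], by_id[7], config.end_length
            )
            cols = dict(zip(ed.labels, ed.values.T))
            tables["end_distances"] = pd.DataFrame({**base_cols(), **cols})
            logger.info("end_distances (%.2fs)", time.perf_counter() - t0)

            if "clustering" in stages:
                t0 = time.perf_counter()
                assignment = cluster_states(
                    ed, k=config.cluster_k, seed=config.cluster_seed
                )
                tables["states"] = pd.DataFrame(
                    {**base_cols(), **cols, "state": assignment.labels}
                )
                rep = state_summary(assignment, traj.times)
                rep_medoids = medoid_frames(assignment, ed)
                summary["states"] = {
                    "fractions": rep.fractions,
                    "centroids": rep.centroids,
                    "sizes": assignment.sizes,
                    "silhouette": assignment.silhouette,
                    "medoid_frames": rep_medoids,
                    "first_frame": rep.first_frame,
                    "last_frame": rep.last_frame,
                    "seed": assignment.seed,
                }
                logger.info("clustering: silhouette %.3f (%.2fs)",
                            assignment.silhouette, time.perf_counter() - t0)

    # --- persist ------------------------------------------------------------
    for name, df in tables.items():
        _write_tsv(df, out / f"{name}.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return ResultBundle(out, tables, summary)


def fixture_analysis_config(structure: str | Path, cluster_seed: int = 0) -> AnalysisConfig:
    """AnalysisConfig matching the synthetic fixture suite's conventions.

    Watches the toggle residues (TM2 tyrosine chi1, TM6 tryptophan chi2
    with two-state bins, TM6 phenylalanine chi1), the conserved-aspartate
    and NPxxY hydration shells at 4 A, the TM7 kink about its proline
    pivot and the TM3/TM6/TM7 end-distance clustering.
    """
    from .synthetic_data import default_helices  # avoid import cycle

    return AnalysisConfig(
        structure=str(structure),
        helices=[hp.definition for hp in default_helices()],
        switch_residues=[
            {"residue": 98, "angle": "chi1"},
            {"residue": 269, "angle": "chi2", "bins": "toggle"},
            {"residue": 265, "angle": "chi1"},
        ],
        hydration_targets=[
            {"label": "D91(2.50)", "selection": "resid 91 and heavy"},
            {"label": "NPxxY", "selection": "resid 307-311 and heavy"},
        ],
        kink={"helix": 7, "pivot": 308, "window": 7},
        cluster_seed=cluster_seed,
    )


@dataclass
class ComparisonReport:
    long: pd.DataFrame                  # condition, observable, frame, value
    hydration_stats: pd.DataFrame       # condition, target, mean, q25, q50, q75

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.long, out / "comparison_long.tsv")
        _write_tsv(self.hydration_stats, out / "hydration_stats.tsv")


def compare_conditions(
    bundles: list[ResultBundle], labels: list[str]
) -> ComparisonReport:
    """Align several condition bundles into one long-format comparison.

    All bundles must share hydration target labels and cutoffs; the
    report carries per-condition hydration means and quartiles.
    """
    if len(bundles) != len(labels):
        raise ComparisonError("one label per bundle required")
    ref_hyd = bundles[0].summary.get("hydration", {})
    for b in bundles[1:]:
        hyd = b.summary.get("hydration", {})
        if set(hyd) != set(ref_hyd):
            raise ComparisonError(
                f"hydration targets differ: {sorted(ref_hyd)} vs {sorted(hyd)}"
            )
        for k in ref_hyd:
            if hyd[k]["cutoff"] != ref_hyd[k]["cutoff"]:
                raise ComparisonError(f"cutoff mismatch for target {k!r}")

    rows = []
    stats = []
    for label, bundle in zip(labels, bundles):
        for name, df in bundle.tables.items():
            value_col = (
                "value" if "value" in df.columns
                else "count" if "count" in df.columns
                else None
            )
            if value_col is None or "frame" not in df.columns:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "observable": name,
                        "frame": df["frame"],
                        "value": df[value_col],
                    }
                )
            )
            if name.startswith("hydration_"):
                q = df[value_col].quantile([0.25, 0.5, 0.75])
                stats.append(
                    {
                        "condition": label,
                        "target": name.removeprefix("hydration_"),
                        "mean": df[value_col].mean(),
                        "q25": q.loc[0.25],
                        "q50": q.loc[0.5],
                        "q75": q.loc[0.75],
                    }
                )
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["condition", "observable", "frame", "value"]
    )
    return ComparisonReport(long, pd.DataFrame(stats))
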
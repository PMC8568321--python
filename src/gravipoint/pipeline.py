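"""End-to-end orchestration: simulate -> qc -> features -> stats -> report.

Stages communicate via files under the output directory so each one can be
replayed in isolation: ``data/`` (trial tables + ground-truth sidecar),
``qc_report.csv``, ``features.csv``, ``emg_features.csv``, ``effects.csv``,
``stats.csv``, ``manifest.json``, and summary plots.  Identical config and
seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .emg import emg_features_table, normalize_iemg
from .errors import GravipointError
from .generate import GeneratorParams, inject_defects, simulate_experiment
from .io import ScreenGeometry, write_dataset
from .kinematics import apply_accuracy_filter, features_table
from .preprocess import qc_dataset
from .stats import aggregate, analyze

KINEMATIC_RESPONSES = ("duration_s", "signed_deviation_mm", "curvature_mm", "rtpv")


@dataclass
class RunManifest:
    """Provenance and per-stage row counts for one pipeline run."""

    config_hash: str
    seed: int
    version: str
    out_dir: str
    trials_generated: int
    qc_excluded: int
    qc_excluded_by_reason: dict
    accuracy_excluded: int
    movements_retained: int
    cells: int
    contrast_rows: int

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def run_experiment(config: RunConfig, defect_spec: dict | None = None) -> RunManifest:
    """Execute all stages with a shared seed; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["emg_band_hz"] = list(config.emg_band_hz)
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    config_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]

    params = GeneratorParams(seed=config.seed, **config.generator_overrides)
    trials, truth = simulate_experiment(
        params, config.n_participants, config.n_parabolas, seed=config.seed
    )
    if defect_spec:
        trials, defect_truth = inject_defects(trials, defect_spec, seed=config.seed)
        truth = truth.drop(columns=["defect"]).merge(
            defect_truth, on="stem", how="left"
        ).fillna({"defect": ""})
    data_dir = out / "data"
    write_dataset(trials, data_dir)
    truth.to_csv(data_dir / "ground_truth.csv", index=False)

    geometry = ScreenGeometry()
    qc = qc_dataset(trials, geometry, config.qc)
    qc.to_csv(out / "qc_report.csv", index=False)

    feats = features_table(trials, qc, geometry, config.accuracy_limit_mm)
    feats = apply_accuracy_filter(feats, config.accuracy_limit_mm)
    feats.to_csv(out / "features.csv", index=False)

    qc_pass = dict(zip(qc["stem"], qc["passed"]))
    retained_map = dict(zip(feats["stem"], feats["retained"]))
    emg_ok = [t for t in trials if retained_map.get(t.stem, False)]
    emg = emg_features_table(emg_ok, config.emg_band_hz, config.emg_envelope_hz)
    try:
        emg = normalize_iemg(emg)
    except GravipointError:
        emg["iemg_normalized"] = np.nan
    emg["retained"] = True
    emg.to_csv(out / "emg_features.csv", index=False)

    stats_rows = []
    n_cells = (
        len(aggregate(feats, ["duration_s"]))
        if feats["retained"].any() and "duration_s" in feats.columns
        else 0
    )
    for response in KINEMATIC_RESPONSES:
        if response not in feats.columns:
            continue
        try:
            con = analyze(feats, response, "target_distance_cm", config.bonferroni_family)
        except GravipointError:
            continue
        stats_rows.append(con)
    if "iemg_normalized" in emg.columns and emg["iemg_normalized"].notna().any():
        try:
            con = analyze(emg, "iemg_normalized", "muscle", config.bonferroni_family)
            stats_rows.append(con)
        except GravipointError:
            pass
    stats = (
        pd.concat(stats_rows, ignore_index=True)
        if stats_rows
        else pd.DataFrame(columns=["response", "direction", "comparison", "z", "p_adjusted"])
    )
    stats.to_csv(out / "stats.csv", index=False)

    if config.make_plots:
        _summary_plots(feats, emg, out)

    qc_fail = qc[~qc["passed"]]
    by_reason: dict[str, int] = {}
    for reasons in qc_fail["reasons"]:
        for r in str(reasons).split(";"):
            if r:
                by_reason[r] = by_reason.get(r, 0) + 1
    acc_excluded = int(
        ((feats["absolute_deviation_mm"] > config.accuracy_limit_mm)
         & feats["stem"].map(qc_pass).fillna(False)).sum()
        if "absolute_deviation_mm" in feats.columns else 0
    )
    manifest = RunManifest(
        config_hash=config_hash,
        seed=config.seed,
        version=__version__,
        out_dir=str(out),
        trials_generated=len(trials),
        qc_excluded=int((~qc["passed"]).sum()),
        qc_excluded_by_reason=by_reason,
        accuracy_excluded=acc_excluded,
        movements_retained=int(feats["retained"].sum()),
        cells=n_cells,
        contrast_rows=len(stats),
    )
    manifest.save(out / "manifest.json")
    (out / "report.txt").write_text(make_report(manifest, stats))
    return manifest


def _summary_plots(feats: pd.DataFrame, emg: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [("micro", False), ("micro", True), ("normo", False), ("normo", True),
             ("hyper", False), ("hyper", True)]
    labels = ["0g", "0gC", "1g", "1gC", "2g", "2gC"]
    panels = [
        (feats, "duration_s", "movement duration (s)"),
        (feats, "absolute_deviation_mm", "absolute deviation (mm)"),
        (feats, "curvature_mm", "curvature max-x (mm)"),
        (emg, "iemg_normalized", "normalized iEMG"),
    ]
    fig, axes = plt.subplots(2, 4, figsize=(16, 7), sharex=True)
    for col, (df, response, title) in enumerate(panels):
        for row, direction in enumerate(("up", "down")):
            ax = axes[row, col]
            if response not in df.columns:
                ax.set_visible(False)
                continue
            sel = df[(df["direction"] == direction) & df.get("retained", True)]
            means, sems = [], []
            for g, c in order:
                v = sel[(sel.gravity_condition == g) & (sel.compensation == c)][response]
                means.append(v.mean())
                sems.append(v.sem() if len(v) > 1 else 0.0)
            ax.bar(labels, means, yerr=sems, capsize=3, color="tab:blue", alpha=0.8)
            ax.set_title(f"{title} ({direction})", fontsize=9)
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=110)
    plt.close(fig)


def make_report(manifest: RunManifest, stats: pd.DataFrame) -> str:
    """Human-readable tabulation of the six planned contrasts per response."""
    lines = [
        "gravipoint run report",
        f"  config {manifest.config_hash}  seed {manifest.seed}  version {manifest.version}",
        f"  trials generated {manifest.trials_generated}, QC-excluded "
        f"{manifest.qc_excluded}, accuracy-excluded {manifest.accuracy_excluded}, "
        f"movements retained {manifest.movements_retained}",
        "",
    ]
    if stats.empty:
        lines.append("no contrasts computed")
        return "\n".join(lines) + "\n"
    for (response, direction), grp in stats.groupby(["response", "direction"]):
        lines.append(f"{response} [{direction}]")
        lines.append("  comparison   z        p(adj)")
        for row in grp.itertuples(index=False):
            if np.isnan(row.z):
                lines.append(f"  {row.comparison:<10} undefined")
            else:
                star = " *" if row.p_adjusted < 0.05 else ""
                lines.append(
                    f"  {row.comparison:<10} {row.z:+7.3f}  {row.p_adjusted:6.4f}{star}"
                )
        lines.append("")
    return "\n".join(lines) + "\n"
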
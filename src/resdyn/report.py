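"""Orchestration of the full WT-vs-variant comparison.

One config drives the whole workflow: per-protein metrics (RMSD, Rg, KDE,
RMSF), DCC category fractions, dynamic residue networks, WT − variant Δ
profiles and the two-standard-deviation outlier screen. Results land in a
machine-readable :class:`ComparisonReport` plus CSV/JSON artefacts under
the configured output directory, and render as fixed-width summary and
outlier tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .correlation import classify_motion, dcc_matrix
from .metrics import (
    DensityEstimate,
    MetricSeries,
    ResidueProfile,
    SummaryRow,
    delta_profile,
    kde_distribution,
    rg_series,
    rmsd_series,
    rmsf_profile,
    round_half_up,
    summary_table,
)
from .network import (
    DEFAULT_CUTOFF,
    OutlierReport,
    average_profiles,
    network_timeseries,
    select_outliers,
)
from .trajectory import Trajectory, TrajectoryError, read_multimodel_pdb

logger = logging.getLogger("resdyn")

__all__ = ["RunConfig", "ComparisonReport", "run_comparison", "render_tables"]


@dataclass
class RunConfig:
    """Configuration of a full comparison run.

    ``proteins`` maps each label to a multi-model PDB path; ``wt_label``
    names the reference protein. Network sampling is controlled by
    ``stride`` directly or by ``interval_ps`` via the trajectory timestep.
    """

    proteins: dict[str, str]
    wt_label: str
    selection: str = "CA"
    network_selection: str = "CB_GLY_CA"
    cutoff: float = DEFAULT_CUTOFF
    stride: int | None = None
    interval_ps: float | None = 100.0
    timestep_ps: float | None = None
    kde_bandwidth: float | None = None
    sd_k: float = 2.0
    dcc_thresholds: tuple[float, float] = (-0.25, 0.25)
    rmsd_reference_frame: int = 0
    frame_range: tuple[int, int] | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.wt_label not in self.proteins:
            raise TrajectoryError(f"wt_label {self.wt_label!r} not among proteins")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "dcc_thresholds" in raw:
            raw["dcc_thresholds"] = tuple(raw["dcc_thresholds"])
        if raw.get("frame_range") is not None:
            raw["frame_range"] = tuple(raw["frame_range"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dict(self.__dict__)
        d["dcc_thresholds"] = list(self.dcc_thresholds)
        if self.frame_range is not None:
            d["frame_range"] = list(self.frame_range)
        return d


@dataclass
class ComparisonReport:
    """Everything one comparison run computes, in memory."""

    summary: list[SummaryRow]
    kde: dict[str, dict[str, DensityEstimate]]  # label -> metric -> estimate
    dcc_fractions: dict[str, dict[str, float]]
    rmsf: dict[str, ResidueProfile]
    network: dict[str, dict[str, ResidueProfile]]  # label -> avgL/avgBC/avgBC_raw
    deltas: dict[str, dict[str, ResidueProfile]]  # variant -> metric -> Δ profile
    outliers: dict[str, dict[str, OutlierReport]]  # variant -> deltaL/deltaBC/deltaRMSF
    provenance: dict

    def variants(self) -> list[str]:
        return list(self.deltas)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _check_topologies(trajs: dict[str, Trajectory], wt_label: str) -> None:
    wt_labels = trajs[wt_label].residue_labels
    for label, traj in trajs.items():
        if label == wt_label:
            continue
        other = traj.residue_labels
        if len(other) != len(wt_labels):
            raise TrajectoryError(
                f"variant {label}: residue count {len(other)} != WT {len(wt_labels)}"
            )
        for a, b in zip(wt_labels, other):
            if a.residue_number != b.residue_number:
                raise TrajectoryError(
                    f"variant {label}: first differing residue {b} (WT has {a})"
                )


def run_comparison(
    config: RunConfig, trajectories: dict[str, Trajectory] | None = None
) -> ComparisonReport:
    """Execute metrics → DCC → DRN → Δ → outlier screen for every protein.

    ``trajectories`` may be supplied in memory (e.g. synthetic ones);
    otherwise they are read from the configured paths. Deterministic given
    identical config and inputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    checksums: dict[str, str] = {}
    if trajectories is None:
        trajectories = {}
        for label, path in config.proteins.items():
            logger.info("stage=read protein=%s path=%s", label, path)
            trajectories[label] = read_multimodel_pdb(
                path, label=label, timestep_ps=config.timestep_ps
            )
            checksums[label] = _checksum(path)
    for lab, traj in trajectories.items():
        traj.label = lab  # report sections are keyed by the configured label
    _check_topologies(trajectories, config.wt_label)
    wt_label = config.wt_label
    variants = [lab for lab in trajectories if lab != wt_label]

    logger.info("stage=metrics")
    rmsd = {
        lab: rmsd_series(t, config.selection, config.rmsd_reference_frame)
        for lab, t in trajectories.items()
    }
    rg = {lab: rg_series(t, config.selection) for lab, t in trajectories.items()}
    summary = summary_table(list(rmsd.values()), wt_label, config.frame_range)
    summary += summary_table(list(rg.values()), wt_label, config.frame_range)

    kde: dict[str, dict[str, DensityEstimate]] = {}
    for lab in trajectories:
        kde[lab] = {}
        for metric, series in (("RMSD", rmsd[lab]), ("Rg", rg[lab])):
            try:
                kde[lab][metric] = kde_distribution(series, config.kde_bandwidth)
            except TrajectoryError:
                logger.warning("stage=kde protein=%s metric=%s degenerate", lab, metric)

    logger.info("stage=dcc")
    dcc_fractions = {}
    for lab, t in trajectories.items():
        mat = dcc_matrix(t, selection=config.selection)
        dcc_fractions[lab] = classify_motion(mat, config.dcc_thresholds).fractions

    logger.info("stage=rmsf")
    rmsf = {lab: rmsf_profile(t, config.selection) for lab, t in trajectories.items()}

    logger.info("stage=drn")
    network: dict[str, dict[str, ResidueProfile]] = {}
    for lab, t in trajectories.items():
        ts = network_timeseries(
            t,
            cutoff=config.cutoff,
            stride=config.stride,
            interval_ps=config.interval_ps if config.stride is None else None,
            selection=config.network_selection,
        )
        avg = average_profiles(ts, label=lab)
        network[lab] = {m: avg.profile(m) for m in ("avgL", "avgBC", "avgBC_raw")}

    logger.info("stage=delta")
    deltas: dict[str, dict[str, ResidueProfile]] = {}
    outliers: dict[str, dict[str, OutlierReport]] = {}
    for var in variants:
        d_rmsf = delta_profile(rmsf[wt_label], rmsf[var])
        d_l = delta_profile(network[wt_label]["avgL"], network[var]["avgL"])
        d_bc = delta_profile(network[wt_label]["avgBC"], network[var]["avgBC"])
        deltas[var] = {"deltaRMSF": d_rmsf, "deltaL": d_l, "deltaBC": d_bc}
        outliers[var] = {
            m: select_outliers(p, k=config.sd_k) for m, p in deltas[var].items()
        }

    provenance = {
        "config": config.echo(),
        "resdyn_version": _version,
        "input_checksums": checksums,
    }
    report = ComparisonReport(
        summary=summary,
        kde=kde,
        dcc_fractions=dcc_fractions,
        rmsf=rmsf,
        network=network,
        deltas=deltas,
        outliers=outliers,
        provenance=provenance,
    )
    if config.output_dir:
        write_artifacts(report, config.output_dir)
    return report


# --------------------------------------------------------------------------
# Artefacts
# --------------------------------------------------------------------------


def _profile_frame(profile: ResidueProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {"residue_label": [str(l) for l in profile.labels], "value": profile.values}
    )


def _outlier_dict(rep: OutlierReport) -> dict:
    pos_meaning, neg_meaning = rep.semantics
    return {
        "metric": rep.metric,
        "mean": rep.mean,
        "sd": rep.sd,
        "k": rep.k,
        "note": rep.note,
        "increase": {
            "meaning": pos_meaning,
            "residues": [str(r) for r in rep.increase_residues],
        },
        "decrease": {
            "meaning": neg_meaning,
            "residues": [str(r) for r in rep.decrease_residues],
        },
    }


def write_artifacts(report: ComparisonReport, output_dir: str | Path) -> None:
    """Write summary.csv, kde_/drn_/delta_ CSVs, outlier JSONs and report.json."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "label": r.label,
                "metric": r.metric,
                "mean": round_half_up(r.mean, 3),
                "pct_diff": round_half_up(r.percent_difference_from_wt, 2),
            }
            for r in report.summary
        ]
    ).to_csv(out / "summary.csv", index=False)
    for lab, per_metric in report.kde.items():
        for metric, est in per_metric.items():
            pd.DataFrame({"grid": est.grid, "density": est.density}).to_csv(
                out / f"kde_{lab}_{metric}.csv", index=False
            )
    for lab, per_metric in report.network.items():
        df = _profile_frame(per_metric["avgL"]).rename(columns={"value": "avg_L_norm"})
        df["avg_BC_norm"] = per_metric["avgBC"].values
        df["avg_BC_raw"] = per_metric["avgBC_raw"].values
        df.to_csv(out / f"drn_{lab}.csv", index=False)
    for lab, prof in report.rmsf.items():
        _profile_frame(prof).to_csv(out / f"rmsf_{lab}.csv", index=False)
    for var, per_metric in report.deltas.items():
        for metric, prof in per_metric.items():
            _profile_frame(prof).to_csv(out / f"delta_{var}_{metric}.csv", index=False)
    for var, per_metric in report.outliers.items():
        with open(out / f"outliers_{var}.json", "w", encoding="utf-8") as fh:
            json.dump(
                {m: _outlier_dict(r) for m, r in per_metric.items()}, fh, indent=2
            )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report_json(report), fh, indent=2, sort_keys=True)


def report_json(report: ComparisonReport) -> dict:
    """The machine-readable report (no timestamps, hence reproducible)."""
    return {
        "summary": [
            {
                "label": r.label,
                "metric": r.metric,
                "mean": round_half_up(r.mean, 3),
                "pct_diff": round_half_up(r.percent_difference_from_wt, 2),
            }
            for r in report.summary
        ],
        "dcc_fractions": report.dcc_fractions,
        "outliers": {
            var: {m: _outlier_dict(r) for m, r in per.items()}
            for var, per in report.outliers.items()
        },
        "provenance": report.provenance,
    }


# --------------------------------------------------------------------------
# Text tables
# --------------------------------------------------------------------------


def _fmt_residues(residues: list) -> str:
    return " ".join(str(r) for r in residues) if residues else "—"


def render_tables(report: ComparisonReport) -> str:
    """Fixed-width summary (means + % difference) and outlier-quadrant tables."""
    lines: list[str] = []
    lines.append("Per-protein metric means and percent difference from WT")
    lines.append(f"{'Protein':<10s} {'Metric':<6s} {'Mean':>9s} {'% diff':>8s}")
    for r in report.summary:
        mean, pct = r.rounded()
        lines.append(f"{r.label:<10s} {r.metric:<6s} {mean:>9.3f} {pct:>8.2f}")
    if report.outliers:
        lines.append("")
        lines.append("Residues beyond the k·SD screen of each Δ distribution")
        for var, per in report.outliers.items():
            lines.append(f"-- {var}")
            for metric in ("deltaL", "deltaBC", "deltaRMSF"):
                if metric not in per:
                    continue
                rep = per[metric]
                pos, neg = rep.semantics
                lines.append(f"   {metric} (+): {pos}: {_fmt_residues(rep.increase_residues)}")
                lines.append(f"   {metric} (−): {neg}: {_fmt_residues(rep.decrease_residues)}")
    return "\n".join(lines) + "\n"
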
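"""End-to-end orchestration: simulate/load -> preprocess -> FC -> stats -> CV.

Every stage writes its artifacts under the output directory and the run
manifest records the configuration hash, master seed and all output files,
so a run is fully reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .classify import CVReport, reports_to_frame, run_classification
from .connectivity import channel_fc, roi_fc, stack_cohort, whole_brain_mean
from .group_stats import run_edge_stats
from .montage import Montage, load_montage
from .preprocess import PreprocConfig, preprocess
from .simulate import CohortSpec, default_calibration, iter_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full run; any field can come from YAML."""

    out_dir: str = "nirsfc_run"
    seed: int = 0
    input_manifest: str | None = None      # if None, simulate
    n_per_group: int = 64
    duration: float = 600.0
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    cohort_overrides: dict = field(default_factory=dict)
    cv_repeats: int = 10
    cv_folds: int = 5
    run_classification: bool = True
    write_matrices: bool = True
    montage_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pre = raw.pop("preproc", {})
        # config keys may use the conventional parameter names
        renames = {"SDThresh": "sd_thresh", "AMPThresh": "amp_thresh",
                   "tMotion": "t_motion", "tMask": "t_mask", "p": "spline_p",
                   "DPF": "dpf"}
        pre = {renames.get(k, k): v for k, v in pre.items()}
        cfg = cls(**raw)
        cfg.preproc = PreprocConfig(**pre)
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (np.ndarray,)):
                return o.tolist()
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_spec(cfg: PipelineConfig, montage: Montage) -> CohortSpec:
    return default_calibration(
        seed=cfg.seed, n_per_group=cfg.n_per_group, duration=cfg.duration,
        montage=montage, **cfg.cohort_overrides,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = load_montage(cfg.montage_path)
    outputs: list[str] = []

    if cfg.input_manifest is not None:
        recordings = nio.read_cohort(cfg.input_manifest)
    else:
        recordings = iter_cohort(_cohort_spec(cfg, montage))

    qc_rows = []
    channel_ms, roi_ms = [], []
    wb_rows = []
    mat_dir = out / "matrices"
    if cfg.write_matrices:
        mat_dir.mkdir(exist_ok=True)
    for rec in recordings:
        hb = preprocess(rec, cfg.preproc)
        cm_ch = channel_fc(hb)
        cm_roi = roi_fc(hb, montage)
        channel_ms.append(cm_ch)
        roi_ms.append(cm_roi)
        qc_rows.append({
            "subject_id": hb.subject_id, "group": hb.group,
            **hb.qc_summary,
        })
        wb_rows.append({"subject_id": hb.subject_id, "group": hb.group,
                        "whole_brain_z": whole_brain_mean(cm_ch)})
        if cfg.write_matrices:
            nio.write_matrix(cm_ch, mat_dir / f"{hb.subject_id}_channel.tsv")
            nio.write_matrix(cm_roi, mat_dir / f"{hb.subject_id}_roi.tsv")
            outputs += [f"matrices/{hb.subject_id}_channel.tsv",
                        f"matrices/{hb.subject_id}_roi.tsv"]
        logger.info("processed %s", hb.subject_id)
    if not qc_rows:
        raise ValueError("empty cohort")

    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    wb = pd.DataFrame(wb_rows)
    wb.to_csv(out / "whole_brain.tsv", sep="\t", index=False, float_format="%.6f")
    stack_cohort(roi_ms).to_csv(out / "roi_edges_long.tsv", sep="\t",
                                index=False, float_format="%.6f")
    outputs += ["qc_report.tsv", "whole_brain.tsv", "roi_edges_long.tsv"]

    stats = {}
    for level, ms in (("channel", channel_ms), ("roi", roi_ms)):
        table = run_edge_stats(ms)
        table.to_csv(out / f"edge_stats_{level}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        outputs.append(f"edge_stats_{level}.tsv")
        stats[level] = table

    reports: list[CVReport] = []
    if cfg.run_classification:
        reports = run_classification(
            {"roi": roi_ms, "channel": channel_ms}, stats,
            k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed,
        )
        if reports:
            reports_to_frame(reports).to_csv(
                out / "cv_report.tsv", sep="\t", index=False,
                float_format="%.4f")
            outputs.append("cv_report.tsv")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": len(qc_rows),
        "outputs": sorted(outputs),
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_report(out_dir: str | Path) -> str:
    """Human-readable summary of a completed (possibly partial) run."""
    out = Path(out_dir)
    lines = [f"nirsfc run report: {out}", "=" * 40]

    wb_path = out / "whole_brain.tsv"
    if wb_path.exists():
        wb = pd.read_csv(wb_path, sep="\t")
        lines.append("\nWhole-brain mean Fisher z by group:")
        for g, sub in wb.groupby("group"):
            lines.append(f"  {g}: {sub.whole_brain_z.mean():.3f} "
                         f"+/- {sub.whole_brain_z.std(ddof=1):.3f} "
                         f"(n={len(sub)})")
    else:
        lines.append("\n[whole-brain summary missing]")

    roi_path = out / "edge_stats_roi.tsv"
    if roi_path.exists():
        roi = pd.read_csv(roi_path, sep="\t")
        top = roi.sort_values("auc", ascending=False).head(6)
        lines.append("\nTop ROI edges by AUC:")
        for r in top.itertuples():
            lines.append(
                f"  {r.node_i}-{r.node_j}: AUC={r.auc:.3f} t={r.t:.2f} "
                f"p_fdr={r.p_fdr:.4f}")
    else:
        lines.append("\n[ROI edge statistics missing]")

    ch_path = out / "edge_stats_channel.tsv"
    if ch_path.exists():
        ch = pd.read_csv(ch_path, sep="\t")
        strong = ch[ch["strong"] == True]  # noqa: E712  (read back as object)
        lines.append(f"\nChannel edges: {int((ch['sig'] == True).sum())} "
                     f"significant, {len(strong)} at the strong threshold:")
        for r in strong.itertuples():
            lines.append(f"  {r.node_i}-{r.node_j}: sens={r.sens:.1%} "
                         f"spec={r.spec:.1%}")
    else:
        lines.append("\n[channel edge statistics missing]")

    cv_path = out / "cv_report.tsv"
    if cv_path.exists():
        cv = pd.read_csv(cv_path, sep="\t")
        lines.append("\nRepeated 5-fold LDA accuracies (%):")
        for r in cv.itertuples():
            lines.append(f"  {r.feature_set}: mean {r.mean:.2f} +/- {r.sd:.2f},"
                         f" max {r.max:.2f}")
    else:
        lines.append("\n[classification report not present]")

    return "\n".join(lines)
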
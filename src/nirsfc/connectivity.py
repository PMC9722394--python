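"""Fisher-z functional connectivity at channel and ROI level.

Connectivity is the Pearson correlation of HbO time courses over the full
recording, variance-stabilised with Fisher's r-to-z transform
(z = atanh r).  With 71 channels the channel-level matrix carries
71*70/2 = 2485 undirected edges; averaging each ROI's member channels
first gives the 9x9 (36-edge) ROI-level matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage, ROI_LABELS
from .preprocess import HbRecording

logger = logging.getLogger(__name__)

#: |r| at or above this is clipped before atanh so z stays finite
#: (atanh(1 - 1e-7) ~ 8.38); immaterial for any downstream statistic.
R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix for one subject at one analysis level."""

    level: str                    # "channel" | "roi"
    labels: tuple[str, ...]
    z: np.ndarray                 # (n, n), NaN diagonal / missing nodes
    subject_id: str = ""
    group: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.z[i, j])

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        return self.z[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.labels, columns=self.labels)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with the |r| -> 1 clipping rule applied."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _corr_z(x: np.ndarray) -> np.ndarray:
    """Pairwise Fisher z between rows of ``x``; zero-variance rows -> NaN."""
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance series yield missing edges", dead.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return z


def channel_fc(hb: HbRecording, labels: tuple[str, ...] | None = None) -> ConnectivityMatrix:
    """Channel-level connectivity; QC-failed channels yield missing entries."""
    x = np.asarray(hb.hbo, float)
    n_ch, n_t = x.shape
    if n_t < 30:
        raise ValueError("series too short for a stable correlation (need >= 30)")
    if hb.qc_pass is not None and int(hb.qc_pass.sum()) < 2:
        raise ValueError("fewer than 2 channels pass QC")
    z = _corr_z(x)
    if hb.qc_pass is not None:
        failed = ~np.asarray(hb.qc_pass, bool)
        z[failed, :] = np.nan
        z[:, failed] = np.nan
    if labels is None:
        labels = tuple(f"CH{i + 1}" for i in range(n_ch))
    return ConnectivityMatrix("channel", labels, z, hb.subject_id, hb.group)


def whole_brain_mean(cm: ConnectivityMatrix) -> float:
    """Mean Fisher z over the upper triangle (missing entries excluded)."""
    vals = cm.upper_values()
    n_valid = int(np.isfinite(vals).sum())
    if n_valid == 0:
        raise ValueError("no valid edges")
    if n_valid < vals.size:
        logger.info("whole-brain mean over %d/%d edges", n_valid, vals.size)
    return float(np.nanmean(vals))


def roi_fc(hb: HbRecording, montage: Montage,
           average: str = "timeseries") -> ConnectivityMatrix:
    """ROI-level connectivity from averaged member-channel HbO series.

    ``average="timeseries"`` (default) averages each ROI's passing member
    channels before correlating the nine ROI mean series.
    ``average="edges"`` instead averages the channel-level Fisher-z values
    over all between-ROI channel pairs (sensitivity alternative).
    """
    x = np.asarray(hb.hbo, float)
    qc = np.ones(x.shape[0], bool) if hb.qc_pass is None else np.asarray(hb.qc_pass, bool)
    labels = tuple(ROI_LABELS)

    if average == "edges":
        ch = channel_fc(hb)
        z = np.full((9, 9), np.nan)
        idx = [montage.roi_indices(r) for r in labels]
        for i in range(9):
            for j in range(i + 1, 9):
                block = ch.z[np.ix_(idx[i], idx[j])]
                z[i, j] = z[j, i] = np.nanmean(block)
        return ConnectivityMatrix("roi", labels, z, hb.subject_id, hb.group)
    if average != "timeseries":
        raise ValueError("average must be 'timeseries' or 'edges'")

    means = np.full((9, x.shape[1]), np.nan)
    for i, roi in enumerate(labels):
        idx = montage.roi_indices(roi)
        idx = idx[qc[idx]]
        if idx.size == 0:
            logger.warning("ROI %s has no passing channels; edges missing", roi)
            continue
        means[i] = x[idx].mean(axis=0)
    valid = np.isfinite(means).all(axis=1)
    z = np.full((9, 9), np.nan)
    if valid.sum() >= 2:
        z_sub = _corr_z(means[valid])
        z[np.ix_(valid, valid)] = z_sub
    return ConnectivityMatrix("roi", labels, z, hb.subject_id, hb.group)


def stack_cohort(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format cohort table: subject, group, node_i, node_j, z."""
    rows = []
    for cm in matrices:
        iu = np.triu_indices(cm.n_nodes, 1)
        for i, j in zip(*iu):
            rows.append((cm.subject_id, cm.group, cm.labels[i], cm.labels[j],
                         cm.z[i, j]))
    return pd.DataFrame(rows, columns=["subject", "group", "node_i", "node_j", "z"])
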
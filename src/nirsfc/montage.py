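"""Probe geometry: the 71-channel montage and its nine-ROI partition.

The measurement grid covers prefrontal, temporal, parietal and occipital
cortex.  Each channel carries a mean MNI coordinate (mm), an anatomical
label and a region-of-interest (ROI) assignment used for the ROI-level
connectivity analysis.  The channel->ROI mapping is data, not code: the
bundled table can be replaced by any file with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ROI labels: left/right prefrontal, left/right temporal,
#: superior parietal, left/right inferior parietal, left/right occipital.
ROI_LABELS: tuple[str, ...] = (
    "LPF", "RPF", "LT", "P", "RT", "LIP", "RIP", "LO", "RO",
)

#: Label normalisation applied at load time.  "MO" (a stray medial-occipital
#: tag on one channel of the bundled table) is folded into the right
#: occipital ROI so that the nine-ROI partition is preserved.
DEFAULT_ROI_ALIASES: Mapping[str, str] = {"MO": "RO"}

MONTAGE_COLUMNS = ["channel_id", "x", "y", "z", "roi", "anatomic_label"]


@dataclass(frozen=True)
class Channel:
    """A single source-detector measurement channel."""

    channel_id: int
    mni: tuple[float, float, float]
    roi: str
    anatomic_label: str = ""
    source_id: int | None = None
    detector_id: int | None = None


@dataclass(frozen=True)
class Montage:
    """An ordered collection of channels plus the ROI partition.

    ``roi_partition`` maps each ROI label to the frozen set of member
    channel ids; the sets are pairwise disjoint and cover every channel.
    """

    channels: tuple[Channel, ...]
    roi_partition: Mapping[str, frozenset[int]]
    #: channel ids whose printed coordinates duplicate another row
    #: (kept verbatim -- coordinates are metadata only).
    coordinate_duplicates: tuple[int, ...] = field(default=())

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(c.channel_id for c in self.channels)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(self.roi_partition)

    def roi_of(self, channel_id: int) -> str:
        for roi, members in self.roi_partition.items():
            if channel_id in members:
                return roi
        raise KeyError(f"unknown channel id {channel_id}")

    def roi_indices(self, roi: str) -> np.ndarray:
        """0-based positions (array rows) of a ROI's member channels."""
        members = roi_members(self, roi)
        return np.array(
            [i for i, c in enumerate(self.channels) if c.channel_id in members],
            dtype=int,
        )

    def roi_sizes(self) -> dict[str, int]:
        return {roi: len(m) for roi, m in self.roi_partition.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "x": [c.mni[0] for c in self.channels],
                "y": [c.mni[1] for c in self.channels],
                "z": [c.mni[2] for c in self.channels],
                "roi": [c.roi for c in self.channels],
                "anatomic_label": [c.anatomic_label for c in self.channels],
            }
        )


def default_montage_path() -> Path:
    return Path(resources.files("nirsfc.data") / "montage_71ch.tsv")


_DEFAULT_MONTAGE: "Montage | None" = None


def default_montage() -> "Montage":
    """The bundled montage, loaded (and validated) once per process."""
    global _DEFAULT_MONTAGE
    if _DEFAULT_MONTAGE is None:
        _DEFAULT_MONTAGE = load_montage()
    return _DEFAULT_MONTAGE


def load_montage(
    path: str | Path | None = None,
    roi_aliases: Mapping[str, str] = DEFAULT_ROI_ALIASES,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> Montage:
    """Load and validate a montage table.

    The file is a tab-separated table with columns
    ``channel_id  x  y  z  roi  anatomic_label`` (1-based channel ids).
    ROI labels are normalised through ``roi_aliases`` before validation;
    duplicate channel ids or unknown ROI labels are hard errors.
    """
    if path is None:
        path = default_montage_path()
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MONTAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"montage table missing columns: {missing}")

    ids = df["channel_id"].astype(int)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate channel ids in montage: {sorted(set(dup))}")

    coords = df[["x", "y", "z"]].to_numpy(float)
    if not np.all(np.isfinite(coords)):
        bad = ids[~np.isfinite(coords).all(axis=1)].tolist()
        raise ValueError(f"non-finite MNI coordinates for channels {bad}")

    rois = []
    for cid, raw in zip(ids, df["roi"].astype(str)):
        roi = roi_aliases.get(raw, raw)
        if roi != raw:
            logger.warning("channel %d: ROI label %r normalised to %r", cid, raw, roi)
        if roi not in roi_labels:
            raise ValueError(f"channel {cid}: unknown ROI label {raw!r}")
        rois.append(roi)

    channels = tuple(
        Channel(
            channel_id=int(cid),
            mni=(float(x), float(y), float(z)),
            roi=roi,
            anatomic_label=str(lbl),
        )
        for cid, (x, y, z), roi, lbl in zip(
            ids, coords, rois, df["anatomic_label"].astype(str)
        )
    )

    partition = {
        roi: frozenset(c.channel_id for c in channels if c.roi == roi)
        for roi in roi_labels
    }
    empty = [roi for roi, m in partition.items() if not m]
    if empty:
        raise ValueError(f"empty ROIs in montage: {empty}")

    # flag verbatim coordinate duplicates (validation report, not an error)
    _, inverse, counts = np.unique(
        coords.round(6), axis=0, return_inverse=True, return_counts=True
    )
    dup_ids = tuple(int(i) for i in ids[counts[inverse] > 1])
    if dup_ids:
        logger.warning("montage rows with duplicated coordinates: %s", dup_ids)

    return Montage(channels=channels, roi_partition=partition,
                   coordinate_duplicates=dup_ids)


def roi_members(montage: Montage, roi: str) -> frozenset[int]:
    """Channel ids belonging to ``roi``; unknown labels raise ``KeyError``."""
    try:
        return montage.roi_partition[roi]
    except KeyError:
        raise KeyError(
            f"unknown ROI label {roi!r}; defined: {list(montage.roi_partition)}"
        ) from None


def write_montage(montage: Montage, path: str | Path) -> None:
    montage.to_frame().to_csv(path, sep="\t", index=False)
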
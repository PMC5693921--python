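"""Transcript conservation scored by the maximally conserved 200-nt window.

Per-base phastCons-like scores in [0, 1] are summarized per transcript as the
maximum, over all contiguous windows of 200 bases (step 1), of the window
mean; transcripts shorter than the window fall back to the mean of all bases.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "max_window_conservation",
    "conservation_filter",
    "read_conservation",
    "write_conservation",
]


def max_window_conservation(track, window: int = 200) -> float:
    """Maximum window-mean conservation along a per-base score track.

    Uses a rolling (cumulative-sum) mean, O(n).  Tracks shorter than
    ``window`` return the mean of the whole track (logged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(track, dtype=float)
    if x.size == 0:
        raise ValueError("empty conservation track")
    if np.nanmin(x) < 0 or np.nanmax(x) > 1:
        raise ValueError("conservation scores must lie in [0, 1]")
    if x.size < window:
        logger.info(
            "track length %d < window %d; using whole-track mean", x.size, window
        )
        return float(x.mean())
    csum = np.concatenate([[0.0], np.cumsum(x)])
    sums = csum[window:] - csum[:-window]
    return float(sums.max() / window)


def conservation_filter(
    tracks: dict[str, np.ndarray], threshold: float = 0.9, window: int = 200
) -> list[str]:
    """Transcript ids whose maximal window conservation reaches ``threshold``."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        tid
        for tid, track in tracks.items()
        if max_window_conservation(track, window) >= threshold
    ]


def read_conservation(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-base conservation tracks from TSV.

    Two layouts are accepted, distinguished by column count:

    * 4 columns (bedGraph-like): transcript_id, start, end, score with
      0-based half-open intervals, expanded to per-base scores;
    * 3 columns: transcript_id, pos (1-based), score.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    tracks: dict[str, np.ndarray] = {}
    if df.shape[1] == 4:
        df.columns = ["tid", "start", "end", "score"]
        for tid, grp in df.groupby("tid", sort=False):
            length = int(grp["end"].max())
            track = np.zeros(length)
            for _, row in grp.iterrows():
                track[int(row["start"]) : int(row["end"])] = row["score"]
            tracks[str(tid)] = track
    elif df.shape[1] == 3:
        df.columns = ["tid", "pos", "score"]
        for tid, grp in df.groupby("tid", sort=False):
            length = int(grp["pos"].max())
            track = np.zeros(length)
            track[grp["pos"].astype(int) - 1] = grp["score"].to_numpy()
            tracks[str(tid)] = track
    else:
        raise ValueError("expected 3 (per-base) or 4 (bedGraph) columns")
    for tid, track in tracks.items():
        if track.min() < 0 or track.max() > 1:
            raise ValueError(f"scores outside [0, 1] for transcript {tid}")
    return tracks


def write_conservation(tracks: dict[str, np.ndarray], path: str | Path) -> Path:
    """Write tracks as bedGraph-like TSV with one interval per base run."""
    path = Path(path)
    with path.open("w") as fh:
        for tid, track in tracks.items():
            start = 0
            for i in range(1, len(track) + 1):
                if i == len(track) or track[i] != track[start]:
                    fh.write(f"{tid}\t{start}\t{i}\t{track[start]:.6g}\n")
                    start = i
    return path
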
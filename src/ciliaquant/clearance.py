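"""Bead tracking and mucociliary-clearance metrics.

Coordinated ciliary beating transports fluorescent beads directionally
across the epithelial surface; uncoordinated or static cilia leave the
beads to diffuse in place.  Beads are detected per frame, linked into
trajectories by mutual nearest neighbour, and clearance is summarized
by mean speed, per-track straightness (net displacement over path
length), and directional coherence — the mean resultant length of the
per-track net-displacement unit vectors.  Clearance is called present
when the transport is both coherent and fast enough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import VideoStack
from .polarity import detect_spots

__all__ = [
    "Track",
    "ClearanceMetrics",
    "detect_beads",
    "link_tracks",
    "compute_clearance_metrics",
    "track_beads",
    "tracks_to_frame",
]


@dataclass
class Track:
    """One linked bead trajectory (positions in µm, consecutive frames)."""

    id: int
    frames: list[int]
    positions: np.ndarray  # (n, 2) of (y, x) µm
    complete: bool = True  # False when the track runs into the field edge

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if len(self.frames) != len(self.positions) or len(self.frames) < 2:
            raise ValueError("a track needs >= 2 positions, one per frame")
        df = np.diff(self.frames)
        if np.any(df != 1):
            raise ValueError("track frames must be strictly consecutive (no gap closing)")

    @property
    def net_displacement(self) -> np.ndarray:
        return self.positions[-1] - self.positions[0]

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum())


@dataclass
class ClearanceMetrics:
    """Directional-transport summary of a set of tracks."""

    n_tracks: int
    mean_speed: float            # µm/s; NaN with no tracks
    straightness: float          # mean of per-track net/path, in [0, 1]
    directional_coherence: float # resultant length of net-direction unit vectors
    mean_direction: float        # rad, CCW from +x (y-down negated); NaN if incoherent
    clearance_call: str          # "present" or "absent"


def detect_beads(
    frame: np.ndarray,
    pixel_size_um: float,
    sigma_um: float = 0.15,
    rel_threshold: float = 0.2,
    min_separation_um: float = 0.6,
) -> np.ndarray:
    """Detect beads in one frame; returns (n, 2) positions in µm."""
    spots = detect_spots(
        frame,
        pixel_size_nm=pixel_size_um * 1000.0,
        sigma_nm=sigma_um * 1000.0,
        min_separation_nm=min_separation_um * 1000.0,
        rel_threshold=rel_threshold,
    )
    return spots.coordinates * pixel_size_um


def link_tracks(
    detections: list[np.ndarray],
    max_step_um: float,
    field_size_um: tuple[float, float] | None = None,
    edge_margin_um: float = 0.0,
) -> list[Track]:
    """Link per-frame detections into tracks by mutual nearest neighbour.

    Frame-to-frame links longer than ``max_step_um`` are forbidden;
    unmatched detections start new tracks; there is no gap closing.
    With ``field_size_um`` given, tracks that approach the field border
    within ``edge_margin_um`` are flagged incomplete.
    """
    open_tracks: list[tuple[list[int], list[np.ndarray]]] = []
    closed: list[tuple[list[int], list[np.ndarray]]] = []
    for t, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 2)
        matched_new = np.zeros(len(dets), dtype=bool)
        still_open = []
        if open_tracks and len(dets):
            last = np.array([trk[1][-1] for trk in open_tracks])
            d = cdist(last, dets)
            for i, trk in enumerate(open_tracks):
                j = int(np.argmin(d[i]))
                ok = (
                    d[i, j] <= max_step_um
                    and int(np.argmin(d[:, j])) == i
                    and np.sum(d[i] == d[i, j]) == 1
                    and np.sum(d[:, j] == d[i, j]) == 1
                )
                if ok:
                    trk[0].append(t)
                    trk[1].append(dets[j])
                    matched_new[j] = True
                    still_open.append(trk)
                else:
                    closed.append(trk)
        else:
            closed.extend(open_tracks)
        open_tracks = still_open
        for j in np.flatnonzero(~matched_new):
            open_tracks.append(([t], [dets[j]]))
    closed.extend(open_tracks)
    tracks = []
    for frames, positions in closed:
        if len(frames) < 2:
            continue
        pos = np.asarray(positions)
        complete = True
        if field_size_um is not None:
            fy, fx = field_size_um
            m = edge_margin_um
            complete = bool(
                np.all((pos[:, 0] >= m) & (pos[:, 0] <= fy - m) & (pos[:, 1] >= m) & (pos[:, 1] <= fx - m))
            )
        tracks.append(Track(id=len(tracks), frames=frames, positions=pos, complete=complete))
    return tracks


def compute_clearance_metrics(
    tracks: list[Track],
    fps: float,
    coherence_threshold: float = 0.6,
    speed_floor: float = 0.5,
) -> ClearanceMetrics:
    """Summarize tracks into clearance metrics and a present/absent call.

    Per track: speed = path length * fps / (n_points - 1); straightness
    = net displacement / path length.  Coherence is the resultant length
    of the per-track net-displacement unit vectors (tracks with zero net
    displacement contribute nothing).  Clearance is "present" iff
    coherence >= ``coherence_threshold`` and mean speed >=
    ``speed_floor`` µm/s.
    """
    if not tracks:
        warnings.warn("no tracks: clearance metrics undefined", stacklevel=2)
        return ClearanceMetrics(0, float("nan"), float("nan"), float("nan"), float("nan"), "absent")
    speeds, straights, units = [], [], []
    for trk in tracks:
        path = trk.path_length
        speeds.append(path * fps / (len(trk.frames) - 1))
        net = trk.net_displacement
        net_norm = float(np.linalg.norm(net))
        if path > 0:
            straights.append(net_norm / path)
            if net_norm > 0:
                units.append(net / net_norm)
        else:
            straights.append(0.0)
    mean_speed = float(np.mean(speeds))
    straightness = float(np.mean(straights))
    if units:
        mean_vec = np.mean(units, axis=0)
        coherence = float(np.linalg.norm(mean_vec))
        direction = float(np.arctan2(-mean_vec[0], mean_vec[1])) if coherence > 1e-12 else float("nan")
    else:
        coherence, direction = 0.0, float("nan")
    call = "present" if (coherence >= coherence_threshold and mean_speed >= speed_floor) else "absent"
    return ClearanceMetrics(len(tracks), mean_speed, straightness, coherence, direction, call)


def track_beads(
    video: VideoStack,
    sigma_um: float = 0.15,
    rel_threshold: float = 0.2,
    max_step_um: float | None = None,
    edge_margin_um: float = 0.0,
) -> list[Track]:
    """Detect and link beads across a whole video."""
    dets = [
        detect_beads(frame, video.pixel_size, sigma_um=sigma_um, rel_threshold=rel_threshold)
        for frame in video.data
    ]
    if max_step_um is None:
        fy, fx = np.array(video.data.shape[1:]) * video.pixel_size
        max_step_um = 0.05 * min(fy, fx)
    field = tuple(np.array(video.data.shape[1:]) * video.pixel_size)
    return link_tracks(dets, max_step_um, field_size_um=field, edge_margin_um=edge_margin_um)


def tracks_to_frame(tracks: list[Track], pixel_size_um: float | None = None) -> pd.DataFrame:
    """Long-format table of track points (track_id, frame, y_um, x_um)."""
    rows = []
    for trk in tracks:
        for f, (y, x) in zip(trk.frames, trk.positions):
            rows.append({"track_id": trk.id, "frame": f, "y_um": y, "x_um": x})
    return pd.DataFrame(rows, columns=["track_id", "frame", "y_um", "x_um"])
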
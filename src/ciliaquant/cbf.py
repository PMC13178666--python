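"""Per-pixel ciliary-beat-frequency mapping and per-cell summaries.

The temporal intensity trace of each pixel in a video of beating,
fluorescently labelled cilia oscillates at the local beat frequency.  A
single-taper periodogram per pixel gives a power spectrum; the dominant
in-band frequency makes the CBF map, and pixels whose spectral peak does
not stand out from the rest of the band are marked inactive (static).
Per-cell CBF is the median dominant frequency over the cell's active
pixels, and cells are classified into automatable beat modes:
``static`` (almost no active pixels), ``restricted`` (active but with
low spectral amplitude relative to the field) or ``beating``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import VideoStack

__all__ = [
    "FrequencyMap",
    "CellCBF",
    "BeatModeThresholds",
    "pixel_power_spectrum",
    "dominant_frequency_map",
    "summarize_cell_cbf",
    "classify_beat_mode",
    "assign_beat_modes",
    "field_motility_index",
    "cells_to_frame",
]

MIN_FRAMES = 16


@dataclass
class FrequencyMap:
    """Per-pixel dominant-frequency map of a video.

    ``dominant_freq`` is in Hz (NaN where no in-band power exists),
    ``peak_power`` and ``total_power`` are the peak and total in-band
    spectral power, and ``active`` marks pixels whose peak passes the
    activity criterion.
    """

    dominant_freq: np.ndarray
    peak_power: np.ndarray
    total_power: np.ndarray
    active: np.ndarray
    band: tuple[float, float]
    freq_resolution: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.active.shape


@dataclass
class CellCBF:
    """Per-cell ciliary beat statistics."""

    label: int
    n_pixels: int
    n_active: int
    active_fraction: float
    cbf_median: float          # Hz; NaN when no active pixels
    cbf_iqr: float             # Hz; NaN when no active pixels
    mean_peak_power: float     # over active pixels; NaN when none
    beat_mode: str = "unclassified"


@dataclass
class BeatModeThresholds:
    """Thresholds for the automatable beat modes.

    ``active_fraction_static``: a cell with a smaller fraction of active
    pixels is static.  ``amplitude_restricted``: an active cell whose
    mean peak power falls below this fraction of the field-median active
    peak power beats with restricted (low) amplitude.  ``min_cbf`` (Hz):
    peaks below this are not treated as beating when summarizing.
    """

    active_fraction_static: float = 0.05
    amplitude_restricted: float = 0.25
    min_cbf: float = 0.5


def _validate_video(video: VideoStack) -> np.ndarray:
    data = np.asarray(video.data, dtype=np.float64)
    if data.shape[0] < MIN_FRAMES:
        raise ValueError(f"insufficient frames: need >= {MIN_FRAMES}, got {data.shape[0]}")
    return data


def pixel_power_spectrum(
    video: VideoStack,
    detrend: str = "linear",
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of every pixel's intensity trace.

    Returns ``(spectrum, freqs)`` where ``spectrum`` has shape
    (floor(T/2)+1, Y, X).  The trace is detrended (``"mean"`` or
    ``"linear"``), tapered (``"none"`` or ``"hann"``), re-centred, and
    Fourier transformed; the power normalization makes the spectrum sum
    to the variance of the tapered trace (Parseval), so the DC bin is
    exactly zero.
    """
    data = _validate_video(video)
    T = data.shape[0]
    flat = data.reshape(T, -1)
    if detrend == "mean":
        flat = flat - flat.mean(axis=0, keepdims=True)
    elif detrend == "linear":
        flat = sps.detrend(flat, axis=0, type="linear")
    else:
        raise ValueError(f"unknown detrend {detrend!r}; use 'mean' or 'linear'")
    if window == "hann":
        taper = sps.windows.hann(T, sym=False)
        flat = flat * taper[:, None]
    elif window != "none":
        raise ValueError(f"unknown window {window!r}; use 'none' or 'hann'")
    flat = flat - flat.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(flat, axis=0)) ** 2 / (T * T)
    # fold negative frequencies into the one-sided spectrum
    if T % 2 == 0:
        spec[1:-1] *= 2.0
    else:
        spec[1:] *= 2.0
    freqs = np.fft.rfftfreq(T, d=1.0 / video.fps)
    return spec.reshape((spec.shape[0],) + data.shape[1:]), freqs


def dominant_frequency_map(
    video: VideoStack,
    band: tuple[float, float] = (0.5, 30.0),
    activity_threshold: float = 0.2,
    floor_factor: float = 5.0,
    detrend: str = "linear",
    window: str = "hann",
) -> FrequencyMap:
    """Map each pixel to its dominant in-band frequency.

    A pixel is active when its spectral peak holds at least
    ``activity_threshold`` of the total in-band power *and* rises at
    least ``floor_factor`` times above the median in-band bin (the noise
    floor).  Ties in the peak search resolve to the lowest frequency.
    """
    f_min, f_max = band
    if not (0.0 < f_min < f_max):
        raise ValueError("band must satisfy 0 < f_min < f_max")
    if f_max > video.fps / 2.0 + 1e-12:
        raise ValueError(
            f"band upper edge {f_max} Hz exceeds the Nyquist frequency {video.fps / 2.0} Hz"
        )
    spec, freqs = pixel_power_spectrum(video, detrend=detrend, window=window)
    in_band = (freqs >= f_min) & (freqs <= f_max) & (freqs > 0)
    if not np.any(in_band):
        raise ValueError("frequency band is empty after discretization; widen it or record longer")
    band_spec = spec[in_band]
    band_freqs = freqs[in_band]
    peak_idx = np.argmax(band_spec, axis=0)  # argmax returns the first (lowest-f) maximum
    peak_power = np.take_along_axis(band_spec, peak_idx[None], axis=0)[0]
    total_power = band_spec.sum(axis=0)
    noise_floor = np.median(band_spec, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total_power > 0, peak_power / np.where(total_power > 0, total_power, 1.0), 0.0)
    # constant traces leave a machine-precision detrending residue; gate on
    # a floor far below any physical modulation but far above that residue
    numerical_floor = 1e-20 * np.mean(np.asarray(video.data, dtype=np.float64) ** 2, axis=0)
    active = (
        (peak_power > numerical_floor)
        & (ratio >= activity_threshold)
        & (peak_power >= floor_factor * noise_floor)
    )
    dominant = np.where(total_power > 0, band_freqs[peak_idx], np.nan)
    return FrequencyMap(
        dominant_freq=dominant,
        peak_power=peak_power,
        total_power=total_power,
        active=active,
        band=(f_min, f_max),
        freq_resolution=video.fps / video.n_frames,
    )


def summarize_cell_cbf(
    fmap: FrequencyMap,
    labels: np.ndarray,
    requested_labels=None,
) -> list[CellCBF]:
    """Summarize the frequency map per cell of an integer label mask.

    ``cbf_median`` is the (interpolated) median dominant frequency over
    the cell's active pixels; NaN when the cell has none.  Labels
    requested but absent from the mask are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != fmap.shape:
        raise ValueError(f"label mask shape {labels.shape} != map shape {fmap.shape}")
    present = np.unique(labels)
    present = present[present > 0]
    if requested_labels is None:
        use = present
    else:
        use = []
        for lab in requested_labels:
            if lab in present:
                use.append(lab)
            else:
                warnings.warn(f"label {lab} absent from mask; skipped", stacklevel=2)
    cells = []
    for lab in use:
        sel = labels == lab
        act = fmap.active & sel
        n_active = int(act.sum())
        if n_active:
            freqs = fmap.dominant_freq[act]
            cbf_median = float(np.median(freqs))
            q75, q25 = np.percentile(freqs, [75, 25])
            cbf_iqr = float(q75 - q25)
            mean_peak = float(fmap.peak_power[act].mean())
        else:
            cbf_median = cbf_iqr = mean_peak = float("nan")
        n_pixels = int(sel.sum())
        cells.append(
            CellCBF(
                label=int(lab),
                n_pixels=n_pixels,
                n_active=n_active,
                active_fraction=n_active / n_pixels if n_pixels else 0.0,
                cbf_median=cbf_median,
                cbf_iqr=cbf_iqr,
                mean_peak_power=mean_peak,
            )
        )
    return cells


def classify_beat_mode(
    cell: CellCBF,
    field_median_active_power: float,
    thresholds: BeatModeThresholds = BeatModeThresholds(),
) -> str:
    """Classify one cell as static, restricted, or beating.

    ``field_median_active_power`` is the median peak power over all
    active pixels of the field, the reference against which "low
    amplitude" is judged (absolute intensities are instrument-dependent).
    The visually defined rigid/rotational waveform classes are not
    automated and are never returned.
    """
    if cell.active_fraction < thresholds.active_fraction_static:
        return "static"
    if (
        np.isfinite(field_median_active_power)
        and np.isfinite(cell.mean_peak_power)
        and cell.mean_peak_power < thresholds.amplitude_restricted * field_median_active_power
    ):
        return "restricted"
    return "beating"


def assign_beat_modes(
    cells: list[CellCBF],
    fmap: FrequencyMap,
    thresholds: BeatModeThresholds = BeatModeThresholds(),
) -> list[CellCBF]:
    """Classify every cell in place (and return the list)."""
    if np.any(fmap.active):
        field_median = float(np.median(fmap.peak_power[fmap.active]))
    else:
        field_median = float("nan")
    for cell in cells:
        cell.beat_mode = classify_beat_mode(cell, field_median, thresholds)
    return cells


def field_motility_index(fmap: FrequencyMap) -> float:
    """Fraction of pixels in the field with an active spectral peak."""
    return float(fmap.active.mean())


def cells_to_frame(cells: list[CellCBF]) -> pd.DataFrame:
    """Tabulate per-cell CBF results, sorted by label."""
    rows = [
        {
            "label": c.label,
            "n_pixels": c.n_pixels,
            "n_active": c.n_active,
            "active_fraction": c.active_fraction,
            "cbf_median": c.cbf_median,
            "cbf_iqr": c.cbf_iqr,
            "mean_peak_power": c.mean_peak_power,
            "beat_mode": c.beat_mode,
        }
        for c in sorted(cells, key=lambda c: c.label)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "n_pixels",
            "n_active",
            "active_fraction",
            "cbf_median",
            "cbf_iqr",
            "mean_peak_power",
            "beat_mode",
        ],
    )
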
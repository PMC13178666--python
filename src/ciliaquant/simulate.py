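"""Synthetic ground-truth generators for every pipeline input.

Patient-derived imagery is not redistributable, so each analysis stage is
exercised on synthetic data that reproduces the statistical structure the
stage assumes:

* beating-cilia videos — per-pixel sinusoidal intensity modulation with
  cell-wise beat frequencies and a linear phase gradient standing in for
  the metachronal wave;
* two-channel spot fields — basal-body / basal-foot puncta pairs whose
  orientation angles are drawn from a von Mises distribution (kappa=0
  recovers the uniform circle);
* two-channel 3D stacks — basal-body blobs with straight ciliary
  filaments of set physical length rooted on a subset of them;
* bead videos — drift + diffusion Brownian motion of point emitters.

All randomness flows through one ``numpy.random.Generator`` seeded from
the spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import VideoStack

__all__ = [
    "CellMotif",
    "CiliaVideoSpec",
    "SpotFieldSpec",
    "CiliationStackSpec",
    "BeadVideoSpec",
    "generate_cilia_video",
    "generate_spot_field",
    "generate_ciliation_stack",
    "generate_bead_video",
    "rect_motif",
]


# ---------------------------------------------------------------------------
# beating-cilia videos
# ---------------------------------------------------------------------------

@dataclass
class CellMotif:
    """One cell's beating pattern inside a synthetic video.

    ``region`` is an (n, 2) integer array of (y, x) pixel coordinates.
    ``beat_frequency`` of 0 marks a static cell.  ``phase_gradient`` is a
    (dy, dx) vector in radians/pixel implementing the metachronal phase
    shift across the cell.
    """

    label: int
    region: np.ndarray
    beat_frequency: float
    amplitude: float
    phase_gradient: tuple[float, float] = (0.0, 0.0)
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        self.region = np.atleast_2d(np.asarray(self.region, dtype=np.intp))
        if self.label <= 0:
            raise ValueError("cell labels must be positive integers")
        if self.region.shape[1] != 2 or self.region.size == 0:
            raise ValueError("region must be a non-empty (n, 2) array of (y, x) pixels")
        if self.beat_frequency < 0:
            raise ValueError("beat_frequency must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def rect_motif(label: int, y0: int, y1: int, x0: int, x1: int, **kwargs) -> CellMotif:
    """Convenience constructor: a rectangular cell covering [y0, y1) x [x0, x1)."""
    yy, xx = np.mgrid[y0:y1, x0:x1]
    region = np.column_stack([yy.ravel(), xx.ravel()])
    return CellMotif(label=label, region=region, **kwargs)


@dataclass
class CiliaVideoSpec:
    """Specification of a synthetic beating-cilia video."""

    n_frames: int
    fps: float
    height: int
    width: int
    cells: list[CellMotif]
    pixel_size: float = 0.2
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 16:
            raise ValueError("n_frames must be >= 16")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = [c.label for c in self.cells]
        if len(labels) != len(set(labels)):
            raise ValueError("cell labels must be unique")
        nyquist = self.fps / 2.0
        for cell in self.cells:
            if cell.beat_frequency >= nyquist:
                raise ValueError(
                    f"cell {cell.label}: beat frequency {cell.beat_frequency} Hz is at or "
                    f"above the Nyquist limit {nyquist} Hz and would alias"
                )
            ys, xs = cell.region[:, 0], cell.region[:, 1]
            if ys.min() < 0 or xs.min() < 0 or ys.max() >= self.height or xs.max() >= self.width:
                raise ValueError(f"cell {cell.label}: region extends outside the image")


def generate_cilia_video(spec: CiliaVideoSpec) -> tuple[VideoStack, np.ndarray, pd.DataFrame]:
    """Render a beating-cilia video, its label mask, and the ground truth.

    Pixel (y, x) of cell c at frame t has mean intensity

        background + A_c * (1 + sin(2 pi f_c t / fps + phi_c + g_c . (y, x))) / 2

    plus i.i.d. Gaussian noise of sd ``noise_sd``.  Static cells (f=0)
    keep a constant mean.  The ground-truth table echoes label, beat
    frequency and amplitude per cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames, dtype=np.float64)
    video = np.full((spec.n_frames, spec.height, spec.width), spec.background_level)
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    rows = []
    for cell in spec.cells:
        ys, xs = cell.region[:, 0], cell.region[:, 1]
        labels[ys, xs] = cell.label
        gy, gx = cell.phase_gradient
        spatial_phase = cell.phase_offset + gy * ys + gx * xs
        phase = (2.0 * math.pi * cell.beat_frequency / spec.fps) * t[:, None] + spatial_phase[None, :]
        video[:, ys, xs] = spec.background_level + cell.amplitude * (1.0 + np.sin(phase)) / 2.0
        rows.append(
            {
                "label": cell.label,
                "beat_frequency": cell.beat_frequency,
                "amplitude": cell.amplitude,
                "n_pixels": len(ys),
            }
        )
    if spec.noise_sd > 0:
        video = video + rng.normal(0.0, spec.noise_sd, size=video.shape)
    truth = pd.DataFrame(rows, columns=["label", "beat_frequency", "amplitude", "n_pixels"])
    return VideoStack(video, fps=spec.fps, pixel_size=spec.pixel_size), labels, truth


# ---------------------------------------------------------------------------
# basal-body / basal-foot spot fields
# ---------------------------------------------------------------------------

@dataclass
class SpotFieldSpec:
    """Specification of a two-channel basal-body / basal-foot image.

    Cells are laid out on a grid; within each cell, basal bodies are
    scattered with a minimum separation and each receives a basal-foot
    partner displaced by ``foot_offset`` nm at an angle drawn from
    vonMises(mu_cell, kappa).  ``kappa=0`` gives uniform angles.  Angles
    follow the mathematical convention: counterclockwise from +x with the
    image y axis pointing down (so +pi/2 points up in the image).
    """

    n_cells: int = 4
    spots_per_cell: int = 30
    cell_size: int = 150            # px, side of each cell's square territory
    pixel_size: float = 50.0        # nm / px
    foot_offset: float = 300.0      # nm, basal-foot lever arm
    mu_per_cell: float | list[float] = 0.0
    kappa: float = 8.0
    psf_sigma: float = 80.0         # nm
    amplitude: float = 1000.0
    noise_sd: float = 0.0
    min_separation: float = 600.0   # nm between basal bodies
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.spots_per_cell < 1:
            raise ValueError("n_cells and spots_per_cell must be >= 1")
        if self.foot_offset <= 0:
            raise ValueError("foot_offset must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0 (0 means uniform angles)")
        if np.ndim(self.mu_per_cell) == 1 and len(self.mu_per_cell) != self.n_cells:
            raise ValueError("mu_per_cell list must have one entry per cell")

    @property
    def grid(self) -> tuple[int, int]:
        ncol = int(math.ceil(math.sqrt(self.n_cells)))
        nrow = int(math.ceil(self.n_cells / ncol))
        return nrow, ncol

    @property
    def image_shape(self) -> tuple[int, int]:
        nrow, ncol = self.grid
        return nrow * self.cell_size, ncol * self.cell_size


def _add_gaussian_2d(img: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    """Accumulate a 2D Gaussian blob at sub-pixel position (y, x)."""
    r = max(2, int(math.ceil(4 * sigma)))
    y0, y1 = max(0, int(y) - r), min(img.shape[0], int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(img.shape[1], int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float64)[:, None]
    xx = np.arange(x0, x1, dtype=np.float64)[None, :]
    img[y0:y1, x0:x1] += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))


def generate_spot_field(spec: SpotFieldSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render the two-channel spot image, cell mask, and truth pair table.

    Returns (image of shape (2, H, W) with channel 0 = basal bodies and
    channel 1 = basal feet, integer cell mask, DataFrame with one row per
    basal-body/foot pair).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    nrow, ncol = spec.grid
    img = np.zeros((2, h, w))
    mask = np.zeros((h, w), dtype=np.int32)
    mus = np.broadcast_to(np.asarray(spec.mu_per_cell, dtype=float), (spec.n_cells,))
    sigma_px = spec.psf_sigma / spec.pixel_size
    offset_px = spec.foot_offset / spec.pixel_size
    min_sep_px = spec.min_separation / spec.pixel_size
    margin = offset_px + 4 * sigma_px + 2
    rows = []
    for c in range(spec.n_cells):
        gy, gx = divmod(c, ncol)
        y0, x0 = gy * spec.cell_size, gx * spec.cell_size
        mask[y0 : y0 + spec.cell_size, x0 : x0 + spec.cell_size] = c + 1
        lo, hi = margin, spec.cell_size - margin
        if hi <= lo:
            raise ValueError("cell_size too small for foot_offset + psf margin")
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < spec.spots_per_cell:
            attempts += 1
            if attempts > 20000:
                raise ValueError("could not place spots with the requested separation")
            y, x = rng.uniform(lo, hi, size=2)
            if all((y - py) ** 2 + (x - px) ** 2 >= min_sep_px**2 for py, px in placed):
                placed.append((y, x))
        if spec.kappa == 0:
            thetas = rng.uniform(-math.pi, math.pi, size=len(placed))
        else:
            thetas = rng.vonmises(mus[c], spec.kappa, size=len(placed))
        for (y, x), theta in zip(placed, thetas):
            # y-down image: a mathematical angle theta moves -sin(theta) in y
            fy = y0 + y - offset_px * math.sin(theta)
            fx = x0 + x + offset_px * math.cos(theta)
            by, bx = y0 + y, x0 + x
            _add_gaussian_2d(img[0], by, bx, sigma_px, spec.amplitude)
            _add_gaussian_2d(img[1], fy, fx, sigma_px, spec.amplitude)
            rows.append(
                {
                    "cell": c + 1,
                    "bb_y": by,
                    "bb_x": bx,
                    "foot_y": fy,
                    "foot_x": fx,
                    "theta": float(np.angle(np.exp(1j * theta))),
                }
            )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    truth = pd.DataFrame(rows, columns=["cell", "bb_y", "bb_x", "foot_y", "foot_x", "theta"])
    return img, mask, truth


# ---------------------------------------------------------------------------
# ciliation stacks
# ---------------------------------------------------------------------------

@dataclass
class CiliationStackSpec:
    """Specification of a two-channel 3D basal-body + cilia stack.

    ``round(n_basal_bodies * ciliated_fraction)`` filaments of physical
    path length ``cilium_length`` (micrometres) grow from distinct basal
    bodies, tilted off the z axis by a polar angle drawn uniformly from
    [0, orientation_jitter] with uniform azimuth.  Roots sit on voxel
    centres.
    """

    n_basal_bodies: int = 12
    ciliated_fraction: float = 0.5
    cilium_length: float = 6.0                      # µm
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)  # (z, y, x) µm
    shape: tuple[int, int, int] = (48, 256, 256)    # (z, y, x) voxels
    orientation_jitter: float = 0.35                # rad, max polar tilt from +z
    bb_sigma: float = 0.25                          # µm, basal-body blob width
    amplitude: float = 1000.0
    noise_sd: float = 0.0
    root_z: float = 1.0                             # µm above stack bottom
    min_separation: float = 4.5                     # µm between roots in xy
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.ciliated_fraction <= 1.0):
            raise ValueError("ciliated_fraction must be in [0, 1]")
        if self.n_basal_bodies < 0 or self.cilium_length < 0:
            raise ValueError("counts and lengths must be non-negative")
        if self.orientation_jitter < 0 or self.orientation_jitter > math.pi / 2:
            raise ValueError("orientation_jitter must be in [0, pi/2]")

    @property
    def n_ciliated(self) -> int:
        return int(round(self.n_basal_bodies * self.ciliated_fraction))


def _add_gaussian_3d(vol: np.ndarray, pos_vox: np.ndarray, sigma_vox: np.ndarray, amp: float) -> None:
    r = np.maximum(2, np.ceil(4 * sigma_vox).astype(int))
    lo = np.maximum(0, np.floor(pos_vox).astype(int) - r)
    hi = np.minimum(vol.shape, np.floor(pos_vox).astype(int) + r + 1)
    if np.any(lo >= hi):
        return
    zz = np.arange(lo[0], hi[0])[:, None, None]
    yy = np.arange(lo[1], hi[1])[None, :, None]
    xx = np.arange(lo[2], hi[2])[None, None, :]
    d2 = (
        ((zz - pos_vox[0]) / sigma_vox[0]) ** 2
        + ((yy - pos_vox[1]) / sigma_vox[1]) ** 2
        + ((xx - pos_vox[2]) / sigma_vox[2]) ** 2
    )
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(-d2 / 2.0)


def generate_ciliation_stack(spec: CiliationStackSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the (2, Z, Y, X) stack and its ground-truth table.

    Channel 0 holds basal-body blobs; channel 1 holds the voxelized
    filaments.  The truth table lists every basal body, whether it is
    ciliated, and the filament direction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vox = np.asarray(spec.voxel_size, dtype=float)
    stack = np.zeros((2,) + tuple(spec.shape))
    extent = np.asarray(spec.shape) * vox  # physical size, µm

    # roots on a jittered grid in xy: guarantees the minimum separation
    # for every seed (rejection sampling can stall near the packing limit)
    reach = spec.cilium_length * math.sin(spec.orientation_jitter)
    margin = reach + 0.5
    usable = extent[1:] - 2 * margin
    if np.any(usable <= 0):
        raise ValueError("stack too small for the cilium reach; enlarge shape")
    n = spec.n_basal_bodies
    roots: list[tuple[float, float]] = []
    if n > 0:
        ncol = int(math.ceil(math.sqrt(n)))
        nrow = int(math.ceil(n / ncol))
        gy, gx = usable[0] / nrow, usable[1] / ncol
        jitter = max(0.0, (min(gy, gx) - spec.min_separation) / 2.0)
        if min(gy, gx) - 2 * jitter < spec.min_separation - 1e-9:
            raise ValueError(
                "cannot fit the requested basal bodies at this separation; "
                "enlarge the stack or lower min_separation"
            )
        order = rng.permutation(nrow * ncol)[:n]
        for cell_idx in sorted(order):
            r, c = divmod(int(cell_idx), ncol)
            y = margin + (r + 0.5) * gy + rng.uniform(-jitter, jitter)
            x = margin + (c + 0.5) * gx + rng.uniform(-jitter, jitter)
            roots.append((y, x))
    sigma_vox = spec.bb_sigma / vox
    rows = []
    order = rng.permutation(spec.n_basal_bodies)
    ciliated = np.zeros(spec.n_basal_bodies, dtype=bool)
    ciliated[order[: spec.n_ciliated]] = True
    for i, (y, x) in enumerate(roots):
        root = np.array([spec.root_z, y, x])
        root_vox = np.round(root / vox)
        root = root_vox * vox  # snap to a voxel centre
        _add_gaussian_3d(stack[0], root_vox, sigma_vox, spec.amplitude)
        direction = np.array([1.0, 0.0, 0.0])
        if ciliated[i] and spec.cilium_length > 0:
            polar = rng.uniform(0.0, spec.orientation_jitter)
            azim = rng.uniform(0.0, 2 * math.pi)
            direction = np.array(
                [math.cos(polar), math.sin(polar) * math.sin(azim), math.sin(polar) * math.cos(azim)]
            )
            end = root + spec.cilium_length * direction
            if np.any(end < 0) or np.any(end > extent - vox):
                raise ValueError("cilium would extend outside the stack; enlarge shape or margin")
            step = vox.min() / 2.0
            n_samples = int(math.ceil(spec.cilium_length / step)) + 1
            pts = root[None, :] + np.linspace(0.0, spec.cilium_length, n_samples)[:, None] * direction
            idx = np.unique(np.round(pts / vox).astype(int), axis=0)
            stack[1][idx[:, 0], idx[:, 1], idx[:, 2]] = spec.amplitude
        rows.append(
            {
                "bb_index": i,
                "z_um": root[0],
                "y_um": root[1],
                "x_um": root[2],
                "ciliated": bool(ciliated[i]),
                "dz": direction[0],
                "dy": direction[1],
                "dx": direction[2],
                "length_um": spec.cilium_length if ciliated[i] else 0.0,
            }
        )
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    truth = pd.DataFrame(
        rows, columns=["bb_index", "z_um", "y_um", "x_um", "ciliated", "dz", "dy", "dx", "length_um"]
    )
    return stack, truth


# ---------------------------------------------------------------------------
# bead videos
# ---------------------------------------------------------------------------

@dataclass
class BeadVideoSpec:
    """Specification of a fluorescent-bead clearance video.

    Beads undergo drift + diffusion: per frame the displacement is
    ``drift * dt + sqrt(2 D dt) * N(0, 1)`` per axis (µm).  Beads that
    leave the field stop being rendered and their truth track is flagged
    truncated.
    """

    n_beads: int = 20
    drift_velocity: tuple[float, float] = (0.0, 2.0)  # (vy, vx) µm/s
    diffusion_coeff: float = 0.0                      # µm²/s
    fps: float = 10.0
    n_frames: int = 50
    height: int = 256
    width: int = 256
    pixel_size: float = 0.1                           # µm / px
    psf_sigma: float = 0.15                           # µm
    amplitude: float = 1000.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_beads < 0 or self.n_frames < 2:
            raise ValueError("need n_beads >= 0 and n_frames >= 2")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def generate_bead_video(spec: BeadVideoSpec) -> tuple[VideoStack, pd.DataFrame]:
    """Render the bead video and its ground-truth tracks.

    The truth table has one row per bead per frame while the bead is in
    the field, with columns bead, frame, y_um, x_um, truncated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.fps
    field = np.array([spec.height, spec.width]) * spec.pixel_size
    sigma_px = spec.psf_sigma / spec.pixel_size
    video = np.full((spec.n_frames, spec.height, spec.width), spec.background_level)
    drift = np.asarray(spec.drift_velocity, dtype=float)
    # keep initial positions clear of the borders so short runs stay in-field
    pad = 4 * spec.psf_sigma + 0.2 * min(field)
    rows = []
    if spec.n_beads > 0:
        pos = rng.uniform([pad, pad], field - pad, size=(spec.n_beads, 2))
        alive = np.ones(spec.n_beads, dtype=bool)
        for t in range(spec.n_frames):
            if t > 0:
                step = drift * dt
                if spec.diffusion_coeff > 0:
                    step = step + math.sqrt(2.0 * spec.diffusion_coeff * dt) * rng.standard_normal(
                        (spec.n_beads, 2)
                    )
                pos = pos + step
                alive &= np.all((pos >= 0) & (pos < field), axis=1)
            for b in range(spec.n_beads):
                if not alive[b]:
                    continue
                y_px, x_px = pos[b] / spec.pixel_size
                _add_gaussian_2d(video[t], y_px, x_px, sigma_px, spec.amplitude)
                rows.append({"bead": b, "frame": t, "y_um": pos[b, 0], "x_um": pos[b, 1]})
    if spec.noise_sd > 0:
        video = video + rng.normal(0.0, spec.noise_sd, size=video.shape)
    truth = pd.DataFrame(rows, columns=["bead", "frame", "y_um", "x_um"])
    if len(truth):
        last = truth.groupby("bead")["frame"].max()
        truth["truncated"] = truth["bead"].map(last < spec.n_frames - 1)
    else:
        truth["truncated"] = pd.Series(dtype=bool)
    return VideoStack(video, fps=spec.fps, pixel_size=spec.pixel_size), truth
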
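"""Per-beamlet retrieval: transmission, subpixel displacement, refraction.

Each beamlet is analysed in a fixed window centred on its nominal grid
position.  Transmission is the ratio of windowed intensity sums with and
without the sample; the beamlet displacement is measured against the flat
frame with upsampled phase cross-correlation (Guizar-Sicairos et al. style
single-step DFT registration) and converted to a refraction angle via

    alpha = displacement * pixel_size / z_od

valid for small angles under geometrical optics.  Raster positions are then
interleaved ("stitched") into maps sampled at period / n_subpitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from scipy import ndimage as ndi

from .core import SetupGeometry
from .simulator import BeamletFrame

__all__ = [
    "TrackingMaps",
    "StitchedProjection",
    "extract_window",
    "transmission",
    "register_subpixel",
    "to_refraction",
    "track_frame",
    "stitch",
    "unstitch",
    "locate_grid",
    "average_frames",
]

DEFAULT_WINDOW = 20
DEFAULT_UPSAMPLING = 100


@dataclass
class TrackingMaps:
    """Per-beamlet retrieval output; invalid beamlets are NaN in every map."""

    t: np.ndarray
    dx: np.ndarray  # px
    dy: np.ndarray  # px
    alpha_x: np.ndarray  # rad
    alpha_y: np.ndarray  # rad
    raster_index: tuple[int, int] = (0, 0)  # (a, b) sub-pitch step indices
    raster_offset: tuple[float, float] = (0.0, 0.0)  # m

    @property
    def mask(self) -> np.ndarray:
        """True where the beamlet was not tracked."""
        return np.isnan(self.t)


@dataclass
class StitchedProjection:
    """Fully sampled retrieval maps at sub-pitch resolution."""

    t: np.ndarray
    alpha_x: np.ndarray
    alpha_y: np.ndarray
    angle: float = 0.0  # rad
    pitch: float = 0.0  # m


def extract_window(frame: BeamletFrame, beamlet_index: tuple[int, int], window: int):
    """Window-by-window patch around the *nominal* beamlet position.

    The window stays on the regular grid; it does not follow the displaced
    spot.  Returns None when the window would cross the frame edge (the
    beamlet is flagged missing rather than clipped).
    """
    i, j = beamlet_index
    cx, cy = frame.beamlet_center(i, j)
    x0 = int(round(cx)) - window // 2
    y0 = int(round(cy)) - window // 2
    ny, nx = frame.intensity.shape
    if x0 < 0 or y0 < 0 or x0 + window > nx or y0 + window > ny:
        return None
    return frame.intensity[y0 : y0 + window, x0 : x0 + window]


def transmission(sample_patch: np.ndarray, flat_patch: np.ndarray) -> float:
    """t = sum(I_sample) / sum(I_flat) over the window."""
    if sample_patch.shape != flat_patch.shape:
        raise ValueError("patches must share a shape")
    denom = float(np.sum(flat_patch))
    if denom <= 0:
        return float("nan")
    return float(np.sum(sample_patch)) / denom


def register_subpixel(
    sample_patch: np.ndarray,
    flat_patch: np.ndarray,
    upsampling: int = DEFAULT_UPSAMPLING,
) -> tuple[float, float]:
    """Subpixel displacement (dx, dy) of the sample beamlet vs the flat.

    Positive dx means the beamlet moved toward +x on the detector.
    Precision is 1/upsampling px.  Constant patches (no beamlet) return
    (nan, nan).
    """
    if sample_patch.shape != flat_patch.shape:
        raise ValueError("patches must share a shape")
    if np.ptp(sample_patch) == 0 or np.ptp(flat_patch) == 0:
        return (float("nan"), float("nan"))
    # normalization=None is the original single-step upsampled
    # cross-correlation; spectral whitening ("phase" normalization) is
    # unreliable on small, smooth, band-limited spots like beamlets.
    shift, _, _ = phase_cross_correlation(
        flat_patch.astype(float),
        sample_patch.astype(float),
        upsample_factor=upsampling,
        normalization=None,
    )
    # phase_cross_correlation returns the (row, col) shift registering the
    # sample back onto the flat, i.e. minus the physical displacement.
    return (-float(shift[1]), -float(shift[0]))


def to_refraction(dx: float, dy: float, geom: SetupGeometry) -> tuple[float, float]:
    """Refraction angles (rad) from pixel displacements: alpha = d * px / z_od."""
    if geom.z_od == 0:
        raise ValueError("z_od must be non-zero")
    f = geom.pixel_size / geom.z_od
    return (dx * f, dy * f)


def average_frames(frames: list[BeamletFrame]) -> BeamletFrame:
    """Mean of repeated frames sharing a grid (e.g. flats before/after)."""
    if not frames:
        raise ValueError("no frames to average")
    first = frames[0]
    stack = np.stack([f.intensity for f in frames])
    return BeamletFrame(
        intensity=stack.mean(axis=0),
        grid_origin=first.grid_origin,
        grid_pitch=first.grid_pitch,
        grid_shape=first.grid_shape,
        modulator_offset=first.modulator_offset,
    )


def track_frame(
    sample_frame: BeamletFrame,
    flat_frame: BeamletFrame,
    dark_frame: np.ndarray | float | None,
    geom: SetupGeometry,
    window: int = DEFAULT_WINDOW,
    upsampling: int = DEFAULT_UPSAMPLING,
) -> TrackingMaps:
    """Retrieve t, (dx, dy) and (alpha_x, alpha_y) for every beamlet.

    Both frames are dark-subtracted first.  Beamlets whose window crosses a
    frame edge, has non-positive flat counts or is constant are masked NaN.
    """
    if sample_frame.grid_shape != flat_frame.grid_shape:
        raise ValueError("sample and flat beamlet grids differ")
    if not math.isclose(sample_frame.grid_pitch, flat_frame.grid_pitch, rel_tol=1e-9):
        raise ValueError("sample and flat grid pitch differ")
    dark = 0.0 if dark_frame is None else dark_frame
    dark_s = dark if np.isscalar(dark) else np.asarray(dark, dtype=float)
    samp = BeamletFrame(
        intensity=sample_frame.intensity - dark_s,
        grid_origin=sample_frame.grid_origin,
        grid_pitch=sample_frame.grid_pitch,
        grid_shape=sample_frame.grid_shape,
        modulator_offset=sample_frame.modulator_offset,
    )
    flat = BeamletFrame(
        intensity=flat_frame.intensity - dark_s,
        grid_origin=flat_frame.grid_origin,
        grid_pitch=flat_frame.grid_pitch,
        grid_shape=flat_frame.grid_shape,
        modulator_offset=flat_frame.modulator_offset,
    )
    n_by, n_bx = sample_frame.grid_shape
    t = np.full((n_by, n_bx), np.nan)
    dx = np.full((n_by, n_bx), np.nan)
    dy = np.full((n_by, n_bx), np.nan)
    for i in range(n_by):
        for j in range(n_bx):
            sp = extract_window(samp, (i, j), window)
            fp = extract_window(flat, (i, j), window)
            if sp is None or fp is None:
                continue
            tv = transmission(sp, fp)
            if not np.isfinite(tv):
                continue
            dxv, dyv = register_subpixel(sp, fp, upsampling)
            if not (np.isfinite(dxv) and np.isfinite(dyv)):
                continue
            t[i, j], dx[i, j], dy[i, j] = tv, dxv, dyv
    ax, ay = to_refraction(dx, dy, geom)
    a, b = (
        int(round(sample_frame.modulator_offset[0] / (geom.modulator_period / geom.n_subpitch))),
        int(round(sample_frame.modulator_offset[1] / (geom.modulator_period / geom.n_subpitch))),
    )
    return TrackingMaps(
        t=t, dx=dx, dy=dy, alpha_x=ax, alpha_y=ay,
        raster_index=(a, b), raster_offset=sample_frame.modulator_offset,
    )


def stitch(
    maps: list[TrackingMaps],
    n_subpitch: int,
    angle: float = 0.0,
    pitch: float = 0.0,
) -> StitchedProjection:
    """Interleave raster positions into sub-pitch-sampled maps.

    Output pixel (i*n + b, j*n + a) comes from raster offset (a, b)'s
    beamlet (i, j): increasing modulator offset in +x fills increasing
    output x.  Requires exactly n_subpitch**2 maps with distinct offsets.
    """
    n = n_subpitch
    if len(maps) != n * n:
        raise ValueError(f"expected {n * n} maps, got {len(maps)}")
    seen = {m.raster_index for m in maps}
    want = {(a, b) for a in range(n) for b in range(n)}
    if seen != want:
        raise ValueError(f"raster offsets {sorted(seen)} do not form the {n}x{n} lattice")
    shp = maps[0].t.shape
    if any(m.t.shape != shp for m in maps):
        raise ValueError("all maps must share a shape")
    out = {
        ch: np.empty((shp[0] * n, shp[1] * n))
        for ch in ("t", "alpha_x", "alpha_y")
    }
    for m in maps:
        a, b = m.raster_index
        for ch in out:
            out[ch][b::n, a::n] = getattr(m, ch)
    return StitchedProjection(
        t=out["t"], alpha_x=out["alpha_x"], alpha_y=out["alpha_y"], angle=angle, pitch=pitch
    )


def unstitch(image: np.ndarray, n_subpitch: int) -> dict[tuple[int, int], np.ndarray]:
    """Inverse of the stitch interleave, keyed by raster index (a, b)."""
    n = n_subpitch
    return {(a, b): image[b::n, a::n] for a in range(n) for b in range(n)}


def locate_grid(
    flat_intensity: np.ndarray, approx_pitch: float
) -> tuple[tuple[float, float], float]:
    """Locate the beamlet lattice on a flat frame.

    Peaks are found on a period-smoothed copy and snapped to the best-fit
    regular lattice by least squares.  Returns ((x0, y0), pitch) in pixels.
    """
    img = ndi.gaussian_filter(np.asarray(flat_intensity, dtype=float), approx_pitch / 6.0)
    peaks = peak_local_max(img, min_distance=int(approx_pitch * 0.5), exclude_border=False)
    if len(peaks) < 4:
        raise ValueError("too few beamlets found to fit a lattice")
    ys, xs = peaks[:, 0].astype(float), peaks[:, 1].astype(float)

    def fit_axis(c: np.ndarray) -> tuple[float, float]:
        idx = np.round((c - c.min()) / approx_pitch)
        A = np.stack([np.ones_like(idx), idx], axis=1)
        (c0, p), *_ = np.linalg.lstsq(A, c, rcond=None)
        return c0, p

    x0, px = fit_axis(xs)
    y0, py = fit_axis(ys)
    return ((float(x0), float(y0)), float((px + py) / 2.0))
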
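"""Fourier-space integration of two orthogonal phase-gradient maps.

The two refraction maps give the transverse gradients of the phase shift,
g_i = k * alpha_i.  The phase is recovered with the complex Fourier method:

    dphi = Re{ IFT[ FT(g_x + i g_y) / (2 pi i (u + i v)) ] }

with (u, v) spatial frequencies in cycles/m.  The DC term is undefined (the
method cannot recover the mean) and is set to zero, then re-anchored to a
declared background region.  Gradient maps are extended to 2x size with the
symmetry of a mirrored potential (g_x odd in x / even in y, g_y the reverse)
before the transform, which makes the extended field exactly periodic and
suppresses wrap-around leakage; the result is cropped back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseMap", "gradients_from_refraction", "integrate_fourier"]


@dataclass
class PhaseMap:
    """Integrated phase-shift map (rad), defined up to an additive constant."""

    dphi: np.ndarray
    pitch: float  # m
    angle: float = 0.0  # rad


def gradients_from_refraction(
    alpha_x: np.ndarray, alpha_y: np.ndarray, k: float
) -> tuple[np.ndarray, np.ndarray]:
    """Phase gradients (rad/m) from refraction angles: g_i = k * alpha_i."""
    alpha_x = np.asarray(alpha_x, dtype=float)
    alpha_y = np.asarray(alpha_y, dtype=float)
    if alpha_x.shape != alpha_y.shape:
        raise ValueError("refraction maps must share a shape")
    return k * alpha_x, k * alpha_y


def _mirror_extend(gx: np.ndarray, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Antisymmetric/symmetric 2x extension consistent with a mirrored phase."""
    gx_top = np.hstack([gx, -gx[:, ::-1]])
    gx_ext = np.vstack([gx_top, gx_top[::-1, :]])
    gy_top = np.hstack([gy, gy[:, ::-1]])
    gy_ext = np.vstack([gy_top, -gy_top[::-1, :]])
    return gx_ext, gy_ext


def integrate_fourier(
    gx: np.ndarray,
    gy: np.ndarray,
    pitch: float,
    background: tuple[slice, slice] | None = None,
    angle: float = 0.0,
    extension: str = "mirror",
) -> PhaseMap:
    """Integrate a 2D gradient field into a phase map.

    Parameters
    ----------
    gx, gy : 2D arrays, rad/m
        Orthogonal phase gradients (x = columns, y = rows).  NaNs (masked
        beamlets) are replaced by zero before the transform.
    pitch : float
        Lateral sampling of the maps, m.
    background : pair of slices or boolean mask, optional
        Region declared sample-free; the output is shifted so its mean there
        is zero.  Default: zero mean over the whole map.
    extension : {"mirror", "periodic"}
        "mirror" (default) extends the gradients to 2x size with mirrored-
        potential symmetry before the transform, suppressing wrap-around
        leakage for fields that do not wrap at the FOV edges — the usual
        measurement situation.  "periodic" transforms the maps as-is and is
        exact for fields that are genuinely periodic on the grid.
    """
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError("gradient maps must share a shape")
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    gx = np.nan_to_num(gx)
    gy = np.nan_to_num(gy)
    if extension == "mirror":
        gxe, gye = _mirror_extend(gx, gy)
    elif extension == "periodic":
        gxe, gye = gx, gy
    else:
        raise ValueError(f"unknown extension {extension!r}")
    ny, nx = gxe.shape
    u = np.fft.fftfreq(nx, d=pitch)  # cycles/m
    v = np.fft.fftfreq(ny, d=pitch)
    U, V = np.meshgrid(u, v)
    denom = 2j * np.pi * (U + 1j * V)
    spec = np.fft.fft2(gxe + 1j * gye)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_spec = spec / denom
    phi_spec[0, 0] = 0.0
    phi = np.real(np.fft.ifft2(phi_spec))[: gx.shape[0], : gx.shape[1]]
    if background is not None:
        sel = background if isinstance(background, tuple) else np.asarray(background, bool)
        phi = phi - phi[sel].mean()
    else:
        phi = phi - phi.mean()
    return PhaseMap(dphi=phi, pitch=pitch, angle=angle)
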
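"""Shared physical/geometric domain types and unit conversions.

Beam-tracking phase-contrast imaging structures the X-ray beam into an
array of beamlets with an absorbing modulator (period ``p``), and infers
the sample's refraction from the transverse displacement of each beamlet
measured a distance ``z_od`` downstream.  Everything downstream of I/O
works in SI units: all lengths are stored in metres; micrometres appear
only at the configuration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "HC_KEV_M",
    "SetupGeometry",
    "energy_to_wavenumber",
    "sampling_pitch",
    "scan_exposure",
]

#: Planck constant times speed of light, in keV * m (CODATA: 1.23984198 keV nm).
HC_KEV_M = 1.23984198e-9

# unit name -> factor to metres, accepted in config files
_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


@dataclass(frozen=True)
class SetupGeometry:
    """Geometry and beam parameters of a beam-tracking set-up.

    All lengths in metres.

    Parameters
    ----------
    z_od : float
        Object-to-detector propagation distance (m).  Taken as the
        sample-to-scintillator distance.
    mean_energy : float
        Mean photon energy of the (pink) beam, keV.  The retrieval uses a
        single effective wavenumber; no spectral weighting.
    pixel_size : float
        Effective detector pixel pitch (m).
    modulator_period : float
        Aperture pitch of the amplitude modulator (m).
    aperture_diameter : float
        Front-face aperture diameter (m).
    n_subpitch : int
        Number of sub-pitch raster steps per period per axis.
    """

    z_od: float
    mean_energy: float
    pixel_size: float
    modulator_period: float
    aperture_diameter: float
    n_subpitch: int = 1

    def __post_init__(self) -> None:
        for name in ("z_od", "pixel_size", "modulator_period", "aperture_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.mean_energy <= 0:
            raise ValueError(f"mean_energy must be > 0, got {self.mean_energy!r}")
        if int(self.n_subpitch) != self.n_subpitch or self.n_subpitch < 1:
            raise ValueError(f"n_subpitch must be an integer >= 1, got {self.n_subpitch!r}")

    @property
    def wavenumber(self) -> float:
        """Vacuum wavenumber k = 2*pi*E/(hc) at the mean energy (1/m)."""
        return energy_to_wavenumber(self.mean_energy)

    @property
    def grid_pitch_px(self) -> float:
        """Beamlet spacing on the detector, in pixels (may be fractional)."""
        return self.modulator_period / self.pixel_size

    @classmethod
    def from_dict(cls, d: dict) -> "SetupGeometry":
        """Build from a config mapping with declared units.

        Lengths are given as ``{"value": x, "unit": "um"}`` pairs or plain
        numbers (then interpreted as metres); energy is keV.
        """

        def length(key: str) -> float:
            v = d[key]
            if isinstance(v, dict):
                unit = v.get("unit", "m")
                if unit not in _LENGTH_UNITS:
                    raise ValueError(f"unknown length unit {unit!r} for {key}")
                return float(v["value"]) * _LENGTH_UNITS[unit]
            return float(v)

        return cls(
            z_od=length("z_od"),
            mean_energy=float(d["mean_energy"]),
            pixel_size=length("pixel_size"),
            modulator_period=length("modulator_period"),
            aperture_diameter=length("aperture_diameter"),
            n_subpitch=int(d.get("n_subpitch", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SetupGeometry":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "geometry" in d:
            d = d["geometry"]
        return cls.from_dict(d)


def energy_to_wavenumber(energy_kev: float) -> float:
    """Vacuum wavenumber k = 2*pi*E/(hc) for a photon energy in keV.

    Returns k in 1/m.  E.g. 16 keV -> 8.108e10 m^-1.
    """
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be > 0 keV, got {energy_kev!r}")
    import math

    return 2.0 * math.pi * energy_kev / HC_KEV_M


def sampling_pitch(geom: SetupGeometry) -> float:
    """Lateral sampling pitch of the stitched images (m).

    Sub-pitch raster scanning in ``n_subpitch`` steps per period samples the
    object every ``modulator_period / n_subpitch``; e.g. a 50 um period
    rastered 8x8 gives 6.25 um sampling.
    """
    if geom.n_subpitch < 1:
        raise ValueError("n_subpitch must be >= 1")
    return geom.modulator_period / geom.n_subpitch


def scan_exposure(n_projections: int, n_raster: int, t_frame: float) -> float:
    """Total scan exposure time in hours.

    ``n_projections`` rotation angles times ``n_raster`` modulator positions
    (e.g. 64 for an 8x8 raster) times the per-frame exposure ``t_frame`` in
    seconds.  1200 x 64 x 0.15 s = 3.2 h.
    """
    if n_projections <= 0 or n_raster <= 0 or t_frame <= 0:
        raise ValueError("n_projections, n_raster and t_frame must all be positive")
    return n_projections * n_raster * t_frame / 3600.0
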
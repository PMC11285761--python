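"""Detector geometry and reciprocal-space conversions for small-angle fiber diffraction.

The scattering wavevector convention used throughout is Q = 2*pi/d, so the
collagen intermolecular feature near d ~ 2.3 nm sits at Q ~ 2.7 nm^-1 and the
third meridional order of a 67 nm D-period sits at Q ~ 0.28 nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import constants

#: Sentinel value marking masked detector pixels (beamstop, dead regions).
MASKED = -1.0


def energy_ev_to_wavelength_nm(energy_ev: float) -> float:
    """Photon energy (eV) to wavelength (nm) via lambda = h c / E."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    return constants.h * constants.c / (energy_ev * constants.e) * 1e9


def q_to_spacing(q_nm_inv):
    """Real-space spacing d = 2*pi/Q (nm from nm^-1)."""
    return 2.0 * np.pi / np.asarray(q_nm_inv)


def spacing_to_q(d_nm):
    """Scattering wavevector Q = 2*pi/d (nm^-1 from nm)."""
    return 2.0 * np.pi / np.asarray(d_nm)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat area detector in transmission scattering geometry.

    Maps detector pixels to (Q, azimuth).  Defaults describe an Eiger2
    4M-class detector 700 mm behind the sample at 0.0979 nm wavelength.

    Parameters
    ----------
    sample_detector_distance_mm:
        Sample-to-detector distance L (mm).
    wavelength_nm:
        X-ray wavelength (nm).
    pixel_pitch_um:
        Square pixel pitch (micrometres).
    detector_shape:
        (rows, cols) in pixels.
    beam_center:
        Direct-beam position (x_px, y_px); defaults to the detector centre.
    beamstop_radius_px:
        Radius of the circular beamstop occlusion around the beam centre.
    """

    sample_detector_distance_mm: float = 700.0
    wavelength_nm: float = 0.0979
    pixel_pitch_um: float = 75.0
    detector_shape: tuple[int, int] = (2162, 2068)
    beam_center: tuple[float, float] | None = None
    beamstop_radius_px: float = 25.0

    def __post_init__(self):
        if self.sample_detector_distance_mm <= 0:
            raise ValueError("sample-detector distance must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        ny, nx = self.detector_shape
        if ny < 2 or nx < 2:
            raise ValueError("detector must be at least 2x2 pixels")
        cx, cy = self.center
        if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
            raise ValueError("beam center must lie inside the detector")
        if self.beamstop_radius_px < 0:
            raise ValueError("beamstop radius must be non-negative")

    @property
    def center(self) -> tuple[float, float]:
        """Beam-center pixel coordinates (x, y)."""
        if self.beam_center is not None:
            return tuple(float(v) for v in self.beam_center)
        ny, nx = self.detector_shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)

    # -- scalar/array conversions ------------------------------------------

    def q_of_radius_mm(self, r_mm):
        """Q (nm^-1) at in-plane distance r (mm) from the beam center.

        Q = (4 pi / lambda) * sin(0.5 * arctan(r / L)).
        """
        r_mm = np.asarray(r_mm, dtype=float)
        theta2 = np.arctan2(r_mm, self.sample_detector_distance_mm)
        return 4.0 * np.pi / self.wavelength_nm * np.sin(0.5 * theta2)

    def radius_mm_of_q(self, q_nm_inv):
        """Inverse of :meth:`q_of_radius_mm`."""
        q = np.asarray(q_nm_inv, dtype=float)
        s = q * self.wavelength_nm / (4.0 * np.pi)
        if np.any(s >= 1.0):
            raise ValueError("Q out of range for this wavelength")
        return self.sample_detector_distance_mm * np.tan(2.0 * np.arcsin(s))

    def radius_px_of_q(self, q_nm_inv):
        return self.radius_mm_of_q(q_nm_inv) / (self.pixel_pitch_um / 1000.0)

    def pixel_to_q(self, x, y):
        """Map pixel coordinates to (Q in nm^-1, azimuth in deg).

        Azimuth is measured counter-clockwise from the detector +x axis in
        [0, 360); the exact beam-center pixel maps to (0, 0) by convention.
        """
        cx, cy = self.center
        dx = np.asarray(x, dtype=float) - cx
        dy = np.asarray(y, dtype=float) - cy
        r_mm = np.hypot(dx, dy) * self.pixel_pitch_um / 1000.0
        q = self.q_of_radius_mm(r_mm)
        az = np.degrees(np.arctan2(dy, dx)) % 360.0
        az = np.where(r_mm == 0.0, 0.0, az)
        if np.ndim(x) == 0 and np.ndim(y) == 0:
            return float(q), float(az)
        return q, az

    # -- full-detector maps -------------------------------------------------

    def q_map(self) -> np.ndarray:
        return _detector_maps(self)[0]

    def azimuth_map(self) -> np.ndarray:
        return _detector_maps(self)[1]

    def radius_px_map(self) -> np.ndarray:
        return _detector_maps(self)[2]

    def beamstop_mask(self) -> np.ndarray:
        """Boolean map, True where the beamstop occludes the detector."""
        return self.radius_px_map() <= self.beamstop_radius_px

    @property
    def q_max_on_axis(self) -> float:
        """Largest Q reached along a detector axis through the beam center."""
        ny, nx = self.detector_shape
        cx, cy = self.center
        r_px = max(cx, nx - 1 - cx, cy, ny - 1 - cy)
        return float(self.q_of_radius_mm(r_px * self.pixel_pitch_um / 1000.0))

    @property
    def q_min_usable(self) -> float:
        """Smallest Q outside the beamstop."""
        r_mm = (self.beamstop_radius_px + 1.0) * self.pixel_pitch_um / 1000.0
        return float(self.q_of_radius_mm(r_mm))


@lru_cache(maxsize=8)
def _detector_maps(geometry: DetectorGeometry):
    ny, nx = geometry.detector_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = geometry.center
    dx = xx - cx
    dy = yy - cy
    r_px = np.hypot(dx, dy)
    q = geometry.q_of_radius_mm(r_px * geometry.pixel_pitch_um / 1000.0)
    az = np.degrees(np.arctan2(dy, dx)) % 360.0
    az[r_px == 0.0] = 0.0
    return q, az, r_px


def axial_angle_distance(azimuth_deg, center_deg):
    """Angular distance (deg) to the nearest of ``center`` and ``center+180``.

    Fibre diffraction has Friedel (180-degree) symmetry, so features live on
    an axis rather than a direction; the result lies in [-90, 90].
    """
    return (np.asarray(azimuth_deg, dtype=float) - center_deg + 90.0) % 180.0 - 90.0
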
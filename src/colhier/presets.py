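"""Study-condition presets: NM/EM/LM region parameters and the scan geometry.

The three turkey-leg-tendon zones — non-mineralizing (NM), early mineralizing
(EM) and late mineralizing (LM) — are parameterized from the reported tissue
means: D-period and intermolecular spacing in nm, fibril and molecular
azimuthal dispersions as FWHM in degrees, and the pSHG organization
parameter I2.  The generator's intrafibrillar twist spread is derived by
quadrature, twist_sigma = sqrt(sigma_molecular^2 - sigma_fibril^2), since the
simulated molecular spread is the quadrature sum of fibril spread and twist.
"""

from __future__ import annotations

import numpy as np

from .geometry import DetectorGeometry
from .synthetic import (
    PSHGScene,
    RegionLayout,
    ScatterScene,
    uniform_pshg_scene,
)

REGIONS = ("NM", "EM", "LM")

#: Full width at half maximum of a Gaussian = 2*sqrt(2 ln 2) * sigma.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

XRD_REGION_PARAMS: dict[str, dict[str, float]] = {
    "NM": dict(
        d_period_nm=66.92,
        intermolecular_spacing_nm=2.37,
        fibril_fwhm_deg=31.19,
        molecular_fwhm_deg=37.43,
        mineral_fraction=0.0,
    ),
    "EM": dict(
        d_period_nm=67.46,
        intermolecular_spacing_nm=2.16,
        fibril_fwhm_deg=15.31,
        molecular_fwhm_deg=24.55,
        mineral_fraction=0.6,
    ),
    "LM": dict(
        d_period_nm=67.21,
        intermolecular_spacing_nm=2.13,
        fibril_fwhm_deg=19.88,
        molecular_fwhm_deg=24.96,
        mineral_fraction=1.0,
    ),
}

#: Region means of the pSHG organization parameter I2.
PSHG_REGION_I2: dict[str, float] = {"NM": 0.21, "EM": 0.29, "LM": 0.33}

#: Acquisitions per region per tendon sample (six NM, four EM, four LM).
PSHG_ACQUISITIONS_PER_SAMPLE: dict[str, int] = {"NM": 6, "EM": 4, "LM": 4}
PSHG_N_SAMPLES = 4

#: Desk-scale detector used by the synthetic study: full azimuthal coverage
#: with on-axis Q reach past 5 nm^-1, small enough to simulate quickly.
SCAN_GEOMETRY = DetectorGeometry(
    pixel_pitch_um=100.0,
    detector_shape=(1100, 1100),
    beamstop_radius_px=20.0,
)


def scatter_scene_for_region(
    region: str,
    preferred_orientation_deg: float = 90.0,
    poisson_noise: bool = True,
    **overrides,
) -> ScatterScene:
    """Ground-truth scatter scene for one tendon region."""
    p = XRD_REGION_PARAMS[region]
    fibril_sigma = p["fibril_fwhm_deg"] / FWHM_FACTOR
    molecular_sigma = p["molecular_fwhm_deg"] / FWHM_FACTOR
    twist_sigma = float(np.sqrt(molecular_sigma**2 - fibril_sigma**2))
    kwargs = dict(
        d_period_nm=p["d_period_nm"],
        intermolecular_spacing_nm=p["intermolecular_spacing_nm"],
        fibril_sigma_deg=fibril_sigma,
        twist_sigma_deg=twist_sigma,
        mineral_fraction=p["mineral_fraction"],
        preferred_orientation_deg=preferred_orientation_deg,
        poisson_noise=poisson_noise,
    )
    kwargs.update(overrides)
    return ScatterScene(**kwargs)


def region_twist_sigma(region: str) -> float:
    """Ground-truth intrafibrillar twist spread (deg) of a region."""
    return scatter_scene_for_region(region).twist_sigma_deg


def three_band_layout(
    n_rows: int,
    n_cols: int,
    preferred_orientation_deg: float = 90.0,
    poisson_noise: bool = True,
    regions=REGIONS,
) -> RegionLayout:
    """Layout with vertical NM/EM/LM bands along the scan x direction."""
    labels = np.empty((n_rows, n_cols), dtype="U2")
    edges = np.linspace(0, n_cols, len(regions) + 1).round().astype(int)
    for label, lo, hi in zip(regions, edges[:-1], edges[1:]):
        labels[:, lo:hi] = label
    scenes = {
        r: scatter_scene_for_region(
            r,
            preferred_orientation_deg=preferred_orientation_deg,
            poisson_noise=poisson_noise,
        )
        for r in regions
    }
    return RegionLayout(labels, scenes)


def pshg_scene_for_region(
    region: str,
    shape=(512, 512),
    a0: float = 500.0,
    phi2: float = 90.0,
    seed: int = 0,
    shot_noise: bool = True,
    **overrides,
) -> PSHGScene:
    """Uniform pSHG scene with the region's ground-truth I2."""
    kwargs = dict(
        shape=shape,
        a0=a0,
        i2=PSHG_REGION_I2[region],
        phi2=phi2,
        i4=0.05,
        phi4=20.0,
        shot_noise=shot_noise,
        seed=seed,
    )
    kwargs.update(overrides)
    return uniform_pshg_scene(**kwargs)
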
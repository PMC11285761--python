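"""Synthetic scatter-pattern and pSHG-stack generators with known ground truth.

Every downstream stage (diffraction reduction, circular-harmonic fitting,
region statistics) is tested against data produced here, so the generators
are first-class, validated code.  Scatter patterns contain a Porod (Q^-4)
background, meridional D-period diffraction orders with azimuthal spread, an
equatorial intermolecular arc, a diffuse low-Q mineral lobe, beamstop
occlusion and optional Poisson noise.  pSHG stacks evaluate the circular
harmonic forward model I(alpha) = a0 (1 + i2 cos 2(alpha-phi2)
+ i4 cos 4(alpha-phi4)) per pixel, with optional shot noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import MASKED, DetectorGeometry, axial_angle_distance, spacing_to_q

# Radial (Q) Gaussian widths of the simulated arcs, chosen so each peak fits
# inside its analysis window rather than for physical fidelity.
D_ORDER_SIGMA_Q = 0.01      # nm^-1, meridional D-period orders
INTERMOLECULAR_SIGMA_Q = 0.25  # nm^-1, equatorial intermolecular arc
# The diffuse mineral feature: the literature gives no functional form, so a
# broad Gaussian lobe (in Q and azimuth, centred perpendicular to the fibril
# axis) stands in for it.  Synthetic stand-in, not a physical model.
MINERAL_CENTER_Q = 0.6      # nm^-1
MINERAL_SIGMA_Q = 0.30      # nm^-1
MINERAL_SIGMA_AZ = 35.0     # deg

N_MERIDIONAL_ORDERS = 3


@dataclass(frozen=True)
class ScatterScene:
    """Ground-truth parameter bundle for one simulated scatter pattern.

    Lengths in nm, angles in degrees, intensities in expected counts.
    ``fibril_sigma_deg`` is the azimuthal standard deviation of fibril
    orientations; ``twist_sigma_deg`` the intrafibrillar molecular spread.
    The molecular (equatorial) azimuthal spread is their quadrature sum.
    """

    d_period_nm: float = 67.0
    intermolecular_spacing_nm: float = 2.3
    fibril_sigma_deg: float = 10.0
    twist_sigma_deg: float = 8.0
    preferred_orientation_deg: float = 90.0
    porod_amplitude: float = 2.0
    flat_background: float = 10.0
    peak_amplitudes: tuple[float, ...] = (600.0, 300.0, 200.0)
    intermolecular_amplitude: float = 40.0
    mineral_fraction: float = 0.0
    mineral_amplitude: float = 30.0
    poisson_noise: bool = True
    noise_seed: int = 0

    def __post_init__(self):
        if self.d_period_nm <= 0:
            raise ValueError("d_period must be positive")
        if self.intermolecular_spacing_nm <= 0:
            raise ValueError("intermolecular spacing must be positive")
        if self.fibril_sigma_deg < 0 or self.twist_sigma_deg < 0:
            raise ValueError("angular spreads must be non-negative")
        if self.mineral_fraction < 0:
            raise ValueError("mineral_fraction must be non-negative")
        if len(self.peak_amplitudes) < N_MERIDIONAL_ORDERS:
            raise ValueError(
                f"need {N_MERIDIONAL_ORDERS} meridional peak amplitudes"
            )

    @property
    def molecular_sigma_deg(self) -> float:
        """Azimuthal spread of the equatorial (molecular) arc."""
        return float(np.hypot(self.fibril_sigma_deg, self.twist_sigma_deg))

    def meridional_order_q(self, order: int) -> float:
        """Center Q (nm^-1) of meridional diffraction order n: 2*pi*n/d."""
        return 2.0 * np.pi * order / self.d_period_nm

    @property
    def intermolecular_q(self) -> float:
        return float(spacing_to_q(self.intermolecular_spacing_nm))


def _azimuthal_factor(azimuth_map, center_deg, sigma_deg):
    """Wrapped (axial, 180-degree periodic) Gaussian azimuthal envelope.

    A zero spread degenerates to an indicator confined to the canonical
    0.5-degree azimuthal analysis bin containing the center axis.
    """
    d = axial_angle_distance(azimuth_map, center_deg)
    if sigma_deg == 0.0:
        return (np.abs(d) <= 0.25).astype(float)
    return np.exp(-0.5 * (d / sigma_deg) ** 2)


def noiseless_scatter_pattern(
    scene: ScatterScene, geometry: DetectorGeometry
) -> np.ndarray:
    """Expected (noise-free) scatter image for a scene; beamstop pixels MASKED."""
    q_T = scene.intermolecular_q
    if geometry.q_max_on_axis < q_T + 3.0 * INTERMOLECULAR_SIGMA_Q:
        raise ValueError(
            "detector geometry too small to contain the intermolecular arc at "
            f"Q = {q_T:.3f} nm^-1 (on-axis Q max {geometry.q_max_on_axis:.3f})"
        )
    q = geometry.q_map()
    az = geometry.azimuth_map()
    stop = geometry.beamstop_mask()

    with np.errstate(divide="ignore"):
        image = scene.porod_amplitude * np.where(q > 0, q, np.inf) ** -4.0
    image = image + scene.flat_background

    for n in range(1, N_MERIDIONAL_ORDERS + 1):
        amp = scene.peak_amplitudes[n - 1]
        if amp == 0:
            continue
        qn = scene.meridional_order_q(n)
        radial = np.exp(-0.5 * ((q - qn) / D_ORDER_SIGMA_Q) ** 2)
        image += amp * radial * _azimuthal_factor(
            az, scene.preferred_orientation_deg, scene.fibril_sigma_deg
        )

    if scene.intermolecular_amplitude:
        radial = np.exp(-0.5 * ((q - q_T) / INTERMOLECULAR_SIGMA_Q) ** 2)
        image += scene.intermolecular_amplitude * radial * _azimuthal_factor(
            az, scene.preferred_orientation_deg + 90.0, scene.molecular_sigma_deg
        )

    if scene.mineral_fraction > 0 and scene.mineral_amplitude:
        radial = np.exp(-0.5 * ((q - MINERAL_CENTER_Q) / MINERAL_SIGMA_Q) ** 2)
        image += (
            scene.mineral_fraction
            * scene.mineral_amplitude
            * radial
            * _azimuthal_factor(
                az, scene.preferred_orientation_deg + 90.0, MINERAL_SIGMA_AZ
            )
        )

    image[stop] = MASKED
    return image


def generate_scatter_pattern(
    scene: ScatterScene,
    geometry: DetectorGeometry,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one 2D scatter pattern (counts; MASKED sentinel on beamstop)."""
    image = noiseless_scatter_pattern(scene, geometry)
    if not scene.poisson_noise:
        return image
    if rng is None:
        rng = np.random.default_rng(scene.noise_seed)
    masked = image == MASKED
    lam = np.where(masked, 0.0, image)
    noisy = rng.poisson(lam).astype(float)
    noisy[masked] = MASKED
    return noisy


# ---------------------------------------------------------------------------
# Scan maps


class RegionLayout:
    """Raster of NM/EM/LM region labels with per-region scene parameters."""

    def __init__(self, labels, scenes: dict[str, ScatterScene]):
        labels = np.asarray(labels)
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError("labels must be a non-empty 2D raster")
        missing = sorted(set(labels.ravel()) - set(scenes))
        if missing:
            raise ValueError(f"no scene parameters for labels: {missing}")
        self.labels = labels
        self.scenes = dict(scenes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ScanPattern:
    """One pattern of a scan: raster indices, stage position, label, image."""

    row: int
    col: int
    x_um: float
    y_um: float
    label: str
    image: np.ndarray


def serpentine_positions(n_rows: int, n_cols: int):
    """(row, col) visit order of a snake scan (even rows left-to-right)."""
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return order


def generate_scatter_map(
    layout: RegionLayout,
    geometry: DetectorGeometry,
    seed: int = 0,
    x_pitch_um: float = 20.0,
    y_pitch_um: float = 100.0,
) -> list[ScanPattern]:
    """Simulate a snake scan over a region layout; deterministic under seed.

    The map seed governs all noise (per-cell substreams spawned from it);
    per-scene ``noise_seed`` values are ignored here.
    """
    n_rows, n_cols = layout.shape
    order = serpentine_positions(n_rows, n_cols)
    children = np.random.SeedSequence(seed).spawn(len(order))
    base_images: dict[str, np.ndarray] = {}
    patterns = []
    for (r, c), child in zip(order, children):
        label = str(layout.labels[r, c])
        scene = layout.scenes[label]
        if label not in base_images:
            base_images[label] = noiseless_scatter_pattern(scene, geometry)
        image = base_images[label]
        if scene.poisson_noise:
            rng = np.random.default_rng(child)
            masked = image == MASKED
            # float32 keeps large scans in memory; counts stay exact below 2^24
            noisy = rng.poisson(np.where(masked, 0.0, image)).astype(np.float32)
            noisy[masked] = MASKED
            image = noisy
        else:
            image = image.astype(np.float32)
        patterns.append(
            ScanPattern(r, c, c * x_pitch_um, r * y_pitch_um, label, image)
        )
    return patterns


# ---------------------------------------------------------------------------
# pSHG stacks

DEFAULT_PSHG_ANGLES = tuple(float(a) for a in range(0, 180, 15))


@dataclass
class PSHGScene:
    """Per-pixel ground-truth fields for a polarization-resolved SHG stack."""

    a0_field: np.ndarray
    i2_field: np.ndarray
    phi2_field: np.ndarray
    i4_field: np.ndarray
    phi4_field: np.ndarray
    angles_deg: tuple[float, ...] = DEFAULT_PSHG_ANGLES
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        fields = [
            np.asarray(f, dtype=float)
            for f in (
                self.a0_field,
                self.i2_field,
                self.phi2_field,
                self.i4_field,
                self.phi4_field,
            )
        ]
        shapes = {f.shape for f in fields}
        if len(shapes) != 1:
            raise ValueError("all parameter fields must share one raster shape")
        (
            self.a0_field,
            self.i2_field,
            self.phi2_field,
            self.i4_field,
            self.phi4_field,
        ) = fields
        angles = np.asarray(self.angles_deg, dtype=float)
        if np.any(np.diff(angles) <= 0):
            raise ValueError("polarization angles must be strictly increasing")
        spacings = np.diff(angles)
        if angles.size < 2 or not np.allclose(spacings, spacings[0]):
            raise ValueError("polarization angles must be uniformly spaced")
        if angles.size * spacings[0] < 180.0 - 1e-9:
            raise ValueError("polarization angles must cover at least 180 deg")
        if np.any(self.i2_field < 0) or np.any(self.i4_field < 0):
            raise ValueError("i2/i4 fields must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.a0_field.shape


def uniform_pshg_scene(
    shape=(512, 512),
    a0: float = 500.0,
    i2: float = 0.25,
    phi2: float = 30.0,
    i4: float = 0.05,
    phi4: float = 20.0,
    angles_deg=DEFAULT_PSHG_ANGLES,
    shot_noise: bool = True,
    seed: int = 0,
) -> PSHGScene:
    """Scene with spatially constant parameters (convenience constructor)."""
    full = lambda v: np.full(shape, float(v))
    return PSHGScene(
        full(a0), full(i2), full(phi2), full(i4), full(phi4),
        angles_deg=tuple(angles_deg), shot_noise=shot_noise, seed=seed,
    )


def pshg_model(a0, i2, phi2_deg, i4, phi4_deg, angles_deg):
    """Evaluate the circular-harmonic forward model at the given angles.

    Returns an array with one trailing angle axis appended to the parameter
    broadcast shape; negative intensities are clipped at zero.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a0 = np.asarray(a0, dtype=float)[..., None]
    i2 = np.asarray(i2, dtype=float)[..., None]
    i4 = np.asarray(i4, dtype=float)[..., None]
    p2 = np.radians(np.asarray(phi2_deg, dtype=float))[..., None]
    p4 = np.radians(np.asarray(phi4_deg, dtype=float))[..., None]
    out = a0 * (1.0 + i2 * np.cos(2.0 * (a - p2)) + i4 * np.cos(4.0 * (a - p4)))
    return np.clip(out, 0.0, None)


def generate_pshg_stack(scene: PSHGScene):
    """Simulate a pSHG stack -> (intensities (ny, nx, n_angles), angles).

    Warns when i2 + i4 > 1 somewhere (pre-clip intensities go negative);
    clipping at zero is applied in that case.
    """
    if np.any(scene.i2_field + scene.i4_field > 1.0 + 1e-12):
        warnings.warn(
            "i2 + i4 > 1 at some pixels: negative model intensities clipped at 0",
            stacklevel=2,
        )
    stack = pshg_model(
        scene.a0_field,
        scene.i2_field,
        scene.phi2_field,
        scene.i4_field,
        scene.phi4_field,
        scene.angles_deg,
    )
    if scene.shot_noise:
        rng = np.random.default_rng(scene.seed)
        stack = rng.poisson(stack).astype(float)
    return stack, np.asarray(scene.angles_deg, dtype=float)
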
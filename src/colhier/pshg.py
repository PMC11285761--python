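"""Per-pixel circular-harmonic fitting of polarization-resolved SHG stacks.

The intensity of each pixel as a function of the linear polarization angle
alpha is projected onto the basis {1, cos 2a, sin 2a, cos 4a, sin 4a} by
ordinary least squares.  The organization parameter I2 is the amplitude of
the 2-alpha term normalized by the mean intensity a0 (larger I2 = higher
organization around the dominant direction phi2); I4/phi4 are computed and
stored but excluded from the region summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Lateral pixel size of the default acquisition: 384.5 um field over 512 px.
DEFAULT_PIXEL_SIZE_UM = 384.5 / 512.0


@dataclass
class PSHGStack:
    """A polarization series: (ny, nx, n_angles) intensities in counts."""

    intensities: np.ndarray
    angles_deg: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("stack must be (ny, nx, n_angles)")
        n = self.angles_deg.size
        if self.intensities.shape[2] != n:
            raise ValueError(
                f"page/angle count mismatch: {self.intensities.shape[2]} image "
                f"pages vs {n} polarization angles"
            )
        if n < 5:
            raise ValueError("need at least 5 angles for the 5-parameter model")
        folded = np.sort(self.angles_deg % 180.0)
        if np.any(np.diff(folded) < 1e-9):
            raise ValueError("polarization angles must be distinct modulo 180 deg")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    def mean_image(self) -> np.ndarray:
        return self.intensities.mean(axis=2)


@dataclass
class PolarizationFitResult:
    """Per-pixel harmonic maps; NaN outside the validity mask.

    ``i2_map``/``i4_map`` are amplitudes normalized by a0; the raw amplitudes
    are kept in ``amp2_map``/``amp4_map``.
    """

    a0_map: np.ndarray
    i2_map: np.ndarray
    phi2_map: np.ndarray
    i4_map: np.ndarray
    phi4_map: np.ndarray
    amp2_map: np.ndarray
    amp4_map: np.ndarray
    mask: np.ndarray          # True where the fit is valid
    residual_map: np.ndarray  # RMS residual of the fit
    angles_deg: np.ndarray = field(default=None)

    def mean_i2(self) -> float:
        """Mean I2 over valid pixels (one value per acquisition)."""
        if not self.mask.any():
            raise ValueError("no valid pixels in this acquisition")
        return float(np.nanmean(self.i2_map[self.mask]))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def design_matrix(angles_deg) -> np.ndarray:
    """(n_angles, 5) circular-harmonic basis {1, cos2a, sin2a, cos4a, sin4a}."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.column_stack(
        [np.ones_like(a), np.cos(2 * a), np.sin(2 * a), np.cos(4 * a), np.sin(4 * a)]
    )


def apply_intensity_threshold(
    stack: PSHGStack,
    fraction: float = 0.10,
    reference_percentile: float = 99.0,
    absolute: float | None = None,
) -> np.ndarray:
    """Keep-mask for pixels with sufficient mean SHG intensity.

    Default rule: keep pixels whose mean intensity over angles reaches 10% of
    the 99th percentile of the mean image; ``absolute`` overrides the
    relative rule.  Raises if every pixel would be masked out.
    """
    mean_img = stack.mean_image()
    thr = absolute if absolute is not None else (
        fraction * float(np.percentile(mean_img, reference_percentile))
    )
    keep = mean_img >= thr
    if not keep.any():
        raise ValueError(
            f"intensity threshold {thr:.4g} masks out every pixel of the stack"
        )
    return keep


def fit_circular_harmonics(
    stack: PSHGStack, mask: np.ndarray | None = None
) -> PolarizationFitResult:
    """Linear least-squares harmonic fit at every (unmasked) pixel.

    The model is linear in its five coefficients, so 12 angles spanning 180
    degrees determine them uniquely and noiseless model data are recovered
    exactly.  Pixels with a0 <= 0 are masked; a rank-deficient angle set
    raises for the whole stack.
    """
    X = design_matrix(stack.angles_deg)
    if np.linalg.matrix_rank(X) < 5:
        raise ValueError("polarization angle list is rank-deficient for the "
                         "5-parameter circular-harmonic basis")
    ny, nx, n = stack.intensities.shape
    Y = stack.intensities.reshape(-1, n).T            # (n_angles, n_pix)
    coef = np.linalg.pinv(X) @ Y                      # (5, n_pix)
    resid = X @ coef - Y
    rms = np.sqrt(np.mean(resid**2, axis=0))

    a0 = coef[0]
    amp2 = np.hypot(coef[1], coef[2])
    amp4 = np.hypot(coef[3], coef[4])
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = amp2 / a0
        i4 = amp4 / a0
    phi2 = (0.5 * np.degrees(np.arctan2(coef[2], coef[1]))) % 180.0
    phi4 = (0.25 * np.degrees(np.arctan2(coef[4], coef[3]))) % 90.0

    valid = a0 > 0
    if mask is not None:
        valid &= mask.reshape(-1)

    def _map(v):
        out = np.where(valid, v, np.nan)
        return out.reshape(ny, nx)

    return PolarizationFitResult(
        a0_map=_map(a0),
        i2_map=_map(i2),
        phi2_map=_map(phi2),
        i4_map=_map(i4),
        phi4_map=_map(phi4),
        amp2_map=_map(amp2),
        amp4_map=_map(amp4),
        mask=valid.reshape(ny, nx),
        residual_map=_map(rms),
        angles_deg=np.asarray(stack.angles_deg, dtype=float),
    )


def evaluate_fit(result: PolarizationFitResult, angles_deg=None) -> np.ndarray:
    """Reconstruct the model stack from fitted maps (NaN where masked)."""
    angles = result.angles_deg if angles_deg is None else angles_deg
    a = np.radians(np.asarray(angles, dtype=float))
    p2 = np.radians(result.phi2_map)[..., None]
    p4 = np.radians(result.phi4_map)[..., None]
    return result.a0_map[..., None] + (
        result.amp2_map[..., None] * np.cos(2 * (a - p2))
        + result.amp4_map[..., None] * np.cos(4 * (a - p4))
    )


@dataclass
class RegionSummary:
    region: str
    mean_i2: float
    std_i2: float
    n_acquisitions: int
    single_acquisition: bool = False


def summarize_regions(acquisition_means: pd.DataFrame) -> pd.DataFrame:
    """Two-level aggregation of I2: acquisitions first, then regions.

    ``acquisition_means`` needs columns 'region' and 'mean_i2' (one row per
    pSHG acquisition).  The region mean and sample standard deviation
    (n - 1 denominator) are taken across acquisition means; a single
    acquisition reports std 0 with a flag.
    """
    required = {"region", "mean_i2"}
    if not required.issubset(acquisition_means.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for region, grp in acquisition_means.groupby("region", sort=False):
        vals = grp["mean_i2"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        single = vals.size == 1
        rows.append(
            RegionSummary(
                region=str(region),
                mean_i2=float(vals.mean()),
                std_i2=0.0 if single else float(vals.std(ddof=1)),
                n_acquisitions=int(vals.size),
                single_acquisition=single,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def acquisition_table(
    results: list[tuple[str, PolarizationFitResult]]
) -> pd.DataFrame:
    """Per-acquisition mean I2 table from (region, fit result) pairs.

    Acquisitions without any valid pixel are excluded (logged via the flags
    column of the output being absent for them).
    """
    rows = []
    for idx, (region, res) in enumerate(results):
        if not res.mask.any():
            continue
        rows.append(
            dict(
                acquisition=idx,
                region=region,
                mean_i2=res.mean_i2(),
                n_valid_pixels=res.n_valid,
            )
        )
    return pd.DataFrame(rows)
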
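"""Camera band adaptation: spectral integration, noise injection, features.

A multispectral camera measures K band reflectances
``r_k = w + sum_lambda b_k(lambda) r(lambda)`` where ``b_k`` is the filter
transmission and ``w`` zero-mean Gaussian noise with standard deviation
``r_k / SNR`` (signal-proportional). Before regression the measurements are
normalized in three stages: l1 normalization (cancels multiplicative
illumination changes from camera distance/angle and sensor scaling), -log
transformation to the absorption domain, and l2 normalization.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .transport import ReflectanceSpectrum

__all__ = [
    "BandSystem",
    "BandMeasurement",
    "boxcar_band_system",
    "camera_band_system",
    "band_integrate",
    "add_noise",
    "normalize_features",
    "CAMERA_CENTERS_NM",
]

#: Center wavelengths of the 8-band laparoscopic camera.
CAMERA_CENTERS_NM = (470.0, 480.0, 511.0, 560.0, 580.0, 600.0, 660.0, 700.0)
#: Band FWHM is 20 nm except the 480 nm band (25 nm).
CAMERA_FWHM_NM = (20.0, 25.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0)


@dataclass(frozen=True)
class BandSystem:
    """K spectral filters defined by transmission weights on a fixed grid.

    Transmissions are normalized to sum to 1 per band (weighted averages);
    absolute throughput is cancelled later by the l1 feature normalization.
    """

    centers: np.ndarray          # (K,) nm
    grid: np.ndarray             # (M,) nm, the simulation grid
    transmissions: np.ndarray    # (K, M), rows sum to 1
    name: str = "custom"

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float)
        g = np.asarray(self.grid, float)
        t = np.asarray(self.transmissions, float)
        if c.size < 2:
            raise ValueError("a band system needs at least 2 bands")
        if t.shape != (c.size, g.size):
            raise ValueError("transmissions must be (n_bands, n_grid)")
        if (t < 0).any() or (t.sum(axis=1) <= 0).any():
            raise ValueError("each band needs non-negative weights with positive sum")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "transmissions", t / t.sum(axis=1, keepdims=True))

    @property
    def n_bands(self) -> int:
        return self.centers.size

    def fingerprint(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for arr in (self.centers, self.grid, self.transmissions):
            # round away normalization float dust so serialization round-trips
            h.update(np.ascontiguousarray(np.round(arr, 12)).tobytes())
        return h.hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "name": self.name,
            "centers_nm": [float(x) for x in self.centers],
            "grid_nm": [float(x) for x in self.grid],
            "transmissions": [[float(x) for x in row]
                              for row in self.transmissions],
        }))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BandSystem":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(raw["centers_nm"]), np.asarray(raw["grid_nm"]),
                   np.asarray(raw["transmissions"]), raw.get("name", "custom"))


@dataclass(frozen=True)
class BandMeasurement:
    """K band reflectances, with the SNR used for noise injection.

    ``snr = inf`` marks a noiseless measurement.
    """

    r_k: np.ndarray
    snr: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_k", np.asarray(self.r_k, float))


def boxcar_band_system(start_nm: float = 470.0, stop_nm: float = 680.0,
                       step_nm: float = 10.0, width_nm: float = 10.0,
                       grid=None) -> BandSystem:
    """Sliding-average boxcar bands, the in-silico camera model.

    Defaults give 22 bands at 470-680 nm with a 10 nm bandwidth: each band is
    the equal-weight average of grid points within +/- width/2 of its center.
    """
    if start_nm >= stop_nm or width_nm <= 0:
        raise ValueError("need start < stop and positive width")
    if grid is None:
        from .transport import default_wavelength_grid
        grid = default_wavelength_grid()
    grid = np.asarray(grid, float)
    centers = np.arange(start_nm, stop_nm + 0.5 * step_nm, step_nm)
    half = width_nm / 2.0
    if centers[0] - half < grid[0] - 1e-9 or centers[-1] + half > grid[-1] + 1e-9:
        raise ValueError("band extends past the simulation grid")
    trans = np.zeros((centers.size, grid.size))
    for k, c in enumerate(centers):
        inside = np.abs(grid - c) <= half + 1e-9
        if not inside.any():
            raise ValueError(f"no grid point inside band at {c} nm")
        trans[k, inside] = 1.0
    return BandSystem(centers, grid, trans, name=f"boxcar{centers.size}")


def camera_band_system(grid=None, centers=CAMERA_CENTERS_NM,
                       fwhm=CAMERA_FWHM_NM) -> BandSystem:
    """The 8-band laparoscopic camera, Gaussian transmission profiles.

    Filter FWHMs are 20 nm except 25 nm at 480 nm; profiles are normalized,
    so only the band shape matters.
    """
    if grid is None:
        from .transport import default_wavelength_grid
        grid = default_wavelength_grid()
    grid = np.asarray(grid, float)
    centers = np.asarray(centers, float)
    fwhm = np.asarray(fwhm, float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    trans = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / sigma[:, None]) ** 2)
    if (trans.sum(axis=1) <= 1e-12).any():
        raise ValueError("band extends past the simulation grid")
    return BandSystem(centers, grid, trans, name="spectrocam8")


def band_integrate(spectrum: ReflectanceSpectrum,
                   bands: BandSystem) -> BandMeasurement:
    """Noiseless camera measurement: r_k = sum_lambda b_k(lambda) r(lambda)."""
    sgrid = np.asarray(spectrum.wavelength_nm, float)
    if sgrid.shape != bands.grid.shape or not np.allclose(sgrid, bands.grid):
        raise ValueError("spectrum grid does not match the band system grid")
    return BandMeasurement(bands.transmissions @ np.asarray(spectrum.r, float))


def band_integrate_array(r: np.ndarray, bands: BandSystem) -> np.ndarray:
    """Vectorized band integration of an (n_spectra, n_grid) array."""
    return np.asarray(r, float) @ bands.transmissions.T


def add_noise(measurement: BandMeasurement, snr: float,
              seed: int | np.random.Generator) -> BandMeasurement:
    """Perturb each band with zero-mean Gaussian noise of std ``r_k / snr``.

    The noise scale is computed from the noiseless band value, making it
    signal-proportional; ``snr = inf`` is the identity.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    if np.isinf(snr):
        return BandMeasurement(measurement.r_k.copy(), snr=np.inf)
    rng = np.random.default_rng(seed)
    r = measurement.r_k
    return BandMeasurement(r + rng.normal(0.0, 1.0, r.shape) * (r / snr),
                           snr=snr)


def add_noise_array(r_k: np.ndarray, snr: float,
                    seed: int | np.random.Generator) -> np.ndarray:
    """Vectorized :func:`add_noise` for an (n_spectra, K) array."""
    if not snr > 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    r_k = np.asarray(r_k, float)
    if np.isinf(snr):
        return r_k.copy()
    rng = np.random.default_rng(seed)
    return r_k + rng.normal(0.0, 1.0, r_k.shape) * (r_k / snr)


# fraction of the spectrum's l1 mass used as a floor for non-positive band
# values after noise injection (the -log transform needs positive input)
_CLIP_FLOOR_FRAC = 1e-6


def normalize_features(measurement: BandMeasurement | np.ndarray) -> np.ndarray:
    """The l1 -> -log -> l2 normalization chain producing feature vectors.

    Accepts one measurement or an (n, K) array; returns unit-l2 vectors that
    are invariant under positive rescaling of the input. Non-positive band
    values (possible after strong noise) are clipped to a small fraction of
    the per-spectrum l1 mass before the log.
    """
    r = measurement.r_k if isinstance(measurement, BandMeasurement) else measurement
    r = np.atleast_2d(np.asarray(r, float))
    if r.shape[1] < 2:
        raise ValueError("need at least 2 bands")
    l1 = np.sum(np.abs(r), axis=1, keepdims=True)
    if (l1 <= 0).any():
        raise ValueError("cannot normalize an all-zero measurement")
    r1 = r / l1
    r1 = np.maximum(r1, _CLIP_FLOOR_FRAC)
    a = -np.log(r1)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    if isinstance(measurement, BandMeasurement) or np.asarray(measurement).ndim == 1:
        return a[0]
    return a
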
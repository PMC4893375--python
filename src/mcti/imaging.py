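"""Per-pixel estimation on multispectral image stacks, plus synthetic phantoms.

The imaging chain mirrors intra-operative processing: subtract the camera's
dark current, divide by a flatfield reference (cancelling light source,
optics and quantum efficiency), mask specular highlights by thresholding,
optionally block-average downsample, then apply a trained inverse model to
every pixel's band reflectance vector. Synthetic phantoms — region layouts
of tissue samples rendered through the full forward chain with dark,
flatfield, noise and injected specular pixels — make the whole path testable
without animal recordings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .bands import BandSystem, add_noise_array, band_integrate_array, \
    normalize_features
from .inversion import RegressorModel, predict
from .tissue_model import ChromophoreTable, TissueSample
from .transport import SimulationConfig, derive_seed, simulate_spectrum

__all__ = [
    "MultispectralImage",
    "ParameterMap",
    "PhantomSpec",
    "PhantomRegion",
    "flatfield_correct",
    "specular_mask",
    "estimate_map",
    "roi_mean_series",
    "synthesize_phantom",
    "block_downsample",
    "read_stack",
    "write_stack",
]

#: Default specular threshold: fraction of the per-band maximum.
DEFAULT_SPECULAR_THRESHOLD = 0.95


@dataclass
class MultispectralImage:
    """An H x W x K raw intensity stack with its dark and flatfield frames."""

    stack: np.ndarray
    dark: np.ndarray
    flatfield: np.ndarray
    band_system_ref: str = ""

    def __post_init__(self) -> None:
        st = np.asarray(self.stack, float)
        if st.ndim != 3:
            raise ValueError("stack must be H x W x K")
        for name in ("dark", "flatfield"):
            f = np.asarray(getattr(self, name), float)
            if f.ndim == 1 and f.size == st.shape[2]:   # per-band scalar
                f = np.broadcast_to(f, st.shape).copy()
            if f.shape != st.shape:
                raise ValueError(f"{name} frame shape mismatch")
            setattr(self, name, f)
        self.stack = st


@dataclass
class ParameterMap:
    """Estimated oxygenation/blood-volume maps with a validity mask."""

    s_map: np.ndarray
    v_hb_map: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.s_map.shape == self.v_hb_map.shape
                == self.valid_mask.shape):
            raise ValueError("map shapes must agree")
        for m in (self.s_map, self.v_hb_map):
            ok = self.valid_mask
            if ok.any() and ((m[ok] < 0).any() or (m[ok] > 1).any()):
                raise ValueError("valid estimates must lie in [0, 1]")


def flatfield_correct(image: MultispectralImage) -> np.ndarray:
    """(stack - dark) / (flatfield - dark), with invalid pixels as NaN.

    Pixels whose flatfield-minus-dark denominator is not positive carry no
    usable calibration and are flagged NaN rather than silently zeroed.
    """
    denom = image.flatfield - image.dark
    out = np.full(image.stack.shape, np.nan)
    ok = denom > 0
    out[ok] = (image.stack[ok] - image.dark[ok]) / denom[ok]
    return out


def specular_mask(reflectance: np.ndarray,
                  threshold: float = DEFAULT_SPECULAR_THRESHOLD) -> np.ndarray:
    """True where a pixel is specular in any band.

    A pixel is masked when any band strictly exceeds ``threshold`` times
    that band's maximum, so ``threshold=1.0`` masks nothing. Masking is
    monotone in the threshold: lower thresholds mask supersets.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    r = np.asarray(reflectance, float)
    band_max = np.nanmax(r.reshape(-1, r.shape[2]), axis=0)
    with np.errstate(invalid="ignore"):
        return np.any(r > threshold * band_max[None, None, :], axis=2)


def block_downsample(stack: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor (trailing rows cropped)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return stack.copy()
    h, w = stack.shape[0] // factor * factor, stack.shape[1] // factor * factor
    s = stack[:h, :w]
    return s.reshape(h // factor, factor, w // factor, factor,
                     *s.shape[2:]).mean(axis=(1, 3))


def estimate_map(reflectance: np.ndarray, model: RegressorModel,
                 bands: BandSystem,
                 specular_threshold: float | None = DEFAULT_SPECULAR_THRESHOLD,
                 chunk_rows: int = 200_000) -> ParameterMap:
    """Apply a trained model per pixel to a corrected reflectance stack.

    Invalid pixels (NaN bands or specular highlights) are excluded from
    estimation and flagged in the mask. Prediction runs in row chunks so
    megapixel stacks stay within memory; chunking does not change results.
    """
    r = np.asarray(reflectance, float)
    if r.ndim != 3 or r.shape[2] != bands.n_bands:
        raise ValueError("reflectance must be H x W x K matching the bands")
    h, w, k = r.shape
    flat = r.reshape(-1, k)
    valid = np.isfinite(flat).all(axis=1) & (np.abs(flat).sum(axis=1) > 0)
    if specular_threshold is not None:
        valid &= ~specular_mask(r, specular_threshold).reshape(-1)
    s_map = np.full(h * w, np.nan)
    v_map = np.full(h * w, np.nan)
    idx = np.flatnonzero(valid)
    for start in range(0, idx.size, chunk_rows):
        sel = idx[start:start + chunk_rows]
        feats = normalize_features(flat[sel])
        pred = predict(model, feats, band_fingerprint=bands.fingerprint())
        s_map[sel] = pred[:, 0]
        v_map[sel] = pred[:, 1]
    return ParameterMap(s_map.reshape(h, w), v_map.reshape(h, w),
                        valid.reshape(h, w))


def roi_mean_series(maps: Sequence[ParameterMap],
                    roi_mask: np.ndarray) -> "pd.DataFrame":
    """Mean oxygenation and blood volume over an ROI for each time point.

    Frames whose ROI contains no valid pixel yield NaN (missing), never 0.
    """
    import pandas as pd
    roi = np.asarray(roi_mask, bool)
    rows = []
    for t, pm in enumerate(maps):
        sel = roi & pm.valid_mask
        if sel.any():
            rows.append({"frame": t, "mean_s": float(pm.s_map[sel].mean()),
                         "mean_v_hb": float(pm.v_hb_map[sel].mean()),
                         "n_valid": int(sel.sum())})
        else:
            rows.append({"frame": t, "mean_s": np.nan, "mean_v_hb": np.nan,
                         "n_valid": 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomRegion:
    """A rectangular region of one tissue type: (row0, row1, col0, col1)."""

    bounds: tuple[int, int, int, int]
    sample: TissueSample


@dataclass
class PhantomSpec:
    """Layout and acquisition settings of a synthetic multispectral phantom.

    Emulates the in-vivo stacks: a region layout of tissue samples rendered
    through the Monte Carlo chain, embedded as
    ``dark + r_k * (flatfield - dark)`` with signal-proportional noise and a
    sprinkling of saturated specular pixels.
    """

    shape: tuple[int, int]
    regions: list[PhantomRegion]
    snr: float = 10.0
    specular_fraction: float = 0.0
    dark_level: float = 100.0
    flat_level: float = 3000.0
    seed: int = 0
    n_photons: int = 5_000

    def __post_init__(self) -> None:
        h, w = self.shape
        for reg in self.regions:
            r0, r1, c0, c1 = reg.bounds
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"region {reg.bounds} outside image {self.shape}")


def synthesize_phantom(spec: PhantomSpec, bands: BandSystem,
                       table: ChromophoreTable,
                       pixel_jitter: float = 0.0
                       ) -> tuple[MultispectralImage, ParameterMap]:
    """Render a phantom stack and its ground-truth parameter maps.

    Each region's spectrum is simulated once (with optional multiplicative
    per-pixel jitter), band-integrated, noise-injected at ``spec.snr`` and
    embedded between the dark and flatfield levels. Specular pixels are set
    to saturation. Deterministic given ``spec.seed``.
    """
    h, w = spec.shape
    k = bands.n_bands
    rng = np.random.default_rng(spec.seed % (2**32))
    sim_cfg = SimulationConfig(n_photons=spec.n_photons,
                               seed=derive_seed(spec.seed, 9),
                               weight_threshold=1e-2)
    band_r = np.zeros((h, w, k))
    s_true = np.full((h, w), np.nan)
    v_true = np.full((h, w), np.nan)
    covered = np.zeros((h, w), bool)
    for i, reg in enumerate(spec.regions):
        spectrum = simulate_spectrum(reg.sample, bands.grid, table, sim_cfg,
                                     sample_index=i)
        r_k = band_integrate_array(spectrum.r[None, :], bands)[0]
        r0, r1, c0, c1 = reg.bounds
        band_r[r0:r1, c0:c1, :] = r_k
        s_true[r0:r1, c0:c1] = reg.sample.s
        v_true[r0:r1, c0:c1] = reg.sample.v_hb
        covered[r0:r1, c0:c1] = True
    if pixel_jitter > 0:
        band_r *= 1.0 + pixel_jitter * rng.standard_normal((h, w, 1))
    noisy = add_noise_array(band_r.reshape(-1, k), spec.snr,
                            derive_seed(spec.seed, 11) % (2**32)
                            ).reshape(h, w, k)
    dark = np.full((h, w, k), spec.dark_level)
    flat = np.full((h, w, k), spec.flat_level)
    stack = dark + noisy * (flat - dark)
    specular = np.zeros((h, w), bool)
    if spec.specular_fraction > 0:
        n_spec = int(round(spec.specular_fraction * h * w))
        idx = rng.choice(h * w, size=n_spec, replace=False)
        specular.reshape(-1)[idx] = True
        stack[specular] = spec.flat_level * 1.5   # saturated highlight
    truth = ParameterMap(np.where(covered, s_true, np.nan),
                         np.where(covered, v_true, np.nan),
                         covered & ~specular)
    image = MultispectralImage(stack, dark, flat,
                               band_system_ref=bands.fingerprint())
    return image, truth


# ---------------------------------------------------------------------------
# TIFF I/O: one page per band, band order = band-system order
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: np.ndarray,
                metadata: dict | None = None) -> None:
    """Write an H x W x K stack as a multi-page TIFF (+ YAML sidecar)."""
    arr = np.moveaxis(np.asarray(stack, np.float32), 2, 0)
    tifffile.imwrite(path, arr)
    if metadata is not None:
        Path(str(path) + ".yaml").write_text(yaml.safe_dump(metadata))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into an H x W x K array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return np.moveaxis(arr, 0, 2).astype(float)
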
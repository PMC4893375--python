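"""Multi-layer Monte Carlo photon transport (MCML-style) for diffuse reflectance.

Photon packets are launched as an infinitely narrow pencil beam at normal
incidence onto a stack of plane-parallel layers. Each packet performs the
classic hop-drop-spin walk: exponential step sampling with the local
attenuation mu_t = mu_a + mu_s, partial absorption by weight reduction,
Henyey-Greenstein deflection, Fresnel reflection/refraction at layer and
external boundaries, and Russian roulette once the weight falls below a
threshold. Scored quantities are the specular reflection, total
(hemispherically integrated) diffuse reflectance, transmittance and absorbed
fraction; no spatial or angular binning is performed.

The random number generator is a counter-seeded xorshift64* stream, one
stream per (sample, wavelength), so results are independent of batch order
and worker count.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed
from numba import njit

from .tissue_model import (ChromophoreTable, OpticalProperties, TissueSample,
                           to_optical_properties)

__all__ = [
    "SimulationConfig",
    "MCResult",
    "ReflectanceSpectrum",
    "simulate_reflectance",
    "simulate_spectrum",
    "batch_simulate",
    "default_wavelength_grid",
    "derive_seed",
    "save_dataset",
    "load_dataset",
]


def default_wavelength_grid(step_nm: float = 2.0) -> np.ndarray:
    """The 450-720 nm simulation grid (2 nm steps by default, 136 points)."""
    return np.arange(450.0, 720.0 + 0.5 * step_nm, step_nm)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo run configuration.

    ``n_photons`` defaults to the full-fidelity 10^6 packets per wavelength;
    desk-scale runs reduce it (the variance estimate reports the cost).
    Roulette constants are the standard MCML choices.
    """

    n_photons: int = 1_000_000
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    ambient_n: float = 1.0           # gas-filled pneumoperitoneum
    max_interactions: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must be in (0, 1)")
        if self.weight_threshold <= 0:
            raise ValueError("weight_threshold must be positive")


@dataclass(frozen=True)
class MCResult:
    """Single-wavelength scoring: all fractions of the launched energy."""

    r_d: float            # diffuse reflectance (>=1 scattering event)
    variance: float       # variance of the r_d estimate
    r_spec: float         # specular + ballistic top-exit component
    transmittance: float
    absorbed: float
    n_overflow: int = 0   # packets terminated at max_interactions


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Diffuse reflectance over a wavelength grid with its MC variance."""

    wavelength_nm: np.ndarray
    r: np.ndarray
    variance: np.ndarray
    n_photons: int

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelength_nm, float)
        r = np.asarray(self.r, float)
        v = np.asarray(self.variance, float)
        if r.shape != lam.shape or v.shape != lam.shape:
            raise ValueError("spectrum arrays must share one grid")
        if (r < -1e-12).any() or (r > 1 + 1e-12).any():
            raise ValueError("reflectance must lie in [0, 1]")
        if (v < 0).any():
            raise ValueError("variance must be non-negative")
        object.__setattr__(self, "wavelength_nm", lam)
        object.__setattr__(self, "r", np.clip(r, 0.0, 1.0))
        object.__setattr__(self, "variance", v)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_U64 = np.uint64


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0xFFFFFFFFFFFFFFFF


def derive_seed(base: int, *indices: int) -> int:
    """Mix a base seed with indices into an independent 64-bit stream seed."""
    x = _splitmix64(base)
    for idx in indices:
        x = _splitmix64(x ^ ((idx + 1) & 0xFFFFFFFFFFFFFFFF))
    return x or 0x9E3779B97F4A7C15


@njit(cache=True, fastmath=True, inline="always")
def _rand(state):
    # xorshift64*: full-period for nonzero state
    x = state
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(27)
    u = ((x * _U64(0x2545F4914F6CDD1D)) >> _U64(11)) * 1.1102230246251565e-16
    return u, x


@njit(cache=True, fastmath=True)
def _propagate(mu_a, mu_s, g, n_layer, zb, n_ambient, n_photons,
               w_threshold, survival, max_inter, seed):
    """Trace ``n_photons`` packets through the slab; return scored fractions.

    ``zb`` holds the n+1 layer boundary depths in cm (zb[0] = 0). Returns
    (rd_mean, rd_var, r_spec, tt, absorbed, n_overflow) normalized to unit
    launched energy.
    """
    n_lay = mu_a.shape[0]
    state = _U64(seed)

    # specular reflection at the ambient / first-layer interface
    rs = ((n_ambient - n_layer[0]) / (n_ambient + n_layer[0])) ** 2
    w0 = 1.0 - rs

    # hoisted per-layer constants
    inv_mu_t = np.empty(n_lay)
    albedo = np.empty(n_lay)
    hg_f = np.empty(n_lay)    # (1-g^2)
    hg_a = np.empty(n_lay)    # (1-g)
    hg_c = np.empty(n_lay)    # (1+g^2)
    hg_i = np.empty(n_lay)    # 1/(2g) (0 for isotropic)
    for i in range(n_lay):
        mt = mu_a[i] + mu_s[i]
        inv_mu_t[i] = 1.0 / mt if mt > 0.0 else 1e30
        albedo[i] = mu_s[i] / mt if mt > 0.0 else 1.0
        gg = g[i]
        hg_f[i] = 1.0 - gg * gg
        hg_a[i] = 1.0 - gg
        hg_c[i] = 1.0 + gg * gg
        hg_i[i] = 0.5 / gg if gg != 0.0 else 0.0

    rd_sum = 0.0
    rd_sq = 0.0
    ballistic = 0.0
    tt_sum = 0.0
    ab_sum = 0.0
    n_over = 0

    for _ in range(n_photons):
        w = w0
        z = 0.0
        uz = 1.0
        ux = 0.0
        uy = 0.0
        lay = 0
        nscat = 0
        sleft = 0.0
        rd_photon = 0.0
        alive = True
        n_inter = 0
        mu_t = mu_a[0] + mu_s[0]
        imt = inv_mu_t[0]
        alb = albedo[0]
        g_l = g[0]
        hgf = hg_f[0]
        hga = hg_a[0]
        hgc = hg_c[0]
        hgi = hg_i[0]
        z_top = zb[0]
        z_bot = zb[1]

        while alive:
            if sleft == 0.0:
                u, state = _rand(state)
                sleft = -math.log(1.0 - u)   # dimensionless step

            # boundary hit iff optical distance to the boundary <= sleft;
            # compare in multiplied form to avoid a division on interior hops
            if uz > 0.0:
                hit = mu_t * (z_bot - z) <= sleft * uz
                hit_bottom = True
            elif uz < 0.0:
                hit = mu_t * (z_top - z) >= sleft * uz
                hit_bottom = False
            else:
                hit = False
                hit_bottom = False

            if hit:
                # hop to the boundary, carry the unused step across
                db = ((z_bot - z) if hit_bottom else (z_top - z)) / uz
                z = z_bot if hit_bottom else z_top
                sleft -= mu_t * db
                ni = n_layer[lay]
                if hit_bottom:
                    nt = n_layer[lay + 1] if lay + 1 < n_lay else n_ambient
                else:
                    nt = n_layer[lay - 1] if lay > 0 else n_ambient
                ca_i = abs(uz)
                # Fresnel reflectance for unpolarized light
                if ni == nt:
                    r_fres = 0.0
                    ca_t = ca_i
                else:
                    sa_i = math.sqrt(max(0.0, 1.0 - ca_i * ca_i))
                    sa_t = ni * sa_i / nt
                    if sa_t >= 1.0:
                        r_fres = 1.0
                        ca_t = 0.0
                    else:
                        ca_t = math.sqrt(1.0 - sa_t * sa_t)
                        if sa_i < 1e-6:
                            rr = (ni - nt) / (ni + nt)
                            r_fres = rr * rr
                        else:
                            cap = ca_i * ca_t - sa_i * sa_t  # cos(ai+at)
                            cam = ca_i * ca_t + sa_i * sa_t  # cos(ai-at)
                            sap = sa_i * ca_t + ca_i * sa_t  # sin(ai+at)
                            sam = sa_i * ca_t - ca_i * sa_t  # sin(ai-at)
                            r_fres = 0.5 * (sam * sam) * \
                                (cam * cam + cap * cap) / \
                                ((sap * sap) * (cam * cam))
                u, state = _rand(state)
                if u <= r_fres:
                    uz = -uz            # internally reflected
                else:
                    if hit_bottom:
                        if lay + 1 < n_lay:
                            ratio = ni / nt
                            ux *= ratio
                            uy *= ratio
                            uz = ca_t
                            lay += 1
                        else:
                            tt_sum += w
                            alive = False
                    else:
                        if lay > 0:
                            ratio = ni / nt
                            ux *= ratio
                            uy *= ratio
                            uz = -ca_t
                            lay -= 1
                        else:
                            if nscat > 0:
                                rd_photon += w
                            else:
                                ballistic += w
                            alive = False
                    if alive:
                        mu_t = mu_a[lay] + mu_s[lay]
                        imt = inv_mu_t[lay]
                        alb = albedo[lay]
                        g_l = g[lay]
                        hgf = hg_f[lay]
                        hga = hg_a[lay]
                        hgc = hg_c[lay]
                        hgi = hg_i[lay]
                        z_top = zb[lay]
                        z_bot = zb[lay + 1]
                continue

            # interior hop: absorb and scatter
            z += sleft * imt * uz
            sleft = 0.0
            n_inter += 1
            if n_inter > max_inter:
                ab_sum += w
                n_over += 1
                alive = False
                continue
            ab_sum += w * (1.0 - alb)
            w *= alb
            nscat += 1

            # Henyey-Greenstein deflection
            u, state = _rand(state)
            if g_l != 0.0:
                tmp = hgf / (hga + 2.0 * g_l * u)
                ct = (hgc - tmp * tmp) * hgi
                if ct < -1.0:
                    ct = -1.0
                elif ct > 1.0:
                    ct = 1.0
            else:
                ct = 2.0 * u - 1.0
            st = math.sqrt(1.0 - ct * ct)
            # azimuth: rejection-sampled point on the unit circle (trig-free)
            while True:
                u, state = _rand(state)
                x1 = 2.0 * u - 1.0
                u, state = _rand(state)
                x2 = 2.0 * u - 1.0
                rr2 = x1 * x1 + x2 * x2
                if 0.0 < rr2 <= 1.0:
                    break
            inv_r2 = 1.0 / rr2
            cp = (x1 * x1 - x2 * x2) * inv_r2
            sp = 2.0 * x1 * x2 * inv_r2
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                inv_den = 1.0 / den
                uxn = st * (ux * uz * cp - uy * sp) * inv_den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) * inv_den + uy * ct
                uzn = -st * cp * den + uz * ct
                ux, uy, uz = uxn, uyn, uzn

            # Russian roulette
            if w < w_threshold:
                u, state = _rand(state)
                if u < survival:
                    w /= survival
                else:
                    alive = False

        rd_sum += rd_photon
        rd_sq += rd_photon * rd_photon

    n = float(n_photons)
    rd_mean = rd_sum / n
    rd_var = max(rd_sq / n - rd_mean * rd_mean, 0.0) / n
    return (rd_mean, rd_var, rs + ballistic / n, tt_sum / n, ab_sum / n,
            n_over)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_reflectance(layers: Sequence[OpticalProperties],
                         config: SimulationConfig) -> MCResult:
    """Run the photon-packet walk for one set of layer optical properties."""
    if len(layers) < 1:
        raise ValueError("at least one layer is required")
    mu_a = np.array([l.mu_a for l in layers], float)
    mu_s = np.array([l.mu_s for l in layers], float)
    g = np.array([l.g for l in layers], float)
    n_l = np.array([l.n_refr for l in layers], float)
    d = np.array([l.d for l in layers], float)
    for arr in (mu_a, mu_s, g, n_l, d):
        if not np.isfinite(arr).all():
            raise ValueError("optical properties must be finite")
    zb = np.concatenate(([0.0], np.cumsum(d)))
    seed = derive_seed(config.seed)
    out = _propagate(mu_a, mu_s, g, n_l, zb, config.ambient_n,
                     config.n_photons, config.weight_threshold,
                     config.roulette_survival, config.max_interactions,
                     np.uint64(seed))
    return MCResult(r_d=out[0], variance=out[1], r_spec=out[2],
                    transmittance=out[3], absorbed=out[4], n_overflow=out[5])


def simulate_spectrum(sample: TissueSample, wavelength_grid,
                      table: ChromophoreTable, config: SimulationConfig,
                      sample_index: int = 0) -> ReflectanceSpectrum:
    """Evaluate the forward model r(lambda) for one tissue sample.

    Each wavelength runs on an independent RNG stream derived from
    ``(config.seed, sample_index, wavelength index)``.
    """
    grid = np.asarray(wavelength_grid, float)
    r = np.empty_like(grid)
    var = np.empty_like(grid)
    for j, lam in enumerate(grid):
        layers = [to_optical_properties(l, lam, table) for l in sample.layers]
        mu_a = np.array([l.mu_a for l in layers])
        mu_s = np.array([l.mu_s for l in layers])
        g = np.array([l.g for l in layers])
        n_l = np.array([l.n_refr for l in layers])
        zb = np.concatenate(([0.0], np.cumsum([l.d for l in layers])))
        seed = derive_seed(config.seed, sample_index, j)
        out = _propagate(mu_a, mu_s, g, n_l, zb, config.ambient_n,
                         config.n_photons, config.weight_threshold,
                         config.roulette_survival, config.max_interactions,
                         np.uint64(seed))
        r[j], var[j] = out[0], out[1]
    return ReflectanceSpectrum(grid, r, var, config.n_photons)


def _sample_cache_key(sample: TissueSample, grid: np.ndarray,
                      config: SimulationConfig, sample_index: int) -> str:
    payload = {
        "layers": [[l.v_hb, l.s, l.a_mie, l.b, l.g, l.n_refr, l.d]
                   for l in sample.layers],
        "grid": list(np.asarray(grid, float)),
        "n_photons": config.n_photons,
        "seed": config.seed,
        "index": sample_index,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:24]


def _simulate_one(sample, grid, table, config, idx, cache_dir):
    if cache_dir is not None:
        key = _sample_cache_key(sample, grid, config, idx)
        path = Path(cache_dir) / f"{key}.json"
        if path.exists():
            blob = json.loads(path.read_text())
            return ReflectanceSpectrum(np.asarray(blob["grid"]),
                                       np.asarray(blob["r"]),
                                       np.asarray(blob["variance"]),
                                       blob["n_photons"])
    try:
        spec = simulate_spectrum(sample, grid, table, config, sample_index=idx)
    except Exception as exc:  # surface which sample failed
        raise RuntimeError(f"simulation failed for sample {idx}: {exc}") from exc
    if cache_dir is not None:
        path.write_text(json.dumps({
            "grid": list(spec.wavelength_nm), "r": list(spec.r),
            "variance": list(spec.variance), "n_photons": spec.n_photons}))
    return spec


def batch_simulate(samples: Sequence[TissueSample], wavelength_grid,
                   table: ChromophoreTable, config: SimulationConfig,
                   n_workers: int = 1, cache_dir: str | Path | None = None,
                   progress: bool = False) -> list[ReflectanceSpectrum]:
    """Simulate many tissue samples; order- and worker-count independent.

    With ``cache_dir`` set, per-sample results are cached on disk keyed by
    the sample parameters, grid, photon count and seed, so interrupted runs
    resume without re-simulating.
    """
    if len(samples) == 0:
        raise ValueError("no samples to simulate")
    grid = np.asarray(wavelength_grid, float)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
    if n_workers == 1:
        out = []
        for i, smp in enumerate(samples):
            out.append(_simulate_one(smp, grid, table, config, i, cache_dir))
            if progress and (i + 1) % 100 == 0:
                print(f"  simulated {i + 1}/{len(samples)} spectra")
        return out
    return Parallel(n_jobs=n_workers)(
        delayed(_simulate_one)(smp, grid, table, config, i, cache_dir)
        for i, smp in enumerate(samples))


# ---------------------------------------------------------------------------
# dataset I/O: CSV table + YAML sidecar
# ---------------------------------------------------------------------------

def save_dataset(path: str | Path, params: pd.DataFrame,
                 spectra: Sequence[ReflectanceSpectrum],
                 config: SimulationConfig) -> None:
    """Write tissue parameters + per-wavelength reflectance to CSV.

    A YAML sidecar (``<path>.yaml``) records the grid, photon count and seed.
    """
    path = Path(path)
    grid = spectra[0].wavelength_nm
    r = np.stack([sp.r for sp in spectra])
    v = np.stack([sp.variance for sp in spectra])
    df = params.reset_index(drop=True).copy()
    for j, lam in enumerate(grid):
        df[f"r_{lam:g}nm"] = r[:, j]
    for j, lam in enumerate(grid):
        df[f"var_{lam:g}nm"] = v[:, j]
    df.to_csv(path, index=False)
    sidecar = {"wavelength_nm": [float(x) for x in grid],
               "n_photons": int(config.n_photons),
               "seed": int(config.seed)}
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def load_dataset(path: str | Path):
    """Read a dataset written by :func:`save_dataset`.

    Returns ``(params, spectra, meta)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    meta = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    grid = np.asarray(meta["wavelength_nm"], float)
    rcols = [f"r_{lam:g}nm" for lam in grid]
    vcols = [f"var_{lam:g}nm" for lam in grid]
    r = df[rcols].to_numpy(float)
    v = df[vcols].to_numpy(float)
    params = df.drop(columns=rcols + vcols)
    spectra = [ReflectanceSpectrum(grid, r[i], v[i], meta["n_photons"])
               for i in range(len(df))]
    return params, spectra, meta
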
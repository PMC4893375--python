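"""Layered tissue model: chromophores, optical coefficients and tissue sampling.

The tissue probed during laparoscopy is modelled as a stack of plane-parallel
layers. Each layer carries a blood volume fraction ``v_hb``, an oxygenation
``s`` (shared by all layers of a sample, since they share one blood supply),
and scattering/geometry parameters. Hemoglobin is the only absorber: the
absorption coefficient at wavelength lambda is

    mu_a = v_hb * c_hb_molar * (s * eps_HbO2 + (1 - s) * eps_Hb) * ln(10)

with ``c_hb_molar`` the molar hemoglobin concentration of whole blood, and the
reduced scattering follows the soft-tissue power law

    mu_s' = a_mie * (lambda / 500 nm)^(-b),      mu_s = mu_s' / (1 - g).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HB_MOLAR_MASS_G_PER_MOL",
    "ChromophoreTable",
    "LayerProperties",
    "TissueSample",
    "ParameterRanges",
    "OpticalProperties",
    "load_extinction_table",
    "load_parameter_ranges",
    "absorption_coefficient",
    "reduced_scattering",
    "scattering_coefficient",
    "to_optical_properties",
    "sample_tissue",
    "samples_to_frame",
    "frame_to_samples",
]

#: Molar mass of the hemoglobin tetramer, g/mol, used to convert the mass
#: concentration of hemoglobin in whole blood (g/L) to molarity.
HB_MOLAR_MASS_G_PER_MOL = 64500.0


class RangeError(ValueError):
    """A wavelength query fell outside the tabulated extinction grid."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated molar extinction of oxy- and deoxy-hemoglobin.

    Parameters
    ----------
    wavelength_nm
        Strictly increasing wavelength grid covering at least 450-720 nm.
    eps_hbo2, eps_hb
        Molar extinction coefficients (L mol^-1 cm^-1) of HbO2 and Hb.
    c_hb_gram_per_liter
        Mass concentration of hemoglobin in whole blood. 120 g/L is typical
        for the colon (150 g/L for general human tissue).
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    c_hb_gram_per_liter: float = 120.0
    hb_molar_mass_gram_per_mol: float = HB_MOLAR_MASS_G_PER_MOL

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelength_nm, dtype=float)
        o = np.asarray(self.eps_hbo2, dtype=float)
        d = np.asarray(self.eps_hb, dtype=float)
        if lam.ndim != 1 or lam.size < 2 or not (np.diff(lam) > 0).all():
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if o.shape != lam.shape or d.shape != lam.shape:
            raise ValueError("extinction columns must match the wavelength grid")
        if (o <= 0).any() or (d <= 0).any():
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelength_nm", lam)
        object.__setattr__(self, "eps_hbo2", o)
        object.__setattr__(self, "eps_hb", d)

    @property
    def c_hb_molar(self) -> float:
        """Molar hemoglobin concentration of whole blood, mol/L."""
        return self.c_hb_gram_per_liter / self.hb_molar_mass_gram_per_mol

    def _check_range(self, lambda_nm) -> np.ndarray:
        lam = np.asarray(lambda_nm, dtype=float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if (lam < lo).any() or (lam > hi).any():
            raise RangeError(
                f"wavelength query outside tabulated range [{lo}, {hi}] nm"
            )
        return lam

    def extinction(self, lambda_nm):
        """Linearly interpolated (eps_hbo2, eps_hb) at the query wavelengths."""
        lam = self._check_range(lambda_nm)
        o = np.interp(lam, self.wavelength_nm, self.eps_hbo2)
        d = np.interp(lam, self.wavelength_nm, self.eps_hb)
        return o, d

    def with_concentration(self, c_hb_gram_per_liter: float) -> "ChromophoreTable":
        return ChromophoreTable(
            self.wavelength_nm, self.eps_hbo2, self.eps_hb,
            c_hb_gram_per_liter, self.hb_molar_mass_gram_per_mol,
        )


def load_extinction_table(path: str | Path | None = None, *,
                          c_hb_gram_per_liter: float = 120.0) -> ChromophoreTable:
    """Load a hemoglobin extinction CSV (wavelength_nm, eps_hbo2, eps_hb).

    With no path, the bundled synthetic reconstruction of the standard
    compiled Hb/HbO2 spectra is used (see its header for provenance).
    """
    if path is None:
        path = resources.files("mcti.data") / "hb_extinction_synthetic.csv"
    df = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "eps_hbo2", "eps_hb"}
    if not required.issubset(df.columns):
        raise ValueError(f"extinction CSV must have columns {sorted(required)}")
    return ChromophoreTable(
        df["wavelength_nm"].to_numpy(float),
        df["eps_hbo2"].to_numpy(float),
        df["eps_hb"].to_numpy(float),
        c_hb_gram_per_liter=c_hb_gram_per_liter,
    )


@dataclass(frozen=True)
class LayerProperties:
    """Physiological and optical parameters of one tissue layer."""

    v_hb: float      # blood volume fraction, [0, 1]
    s: float         # oxygenation, [0, 1]
    a_mie: float     # scattering amplitude at 500 nm, cm^-1
    b: float         # scattering power
    g: float         # anisotropy, [0, 1)
    n_refr: float    # refractive index
    d: float         # thickness, micrometers

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_hb <= 1.0:
            raise ValueError(f"v_hb must be in [0, 1], got {self.v_hb}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.a_mie <= 0:
            raise ValueError("a_mie must be positive")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.n_refr < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.d <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class TissueSample:
    """Ordered layer stack, top (illuminated) layer first.

    All layers must share one oxygenation value.
    """

    layers: tuple[LayerProperties, ...]

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if len(layers) < 1:
            raise ValueError("a tissue sample needs at least one layer")
        s0 = layers[0].s
        if any(abs(l.s - s0) > 1e-12 for l in layers):
            raise ValueError("oxygenation must be shared by all layers")
        object.__setattr__(self, "layers", layers)

    @property
    def s(self) -> float:
        return self.layers[0].s

    @property
    def v_hb(self) -> float:
        """Blood volume fraction of the first (top) layer, the regression target."""
        return self.layers[0].v_hb


@dataclass(frozen=True)
class OpticalProperties:
    """Wavelength-resolved transport coefficients of one layer (cm units)."""

    mu_a: float      # absorption coefficient, cm^-1
    mu_s: float      # scattering coefficient, cm^-1
    g: float
    n_refr: float
    d: float         # thickness, cm

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("transport coefficients must be non-negative")


def absorption_coefficient(v_hb: float, s: float, lambda_nm,
                           table: ChromophoreTable):
    """Hemoglobin absorption coefficient mu_a in cm^-1.

    Linear in ``v_hb`` and affine in ``s``; ln(10) converts the decadic
    extinction coefficients to a natural-log transport coefficient.
    """
    if not 0.0 <= v_hb <= 1.0 or not 0.0 <= s <= 1.0:
        raise ValueError("v_hb and s must be fractions in [0, 1]")
    eps_o, eps_d = table.extinction(lambda_nm)
    return v_hb * table.c_hb_molar * (s * eps_o + (1.0 - s) * eps_d) * math.log(10.0)


def reduced_scattering(a_mie: float, b: float, lambda_nm):
    """Reduced scattering coefficient mu_s' = a_mie * (lambda/500nm)^-b, cm^-1."""
    if a_mie <= 0:
        raise ValueError("a_mie must be positive")
    lam = np.asarray(lambda_nm, dtype=float)
    out = a_mie * (lam / 500.0) ** (-b)
    return float(out) if out.ndim == 0 else out


def scattering_coefficient(mu_s_prime, g: float):
    """mu_s = mu_s' / (1 - g); anisotropy is wavelength-independent here."""
    if not 0.0 <= g < 1.0:
        raise ValueError("anisotropy g must be in [0, 1)")
    return mu_s_prime / (1.0 - g)


def to_optical_properties(layer: LayerProperties, lambda_nm: float,
                          table: ChromophoreTable) -> OpticalProperties:
    """Convert one layer's tissue parameters to transport coefficients at lambda."""
    mu_a = float(absorption_coefficient(layer.v_hb, layer.s, lambda_nm, table))
    mu_sp = reduced_scattering(layer.a_mie, layer.b, lambda_nm)
    mu_s = scattering_coefficient(mu_sp, layer.g)
    return OpticalProperties(mu_a=mu_a, mu_s=float(mu_s), g=layer.g,
                             n_refr=layer.n_refr, d=layer.d * 1e-4)


# ---------------------------------------------------------------------------
# Parameter ranges and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Range:
    lo: float
    hi: float
    distribution: str = "uniform"   # "uniform" or "truncnorm"
    mean: float | None = None       # truncnorm only
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"range min {self.lo} exceeds max {self.hi}")

    @property
    def fixed(self) -> bool:
        return self.lo == self.hi

    def draw(self, rng: np.random.Generator, size=None):
        if self.fixed:
            return np.full(size, self.lo) if size is not None else self.lo
        if self.distribution == "truncnorm":
            # rejection sampling; ranges here are ~1 sd wide so this is cheap
            out = rng.normal(self.mean, self.sd, size=size)
            bad = (out < self.lo) | (out > self.hi)
            while np.any(bad):
                out = np.where(bad, rng.normal(self.mean, self.sd, size=size), out)
                bad = (out < self.lo) | (out > self.hi)
            return out
        return rng.uniform(self.lo, self.hi, size=size)


_PARAM_NAMES = ("v_hb", "s", "a_mie", "b", "g", "n_refr", "d")


@dataclass(frozen=True)
class ParameterRanges:
    """Per-layer sampling ranges for a tissue model.

    ``layers`` maps each of v_hb, s, a_mie, b, g, n_refr, d to a ``_Range``;
    fixed values are ranges with lo == hi. ``total_thickness_um_max``, if set,
    rescales all layer thicknesses of a drawn sample so they total at most
    that depth.
    """

    name: str
    layers: tuple[dict, ...]
    c_hb_gram_per_liter: float = 120.0
    total_thickness_um_max: float | None = None
    a_mie_distribution: str = "uniform"

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _parse_entry(value, name: str, distribution: str = "uniform") -> _Range:
    if isinstance(value, dict):
        mean, hw = float(value["mean"]), float(value["halfwidth"])
        if distribution == "truncnorm":
            return _Range(mean - hw, mean + hw, "truncnorm", mean=mean, sd=hw)
        return _Range(mean - hw, mean + hw)
    if isinstance(value, (list, tuple)):
        lo, hi = float(value[0]), float(value[1])
        return _Range(lo, hi)
    v = float(value)
    return _Range(v, v)


def load_parameter_ranges(source: str | Path = "colon", *,
                          a_mie_distribution: str = "uniform") -> ParameterRanges:
    """Load tissue-model ranges from YAML.

    ``source`` may be ``"colon"`` or ``"generic"`` (bundled models) or a path.
    ``a_mie_distribution`` switches the scattering-amplitude draw between a
    uniform range over mean +/- halfwidth (default) and a truncated normal.
    """
    if source in ("colon", "generic"):
        path = resources.files("mcti.data") / f"{source}_model.yaml"
        raw = yaml.safe_load(path.read_text())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    if not raw.get("layers"):
        raise ValueError("model config has no layers")
    layers = []
    for spec in raw["layers"]:
        entry = {}
        for p in _PARAM_NAMES:
            dist = a_mie_distribution if p == "a_mie" else "uniform"
            entry[p] = _parse_entry(spec[p], p, dist)
        layers.append(entry)
    return ParameterRanges(
        name=raw.get("name", "custom"),
        layers=tuple(layers),
        c_hb_gram_per_liter=float(raw.get("c_hb_gram_per_liter", 120.0)),
        total_thickness_um_max=raw.get("total_thickness_um_max"),
        a_mie_distribution=a_mie_distribution,
    )


def ranges_to_dict(ranges: ParameterRanges) -> dict:
    """Serializable representation mirroring the YAML schema."""
    layers = []
    for layer in ranges.layers:
        out = {}
        for p, r in layer.items():
            out[p] = r.lo if r.fixed else [r.lo, r.hi]
        layers.append(out)
    return {
        "name": ranges.name,
        "c_hb_gram_per_liter": ranges.c_hb_gram_per_liter,
        "shared_oxygenation": True,
        "total_thickness_um_max": ranges.total_thickness_um_max,
        "layers": layers,
    }


_MIN_THICKNESS_UM = 1.0  # keep degenerate zero-thickness draws well-posed


def sample_tissue(ranges: ParameterRanges, n_samples: int,
                  seed: int | np.random.Generator) -> list[TissueSample]:
    """Draw tissue samples uniformly from the model's parameter ranges.

    Every per-layer parameter is drawn independently across layers, except
    the oxygenation ``s``, which is drawn once per sample and shared.
    Deterministic for a given integer seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    s_shared = ranges.layers[0]["s"].draw(rng, n_samples)
    draws = []   # per layer: dict of param -> array
    for layer in ranges.layers:
        draws.append({p: layer[p].draw(rng, n_samples)
                      for p in _PARAM_NAMES if p != "s"})
    samples: list[TissueSample] = []
    for i in range(n_samples):
        d_total = sum(ld["d"][i] for ld in draws)
        scale = 1.0
        if ranges.total_thickness_um_max and d_total > ranges.total_thickness_um_max:
            scale = ranges.total_thickness_um_max / d_total
        layers = []
        for ld in draws:
            layers.append(LayerProperties(
                v_hb=float(ld["v_hb"][i]), s=float(s_shared[i]),
                a_mie=float(ld["a_mie"][i]), b=float(ld["b"][i]),
                g=float(ld["g"][i]), n_refr=float(ld["n_refr"][i]),
                d=max(float(ld["d"][i]) * scale, _MIN_THICKNESS_UM),
            ))
        samples.append(TissueSample(tuple(layers)))
    return samples


def samples_to_frame(samples: Sequence[TissueSample]) -> pd.DataFrame:
    """One row per sample, columns layer{i}_{param} plus the shared s."""
    rows = []
    for smp in samples:
        row = {"s": smp.s}
        for i, layer in enumerate(smp.layers, start=1):
            for p in _PARAM_NAMES:
                if p == "s":
                    continue
                row[f"layer{i}_{p}"] = getattr(layer, p)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[TissueSample]:
    """Inverse of :func:`samples_to_frame`."""
    n_layers = max(int(c.split("_")[0][5:]) for c in df.columns
                   if c.startswith("layer"))
    samples = []
    for _, row in df.iterrows():
        layers = []
        for i in range(1, n_layers + 1):
            kw = {p: float(row[f"layer{i}_{p}"]) for p in _PARAM_NAMES if p != "s"}
            layers.append(LayerProperties(s=float(row["s"]), **kw))
        samples.append(TissueSample(tuple(layers)))
    return samples
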
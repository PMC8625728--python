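"""Model configuration: parameter containers, unit conversion, packaged fixtures.

All internal computation is in SI units (metres, seconds).  Config files use
unit-suffixed key names (``Rr_um``, ``rs_nm``, ``delta_t_ms`` ...) which are
converted on load; this keeps every unit explicit and auditable, since the
hitting-fraction exponentials mix metre and inverse-metre scales and silent
unit mix-ups are the dominant bug risk in this kind of model.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23


class ConfigError(ValueError):
    """Raised for invalid, inconsistent or unknown configuration input."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


# ---------------------------------------------------------------------------
# Parameter containers (SI units)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumParams:
    """Diffusive propagation medium.

    Either the diffusion coefficient ``D`` is given directly, or it is derived
    from temperature ``T`` (K), viscosity ``eta`` (Pa*s) and molecule radius
    ``rm`` (m) via the Stokes-Einstein relation D = kB*T / (6*pi*eta*rm).
    """

    D: float | None = None
    T: float | None = None
    eta: float | None = None
    rm: float | None = None

    def __post_init__(self) -> None:
        if self.D is None:
            ingredients = (self.T, self.eta, self.rm)
            _require(all(v is not None for v in ingredients), "medium",
                     "either D_m2s or all of (T_K, eta_Pas, rm_nm) must be given")
            from .diffusion import stokes_einstein_D  # local import: no cycle at call time
            object.__setattr__(self, "D", stokes_einstein_D(self.T, self.eta, self.rm))
        _require(self.D > 0 and math.isfinite(self.D), "medium.D_m2s",
                 f"diffusion coefficient must be positive and finite, got {self.D}")


@dataclass(frozen=True)
class GeometryParams:
    """Receiver geometry: sphere of radius ``Rr`` carrying ``n`` circular
    receptors of radius ``rs``, at centre distance ``d`` from the point
    transmitter."""

    Rr: float
    rs: float
    n: int
    d: float

    def __post_init__(self) -> None:
        _require(self.Rr > 0, "geometry.Rr_um", "receiver radius must be > 0")
        _require(self.rs > 0, "geometry.rs_nm", "receptor radius must be > 0")
        _require(int(self.n) == self.n and self.n >= 1, "geometry.n",
                 f"receptor count must be a positive integer, got {self.n}")
        _require(self.d > self.Rr, "geometry.d_um",
                 f"TX-RX distance d={self.d} must exceed receiver radius Rr={self.Rr}")
        if self.n * math.pi * self.rs**2 > 4 * math.pi * self.Rr**2:
            warnings.warn(
                f"total receptor area (n*pi*rs^2 = {self.n * math.pi * self.rs**2:.3e} m^2) "
                f"exceeds the receiver surface (4*pi*Rr^2 = {4 * math.pi * self.Rr**2:.3e} m^2)",
                UserWarning, stacklevel=2)


@dataclass(frozen=True)
class EmissionSchedule:
    """Pulsed emission: ``Q`` molecules every ``delta_t`` seconds up to
    horizon ``t_end``; the net release rate is ``Q / delta_t``."""

    Q: int
    delta_t: float
    t_end: float

    def __post_init__(self) -> None:
        _require(self.Q >= 1, "emission.Q", f"pulse size must be >= 1, got {self.Q}")
        _require(self.delta_t > 0, "emission.delta_t_ms", "pulse period must be > 0")
        _require(self.t_end >= self.delta_t, "emission.t_end_s",
                 "horizon must cover at least one pulse period")

    @property
    def rate(self) -> float:
        """Net emission rate Q/delta_t, molecules/s."""
        return self.Q / self.delta_t


@dataclass(frozen=True)
class ReceptorKinetics:
    """Receptor service: trafficking (internalisation) is exponential with
    mean 1/mu, during which the receptor cannot bind again."""

    mu: float

    def __post_init__(self) -> None:
        _require(self.mu > 0 and math.isfinite(self.mu), "kinetics.mu_per_s",
                 f"trafficking rate must be positive and finite, got {self.mu}")


@dataclass(frozen=True)
class NumericsParams:
    """Numerical controls.

    ``dt_particle`` is the particle-simulation time step entering the bounce
    distance d*; it is a model parameter even though the closed forms have no
    particle step.  ``grid_dt`` is the rate-evaluation grid spacing.
    """

    dt_particle: float = 1e-7
    grid_dt: float = 0.01
    integrator: str = "trapezoid"

    def __post_init__(self) -> None:
        _require(self.dt_particle > 0, "numerics.dt_particle_ns", "must be > 0")
        _require(self.grid_dt > 0, "numerics.grid_dt_ms", "must be > 0")
        _require(self.integrator == "trapezoid", "numerics.integrator",
                 f"only 'trapezoid' is supported, got {self.integrator!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Full model configuration (all fields in SI units)."""

    geometry: GeometryParams
    medium: MediumParams
    emission: EmissionSchedule
    kinetics: ReceptorKinetics
    numerics: NumericsParams = field(default_factory=NumericsParams)
    label: str = ""

    def __post_init__(self) -> None:
        _require(self.numerics.grid_dt <= self.emission.delta_t + 1e-15,
                 "numerics.grid_dt_ms",
                 f"rate grid spacing {self.numerics.grid_dt} must not exceed "
                 f"the pulse period {self.emission.delta_t}")


# ---------------------------------------------------------------------------
# Unit-suffixed key schema
# ---------------------------------------------------------------------------

# section -> config key -> (dataclass field, scale to SI)
_SCHEMA: dict[str, dict[str, tuple[str, float]]] = {
    "geometry": {
        "Rr_um": ("Rr", 1e-6), "Rr_m": ("Rr", 1.0),
        "rs_nm": ("rs", 1e-9), "rs_m": ("rs", 1.0),
        "n": ("n", 1.0),
        "d_um": ("d", 1e-6), "d_m": ("d", 1.0),
    },
    "medium": {
        "D_m2s": ("D", 1.0),
        "T_K": ("T", 1.0),
        "eta_Pas": ("eta", 1.0),
        "rm_nm": ("rm", 1e-9), "rm_m": ("rm", 1.0),
    },
    "emission": {
        "Q": ("Q", 1.0),
        "delta_t_ms": ("delta_t", 1e-3), "delta_t_s": ("delta_t", 1.0),
        "t_end_s": ("t_end", 1.0),
    },
    "kinetics": {
        "mu_per_s": ("mu", 1.0),
        "trafficking_time_s": ("mu", -1.0),  # sentinel: reciprocal, see below
    },
    "numerics": {
        "dt_particle_ns": ("dt_particle", 1e-9), "dt_particle_s": ("dt_particle", 1.0),
        "grid_dt_ms": ("grid_dt", 1e-3), "grid_dt_s": ("grid_dt", 1.0),
        "integrator": ("integrator", 1.0),
    },
}

_SECTION_TYPES = {
    "geometry": GeometryParams,
    "medium": MediumParams,
    "emission": EmissionSchedule,
    "kinetics": ReceptorKinetics,
    "numerics": NumericsParams,
}

#: fixture used to fill unspecified sections/fields.
DEFAULT_FIXTURE = "table1_q50_mu4"


def _parse_section(section: str, raw: Mapping[str, Any]) -> dict[str, Any]:
    schema = _SCHEMA[section]
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in schema:
            raise ConfigError(f"{section}.{key}: unknown configuration key "
                              f"(known: {', '.join(sorted(schema))})")
        fld, scale = schema[key]
        if fld in out:
            raise ConfigError(f"{section}.{key}: field {fld!r} already set by "
                              f"another unit variant of the same key")
        if key == "integrator":
            out[fld] = str(value)
        elif key == "n" or key == "Q":
            _require(float(value) == int(value), f"{section}.{key}",
                     f"must be an integer count, got {value}")
            out[fld] = int(value)
        elif key == "trafficking_time_s":
            _require(float(value) > 0, f"{section}.{key}", "must be > 0")
            out[fld] = 1.0 / float(value)
        else:
            out[fld] = float(value) * scale
    return out


def config_from_dict(data: Mapping[str, Any], *, fill_defaults: bool = True) -> ModelConfig:
    """Build a :class:`ModelConfig` from a unit-suffixed nested mapping.

    Unspecified sections or fields are filled from the packaged Table-1
    fixture (``table1_q50_mu4``) when ``fill_defaults`` is true.
    """
    if not isinstance(data, Mapping):
        raise ConfigError(f"top level must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_SECTION_TYPES) - {"label"}
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {', '.join(sorted(unknown))}")

    base: dict[str, dict[str, Any]] = {}
    if fill_defaults:
        base = {s: _parse_section(s, v) for s, v in _fixture_dict(DEFAULT_FIXTURE).items()
                if s in _SECTION_TYPES}

    sections: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        raw = data.get(section, {})
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{section}: must be a mapping of keys to values")
        parsed = _parse_section(section, raw)
        if section == "medium" and ("D" in parsed or not fill_defaults):
            merged = parsed  # explicit D (or strict mode) overrides fixture ingredients
        else:
            merged = {**base.get(section, {}), **parsed}
        try:
            sections[section] = cls(**merged)
        except TypeError as exc:  # missing mandatory field
            raise ConfigError(f"{section}: missing mandatory value(s) ({exc})") from exc
    return ModelConfig(label=str(data.get("label", "")), **sections)


def load_config(source: str | Path) -> ModelConfig:
    """Load a configuration from a YAML/JSON file or a packaged fixture name.

    ``source`` may be a filesystem path or the bare name of a packaged
    fixture (see :func:`list_fixtures`).
    """
    path = Path(source)
    if not path.exists() and isinstance(source, str) and source in list_fixtures():
        return config_from_dict(_fixture_dict(source))
    if not path.exists():
        raise ConfigError(f"config file not found: {source}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def config_to_dict(cfg: ModelConfig) -> dict[str, Any]:
    """Serialise a config back to the unit-suffixed mapping (round-trips
    through :func:`config_from_dict` to machine precision)."""
    g, m, e, k, u = cfg.geometry, cfg.medium, cfg.emission, cfg.kinetics, cfg.numerics
    out: dict[str, Any] = {
        "label": cfg.label,
        "geometry": {"Rr_um": g.Rr / 1e-6, "rs_nm": g.rs / 1e-9, "n": g.n, "d_um": g.d / 1e-6},
        "medium": {"D_m2s": m.D},
        "emission": {"Q": e.Q, "delta_t_ms": e.delta_t / 1e-3, "t_end_s": e.t_end},
        "kinetics": {"mu_per_s": k.mu},
        "numerics": {"dt_particle_ns": u.dt_particle / 1e-9,
                     "grid_dt_ms": u.grid_dt / 1e-3,
                     "integrator": u.integrator},
    }
    return out


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML with unit-suffixed keys."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_root():
    return resources.files("receptorq") / "fixtures"


def list_fixtures() -> list[str]:
    """Names of the packaged parameter fixtures."""
    return sorted(p.name[:-5] for p in _fixture_root().iterdir() if p.name.endswith(".yaml"))


def _fixture_dict(name: str) -> dict[str, Any]:
    f = _fixture_root() / f"{name}.yaml"
    try:
        text = f.read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown fixture {name!r} (known: {', '.join(list_fixtures())})") from exc
    return yaml.safe_load(text)


def load_fixture(name: str = DEFAULT_FIXTURE) -> ModelConfig:
    """Load one of the packaged parameter sets by name."""
    return config_from_dict(_fixture_dict(name))
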
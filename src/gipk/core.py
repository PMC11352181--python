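"""Domain types, physiological defaults, drug fixtures, and series I/O.

Unit conventions used throughout the package
--------------------------------------------
mass        mg
volume      L          (bolus volumes converted to m^3 where geometry needs it)
length      m
time        s
concentration  mg/L
solubility  mol/L in fixtures, converted to mg/L via ``molar_mass`` at load
density     g/mL as tabulated
lambda_j / lambda_ic   tabulated scale, i.e. a stored value of 5.157 means
                       5.157e-3 in the axial permeability profile
kd          1/s (absolute)
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DrugProperties",
    "PhysiologyParams",
    "AbsorptionParams",
    "ConcentrationSeries",
    "load_drug_fixture",
    "load_drug_file",
    "load_physiology_file",
    "default_physiology",
    "available_drugs",
    "read_series_csv",
    "write_series_csv",
]

# scale factor between the tabulated lambda values and the absolute
# Cauchy scale entering the permeability profile
LAMBDA_SCALE = 1.0e-3


@dataclass
class DrugProperties:
    """Physicochemical constants of one drug.

    ``S0`` is the intrinsic (un-ionized) aqueous solubility in mol/L, ``D``
    the diffusion coefficient in gastric fluid in m^2/s, ``rho`` the solid
    density in g/mL, ``pKa`` the acid dissociation constant and ``dose`` the
    administered mass in mg (may be left unset until a simulation supplies
    it). ``molar_mass`` (g/mol) converts between mol/L and mg/L.
    """

    name: str
    S0: float
    D: float
    rho: float
    pKa: float
    molar_mass: float
    dose: float | None = None

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not -2.0 < self.pKa < 20.0:
            raise ValueError(f"pKa must lie in (-2, 20), got {self.pKa}")
        if self.dose is not None and not self.dose > 0:
            raise ValueError(f"dose must be > 0, got {self.dose}")

    @property
    def S0_mg_per_L(self) -> float:
        """Intrinsic solubility converted to mg/L."""
        return self.S0 * self.molar_mass * 1000.0

    def with_dose(self, dose_mg: float) -> "DrugProperties":
        return replace(self, dose=float(dose_mg))


@dataclass
class PhysiologyParams:
    """Anatomical and transit constants of the fasted adult GI tract.

    Defaults are the reference physiology: gastric emptying every
    ``Te`` = 600 s discharging ``emptying_fraction`` = 1/20 of the stomach
    volume, bolus velocity ``u`` = 1 m/h, countercurrent blood velocity
    ``vb`` = 0.21 m/s, splanchnic flow ``Qb`` = 0.033 L/s, peripheral
    volume ``Vb`` = 4 L with circulation delay ``delta`` = 90 s, and
    segment lengths Lj = 2 m, Li = 4 m, Lc = 1.5 m with radius 0.01 m.

    ``Qgj``/``Qpj`` (gastric/pancreatic juice secretion, L/s) and
    ``gastric_pH`` are not part of the tabulated set; defaults correspond
    to ~2 L/day, ~1 L/day and fasted-stomach pH 2.
    """

    delta: float = 90.0
    Te: float = 600.0
    emptying_fraction: float = 1.0 / 20.0
    vb: float = 0.21
    u: float = 1.0 / 3600.0
    Qb: float = 0.033
    Lj: float = 2.0
    Li: float = 4.0
    Lc: float = 1.5
    Vb: float = 4.0
    rint: float = 0.01
    gastric_pH: float = 2.0
    Qgj: float = 2.3e-5
    Qpj: float = 1.2e-5
    V_stop_frac: float = 0.01

    def __post_init__(self) -> None:
        for name in ("Te", "vb", "u", "Qb", "Lj", "Li", "Lc", "Vb", "rint"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        # delta = 0 disables the circulation delay (used by reduced-model checks)
        for name in ("Qgj", "Qpj", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 < self.emptying_fraction < 1:
            raise ValueError("emptying_fraction must lie in (0, 1)")
        if not 0 < self.V_stop_frac < 1:
            raise ValueError("V_stop_frac must lie in (0, 1)")

    @property
    def fe(self) -> float:
        """Gastric emptying frequency, Hz (reciprocal of ``Te``)."""
        return 1.0 / self.Te

    @property
    def L_ic(self) -> float:
        """Combined ileum-colon length, m."""
        return self.Li + self.Lc

    @property
    def L_total(self) -> float:
        """Total modeled intestinal length (jejunum inlet to colon end), m."""
        return self.Lj + self.Li + self.Lc


@dataclass
class AbsorptionParams:
    """The three estimated parameters plus the permeability peak locations.

    ``lambda_j`` and ``lambda_ic`` are the Cauchy scales of the axial
    permeability profiles, stored on the tabulated 1e-3 scale (a value of
    5.157 corresponds to an absolute scale of 5.157e-3). ``kd`` is the
    first-order peripheral elimination constant in 1/s. Peak locations
    default to Lj/3 (jejunum, global coordinate) and (Lj+Li+Lc)/5 measured
    from the ileum inlet; pass ``None`` to use those defaults.
    """

    lambda_j: float
    lambda_ic: float
    kd: float
    Ltilde_j: float | None = None
    Ltilde_ic: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_j < 0 or self.lambda_ic < 0 or self.kd < 0:
            raise ValueError("lambda_j, lambda_ic and kd must be >= 0")

    def peak_locations(self, phys: PhysiologyParams) -> tuple[float, float]:
        """Resolve (Ltilde_j, Ltilde_ic), validating them against geometry."""
        ltj = self.Ltilde_j if self.Ltilde_j is not None else phys.Lj / 3.0
        ltic = self.Ltilde_ic if self.Ltilde_ic is not None else phys.L_total / 5.0
        if not 0.0 <= ltj <= phys.Lj:
            raise ValueError(f"Ltilde_j={ltj} outside [0, Lj={phys.Lj}]")
        if not 0.0 <= ltic <= phys.L_ic:
            raise ValueError(f"Ltilde_ic={ltic} outside [0, Li+Lc={phys.L_ic}]")
        return ltj, ltic


@dataclass
class ConcentrationSeries:
    """Sampled drug concentration vs time.

    ``times`` in seconds, strictly increasing; ``values`` nonnegative in
    ``unit`` (mg/L, ng/mL, or "1" once normalized by the series maximum).
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "mg/L"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size or self.times.size < 1:
            raise ValueError("times and values must have equal length >= 1")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return int(self.times.size)

    def normalize(self) -> "ConcentrationSeries":
        """Divide by the series maximum (error if identically zero)."""
        vmax = float(self.values.max())
        if vmax <= 0:
            raise ValueError("cannot normalize an all-zero series")
        return ConcentrationSeries(
            self.times.copy(), self.values / vmax, unit="1", normalized=True
        )

    @property
    def cmax(self) -> float:
        return float(self.values.max())

    @property
    def tmax(self) -> float:
        return float(self.times[int(np.argmax(self.values))])


def default_physiology() -> PhysiologyParams:
    """Reference fasted-state physiology (see :class:`PhysiologyParams`)."""
    return PhysiologyParams()


# ---------------------------------------------------------------------------
# fixtures and config files

_DRUG_ALIASES = {"ketoconazole": "ketokenazole"}


def _fixture_dir():
    return resources.files("gipk.data") / "drugs"


def available_drugs() -> list[str]:
    """Names of the packaged drug fixtures."""
    names = []
    for entry in _fixture_dir().iterdir():
        if entry.name.endswith(".toml"):
            with entry.open("rb") as fh:
                names.append(tomllib.load(fh)["name"])
    return sorted(names)


def _drug_from_mapping(data: dict, source: str) -> DrugProperties:
    required = {"name", "S0", "D", "rho", "pKa", "molar_mass"}
    missing = required - data.keys()
    if missing:
        raise ValueError(f"{source}: missing drug fields {sorted(missing)}")
    return DrugProperties(
        name=str(data["name"]),
        S0=float(data["S0"]),
        D=float(data["D"]),
        rho=float(data["rho"]),
        pKa=float(data["pKa"]),
        molar_mass=float(data["molar_mass"]),
        dose=float(data["dose"]) if data.get("dose") is not None else None,
    )


def load_drug_fixture(name: str) -> DrugProperties:
    """Load one of the packaged drug records by name (case-insensitive).

    The dose is left unset; supply it with :meth:`DrugProperties.with_dose`
    or the simulation configuration.
    """
    key = name.strip().lower()
    key = _DRUG_ALIASES.get(key, key)
    entry = _fixture_dir() / f"{key}.toml"
    if not entry.is_file():
        raise KeyError(
            f"unknown drug fixture {name!r}; available: {', '.join(available_drugs())}"
        )
    with entry.open("rb") as fh:
        return _drug_from_mapping(tomllib.load(fh), source=name)


def load_drug_file(path: str | Path) -> DrugProperties:
    """Load a drug record from a user TOML file (same keys as the fixtures)."""
    with open(path, "rb") as fh:
        return _drug_from_mapping(tomllib.load(fh), source=str(path))


def load_physiology_file(path: str | Path) -> PhysiologyParams:
    """Load physiology overrides from TOML; unspecified keys keep defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    valid = set(PhysiologyParams.__dataclass_fields__)
    unknown = data.keys() - valid
    if unknown:
        raise ValueError(f"{path}: unknown physiology keys {sorted(unknown)}")
    return PhysiologyParams(**{k: float(v) for k, v in data.items()})


# ---------------------------------------------------------------------------
# concentration-series CSV I/O

_CSV_COLUMNS = ["time_s", "concentration", "unit"]


def read_series_csv(path: str | Path) -> ConcentrationSeries:
    """Read a concentration series from CSV with columns time_s, concentration, unit.

    Rows are sorted ascending by time; duplicate times and negative
    concentrations are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.sort_values("time_s", kind="stable")
    times = df["time_s"].to_numpy(dtype=float)
    values = df["concentration"].to_numpy(dtype=float)
    if np.any(np.diff(times) == 0):
        raise ValueError(f"{path}: duplicate sample times")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative concentrations")
    if "unit" in df.columns:
        units = df["unit"].astype(str).unique()
        if len(units) > 1:
            raise ValueError(f"{path}: mixed units {list(units)}")
        unit = str(units[0])
    else:
        unit = "mg/L"
    return ConcentrationSeries(times, values, unit=unit, normalized=(unit == "1"))


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    """Write a series to CSV, preserving full double precision."""
    df = pd.DataFrame(
        {
            "time_s": series.times,
            "concentration": series.values,
            "unit": series.unit,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
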
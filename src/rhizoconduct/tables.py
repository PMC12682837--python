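"""Packaged architectural parameter tables and configuration plumbing.

The package ships the measured maize (B73) architecture parameters as three
plain-text CSVs, one block each for root-system scheduling (seminal/crown
emergence, seed position), per-root-type organ parameters and shoot organ
parameters.  Every numeric parameter is a (mean, s.d.) pair; the four soil-P
treatments are labelled P0 (severe deficiency, 1.8 mg P per 100 g soil) to
P3 (sufficient, 7.7 mg P per 100 g soil).  A fifth "general" column holds
the across-treatment base set used by the P-response pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["ParameterTable", "load_parameter_table", "load_config", "RunConfig",
           "TREATMENTS", "SOIL_P_LEVELS", "data_path"]

TREATMENTS = ("P0", "P1", "P2", "P3")

#: Plant-available soil P (mg per 100 g soil, CAL extraction) per treatment.
SOIL_P_LEVELS = {"P0": 1.8, "P1": 3.3, "P2": 4.6, "P3": 7.7}

ROOT_TYPES = ("primary", "seminal", "crown", "l-lateral", "s-lateral")


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(resources.files("rhizoconduct.data") / name)


@dataclass
class ParameterTable:
    """All (mean, s.d.) architecture parameters for one treatment."""

    treatment: str
    root_system: dict = field(default_factory=dict)  # name -> float
    root_types: dict = field(default_factory=dict)  # type -> param -> (mean, sd)
    shoot: dict = field(default_factory=dict)  # organ -> param -> (mean, sd)

    def get(self, organ: str, param: str) -> tuple[float, float]:
        """(mean, s.d.) for ``param`` of ``organ``; root-system scalars have s.d. 0."""
        if organ == "root-system":
            if param not in self.root_system:
                raise KeyError(f"root-system parameter {param!r} missing "
                               f"for treatment {self.treatment}")
            return (self.root_system[param], 0.0)
        pool = self.root_types if organ in self.root_types else self.shoot
        if organ not in pool or param not in pool[organ]:
            raise KeyError(f"parameter {param!r} for organ {organ!r} missing "
                           f"for treatment {self.treatment}")
        return pool[organ][param]

    def copy(self) -> "ParameterTable":
        return replace(
            self,
            root_system=dict(self.root_system),
            root_types={k: dict(v) for k, v in self.root_types.items()},
            shoot={k: dict(v) for k, v in self.shoot.items()},
        )

    def validate(self) -> None:
        for organ, params in list(self.root_types.items()) + list(self.shoot.items()):
            for name, (mean, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{organ}/{name}: s.d. must be >= 0")
                if name in ("a", "l_b", "l_n", "r", "l_max") and mean < 0:
                    raise ValueError(f"{organ}/{name}: mean must be >= 0")


def _read_csv(name: str) -> pd.DataFrame:
    return pd.read_csv(data_path(name), comment="#")


def load_parameter_table(treatment: str, data_dir=None) -> ParameterTable:
    """Load the packaged parameter tables for one treatment label.

    ``treatment`` is one of P0–P3 or ``"general"``.  For the general base
    set, per-type organ parameters come from the table's dedicated general
    column while scheduling and shoot parameters are the across-treatment
    means (the base the P-response functions act on).  ``data_dir``
    optionally points at a directory with identically named CSVs.
    """
    if treatment not in TREATMENTS + ("general",):
        raise ValueError(f"unknown treatment label {treatment!r}; "
                         f"expected one of {TREATMENTS + ('general',)}")

    def read(name):
        if data_dir is not None:
            return pd.read_csv(Path(data_dir) / name, comment="#")
        return _read_csv(name)

    rs = read("root_system_parameters.csv").set_index("parameter")
    types_df = read("root_type_parameters.csv")
    shoot_df = read("shoot_parameters.csv")

    table = ParameterTable(treatment=treatment)

    if treatment == "general":
        table.root_system = {p: float(rs.loc[p, list(TREATMENTS)].mean())
                             for p in rs.index}
    else:
        table.root_system = {p: float(rs.loc[p, treatment]) for p in rs.index}

    for _, row in types_df.iterrows():
        col = treatment
        mean, sd = float(row[f"{col}_mean"]), float(row[f"{col}_sd"])
        table.root_types.setdefault(row["type"], {})[row["parameter"]] = (mean, sd)

    for _, row in shoot_df.iterrows():
        if treatment == "general":
            mean = float(pd.to_numeric(
                row[[f"{t}_mean" for t in TREATMENTS]]).mean())
            sds = pd.to_numeric(row[[f"{t}_sd" for t in TREATMENTS]]).fillna(0.0)
            sd = float(sds.mean())
        else:
            mean = float(row[f"{treatment}_mean"])
            sd_raw = row[f"{treatment}_sd"]
            sd = 0.0 if pd.isna(sd_raw) else float(sd_raw)
        table.shoot.setdefault(row["organ"], {})[row["parameter"]] = (mean, sd)

    table.validate()
    return table


@dataclass
class RunConfig:
    """Run configuration for the simulation/ensemble pipeline."""

    treatment: str = "P3"
    days: float = 28.0
    ensemble: int = 100
    seed: int = 1
    times: tuple = (7.0, 14.0, 21.0, 28.0)
    out: str = "results"
    mode: str = "tabulated"  # or "response-driven"


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration key {key!r}")
        if key == "times":
            value = tuple(float(v) for v in value)
        setattr(cfg, key, value)
    return cfg
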
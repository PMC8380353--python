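"""YAML configuration for the synthetic-registry simulator.

A config file looks like::

    seed: 20210821
    accrual_start: 1999-01-01
    accrual_end: 2020-06-01
    extraction_date: 2020-06-01
    death_hazard: 0.025          # per year
    base_hazard: 0.004           # default revision hazard, per year
    constructs:
      - {stem: MS30, cup: Fitmore, bearing: MP, n: 4000,
         relative_risk: 1.0, reference: true, female_fraction: 0.60}
      - {stem: ExeterV40, cup: Trident, bearing: MP, n: 6000,
         relative_risk: 1.05}

or, instead of an explicit ``constructs`` list, a heavy-tailed catalogue::

    long_tail: {n_constructs: 200, singleton_fraction: 0.3, total: 8000}
"""

from __future__ import annotations

from dataclasses import replace
from datetime import date, datetime
from pathlib import Path
from typing import Any, Union

import yaml

from .registry import Bearing, Construct, HipbenchError
from .simulate import ConstructSpec, SyntheticRegistryConfig, long_tail_catalogue

__all__ = ["ConfigError", "load_simulation_config"]


class ConfigError(HipbenchError, ValueError):
    """Malformed simulation configuration file."""


def _as_date(value: Any, key: str) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        try:
            return date.fromisoformat(value)
        except ValueError:
            pass
    raise ConfigError(f"{key!r} must be an ISO-8601 date, got {value!r}")


def load_simulation_config(
    path: Union[str, Path], seed: int | None = None
) -> SyntheticRegistryConfig:
    """Load a simulation config; ``seed`` (if given) overrides the file's."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("accrual_start", "accrual_end", "extraction_date"):
        if key not in data:
            raise ConfigError(f"{path}: missing required key {key!r}")

    base_hazard = float(data.get("base_hazard", 0.004))
    file_seed = int(data.get("seed", 0))
    has_constructs = "constructs" in data
    has_long_tail = "long_tail" in data
    if has_constructs == has_long_tail:
        raise ConfigError(f"{path}: provide exactly one of 'constructs' or 'long_tail'")

    if has_constructs:
        catalogue = []
        for i, entry in enumerate(data["constructs"]):
            try:
                construct = Construct(
                    stem_brand=str(entry["stem"]),
                    cup_brand=str(entry["cup"]),
                    bearing=Bearing(entry["bearing"]),
                )
                spec = ConstructSpec(
                    construct=construct,
                    n_procedures=int(entry["n"]),
                    revision_hazard=float(entry.get("hazard", base_hazard)),
                    relative_risk=float(entry.get("relative_risk", 1.0)),
                    female_fraction=float(entry.get("female_fraction", 0.55)),
                    is_reference=bool(entry.get("reference", False)),
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"{path}: constructs[{i}]: {exc}") from exc
            catalogue.append(spec)
    else:
        lt = data["long_tail"]
        catalogue = long_tail_catalogue(
            n_constructs=int(lt["n_constructs"]),
            singleton_fraction=float(lt["singleton_fraction"]),
            seed=file_seed if seed is None else seed,
            total_procedures=int(lt.get("total", 20000)),
            base_hazard=base_hazard,
        )

    return SyntheticRegistryConfig(
        catalogue=tuple(catalogue),
        accrual_start=_as_date(data["accrual_start"], "accrual_start"),
        accrual_end=_as_date(data["accrual_end"], "accrual_end"),
        extraction_date=_as_date(data["extraction_date"], "extraction_date"),
        death_hazard=float(data.get("death_hazard", 0.0)),
        seed=file_seed if seed is None else seed,
    )
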
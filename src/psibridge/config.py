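"""Configuration files for the CLI: YAML (or INI) with the documented defaults.

Recognised keys::

    adaptor_side_len: 10        # k, adaptor-side splint half
    rna_side_len: 10            # m, RNA-side splint half
    add_3prime_spacer: true
    tm:
      method: nearest_neighbor  # or wallace
      oligo_concentration: 2.5e-7
      monovalent_salt: 0.05
      max_pair_delta: 5.0

INI files use sections ``[design]`` and ``[tm]`` with the same keys.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .bridge import DesignParams
from .seqcore import PsiBridgeError
from .thermo import TmSettings


class ConfigError(PsiBridgeError):
    """A configuration file could not be interpreted."""


@dataclass(frozen=True)
class Config:
    design: DesignParams = DesignParams()
    tm: TmSettings = TmSettings()


def load_config(path: Optional[Union[str, Path]]) -> Config:
    if path is None:
        return Config()
    path = Path(path)
    if path.suffix.lower() in (".ini", ".cfg"):
        data = _read_ini(path)
    else:
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        design = DesignParams(
            adaptor_side_len=int(data.get("adaptor_side_len", 10)),
            rna_side_len=int(data.get("rna_side_len", 10)),
            add_3prime_spacer=_as_bool(data.get("add_3prime_spacer", True)),
        )
        tm_data = data.get("tm") or {}
        tm = TmSettings(
            method=str(tm_data.get("method", "nearest_neighbor")),
            oligo_concentration=float(
                tm_data.get("oligo_concentration", 2.5e-7)
            ),
            monovalent_salt=float(tm_data.get("monovalent_salt", 0.05)),
            max_pair_delta=float(tm_data.get("max_pair_delta", 5.0)),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err
    return Config(design, tm)


def _read_ini(path: Path) -> dict:
    parser = configparser.ConfigParser()
    parser.read(path, encoding="utf-8")
    data: dict = {}
    if parser.has_section("design"):
        data.update(dict(parser.items("design")))
    if parser.has_section("tm"):
        data["tm"] = dict(parser.items("tm"))
    return data


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes", "on")
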
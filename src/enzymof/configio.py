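"""YAML configuration loading for spaces, stocks, oracles, and campaigns.

A single config file can carry any of the blocks ``space``, ``stocks``,
``oracle``, ``campaign``, and ``acquisition``; absent blocks fall back to the
package defaults. Axes accept either a ``step`` or an ``n_levels`` key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .acquisition import AcquisitionConfig
from .campaign import CampaignConfig
from .design_space import Axis, DesignGrid, StockSet, default_axes, enumerate_grid
from .errors import ConfigurationError
from .oracle import OracleConfig
from .surrogate import ModelFamily

__all__ = ["load_config", "parse_space", "parse_stocks", "parse_oracle", "parse_campaign"]


def _read(path_or_mapping: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(path_or_mapping, Mapping):
        return path_or_mapping
    with open(path_or_mapping) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config {path_or_mapping} is not a mapping")
    return data


def parse_space(block: Optional[Mapping]) -> DesignGrid:
    if not block:
        return enumerate_grid(default_axes())
    axes = []
    for spec in block["axes"]:
        name = spec["name"]
        lo, hi = float(spec["min"]), float(spec["max"])
        if "step" in spec and "n_levels" in spec:
            raise ConfigurationError(f"axis {name!r}: give step or n_levels, not both")
        if "step" in spec:
            axes.append(Axis(name, lo, hi, float(spec["step"])))
        elif "n_levels" in spec:
            axes.append(Axis.from_levels(name, lo, hi, int(spec["n_levels"])))
        else:
            raise ConfigurationError(f"axis {name!r}: needs step or n_levels")
    return enumerate_grid(axes)


def parse_stocks(block: Optional[Mapping]) -> StockSet:
    if not block:
        return StockSet()
    return StockSet(
        ca_stock=float(block.get("ca_mM", 100.0)),
        idc_stock=float(block.get("idc_mM", 125.0)),
        enzyme_stock=float(block.get("enzyme_mg_per_ml", 2.0)),
        total_volume=float(block.get("total_volume_ul", 500.0)),
    )


def parse_oracle(block: Optional[Mapping]) -> OracleConfig:
    if not block:
        return OracleConfig()
    kwargs = dict(block)
    return OracleConfig(**kwargs)


def parse_campaign(block: Optional[Mapping], acquisition: Optional[Mapping] = None) -> CampaignConfig:
    kwargs = dict(block) if block else {}
    fams = kwargs.pop("families", None)
    if fams is not None:
        kwargs["families"] = [
            ModelFamily(f) if isinstance(f, str) else ModelFamily(f["name"], f.get("hyperparameters", {}))
            for f in fams
        ]
    if acquisition:
        kwargs["acquisition"] = AcquisitionConfig(**acquisition)
    return CampaignConfig(**kwargs)


def load_config(path_or_mapping: Union[str, Path, Mapping]) -> dict:
    """Parse a full config file into package objects.

    Returns a dict with keys ``grid``, ``stocks``, ``oracle``, ``campaign``.
    """
    data = _read(path_or_mapping)
    return {
        "grid": parse_space(data.get("space")),
        "stocks": parse_stocks(data.get("stocks")),
        "oracle": parse_oracle(data.get("oracle")),
        "campaign": parse_campaign(data.get("campaign"), data.get("acquisition")),
    }
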
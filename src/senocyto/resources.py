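"""Accessors for the configuration files shipped with the package."""

from __future__ import annotations

from importlib import resources as _ir
from pathlib import Path


def _config_path(name: str) -> Path:
    return Path(str(_ir.files("senocyto").joinpath("config", name)))


def default_panel():
    from .panel import load_panel

    return load_panel(_config_path("default_panel.yaml"))


def default_cohort_config():
    from .simulate import SimulationConfig

    return SimulationConfig.from_yaml(_config_path("default_cohort.yaml"))


def table2_rules():
    from .cluster import load_rules

    return load_rules(_config_path("table2_rules.yaml"))


def default_cohort_config_path() -> Path:
    return _config_path("default_cohort.yaml")
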
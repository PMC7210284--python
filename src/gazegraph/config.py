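"""YAML/JSON configuration for the CLI and batch runs.

A config file may set any of:

.. code-block:: yaml

    screen: {width: 1600, height: 900}
    mesh: {cols: 16, rows: 9}
    windows:
      early: [0, 2000]
      late: [4000, 6000]
    column_map:        # canonical name -> column name in the export
      onset_ms: "Event Start Trial Time [ms]"
    simulation:        # any SimulationConfig field
      n_per_group: 20
      green_bias_early: 0.65
    seed: 0

Absent keys fall back to the study defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .aoi_grid import AOIGrid
from .synthetic_scanpaths import SimulationConfig
from .time_windows import DEFAULT_WINDOWS, TimeWindow


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML or JSON config file; None gives an empty config."""
    if path is None:
        return {}
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text) or {}
    return yaml.safe_load(text) or {}


def grid_from_config(cfg: Mapping[str, Any]) -> AOIGrid:
    screen = cfg.get("screen", {})
    mesh = cfg.get("mesh", {})
    return AOIGrid(
        screen_w_px=int(screen.get("width", 1600)),
        screen_h_px=int(screen.get("height", 900)),
        n_cols=int(mesh.get("cols", 16)),
        n_rows=int(mesh.get("rows", 9)),
    )


def windows_from_config(cfg: Mapping[str, Any]) -> dict[str, TimeWindow]:
    """Build the analysis windows, starting from the defaults.

    Config entries override or add windows: ``windows: {early: [0, 2000]}``.
    """
    windows = dict(DEFAULT_WINDOWS)
    for label, bounds in cfg.get("windows", {}).items():
        start, end = bounds
        windows[label] = TimeWindow(label, float(start), float(end))
    return windows


def simulation_from_config(cfg: Mapping[str, Any],
                           seed: int | None = None) -> SimulationConfig:
    kwargs = dict(cfg.get("simulation", {}))
    for key in ("group_dur_scale", "group_gap_ms"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "seed" in cfg and "seed" not in kwargs:
        kwargs["seed"] = int(cfg["seed"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    kwargs.setdefault("grid", grid_from_config(cfg))
    return SimulationConfig(**kwargs)
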
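"""YAML configuration mirroring the parameter dataclasses.

A config file has optional sections ``jr``, ``gains``, ``noise``, ``sim``,
``hemo`` and ``analysis`` whose keys match the corresponding dataclass
fields, e.g.::

    gains: {alpha: 0.5, beta: 0.25, r0: 0.56}
    sim: {duration: 660.0, transient: 60.0, seeds: [0, 1, 2, 3, 4, 5]}

``scaled_test_profile`` returns the reduced configuration used for quick
desk-scale runs (shorter recordings, fewer seeds, smaller connectome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hemodynamics import HemoParams
from .neural_mass import GainSet, JRParams, NoiseSpec, SimConfig
from .pipeline import AnalysisConfig

__all__ = ["RunConfig", "load_config", "scaled_test_profile"]


@dataclass
class RunConfig:
    jr: JRParams = field(default_factory=JRParams)
    gains: GainSet = field(default_factory=GainSet)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    hemo: HemoParams = field(default_factory=HemoParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    connectome_nodes: int = 90


_SECTIONS = {
    "jr": JRParams,
    "gains": GainSet,
    "noise": NoiseSpec,
    "sim": SimConfig,
    "hemo": HemoParams,
    "analysis": AnalysisConfig,
}


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for section, cls in _SECTIONS.items():
        vals = raw.get(section, {})
        if "band" in vals:
            vals["band"] = tuple(vals["band"])
        kwargs[section] = cls(**vals)
    if "connectome_nodes" in raw:
        kwargs["connectome_nodes"] = int(raw["connectome_nodes"])
    return RunConfig(**kwargs)


def scaled_test_profile() -> RunConfig:
    """Reduced problem size for quick runs: 300 s recordings, 2 seeds, 30 nodes."""
    return RunConfig(
        sim=SimConfig(duration=360.0, transient=60.0, seeds=(0, 1)),
        connectome_nodes=30,
    )
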
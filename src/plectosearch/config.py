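"""Declarative run configuration (YAML, schema-validated).

One document collects every tunable of the pipeline; unknown keys are
rejected so typos fail loudly.  Defaults mirror the standard study
conditions: N_c = 50 bp, d_cutoff = 60 A, 10 A roughness cells, 300 K,
and the Fis search rates (L = 336, k_off = 9e-5/s, u = 1e3/s,
k_on = 112500/s, k_t = 1e6/s).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChainSection(_Strict):
    n_bp: int = 336
    delta_lk: list[int] = Field(default_factory=lambda: [-1, 0, 3])
    n_replicas: int = 2
    n_steps: int = 40_000
    frame_interval: int = 400
    bending_persistence: float = 500.0
    torsional_persistence: float = 750.0
    temperature: float = 300.0
    excluded_diameter: float = 20.0
    box_edge: float = 600.0


class JpSection(_Strict):
    n_c: int = 50
    d_cutoff: float = 60.0
    cell_size: float = 10.0
    link_threshold: int = 20


class WalkerSection(_Strict):
    contact_strength: float = 4.0
    screening_length: float = 10.0
    slide_step: float = 0.7
    hop_rate: float = 0.01
    detach_rate: float = 0.002
    jump_rate_at_jp: float = 0.05
    groove_coupling: float = 1.0
    steps_per_frame: int = 20


class ModeSection(_Strict):
    r_slide: float = 15.0
    r_hop: float = 30.0
    rebind_window: int = 20
    jump_sep: int = 50
    jump_spatial_max: float = 60.0


class SearchSection(_Strict):
    L: int = 336
    k_on: float = 112_500.0
    k_off: float = 9e-5
    u: float = 1e3
    k_t: float = 1e6
    target: int = 336
    kmc_walkers: int = 500


class TwistPropSection(_Strict):
    c_thresh: float = 0.8
    max_lag: int | None = None


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "plectosearch_run"
    chain: ChainSection = Field(default_factory=ChainSection)
    jp: JpSection = Field(default_factory=JpSection)
    walker: WalkerSection = Field(default_factory=WalkerSection)
    modes: ModeSection = Field(default_factory=ModeSection)
    search: SearchSection = Field(default_factory=SearchSection)
    twistprop: TwistPropSection = Field(default_factory=TwistPropSection)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration next to the outputs."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
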
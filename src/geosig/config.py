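"""Threshold/parameter configuration loading for the CLI.

A config file (YAML or JSON) may override any of the dataclass defaults
used across the toolkit, grouped by section::

    cd:          {gamma: 0.5, subspace_frac: 0.95, top_n: 500}
    autoextract: {study_prob_threshold: 0.9, dbscan_eps: 3.0, ...}
    sanitize:    {tau: 1.0, curator_threshold: 0.1}
    simulate:    {n_studies: 30, n_genes: 1000, ...}
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .autoextract import AutoExtractConfig
from .diffexp import CDParams
from .synthdata import SimConfig


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def cd_params(cfg: dict) -> CDParams:
    return CDParams(**cfg.get("cd", {}))


def autoextract_config(cfg: dict) -> AutoExtractConfig:
    return AutoExtractConfig(**cfg.get("autoextract", {}))


def sim_config(cfg: dict, seed: int | None = None) -> SimConfig:
    kwargs = dict(cfg.get("simulate", {}))
    if seed is not None:
        kwargs["seed"] = seed
    if "samples_per_group" in kwargs:
        kwargs["samples_per_group"] = tuple(kwargs["samples_per_group"])
    return SimConfig(**kwargs)
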
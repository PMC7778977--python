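"""Flat key-value configuration.

Every calling threshold, rank weight and generator parameter is exposed
under one flat YAML mapping (no nesting) so that a run is fully described by
a single small file.  Unknown keys are rejected, which catches typos early.
"""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .simulate import FixtureSpec

#: analysis-side defaults (generator defaults live on FixtureSpec)
ANALYSIS_DEFAULTS = {
    "rnaseq_alpha": 0.05,
    "affy_p_present_high": 0.03,
    "affy_p_present_low": 0.12,
    "est_high_min": 7,
    "est_low_min": 1,
    "insitu_weight_high": 1.0,
    "insitu_weight_low": 0.5,
    "elim_alpha": 0.01,
    "min_confidence": "bronze",
    "gene_page_stage_aggregation": "min",  # min | mean rank per anatomical entity
}


def default_config() -> dict:
    cfg = dict(ANALYSIS_DEFAULTS)
    for f in fields(FixtureSpec):
        if f.name == "seed":
            continue
        v = getattr(FixtureSpec(), f.name)
        cfg[f.name] = list(v) if isinstance(v, tuple) else v
    return cfg


def load_config(path: str | None) -> dict:
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"{path}: unknown config key {key!r}")
        if isinstance(value, dict):
            raise ValueError(f"{path}: nested value under key {key!r}; config is flat")
        cfg[key] = value
    return cfg


def fixture_spec_from_config(cfg: dict, seed: int) -> FixtureSpec:
    kwargs = {}
    for f in fields(FixtureSpec):
        if f.name == "seed":
            continue
        v = cfg[f.name]
        kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return FixtureSpec(seed=seed, **kwargs)
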
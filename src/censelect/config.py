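"""YAML configuration for the benchmark runner.

A config file has up to four sections::

    design:      {p: 1000, n: 2000, blocks: [[5, 0.97], ...], missing_rate: 0.02}
    methods:     [UNIV-BFN, LASSO-MIN, ...]        # plus optional settings map
    evaluation:  {family: binary, n_reps: 500, validation_mode: univariable,
                  surrogate_threshold: 0.8, power: 0.8, alpha: 5.0e-5}
    seeds:       {master_seed: 20201210, design_seed: 0}

Missing keys fall back to the defaults mirroring the study conditions
(p=1000, n=2000, 10 truths, 500 replicates).
"""
from __future__ import annotations

from dataclasses import asdict

import yaml

from .evalbench import BenchmarkConfig
from .simdata import CovariateDesign, default_design

__all__ = ["load_config", "default_config_yaml"]


def _design_from_dict(d: dict, seed: int) -> CovariateDesign:
    base = default_design(p=d.get("p", 1000), n=d.get("n", 2000), seed=seed)
    kwargs = dict(
        p=base.p, n=base.n,
        blocks=tuple(tuple(b) for b in d["blocks"]) if "blocks" in d else base.blocks,
        marginal_spec=d.get("marginals", base.marginal_spec),
        missing_rate=d.get("missing_rate", base.missing_rate),
        background=d.get("background", base.background),
        seed=seed,
    )
    return CovariateDesign(**kwargs)


def load_config(path) -> BenchmarkConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seeds = raw.get("seeds", {})
    design = _design_from_dict(raw.get("design", {}), seed=seeds.get("design_seed", 0))
    ev = raw.get("evaluation", {})
    methods = raw.get("methods", None)
    cfg = BenchmarkConfig(design=design)
    if methods:
        if isinstance(methods, dict):
            cfg.methods = tuple(methods.keys())
            cfg.method_settings = {k: (v or {}) for k, v in methods.items()}
        else:
            cfg.methods = tuple(methods)
    cfg.family = ev.get("family", cfg.family)
    cfg.n_reps = ev.get("n_reps", cfg.n_reps)
    cfg.power = ev.get("power", cfg.power)
    cfg.alpha = ev.get("alpha", cfg.alpha)
    cfg.beta = ev.get("beta", cfg.beta)
    cfg.validation_mode = ev.get("validation_mode", cfg.validation_mode)
    cfg.surrogate_threshold = ev.get("surrogate_threshold", cfg.surrogate_threshold)
    cfg.master_seed = seeds.get("master_seed", cfg.master_seed)
    return cfg


def default_config_yaml() -> str:
    cfg = BenchmarkConfig()
    d = cfg.design
    payload = {
        "design": {
            "p": d.p, "n": d.n, "blocks": [list(b) for b in d.blocks],
            "missing_rate": d.missing_rate, "background": d.background,
        },
        "methods": list(cfg.methods),
        "evaluation": {
            "family": cfg.family, "n_reps": cfg.n_reps, "power": cfg.power,
            "alpha": cfg.alpha, "validation_mode": cfg.validation_mode,
            "surrogate_threshold": cfg.surrogate_threshold,
        },
        "seeds": {"master_seed": cfg.master_seed, "design_seed": d.seed},
    }
    return yaml.safe_dump(payload, sort_keys=False)
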
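"""End-to-end experiment orchestration from a YAML config.

A config declares the comparison to run — which feedback modes, how many
seeds, at which scale — and ``run_experiment`` executes the declared
pipeline (simulate -> calibrate -> HF -> RL -> report), writing every
artifact (run curves, comparison reports, the echoed config and its hash)
into the output directory.

Schema (YAML):

.. code-block:: yaml

    scale: desk            # desk | full
    modes: [sparse, hf-oracle, hf-noisy:0.3]
    seeds: 5               # or an explicit list
    world: {dims: [9, 9, 5]}          # optional overrides
    rl: {episodes: 300}               # optional DDPGConfig overrides
    hf: {n_labels: 1000}              # optional HFConfig overrides
    final_window: 50

Unknown fields, unknown modes, or type mismatches raise
:class:`ConfigError` naming the offending field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from .ddpg import DDPGConfig, desk_config, train
from .feedback import HFConfig, make_channel, train_hf_policy
from .gridworld import GridWorld
from .metrics import RunCurve, aggregate_runs

logger = logging.getLogger(__name__)

_TOP_FIELDS = {"scale", "modes", "seeds", "world", "rl", "hf", "final_window"}


class ConfigError(ValueError):
    """Raised for schema violations; the message names the field path."""


def _check(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def validate_config(cfg: dict) -> dict:
    """Validate and normalize an experiment config dict."""
    _check(isinstance(cfg, dict), "<root>", "config must be a mapping")
    unknown = set(cfg) - _TOP_FIELDS
    _check(not unknown, ",".join(sorted(unknown)), "unknown field(s)")
    out = dict(cfg)
    scale = out.setdefault("scale", "desk")
    _check(scale in ("desk", "full"), "scale", f"unknown scale '{scale}'")
    modes = out.get("modes")
    _check(isinstance(modes, list) and modes, "modes",
           "must be a non-empty list")
    for i, mode in enumerate(modes):
        ok = mode == "sparse" or mode.startswith(("hf-oracle", "hf-noisy",
                                                  "hf-bci-sim"))
        _check(ok, f"modes[{i}]", f"unknown mode '{mode}'")
    seeds = out.setdefault("seeds", 5)
    if isinstance(seeds, int):
        _check(seeds >= 2, "seeds", "need at least 2 seeds")
        out["seeds"] = list(range(seeds))
    else:
        _check(isinstance(seeds, list) and len(seeds) >= 2, "seeds",
               "must be an int >= 2 or a list of at least 2 integers")
    for section, cls in (("rl", DDPGConfig), ("hf", HFConfig)):
        extra = out.get(section, {})
        _check(isinstance(extra, dict), section, "must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(extra) - valid
        _check(not unknown, f"{section}.{','.join(sorted(unknown))}",
               "unknown field(s)")
    world = out.get("world", {})
    _check(isinstance(world, dict), "world", "must be a mapping")
    out.setdefault("final_window", 50 if scale == "desk" else 500)
    return out


def _rl_config(cfg: dict) -> DDPGConfig:
    overrides = dict(cfg.get("rl", {}))
    if cfg["scale"] == "desk":
        return desk_config(**overrides)
    return DDPGConfig(**overrides)


def _make_world(cfg: dict, rl_cfg: DDPGConfig) -> GridWorld:
    world_kw = dict(cfg.get("world", {}))
    if "dims" in world_kw:
        world_kw["dims"] = tuple(world_kw["dims"])
    elif cfg["scale"] == "desk":
        world_kw["dims"] = (9, 9, 5)
    world_kw.setdefault("max_steps", rl_cfg.max_steps)
    return GridWorld(**world_kw)


def _channel_for_mode(mode: str):
    if mode == "sparse":
        return None
    spec = mode[len("hf-"):]
    return make_channel(spec)


def run_mode(cfg: dict, mode: str, seed: int) -> RunCurve:
    """One trained model: (optionally) HF policy, then the RL run."""
    rl_cfg = _rl_config(cfg)
    world = _make_world(cfg, rl_cfg)
    channel = _channel_for_mode(mode)
    hf = None
    if channel is not None:
        hf_cfg = HFConfig(**cfg.get("hf", {}))
        hf = train_hf_policy(world, channel, hf_cfg, seed=seed)
    curve = train(world, hf=hf, cfg=rl_cfg, seed=seed, mode=mode)
    curve.agent_ = None  # keep curves serializable
    return curve


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_experiment(config, out_dir) -> dict:
    """Execute a full comparison experiment; returns {mode: ComparisonReport}.

    ``config`` is a path to a YAML file or a dict.  Artifacts written to
    ``out_dir``: ``config.yaml`` (echoed, with hash), one
    ``curve_<mode>_<seed>.json`` per run, and ``report_<mode>.json`` per
    mode.
    """
    if not isinstance(config, dict):
        with open(config) as f:
            config = yaml.safe_load(f)
    cfg = validate_config(config)
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump({"hash": chash, **cfg}))
    reports = {}
    for mode in cfg["modes"]:
        curves = []
        for seed in cfg["seeds"]:
            logger.info("mode=%s seed=%d: training", mode, seed)
            curve = run_mode(cfg, mode, seed)
            curve.config_hash = chash
            slug = mode.replace(":", "_")
            (out / f"curve_{slug}_{seed}.json").write_text(curve.to_json())
            curves.append(curve)
        report = aggregate_runs(curves, final_window=cfg["final_window"])
        reports[mode] = report
        (out / f"report_{mode.replace(':', '_')}.json").write_text(
            report.to_json())
        logger.info("mode=%s: final SPL %.3f [%.3f, %.3f]", mode,
                    report.final_summary.mean, report.final_summary.ci_low,
                    report.final_summary.ci_high)
    return reports
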
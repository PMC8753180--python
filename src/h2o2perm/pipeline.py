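"""Configuration, provenance and stage orchestration.

A run is described by a :class:`RunConfig` (YAML on disk): an ordered list of
stages with per-stage parameter blocks, plus a seed.  ``run_pipeline``
executes the stages against synthetic inputs generated from the seed and
returns a JSON-serialisable bundle in which every stage's intermediates are
recorded alongside provenance (config hash, seed, constants version).  The
same config and seed always produce the same bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import constants
from .kinetics import (
    KineticScenario,
    RBCKineticsModel,
    forward_latency,
    steady_state_gradient,
)
from .latency import Geometry, LatencyExperiment
from .membrane import SlabProfile, permeability_from_profile, resistance_shares
from .partition import (
    VantHoffModel,
    delta_g,
    kd_from_double_partition,
)
from .synthetic import gen_partition, gen_timecourse_series

log = logging.getLogger("h2o2perm")

KNOWN_STAGES = ("partition", "profile", "latency", "kinetics")
_CONFIG_KEYS = {"stages", "seed", "out_dir", "params", "verbosity"}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    stages: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str | None = None
    params: dict = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
        unknown = set(self.params) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"params for unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_partition(params: dict, seed: int) -> dict:
    sample = gen_partition(seed=seed, **params)
    K_D = kd_from_double_partition(sample.system)
    out = {
        "K_D": K_D,
        "dG_kJ_mol": delta_g(K_D, sample.system.T),
        "fold_less_soluble": 1.0 / K_D if K_D > 0 else None,
        "truth": sample.truth,
    }
    log.info("partition: K_D = %.4g (truth %.4g)", K_D, sample.truth["K_D"])
    return out


def _stage_profile(params: dict, seed: int) -> dict:
    slabs = params.get("slabs")
    profile = SlabProfile.from_dicts(slabs) if slabs else SlabProfile.h2o2_default()
    P_m = permeability_from_profile(profile)
    log.info("profile: P_m = %.4g cm/s over %d slabs", P_m, len(profile.slabs))
    return {
        "P_m_cm_s": P_m,
        "total_thickness_nm": profile.total_thickness_nm,
        "shares": resistance_shares(profile).to_dict(orient="records"),
    }


def _stage_latency(params: dict, seed: int) -> dict:
    gen_params = dict(params.get("generate", {}))
    sample = gen_timecourse_series(seed=seed, **gen_params)
    model = LatencyExperiment(
        intact=sample.intact,
        disrupted=sample.disrupted,
        geometry=sample.geometry,
        k_catalase=sample.truth["k_catalase"],
        temperature=sample.truth["temperature_K"],
    )
    res = model.fit()
    log.info("latency: k_intact = %.4g +- %.2g, k_disrupted = %.4g +- %.2g",
             res.intact.slope, res.intact.slope_stderr,
             res.disrupted.slope, res.disrupted.slope_stderr)
    log.info("latency: R = %.4g, P_m = %.4g +- %.2g cm/s (truth %.4g)",
             res.R, res.P_m, res.P_m_stderr, sample.truth["P_m"])
    return {
        "k_intact": res.intact.slope,
        "k_intact_stderr": res.intact.slope_stderr,
        "k_disrupted": res.disrupted.slope,
        "k_disrupted_stderr": res.disrupted.slope_stderr,
        "R": res.R,
        "P_m_cm_s": res.P_m,
        "P_m_stderr": res.P_m_stderr,
        "truth": sample.truth,
    }


def _stage_kinetics(params: dict, seed: int) -> dict:
    sc_params = dict(params.get("scenario", {}))
    sc_params.setdefault("P_m", constants.PM_RBC_37C)
    sc_params.setdefault("hematocrit", constants.HEMATOCRIT_PHYSIOLOGICAL)
    sc_params.setdefault("C0_out", 1e-6)
    sc_params.setdefault("k_cat", constants.K_CATALASE_RBC)
    sc_params.setdefault("k_prx", constants.K_PRX2)
    sc_params.setdefault("prx_total", constants.PRX2_TOTAL_M)
    scenario = KineticScenario(**sc_params)
    model = RBCKineticsModel(scenario)
    res = model.simulate()
    out = {
        "gradient_closed_form": steady_state_gradient(scenario),
        "gradient_ode": res.gradient,
        "half_life_s": res.half_life(),
        "mass_error": res.mass_error,
        "scenario": scenario.to_dict(),
    }
    log.info("kinetics: gradient = %.4g, half-life = %.4g ms",
             out["gradient_ode"], out["half_life_s"] * 1e3)
    return out


_STAGE_FUNCS = {
    "partition": _stage_partition,
    "profile": _stage_profile,
    "latency": _stage_latency,
    "kinetics": _stage_kinetics,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the result bundle.

    The bundle carries full provenance (config hash, seed, constants version)
    and one sub-dict per executed stage.  An empty stage list is a warned
    no-op.  Stage failures propagate annotated with the stage name.
    """
    if not config.stages:
        warnings.warn("pipeline run with no stages: nothing to do", stacklevel=2)
    bundle: dict[str, Any] = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "constants_version": constants.CONSTANTS_VERSION,
        },
        "stages": {},
    }
    for stage in config.stages:
        try:
            bundle["stages"][stage] = _STAGE_FUNCS[stage](
                config.params.get(stage, {}), config.seed
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(bundle, indent=2) + "\n")
    return bundle
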
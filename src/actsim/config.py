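"""Model/scenario configuration files (YAML) and result serialization.

A config file has sections ``space``, ``cancer``, ``tcells``, ``cytokines``,
``K``/``mu_scaling``, and optionally ``init`` (initial counts) and ``run``
(therapy schedule, horizon, ensemble settings).  Kernel keys that are trait
tuples are written joined with ``|`` (e.g. ``"x|y": 0.5``).  Unknown keys are
rejected with their paths; the loaded parameter set must pass
:func:`actsim.traits.validate_parameters`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .therapy import Scenario, Thresholds
from .traits import ModelParams, validate_parameters

__all__ = ["ConfigError", "load_config", "save_config", "params_to_json",
           "params_from_json"]

_TOP_KEYS = {"space", "cancer", "tcells", "cytokines", "K", "mu_scaling",
             "init", "run"}
_SPACE_KEYS = {"genotypes", "phenotypes_of", "tcell_types", "cytokine_types"}
_CANCER_KEYS = {"b", "d", "c", "c_b", "t_kill", "kill_burst", "s_nat", "s_cyt",
                "mu", "m_law"}
_TCELL_KEYS = {"b_T", "d_T", "t_prod", "rep_burst"}
_CYTO_KEYS = {"d_W"}
_RUN_KEYS = {"name", "t_max", "t_start", "replicates", "base_seed", "record_dt",
             "therapy_schedule", "thresholds"}
_THRESH_KEYS = {"relapse_frac", "remission_frac", "differentiated"}


class ConfigError(ValueError):
    """Raised for parse errors, unknown keys, or validation violations."""


def _reject_unknown(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under '{path}' "
            f"(allowed: {sorted(allowed)})")


def load_config(path) -> tuple[ModelParams, Scenario | None]:
    """Load and validate a model configuration; returns (params, scenario).

    The scenario is None when the file has no ``init``/``run`` sections.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "<top>")
    if "space" not in data:
        raise ConfigError("missing required section 'space'")
    _reject_unknown(data["space"], _SPACE_KEYS, "space")
    for section, allowed in (("cancer", _CANCER_KEYS), ("tcells", _TCELL_KEYS),
                             ("cytokines", _CYTO_KEYS)):
        if section in data and data[section]:
            _reject_unknown(data[section], allowed, section)
    if data["space"].get("tcell_types") and "tcells" not in data:
        raise ConfigError("section 'tcells' is required: T-cell traits declared")
    if data["space"].get("cytokine_types") and "cytokines" not in data:
        raise ConfigError("section 'cytokines' is required: cytokine traits declared")

    params = ModelParams.from_dict({k: v for k, v in data.items()
                                    if k in ("space", "cancer", "tcells",
                                             "cytokines", "K", "mu_scaling")})
    violations = validate_parameters(params)
    if violations:
        raise ConfigError("invalid parameters:\n  " + "\n  ".join(violations))

    scenario = None
    if "init" in data or "run" in data:
        init = data.get("init") or {}
        run = data.get("run") or {}
        _reject_unknown(init, {"counts"}, "init")
        _reject_unknown(run, _RUN_KEYS, "run")
        thr = run.get("thresholds") or {}
        _reject_unknown(thr, _THRESH_KEYS, "run.thresholds")
        thresholds = Thresholds(
            relapse_frac=float(thr.get("relapse_frac", 0.9)),
            remission_frac=float(thr.get("remission_frac", 0.01)),
            differentiated=tuple(thr.get("differentiated", ("x",))),
        )
        schedule = [(float(t), str(lab), int(n))
                    for t, lab, n in (run.get("therapy_schedule") or [])]
        scenario = Scenario(
            name=str(run.get("name", path.stem)),
            params=params,
            initial_counts={str(k): int(v)
                            for k, v in (init.get("counts") or {}).items()},
            therapy_schedule=schedule,
            t_max=float(run.get("t_max", 100.0)),
            replicates=int(run.get("replicates", 50)),
            base_seed=int(run.get("base_seed", 0)),
            thresholds=thresholds,
            record_dt=float(run.get("record_dt", 0.25)),
            t_start=float(run.get("t_start", 0.0)),
        )
    return params, scenario


def save_config(path, params: ModelParams, scenario: Scenario | None = None) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    data = params.to_dict()
    if scenario is not None:
        data["init"] = {"counts": dict(scenario.initial_counts)}
        data["run"] = {
            "name": scenario.name,
            "t_max": scenario.t_max,
            "t_start": scenario.t_start,
            "replicates": scenario.replicates,
            "base_seed": scenario.base_seed,
            "record_dt": scenario.record_dt,
            "therapy_schedule": [[t, lab, n]
                                 for t, lab, n in scenario.therapy_schedule],
            "thresholds": {
                "relapse_frac": scenario.thresholds.relapse_frac,
                "remission_frac": scenario.thresholds.remission_frac,
                "differentiated": list(scenario.thresholds.differentiated),
            },
        }
    # drop empty kernel sections for readability
    for sec in ("cancer", "tcells", "cytokines"):
        data[sec] = {k: v for k, v in data[sec].items() if v}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def params_to_json(params: ModelParams) -> str:
    """JSON round-trip serialization with stable key ordering."""
    return json.dumps(params.to_dict(), sort_keys=True, indent=1)


def params_from_json(text: str) -> ModelParams:
    return ModelParams.from_dict(json.loads(text))


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
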
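"""YAML run configuration with strict key validation.

The YAML schema mirrors the dataclass field names of
:class:`~irllc.cohort.CohortConfig` and
:class:`~irllc.phantom.AcquisitionSpec`; distribution entries are
``{mean, sd, lower, upper}`` mappings.  Unknown keys are rejected with
the full key path so typos never silently fall back to defaults, and
every run writes its resolved configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cohort import CohortConfig, TruncNorm
from .errors import SchemaError
from .phantom import AcquisitionSpec
from .signal_models import SPGRParams

__all__ = ["load_run_config", "cohort_config_from_dict", "acquisition_from_dict", "dump_resolved_config"]

_TRUNCNORM_KEYS = {"mean", "sd", "lower", "upper"}


def _truncnorm_from(d: dict, path: str) -> TruncNorm:
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: expected a mapping with keys {_TRUNCNORM_KEYS}")
    unknown = set(d) - _TRUNCNORM_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    missing = _TRUNCNORM_KEYS - set(d)
    if missing:
        raise SchemaError(f"{path}: missing key(s) {sorted(missing)}")
    return TruncNorm(**{k: float(v) for k, v in d.items()})


def cohort_config_from_dict(d: dict, path: str = "cohort") -> CohortConfig:
    allowed = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("lesion_t1_dist", "liver_t1_dist"):
        if key in kwargs:
            kwargs[key] = {
                name: _truncnorm_from(spec, f"{path}.{key}.{name}")
                for name, spec in kwargs[key].items()
            }
    for key in ("diameter_dist", "m0_ratio_dist"):
        if key in kwargs:
            kwargs[key] = _truncnorm_from(kwargs[key], f"{path}.{key}")
    return CohortConfig(**kwargs)


def acquisition_from_dict(d: dict, path: str = "acquisition") -> AcquisitionSpec:
    allowed = {f.name for f in dataclasses.fields(AcquisitionSpec)}
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = dict(d)
    if "ti_list_ms" in kwargs:
        kwargs["ti_list_ms"] = tuple(float(t) for t in kwargs["ti_list_ms"])
    if "spgr" in kwargs:
        spgr = kwargs["spgr"]
        s_allowed = {f.name for f in dataclasses.fields(SPGRParams)}
        s_unknown = set(spgr) - s_allowed
        if s_unknown:
            raise SchemaError(f"{path}.spgr: unknown key(s) {sorted(s_unknown)}")
        kwargs["spgr"] = SPGRParams(**spgr)
    return AcquisitionSpec(**kwargs)


_TOP_KEYS = {"cohort", "acquisition", "seed", "stats", "optimizer"}


def load_run_config(path) -> dict:
    """Load and validate a YAML run configuration file.

    Returns ``{"cohort": CohortConfig, "acquisition": AcquisitionSpec,
    "seed": int, "stats": dict, "optimizer": dict}``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("top level of the config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown top-level key(s) {sorted(unknown)}")
    cohort_d = dict(raw.get("cohort", {}))
    if "seed" in raw and "seed" not in cohort_d:
        cohort_d["seed"] = int(raw["seed"])
    return {
        "cohort": cohort_config_from_dict(cohort_d),
        "acquisition": acquisition_from_dict(dict(raw.get("acquisition", {}))),
        "seed": int(raw.get("seed", 0)),
        "stats": dict(raw.get("stats", {})),
        "optimizer": dict(raw.get("optimizer", {})),
    }


def dump_resolved_config(cfg: dict, path) -> Path:
    """Write the resolved configuration as YAML next to the outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    path.write_text(yaml.safe_dump(plain(cfg), sort_keys=True))
    return path
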
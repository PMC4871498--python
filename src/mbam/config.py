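"""Run configuration: serializable descriptions of reproducible runs.

A :class:`RunConfig` fully determines a command-line run: the model (zoo
name or SBML path), the log-parameter values or the fixture-sampler seed,
the QoI specification, geodesic/reduction options and the output
directory.  Every artifact a run writes embeds the hash of the resolved
configuration and the package version, and re-running from the emitted
``resolved_config.json`` reproduces the same outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .geodesic import GeodesicOptions
from .infogeo import FDOptions
from .models import InputProtocol, QoISpec
from .params import ParameterVector
from .reduction import MBAMOptions
from .zoo import adaptation_qoi, sample_adaptive_params, zoo

__all__ = ["RunConfig", "ConfigError", "load_config", "write_artifact"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass
class RunConfig:
    model: str  # zoo name, or path to an SBML file
    params: dict[str, float] | None = None  # natural log values
    params_linear: dict[str, float] | None = None
    fixture_seed: int | None = None
    observable: str | None = None
    times: list[float] | None = None
    sigmas: float | list[float] | None = None
    input_kind: str | None = None
    input_magnitude: float | None = None
    input_onset: float = 0.0
    geodesic: dict = field(default_factory=dict)
    reduction: dict = field(default_factory=dict)
    outdir: str = "mbam_out"
    seed: int = 0

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "model" not in data:
            raise ConfigError("config field 'model' is required")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- resolution --------------------------------------------------------
    def resolve(self):
        """Instantiate (model, params, qoi, geodesic opts, mbam opts)."""
        if self.model.endswith(".xml") or self.model.endswith(".sbml"):
            from .sbml import load_sbml

            model, ref = load_sbml(self.model)
            default_qoi = None
        else:
            try:
                model, ref, default_qoi = zoo(self.model)
            except KeyError as err:
                raise ConfigError(str(err)) from None

        if self.params is not None and self.params_linear is not None:
            raise ConfigError("give params (log) or params_linear, not both")
        if self.params is not None:
            params = ParameterVector.from_log(
                {n: float(self.params[n]) for n in model.parameter_names}
                if set(self.params) >= set(model.parameter_names)
                else _missing(self.params, model)
            )
        elif self.params_linear is not None:
            params = ParameterVector.from_linear(
                {n: float(self.params_linear[n]) for n in model.parameter_names}
                if set(self.params_linear) >= set(model.parameter_names)
                else _missing(self.params_linear, model)
            )
        elif self.fixture_seed is not None:
            params = sample_adaptive_params(model, seed=int(self.fixture_seed))
        elif ref is not None:
            params = ref
        else:
            raise ConfigError(
                f"model {self.model!r} has no reference parameters; provide "
                "params, params_linear or fixture_seed"
            )

        qoi = default_qoi
        if self.fixture_seed is not None and self.times is None:
            qoi = adaptation_qoi(model, params)
        if self.times is not None:
            protocol = qoi.protocol if qoi is not None else InputProtocol("constant", 0.0)
            if self.input_kind is not None:
                protocol = InputProtocol(
                    self.input_kind, float(self.input_magnitude or 0.0),
                    float(self.input_onset),
                )
            try:
                qoi = QoISpec(
                    self.observable or (qoi.observable if qoi else model.state_names[-1]),
                    np.asarray(self.times, dtype=float),
                    self.sigmas if self.sigmas is not None else 1.0,
                    protocol,
                )
            except ValueError as err:
                raise ConfigError(f"invalid QoI specification: {err}") from None
        elif qoi is not None and (
            self.observable or self.sigmas is not None or self.input_kind
        ):
            protocol = qoi.protocol
            if self.input_kind is not None:
                protocol = InputProtocol(
                    self.input_kind, float(self.input_magnitude or 0.0),
                    float(self.input_onset),
                )
            qoi = QoISpec(
                self.observable or qoi.observable,
                qoi.times,
                self.sigmas if self.sigmas is not None else qoi.sigmas,
                protocol,
            )
        if qoi is None:
            raise ConfigError("no QoI specification: provide times (and observable)")

        try:
            geo = GeodesicOptions(**{
                k: (FDOptions(**v) if k == "fd" else v)
                for k, v in self.geodesic.items()
            })
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid geodesic options: {err}") from None
        try:
            red_kwargs = dict(self.reduction)
            red = MBAMOptions(geodesic=geo, seed=self.seed, **red_kwargs)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid reduction options: {err}") from None
        return model, params, qoi, geo, red


def _missing(given: dict, model) -> dict:
    missing = set(model.parameter_names) - set(given)
    raise ConfigError(
        f"missing parameter values for {sorted(missing)} "
        f"(model {model.name!r} needs {list(model.parameter_names)})"
    )


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: not valid YAML/JSON: {err}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_artifact(outdir, name: str, payload: dict, config: RunConfig) -> Path:
    """Write a JSON artifact stamped with the config hash and version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload["config_hash"] = config.hash()
    payload["package_version"] = __version__
    path = outdir / name
    path.write_text(json.dumps(payload, indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
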
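"""Configuration loading, result serialization and run manifests.

Units throughout: concentrations µM, time s, rates µM⁻ⁿ·s⁻¹.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .gsa import GSAConfig, PRCCTable
from .network import SPECIES, SimulationResult
from .parameters import ParameterSet, default_parameters
from .stimulus import StimulusProtocol, make_protocol

__all__ = ["load_config", "write_results", "read_result_csv", "RunManifest"]

_CONFIG_SECTIONS = {"parameters", "protocol", "gsa"}


def load_config(path) -> tuple[ParameterSet, StimulusProtocol, GSAConfig]:
    """Parse a YAML config into typed objects with all defaults resolved.

    Schema: optional ``parameters`` (name → value overrides), ``protocol``
    (``name`` plus any protocol field) and ``gsa`` (GSAConfig fields).
    Unknown sections or keys are rejected with their key path.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise KeyError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    p = default_parameters()
    overrides = raw.get("parameters") or {}
    bad = set(overrides) - set(p.names())
    if bad:
        raise KeyError("unknown key(s) under 'parameters': "
                       + ", ".join(f"parameters.{k}" for k in sorted(bad)))
    if overrides:
        p = p.replace(**{k: float(v) for k, v in overrides.items()})

    proto_cfg = dict(raw.get("protocol") or {})
    name = proto_cfg.pop("name", "LFS")
    proto = make_protocol(name, Ca_basal=p.Ca_basal, tau=p.tau_decay, **proto_cfg)

    gsa_cfg = dict(raw.get("gsa") or {})
    known = {f.name for f in dataclasses.fields(GSAConfig)}
    bad = set(gsa_cfg) - known
    if bad:
        raise KeyError("unknown key(s) under 'gsa': "
                       + ", ".join(f"gsa.{k}" for k in sorted(bad)))
    if "parameters" in gsa_cfg:
        gsa_cfg["parameters"] = tuple(gsa_cfg["parameters"])
    gsa = GSAConfig(**gsa_cfg)
    return p, proto, gsa


def write_results(obj, path, fmt: str = "csv") -> Path:
    """Serialize a SimulationResult or PRCCTable; loss-free round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, SimulationResult):
        if fmt == "csv":
            df = pd.DataFrame(obj.y.T, columns=list(SPECIES))
            df.insert(0, "time", obj.t)
            df.to_csv(path, index=False, float_format="%.17g")
        elif fmt == "json":
            payload = {
                "time": obj.t.tolist(),
                "species": {n: obj.y[i].tolist() for i, n in enumerate(SPECIES)},
                "protocol": obj.protocol.to_config(),
                "mode": obj.mode,
            }
            path.write_text(json.dumps(payload))
        else:
            raise ValueError(f"unknown format: {fmt!r}")
        return path
    if isinstance(obj, PRCCTable):
        if fmt == "csv":
            obj.table.rename_axis("parameter").to_csv(path)
        elif fmt == "json":
            payload = {
                "observable": obj.observable, "protocol": obj.protocol,
                "summary": obj.summary, "n_samples": obj.n_samples,
                "seed": obj.seed, "alpha": obj.alpha,
                "parameters": obj.table.to_dict(orient="index"),
            }
            path.write_text(json.dumps(payload, indent=1))
        else:
            raise ValueError(f"unknown format: {fmt!r}")
        return path
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_result_csv(path, protocol: StimulusProtocol, params: ParameterSet,
                    mode: str = "reduced_pka") -> SimulationResult:
    """Re-hydrate a SimulationResult written by `write_results`."""
    df = pd.read_csv(path)
    return SimulationResult(
        t=df["time"].to_numpy(),
        y=df[list(SPECIES)].to_numpy().T,
        protocol=protocol, params=params, mode=mode,
    )


@dataclass
class RunManifest:
    """Reproducibility record written alongside every run's outputs."""

    tool_version: str
    parameter_hash: str
    protocol: dict
    variant: str
    mode: str
    seed: int | None
    solver: dict
    started: str = ""
    finished: str = ""
    outputs: list[str] = dataclasses.field(default_factory=list)

    @classmethod
    def begin(cls, p: ParameterSet, proto: StimulusProtocol, variant: str,
              mode: str, seed: int | None = None,
              rtol: float = 1e-8, atol: float = 1e-12) -> "RunManifest":
        from . import __version__
        return cls(
            tool_version=__version__,
            parameter_hash=p.digest(),
            protocol=proto.to_config(),
            variant=variant, mode=mode, seed=seed,
            solver={"method": "LSODA", "rtol": rtol, "atol": atol},
            started=datetime.datetime.now(datetime.UTC).isoformat(),
        )

    def finalize(self, outputs: list[str]) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.UTC).isoformat()
        self.outputs = [str(o) for o in outputs]
        return self

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path
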
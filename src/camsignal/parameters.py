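"""Model constants, total pools, and parameter transforms.

All concentrations are µM, times s, rates µM⁻ⁿ·s⁻¹.  Values printed in the
model's parameter and variable tables are transcribed here verbatim; the
nine-state CaM rates and a handful of constants the tables omit are loaded
from the packaged ``data/cam_kinetics.yaml`` and the loader fails loudly if
any symbol is missing.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import importlib.resources
import json
from dataclasses import dataclass

import yaml

__all__ = [
    "ParameterSet",
    "Variant",
    "default_parameters",
    "apply_variant",
    "perturb",
    "load_supplementary_constants",
]

#: symbols that must be present in the packaged constants file
_SUPPLEMENTARY = (
    "kon_NT", "koff_NT", "kon_NR", "koff_NR",
    "kon_CT", "koff_CT", "kon_CR", "koff_CR",
    "Km7", "Km9", "K1", "n_canb", "kon_i1pp1", "koff_i1pp1",
)


def load_supplementary_constants() -> dict[str, float]:
    """Read the packaged constants file, enforcing completeness."""
    ref = importlib.resources.files("camsignal.data").joinpath("cam_kinetics.yaml")
    raw = yaml.safe_load(ref.read_text())
    missing = [k for k in _SUPPLEMENTARY if k not in raw]
    if missing:
        raise KeyError(
            f"constants file is missing required symbol(s): {', '.join(missing)}"
        )
    return {k: float(raw[k]) for k in _SUPPLEMENTARY}


@dataclass(frozen=True)
class ParameterSet:
    """Every rate constant, Michaelis/Hill constant and total pool of the model."""

    # --- nine-state CaM rates (T/R lobe scheme) ---
    kon_NT: float
    koff_NT: float
    kon_NR: float
    koff_NR: float
    kon_CT: float
    koff_CT: float
    kon_CR: float
    koff_CR: float
    # --- CaM4-target binding ---
    kc1f: float = 50.0      # AC1 on
    kc1b: float = 1.0
    kc2f: float = 20.0      # AC8 on
    kc2b: float = 1.0
    kc3f: float = 100.0     # PDE1 on
    kc3b: float = 1.0
    kc4f: float = 46.0      # CaNA (PP2B) on
    kc4b1: float = 0.0012   # CaNA off, high Ca2+
    Kd1: float = 0.5
    n1: float = 1.8
    kc4b2: float = 2.0      # CaNA off, low Ca2+
    Kd2: float = 0.1
    n2: float = 3.0
    kc5f: float = 21.0      # CaMKII (phos or not) on
    kc5b1: float = 1.1      # unphosphorylated off
    kc5b2: float = 0.0011   # T286-phosphorylated off (1000x slower)
    # --- catalysis ---
    kcat1: float = 2.843    # CaMAC1 -> cAMP
    kcat2: float = 2.843    # CaMAC8 -> cAMP
    kcat3: float = 3.0      # AC* -> cAMP
    kcat4: float = 18.0     # PKAc phosphorylates PDE4B/D
    Km4: float = 25.0
    k10: float = 0.25       # PDE4B/D^P dephosphorylation
    kcat5: float = 1.7      # PDE1 (basal) hydrolyzing cAMP
    kcat6: float = 3.12     # CaM-bound PDE1 (stimulated)
    Km5: float = 10.0
    kcat7: float = 1.56     # PDE4B basal
    kcat8: float = 3.12     # PDE4B^P stimulated
    Km7: float = 4.0
    kcat9: float = 5.4      # PDE4D basal
    kcat10: float = 10.8    # PDE4D^P stimulated
    Km9: float = 2.0
    kcat11: float = 1.4     # PKAc phosphorylates I-1
    Km11: float = 5.0
    kcat12: float = 2.0     # PP2A dephosphorylates I-1^P
    Km12: float = 16.0
    kcat13: float = 2.8     # CaM-bound PP2B dephosphorylates I-1^P
    Km13: float = 3.0
    kcat14: float = 1.2     # T286 autophosphorylation
    kcat15: float = 1.72    # PP1 dephosphorylates (CaM)CaMKII^P
    Km15: float = 11.0
    kcat16: float = 2.0     # PP2A dephosphorylates (CaM)CaMKII^P
    Km16: float = 16.0
    # --- PKA activation ---
    k17f: float = 8.0       # µM^-2 s^-1, R2C2 + 2 cAMP
    k17b: float = 0.02
    k18f: float = 0.7       # µM^-2 s^-1, R2C2cAMP2 + 2 cAMP
    k18b: float = 0.2
    k19f: float = 0.25      # µM^-2 s^-1 (rebinding under the selected orientation)
    k19b: float = 0.0016    # s^-1 (catalytic-subunit release)
    # --- reduced-PKA Hill constants ---
    pka_max: float = 0.2170
    pka_ic50: float = 0.3760
    pka_n: float = 2.569
    # --- total pools (µM) ---
    CaM_T: float = 17.7
    CaMKII_T: float = 20.0
    AC1_T: float = 2.5
    AC8_T: float = 0.625
    ACstar_T: float = 2.5
    PDE1_T: float = 4.0
    PP2B_T: float = 2.1
    PP1_T: float = 3.5
    PP2A_T: float = 0.11111
    I1_T: float = 1.5
    PDE4B_T: float = 1.0
    PDE4D_T: float = 1.0
    R2C2_T: float = 1.2
    # --- auxiliary constants (from the packaged file) ---
    K1: float = 0.5
    n_canb: float = 3.0
    kon_i1pp1: float = 10.0
    koff_i1pp1: float = 0.01
    # --- stimulus defaults (config, never hard-coded in logic) ---
    Ca_basal: float = 0.1
    tau_decay: float = 0.05

    def __post_init__(self) -> None:
        import math
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")

    # -- accessors / serialization -------------------------------------
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(self))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **kwargs: float) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def digest(self) -> str:
        """Stable SHA-256 of the full parameter table (provenance hash)."""
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown parameter name(s): {', '.join(sorted(unknown))}")
        return cls(**{k: float(v) for k, v in raw.items()})

    def to_csv(self, path) -> None:
        import pandas as pd
        d = self.as_dict()
        pd.DataFrame({"parameter": list(d), "value": list(d.values())}).to_csv(
            path, index=False
        )


class Variant(str, enum.Enum):
    """Knockout/knock-in variants of the network."""

    WT = "wt"
    T286A = "t286a"       # no T286 autophosphorylation
    PP1_KO = "pp1ko"      # no PP1
    PDE1_KO = "pde1ko"    # no PDE1


def default_parameters() -> ParameterSet:
    """Baseline parameter set: table transcriptions plus packaged constants."""
    c = load_supplementary_constants()
    return ParameterSet(
        kon_NT=c["kon_NT"], koff_NT=c["koff_NT"],
        kon_NR=c["kon_NR"], koff_NR=c["koff_NR"],
        kon_CT=c["kon_CT"], koff_CT=c["koff_CT"],
        kon_CR=c["kon_CR"], koff_CR=c["koff_CR"],
        Km7=c["Km7"], Km9=c["Km9"], K1=c["K1"], n_canb=c["n_canb"],
        kon_i1pp1=c["kon_i1pp1"], koff_i1pp1=c["koff_i1pp1"],
    )


def apply_variant(p: ParameterSet, variant: Variant | str) -> ParameterSet:
    """Return the parameter set of a knockout variant (WT is the identity)."""
    variant = Variant(variant)
    if variant is Variant.WT:
        return p
    if variant is Variant.T286A:
        return p.replace(kcat14=0.0)
    if variant is Variant.PP1_KO:
        return p.replace(PP1_T=0.0)
    if variant is Variant.PDE1_KO:
        return p.replace(PDE1_T=0.0)
    raise ValueError(f"unknown variant: {variant!r}")


def perturb(p: ParameterSet, name: str, fraction: float) -> ParameterSet:
    """Scale one named parameter by ``(1 + fraction)``; fraction must exceed -1."""
    if fraction <= -1.0:
        raise ValueError(f"fraction must be > -1 (got {fraction}): rate would go negative")
    if name not in p.names():
        raise KeyError(f"unrecognized parameter name: {name}")
    return p.replace(**{name: getattr(p, name) * (1.0 + fraction)})
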
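"""Parameter sets for the three β-cell model variants.

Every model constant is declared once in :data:`PARAM_SPEC` with its unit and
a short description.  Concrete values ship as structured YAML files (one per
variant) under ``isletburst/parameter_sets/``; each entry records name, value,
unit and provenance.  The loader validates completeness, units and positivity
constraints — unknown or missing keys are errors, not warnings, because a
silent typo among 60+ constants is the dominant failure mode in models of
this size.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = ["Variant", "ParameterSet", "PARAM_SPEC", "PARAM_ORDER", "load_parameters"]


class Variant(str, Enum):
    """Which K+ conductance couples (or replaces) metabolism to the membrane.

    WT_KATP      – wild type: nucleotide-gated K(ATP) current.
    KO_KIR21     – SUR1 knockout rescued by a cAMP-potentiated Kir2.1 current.
    KO_LEAK_KCA  – SUR1 knockout rescued by a constant-conductance K+ leak
                   together with an elevated Ca2+-activated K+ conductance.
    """

    WT_KATP = "WT_KATP"
    KO_KIR21 = "KO_KIR21"
    KO_LEAK_KCA = "KO_LEAK_KCA"


# name -> (unit, description).  Order defines the packed-array layout used by
# the numerical kernels; append only.
PARAM_SPEC: dict[str, tuple[str, str]] = {
    # membrane / electrical
    "Cm": ("fF", "membrane capacitance"),
    "gK": ("pS", "delayed-rectifier K+ maximal conductance"),
    "gCa": ("pS", "voltage-gated Ca2+ maximal conductance"),
    "gKCa": ("pS", "Ca2+-activated K+ maximal conductance"),
    "gKATP_bar": ("pS", "K(ATP) maximal conductance scale (WT only)"),
    "gKir": ("pS", "Kir2.1 maximal conductance (KO_KIR21 only)"),
    "gleak": ("pS", "constant K+ leak conductance (KO_LEAK_KCA only)"),
    "VK": ("mV", "K+ reversal potential"),
    "VCa": ("mV", "Ca2+ reversal potential"),
    "vm": ("mV", "ICa activation half-max voltage"),
    "sm": ("mV", "ICa activation slope"),
    "vn": ("mV", "IK activation half-max voltage"),
    "sn": ("mV", "IK activation slope"),
    "tau_n": ("ms", "IK activation time constant"),
    "Kc": ("uM", "K(Ca) half-activation Ca2+"),
    # calcium handling
    "fcyt": ("1", "free fraction of cytosolic Ca2+"),
    "alpha": ("uM/(fA*ms)", "current-to-flux conversion factor"),
    "kpmca": ("1/ms", "plasma-membrane Ca2+ pump rate"),
    "kleak": ("1/ms", "ER leak rate"),
    "kSERCA": ("1/ms", "SERCA pump rate into ER"),
    "fer": ("1", "free fraction of ER Ca2+"),
    "Vcte": ("1", "cytosol/ER volume ratio"),
    # Kir2.1 gating
    "VKir": ("mV", "Kir2.1 half-block voltage (polyamine block)"),
    "sKir": ("mV", "Kir2.1 block slope factor"),
    "alpha_camp": ("1", "cAMP-independent Kir2.1 activation weight"),
    "beta_camp": ("1", "cAMP-dependent Kir2.1 activation weight"),
    "Kcamp": ("uM", "Kir2.1 cAMP half-activation"),
    # cAMP turnover (adenylyl cyclase / phosphodiesterase)
    "vAC_bar": ("uM/ms", "maximal adenylyl-cyclase rate"),
    "alphaAC": ("1", "Ca2+-independent AC weight"),
    "betaAC": ("1", "Ca2+-dependent AC weight"),
    "KACca": ("uM", "AC Ca2+ half-activation"),
    "beta_amp": ("1", "AMP inhibition weight of AC"),
    "Kamp": ("uM", "AC AMP half-inhibition"),
    "amp_exp": ("1", "Hill exponent of AMP inhibition of AC"),
    "vPDE_bar": ("uM/ms", "maximal phosphodiesterase rate"),
    "alphaPDE": ("1", "Ca2+-independent PDE weight"),
    "betaPDE": ("1", "Ca2+-dependent PDE weight"),
    "KPDEca": ("uM", "PDE Ca2+ half-activation"),
    "KPDEcamp": ("uM", "PDE cAMP Michaelis constant"),
    # glycolysis (glucokinase influx + Smolen-type allosteric PFK)
    "JGK": ("uM/ms", "glucokinase reaction rate (glycolytic influx)"),
    "vPFK": ("uM/ms", "maximal PFK rate"),
    "lambda_pfk": ("1", "relative PFK rate with no activator bound"),
    "Kamp_pfk": ("uM", "PFK AMP dissociation constant"),
    "Kfbp_pfk": ("uM", "PFK FBP dissociation constant"),
    "Kf6p_pfk": ("uM^2", "PFK F6P^2 dissociation constant"),
    "Katp_pfk": ("uM^2", "PFK ATP^2 dissociation constant"),
    "f13": ("1", "AMP/F6P binding interaction factor"),
    "f23": ("1", "FBP/F6P binding interaction factor"),
    "f41": ("1", "ATP/AMP binding interaction factor"),
    "f42": ("1", "ATP/FBP binding interaction factor"),
    "f43": ("1", "ATP/F6P binding interaction factor"),
    "kgpdh": ("uM/ms", "GPDH flux scale (per sqrt(uM) of FBP)"),
    "kFBP": ("1", "stoichiometric weight of FBP consumption by GPDH flux"),
    "f6p_frac": ("1", "G6P/F6P isomerase equilibrium fraction"),
    # adenine nucleotides
    "Atot": ("uM", "conserved adenine nucleotide total (ATP+ADP+AMP)"),
    "tau_a": ("ms", "nucleotide interconversion time constant"),
    "r_base": ("1", "basal ATP production exponent"),
    "r1": ("uM/ms", "Ca2+-ATPase pump-flux scale of ATP hydrolysis"),
    "w_pmca": ("1", "ATP cost of plasma-membrane relative to SERCA Ca2+ pumping"),
    "vgamma": ("1", "maximal glycolytic boost of ATP production"),
    "kgamma": ("uM/ms", "GPDH flux at half-maximal boost"),
    # K(ATP) channel nucleotide gating (Magnus–Keizer type open probability)
    "kdd": ("uM", "MgADP activation constant"),
    "ktd": ("uM", "ADP3- inhibition constant"),
    "ktt": ("uM", "ATP4- inhibition constant"),
    "frac_mgadp": ("1", "fraction of ADP present as MgADP"),
    "frac_adp3": ("1", "fraction of ADP present as ADP3-"),
    "frac_atp4": ("1", "fraction of ATP present as ATP4-"),
}

PARAM_ORDER: tuple[str, ...] = tuple(PARAM_SPEC)

# Conductances that define the variant identity: exactly one of these is
# non-zero in a valid parameter set.
_VARIANT_CONDUCTANCE = {
    Variant.WT_KATP: "gKATP_bar",
    Variant.KO_KIR21: "gKir",
    Variant.KO_LEAK_KCA: "gleak",
}

_ALWAYS_POSITIVE = (
    "Cm", "gK", "gCa", "gKCa", "sm", "sn", "sKir", "tau_n", "Kc",
    "fcyt", "alpha", "kpmca", "kleak", "kSERCA", "fer", "Vcte",
    "beta_camp", "Kcamp", "vAC_bar", "KACca", "beta_amp", "Kamp", "amp_exp",
    "vPDE_bar", "KPDEca", "KPDEcamp", "JGK", "vPFK", "lambda_pfk",
    "Kamp_pfk", "Kfbp_pfk", "Kf6p_pfk", "Katp_pfk",
    "f13", "f23", "f41", "f42", "f43", "kgpdh", "kFBP", "f6p_frac",
    "Atot", "tau_a", "r1", "w_pmca", "kdd", "ktd", "ktt",
    "frac_mgadp", "frac_adp3", "frac_atp4",
)


class ParameterError(ValueError):
    """Raised when a parameter set fails validation."""


@dataclass
class ParameterSet:
    """All model constants for one variant, as a flat named record.

    Construct via :meth:`default` (ships calibrated defaults per variant),
    :meth:`from_yaml`, or by :meth:`replace`-ing individual values.
    """

    variant: Variant
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        self.validate()

    # -- access ---------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        unknown = set(self.values) - set(PARAM_SPEC)
        if unknown:
            raise ParameterError(f"unknown parameters: {sorted(unknown)}")
        missing = set(PARAM_SPEC) - set(self.values)
        if missing:
            raise ParameterError(f"missing parameters: {sorted(missing)}")
        v = self.values
        for name in _ALWAYS_POSITIVE:
            if not v[name] > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v[name]}")
        if v["alpha_camp"] < 0:
            raise ParameterError("alpha_camp must be >= 0")
        if v["alpha_camp"] + v["beta_camp"] > 1 + 1e-12:
            raise ParameterError("alpha_camp + beta_camp must be <= 1")
        for name, val in v.items():
            if not math.isfinite(val):
                raise ParameterError(f"{name} is not finite: {val}")
        # exactly the variant's metabolic-coupling conductance is active
        active = _VARIANT_CONDUCTANCE[self.variant]
        for var, cond in _VARIANT_CONDUCTANCE.items():
            if cond == active:
                if not v[cond] > 0:
                    raise ParameterError(
                        f"{cond} must be > 0 for variant {self.variant.value}")
            elif v[cond] != 0.0:
                raise ParameterError(
                    f"{cond} must be 0 for variant {self.variant.value}, got {v[cond]}")

    # -- construction ---------------------------------------------------
    @classmethod
    def default(cls, variant: Variant | str) -> "ParameterSet":
        """Load the calibrated default parameter file for ``variant``."""
        variant = Variant(variant)
        fname = f"{variant.value.lower()}.yaml"
        ref = resources.files("isletburst") / "parameter_sets" / fname
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "variant" not in doc or "parameters" not in doc:
            raise ParameterError(f"{path}: expected mapping with 'variant' and 'parameters'")
        variant = Variant(doc["variant"])
        values: dict[str, float] = {}
        for name, entry in doc["parameters"].items():
            if name not in PARAM_SPEC:
                raise ParameterError(f"{path}: unknown parameter {name!r}")
            if not isinstance(entry, dict) or "value" not in entry or "unit" not in entry:
                raise ParameterError(f"{path}: entry {name!r} needs 'value' and 'unit'")
            expected_unit = PARAM_SPEC[name][0]
            if str(entry["unit"]) != expected_unit:
                raise ParameterError(
                    f"{path}: {name} has unit {entry['unit']!r}, expected {expected_unit!r}")
            values[name] = float(entry["value"])
        return cls(variant=variant, values=values)

    def to_yaml(self, path: str | Path, provenance: dict[str, str] | None = None) -> None:
        doc = {
            "variant": self.variant.value,
            "parameters": {
                name: {
                    "value": self.values[name],
                    "unit": PARAM_SPEC[name][0],
                    "source": (provenance or {}).get(name, "package calibration"),
                }
                for name in PARAM_ORDER
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    # -- derived --------------------------------------------------------
    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with named values changed (validated)."""
        vals = dict(self.values)
        for k, v in changes.items():
            if k not in PARAM_SPEC:
                raise ParameterError(f"unknown parameter {k!r}")
            vals[k] = float(v)
        return ParameterSet(variant=self.variant, values=vals)

    def to_array(self) -> np.ndarray:
        """Pack values into the fixed-order float array the kernels consume."""
        return np.array([self.values[n] for n in PARAM_ORDER], dtype=np.float64)

    def digest(self) -> str:
        """Short stable hash identifying variant + every value."""
        h = hashlib.sha256(self.variant.value.encode())
        for n in PARAM_ORDER:
            h.update(np.float64(self.values[n]).tobytes())
        return h.hexdigest()[:12]


def load_parameters(source: str | Path | Variant) -> ParameterSet:
    """Load a parameter set from a variant name or a YAML file path."""
    if isinstance(source, Variant):
        return ParameterSet.default(source)
    try:
        return ParameterSet.default(Variant(str(source)))
    except ValueError:
        return ParameterSet.from_yaml(source)
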
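"""Parameter and state data model for phosphorylation-dephosphorylation cycles.

A PDC interconverts a substrate between its unphosphorylated form S and its
phosphorylated form Sp through two antagonistic converter enzymes: a kinase K
(S + K <-> SK -> Sp + K) and a phosphatase P (Sp + P <-> SpP -> S + P).  The
extended model adds reversible association of the two enzymes into a single
complex PK, which may itself carry phosphatase activity (Sp + PK -> S + PK),
kinase activity (S + PK -> Sp + PK), both, or neither.

Units are fixed globally: concentrations in uM, time in seconds.  Association
rates (lambda_i, kappa_1) are uM^-1 s^-1; dissociation (lambda_mi, kappa_m1)
and catalytic rates (k_i) are s^-1.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "RateParams",
    "DerivedConstants",
    "Pools",
    "ModelVariant",
    "ParameterError",
    "derive_constants",
    "validate_variant",
    "fixture",
    "fixture_names",
    "sample_params",
    "to_config",
    "from_config",
    "save_config",
    "load_config",
]


class ParameterError(ValueError):
    """Raised when a rate constant or pool fails validation."""


class ModelVariant(str, enum.Enum):
    """Which enzymatic arms of the kinase-phosphatase complex are active.

    ``basic`` is the plain two-enzyme cycle (no complex at all).  The four
    extended variants differ in the catalytic competence of the PK complex:
    neither enzyme active, phosphatase active only, kinase active only, or
    both active.
    """

    BASIC = "basic"
    COMPLEX_INACTIVE = "complex_inactive"
    COMPLEX_P_ACTIVE = "complex_P_active"
    COMPLEX_K_ACTIVE = "complex_K_active"
    COMPLEX_BOTH_ACTIVE = "complex_both_active"

    @property
    def is_extended(self) -> bool:
        return self is not ModelVariant.BASIC


_RATE_FIELDS = (
    "lambda1", "lambda_m1", "k1",
    "lambda2", "lambda_m2", "k2",
    "lambda3", "lambda_m3", "k3",
    "lambda4", "lambda_m4", "k4",
    "kappa1", "kappa_m1",
)


@dataclass(frozen=True)
class RateParams:
    """All kinetic rate constants of a model variant.

    Arm 1 is the free-phosphatase reaction (Sp + P), arm 2 the free-kinase
    reaction (S + K), arm 3 the complex-phosphatase reaction (Sp + PK), arm 4
    the complex-kinase reaction (S + PK); kappa1/kappa_m1 govern P + K <-> PK.
    """

    lambda1: float
    lambda_m1: float
    k1: float
    lambda2: float
    lambda_m2: float
    k2: float
    lambda3: float = 0.0
    lambda_m3: float = 0.0
    k3: float = 0.0
    lambda4: float = 0.0
    lambda_m4: float = 0.0
    k4: float = 0.0
    kappa1: float = 0.0
    kappa_m1: float = 0.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(
                    f"rate constant {name!r} must be finite and >= 0, got {value!r}"
                )
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ParameterError(
                "lambda1 and lambda2 must be > 0 for any simulated model"
            )

    def replace(self, **changes: float) -> "RateParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _RATE_FIELDS}


@dataclass(frozen=True)
class Pools:
    """Total (conserved) concentrations of kinase, phosphatase and substrate, uM.

    For dose-response sweeps the swept pool is overridden per grid point; a
    fixture whose figure sweeps Kt ships with ``Kt=0``.
    """

    Kt: float
    Pt: float
    St: float

    def __post_init__(self) -> None:
        for name in ("Kt", "Pt", "St"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"pool {name!r} must be finite and >= 0, got {value!r}")

    def replace(self, **changes: float) -> "Pools":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {"Kt": float(self.Kt), "Pt": float(self.Pt), "St": float(self.St)}


@dataclass(frozen=True)
class DerivedConstants:
    """Dimensionless and Michaelis-type constants derived from the raw rates.

    ``alpha = k2/k1`` compares catalytic speeds of the free kinase and
    phosphatase; ``Mi = (lambda_mi + ki)/lambdai`` are Michaelis constants
    (uM) per arm; ``omega = kappa_m1/kappa1`` (uM) is the dissociation
    constant of the PK complex.  Fields whose defining rate is zero are None.
    """

    alpha: float | None
    M1: float | None
    M2: float | None
    M3: float | None
    M4: float | None
    omega: float | None


def derive_constants(params: RateParams) -> DerivedConstants:
    """Compute alpha, M1..M4 and omega; undefined entries come back as None."""
    alpha = params.k2 / params.k1 if params.k1 > 0 else None

    def michaelis(lam_m: float, k: float, lam: float) -> float | None:
        return (lam_m + k) / lam if lam > 0 else None

    return DerivedConstants(
        alpha=alpha,
        M1=michaelis(params.lambda_m1, params.k1, params.lambda1),
        M2=michaelis(params.lambda_m2, params.k2, params.lambda2),
        M3=michaelis(params.lambda_m3, params.k3, params.lambda3),
        M4=michaelis(params.lambda_m4, params.k4, params.lambda4),
        omega=params.kappa_m1 / params.kappa1 if params.kappa1 > 0 else None,
    )


# Arms that must be silent for each variant.  "Inactive" means no association
# and no catalysis; dissociation is retained so that pre-populated complexes
# can drain (relevant to the triggered activity switch in the transient
# scenarios).
_FORBIDDEN_ARMS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.BASIC: ("lambda3", "k3", "lambda4", "k4", "kappa1", "kappa_m1"),
    ModelVariant.COMPLEX_INACTIVE: ("lambda3", "k3", "lambda4", "k4"),
    ModelVariant.COMPLEX_P_ACTIVE: ("lambda4", "k4"),
    ModelVariant.COMPLEX_K_ACTIVE: ("lambda3", "k3"),
    ModelVariant.COMPLEX_BOTH_ACTIVE: (),
}


def validate_variant(
    params: RateParams, variant: ModelVariant
) -> tuple[RateParams, list[str]]:
    """Force rates forbidden by the variant to zero.

    Returns the (possibly modified) parameter set and the list of fields that
    were zeroed.  A nonzero rate on a forbidden arm is a warning, not an
    error: the caller's intent (the variant tag) wins.
    """
    variant = ModelVariant(variant)
    zeroed = [f for f in _FORBIDDEN_ARMS[variant] if getattr(params, f) != 0.0]
    if zeroed:
        warnings.warn(
            f"variant {variant.value!r} forbids nonzero {zeroed}; zeroing them",
            stacklevel=2,
        )
        params = params.replace(**{f: 0.0 for f in zeroed})
    return params, zeroed


# ---------------------------------------------------------------------------
# Fixture registry: every printed parameterization, one entry per figure panel.
# ---------------------------------------------------------------------------

def _fx(variant, Kt, Pt, St, **rates):
    return (RateParams(**rates), Pools(Kt=Kt, Pt=Pt, St=St), ModelVariant(variant))


_BASIC36 = dict(lambda_m1=10, lambda1=1, k1=1, lambda_m2=10, lambda2=20, k2=1)
_ARM3_68 = dict(lambda_m3=10, lambda3=1, k3=100)
_FIG9_SHARED = dict(
    lambda_m1=10, lambda1=1, k1=1, lambda_m2=10, lambda2=1, k2=1,
    kappa_m1=50, kappa1=1,
)

_FIXTURES: dict[str, tuple[RateParams, Pools, ModelVariant]] = {
    # R_inf / Hill-number scans of the basic cycle
    "fig3a": _fx("basic", 0, 1, 10,
                 lambda_m1=1, lambda1=1, k1=1, lambda_m2=1, lambda2=1, k2=0.01),
    "fig3b": _fx("basic", 0, 1, 100,
                 lambda_m1=1, lambda1=1, k1=1, lambda_m2=1, lambda2=1, k2=1),
    # bell-shaped St-sweeps; Pt stated as a fraction of the (fixed) kinase pool
    "fig4a_p1001": _fx("basic", 2000, 0.1001 * 2000, 0,
                       lambda_m1=0.1, lambda1=0.1, k1=1, lambda_m2=0.1, lambda2=0.1, k2=0.1),
    "fig4a_p2": _fx("basic", 2000, 0.2 * 2000, 0,
                    lambda_m1=0.1, lambda1=0.1, k1=1, lambda_m2=0.1, lambda2=0.1, k2=0.1),
    "fig4a_p08": _fx("basic", 2000, 0.08 * 2000, 0,
                     lambda_m1=0.1, lambda1=0.1, k1=1, lambda_m2=0.1, lambda2=0.1, k2=0.1),
    "fig4b": _fx("basic", 2000, 0, 0,
                 lambda_m1=0.1, lambda1=0.1, k1=1, lambda_m2=0.1, lambda2=0.1, k2=0.1),
    # ultrasensitivity outside the zero-order regime (St < Pt)
    "fig5a_basic": _fx("basic", 0, 10, 1,
                       lambda_m1=10, lambda1=1, k1=100, lambda_m2=10, lambda2=1, k2=100),
    "fig5a_Kactive": _fx("complex_K_active", 0, 10, 1,
                         lambda_m1=10, lambda1=1, k1=100, lambda_m2=10, lambda2=1, k2=100,
                         lambda_m4=10, lambda4=100, k4=0.01, kappa_m1=10, kappa1=1),
    "fig5b_basic": _fx("basic", 0, 10, 1,
                       lambda_m1=10, lambda1=1, k1=100, lambda_m2=10, lambda2=1, k2=100),
    "fig5b_Pactive": _fx("complex_P_active", 0, 10, 1,
                         lambda_m1=10, lambda1=1, k1=100, lambda_m2=10, lambda2=1, k2=100,
                         lambda_m3=10, lambda3=100, k3=0.01, kappa_m1=10, kappa1=1),
    # bell-shaped Kt-sweeps of the phosphatase-active complex
    "fig6a": _fx("complex_P_active", 0, 1, 10,
                 **_BASIC36, **_ARM3_68, kappa_m1=50, kappa1=1),
    "fig6b": _fx("complex_P_active", 0, 1, 0.1,
                 **_BASIC36, **_ARM3_68, kappa_m1=50, kappa1=1),
    "fig7": _fx("complex_P_active", 0, 1, 10,
                **_BASIC36, **_ARM3_68, kappa_m1=10, kappa1=1),
    "fig8_basic": _fx("basic", 0, 1, 10, **_BASIC36),
    "fig8_extended": _fx("complex_P_active", 0, 1, 10,
                         **_BASIC36, **_ARM3_68, kappa_m1=50, kappa1=1),
    # transient phosphoinositide-regulation scenarios
    "fig9_trigger": _fx("complex_K_active", 0.1, 0.2, 300,
                        **_FIG9_SHARED, lambda_m4=1, lambda4=75, k4=100),
    "fig9_recruitment": _fx("complex_P_active", 0.0, 0.2, 300,
                            **_FIG9_SHARED, lambda_m3=10, lambda3=10, k3=500),
}

# post-switch rates of the triggered scenario (complex turns phosphatase-active)
FIG9_TRIGGER_POST = dict(lambda_m3=10.0, lambda3=10.0, k3=500.0)
FIG9_RECRUITMENT_RATE = 0.0003  # uM/s, linear kinase recruitment Kt = 0.0003 t
FIG9_SWITCH_TIME = 300.0  # s


def fixture(name: str) -> tuple[RateParams, Pools, ModelVariant]:
    """Return the printed parameter set for a named figure panel."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        ) from None


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


# ---------------------------------------------------------------------------
# Random parameter sampling (property tests, robustness scans)
# ---------------------------------------------------------------------------

def sample_params(
    ranges: Mapping[str, tuple[float, float]],
    seed: int | np.random.Generator,
) -> RateParams:
    """Draw one rate set, each listed field log-uniform within its bounds.

    Fields not listed keep the RateParams defaults (zero for complex arms),
    except lambda1/lambda2 which default to 1 so the set always validates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {"lambda1": 1.0, "lambda_m1": 1.0, "k1": 1.0,
              "lambda2": 1.0, "lambda_m2": 1.0, "k2": 1.0}
    for name, (lo, hi) in ranges.items():
        if name not in _RATE_FIELDS:
            raise ParameterError(f"unknown rate field {name!r}")
        if not (0 < lo <= hi) or not np.isfinite(hi):
            raise ParameterError(f"bounds for {name!r} must satisfy 0 < lo <= hi")
        values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return RateParams(**values)


# ---------------------------------------------------------------------------
# Flat config serialization (JSON or YAML)
# ---------------------------------------------------------------------------

def to_config(params: RateParams, pools: Pools, variant: ModelVariant) -> dict:
    doc = params.as_dict()
    doc.update(pools.as_dict())
    doc["variant"] = ModelVariant(variant).value
    return doc


def from_config(doc: Mapping) -> tuple[RateParams, Pools, ModelVariant]:
    doc = dict(doc)
    variant = ModelVariant(doc.pop("variant", "basic"))
    pools = Pools(Kt=doc.pop("Kt"), Pt=doc.pop("Pt"), St=doc.pop("St"))
    unknown = set(doc) - set(_RATE_FIELDS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    params = RateParams(**{k: float(v) for k, v in doc.items()})
    return params, pools, variant


def save_config(path, params: RateParams, pools: Pools, variant: ModelVariant) -> None:
    path = Path(path)
    doc = to_config(params, pools, variant)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> tuple[RateParams, Pools, ModelVariant]:
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return from_config(doc)
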
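"""Model parameters and effective rate laws.

The model tracks three species in a single cell: ``L``, the number of active
autonomous retrotransposon copies (LINE-1); ``S``, the number of active
non-autonomous copies (Alu); and ``R_L``, the number of L1-encoded
endonuclease/reverse-transcriptase complexes that both element types need to
insert new copies.  Competition for this shared machinery gives the system its
predator-prey character.

Five model variants are supported:

``basic``
    Mass-action rates; the production rate of ``R_L`` is linear in ``L``.
``ribosome``
    ``R_L`` production saturates in ``L`` (Michaelis-Menten) because L1 mRNAs
    compete with all other cellular mRNAs for free ribosomes; the competition
    strength is the parameter ``k_r``.
``energy``
    Translation and integration rate constants are scaled by Michaelis-Menten
    factors in the available energy ``e`` (half-saturations ``k_tr`` for
    translation and ``k_int`` for integration).
``mixed``
    Both resource limitations combined.
``two_predator``
    Basic rates plus a second non-autonomous element ``S2`` (e.g. SVA) with
    its own insertion rate constant ``b_S2``.

Rates are expressed per cell generation; concentrations are copy numbers
divided by the cell volume parameter ``V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable

import numpy as np
import yaml

VARIANTS = ("basic", "ribosome", "energy", "mixed", "two_predator")

#: Reference rate constants shared by every variant.
REFERENCE_CONSTANTS = {
    "b_R": 2.0,
    "b_L": 1.0,
    "b_S": 1.0,
    "d_R": 2.0,
    "d_L": 0.5,
    "d_S": 0.5,
    "V": 500.0,
}

#: Reference maximal translation rate (concentration units per generation)
#: and the competition parameter at which the saturating production law
#: reproduces the basic model at its stationary state.
REFERENCE_VMAX = 300.0
REFERENCE_KR = 149.0

#: Reference energy half-saturations for translation and integration.
REFERENCE_KTR = 0.2
REFERENCE_KINT = 3.2

#: The second predator's insertion constant relative to b_S.
REFERENCE_BS2_RATIO = 0.98


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants and resource parameters of one model instance.

    Fields not used by ``variant`` may be left as ``None``.
    """

    variant: str = "basic"
    b_R: float = 2.0
    b_L: float = 1.0
    b_S: float = 1.0
    d_R: float = 2.0
    d_L: float = 0.5
    d_S: float = 0.5
    V: float = 500.0
    v_max: float | None = None
    k_r: float | None = None
    e: float | None = None
    k_tr: float | None = None
    k_int: float | None = None
    b_S2: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        for name in ("b_R", "b_L", "b_S", "d_R", "d_L", "d_S", "V"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name in ("k_r", "e", "k_tr", "k_int"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be non-negative, got {value}")
        for name in ("v_max", "b_S2"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value <= 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.variant in ("ribosome", "mixed"):
            if self.v_max is None or self.k_r is None:
                raise ValueError(f"variant {self.variant!r} requires v_max and k_r")
        if self.variant in ("energy", "mixed"):
            if self.e is None or self.k_tr is None or self.k_int is None:
                raise ValueError(
                    f"variant {self.variant!r} requires e, k_tr and k_int"
                )
        if self.variant == "two_predator" and self.b_S2 is None:
            raise ValueError("variant 'two_predator' requires b_S2")

    @property
    def has_second_predator(self) -> bool:
        return self.variant == "two_predator"

    def with_updates(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParameters":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("parameter YAML must be a mapping")
        return cls.from_dict(data)


def default_parameters(variant: str, *, e: float | None = None) -> ModelParameters:
    """Reference parameter set for a model variant.

    The basic rate constants are ``b_R=2, b_L=1, b_S=1, d_R=2, d_L=0.5,
    d_S=0.5, V=500``.  The ribosome variant adds ``v_max=300`` and the
    reference competition level ``k_r=149`` (the value at which the
    saturating production law reproduces the basic model's stationary
    dynamics).  The energy and mixed variants add ``k_tr=0.2`` and
    ``k_int=3.2`` and require the energy level ``e`` as an argument.  The
    two-predator variant adds ``b_S2 = 0.98 * b_S``.
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    kwargs: dict = dict(REFERENCE_CONSTANTS)
    if variant in ("ribosome", "mixed"):
        kwargs["v_max"] = REFERENCE_VMAX
        kwargs["k_r"] = REFERENCE_KR
    if variant in ("energy", "mixed"):
        if e is None:
            raise ValueError(f"variant {variant!r} requires the energy level e")
        kwargs["e"] = float(e)
        kwargs["k_tr"] = REFERENCE_KTR
        kwargs["k_int"] = REFERENCE_KINT
    if variant == "two_predator":
        kwargs["b_S2"] = REFERENCE_BS2_RATIO * kwargs["b_S"]
    return ModelParameters(variant=variant, **kwargs)


@dataclass(frozen=True)
class EffectiveRates:
    """Variant-resolved rate constants and the R_L production law.

    ``v_R`` maps an L concentration to the R_L production rate (concentration
    per generation); ``v_R_prime`` is its derivative, used by the Jacobian.
    ``b_R_eff`` is the slope of the linear production law (``None`` when the
    saturating law applies, i.e. ``uses_mm`` is true).
    """

    b_L_eff: float
    b_S_eff: float
    b_S2_eff: float | None
    b_R_eff: float | None
    v_max_eff: float | None
    k_r: float | None
    uses_mm: bool
    v_R: Callable[[float], float] = field(compare=False)
    v_R_prime: Callable[[float], float] = field(compare=False)


def energy_factors(params: ModelParameters) -> tuple[float, float]:
    """Michaelis-Menten energy scalings for translation and integration."""
    e, k_tr, k_int = params.e, params.k_tr, params.k_int
    return e / (k_tr + e), e / (k_int + e)


def effective_rate_constants(params: ModelParameters) -> EffectiveRates:
    """Resolve a parameter set into effective constants and the v_R law.

    In the energy and mixed variants the insertion constants are scaled by
    ``e/(k_int+e)`` and the translation-side rates by ``e/(k_tr+e)``; in the
    ribosome and mixed variants the production law saturates as
    ``v_max * l / (k_r + l)``.
    """
    b_L_eff, b_S_eff = params.b_L, params.b_S
    b_S2_eff = params.b_S2 if params.has_second_predator else None
    if params.variant in ("energy", "mixed"):
        f_tr, f_int = energy_factors(params)
        b_L_eff = params.b_L * f_int
        b_S_eff = params.b_S * f_int
    else:
        f_tr = 1.0

    if params.variant in ("ribosome", "mixed"):
        v_max_eff = params.v_max * f_tr
        k_r = params.k_r

        def v_R(ell: float) -> float:
            if ell < 0:
                raise ValueError(f"negative L concentration: {ell}")
            return v_max_eff * ell / (k_r + ell)

        def v_R_prime(ell: float) -> float:
            return v_max_eff * k_r / (k_r + ell) ** 2

        return EffectiveRates(
            b_L_eff=b_L_eff,
            b_S_eff=b_S_eff,
            b_S2_eff=b_S2_eff,
            b_R_eff=None,
            v_max_eff=v_max_eff,
            k_r=k_r,
            uses_mm=True,
            v_R=v_R,
            v_R_prime=v_R_prime,
        )

    b_R_eff = params.b_R * f_tr

    def v_R(ell: float) -> float:
        if ell < 0:
            raise ValueError(f"negative L concentration: {ell}")
        return b_R_eff * ell

    def v_R_prime(ell: float) -> float:
        return b_R_eff

    return EffectiveRates(
        b_L_eff=b_L_eff,
        b_S_eff=b_S_eff,
        b_S2_eff=b_S2_eff,
        b_R_eff=b_R_eff,
        v_max_eff=None,
        k_r=None,
        uses_mm=False,
        v_R=v_R,
        v_R_prime=v_R_prime,
    )
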
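"""Core two-strain mutualistic consortium model.

The consortium couples two engineered *Pseudomonas putida* strains:

* **CP-X** (OD ``X``) eats xylose but carries the β-glucosidase BglC, which
  hydrolyses cellobiose into the glucose that feeds its partner.
* **CP-G** (OD ``G``) eats glucose but carries the β-xylosidase Xyl43A, which
  hydrolyses xylobiose into the xylose that feeds CP-X.

Each strain therefore grows only insofar as its partner is present to supply
its monosaccharide.  The population dynamics are logistic growth with a
Monod-type cross-feeding factor:

.. math::

    \\frac{dX}{dt} = \\frac{r_{mx}}{\\alpha_{Bx}}
        \\cdot \\frac{\\alpha_{Dg}\\,G}{C_g + G}
        \\cdot \\Bigl(1 - \\frac{G + X}{\\alpha_K K}\\Bigr) X

    \\frac{dG}{dt} = r_{mg}
        \\cdot \\frac{\\alpha_{Dx}\\,X}{C_x/\\alpha_{Ex} + X}
        \\cdot \\Bigl(1 - \\frac{G + X}{\\alpha_K K}\\Bigr) G

``r_mx`` and ``r_mg`` are the strains' maximum specific growth rates (h⁻¹);
``C_x`` and ``C_g`` are half-saturation-like constants inversely proportional
to the amounts of BglC and Xyl43A; ``K`` is the carrying capacity of the
medium (all densities in OD600 units, time in hours).

The dimensionless α factors express *in silico* scenario changes relative to
the reference cultivation (1 g/l of each disaccharide, unmodified strains):
``alpha_Dx``/``alpha_Dg`` scale with the initial cellobiose/xylobiose
amounts, ``alpha_Bx`` is the expression/degradation burden on CP-X, and
``alpha_Ex`` scales with the BglC amount.  The carrying capacity is scaled by
the most restrictive factor, ``alpha_K = min(alpha_Ex, alpha_Dx, alpha_Dg)``.
Setting every α to 1 recovers the unscaled model.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError

__all__ = [
    "ConsortiumState",
    "ModelParameters",
    "ScalingFactors",
    "BASELINE_PARAMETERS",
    "IDENTITY_SCALING",
    "effective_alpha_K",
    "derivatives",
]


@dataclass(frozen=True)
class ConsortiumState:
    """Optical densities of the two strains (OD600, dimensionless).

    Attributes
    ----------
    X : float
        OD of the xylose-eating, cellobiose-cleaving strain CP-X.
    G : float
        OD of the glucose-eating, xylobiose-cleaving strain CP-G.
    """

    X: float
    G: float

    def __post_init__(self) -> None:
        if not (self.X >= 0.0 and self.G >= 0.0):
            raise ValidationError(
                f"strain ODs must be non-negative, got X={self.X}, G={self.G}"
            )

    @property
    def total(self) -> float:
        return self.X + self.G


@dataclass(frozen=True)
class ModelParameters:
    """The five fitted constants of the consortium model.

    Attributes
    ----------
    r_mx, r_mg : float
        Maximum specific growth rates of CP-X and CP-G (h⁻¹).
    C_x, C_g : float
        Half-saturation-like constants (OD units), inversely proportional to
        the amounts of the BglC and Xyl43A glycoside hydrolases.
    K : float
        Carrying capacity of the medium (OD units).
    """

    r_mx: float
    r_mg: float
    C_x: float
    C_g: float
    K: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0.0:
                raise ValidationError(f"parameter {f.name} must be > 0, got {v}")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        extra = set(d) - {f.name for f in fields(cls)}
        if extra:
            raise ValidationError(f"unknown model parameter keys: {sorted(extra)}")
        try:
            return cls(**{f.name: float(d[f.name]) for f in fields(cls)})
        except KeyError as e:
            raise ValidationError(f"missing model parameter: {e.args[0]}") from None


@dataclass(frozen=True)
class ScalingFactors:
    """Dimensionless α multipliers defining a cultivation scenario.

    ``alpha_Dx`` and ``alpha_Dg`` scale with the initial cellobiose and
    xylobiose amounts (relative to the 1 g/l reference each), ``alpha_Bx``
    is the BglC expression/degradation burden on CP-X's growth rate, and
    ``alpha_Ex`` scales ``C_x`` inversely with the BglC amount.  The derived
    carrying-capacity factor is ``min(alpha_Ex, alpha_Dx, alpha_Dg)`` —
    the burden factor alpha_Bx does not limit the attainable biomass.
    """

    alpha_Dx: float = 1.0
    alpha_Dg: float = 1.0
    alpha_Bx: float = 1.0
    alpha_Ex: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0.0:
                raise ValidationError(f"scaling factor {f.name} must be > 0, got {v}")

    @property
    def alpha_K(self) -> float:
        return min(self.alpha_Ex, self.alpha_Dx, self.alpha_Dg)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ScalingFactors":
        extra = set(d) - {f.name for f in fields(cls)}
        if extra:
            raise ValidationError(f"unknown scaling factor keys: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})


#: Parameter set fitted to the reference cooperating-consortium cultivation
#: (1 g/l cellobiose + 1 g/l xylobiose, all alpha = 1).
BASELINE_PARAMETERS = ModelParameters(r_mx=0.12, r_mg=0.34, C_x=0.04, C_g=0.02, K=0.82)

#: The identity scenario: every alpha factor equal to 1.
IDENTITY_SCALING = ScalingFactors()


def effective_alpha_K(scaling: ScalingFactors) -> float:
    """Carrying-capacity scaling by the most restrictive resource factor.

    Returns ``min(alpha_Ex, alpha_Dx, alpha_Dg)``; the burden factor
    ``alpha_Bx`` slows CP-X but does not cap the attainable biomass.
    """
    if not isinstance(scaling, ScalingFactors):
        scaling = ScalingFactors(**scaling)
    return scaling.alpha_K


def derivatives(
    state: ConsortiumState,
    params: ModelParameters,
    scaling: ScalingFactors = IDENTITY_SCALING,
) -> tuple[float, float]:
    """Right-hand side of the consortium ODEs: ``(dX/dt, dG/dt)`` in OD/h.

    Each strain's growth rate is the product of its (burden-scaled) maximum
    rate, the saturating cross-feeding factor supplied by its partner, and
    the free fraction of the scaled carrying capacity.  At a state with
    ``X + G == alpha_K * K`` both rates vanish.
    """
    if isinstance(state, tuple):
        state = ConsortiumState(*state)
    X, G = state.X, state.G
    a = scaling
    cap = 1.0 - (G + X) / (a.alpha_K * params.K)
    dX = (params.r_mx / a.alpha_Bx) * (a.alpha_Dg * G / (params.C_g + G)) * cap * X
    dG = params.r_mg * (a.alpha_Dx * X / (params.C_x / a.alpha_Ex + X)) * cap * G
    return dX, dG
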
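"""Metabolic heat production from wrist-surface heat loss.

Under an energy-balance assumption a resting body dissipates exactly the
heat it produces, and dissipation happens through three channels measurable
at the skin surface:

* radiation       ``R = eps * sigma * Tr**4``          (Stefan–Boltzmann law
  with skin emissivity ``eps``; ``Tr`` is the absolute radiometric
  temperature of the wrist in kelvin),
* convection      ``C = 2.38 * (tw - ts)**1.25``       (Newton cooling with a
  temperature-dependent transfer coefficient; ``tw``/``ts`` are wrist-skin
  and ambient temperature in deg C),
* evaporation     ``E = 3.054 * Psk * (1 - He)``       where
  ``Psk = 0.256*tw - 3.37`` (kPa) is the saturation water-vapour pressure at
  skin temperature and ``He`` the ambient relative humidity as a fraction;
  the constant 3.054 fuses the latent heat of vaporisation with the skin
  permeability coefficient.

The total metabolic heat flux is ``H = R + C + E`` in W/m^2.  ``H`` is used
downstream as a regression feature, so no whole-body surface-area scaling is
applied.

Units are strict: ``Tr`` kelvin, ``tw``/``ts`` deg C, ``He`` a fraction in
[0, 1], fluxes W/m^2.  Mixing kelvin/Celsius or percent/fraction is the most
dangerous mistake this model admits, hence the validation below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EnergyConstants",
    "SensorFrame",
    "HeatFlux",
    "OutOfModelError",
    "radiative_heat",
    "convective_heat",
    "saturation_vapor_pressure",
    "evaporative_heat",
    "metabolic_heat",
]


class OutOfModelError(ValueError):
    """Raised when inputs leave the model's physical domain.

    The offending field is named in the message so CSV-level failures are
    traceable to a sensor column.
    """


@dataclass(frozen=True)
class EnergyConstants:
    """Physical constants of the heat-loss model.

    Attributes
    ----------
    emissivity : float
        Skin emissivity ``eps`` (dimensionless, in (0, 1]).  Human skin is
        close to a black body; the working value is 0.96.
    stefan_boltzmann : float
        Stefan–Boltzmann constant ``sigma``, W m^-2 K^-4.
    convective_coefficient_base : float
        Base of the convective transfer coefficient, W m^-2 K^-1.25, so that
        ``C = base * dt**1.25``.
    evaporative_rm : float
        Fused latent-heat x skin-permeability constant multiplying the
        vapour-pressure deficit.
    saturation_slope, saturation_intercept : float
        Linear saturation vapour pressure at skin temperature,
        ``Psk = slope * tw - intercept`` (kPa, with ``tw`` in deg C).
    """

    emissivity: float = 0.96
    stefan_boltzmann: float = 5.67e-8
    convective_coefficient_base: float = 2.38
    evaporative_rm: float = 3.054
    saturation_slope: float = 0.256
    saturation_intercept: float = 3.37

    def __post_init__(self) -> None:
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        for name in (
            "stefan_boltzmann",
            "convective_coefficient_base",
            "evaporative_rm",
            "saturation_slope",
            "saturation_intercept",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def min_skin_temp(self) -> float:
        """Lowest admissible skin temperature (deg C): the root of Psk."""
        return self.saturation_intercept / self.saturation_slope


DEFAULT_CONSTANTS = EnergyConstants()


@dataclass(frozen=True)
class SensorFrame:
    """One measurement episode's raw physical readings.

    Parameters
    ----------
    Tr : float
        Absolute radiometric temperature of the wrist, kelvin.  ``None``
        requests the explicit fallback ``tw + 273.15`` (logged via the
        ``tr_from_skin`` flag; never applied silently).
    tw : float
        Wrist skin temperature, deg C.
    ts : float
        Ambient temperature, deg C.
    He : float
        Ambient relative humidity, fraction in [0, 1].
    BF : float
        Blood flow from laser Doppler flowmetry, perfusion units (opaque
        positive scalar).
    """

    Tr: float | None
    tw: float
    ts: float
    He: float
    BF: float
    tr_from_skin: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.Tr is None:
            object.__setattr__(self, "Tr", self.tw + 273.15)
            object.__setattr__(self, "tr_from_skin", True)
        if not math.isfinite(self.Tr) or self.Tr <= 0:
            raise OutOfModelError(f"Tr must be a positive kelvin temperature, got {self.Tr}")
        if not 0.0 <= self.He <= 1.0:
            raise OutOfModelError(f"He must be a fraction in [0, 1], got {self.He}")
        if self.BF <= 0:
            raise OutOfModelError(f"BF must be positive, got {self.BF}")
        if self.tw <= DEFAULT_CONSTANTS.min_skin_temp:
            raise OutOfModelError(
                f"tw={self.tw} deg C gives a non-positive saturation vapour pressure "
                f"(admissible above {DEFAULT_CONSTANTS.min_skin_temp} deg C)"
            )


@dataclass(frozen=True)
class HeatFlux:
    """Decomposed energy budget, all terms in W/m^2; ``H = R + C + E``."""

    R: float
    C: float
    E: float
    H: float


def radiative_heat(Tr: float, constants: EnergyConstants = DEFAULT_CONSTANTS) -> float:
    """Radiative heat flux ``eps * sigma * Tr**4`` (W/m^2), ``Tr`` in kelvin.

    The model radiates against cold surroundings, i.e. there is no ambient
    ``Tr**4 - Ta**4`` exchange term; the absolute fourth power is used.
    """
    if Tr < 0:
        raise OutOfModelError(f"Tr must be non-negative kelvin, got {Tr}")
    return constants.emissivity * constants.stefan_boltzmann * Tr**4


def convective_heat(
    tw: float,
    ts: float,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
    *,
    allow_signed: bool = False,
) -> float:
    """Convective heat flux ``2.38 * (tw - ts)**1.25`` (W/m^2).

    The 1.25 exponent composes Newton cooling ``hc * (tw - ts)`` with the
    empirical transfer coefficient ``hc = 2.38 * (tw - ts)**0.25``.

    The model assumes net heat loss (skin warmer than air).  For ``tw < ts``
    the fractional power of a negative difference is undefined;
    :class:`OutOfModelError` is raised unless ``allow_signed=True``, which
    returns the exploratory signed value ``-2.38 * |dt|**1.25``.
    """
    dt = tw - ts
    if dt < 0:
        if allow_signed:
            return -constants.convective_coefficient_base * abs(dt) ** 1.25
        raise OutOfModelError(
            f"tw ({tw} deg C) below ambient ts ({ts} deg C): convective term "
            "out of model (pass allow_signed=True for the signed extension)"
        )
    return constants.convective_coefficient_base * dt**1.25


def saturation_vapor_pressure(
    tw: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Saturation water-vapour pressure at skin temperature (kPa).

    Linearised as ``0.256 * tw - 3.37`` over the physiological skin range;
    below ~13.16 deg C the line goes negative, which is unphysical and
    rejected.
    """
    p = constants.saturation_slope * tw - constants.saturation_intercept
    if p < 0:
        raise OutOfModelError(
            f"tw={tw} deg C is below the admissible range "
            f"(> {constants.min_skin_temp} deg C): saturation pressure would be negative"
        )
    return p


def evaporative_heat(
    tw: float, He: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Evaporative heat flux ``3.054 * Psk(tw) * (1 - He)`` (W/m^2).

    ``He`` is ambient relative humidity as a fraction; the ambient vapour
    pressure is ``He * Psk``, so saturated air (``He = 1``) shuts evaporation
    off entirely.
    """
    if not 0.0 <= He <= 1.0:
        raise OutOfModelError(f"He must be a fraction in [0, 1], got {He}")
    return constants.evaporative_rm * saturation_vapor_pressure(tw, constants) * (1.0 - He)


def metabolic_heat(
    frame: SensorFrame, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> HeatFlux:
    """Total metabolic heat flux of a sensor frame, decomposed.

    Returns a :class:`HeatFlux` whose ``H`` is exactly the sum of the three
    component terms computed by :func:`radiative_heat`,
    :func:`convective_heat` and :func:`evaporative_heat`.

    Raises
    ------
    OutOfModelError
        Propagated from any component, naming the offending field.
    """
    R = radiative_heat(frame.Tr, constants)
    C = convective_heat(frame.tw, frame.ts, constants)
    E = evaporative_heat(frame.tw, frame.He, constants)
    return HeatFlux(R=R, C=C, E=E, H=R + C + E)
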
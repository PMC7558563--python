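"""Dynamic corrections of clothing thermophysical properties.

Static clothing insulation and evaporative resistance are measured on a
standing manikin in still air.  A walking person in wind experiences a
"pumping" effect that ventilates the clothing microclimate and compresses the
boundary air layer, so the effective (dynamic) insulation and evaporative
resistance are lower.  This module implements three published regression
families that convert static values to dynamic ones:

* ``ISO7933`` — the exponential correction factors of ISO 7933 (Holmér's
  regressions), applied to all clothing categories; light clothing (< 0.6 clo)
  blends the garment and boundary-layer factors linearly in ``Icl``.
* ``ISO9920`` — ISO 9920's revised factors, which dispatch on clothing
  category: normal clothing (0.6–1.4 clo), cold-protective clothing
  (> 1.4 clo, with an air-permeability term), and an interpolation between the
  corrected dressed total and the dynamic boundary layer for light clothing.
* ``LU`` — a single-factor regression for light clothing that corrects the
  total insulation directly instead of interpolating towards nudity.

All insulation algebra is carried out in clo (1 clo = 0.155 m²·K/W);
conversion to SI happens only where the Lewis relation (16.7 K/kPa) links
thermal insulation to evaporative resistance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

logger = logging.getLogger(__name__)

#: SI value of one clo unit, m²·K/W.
CLO_TO_SI = 0.155
#: Static boundary-air-layer insulation around a standing person, clo.
IA_STATIC_CLO = 0.716
#: Lewis relation between thermal and evaporative transfer, K/kPa.
LEWIS_CONSTANT = 16.7
#: Upper bound on the dynamic moisture permeability index.
IMT_DYN_CAP = 0.9

#: Category cutpoints in clo: light below, cold-protective above.
LC_UPPER = 0.6
NC_UPPER = 1.4


class Category(str, Enum):
    """Clothing category: light (LC), normal (NC), cold-protective (SC)."""

    LC = "LC"
    NC = "NC"
    SC = "SC"


class Algorithm(str, Enum):
    """Dynamic-correction algorithm family."""

    ISO7933 = "ISO7933"
    ISO9920 = "ISO9920"
    LU = "LU"


def category_for_icl(icl: float) -> Category:
    """Clothing category implied by the basic insulation.

    Boundary values 0.6 and 1.4 clo are assigned to NC (the published
    intervals are open and no studied ensemble sits on a boundary, so the tie
    rule is a convention).
    """
    if icl < LC_UPPER:
        return Category.LC
    if icl <= NC_UPPER:
        return Category.NC
    return Category.SC


def fcl_ratio(icl: float) -> float:
    """Clothing area factor fcl = 1 + 0.3·Icl (Icl in clo).

    Ratio of the clothed to the nude body surface area; must be applied to
    every surface heat-exchange coefficient and to the boundary-layer share of
    the total insulation.
    """
    if icl < 0:
        raise ValueError(f"basic insulation must be non-negative, got {icl}")
    return 1.0 + 0.3 * icl


@dataclass(frozen=True)
class ClothingEnsemble:
    """Static thermophysical description of a clothing ensemble.

    Parameters
    ----------
    icl : float
        Basic (static) clothing insulation, clo.
    rt_static : float
        Static total evaporative resistance, m²·kPa/W.
    imt : float
        Static moisture permeability index, dimensionless in (0, 1].
    pr : float
        Outer-fabric air permeability, L/(m²·s); only the cold-protective
        ISO 9920 correction uses it.  Defaults to 1 (airtight shell), which
        makes its power-law term the identity.
    category : Category, optional
        Clothing category; derived from ``icl`` when omitted.
    """

    icl: float
    rt_static: float
    imt: float
    pr: float = 1.0
    category: Category = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        if self.icl <= 0:
            raise ValueError(f"icl must be positive, got {self.icl}")
        if not (0.0 < self.imt <= 1.0):
            raise ValueError(f"imt must lie in (0, 1], got {self.imt}")
        if self.rt_static <= 0:
            raise ValueError(f"rt_static must be positive, got {self.rt_static}")
        if self.pr < 1:
            raise ValueError(f"air permeability must be >= 1 L/m²s, got {self.pr}")
        if self.category is None:
            object.__setattr__(self, "category", category_for_icl(self.icl))

    @property
    def fcl(self) -> float:
        return fcl_ratio(self.icl)

    @property
    def itot_static(self) -> float:
        """Total static insulation Itot = Icl + Ia/fcl, clo."""
        return self.icl + IA_STATIC_CLO / self.fcl


@dataclass(frozen=True)
class Kinematics:
    """Air and body movement state.

    ``var`` is the relative air velocity seen by the moving body.  When not
    given it defaults to the omni-directional walking convention
    ``max(va, vw)``.
    """

    va: float
    vw: float
    var: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.va < 0 or self.vw < 0:
            raise ValueError("air and walking speed must be non-negative")
        if self.var is None:
            object.__setattr__(self, "var", max(self.va, self.vw))
        elif self.var < 0:
            raise ValueError("relative air velocity must be non-negative")


@dataclass(frozen=True)
class DynamicClothing:
    """Dynamic (movement-corrected) clothing quantities, insulation in clo."""

    corr_tot: float
    corr_a: float
    itot_dyn: float
    ia_dyn: float
    icl_dyn: float
    algorithm: str
    clamped: bool = False
    rt_dyn: float = float("nan")
    imt_dyn: float = float("nan")

    @property
    def itot_dyn_si(self) -> float:
        """Dynamic total insulation in m²·K/W."""
        return self.itot_dyn * CLO_TO_SI


# --- correction-factor regressions -----------------------------------------

def _clamp(value: float, lo: float, hi: float) -> tuple[float, bool]:
    if value < lo:
        return lo, True
    if value > hi:
        return hi, True
    return value, False


def _iso7933_factors(var: float, vw: float) -> tuple[float, float, bool]:
    # validity: 0 <= var <= 3 m/s, 0 <= vw <= 1.5 m/s
    var_c, c1 = _clamp(var, 0.0, 3.0)
    vw_c, c2 = _clamp(vw, 0.0, 1.5)
    corr_tot = math.exp(
        0.043 - 0.398 * var_c + 0.066 * var_c**2 - 0.378 * vw_c + 0.094 * vw_c**2
    )
    corr_a = math.exp(
        -0.472 * var_c + 0.047 * var_c**2 - 0.342 * vw_c + 0.117 * vw_c**2
    )
    return corr_tot, corr_a, c1 or c2


def _iso9920_nc_factors(var: float, vw: float) -> tuple[float, float, bool]:
    # validity: 0.15 <= var <= 3.5 m/s, 0 <= vw <= 1.2 m/s
    var_c, c1 = _clamp(var, 0.15, 3.5)
    vw_c, c2 = _clamp(vw, 0.0, 1.2)
    x = var_c - 0.15
    corr_tot = math.exp(-0.281 * x + 0.044 * x**2 - 0.492 * vw_c + 0.176 * vw_c**2)
    corr_a = math.exp(-0.533 * x + 0.069 * x**2 - 0.462 * vw_c + 0.201 * vw_c**2)
    return corr_tot, corr_a, c1 or c2


def _iso9920_sc_corr_tot(var: float, vw: float, pr: float) -> tuple[float, bool]:
    # validity: 0.4 <= var <= 18 m/s, 0 <= vw <= 1.2 m/s, 1 <= pr <= 1000 L/m²s
    var_c, c1 = _clamp(var, 0.4, 18.0)
    vw_c, c2 = _clamp(vw, 0.0, 1.2)
    pr_c, c3 = _clamp(pr, 1.0, 1000.0)
    x = var_c - 0.4
    corr_tot = math.exp(-0.0512 * x + 0.000794 * x**2 - 0.0639 * vw_c) * pr_c**0.144
    return corr_tot, c1 or c2 or c3


def _lu_factor(var: float, vw: float) -> tuple[float, bool]:
    # validity: 0.15 <= var <= 5.2 m/s, 0 <= vw <= 1.2 m/s
    var_c, c1 = _clamp(var, 0.15, 5.2)
    vw_c, c2 = _clamp(vw, 0.0, 1.2)
    x = var_c - 0.15
    factor = math.exp(-0.393 * x + 0.0393 * x**2 - 0.0728 * vw_c + 0.053 * vw_c**2)
    return factor, c1 or c2


def correction_factors(
    algorithm: str,
    kin: Kinematics,
    pr: Optional[float] = None,
) -> tuple[float, float, bool]:
    """Raw (corr_tot, corr_a, clamped) for one regression variant.

    ``algorithm`` is one of ``ISO7933_NC``, ``ISO9920_NC``, ``ISO9920_SC``.
    The cold-protective variant needs the air permeability ``pr`` and reuses
    the normal-clothing boundary-layer factor (no SC-specific corr_a was ever
    published).  Inputs outside a regression's validity range are clamped to
    the nearest bound and flagged.
    """
    if algorithm == "ISO7933_NC":
        return _iso7933_factors(kin.var, kin.vw)
    if algorithm == "ISO9920_NC":
        return _iso9920_nc_factors(kin.var, kin.vw)
    if algorithm == "ISO9920_SC":
        if pr is None:
            raise ValueError("ISO9920_SC requires the air permeability pr")
        corr_tot, clamped1 = _iso9920_sc_corr_tot(kin.var, kin.vw, pr)
        _, corr_a, clamped2 = _iso9920_nc_factors(kin.var, kin.vw)
        return corr_tot, corr_a, clamped1 or clamped2
    raise ValueError(f"unknown correction variant {algorithm!r}")


# --- dynamic insulation ------------------------------------------------------

def dynamic_insulation(
    ens: ClothingEnsemble,
    kin: Kinematics,
    algorithm: Algorithm | str,
) -> DynamicClothing:
    """Dynamic total, boundary-layer and intrinsic clothing insulation.

    Dispatches the requested algorithm on the ensemble's category and applies

        Itot     = Icl + Ia/fcl
        Itot,dyn = Corr_tot · Itot            (category-specific Corr_tot)
        Ia,dyn   = Corr_a · Ia
        Icl,dyn  = Itot,dyn − Ia,dyn/fcl

    ISO 7933 applies its normal-clothing factors to every category, blending
    Corr_tot and Corr_a linearly in Icl below 0.6 clo.  ISO 9920 uses distinct
    regressions per category.  LU is defined for light clothing only.
    """
    algorithm = Algorithm(algorithm)
    fcl = ens.fcl
    itot = ens.itot_static

    if algorithm is Algorithm.ISO7933:
        corr_tot, corr_a, clamped = _iso7933_factors(kin.var, kin.vw)
        if ens.icl <= LC_UPPER:
            # light clothing: blend garment and boundary-layer factors
            corr_tot = ((LC_UPPER - ens.icl) * corr_a + ens.icl * corr_tot) / LC_UPPER
        itot_dyn = corr_tot * itot
        ia_dyn = corr_a * IA_STATIC_CLO
    elif algorithm is Algorithm.ISO9920:
        if ens.category is Category.NC:
            corr_tot, corr_a, clamped = _iso9920_nc_factors(kin.var, kin.vw)
            itot_dyn = corr_tot * itot
            ia_dyn = corr_a * IA_STATIC_CLO
        elif ens.category is Category.SC:
            corr_tot, corr_a, clamped = correction_factors("ISO9920_SC", kin, ens.pr)
            itot_dyn = corr_tot * itot
            ia_dyn = corr_a * IA_STATIC_CLO
        else:  # LC: interpolate between dynamic boundary layer and dressed total
            corr_nc, corr_a, clamped = _iso9920_nc_factors(kin.var, kin.vw)
            ia_dyn = corr_a * IA_STATIC_CLO
            itot_dress = corr_nc * itot
            itot_dyn = ((LC_UPPER - ens.icl) * ia_dyn + ens.icl * itot_dress) / LC_UPPER
            corr_tot = itot_dyn / itot
    elif algorithm is Algorithm.LU:
        if ens.category is not Category.LC:
            raise ValueError(
                f"LU corrections are defined for light clothing only, "
                f"got category {ens.category.value}"
            )
        corr_tot, clamped_lu = _lu_factor(kin.var, kin.vw)
        _, corr_a, clamped_nc = _iso9920_nc_factors(kin.var, kin.vw)
        clamped = clamped_lu or clamped_nc
        itot_dyn = corr_tot * itot
        ia_dyn = corr_a * IA_STATIC_CLO
    else:  # pragma: no cover - Algorithm() already validates
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if clamped:
        logger.warning(
            "kinematics (var=%.3g, vw=%.3g) outside the %s validity range; clamped",
            kin.var, kin.vw, algorithm.value,
        )

    icl_dyn = itot_dyn - ia_dyn / fcl
    return DynamicClothing(
        corr_tot=corr_tot,
        corr_a=corr_a,
        itot_dyn=itot_dyn,
        ia_dyn=ia_dyn,
        icl_dyn=icl_dyn,
        algorithm=algorithm.value,
        clamped=clamped,
    )


# --- dynamic evaporative resistance -----------------------------------------

def dynamic_evaporative_resistance(
    ens: ClothingEnsemble,
    dyn: DynamicClothing,
    algorithm: Algorithm | str,
) -> tuple[float, float]:
    """Dynamic total evaporative resistance and permeability index.

    ISO 7933 performs a double correction: the permeability index is scaled by
    Corr_E = 2.6·Corr_tot² − 6.5·Corr_tot + 4.9 (capped at 0.9) and the Lewis
    relation converts the dynamic insulation to an evaporative resistance,

        Rt,dyn = Itot,dyn[SI] / (imt,dyn · 16.7).

    ISO 9920 applies a single polynomial factor to the static resistance,

        Rt,dyn = (1.2·Corr_tot² − 0.5·Corr_tot + 0.3) · Rt;

    its implied dynamic permeability index is reported via the Lewis relation.
    LU ensembles reuse the ISO 7933 double correction with LU's Corr_tot.

    Returns ``(rt_dyn, imt_dyn)`` with rt_dyn in m²·kPa/W.
    """
    algorithm = Algorithm(algorithm)
    corr_tot = dyn.corr_tot
    if corr_tot <= 0:
        raise ValueError(f"corr_tot must be positive, got {corr_tot}")

    if algorithm in (Algorithm.ISO7933, Algorithm.LU):
        corr_e = 2.6 * corr_tot**2 - 6.5 * corr_tot + 4.9
        imt_dyn = min(ens.imt * corr_e, IMT_DYN_CAP)
        rt_dyn = dyn.itot_dyn_si / (imt_dyn * LEWIS_CONSTANT)
    else:
        factor = 1.2 * corr_tot**2 - 0.5 * corr_tot + 0.3
        rt_dyn = factor * ens.rt_static
        imt_dyn = dyn.itot_dyn_si / (LEWIS_CONSTANT * rt_dyn)
    return rt_dyn, imt_dyn


def dynamic_clothing(
    ens: ClothingEnsemble,
    kin: Kinematics,
    algorithm: Algorithm | str,
) -> DynamicClothing:
    """Full dynamic clothing state: insulation plus evaporative quantities."""
    dyn = dynamic_insulation(ens, kin, algorithm)
    rt_dyn, imt_dyn = dynamic_evaporative_resistance(ens, dyn, algorithm)
    return DynamicClothing(
        corr_tot=dyn.corr_tot,
        corr_a=dyn.corr_a,
        itot_dyn=dyn.itot_dyn,
        ia_dyn=dyn.ia_dyn,
        icl_dyn=dyn.icl_dyn,
        algorithm=dyn.algorithm,
        clamped=dyn.clamped,
        rt_dyn=rt_dyn,
        imt_dyn=imt_dyn,
    )
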
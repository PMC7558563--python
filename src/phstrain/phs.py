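"""Minute-by-minute Predicted Heat Strain (PHS) simulation.

The PHS model (ISO 7933) is a rational heat-balance model of a working,
clothed person.  Each simulated minute it

1. moves the equilibrium core temperature towards a metabolic-rate-dependent
   setpoint by exponential averaging (10-min time constant),
2. predicts the mean skin temperature from regressions for clothed and nude
   subjects (3-min time constant),
3. solves the clothing-surface temperature from the dry heat balance
   (convection + radiation through the dynamic insulation),
4. computes the evaporation *required* to close the heat balance, converts it
   to a required sweat rate through the evaporative efficiency of a partly
   wet skin, limits it by the maximum sweat rate, smooths it (10-min time
   constant), and caps the achieved evaporation by the maximum skin
   wettedness,
5. stores the unbalanced heat in the body, updating core and rectal
   temperature through a core/skin mass weighting, and
6. accumulates water loss (sweat + respiratory evaporation).

Duration limits are the first minute the rectal temperature reaches 38 °C
(``dlim_tre``) and the first minute cumulative water loss reaches 5 %
(``dlim_loss95``) or 7.5 % (``dlim_loss50``) of the body mass.

The clothing path is pluggable: any of the correction algorithms in
:mod:`phstrain.clothing` can supply the dynamic insulation and evaporative
resistance, and the walking speed fed to those corrections is either a
measured value or the standard estimate from the metabolic rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clothing import (
    Algorithm,
    ClothingEnsemble,
    DynamicClothing,
    Kinematics,
    dynamic_clothing,
)

logger = logging.getLogger(__name__)

STEFAN_BOLTZMANN = 5.67e-8
#: Initial rectal/core and skin temperatures, °C.
TRE_INIT = 36.8
TSK_INIT = 34.1
#: Rectal-temperature duration-limit criterion, °C.
TRE_LIMIT = 38.0


def body_surface_area(height_m: float, weight_kg: float) -> float:
    """DuBois body surface area, m²."""
    return 0.202 * weight_kg**0.425 * height_m**0.725


@dataclass(frozen=True)
class Subject:
    """Anthropometry and state of the simulated subject."""

    height: float = 1.8
    weight: float = 75.0
    acclimatized: bool = False
    drink_allowed: bool = True

    def __post_init__(self) -> None:
        if not (1.0 < self.height < 2.5):
            raise ValueError(f"height {self.height} m out of plausible range")
        if not (30.0 < self.weight < 200.0):
            raise ValueError(f"weight {self.weight} kg out of plausible range")

    @property
    def bsa(self) -> float:
        return body_surface_area(self.height, self.weight)


def saturation_vapour_pressure(t_c: float) -> float:
    """Saturated water vapour pressure over water, kPa (Magnus form)."""
    return 0.6105 * math.exp(17.27 * t_c / (t_c + 237.3))


@dataclass(frozen=True)
class ScenarioInput:
    """One exposure scenario: environment + work + clothing + duration."""

    label: str
    ensemble: ClothingEnsemble
    ta: float
    pw: float
    va: float
    met: float
    duration: int = 70
    tr: Optional[float] = None
    vw_measured: Optional[float] = None
    subject: Subject = field(default_factory=Subject)

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be at least 1 minute")
        if self.met < 58:
            raise ValueError(f"metabolic rate {self.met} below resting (58 W/m²)")
        if self.pw >= saturation_vapour_pressure(self.ta):
            raise ValueError(
                f"vapour pressure {self.pw} kPa exceeds saturation at {self.ta} °C"
            )
        if self.tr is None:
            # climate-chamber convention: no radiant source, Tr = Ta
            object.__setattr__(self, "tr", self.ta)


@dataclass
class PHSResult:
    """Minute-wise physiological trajectories plus duration limits."""

    minutes: np.ndarray
    tre: np.ndarray            # rectal temperature, °C
    tcr: np.ndarray            # core temperature, °C
    tsk: np.ndarray            # mean skin temperature, °C
    sweat_rate: np.ndarray     # predicted sweat rate, g/h
    water_loss: np.ndarray     # cumulative water loss, g
    storage: np.ndarray        # heat storage rate, W/m²
    balance_residual: np.ndarray  # storage − (M−W−Cres−Eres−C−R−E), W/m²
    dlim_tre: int
    dlim_loss95: int
    dlim_loss50: int
    duration: int
    algorithm: str
    use_measured_vw: bool
    clothing: DynamicClothing

    @property
    def max_time(self) -> int:
        """Maximum allowable exposure time: min of the rectal and 5 %-loss limits."""
        return min(self.dlim_tre, self.dlim_loss95)

    @property
    def final_tre(self) -> float:
        return float(self.tre[-1])

    @property
    def total_water_loss(self) -> float:
        return float(self.water_loss[-1])


def estimate_walking_speed(met: float) -> float:
    """Walking speed implied by the metabolic rate: 0.0052·(Met−58), ≤ 0.7 m/s."""
    if met < 58:
        logger.warning("metabolic rate %.3g below resting; walking speed set to 0", met)
        return 0.0
    return min(0.0052 * (met - 58.0), 0.7)


def relative_air_velocity(va: float, vw: float, walking_defined: bool) -> float:
    """Relative air velocity for an omni-directional walker, capped at 3 m/s.

    With a defined walking speed the body moves through the air and
    experiences ``max(va, vw)``; with walking speed unknown only the ambient
    air speed acts.
    """
    if va < 0 or vw < 0:
        raise ValueError("velocities must be non-negative")
    var = max(va, vw) if walking_defined else va
    return min(var, 3.0)


def max_exposure_time(result: PHSResult) -> int:
    """Maximum allowable exposure time, minutes (38 °C rectal or 5 % mass loss)."""
    return result.max_time


def simulate(
    scenario: ScenarioInput,
    algorithm: Algorithm | str = Algorithm.ISO7933,
    use_measured_vw: bool = False,
    vw_affects_var: bool = True,
) -> PHSResult:
    """Run the PHS minute loop for one scenario.

    Parameters
    ----------
    scenario : ScenarioInput
    algorithm : Algorithm
        Clothing-dynamics correction family feeding the heat balance.
    use_measured_vw : bool
        When True (and the scenario carries a measured walking speed), the
        measured value drives the clothing corrections; otherwise the walking
        speed is estimated from the metabolic rate.
    vw_affects_var : bool
        Whether a measured walking speed also enters the relative-air-velocity
        rule (default) or only the clothing corrections.
    """
    algorithm = Algorithm(algorithm)
    ens = scenario.ensemble
    subj = scenario.subject

    if use_measured_vw and scenario.vw_measured is not None:
        vw = scenario.vw_measured
        var = relative_air_velocity(scenario.va, vw, walking_defined=True)
        if not vw_affects_var:
            var = relative_air_velocity(scenario.va, 0.0, walking_defined=False)
    else:
        vw = estimate_walking_speed(scenario.met)
        var = relative_air_velocity(scenario.va, vw, walking_defined=False)

    kin = Kinematics(va=scenario.va, vw=vw, var=var)
    dyn = dynamic_clothing(ens, kin, algorithm)
    itot_dyn_si = dyn.itot_dyn_si
    rt_dyn = dyn.rt_dyn
    fcl = ens.fcl

    ta, tr, pa, va = scenario.ta, scenario.tr, scenario.pw, scenario.va
    met, work = scenario.met, 0.0
    duration = scenario.duration

    adu = subj.bsa
    # body heat capacity per unit area and per minute, W·min/(m²·K)
    sp_heat = 57.83 * subj.weight / adu

    dmax50 = 0.075 * subj.weight * 1000.0
    dmax95 = 0.05 * subj.weight * 1000.0
    if not subj.drink_allowed:
        dmax50 = 0.03 * subj.weight * 1000.0
        dmax95 = dmax50

    # maximum sweat rate, W/m² (+25 % if acclimatized); max wettedness
    sw_max = min(max((met - 32.0) * adu, 250.0), 400.0)
    if subj.acclimatized:
        sw_max *= 1.25
        w_max = 1.0
    else:
        w_max = 0.85

    const_teq = math.exp(-1.0 / 10.0)
    const_tsk = math.exp(-1.0 / 3.0)
    const_sw = math.exp(-1.0 / 10.0)

    # standing posture: effective radiating area fraction
    ar_du = 0.77
    f_cl_r = 0.97  # no reflective outer layer
    aux_r = STEFAN_BOLTZMANN * ar_du

    # forced-convection floor of the convective coefficient
    z = 3.5 + 5.2 * var if var <= 1.0 else 8.7 * var**0.6

    t_exp = 28.56 + 0.115 * ta + 0.641 * pa  # expired air temperature

    tre = TRE_INIT
    tcr = TRE_INIT
    tsk = TSK_INIT
    tcr_eq = TRE_INIT
    wg = 0.3  # skin/core mass weighting
    sw_p = 0.0  # smoothed sweat rate, W/m²
    sw_tot = 0.0
    dlim_tre = dlim_l50 = dlim_l95 = 0

    out_tre = np.empty(duration)
    out_tcr = np.empty(duration)
    out_tsk = np.empty(duration)
    out_swg = np.empty(duration)
    out_loss = np.empty(duration)
    out_store = np.empty(duration)
    out_resid = np.empty(duration)

    for minute in range(1, duration + 1):
        tsk0, tre0, tcr0, tcr_eq0, wg0 = tsk, tre, tcr, tcr_eq, wg

        # core setpoint pulled by the metabolic rate, exponential approach
        tcr_eq_m = 0.0036 * met + 36.6
        tcr_eq = tcr_eq0 * const_teq + tcr_eq_m * (1.0 - const_teq)
        d_store_eq = sp_heat * (tcr_eq - tcr_eq0) * (1.0 - wg0)

        # skin temperature: clothed / nude regressions, blended in Icl
        tsk_eq_cl = (12.165 + 0.02017 * ta + 0.04361 * tr + 0.19354 * pa
                     - 0.25315 * va + 0.005346 * met + 0.51274 * tre)
        tsk_eq_nu = (7.191 + 0.064 * ta + 0.061 * tr + 0.198 * pa
                     - 0.348 * va + 0.616 * tre)
        if ens.icl >= 0.6:
            tsk_eq = tsk_eq_cl
        elif ens.icl <= 0.2:
            tsk_eq = tsk_eq_nu
        else:
            tsk_eq = tsk_eq_nu + 2.5 * (tsk_eq_cl - tsk_eq_nu) * (ens.icl - 0.2)
        tsk = tsk0 * const_tsk + tsk_eq * (1.0 - const_tsk)
        p_sk = saturation_vapour_pressure(tsk)

        # dry heat exchange: solve the clothing surface temperature
        hc_dyn = max(2.38 * abs(tsk - ta) ** 0.25, z)
        tcl = tr + 0.1
        while True:
            if abs(tcl - tr) > 1e-12:
                h_r = f_cl_r * aux_r * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4) / (tcl - tr)
            else:
                h_r = f_cl_r * aux_r * 4.0 * (tr + 273.0) ** 3
            tcl_new = ((fcl * (hc_dyn * ta + h_r * tr) + tsk / itot_dyn_si)
                       / (fcl * (hc_dyn + h_r) + 1.0 / itot_dyn_si))
            if abs(tcl - tcl_new) <= 0.001:
                break
            tcl = (tcl + tcl_new) / 2.0

        conv = fcl * hc_dyn * (tcl - ta)
        rad = fcl * h_r * (tcl - tr)

        e_max = (p_sk - pa) / rt_dyn

        # respiratory heat losses
        c_res = 0.001516 * met * (t_exp - ta)
        e_res = 0.00127 * met * (59.34 + 0.53 * ta - 11.63 * pa)

        # evaporation required to close the balance
        e_req = met - d_store_eq - work - c_res - e_res - conv - rad

        if e_req <= 0.0:
            e_req = 0.0
            sw_req = 0.0
        elif e_max <= 0.0:
            e_max = 0.0
            sw_req = sw_max
        else:
            w_req = e_req / e_max
            if w_req >= 1.7:
                sw_req = sw_max
            else:
                # evaporative efficiency of a partly wet skin
                eff = 1.0 - w_req**2 / 2.0 if w_req <= 1.0 else (2.0 - w_req) ** 2 / 2.0
                sw_req = min(e_req / eff, sw_max)

        sw_p = sw_p * const_sw + sw_req * (1.0 - const_sw)
        if sw_p <= 0.0:
            e_p = 0.0
            sw_p = 0.0
        else:
            k = e_max / sw_p
            wp = 1.0
            if k >= 0.5:
                wp = -k + math.sqrt(k * k + 2.0)
            wp = min(wp, w_max)
            e_p = wp * e_max

        d_storage = e_req - e_p + d_store_eq

        # core temperature through the skin/core weighting (implicit in Tcr)
        tcr_1 = tcr0
        while True:
            wg = min(max(0.3 - 0.09 * (tcr_1 - 36.8), 0.1), 0.3)
            tcr_new = (d_storage / sp_heat + tsk0 * wg0 / 2.0 - tsk * wg / 2.0
                       + tcr0 * (1.0 - wg0 / 2.0)) / (1.0 - wg / 2.0)
            if abs(tcr_new - tcr_1) <= 0.001:
                break
            tcr_1 = (tcr_1 + tcr_new) / 2.0
        tcr = tcr_new

        tre = tre0 + (2.0 * tcr - 1.962 * tre0 - 1.31) / 9.0
        if not math.isfinite(tre) or not math.isfinite(tsk):
            raise ArithmeticError(f"simulation diverged at minute {minute}")
        if dlim_tre == 0 and tre >= TRE_LIMIT:
            dlim_tre = minute

        # water loss: sweat + respiratory evaporation, W/m²·min → g
        sw_tot += sw_p + e_res
        sw_tot_g = sw_tot * 2.67 * adu / 1.8 / 60.0
        if dlim_l50 == 0 and sw_tot_g >= dmax50:
            dlim_l50 = minute
        if dlim_l95 == 0 and sw_tot_g >= dmax95:
            dlim_l95 = minute

        i = minute - 1
        out_tre[i] = tre
        out_tcr[i] = tcr
        out_tsk[i] = tsk
        out_swg[i] = sw_p * 2.67 * adu / 1.8  # g/h
        out_loss[i] = sw_tot_g
        out_store[i] = d_storage
        out_resid[i] = d_storage - (met - work - c_res - e_res - conv - rad - e_p)

    return PHSResult(
        minutes=np.arange(1, duration + 1),
        tre=out_tre,
        tcr=out_tcr,
        tsk=out_tsk,
        sweat_rate=out_swg,
        water_loss=out_loss,
        storage=out_store,
        balance_residual=out_resid,
        dlim_tre=dlim_tre or duration,
        dlim_loss95=dlim_l95 or duration,
        dlim_loss50=dlim_l50 or duration,
        duration=duration,
        algorithm=algorithm.value,
        use_measured_vw=use_measured_vw,
        clothing=dyn,
    )
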
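"""Scenario registry, algorithm comparison grids and the exposure matrix.

The nine exposure scenarios (one light-clothing, six normal-clothing, two
cold-protective-clothing conditions on a treadmill in a climate chamber) ship
with the package: all of their inputs — basic insulation, static evaporative
resistance, permeability index, air temperature, vapour pressure, air and
walking speed, metabolic rate, duration — are published values.

Two analysis products are built on top:

* :func:`comparison_grid` evaluates the correction algorithms over a factorial
  grid of air speed × walking speed × basic insulation and tabulates the
  pairwise percent differences between ISO 9920 and ISO 7933.
* :func:`run_matrix` runs the PHS simulation for every scenario × algorithm ×
  walking-speed-mode combination and collects the duration limits.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .clothing import (
    Algorithm,
    Category,
    ClothingEnsemble,
    Kinematics,
    LEWIS_CONSTANT,
    dynamic_clothing,
    dynamic_insulation,
)
from .phs import ScenarioInput, Subject, simulate

logger = logging.getLogger(__name__)

#: Factorial comparison grid: ambient air speeds and walking speeds, m/s.
GRID_VA = (0.5, 1.0, 3.0)
GRID_VW = (0.4, 0.8, 1.2)
#: Basic-insulation subsets per category, clo.
GRID_ICL = {
    Category.NC: (0.6, 0.8, 1.0),
    Category.SC: (1.5, 2.0),
    Category.LC: (0.2, 0.4),
}
#: Single representative insulation per category for the evaporative grid, clo.
GRID_ICL_EVAP = {Category.LC: 0.4, Category.NC: 1.0, Category.SC: 2.0}
#: Default permeability index for synthetic grid ensembles (work clothing).
GRID_IMT = 0.38

#: Algorithms applicable per category (LU was fitted on light clothing only).
ALGORITHMS_BY_CATEGORY = {
    Category.NC: (Algorithm.ISO7933, Algorithm.ISO9920),
    Category.SC: (Algorithm.ISO7933, Algorithm.ISO9920),
    Category.LC: (Algorithm.ISO7933, Algorithm.ISO9920, Algorithm.LU),
}

_SUBJECT_NC_SC = Subject(height=1.78, weight=80.0)
_SUBJECT_LC = Subject(height=1.76, weight=77.0)

# label, icl (clo), rt_static (m²·kPa/W), imt, ta (°C), pw (kPa), va (m/s),
# vw (m/s), met (W/m²), duration (min)
_TABLE_ROWS = [
    ("LC",   0.48, 0.0198, 0.49, 30, 2.0, 0.33, 1.25, 163, 70),
    ("NC-1", 0.63, 0.0257, 0.43, 20, 2.0, 0.33, 1.25, 169, 70),
    ("NC-2", 0.63, 0.0257, 0.43, 40, 2.2, 0.33, 1.25, 171, 70),
    ("NC-3", 1.08, 0.0421, 0.36, 20, 2.0, 0.33, 1.25, 163, 70),
    ("NC-4", 1.08, 0.0421, 0.37, 40, 3.3, 0.33, 1.25, 155, 70),
    ("NC-5", 1.11, 0.0745, 0.21, 20, 2.0, 0.33, 1.25, 167, 70),
    ("NC-6", 1.11, 0.0745, 0.21, 30, 2.0, 0.33, 1.25, 175, 70),
    ("SC-1", 2.01, 0.1224, 0.20, 30, 2.0, 0.33, 1.25, 190, 70),
    ("SC-2", 2.01, 0.1224, 0.20, 40, 2.2, 0.33, 1.25, 190, 70),
]


def _build_scenario(row) -> ScenarioInput:
    label, icl, rt, imt, ta, pw, va, vw, met, dur = row
    ens = ClothingEnsemble(icl=icl, rt_static=rt, imt=imt, label=label)
    subj = _SUBJECT_LC if ens.category is Category.LC else _SUBJECT_NC_SC
    return ScenarioInput(
        label=label, ensemble=ens, ta=ta, pw=pw, va=va, met=met,
        duration=dur, vw_measured=vw, subject=subj,
    )


def standard_scenarios() -> list[ScenarioInput]:
    """The nine packaged exposure scenarios."""
    return [_build_scenario(r) for r in _TABLE_ROWS]


def get_scenario(label: str) -> ScenarioInput:
    for row in _TABLE_ROWS:
        if row[0] == label:
            return _build_scenario(row)
    raise KeyError(f"unknown scenario {label!r}; known: {[r[0] for r in _TABLE_ROWS]}")


def percent_difference(value: float, baseline: float) -> float:
    """Percent difference relative to the ISO 7933 (incumbent) baseline."""
    return 100.0 * (value - baseline) / baseline


def _grid_ensemble(icl: float, category: Category) -> ClothingEnsemble:
    """Synthetic grid ensemble: static evaporative resistance is tied to the
    insulation through the Lewis relation at the default permeability index."""
    itot_si = (icl + 0.716 / (1 + 0.3 * icl)) * 0.155
    rt_static = itot_si / (LEWIS_CONSTANT * GRID_IMT)
    return ClothingEnsemble(
        icl=icl, rt_static=rt_static, imt=GRID_IMT, category=category,
    )


def comparison_grid(
    category: Category | str,
    quantity: str = "insulation",
    vas: Sequence[float] = GRID_VA,
    vws: Sequence[float] = GRID_VW,
) -> pd.DataFrame:
    """Algorithm comparison over the factorial kinematics grid.

    For ``quantity="insulation"`` every algorithm applicable to the category
    is evaluated at each (icl, va, vw) point and the dynamic clothing
    insulation Icl,dyn is tabulated; for ``quantity="evaporative_resistance"``
    the dynamic total evaporative resistance Rt,dyn is tabulated for the
    category's single representative insulation.  The relative air velocity
    follows the omni-directional walking rule var = max(va, vw).

    Returns a tidy frame with one row per grid point, one value column per
    algorithm, and ``pct_diff_9920_vs_7933`` (signed, ISO 7933 baseline).
    """
    category = Category(category)
    if quantity == "insulation":
        icls = GRID_ICL[category]
    elif quantity == "evaporative_resistance":
        icls = (GRID_ICL_EVAP[category],)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    algorithms = ALGORITHMS_BY_CATEGORY[category]
    rows = []
    for icl in icls:
        ens = _grid_ensemble(icl, category)
        for va in vas:
            for vw in vws:
                kin = Kinematics(va=va, vw=vw)  # var = max(va, vw)
                rec: dict = {"icl_clo": icl, "va_ms": va, "vw_ms": vw}
                for algo in algorithms:
                    dyn = dynamic_clothing(ens, kin, algo)
                    if quantity == "insulation":
                        rec[algo.value] = dyn.icl_dyn
                    else:
                        rec[algo.value] = dyn.rt_dyn
                    rec[f"clamped_{algo.value}"] = dyn.clamped
                rec["pct_diff_9920_vs_7933"] = percent_difference(
                    rec[Algorithm.ISO9920.value], rec[Algorithm.ISO7933.value]
                )
                rows.append(rec)
    return pd.DataFrame(rows)


def grid_summary(grid: pd.DataFrame) -> dict:
    """Min/max absolute percent difference over a comparison grid."""
    pct = grid["pct_diff_9920_vs_7933"].abs()
    imin, imax = pct.idxmin(), pct.idxmax()
    return {
        "max_abs_pct_diff": float(pct[imax]),
        "min_abs_pct_diff": float(pct[imin]),
        "argmax": grid.loc[imax, ["icl_clo", "va_ms", "vw_ms"]].to_dict(),
        "argmin": grid.loc[imin, ["icl_clo", "va_ms", "vw_ms"]].to_dict(),
    }


def run_matrix(
    scenarios: Optional[Iterable[ScenarioInput]] = None,
) -> pd.DataFrame:
    """PHS duration limits for every scenario × algorithm × vw-mode cell.

    Walking-speed modes are ``estimated`` (from the metabolic rate, the
    standard default) and ``measured`` (the recorded treadmill speed).  A
    failing cell is recorded with its error message instead of aborting the
    whole matrix.
    """
    if scenarios is None:
        scenarios = standard_scenarios()
    rows = []
    for sc in scenarios:
        for algo in ALGORITHMS_BY_CATEGORY[sc.ensemble.category]:
            for mode in ("estimated", "measured"):
                rec = {
                    "scenario": sc.label,
                    "algorithm": algo.value,
                    "vw_mode": mode,
                }
                try:
                    res = simulate(sc, algo, use_measured_vw=(mode == "measured"))
                    rec.update(
                        dlim_tre=res.dlim_tre,
                        dlim_loss95=res.dlim_loss95,
                        max_time=res.max_time,
                        final_tre_C=res.final_tre,
                        water_loss_g=res.total_water_loss,
                        error="",
                    )
                except Exception as exc:  # propagate per row, keep the matrix
                    logger.error("matrix cell %s/%s/%s failed: %s",
                                 sc.label, algo.value, mode, exc)
                    rec.update(
                        dlim_tre=float("nan"),
                        dlim_loss95=float("nan"),
                        max_time=float("nan"),
                        final_tre_C=float("nan"),
                        water_loss_g=float("nan"),
                        error=str(exc),
                    )
                rows.append(rec)
    return pd.DataFrame(rows)
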
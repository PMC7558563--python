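"""Validation metrics for physiological time series.

A model trajectory is compared against an observed one with the root mean
square deviation (goodness of fit) and the bias (mean signed error, measured
minus predicted).  The fit is conventionally called acceptable when the rmsd
is smaller than the standard deviation of the observations themselves; the
first minutes of an exposure are discarded so the arbitrary initial state
does not dominate the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

DEFAULT_BURN_IN = 10


@dataclass(frozen=True)
class EvalMetrics:
    """rmsd/bias summary for one observed-vs-predicted comparison."""

    rmsd: float
    bias: float
    n_points: int
    sd_observed: Optional[float] = None
    accepted: Optional[bool] = None


def rmsd_bias(
    observed: Sequence[float],
    predicted: Sequence[float],
    burn_in: int = DEFAULT_BURN_IN,
    sd_observed: Optional[float] = None,
) -> EvalMetrics:
    """rmsd and bias between two equal-length series.

    The first ``burn_in`` samples are dropped.  Bias uses the
    measured-minus-predicted sign convention, so a positive bias means the
    model under-predicts.  When ``sd_observed`` (the experimental SD) is
    supplied, ``accepted`` records whether rmsd < sd_observed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D series")
    if burn_in < 0 or burn_in >= obs.size:
        raise ValueError(f"burn_in {burn_in} leaves no data (n={obs.size})")
    diff = obs[burn_in:] - pred[burn_in:]
    rmsd = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    accepted = None if sd_observed is None else bool(rmsd < sd_observed)
    return EvalMetrics(
        rmsd=rmsd,
        bias=bias,
        n_points=int(diff.size),
        sd_observed=sd_observed,
        accepted=accepted,
    )
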
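"""Non-compartmental pharmacokinetics: trapezoidal AUC, bioavailability, Cmax/Tmax.

Linear trapezoid throughout, with no terminal-phase extrapolation — the AUC
is the area over the observed sampling window only.  Bioavailability is the
dose-normalized AUC ratio of an extravascular route against intravenous
administration.
"""

from __future__ import annotations

import numpy as np

ROUTES = ("IV", "SC", "PO")


class ConcentrationTimeSeries:
    """Plasma concentration-time profile for one animal and route.

    ``times`` in minutes (strictly increasing, >= 0), ``concentrations`` in
    nM (>= 0), ``dose`` in nmol, ``route`` one of IV/SC/PO.
    """

    def __init__(
        self,
        times,
        concentrations,
        dose: float = 1.0,
        route: str = "IV",
    ) -> None:
        times = np.asarray(times, dtype=float)
        concentrations = np.asarray(concentrations, dtype=float)
        if times.ndim != 1 or times.shape != concentrations.shape:
            raise ValueError("times and concentrations must be 1D and equal length")
        if len(times) < 2:
            raise ValueError("need at least 2 samples")
        if times[0] < 0 or (np.diff(times) <= 0).any():
            raise ValueError("times must be strictly increasing and start >= 0")
        if (concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")
        if route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if not dose > 0:
            raise ValueError("dose must be > 0")
        self.times = times
        self.concentrations = concentrations
        self.dose = dose
        self.route = route


def auc_trapezoid(series: ConcentrationTimeSeries) -> float:
    """Area under the concentration-time curve by the linear trapezoidal rule, nM·min."""
    return float(np.trapezoid(series.concentrations, series.times))


def bioavailability(
    test: ConcentrationTimeSeries, iv: ConcentrationTimeSeries
) -> float:
    """Absolute bioavailability F = (AUC_test / dose_test) / (AUC_iv / dose_iv).

    Raises
    ------
    ValueError
        If the IV AUC is zero.
    """
    auc_iv = auc_trapezoid(iv)
    if auc_iv == 0:
        raise ValueError("IV AUC is zero: bioavailability undefined")
    return (auc_trapezoid(test) / test.dose) / (auc_iv / iv.dose)


def cmax_tmax(series: ConcentrationTimeSeries) -> tuple[float, float]:
    """Peak observed concentration and its sample time (earliest on ties)."""
    i = int(np.argmax(series.concentrations))
    return float(series.concentrations[i]), float(series.times[i])
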
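"""Steady-state dose-response curves and the critical stimulus dose.

The executioner caspase's steady state as a function of the clamped TNF-α
dose is all-or-none: a low (survival) plateau and a high (apoptosis) plateau
separated by a critical dose Cd.  Cd is located by a coarse bracketing scan
followed by bisection on the fate classification.  All steady states start
from the common resting initial condition; no hysteresis sweep is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ReactionNetwork, SolverOptions

DEFAULT_DOSE_MAX = 1e-2  # amol; the in-vitro-equivalent stimulus range is 0..1e-2

__all__ = [
    "DEFAULT_DOSE_MAX",
    "DoseResponseCurve",
    "CriticalDoseResult",
    "NoSwitchError",
    "DegenerateModelError",
    "scan_doses",
    "classify_fate",
    "find_critical_dose",
    "steady_state_cached",
    "clear_steady_state_cache",
]


class NoSwitchError(RuntimeError):
    """The dose-response curve has no distinguishable low/high plateaus."""


class DegenerateModelError(RuntimeError):
    """The model is already apoptotic at dose 0; no critical dose exists."""


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    executioner_ss: np.ndarray
    converged_flags: np.ndarray
    low_plateau: float
    high_plateau: float
    executioner_id: str
    has_switch: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_amol": self.doses,
             f"{self.executioner_id}_steady_state_amol": self.executioner_ss,
             "converged": self.converged_flags}
        )


@dataclass
class CriticalDoseResult:
    cd: float | None
    bracket: tuple[float, float] | None
    apoptosis_achievable: bool
    dose_max: float
    low_plateau: float = np.nan
    high_plateau: float = np.nan


# Steady states are deterministic in (network content, dose, solver settings);
# caching makes the ~2 x n_parameters critical-dose searches of a sensitivity
# spectrum tractable.
_SS_CACHE: dict[tuple, tuple[np.ndarray, bool]] = {}
_SS_CACHE_MAX = 200_000


def clear_steady_state_cache() -> None:
    _SS_CACHE.clear()


def steady_state_cached(
    network: ReactionNetwork, dose: float, opts: SolverOptions
) -> tuple[np.ndarray, bool]:
    key = (network.content_hash(), float(dose), opts.ss_tol, opts.t_max, opts.rtol)
    hit = _SS_CACHE.get(key)
    if hit is not None:
        return hit
    res = network.steady_state(dose, solver_opts=opts)
    if len(_SS_CACHE) > _SS_CACHE_MAX:  # pragma: no cover - safety valve
        _SS_CACHE.clear()
    _SS_CACHE[key] = (res.state, res.converged)
    return _SS_CACHE[key]


def scan_doses(
    network: ReactionNetwork,
    dose_grid: np.ndarray,
    executioner_id: str,
    solver_opts: SolverOptions | None = None,
) -> DoseResponseCurve:
    """Steady-state executioner level at each dose, with plateau estimates.

    A switch is declared when the largest single inter-dose jump of the
    (converged) curve covers at least half of the curve's total range — an
    all-or-none response concentrates essentially all of its rise in the jump
    across the critical dose, whereas a smooth sub-threshold curve spreads it
    over the whole grid.  The low plateau is the median of the three
    lowest-dose points; the high plateau is the median of the (up to three)
    highest-dose points beyond the jump.  Non-converged points are flagged
    and excluded from plateau estimation.
    """
    opts = solver_opts or SolverOptions()
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(dose_grid < 0):
        raise ValueError("doses must be >= 0")
    idx = network.species_index(executioner_id)
    ss = np.empty_like(dose_grid)
    ok = np.zeros(dose_grid.shape, dtype=bool)
    for i, d in enumerate(dose_grid):
        state, conv = steady_state_cached(network, d, opts)
        ss[i] = state[idx]
        ok[i] = conv
    if ok.sum() < 3:
        raise NoSwitchError("fewer than 3 converged steady states; cannot estimate plateaus")
    order = np.argsort(dose_grid[ok])
    vals = ss[ok][order]
    low = float(np.median(vals[:3]))
    jumps = np.diff(vals)
    rng = float(vals.max() - vals.min())
    has_switch = bool(rng > 0 and jumps.size > 0 and jumps.max() >= 0.5 * rng)
    if has_switch:
        j = int(np.argmax(jumps))
        high = float(np.median(vals[j + 1:][-3:]))
        has_switch = high >= 2.0 * low
    if not has_switch:
        high = float(np.median(vals[-3:]))
    return DoseResponseCurve(doses=dose_grid, executioner_ss=ss, converged_flags=ok,
                             low_plateau=low, high_plateau=high,
                             executioner_id=executioner_id, has_switch=has_switch)


def classify_fate(executioner_ss: float, low_plateau: float, high_plateau: float) -> str:
    """'apoptosis' iff the steady level reaches the midpoint of the two plateaus.

    The tie (exactly at the midpoint) counts as apoptosis.  Plateaus closer
    than a factor of two are treated as indistinguishable (no switch).
    """
    if high_plateau < 2.0 * low_plateau:
        raise NoSwitchError(
            f"plateaus indistinguishable (low={low_plateau:.3g}, high={high_plateau:.3g})"
        )
    mid = 0.5 * (low_plateau + high_plateau)
    return "apoptosis" if executioner_ss >= mid else "survival"


def _fate_at(network, dose, executioner_id, low, high, opts) -> str:
    state, _ = steady_state_cached(network, dose, opts)
    return classify_fate(state[network.species_index(executioner_id)], low, high)


def find_critical_dose(
    network: ReactionNetwork,
    executioner_id: str,
    dose_max: float = DEFAULT_DOSE_MAX,
    tol: float | None = None,
    solver_opts: SolverOptions | None = None,
    coarse_points: int = 12,
    plateaus: tuple[float, float] | None = None,
    initial_bracket: tuple[float, float] | None = None,
) -> CriticalDoseResult:
    """Locate the critical dose by coarse bracketing plus bisection.

    ``plateaus`` and ``initial_bracket`` let callers that already know the
    base model's response (e.g. the one-at-a-time sensitivity protocol) skip
    the coarse scan; the bracket is validated and expanded if the perturbed
    switch moved outside it.
    """
    opts = solver_opts or SolverOptions()
    if tol is None:
        tol = dose_max / 2000.0

    if plateaus is None:
        grid = np.concatenate([[0.0], np.geomspace(dose_max / 300.0, dose_max,
                                                   coarse_points)])
        curve = scan_doses(network, grid, executioner_id, opts)
        if not curve.has_switch:
            return CriticalDoseResult(cd=None, bracket=None, apoptosis_achievable=False,
                                      dose_max=dose_max, low_plateau=curve.low_plateau,
                                      high_plateau=curve.high_plateau)
        low, high = curve.low_plateau, curve.high_plateau
        fates = [classify_fate(v, low, high) for v in curve.executioner_ss]
        if fates[0] == "apoptosis":
            raise DegenerateModelError("model is apoptotic at dose 0")
        apo = [i for i, f in enumerate(fates) if f == "apoptosis"]
        if not apo:
            return CriticalDoseResult(cd=None, bracket=None, apoptosis_achievable=False,
                                      dose_max=dose_max, low_plateau=low, high_plateau=high)
        i_hi = apo[0]
        lo, hi = grid[i_hi - 1], grid[i_hi]
    else:
        low, high = plateaus
        if _fate_at(network, 0.0, executioner_id, low, high, opts) == "apoptosis":
            raise DegenerateModelError("model is apoptotic at dose 0")
        lo, hi = initial_bracket if initial_bracket is not None else (0.0, dose_max)
        hi = min(hi, dose_max)
        # validate / expand the proposed bracket
        if lo > 0 and _fate_at(network, lo, executioner_id, low, high, opts) == "apoptosis":
            lo = 0.0
        while _fate_at(network, hi, executioner_id, low, high, opts) == "survival":
            if hi >= dose_max:
                return CriticalDoseResult(cd=None, bracket=None,
                                          apoptosis_achievable=False,
                                          dose_max=dose_max,
                                          low_plateau=low, high_plateau=high)
            lo, hi = hi, min(2.0 * hi, dose_max)

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fate_at(network, mid, executioner_id, low, high, opts) == "apoptosis":
            hi = mid
        else:
            lo = mid
    return CriticalDoseResult(cd=hi, bracket=(lo, hi), apoptosis_achievable=True,
                              dose_max=dose_max, low_plateau=low, high_plateau=high)
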
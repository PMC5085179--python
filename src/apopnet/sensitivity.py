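"""One-at-a-time parameter sensitivity of the critical dose.

Each kinetic parameter is perturbed by ±20% (default) from its reference
value and the critical dose Cd is recomputed for both directions.  Only
*increases* of Cd are recorded (an increased apoptosis threshold is the
oncogenically relevant direction): ΔCd is the larger of the two increases, or
zero if neither direction raises Cd.  A parameter is *sensitive* when
ΔCd ≥ 10%·Cd (default cutoff).  A perturbation that abolishes apoptosis
within the dose range altogether is treated as an unbounded Cd increase and
is always sensitive.

``cutoff_roc`` justifies the cutoff choice: sweeping the cutoff over the
observed relative ΔCd values against an external Boolean truth (e.g. a
mutation spectrum) yields ROC points and Youden's J = TPR − FPR per cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import (
    DEFAULT_DOSE_MAX,
    CriticalDoseResult,
    find_critical_dose,
)
from .network import ReactionNetwork, SolverOptions
from .spectra import BooleanSpectrum

__all__ = [
    "SensitivityConfig",
    "SensitivityRecord",
    "SensitivitySpectrum",
    "RocResult",
    "UndefinedRocError",
    "perturb",
    "single_parameter_sensitivity",
    "build_spectrum",
    "multi_parameter_delta",
    "cutoff_roc",
]

UNBOUNDED = math.inf


class UndefinedRocError(ValueError):
    """All truth labels equal; TPR or FPR is undefined at every cutoff."""


@dataclass
class SensitivityConfig:
    perturb_fraction: float = 0.20
    sensitive_cutoff: float = 0.10
    dose_max: float = DEFAULT_DOSE_MAX
    tol: float | None = None
    executioner_id: str = "C3"
    solver_opts: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if not 0 < self.perturb_fraction < 1:
            raise ValueError("perturb_fraction must be in (0, 1)")
        if not 0 < self.sensitive_cutoff < 1:
            raise ValueError("sensitive_cutoff must be in (0, 1)")


@dataclass
class SensitivityRecord:
    parameter_id: str
    cd_base: float
    cd_up: float  # Cd after k * (1 + f); UNBOUNDED if apoptosis is lost
    cd_down: float  # Cd after k * (1 - f)
    delta_cd: float  # max(0, max(cd_up, cd_down) - cd_base)
    relative_delta: float
    sensitive: bool
    increasing_direction: str | None = None  # 'up', 'down' or None (no increase)
    error: str | None = None


@dataclass
class SensitivitySpectrum:
    parameter_ids: list[str]
    flags: np.ndarray
    records: list[SensitivityRecord]

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.parameter_ids) != len(self.flags) != len(self.records):
            raise ValueError("parameter_ids, flags and records must align")

    def as_boolean_spectrum(self) -> BooleanSpectrum:
        return BooleanSpectrum(list(self.parameter_ids), self.flags.copy(),
                               provenance="sensitivity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"parameter_id": r.parameter_id, "cd_base": r.cd_base,
                 "cd_up": r.cd_up, "cd_down": r.cd_down,
                 "relative_delta": r.relative_delta, "sensitive": r.sensitive,
                 "error": r.error}
                for r in self.records
            ]
        )


def perturb(network: ReactionNetwork, parameter_id: str, factor: float) -> ReactionNetwork:
    """Copy of the network with one rate constant scaled by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if parameter_id not in network.parameters:
        raise KeyError(f"unknown parameter {parameter_id!r}")
    return network.with_parameter_value(
        parameter_id, factor * network.parameters[parameter_id].value
    )


def _cd_of(network, config: SensitivityConfig, base: CriticalDoseResult | None) -> float:
    kwargs = {}
    if base is not None and base.apoptosis_achievable:
        kwargs["plateaus"] = (base.low_plateau, base.high_plateau)
        lo, hi = base.bracket
        kwargs["initial_bracket"] = (lo / 2.0, min(hi * 2.0, config.dose_max))
    res = find_critical_dose(network, config.executioner_id,
                             dose_max=config.dose_max, tol=config.tol,
                             solver_opts=config.solver_opts, **kwargs)
    return res.cd if res.apoptosis_achievable else UNBOUNDED


def _base_cd(network, config) -> CriticalDoseResult:
    res = find_critical_dose(network, config.executioner_id, dose_max=config.dose_max,
                             tol=config.tol, solver_opts=config.solver_opts)
    if not res.apoptosis_achievable:
        raise RuntimeError("base model has no finite critical dose within dose_max")
    return res


def single_parameter_sensitivity(
    network: ReactionNetwork,
    parameter_id: str,
    config: SensitivityConfig | None = None,
    base: CriticalDoseResult | None = None,
) -> SensitivityRecord:
    """±perturb_fraction one-at-a-time sensitivity of the critical dose."""
    config = config or SensitivityConfig()
    if base is None:
        base = _base_cd(network, config)
    f = config.perturb_fraction
    cd_up = _cd_of(perturb(network, parameter_id, 1.0 + f), config, base)
    cd_down = _cd_of(perturb(network, parameter_id, 1.0 - f), config, base)
    best = max(cd_up, cd_down)
    delta = max(0.0, best - base.cd)
    direction = None
    if delta > 0:
        direction = "up" if cd_up >= cd_down else "down"
    rel = delta / base.cd
    return SensitivityRecord(
        parameter_id=parameter_id, cd_base=base.cd, cd_up=cd_up, cd_down=cd_down,
        delta_cd=delta, relative_delta=rel,
        sensitive=bool(rel >= config.sensitive_cutoff),
        increasing_direction=direction,
    )


def build_spectrum(
    network: ReactionNetwork,
    parameter_ids: list[str] | None = None,
    config: SensitivityConfig | None = None,
) -> SensitivitySpectrum:
    """Sensitivity record for every parameter, in the given (or model) order.

    A failure on one parameter is recorded on that parameter and the run
    continues.
    """
    config = config or SensitivityConfig()
    pids = list(parameter_ids) if parameter_ids is not None else network.parameter_ids
    base = _base_cd(network, config)
    records = []
    for pid in pids:
        try:
            records.append(single_parameter_sensitivity(network, pid, config, base))
        except Exception as exc:  # noqa: BLE001 - per-parameter isolation
            records.append(SensitivityRecord(
                parameter_id=pid, cd_base=base.cd, cd_up=math.nan, cd_down=math.nan,
                delta_cd=math.nan, relative_delta=math.nan, sensitive=False,
                error=f"{type(exc).__name__}: {exc}",
            ))
    return SensitivitySpectrum(
        parameter_ids=pids,
        flags=np.array([r.sensitive for r in records], dtype=bool),
        records=records,
    )


def multi_parameter_delta(
    network: ReactionNetwork,
    parameter_ids: list[str],
    config: SensitivityConfig | None = None,
) -> float:
    """Relative Cd change when several parameters are perturbed simultaneously.

    Each parameter moves by ±perturb_fraction in its own single-parameter
    Cd-increasing direction (ties and no-increase default to 'up').  Duplicate
    ids are applied once.  Returns (Cd_pert − Cd_base)/Cd_base; +inf if the
    joint perturbation abolishes apoptosis.
    """
    config = config or SensitivityConfig()
    if len(parameter_ids) < 2:
        raise ValueError("need at least 2 parameter ids")
    base = _base_cd(network, config)
    seen: dict[str, None] = {}
    for pid in parameter_ids:
        seen.setdefault(pid)
    net = network
    f = config.perturb_fraction
    for pid in seen:
        rec = single_parameter_sensitivity(network, pid, config, base)
        factor = (1.0 - f) if rec.increasing_direction == "down" else (1.0 + f)
        net = perturb(net, pid, factor)
    cd = _cd_of(net, config, base)
    if cd is UNBOUNDED or math.isinf(cd):
        return math.inf
    return (cd - base.cd) / base.cd


@dataclass
class RocResult:
    table: pd.DataFrame  # columns: cutoff, tpr, fpr, youden
    best_cutoff: float
    best_youden: float


def cutoff_roc(records: list[SensitivityRecord], truth_labels: np.ndarray) -> RocResult:
    """ROC of the rule ``sensitive iff relative_delta >= cutoff`` against a
    Boolean truth vector, with Youden's J per cutoff.

    Ties in J are broken toward the smaller cutoff (the more inclusive rule).
    """
    from sklearn.metrics import roc_curve

    truth = np.asarray(truth_labels, dtype=bool)
    if len(truth) != len(records):
        raise ValueError("truth_labels must align with records")
    if truth.all() or not truth.any():
        raise UndefinedRocError("truth labels are all equal; ROC undefined")
    scores = np.array([r.relative_delta for r in records], dtype=float)
    finite_max = np.nanmax(np.where(np.isinf(scores), np.nan, scores))
    if np.isnan(finite_max):
        finite_max = 1.0
    scores = np.where(np.isinf(scores), 10.0 * (finite_max + 1.0), scores)
    fpr, tpr, thresholds = roc_curve(truth.astype(int), scores)
    youden = tpr - fpr
    tbl = pd.DataFrame({"cutoff": thresholds, "tpr": tpr, "fpr": fpr, "youden": youden})
    best_j = youden.max()
    best_cut = tbl.loc[np.isclose(tbl["youden"], best_j), "cutoff"].min()
    return RocResult(table=tbl, best_cutoff=float(best_cut), best_youden=float(best_j))
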
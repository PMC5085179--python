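"""Candidate caspase→NFκB feedback loops: injection, phenotype, HD scans.

A positive loop contributes production of the target driven by the source
caspase (+k_positive·[caspase]); a negative loop contributes bimolecular
degradation (−k_negative·[caspase]·[NFκB]).  The two loop types leave distinct
fingerprints on the apoptotic phenotype at a supra-critical probe dose:
negative feedback shortens the initial death time, positive feedback lowers
the executioner's steady level.  Admissible strength ranges keep that
phenotype within 20% of the unmodified model, and a Hamming-distance scan
over strengths asks whether the modified model's sensitivity spectrum agrees
better with a mutation spectrum than the original does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import ExtraRateTerm, ReactionNetwork, SolverOptions
from .sensitivity import SensitivityConfig, build_spectrum
from .spectra import BooleanSpectrum, hamming

__all__ = [
    "FeedbackSpec",
    "ApoptosisMetrics",
    "StrengthRange",
    "HDScan",
    "inject",
    "apoptosis_metrics",
    "calibrate_range",
    "hd_strength_scan",
    "default_strength_grid",
]

CASPASE_ROLES = ("caspase3_active", "caspase6_active", "caspase8_active")
DEFAULT_PROBE_DOSE = 1e-2  # amol; a supra-critical sustained stimulus


@dataclass(frozen=True)
class FeedbackSpec:
    source_role: str  # one of CASPASE_ROLES
    sign: str  # 'positive' or 'negative'
    strength: float  # k_positive (1/s) or k_negative (1/(amol*s))
    target_role: str = "nfkb_active"

    def __post_init__(self):
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass
class ApoptosisMetrics:
    initial_death_time: float  # seconds; nan if apoptosis does not occur
    steady_level: float  # executioner steady state at the probe dose (amol)
    probe_dose: float
    apoptotic: bool


@dataclass
class StrengthRange:
    lo: float
    hi: float
    metric: str  # 'initial_death_time' (negative loop) or 'steady_level' (positive)
    limit_fraction: float


@dataclass
class HDScan:
    strengths: np.ndarray
    hd_values: np.ndarray  # int; -1 marks a failed strength point
    baseline_hd: int
    errors: dict[float, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strength": self.strengths, "hd": self.hd_values})

    @property
    def min_hd_strength(self) -> float:
        """Strength minimizing HD; a tied plateau returns its (geometric) middle
        grid point."""
        ok = self.hd_values >= 0
        vals = self.hd_values[ok]
        sts = self.strengths[ok]
        ties = np.where(vals == vals.min())[0]
        return float(sts[ties[len(ties) // 2]])


def inject(
    network: ReactionNetwork,
    spec: FeedbackSpec,
    key_species_map: dict[str, str],
) -> ReactionNetwork:
    """Copy of the network with the feedback term added to the target balance."""
    try:
        source = key_species_map[spec.source_role]
        target = key_species_map[spec.target_role]
    except KeyError as exc:
        raise ValueError(f"role {exc} not resolved by the key-species map") from None
    term = ExtraRateTerm(source=source, target=target, sign=spec.sign,
                         strength=spec.strength)
    return network.with_extra_terms([term])


def apoptosis_metrics(
    network: ReactionNetwork,
    probe_dose: float,
    executioner_id: str,
    fate_threshold: float,
    solver_opts: SolverOptions | None = None,
) -> ApoptosisMetrics:
    """Initial death time and steady executioner level at a probe dose.

    The initial death time is the first time the executioner crosses 50% of
    its own final steady level, located by the integrator's event detection
    (root-found to solver precision).  If the steady level stays below
    ``fate_threshold`` (the survival/apoptosis midpoint of the base model),
    the probe is flagged non-apoptotic and the death time is NaN.
    """
    from scipy.integrate import solve_ivp

    opts = solver_opts or SolverOptions()
    ss = network.steady_state(probe_dose, solver_opts=opts)
    level = float(ss.state[network.species_index(executioner_id)])
    if not ss.converged or level < fate_threshold:
        return ApoptosisMetrics(initial_death_time=math.nan, steady_level=level,
                                probe_dose=probe_dose, apoptotic=False)
    half = 0.5 * level
    idx = network.species_index(executioner_id)

    def crossing(t, y):
        return y[idx] - half

    crossing.terminal = True
    crossing.direction = 1
    y0 = network.initial_state()
    y0[network.species_index(network.input_species_id)] = probe_dose
    sol = solve_ivp(lambda t, y: network._derivative_raw(y), (0.0, ss.t_reached),
                    y0, method=opts.method, rtol=opts.rtol, atol=opts.atol,
                    jac=lambda t, y: network._jacobian(y), events=crossing)
    if sol.t_events[0].size:
        t_cross = float(sol.t_events[0][0])
    else:  # crossed only in the final approach to the settled horizon
        t_cross = float(sol.t[-1])
    return ApoptosisMetrics(initial_death_time=t_cross, steady_level=level,
                            probe_dose=probe_dose, apoptotic=True)


def default_strength_grid(
    lo_decade: int, hi_decade: int, points_per_decade: int = 5
) -> np.ndarray:
    """Log-spaced strength grid spanning [10**lo_decade, 10**hi_decade]."""
    n = (hi_decade - lo_decade) * points_per_decade + 1
    return np.geomspace(10.0 ** lo_decade, 10.0 ** hi_decade, n)


def calibrate_range(
    network: ReactionNetwork,
    spec_template: FeedbackSpec,
    key_species_map: dict[str, str],
    executioner_id: str,
    fate_threshold: float,
    scan_grid: np.ndarray,
    limit_fraction: float = 0.20,
    probe_dose: float = DEFAULT_PROBE_DOSE,
    solver_opts: SolverOptions | None = None,
) -> StrengthRange:
    """Admissible strength interval: the maximal contiguous grid prefix where
    the loop-type's phenotype metric stays within ``limit_fraction`` of the
    unmodified model's value.

    Negative loops are bounded by the initial death time, positive loops by
    the steady executioner level (both only ever decrease with strength).
    """
    base = apoptosis_metrics(network, probe_dose, executioner_id, fate_threshold,
                             solver_opts)
    metric_name = ("initial_death_time" if spec_template.sign == "negative"
                   else "steady_level")
    base_val = getattr(base, metric_name)
    if not base.apoptotic or not math.isfinite(base_val):
        raise RuntimeError("baseline phenotype undefined: probe dose is not apoptotic")
    floor = (1.0 - limit_fraction) * base_val
    hi = None
    for s in np.asarray(scan_grid, dtype=float):
        m = apoptosis_metrics(
            inject(network, replace(spec_template, strength=float(s)), key_species_map),
            probe_dose, executioner_id, fate_threshold, solver_opts)
        val = getattr(m, metric_name)
        if not m.apoptotic or not (val >= floor):
            break
        hi = float(s)
    if hi is None:
        return StrengthRange(lo=0.0, hi=0.0, metric=metric_name,
                             limit_fraction=limit_fraction)
    return StrengthRange(lo=float(scan_grid[0]), hi=hi, metric=metric_name,
                         limit_fraction=limit_fraction)


def hd_strength_scan(
    network: ReactionNetwork,
    spec_template: FeedbackSpec,
    strengths: np.ndarray,
    mutation_spectrum: BooleanSpectrum,
    key_species_map: dict[str, str],
    sens_config: SensitivityConfig | None = None,
) -> HDScan:
    """Hamming distance between the modified model's sensitivity spectrum and a
    parameter-projected mutation spectrum, at each feedback strength.

    The mutation spectrum must already be projected onto parameter ids
    (production parameters dropped); the sensitivity spectrum is restricted to
    the same ids before comparison.  Per-strength failures are recorded and
    the scan continues.
    """
    cfg = sens_config or SensitivityConfig()
    ids = list(mutation_spectrum.ids)

    def spectrum_hd(net: ReactionNetwork) -> int:
        spec = build_spectrum(net, parameter_ids=ids, config=cfg)
        failed = [r.parameter_id for r in spec.records if r.error]
        if failed:
            raise RuntimeError(f"sensitivity failed for {failed}")
        return hamming(spec.as_boolean_spectrum(), mutation_spectrum).hd

    baseline_hd = spectrum_hd(network)
    strengths = np.asarray(strengths, dtype=float)
    hds = np.full(strengths.shape, -1, dtype=int)
    errors: dict[float, str] = {}
    for i, s in enumerate(strengths):
        if s == 0.0:
            hds[i] = baseline_hd
            continue
        try:
            hds[i] = spectrum_hd(
                inject(network, replace(spec_template, strength=float(s)),
                       key_species_map)
            )
        except Exception as exc:  # noqa: BLE001 - per-strength isolation
            errors[float(s)] = f"{type(exc).__name__}: {exc}"
    return HDScan(strengths=strengths, hd_values=hds, baseline_hd=baseline_hd,
                  errors=errors)
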
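"""Free energy estimation from two-ensemble work samples.

Each alchemical transformation between a ligand pair is sampled over a
λ schedule; for every adjacent window pair the forward samples are
U(λ_{k+1})−U(λ_k) evaluated in ensemble k and the reverse samples
U(λ_k)−U(λ_{k+1}) in ensemble k+1.  The window free energy is the Bennett
acceptance ratio (BAR) solution — the statistically optimal two-ensemble
estimator — and a leg (receptor complex or water) is the sum over its
windows.  The binding cycle gives ΔΔG_bind = ΔG_complex − ΔG_water, and
replicate ΔΔG values are aggregated into a mean ± SEM edge estimate.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from . import GAS_CONSTANT_KCAL

__all__ = [
    "Environment",
    "LambdaSchedule",
    "WindowSamples",
    "LegResult",
    "EdgeEstimate",
    "sigmoidal_lambda_schedule",
    "linear_lambda_schedule",
    "bar_window",
    "zwanzig_forward",
    "zwanzig_reverse",
    "leg_free_energy",
    "edge_ddg",
    "aggregate_replicates",
]

DEFAULT_T_KELVIN = 298.0


class Environment(str, enum.Enum):
    RECEPTOR_COMPLEX = "receptor_complex"
    WATER = "water"


@dataclass(frozen=True)
class LambdaSchedule:
    values: tuple[float, ...]
    shape: str = "sigmoidal"

    def __post_init__(self) -> None:
        v = self.values
        if len(v) < 2 or v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing")


def sigmoidal_lambda_schedule(n_windows: int, steepness: float = 4.0) -> LambdaSchedule:
    """λ values denser near the end states than at the midpoint.

    Realized as a scaled inverse-logistic: t ∈ [0,1] is mapped through
    σ(a(2t−1)) and renormalized to span [0,1] exactly.  The schedule is
    symmetric, λ_i + λ_{n−1−i} = 1.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    t = np.linspace(0.0, 1.0, n_windows)
    raw = expit(steepness * (2.0 * t - 1.0))
    lam = (raw - raw[0]) / (raw[-1] - raw[0])
    lam[0], lam[-1] = 0.0, 1.0
    # enforce exact symmetry against floating point drift
    lam = 0.5 * (lam + 1.0 - lam[::-1])
    return LambdaSchedule(values=tuple(float(x) for x in lam), shape="sigmoidal")


def linear_lambda_schedule(n_windows: int) -> LambdaSchedule:
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    return LambdaSchedule(
        values=tuple(float(x) for x in np.linspace(0.0, 1.0, n_windows)),
        shape="linear",
    )


@dataclass(frozen=True)
class WindowSamples:
    """Forward/reverse energy-difference samples for one window pair
    (kcal/mol)."""

    w_forward: np.ndarray
    w_reverse: np.ndarray
    T_kelvin: float = DEFAULT_T_KELVIN

    def __post_init__(self) -> None:
        wf = np.asarray(self.w_forward, dtype=float)
        wr = np.asarray(self.w_reverse, dtype=float)
        object.__setattr__(self, "w_forward", wf)
        object.__setattr__(self, "w_reverse", wr)
        if wf.size == 0 or wr.size == 0:
            raise ValueError("both sample sets must be non-empty")
        if not (np.isfinite(wf).all() and np.isfinite(wr).all()):
            raise ValueError("work samples must be finite")
        if self.T_kelvin <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.T_kelvin


def _bar_function(dg: float, wf: np.ndarray, wr: np.ndarray, rt: float) -> float:
    """Self-consistency residual: Fermi-weighted forward count minus the
    Fermi-weighted reverse count, at offset C = dg − RT·ln(nF/nR).

    The maximum-likelihood balance condition equates the expected
    misclassification counts of the pooled two-ensemble sample; it is
    monotonically increasing in ``dg`` and its root is the BAR estimate.
    """
    n_f, n_r = len(wf), len(wr)
    c = dg - rt * math.log(n_f / n_r)
    return float(expit(-(wf - c) / rt).sum() - expit(-(wr + c) / rt).sum())


def bar_window(
    samples: WindowSamples, tol: float = 1e-7, max_iter: int = 200
) -> tuple[float, float]:
    """Bennett acceptance ratio free energy of one window (kcal/mol).

    Solves the BAR self-consistency equation by bracketed root-finding
    (the residual is monotone in ΔG, and the sample extrema always
    bracket the root).  Returns ``(dg, stderr)`` where the standard error
    comes from Bennett's asymptotic variance estimate.  Degenerate
    constant samples are handled analytically.
    """
    wf, wr, rt = samples.w_forward, samples.w_reverse, samples.rt
    n_f, n_r = len(wf), len(wr)
    log_ratio = rt * math.log(n_f / n_r)

    if np.ptp(wf) == 0.0 and np.ptp(wr) == 0.0 and n_f == n_r:
        # f(x) = f(y) iff x = y for the logistic: closed-form root
        dg = 0.5 * (wf[0] - wr[0])
        return float(dg), 0.0

    lo = float(min(wf.min(), -wr.max())) - 10.0 * rt - abs(log_ratio)
    hi = float(max(wf.max(), -wr.min())) + 10.0 * rt + abs(log_ratio)
    f_lo = _bar_function(lo, wf, wr, rt)
    f_hi = _bar_function(hi, wf, wr, rt)
    for _ in range(60):
        if f_lo < 0.0 < f_hi:
            break
        span = hi - lo
        if f_lo >= 0.0:
            lo -= span
            f_lo = _bar_function(lo, wf, wr, rt)
        if f_hi <= 0.0:
            hi += span
            f_hi = _bar_function(hi, wf, wr, rt)
    else:  # pragma: no cover - cannot happen for finite samples
        raise RuntimeError("failed to bracket the BAR root")

    dg = brentq(
        _bar_function, lo, hi, args=(wf, wr, rt), xtol=tol, maxiter=max_iter
    )

    # Bennett's asymptotic variance from the fitted Fermi weights.
    c = dg - log_ratio
    f_f = expit(-(wf - c) / rt)
    f_r = expit(-(wr + c) / rt)
    var = 0.0
    for f, n in ((f_f, n_f), (f_r, n_r)):
        mean = f.mean()
        if mean > 0:
            var += (np.mean(f**2) / mean**2 - 1.0) / n
    stderr = rt * math.sqrt(max(var, 0.0))
    return float(dg), float(stderr)


def zwanzig_forward(samples: WindowSamples) -> float:
    """One-sided exponential-average (Zwanzig) estimate from the forward
    ensemble; used as an independent bound on BAR."""
    wf, rt = samples.w_forward, samples.rt
    return float(-rt * (logsumexp(-wf / rt) - math.log(len(wf))))


def zwanzig_reverse(samples: WindowSamples) -> float:
    """Negated reverse Zwanzig estimate (same ΔG sign convention as
    forward)."""
    wr, rt = samples.w_reverse, samples.rt
    return float(rt * (logsumexp(-wr / rt) - math.log(len(wr))))


@dataclass
class LegResult:
    environment: Environment
    window_dg: list[float]
    window_stderr: list[float]
    total_dg: float = field(init=False)
    total_stderr: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_dg = float(sum(self.window_dg))
        self.total_stderr = float(
            math.sqrt(sum(s * s for s in self.window_stderr))
        )


def leg_free_energy(
    windows: Sequence[WindowSamples], environment: Environment | str
) -> LegResult:
    """Accumulate BAR window free energies into one transformation leg."""
    if len(windows) == 0:
        raise ValueError("a leg needs at least one window")
    environment = Environment(environment)
    dgs, errs = [], []
    for w in windows:
        dg, err = bar_window(w)
        dgs.append(dg)
        errs.append(err)
    return LegResult(environment=environment, window_dg=dgs, window_stderr=errs)


def edge_ddg(complex_leg: LegResult, water_leg: LegResult) -> float:
    """Relative binding free energy from the thermodynamic cycle:
    ΔΔG_bind = ΔG(complex) − ΔG(water)."""
    if complex_leg.environment is not Environment.RECEPTOR_COMPLEX:
        raise ValueError("first leg must be the receptor-complex leg")
    if water_leg.environment is not Environment.WATER:
        raise ValueError("second leg must be the water leg")
    return complex_leg.total_dg - water_leg.total_dg


@dataclass(frozen=True)
class EdgeEstimate:
    """Replicate-aggregated ΔΔG_bind for one network edge (kcal/mol)."""

    edge: tuple[str, str]
    replicates: tuple[float, ...]
    mean: float
    sem: float

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def aggregate_replicates(
    edge: tuple[str, str], ddg_values: Sequence[float]
) -> EdgeEstimate:
    """Mean ± SEM over parallel replicate ΔΔG values.

    SEM is the sample standard deviation (ddof=1) over √n.  A single
    replicate has undefined dispersion; it is reported as SEM 0 with a
    warning.
    """
    vals = np.asarray(ddg_values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate")
    if vals.size == 1:
        warnings.warn(
            f"edge {edge}: single replicate, SEM undefined (reported as 0)",
            stacklevel=2,
        )
        sem = 0.0
    else:
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return EdgeEstimate(
        edge=tuple(edge),
        replicates=tuple(float(v) for v in vals),
        mean=float(vals.mean()),
        sem=sem,
    )
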
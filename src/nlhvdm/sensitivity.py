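"""Parameter sensitivity: perturbation error ratios and adjacent-model drift.

Two complementary views of how the four kinetic rates shape the solution:

* ``error_ratio`` — re-simulate with one parameter scaled by a factor and
  compare the fit mismatch at a horizon T against the unperturbed mismatch,
  ratio = |x_pert(T) - data(T)| / |x(T) - data(T)|.

* ``khalil_sensitivity`` — the adjacent (variational) model: for parameter p
  the drift E_p(t) of the solution under a unit parameter perturbation solves

      dE/dt = (dF/dx) * E + dF/dp,   E(0) = 0,

  with F the ODE right-hand side (dF/dx = -d here); integrated jointly with
  the base trajectory by RK4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, UndefinedRatioError
from .model import (
    RK4_STEP_DEFAULT,
    GeneKinetics,
    TFActivityProfile,
    _rk4_grid,
    delayed_activity,
    simulate_gene,
)

__all__ = ["SensitivityTrajectory", "error_ratio", "khalil_sensitivity"]

_PARAMS = ("c", "k", "K", "d")


@dataclass
class SensitivityTrajectory:
    """Drift E_p(t) of the solution per unit perturbation of one parameter."""

    parameter: str
    times: np.ndarray
    values: np.ndarray


def _perturbed(kinetics: GeneKinetics, parameter: str, factor: float) -> GeneKinetics:
    if parameter not in _PARAMS:
        raise InvalidParameterError(f"unknown parameter '{parameter}' (expected one of {_PARAMS})")
    kwargs = dict(c=kinetics.c, k=kinetics.k, K=kinetics.K, d=kinetics.d,
                  tau=kinetics.tau, delta=kinetics.delta, n=kinetics.n, m=kinetics.m,
                  w_max=kinetics.w_max, tau_max=kinetics.tau_max)
    kwargs[parameter] = kwargs[parameter] * factor
    return GeneKinetics(**kwargs)


def error_ratio(kinetics: GeneKinetics, profile: TFActivityProfile, x0: float,
                data_at_T: float, T: float, parameter: str, factor: float,
                step: float = RK4_STEP_DEFAULT) -> float:
    """Simulation-error ratio at horizon T under a multiplicative perturbation.

    1 means the perturbation left the fit at T unchanged; > 1 means a worse
    fit.  Raises when the unperturbed simulation matches the datum exactly.
    """
    if factor <= 0:
        raise InvalidParameterError("factor must be > 0")
    times = np.array([0.0, float(T)])
    x_T = simulate_gene(kinetics, profile, x0, times, step=step).values[-1]
    denom = abs(x_T - data_at_T)
    if denom == 0.0:
        raise UndefinedRatioError("exact fit at the horizon; ratio undefined")
    pert = _perturbed(kinetics, parameter, factor)
    x_T_pert = simulate_gene(pert, profile, x0, times, step=step).values[-1]
    return float(abs(x_T_pert - data_at_T) / denom)


def khalil_sensitivity(kinetics: GeneKinetics, profile: TFActivityProfile, x0: float,
                       parameter: str, times: Sequence[float],
                       step: float = RK4_STEP_DEFAULT) -> SensitivityTrajectory:
    """Integrate the adjacent model for one of (c, k, K, d).

    The augmented system (x, E) is advanced with the same fixed-step RK4 as
    the base model; E(0) = 0.  Analytic partials of the right-hand side:
    dF/dc = 1, dF/dk = f, dF/dK = k*(2*delta - 1)*dh/dK, dF/dd = -x.
    """
    if parameter not in _PARAMS:
        raise InvalidParameterError(f"unknown parameter '{parameter}' (expected one of {_PARAMS})")
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise InvalidInputError("need at least two output times")
    h, n_steps, nodes, record_idx = _rk4_grid(t, step)

    c, k, K, d = kinetics.c, kinetics.k, kinetics.K, kinetics.d
    n, m, delta = kinetics.n, kinetics.m, kinetics.delta
    p = np.asarray(delayed_activity(profile, nodes, kinetics.tau), dtype=float)
    r = (p / K) ** n
    g = r / (1.0 + r)
    hill = g**m
    f = delta * hill + (1 - delta) * (1.0 - hill)
    A = c + k * f  # forcing of the base model at every node

    if parameter == "c":
        src = np.ones_like(nodes)
    elif parameter == "k":
        src = f
    elif parameter == "K":
        dh_dK = m * np.where(g > 0, g ** (m - 1), 0.0) * (-n * r / (K * (1.0 + r) ** 2))
        src = k * (2 * delta - 1) * dh_dK
    else:  # d: source is -x, handled stage-wise below
        src = None

    x, E = float(x0), 0.0
    out = np.empty(t.size)
    out[0] = 0.0
    pos, rec = 1, set(record_idx.tolist())
    for j in range(n_steps):
        a = (A[2 * j], A[2 * j + 1], A[2 * j + 1], A[2 * j + 2])
        if parameter == "d":
            s = None
        else:
            s = (src[2 * j], src[2 * j + 1], src[2 * j + 1], src[2 * j + 2])
        # joint RK4 stages for (x, E)
        kx, kE = [], []
        xs, Es = x, E
        for stage, frac in enumerate((0.0, 0.5, 0.5, 1.0)):
            xv = x + frac * h * (kx[-1] if kx else 0.0)
            Ev = E + frac * h * (kE[-1] if kE else 0.0)
            fx = a[stage] - d * xv
            if parameter == "d":
                fE = -d * Ev - xv
            else:
                fE = -d * Ev + s[stage]
            kx.append(fx)
            kE.append(fE)
        x = x + (h / 6.0) * (kx[0] + 2 * kx[1] + 2 * kx[2] + kx[3])
        E = E + (h / 6.0) * (kE[0] + 2 * kE[1] + 2 * kE[2] + kE[3])
        if j in rec:
            out[pos] = E
            pos += 1
    return SensitivityTrajectory(parameter=parameter, times=t, values=out)
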
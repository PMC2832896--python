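"""Joint inference of hidden TF activity and training-gene kinetics.

For N training target genes measured at M time points the unknowns are the
per-gene rates (c_i, k_i, K_i, d_i) and the TF activity values at the M-1
post-stimulus time points (activity at t=0 is pinned at the baseline), i.e.
``4N + (M-1)`` free parameters — 26 for the canonical 5-gene, 7-time-point
design.  The time delay is fixed at zero for training fits.  A real-coded GA
(optionally polished with bounded L-BFGS-B) minimises the summed per-gene
relative squared error

    eps_i = sum_j (u_ij - x_ij)^2 / sum_j x_ij^2,      E = sum_i eps_i,

with u the RK4-simulated and x the measured levels at the post-initial
measurement times.

Identifiability note: the Hill term depends on activity only through p/K, so
(p(t), K_i) are determined jointly up to a common positive scale inside the
unit activity box.  Estimates are canonicalised to unit peak activity (knots
and K divided by the maximum knot value), which leaves the objective exactly
unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset
from .errors import InvalidConfigError, InvalidInputError, UndefinedNormalizationError
from .ga import GASettings, minimize_ga
from .model import (
    RK4_STEP_DEFAULT,
    W_MAX_DEFAULT,
    GeneKinetics,
    TFActivityProfile,
    _rk4_forced_linear,
    _rk4_grid,
)

__all__ = [
    "ActivityCodec",
    "ActivityEstimate",
    "TFActivityEstimator",
    "training_objective",
    "infer_activity",
    "activity_confidence_band",
    "relative_fit_error",
]

logger = logging.getLogger(__name__)

#: Lower bound used for K inside search boxes (K must stay positive).
K_FLOOR = 1e-3


class ActivityCodec:
    """Flat-vector codec for the joint (kinetics, activity-knots) parameter set.

    Layout: ``[c_1, k_1, K_1, d_1, ..., c_N, k_N, K_N, d_N, p_1, ..., p_{M-1}]``
    with the activity at the first time point fixed at the baseline.
    """

    def __init__(self, n_genes: int, times: Sequence[float], w_max=W_MAX_DEFAULT):
        self.n_genes = int(n_genes)
        self.times = np.asarray(times, dtype=float)
        if self.n_genes < 1:
            raise InvalidConfigError("need at least one training gene")
        if self.times.size < 2 or not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing (>= 2 points)")
        self.w_max = tuple(float(w) for w in w_max)
        self.n_knots_free = self.times.size - 1

    @property
    def n_parameters(self) -> int:
        return 4 * self.n_genes + self.n_knots_free

    def bounds(self):
        lb = np.concatenate([
            np.tile([0.0, 0.0, K_FLOOR, 0.0], self.n_genes),
            np.zeros(self.n_knots_free),
        ])
        ub = np.concatenate([
            np.tile(self.w_max, self.n_genes),
            np.ones(self.n_knots_free),
        ])
        return lb, ub

    def decode(self, vector: np.ndarray):
        v = np.asarray(vector, dtype=float)
        if v.shape[-1] != self.n_parameters:
            raise InvalidInputError(f"expected {self.n_parameters} parameters, got {v.shape[-1]}")
        kin = v[..., : 4 * self.n_genes].reshape(*v.shape[:-1], self.n_genes, 4)
        knots = v[..., 4 * self.n_genes :]
        return kin, knots

    def encode(self, kinetics: np.ndarray, knots: np.ndarray) -> np.ndarray:
        kin = np.asarray(kinetics, dtype=float)
        kn = np.asarray(knots, dtype=float)
        return np.concatenate([kin.reshape(*kin.shape[:-2], 4 * self.n_genes), kn], axis=-1)


@dataclass
class ActivityEstimate:
    """Best-of-restarts activity estimate with the spread across runs."""

    profile: TFActivityProfile
    per_gene_kinetics: list
    objective: float
    run_objectives: np.ndarray
    run_knots: np.ndarray = field(repr=False)  # (runs, M) canonicalised knot values
    ci_low: np.ndarray = None
    ci_high: np.ndarray = None
    mean: np.ndarray = None
    seed: int | None = None


def _make_objective(x_meas: np.ndarray, times: np.ndarray, signs: np.ndarray,
                    codec: ActivityCodec, hill_n: int, sites_m: int,
                    step: float, baseline: float):
    """Vectorised training objective over a population matrix.

    The ODE right-hand side is affine in the state, so each candidate's
    forcing A(t) = c + k*f(t) is evaluated once on the RK4 node grid and the
    integration collapses to a cumulative recursion (see model._rk4_forced_linear).

    Returns ``(objective, residuals)``: the population objective and a
    single-vector residual function whose sum of squares equals the objective
    (used by the least-squares polish).
    """
    h, n_steps, nodes, record_idx = _rk4_grid(times, step)
    x0 = x_meas[:, 0]
    x_post = x_meas[:, 1:]
    denom = (x_post**2).sum(axis=1)
    if np.any(denom <= 0):
        raise UndefinedNormalizationError("a training gene has all-zero post-initial measurements")
    lb, ub = codec.bounds()
    delta = signs[None, :, None]  # (1, N, 1)

    def _simulate(pop: np.ndarray) -> np.ndarray:
        P = np.clip(np.atleast_2d(pop), lb, ub)
        kin, knots = codec.decode(P)
        c, k, K, d = (kin[..., i] for i in range(4))
        knot_mat = np.concatenate(
            [np.full((P.shape[0], 1), baseline), knots], axis=1
        )  # (pop, M)
        spline = CubicSpline(times, knot_mat.T, bc_type="natural")
        act = np.clip(spline(nodes), 0.0, 1.0).T  # (pop, nodes)
        p = act[:, None, :]
        r = (p / K[..., None]) ** hill_n
        hill = (r / (1.0 + r)) ** sites_m
        f = delta * hill + (1 - delta) * (1.0 - hill)
        A = c[..., None] + k[..., None] * f
        x0b = np.broadcast_to(x0, (P.shape[0], x0.size))
        xs = _rk4_forced_linear(A, d, h, x0b)  # (pop, N, steps)
        return xs[..., record_idx]

    def objective(pop: np.ndarray) -> np.ndarray:
        u = _simulate(pop)
        eps = ((u - x_post) ** 2).sum(axis=-1) / denom
        return eps.sum(axis=-1)

    def residuals(vector: np.ndarray) -> np.ndarray:
        u = _simulate(vector[None, :])[0]
        return ((u - x_post) / np.sqrt(denom)[:, None]).ravel()

    return objective, residuals


def training_objective(params: np.ndarray, dataset: ExpressionDataset,
                       training_signs: Sequence[int] | None = None,
                       hill_n: int = 4, sites_m: int = 1,
                       step: float = RK4_STEP_DEFAULT, baseline: float = 0.0,
                       w_max=W_MAX_DEFAULT) -> float:
    """Objective value E for one flat parameter vector (GA contract: clamps).

    Out-of-bounds entries are clamped into the search box with a warning,
    never an exception.
    """
    x = dataset.replicate_mean()
    codec = ActivityCodec(dataset.n_probes, dataset.times, w_max=w_max)
    signs = _resolve_signs(training_signs, dataset.n_probes)
    lb, ub = codec.bounds()
    v = np.asarray(params, dtype=float)
    if np.any(v < lb) or np.any(v > ub):
        warnings.warn("parameter vector outside the search box; clamped", stacklevel=2)
    obj, _ = _make_objective(x, dataset.times, signs, codec, hill_n, sites_m, step, baseline)
    return float(obj(v[None, :])[0])


def _resolve_signs(training_signs, n: int) -> np.ndarray:
    if training_signs is None:
        return np.ones(n, dtype=int)
    signs = np.asarray(training_signs, dtype=int)
    if signs.size != n or not set(np.unique(signs)) <= {0, 1}:
        raise InvalidConfigError("training_signs must give one delta in {0,1} per gene")
    return signs


def _canonicalise(knots: np.ndarray, kin: np.ndarray):
    """Rescale to unit peak activity; K scales with the activity (p/K gauge)."""
    peak = knots.max()
    if peak <= 0:
        return knots, kin
    kin = kin.copy()
    kin[:, 2] = np.maximum(kin[:, 2] / peak, K_FLOOR)
    return knots / peak, kin


class TFActivityEstimator(BaseEstimator):
    """Infer a hidden TF activity profile from training target genes.

    scikit-learn style estimator: ``fit(dataset)`` runs ``restarts``
    independent GA searches (sub-seed = random_state + run index) and exposes
    the best run as ``profile_`` / ``kinetics_`` / ``objective_`` plus a
    percentile confidence band over runs.

    Parameters
    ----------
    restarts : independent GA restarts per fitted time course.
    mode : "mean" fits the replicate-averaged course; "per-replicate" fits each
        replicate separately (restarts x replicates runs in total).
    training_signs : per-gene regulation direction delta in {0,1}; defaults to
        all induced (the canonical positively-regulated training panel).
    normalize_peak : canonicalise runs to unit peak activity (see module note).
    """

    def __init__(self, restarts: int = 10, random_state: int = 0,
                 ga: GASettings | None = None, mode: str = "mean",
                 training_signs=None, hill_n: int = 4, sites_m: int = 1,
                 step: float = RK4_STEP_DEFAULT, w_max=W_MAX_DEFAULT,
                 baseline: float = 0.0, normalize_peak: bool = True):
        self.restarts = restarts
        self.random_state = random_state
        self.ga = ga
        self.mode = mode
        self.training_signs = training_signs
        self.hill_n = hill_n
        self.sites_m = sites_m
        self.step = step
        self.w_max = w_max
        self.baseline = baseline
        self.normalize_peak = normalize_peak

    # -- fitting ------------------------------------------------------------

    def fit(self, X: ExpressionDataset, y=None, training_ids: Sequence[str] | None = None):
        if self.restarts < 1:
            raise InvalidConfigError("restarts must be >= 1")
        if self.mode not in ("mean", "per-replicate"):
            raise InvalidConfigError("mode must be 'mean' or 'per-replicate'")
        ds = X.subset(training_ids) if training_ids is not None else X
        if ds.n_times < 2:
            raise InvalidInputError("need at least two time points")
        codec = ActivityCodec(ds.n_probes, ds.times, w_max=self.w_max)
        signs = _resolve_signs(self.training_signs, ds.n_probes)
        ga = self.ga or GASettings()

        courses = ([ds.replicate_mean()] if self.mode == "mean"
                   else [ds.values[:, :, r] for r in range(ds.n_replicates)])
        lb, ub = codec.bounds()
        run_objs, run_knots, run_kin, results = [], [], [], []
        run_id = 0
        for x_meas in courses:
            obj, resid = _make_objective(x_meas, ds.times, signs, codec,
                                         self.hill_n, self.sites_m, self.step, self.baseline)
            for _ in range(self.restarts):
                seed = int(self.random_state) + run_id  # sub-seed = master + j
                res = minimize_ga(obj, lb, ub, settings=ga,
                                  rng=np.random.default_rng(seed), residuals=resid)
                kin, knots = codec.decode(res.x)
                knots = np.concatenate([[self.baseline], knots])
                if self.normalize_peak:
                    knots, kin = _canonicalise(knots, kin)
                run_objs.append(res.fun)
                run_knots.append(knots)
                run_kin.append(kin)
                results.append(res)
                run_id += 1

        run_objs = np.asarray(run_objs)
        run_knots = np.asarray(run_knots)
        best = int(np.argmin(run_objs))
        kin = run_kin[best]
        profile = TFActivityProfile(ds.times, run_knots[best], baseline_value=self.baseline)
        kinetics = [
            GeneKinetics(c=row[0], k=row[1], K=max(row[2], K_FLOOR), d=row[3],
                         tau=0.0, delta=int(s), n=self.hill_n, m=self.sites_m,
                         w_max=self.w_max)
            for row, s in zip(kin, signs)
        ]
        mean, lo, hi = activity_confidence_band(run_knots)
        self.codec_ = codec
        self.n_parameters_ = codec.n_parameters
        self.profile_ = profile
        self.kinetics_ = kinetics
        self.objective_ = float(run_objs[best])
        self.run_objectives_ = run_objs
        self.ga_results_ = results
        self.estimate_ = ActivityEstimate(
            profile=profile, per_gene_kinetics=kinetics, objective=self.objective_,
            run_objectives=run_objs, run_knots=run_knots,
            ci_low=lo, ci_high=hi, mean=mean, seed=int(self.random_state),
        )
        return self

    def predict(self, times) -> np.ndarray:
        """Evaluate the fitted activity profile at arbitrary times."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "profile_")
        return np.asarray(self.profile_.value(np.asarray(times, dtype=float)))


def infer_activity(dataset: ExpressionDataset, training_ids: Sequence[str] | None = None,
                   config: GASettings | None = None, restarts: int = 10,
                   seed: int = 0, mode: str = "mean", **kwargs) -> ActivityEstimate:
    """Functional wrapper over :class:`TFActivityEstimator`."""
    est = TFActivityEstimator(restarts=restarts, random_state=seed, ga=config,
                              mode=mode, **kwargs)
    est.fit(dataset, training_ids=training_ids)
    return est.estimate_


def activity_confidence_band(run_knots: np.ndarray):
    """Per-knot mean and percentile (2.5/97.5) band across runs."""
    runs = np.atleast_2d(np.asarray(run_knots, dtype=float))
    if runs.shape[0] < 2:
        warnings.warn("confidence band from a single run collapses to the point")
        m = runs.mean(axis=0)
        return m, m.copy(), m.copy()
    mean = runs.mean(axis=0)
    lo = np.percentile(runs, 2.5, axis=0)
    hi = np.percentile(runs, 97.5, axis=0)
    return mean, lo, hi


def relative_fit_error(estimate, reference) -> float:
    """Relative squared error sum((p_hat - p)^2) / sum(p^2) over the knots."""
    if isinstance(estimate, ActivityEstimate):
        p_hat = estimate.profile.knot_values
    elif isinstance(estimate, TFActivityProfile):
        p_hat = estimate.knot_values
    else:
        p_hat = np.asarray(estimate, dtype=float)
    p = np.asarray(reference, dtype=float)
    if p.shape != p_hat.shape:
        raise InvalidInputError("estimate and reference must share the knot grid")
    denom = float((p**2).sum())
    if denom == 0.0:
        raise UndefinedNormalizationError("all-zero reference activity")
    return float(((p_hat - p) ** 2).sum() / denom)
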
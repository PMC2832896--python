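"""Expression preprocessing: centring, z-scores, responsiveness screening.

The pipeline mirrors standard two-colour-era time-course practice: each array
(one time point x replicate column) is median-centred, probes are transformed
to z-scores across all arrays, and a pairwise Fisher's-linear-discriminant
statistic against the pre-stimulus baseline ranks probes by responsiveness;
the top fraction (15% by default) enters the dynamic model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset
from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "ProbeScore",
    "median_center",
    "zscore",
    "fisher_pairwise_score",
    "score_dataset",
    "select_top",
    "ResponsiveProbeSelector",
]

logger = logging.getLogger(__name__)


@dataclass
class ProbeScore:
    probe_id: str
    score: float
    rank: int
    selected: bool


def median_center(dataset: ExpressionDataset) -> ExpressionDataset:
    """Subtract each array's median so every time x replicate column has median 0."""
    values = dataset.values - np.median(dataset.values, axis=0, keepdims=True)
    return ExpressionDataset(list(dataset.probe_ids), dataset.times.copy(), values,
                             list(dataset.gene_symbols) if dataset.gene_symbols else None)


def zscore(dataset: ExpressionDataset) -> ExpressionDataset:
    """Per-probe z-scores across all arrays; zero-variance probes are dropped."""
    flat = dataset.values.reshape(dataset.n_probes, -1)
    sd = flat.std(axis=1)  # population sd
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance probe(s)", n_dropped)
    mean = flat[keep].mean(axis=1, keepdims=True)
    z = (flat[keep] - mean) / sd[keep, None]
    ids = [p for p, k in zip(dataset.probe_ids, keep) if k]
    genes = ([g for g, k in zip(dataset.gene_symbols, keep) if k]
             if dataset.gene_symbols else None)
    return ExpressionDataset(ids, dataset.times.copy(),
                             z.reshape(-1, dataset.n_times, dataset.n_replicates), genes)


def fisher_pairwise_score(row: np.ndarray, baseline_index: int = 0,
                          all_pairs: bool = False) -> float:
    """Responsiveness of one probe: max pairwise Fisher discriminant ratio.

    For each post-baseline time point t the discriminant against the baseline
    is ``(mean_t - mean_0)^2 / (var_t + var_0)`` across replicates (sample
    variances); the score is the maximum over t.  With ``all_pairs`` the
    maximum runs over every pair of time points instead.  Two zero-variance
    groups score 0 when their means agree and +inf otherwise.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 2 or row.shape[1] < 2:
        raise InvalidInputError("need a (time, replicate) matrix with >= 2 replicates")
    means = row.mean(axis=1)
    var = row.var(axis=1, ddof=1)
    T = row.shape[0]
    if all_pairs:
        pairs = [(i, j) for i in range(T) for j in range(i + 1, T)]
    else:
        pairs = [(baseline_index, t) for t in range(T) if t != baseline_index]
    best = 0.0
    for i, j in pairs:
        num = (means[j] - means[i]) ** 2
        den = var[i] + var[j]
        if den == 0.0:
            score = 0.0 if num == 0.0 else math.inf
        else:
            score = num / den
        best = max(best, score)
    return best


def score_dataset(dataset: ExpressionDataset, baseline_index: int = 0,
                  all_pairs: bool = False) -> dict:
    return {
        pid: fisher_pairwise_score(dataset.values[i], baseline_index, all_pairs)
        for i, pid in enumerate(dataset.probe_ids)
    }


def select_top(scores: dict, fraction: float = 0.15) -> list:
    """Top ceil(fraction * n) probes by score; ties break on probe id."""
    if not 0 < fraction <= 1:
        raise InvalidConfigError("fraction must lie in (0, 1]")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    n_sel = math.ceil(fraction * len(items))
    return [
        ProbeScore(probe_id=pid, score=sc, rank=i + 1, selected=i < n_sel)
        for i, (pid, sc) in enumerate(items)
    ]


class ResponsiveProbeSelector(BaseEstimator):
    """Centre, z-score and keep the most stimulus-responsive probes.

    ``fit`` computes Fisher scores on the centred/z-scored data;
    ``transform`` returns the preprocessed dataset restricted to the selected
    probes (in score order).
    """

    def __init__(self, fraction: float = 0.15, baseline_index: int = 0,
                 all_pairs: bool = False, center: bool = True, standardize: bool = True):
        self.fraction = fraction
        self.baseline_index = baseline_index
        self.all_pairs = all_pairs
        self.center = center
        self.standardize = standardize

    def _prepare(self, X: ExpressionDataset) -> ExpressionDataset:
        ds = median_center(X) if self.center else X
        return zscore(ds) if self.standardize else ds

    def fit(self, X: ExpressionDataset, y=None):
        ds = self._prepare(X)
        scores = score_dataset(ds, self.baseline_index, self.all_pairs)
        self.scores_ = select_top(scores, self.fraction)
        self.selected_ids_ = [s.probe_id for s in self.scores_ if s.selected]
        return self

    def transform(self, X: ExpressionDataset) -> ExpressionDataset:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selected_ids_")
        return self._prepare(X).subset(
            [p for p in self.selected_ids_])

    def fit_transform(self, X: ExpressionDataset, y=None) -> ExpressionDataset:
        return self.fit(X).transform(X)
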
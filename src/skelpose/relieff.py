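"""Multi-class ReliefF feature weighting and selection.

ReliefF scores each feature by how well it separates nearest neighbors
of the same class ("hits") from nearest neighbors of every other class
("misses").  For each of m sampled instances x with class c, and each
feature a, the weight update is

    W[a] -= sum_hits   diff(a, x, hit)  / (m * k)
    W[a] += sum_{c' != c} [ P(c') / (1 - P(c)) ] *
            sum_misses diff(a, x, miss_{c'}) / (m * k)

where diff is the absolute difference after scaling every feature to
[0, 1] range and the k nearest neighbors are found under the Manhattan
metric on the scaled features.  Features that carry class structure end
up with large positive weights; pure-noise features hover near zero.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data


class ReliefF(SelectorMixin, BaseEstimator):
    """ReliefF feature weighting, as a scikit-learn selector.

    Parameters
    ----------
    n_features_to_select : int, default=10
        How many top-ranked features :meth:`transform` keeps.
    n_neighbors : int, default=10
        k — nearest hits per instance, and nearest misses per other class.
    n_samples : int or None, default=None
        m — instances sampled for updates.  None uses every row
        (deterministic); otherwise sampling is without replacement,
        driven by ``random_state``.
    random_state : int, RandomState or None
        Controls instance sampling only.

    Attributes
    ----------
    weights_ : (n_features,) ndarray
        ReliefF weight per feature (higher = more relevant).
    ranking_ : (n_features,) ndarray
        Feature indices sorted by descending weight.
    """

    def __init__(self, n_features_to_select: int = 10, n_neighbors: int = 10,
                 n_samples: int | None = None, random_state=None):
        self.n_features_to_select = n_features_to_select
        self.n_neighbors = n_neighbors
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        n, p = X.shape
        k = self.n_neighbors
        classes, counts = np.unique(y, return_counts=True)
        for cls, cnt in zip(classes, counts):
            if cnt < k + 1:
                raise ValueError(
                    f"class {cls!r} has only {cnt} rows; ReliefF with "
                    f"k={k} needs at least {k + 1} per class")
        priors = {cls: cnt / n for cls, cnt in zip(classes, counts)}

        # diff() works on features scaled to [0, 1] range; constant
        # features get range 1 so their diff is identically zero.
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        Xs = (X - lo) / span

        rng = check_random_state(self.random_state)
        if self.n_samples is None or self.n_samples >= n:
            sample_idx = np.arange(n)
        else:
            sample_idx = rng.choice(n, size=self.n_samples, replace=False)
        m = len(sample_idx)

        by_class = {cls: np.flatnonzero(y == cls) for cls in classes}
        nn = {cls: NearestNeighbors(n_neighbors=min(k + 1, len(idx)),
                                    metric="manhattan").fit(Xs[idx])
              for cls, idx in by_class.items()}

        W = np.zeros(p)
        for cls in classes:
            mask = np.isin(sample_idx, by_class[cls])
            rows = sample_idx[mask]
            if len(rows) == 0:
                continue
            Q = Xs[rows]
            # hits: k nearest same-class neighbors, self excluded
            _, hit_local = nn[cls].kneighbors(Q)
            hit_global = by_class[cls][hit_local]
            for i, row in enumerate(rows):
                hits = hit_global[i][hit_global[i] != row][:k]
                W -= np.abs(Xs[row] - Xs[hits]).sum(axis=0) / (m * k)
            # misses: k nearest neighbors in each other class, weighted
            # by that class's prior (normalized over the non-self mass)
            for other in classes:
                if other == cls:
                    continue
                factor = priors[other] / (1.0 - priors[cls])
                _, miss_local = nn[other].kneighbors(Q, n_neighbors=min(k, len(by_class[other])))
                miss_global = by_class[other][miss_local]
                diffs = np.abs(Q[:, None, :] - Xs[miss_global]).sum(axis=(0, 1))
                W += factor * diffs / (m * k)
        self.weights_ = W
        self.ranking_ = np.argsort(-W, kind="stable")
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(len(self.weights_), dtype=bool)
        mask[self.ranking_[: self.n_features_to_select]] = True
        return mask


def relieff_rank(X, y, k_neighbors: int = 10, m_samples: int | None = None,
                 seed: int | None = None):
    """Functional wrapper: returns ``(weights, ranking)`` arrays."""
    sel = ReliefF(n_neighbors=k_neighbors, n_samples=m_samples,
                  random_state=seed).fit(X, y)
    return sel.weights_, sel.ranking_
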
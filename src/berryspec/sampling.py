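"""Sample partitioning: repeated stratified splits for classification,
PLS-based outlier screening and SPXY partitioning for regression.

SPXY selects a representative calibration set by Kennard-Stone-style maximin
selection on a joint distance that normalizes and adds the Euclidean
predictor distance and the response distance:
``d(i,j) = dX(i,j)/max(dX) + dy(i,j)/max(dy)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, cross_val_predict

__all__ = ["SplitIndices", "class_stratified_split", "pls_outlier_removal", "spxy_split"]


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index sets for one repeat."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    repeat_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        if (
            sets[0] & sets[1]
            or sets[0] & sets[2]
            or sets[1] & sets[2]
        ):
            raise ValueError("train/validation/test sets must be pairwise disjoint")


def class_stratified_split(
    labels: np.ndarray,
    n_val_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
    repeat_id: int = 0,
) -> SplitIndices:
    """Per class, draw validation then test indices uniformly without
    replacement; the remainder is the training set.

    At the full study scale (204 samples per class, 34 validation and 34 test
    per class) this yields the 136/34/34 per-class partition.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_val_per_class + n_test_per_class:
            raise ValueError(
                f"class {cls} has {idx.size} samples, fewer than "
                f"n_val+n_test = {n_val_per_class + n_test_per_class}"
            )
        perm = rng.permutation(idx)
        val.append(perm[:n_val_per_class])
        test.append(perm[n_val_per_class : n_val_per_class + n_test_per_class])
        train.append(perm[n_val_per_class + n_test_per_class :])
    return SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
        test=np.sort(np.concatenate(test)),
        repeat_id=repeat_id,
        seed=seed,
    )


def pls_outlier_removal(
    X: np.ndarray,
    y: np.ndarray,
    k: float = 3.0,
    n_components: int | None = None,
    n_splits: int = 5,
    n_rounds: int = 2,
    max_removed_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag samples whose cross-validated PLS prediction residual is extreme.

    A PLS regression of y on X is fit with K-fold cross-validation; samples
    whose studentized CV residual exceeds ``k`` standard deviations are
    flagged.  The screen is repeated once on the retained set (``n_rounds=2``
    by default: one initial pass plus one iteration).

    Returns ``(retained_indices, flagged_indices)``, both sorted.  Raises if
    more than ``max_removed_fraction`` of the samples would be removed
    (screening should trim a few gross outliers, not reshape the set).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length must match")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for outlier screening")
    if np.allclose(X.std(axis=0), 0):
        raise np.linalg.LinAlgError("X has zero variance; PLS is degenerate")

    retained = np.arange(X.shape[0])
    flagged: list[int] = []
    for _ in range(max(1, n_rounds)):
        Xr, yr = X[retained], y[retained]
        ncomp = n_components or min(10, Xr.shape[1], Xr.shape[0] - 2)
        pls = PLSRegression(n_components=ncomp, scale=True)
        cv = KFold(n_splits=min(n_splits, Xr.shape[0]), shuffle=False)
        y_cv = cross_val_predict(pls, Xr, yr, cv=cv).ravel()
        resid = yr - y_cv
        sd = resid.std(ddof=1)
        if not np.isfinite(k) or sd == 0:
            break
        bad = np.abs(resid - resid.mean()) > k * sd
        if not bad.any():
            break
        flagged.extend(retained[bad].tolist())
        retained = retained[~bad]
    flagged_arr = np.sort(np.array(flagged, dtype=int))
    if flagged_arr.size > max_removed_fraction * X.shape[0]:
        raise RuntimeError(
            f"outlier screen flagged {flagged_arr.size} of {X.shape[0]} samples "
            f"(> {max_removed_fraction:.0%}); check the data or the threshold"
        )
    return retained, flagged_arr


def _joint_distance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    dX = squareform(pdist(X, metric="euclidean"))
    dy = squareform(pdist(y.reshape(-1, 1), metric="euclidean"))
    mX, my = dX.max(), dy.max()
    if mX == 0 and my == 0:
        raise ValueError("all samples identical in X and y; SPXY distance undefined")
    out = np.zeros_like(dX)
    if mX > 0:
        out += dX / mX
    if my > 0:
        out += dy / my
    return out


def spxy_split(
    X: np.ndarray,
    y: np.ndarray,
    n_train: int,
    n_val: int,
    n_test: int,
) -> SplitIndices:
    """SPXY partition: maximin (Kennard-Stone) training selection on the
    joint X/y distance; the held-out samples are ranked by their distance to
    the training set (descending) and assigned alternately to validation and
    test, which keeps the two held-out sets distributionally balanced.

    Fully deterministic; ties break to the lowest index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n_train + n_val + n_test > n:
        raise ValueError(f"requested {n_train + n_val + n_test} samples from {n}")
    if n_train < 2:
        raise ValueError("SPXY needs at least 2 training samples")
    d = _joint_distance(X, y)

    # initialize with the pair at maximal joint distance (lowest indices on ties)
    flat = np.argmax(d)  # argmax scans row-major -> lowest (i, j) pair wins ties
    i, j = np.unravel_index(flat, d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [r for r in range(n) if r not in selected]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_train:
        cand = remaining[int(np.argmax(min_dist[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, d[cand])
    train = np.sort(np.array(selected))

    rest = np.array(remaining)
    # distance of each held-out sample to the training set, most distant first;
    # stable ordering so equal distances keep index order
    dist_to_train = d[np.ix_(rest, train)].min(axis=1)
    order = rest[np.argsort(-dist_to_train, kind="stable")]
    val, test = [], []
    take_val = True
    for idx in order:
        if take_val and len(val) < n_val:
            val.append(idx)
        elif len(test) < n_test:
            test.append(idx)
        elif len(val) < n_val:
            val.append(idx)
        take_val = not take_val
        if len(val) >= n_val and len(test) >= n_test:
            break
    return SplitIndices(
        train=train,
        validation=np.sort(np.array(val, dtype=int)),
        test=np.sort(np.array(test, dtype=int)),
    )
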
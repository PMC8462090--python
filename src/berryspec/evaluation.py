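"""Metrics and statistics: confusion matrices, overall accuracy, R2/RMSE,
ANOVA across repeated runs, and grouped summaries with compact significance
letters (Tukey HSD)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ConfusionMatrix",
    "RegressionMetrics",
    "confusion_matrix",
    "overall_accuracy",
    "regression_metrics",
    "anova_across_repeats",
    "group_stats_letters",
]

N_CLASSES = 4


@dataclass
class ConfusionMatrix:
    """4x4 count grid; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    set_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected a {N_CLASSES}x{N_CLASSES} matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [f"D{i + 1}" for i in range(N_CLASSES)]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class RegressionMetrics:
    """R2 and RMSE for one sample set."""

    r2: float
    rmse: float
    set_tag: str = ""


def confusion_matrix(true_labels: np.ndarray, predicted_labels: np.ndarray, set_tag: str = "") -> ConfusionMatrix:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for v in (t, p):
        if v.size and (v.min() < 0 or v.max() >= N_CLASSES):
            raise ValueError(f"labels must be in 0..{N_CLASSES - 1}")
    counts = _sk_confusion(t, p, labels=np.arange(N_CLASSES))
    return ConfusionMatrix(counts.astype(int), set_tag=set_tag)


def overall_accuracy(matrix: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 x trace / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(matrix.counts)) / matrix.total


def regression_metrics(measured: np.ndarray, predicted: np.ndarray, set_tag: str = "") -> RegressionMetrics:
    """R2 = 1 - SSres/SStot and RMSE = sqrt(mean squared error)."""
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValueError("need equal-length vectors with at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured values have zero variance; R2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return RegressionMetrics(r2=1.0 - ss_res / ss_tot, rmse=rmse, set_tag=set_tag)


def anova_across_repeats(accuracy_table: np.ndarray | pd.DataFrame, alpha: float = 0.01) -> dict:
    """One-way ANOVA comparing models across repeated runs.

    ``accuracy_table`` has one column per model (e.g. 1D vs 3D) and one row
    per repeat (pooled over sets, or per-set tables can be passed
    separately).  Returns F, p and whether the difference is significant at
    ``alpha`` (default 0.01).
    """
    table = pd.DataFrame(accuracy_table)
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise ValueError("need >= 2 models and >= 2 repeats")
    groups = [table[c].to_numpy(dtype=float) for c in table.columns]
    if any(g.std() == 0 for g in groups) and all(g.std() == 0 for g in groups) and all(
        np.allclose(g, groups[0]) for g in groups
    ):
        return {"F": 0.0, "p": 1.0, "significant": False, "alpha": alpha}
    f_stat, p_val = stats.f_oneway(*groups)
    return {"F": float(f_stat), "p": float(p_val), "significant": bool(p_val < alpha), "alpha": alpha}


def _compact_letters(group_names: list[str], means: dict[str, float], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Maximal cliques of the graph whose edges join statistically
    indistinguishable groups each get one letter, assigned in descending
    order of the clique's best mean; a group's letters are those of the
    cliques containing it.
    """
    g = nx.Graph()
    g.add_nodes_from(group_names)
    g.add_edges_from(nonsig)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters = {name: "" for name in group_names}
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_idx)
        for member in clique:
            letters[member] += letter
    return {name: "".join(sorted(v)) for name, v in letters.items()}


def group_stats_letters(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group mean +/- SD with compact significance letters.

    One-way ANOVA followed by Tukey HSD pairwise comparisons at ``alpha``;
    groups that are not significantly different share a letter.  Letters are
    ordered so that 'a' tags the highest-mean clique (the convention used in
    fruit-quality tables, where e.g. the two lowest, mutually similar classes
    share 'c' while the top class gets 'a').
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValueError("values and groups must have equal length")
    names = [str(gn) for gn in pd.unique(groups)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {str(gn): values[groups == gn] for gn in pd.unique(groups)}
    if any(v.size < 2 for v in per_group.values()):
        raise ValueError("every group needs >= 2 values")
    if all(np.allclose(v.std(ddof=1), 0) for v in per_group.values()):
        raise ValueError("all groups have zero variance; comparisons are degenerate")

    tukey = pairwise_tukeyhsd(values, groups.astype(str), alpha=alpha)
    nonsig: set[tuple[str, str]] = set()
    res = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    for _, row in res.iterrows():
        if not bool(row["reject"]):
            nonsig.add((str(row["group1"]), str(row["group2"])))
    means = {name: float(v.mean()) for name, v in per_group.items()}
    letters = _compact_letters(names, means, nonsig)
    out = pd.DataFrame(
        {
            "group": names,
            "n": [per_group[n].size for n in names],
            "mean": [means[n] for n in names],
            "sd": [float(per_group[n].std(ddof=1)) for n in names],
            "letters": [letters[n] for n in names],
        }
    )
    return out.sort_values("group").reset_index(drop=True)
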
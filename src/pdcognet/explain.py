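"""Model explainability: Shapley attributions and masking-based importance.

Three complementary procedures interrogate a trained classifier:

* **Shapley values** of the coalition game v(S) = P(Impaired | features
  outside S replaced by background), computed exactly by subset enumeration
  for small feature counts and by Monte-Carlo permutation sampling in
  general. The background is all-zeros, i.e. the per-feature means after
  standardization, which makes the three methods commensurable.
* **Group-wise masking**: zero one group's columns (equivalent to replacing
  the standardized features by their means), re-predict without retraining,
  and record the change in Impaired-class recall (ΔRecall = masked −
  baseline; large negative = important).
* **Brute-force combinatorial masking**: the same recall measurement for
  every subset of groups of size 1..max_size (default 5), enumerated in
  deterministic lexicographic order and reported sorted by ascending recall.

For n_groups = 20 and max_size = 5 the subset count is
sum_{k=1..5} C(20,k) = 21,699.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd

from . import network as net
from .evaluation import confusion_from_predictions
from .preprocessing import GroupMap

__all__ = [
    "ValueFunctionConfig",
    "AttributionResult",
    "shapley_exact",
    "shapley_sampling",
    "group_mask_delta_recall",
    "combo_mask_recall",
    "n_subsets",
    "aggregate_mean_abs_by_group",
]

#: exact enumeration cost is 2^d model evaluations per subject
MAX_EXACT_FEATURES = 15


@dataclass(frozen=True)
class ValueFunctionConfig:
    """Configuration of the attribution value function.

    The target is fixed as the predicted probability of the Impaired class;
    ``background`` gives the per-feature replacement values for coalitions a
    feature does not join (default all zeros = post-standardization means).
    """

    n_permutations: int = 200
    seed: int = 0
    background: np.ndarray | None = None

    def resolve_background(self, d: int) -> np.ndarray:
        if self.background is None:
            return np.zeros(d)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (d,):
            raise ValueError(f"background length {bg.shape} != feature count {d}")
        return bg


@dataclass
class AttributionResult:
    """Per-subject per-feature Shapley estimates and their global summary."""

    phi: pd.DataFrame  # subjects x features
    mean_abs: pd.Series  # per-feature mean |phi| across subjects
    ranking: list[str]  # features sorted by mean_abs, descending


def _masked_value(params, x, masks, background):
    """v(S) for each boolean row of ``masks``: features in S keep x, the rest
    take the background value."""
    X = np.where(masks, x, background)
    return net.predict_proba_impaired(params, X)


def shapley_exact(
    params: net.NetworkParams,
    x: np.ndarray,
    config: ValueFunctionConfig | None = None,
) -> np.ndarray:
    """Exact Shapley values by enumeration of all feature coalitions.

    Satisfies efficiency: sum_i phi_i = v(full) - v(empty). Guarded to
    <= 15 features; use :func:`shapley_sampling` beyond that.
    """
    config = config or ValueFunctionConfig()
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{d} features exceeds the enumeration guard ({MAX_EXACT_FEATURES}); "
            "use shapley_sampling"
        )
    background = config.resolve_background(d)
    n_sets = 1 << d
    codes = np.arange(n_sets)
    masks = (codes[:, None] >> np.arange(d)) & 1  # subset bitmask -> bool rows
    values = _masked_value(params, x, masks.astype(bool), background)
    sizes = masks.sum(axis=1)

    # w(s) = s! (d-1-s)! / d!  for the subset S (not containing i) of size s
    w = np.array(
        [factorial(s) * factorial(d - 1 - s) / factorial(d) for s in range(d)]
    )
    phi = np.zeros(d)
    for i in range(d):
        bit = 1 << i
        without = codes[(codes & bit) == 0]
        gain = values[without | bit] - values[without]
        phi[i] = np.sum(w[sizes[without]] * gain)
    return phi


def shapley_sampling(
    params: net.NetworkParams,
    X: np.ndarray,
    config: ValueFunctionConfig | None = None,
    feature_names: list[str] | None = None,
) -> AttributionResult:
    """Monte-Carlo Shapley estimates over random feature orderings.

    For each subject and each sampled permutation, features are added one by
    one and each feature is credited its marginal change in P(Impaired); the
    estimate is the average over permutations, an unbiased estimator of the
    exact Shapley value. Deterministic given the seed.
    """
    config = config or ValueFunctionConfig()
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    background = config.resolve_background(d)
    names = feature_names or [f"f{i}" for i in range(d)]
    n_perm = config.n_permutations

    phi = np.zeros((n, d))
    for s in range(n):
        rng = np.random.default_rng((config.seed, s))
        orders = np.array([rng.permutation(d) for _ in range(n_perm)])
        # masks[p, j, :] = features present after adding the first j of perm p
        masks = np.zeros((n_perm, d + 1, d), dtype=bool)
        for j in range(d):
            masks[:, j + 1, :] = masks[:, j, :]
            masks[np.arange(n_perm), j + 1, orders[:, j]] = True
        values = _masked_value(
            params, X[s], masks.reshape(-1, d), background
        ).reshape(n_perm, d + 1)
        marginals = np.diff(values, axis=1)  # contribution of j-th added feature
        contrib = np.zeros(d)
        np.add.at(contrib, orders.ravel(), marginals.ravel())
        phi[s] = contrib / n_perm

    phi_df = pd.DataFrame(phi, columns=names)
    mean_abs = phi_df.abs().mean(axis=0)
    ranking = mean_abs.sort_values(ascending=False, kind="mergesort").index.tolist()
    return AttributionResult(phi=phi_df, mean_abs=mean_abs, ranking=ranking)


def aggregate_mean_abs_by_group(mean_abs: pd.Series, groups: GroupMap) -> pd.Series:
    """Sum per-feature mean-|phi| over each group's (reduced) columns."""
    if groups.reduced_entries is None:
        raise ValueError("group map has no reduced_entries")
    return pd.Series(
        {g: float(mean_abs[cols].sum()) for g, cols in groups.reduced_entries.items()}
    )


def _recall_with_mask(params, X, y_true, cols_idx, threshold):
    X_masked = np.asarray(X, dtype=float).copy()
    if len(cols_idx):
        X_masked[:, cols_idx] = 0.0
    pred = net.predict(params, X_masked, threshold)
    c = confusion_from_predictions(y_true, pred)
    return c.TP / (c.TP + c.FN) if c.TP + c.FN else float("nan")


def _group_indices(groups: GroupMap, columns: list[str]) -> dict[str, np.ndarray]:
    if groups.reduced_entries is None:
        raise ValueError("group map has no reduced_entries; run groupwise_pca")
    col_pos = {c: i for i, c in enumerate(columns)}
    out = {}
    for g, cols in groups.reduced_entries.items():
        missing = [c for c in cols if c not in col_pos]
        if missing:
            raise ValueError(f"group {g!r} references unknown columns {missing}")
        out[g] = np.array([col_pos[c] for c in cols], dtype=int)
    return out


def group_mask_delta_recall(
    params: net.NetworkParams,
    X: np.ndarray,
    y_true,
    groups: GroupMap,
    columns: list[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """ΔRecall for each group: recall with the group's columns zeroed minus
    the unmasked recall. No retraining; input dimensionality is preserved."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    columns = columns or groups.columns(reduced=True)
    idx = _group_indices(groups, columns)
    baseline = _recall_with_mask(params, X, y_true, np.array([], dtype=int), threshold)
    rows = []
    for g, cols_idx in idx.items():
        masked = _recall_with_mask(params, X, y_true, cols_idx, threshold)
        rows.append(
            {
                "group": g,
                "baseline_recall": baseline,
                "masked_recall": masked,
                "delta_recall": masked - baseline,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "delta_recall", kind="mergesort"
    ).reset_index(drop=True)


def n_subsets(n_groups: int, max_size: int) -> int:
    """Number of non-empty group subsets of size <= max_size."""
    return sum(comb(n_groups, k) for k in range(1, max_size + 1))


def combo_mask_recall(
    params: net.NetworkParams,
    X: np.ndarray,
    y_true,
    groups: GroupMap,
    max_size: int = 5,
    columns: list[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Masked recall for every group subset S with 1 <= |S| <= max_size.

    Subsets are enumerated in lexicographic order over the group-map order
    (streaming, constant memory per subset); the report is sorted ascending
    by recall, ties broken lexicographically, so low-recall rows name the
    jointly critical group combinations.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    columns = columns or groups.columns(reduced=True)
    idx = _group_indices(groups, columns)
    names = list(idx)
    if max_size > len(names):
        raise ValueError("max_size exceeds the number of groups")
    rows = []
    for k in range(1, max_size + 1):
        for subset in itertools.combinations(names, k):
            cols_idx = np.concatenate([idx[g] for g in subset])
            recall = _recall_with_mask(params, X, y_true, cols_idx, threshold)
            rows.append(
                {"subset": "+".join(subset), "size": k, "masked_recall": recall}
            )
    report = pd.DataFrame(rows).sort_values(
        by=["masked_recall", "subset"], kind="mergesort"
    )
    return report.reset_index(drop=True)
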
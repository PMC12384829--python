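"""Feature-table preprocessing: imputation, standardization, group-wise PCA,
and MoCA label handling.

The raw table holds 166 baseline variables organized into 20 named groups
(scores and sub-items of clinical instruments, DAT-imaging uptake values,
genetic markers, socio-demographics). Preprocessing proceeds in the order the
analysis assumes:

1. missing cells (MCAR, < 20% per column) are imputed;
2. every column is z-scored;
3. each group with at least ``min_group_size_for_pca`` variables is replaced
   by the scores of the principal components of its correlation matrix whose
   eigenvalue is >= ``eigenvalue_min`` (a conservative Kaiser-style rule);
4. MoCA totals are binarized at the standard cut-off (>= 26 = intact) and the
   four baseline->follow-up transition classes are assigned.

PCA here is purely a dimensionality-reduction device: components are named
``<GROUP>_PCk`` and are never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "INTACT",
    "IMPAIRED",
    "MOCA_CUTOFF",
    "TRANSITION_CLASSES",
    "GroupMap",
    "PCAConfig",
    "FeatureMatrix",
    "ImputeConfig",
    "impute_missing",
    "standardize",
    "groupwise_pca",
    "binarize_moca",
    "binarize_moca_series",
    "assign_transition_class",
    "transition_classes_series",
]

INTACT = "Intact"
IMPAIRED = "Impaired"

#: MoCA total >= 26 indicates preserved cognition.
MOCA_CUTOFF = 26

CLASS_INTACT = "Cognitively Intact"
CLASS_STABLE_IMPAIRED = "Stable Impaired"
CLASS_CONVERSION = "Conversion to Impaired"
CLASS_REVERSION = "Reversion to Cognitively Intact"

TRANSITION_CLASSES = (
    CLASS_INTACT,
    CLASS_STABLE_IMPAIRED,
    CLASS_CONVERSION,
    CLASS_REVERSION,
)

#: Columns with at least this many missing cells (as a fraction) are rejected.
MAX_MISSING_FRACTION = 0.20


@dataclass
class GroupMap:
    """Ordered mapping from variable-group names to column identifiers.

    ``entries`` describes the raw table; ``reduced_entries`` (populated by
    :func:`groupwise_pca`) describes the table after PCA replacement, in the
    same group order.
    """

    entries: dict[str, list[str]]
    reduced_entries: dict[str, list[str]] | None = None

    @property
    def group_names(self) -> list[str]:
        return list(self.entries)

    def columns(self, reduced: bool = False) -> list[str]:
        source = self.reduced_entries if reduced else self.entries
        if source is None:
            raise ValueError("reduced_entries not set; run groupwise_pca first")
        return [c for cols in source.values() for c in cols]

    def validate_partition(self, columns: list[str]) -> None:
        """Check that groups partition ``columns`` exactly."""
        own = self.columns()
        if len(own) != len(set(own)):
            raise ValueError("group map assigns some column to more than one group")
        if set(own) != set(columns) or len(own) != len(columns):
            raise ValueError("group map does not partition the table's columns")


@dataclass(frozen=True)
class PCAConfig:
    """Retention rule for the group-wise PCA step."""

    eigenvalue_min: float = 1.5
    min_group_size_for_pca: int = 6
    standardize_first: bool = True

    def __post_init__(self) -> None:
        if self.eigenvalue_min <= 0:
            raise ValueError("eigenvalue_min must be > 0")


@dataclass
class FeatureMatrix:
    """A fully observed numeric table plus the scaling used to produce it."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored scaling to new data (constant columns map to 0)."""
        sds = self.sds.replace(0.0, 1.0)
        return (new[self.column_names] - self.means) / sds


@dataclass(frozen=True)
class ImputeConfig:
    """Settings for the missing-data imputer.

    ``method="forest"`` runs round-robin iterative imputation with an
    extremely-randomized-trees regressor per column (a nonparametric,
    random-forest-style scheme); ``method="mean"`` is a fast fallback.
    """

    method: str = "forest"
    seed: int = 0
    max_iter: int = 10
    tol: float = 1e-3
    n_estimators: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("forest", "mean"):
            raise ValueError(f"unknown imputation method {self.method!r}")


def impute_missing(X: pd.DataFrame, config: ImputeConfig | None = None) -> pd.DataFrame:
    """Fill every missing cell; observed cells pass through unchanged.

    Raises if any column is entirely missing or has >= 20% missing cells
    (the analysis only admits variables below that threshold).
    """
    config = config or ImputeConfig()
    X = X.copy()
    miss = X.isna()
    frac = miss.mean(axis=0)
    empty = frac[frac >= 1.0].index.tolist()
    if empty:
        raise ValueError(f"column(s) entirely missing: {empty}")
    too_sparse = frac[frac >= MAX_MISSING_FRACTION].index.tolist()
    if too_sparse:
        raise ValueError(
            f"column(s) with >= {MAX_MISSING_FRACTION:.0%} missing cells: {too_sparse}"
        )
    if not miss.to_numpy().any():
        return X

    if config.method == "mean":
        filled = X.fillna(X.mean(axis=0))
    else:
        # sqrt(p) candidate features per split, as random-forest imputers use
        estimator = ExtraTreesRegressor(
            n_estimators=config.n_estimators,
            max_features="sqrt",
            random_state=config.seed,
            n_jobs=1,
        )
        imputer = IterativeImputer(
            estimator=estimator,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=config.seed,
            sample_posterior=False,
            keep_empty_features=True,
        )
        filled = pd.DataFrame(
            imputer.fit_transform(X), index=X.index, columns=X.columns
        )
        # guard: the imputer must never touch observed cells
        filled = filled.where(miss, X)
    assert not filled.isna().to_numpy().any()
    return filled


def standardize(X: pd.DataFrame) -> FeatureMatrix:
    """Z-score every column (population SD); constant columns become all-zero."""
    if X.isna().to_numpy().any():
        raise ValueError("standardize requires a fully observed table")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    safe_sds = sds.replace(0.0, 1.0)
    Z = (X - means) / safe_sds
    return FeatureMatrix(values=Z, means=means, sds=sds)


def _pca_group(Zg: np.ndarray, eigenvalue_min: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose the sample correlation matrix of z-scored columns.

    Returns (scores, eigenvalues_retained, loadings_retained). Retains every
    component with eigenvalue >= eigenvalue_min; if none qualifies, the first
    component is kept anyway so the group is never dropped from the feature
    space.
    """
    corr = np.corrcoef(Zg, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_keep = int(np.sum(eigvals >= eigenvalue_min))
    n_keep = max(n_keep, 1)
    vals = eigvals[:n_keep]
    vecs = eigvecs[:, :n_keep]
    # sign convention: the largest-|loading| entry of each component is positive
    for k in range(n_keep):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return Zg @ vecs, vals, vecs


def groupwise_pca(
    Z: FeatureMatrix,
    groups: GroupMap,
    config: PCAConfig | None = None,
) -> tuple[FeatureMatrix, GroupMap, dict[str, dict]]:
    """Replace each large group's columns by its retained principal components.

    Groups with fewer than ``min_group_size_for_pca`` variables pass through
    unchanged. Returns the reduced matrix, an updated group map whose
    ``reduced_entries`` names component columns ``<GROUP>_PCk``, and a per-group
    record of eigenvalues and loadings for audit/serialization.
    """
    config = config or PCAConfig()
    values = Z.values
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("non-finite values in standardized matrix")
    groups.validate_partition(list(values.columns))

    out_cols: dict[str, pd.Series] = {}
    reduced_entries: dict[str, list[str]] = {}
    pca_info: dict[str, dict] = {}
    for name, cols in groups.entries.items():
        if len(cols) >= config.min_group_size_for_pca:
            scores, vals, vecs = _pca_group(
                values[cols].to_numpy(), config.eigenvalue_min
            )
            comp_names = [f"{name}_PC{k + 1}" for k in range(scores.shape[1])]
            for k, cname in enumerate(comp_names):
                out_cols[cname] = pd.Series(scores[:, k], index=values.index)
            reduced_entries[name] = comp_names
            pca_info[name] = {
                "eigenvalues": vals.tolist(),
                "loadings": vecs.tolist(),
                "input_columns": list(cols),
            }
        else:
            for c in cols:
                out_cols[c] = values[c]
            reduced_entries[name] = list(cols)
    reduced = pd.DataFrame(out_cols)
    new_map = GroupMap(entries=dict(groups.entries), reduced_entries=reduced_entries)
    fm = FeatureMatrix(
        values=reduced,
        means=pd.Series(0.0, index=reduced.columns),
        sds=pd.Series(1.0, index=reduced.columns),
    )
    return fm, new_map, pca_info


def binarize_moca(score: int, cutoff: int = MOCA_CUTOFF) -> str:
    """Map a MoCA total to the binary cognitive label (>= cutoff -> Intact)."""
    if not 0 <= score <= 30:
        raise ValueError(f"MoCA score {score} outside [0, 30]")
    return INTACT if score >= cutoff else IMPAIRED


def binarize_moca_series(scores, cutoff: int = MOCA_CUTOFF) -> np.ndarray:
    scores = np.asarray(scores)
    if ((scores < 0) | (scores > 30)).any():
        raise ValueError("MoCA score outside [0, 30]")
    return np.where(scores >= cutoff, INTACT, IMPAIRED)


def assign_transition_class(baseline: str, followup: str) -> str:
    """Four-way baseline->follow-up trajectory (stable intact / stable impaired /
    conversion / reversion)."""
    table = {
        (INTACT, INTACT): CLASS_INTACT,
        (IMPAIRED, IMPAIRED): CLASS_STABLE_IMPAIRED,
        (INTACT, IMPAIRED): CLASS_CONVERSION,
        (IMPAIRED, INTACT): CLASS_REVERSION,
    }
    try:
        return table[(baseline, followup)]
    except KeyError:
        raise ValueError(f"labels must be {INTACT!r} or {IMPAIRED!r}") from None


def transition_classes_series(baseline_labels, followup_labels) -> np.ndarray:
    return np.array(
        [
            assign_transition_class(b, f)
            for b, f in zip(baseline_labels, followup_labels, strict=True)
        ]
    )
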
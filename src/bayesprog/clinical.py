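"""Clinical-table pruning and k-NN imputation with cross-validated k.

Time-varying clinical variables are segmented by visit (one column per
(variable, year) pair) before any rule is applied.  Pruning order matters and
is fixed: variable columns with more than 5% missing cells are removed first,
then participants with more than 20% missing cells among the surviving
columns.  Remaining gaps are filled by distance-weighted k-nearest-neighbour
imputation over standardized columns, with k chosen by cross-validated
mask-and-predict error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .cohort import make_column
from .genotypes import QCReport

__all__ = ["pivot_clinical", "prune_clinical", "CVKNNImputer", "knn_impute"]


def pivot_clinical(long: pd.DataFrame) -> pd.DataFrame:
    """Long (participant_id, visit_year, variable, value) -> wide columns
    ``var`` (time-invariant) / ``var@year``."""
    df = long.copy()
    cols = {}
    for (var, year), sub in df.groupby(
            ["variable", df["visit_year"].astype("Int64")], dropna=False):
        name = make_column(var, None if pd.isna(year) else int(year))
        cols[name] = sub.set_index("participant_id")["value"]
    wide = pd.DataFrame(cols)
    return wide.sort_index()


def prune_clinical(
    table: pd.DataFrame,
    var_miss_max: float = 0.05,
    participant_miss_max: float = 0.20,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the two pruning rules and report every decision.

    ``table`` is either the long clinical format or an already-pivoted wide
    table.  A column is removed iff its missing fraction is strictly greater
    than ``var_miss_max`` (exactly 5% survives); then a row is removed iff its
    missing fraction over surviving columns is strictly greater than
    ``participant_miss_max``.
    """
    if len(table) == 0:
        raise ValueError("empty clinical table")
    wide = table if "variable" not in table.columns else pivot_clinical(table)
    var_miss = wide.isna().mean(axis=0)
    keep_vars = var_miss <= var_miss_max
    if not keep_vars.any():
        raise ValueError(
            "all clinical variables exceed the missingness threshold "
            f"(missing fractions: {var_miss.to_dict()})")
    pruned = wide.loc[:, keep_vars]
    part_miss = pruned.isna().mean(axis=1)
    keep_parts = part_miss <= participant_miss_max
    pruned = pruned.loc[keep_parts]
    report = QCReport(
        variables=pd.DataFrame({
            "variable": wide.columns,
            "missing_fraction": var_miss.to_numpy(),
            "passed": keep_vars.to_numpy(),
            "reason": np.where(keep_vars, "ok", "missingness"),
        }),
        participants=pd.DataFrame({
            "participant": wide.index,
            "missing_fraction": part_miss.reindex(wide.index).to_numpy(),
            "passed": keep_parts.reindex(wide.index).fillna(False).to_numpy(),
            "reason": np.where(keep_parts.reindex(wide.index).fillna(False),
                               "ok", "missingness"),
        }),
    )
    return pruned, report


class CVKNNImputer:
    """k-NN imputer whose k is selected by cross-validated mask-and-predict MSE.

    Columns are standardized by their observed mean/sd; neighbour distances
    are (nan-)Euclidean over co-observed coordinates and imputed values are
    distance-weighted means over the k nearest rows.  Cross-validation masks
    random subsets of the observed cells, imputes them, and scores squared
    error in standardized units; the k with the smallest pooled error wins
    (ties to the smaller k).  Observed cells are never altered.
    """

    def __init__(self, k_candidates=(1, 3, 5, 10), cv_folds: int = 5,
                 random_state: int = 0):
        self.k_candidates = k_candidates
        self.cv_folds = cv_folds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k_candidates": self.k_candidates, "cv_folds": self.cv_folds,
                "random_state": self.random_state}

    def set_params(self, **params) -> "CVKNNImputer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        self.means_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = 1.0
        self.sds_ = sd
        return (X - self.means_) / self.sds_

    def fit(self, X, y=None) -> "CVKNNImputer":
        if not len(tuple(self.k_candidates)):
            raise ValueError("k_candidates is empty")
        X = pd.DataFrame(X)
        A = X.to_numpy(dtype=float)
        if np.any(np.all(np.isnan(A), axis=1)):
            rows = list(X.index[np.all(np.isnan(A), axis=1)])
            raise ValueError(f"rows with no observed values: {rows}")
        if np.any(np.all(np.isnan(A), axis=0)):
            cols = list(X.columns[np.all(np.isnan(A), axis=0)])
            raise ValueError(f"columns with no observed values: {cols}")
        Z = self._standardize(A)
        rng = np.random.default_rng(self.random_state)
        obs = np.argwhere(~np.isnan(Z))
        order = rng.permutation(len(obs))
        folds = np.array_split(order, self.cv_folds)
        candidates = sorted(set(int(k) for k in self.k_candidates))
        sse = {k: 0.0 for k in candidates}
        cnt = {k: 0 for k in candidates}
        for fold in folds:
            if len(fold) == 0:
                continue
            held = obs[fold]
            masked = Z.copy()
            masked[held[:, 0], held[:, 1]] = np.nan
            # a fully-masked row/column cannot be scored; skip such folds
            if np.any(np.all(np.isnan(masked), axis=0)):
                continue
            for k in candidates:
                imp = KNNImputer(n_neighbors=min(k, Z.shape[0] - 1),
                                 weights="distance")
                filled = imp.fit_transform(masked)
                pred = filled[held[:, 0], held[:, 1]]
                truth = Z[held[:, 0], held[:, 1]]
                sse[k] += float(np.sum((pred - truth) ** 2))
                cnt[k] += len(held)
        self.cv_mse_ = {k: (sse[k] / cnt[k] if cnt[k] else np.nan)
                        for k in candidates}
        self.k_ = min(candidates, key=lambda k: (self.cv_mse_[k], k))
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        A = X.to_numpy(dtype=float)
        if not np.any(np.isnan(A)):
            return X.copy()
        Z = (A - self.means_) / self.sds_
        imp = KNNImputer(n_neighbors=min(self.k_, Z.shape[0] - 1),
                         weights="distance")
        filled = imp.fit_transform(Z) * self.sds_ + self.means_
        out = A.copy()
        mask = np.isnan(A)
        out[mask] = filled[mask]
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def knn_impute(matrix: pd.DataFrame, k_candidates=(1, 3, 5, 10),
               cv_folds: int = 5, seed: int = 0) -> tuple[pd.DataFrame, int]:
    """Impute a participant x variable table; returns (complete table, chosen k)."""
    imputer = CVKNNImputer(k_candidates=k_candidates, cv_folds=cv_folds,
                           random_state=seed)
    return imputer.fit_transform(matrix), imputer.k_
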
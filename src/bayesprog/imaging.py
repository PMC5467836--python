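"""Mixed-effects interpolation of imaging variables onto the visit grid.

DAT-imaging measures are acquired on their own schedule (months 0 and 22 by
default) while the clinical battery is annual.  Per imaging variable a linear
mixed model in time is fitted by REML — fixed intercept and slope plus a
participant-level random intercept and slope with diagonal covariance — and
each participant's line (fixed effects + BLUPs) is re-sampled at the clinical
visit years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .cohort import make_column

__all__ = ["blup_random_effects", "ImagingInterpolator", "interpolate_imaging"]


def blup_random_effects(times, values, beta, cov_re, sigma2) -> np.ndarray:
    """Best linear unbiased predictor of one participant's (intercept, slope).

    ``b_i = G Z_i' (Z_i G Z_i' + sigma^2 I)^{-1} (y_i - X_i beta)`` with
    ``Z_i = X_i = [1, t]``.  Depends only on this participant's own data once
    the variance components ``(cov_re, sigma2)`` and fixed effects are fixed.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    Z = np.column_stack([np.ones_like(t), t])
    G = np.asarray(cov_re, dtype=float)
    V = Z @ G @ Z.T + sigma2 * np.eye(len(t))
    resid = y - Z @ np.asarray(beta, dtype=float)
    return G @ Z.T @ np.linalg.solve(V, resid)


class ImagingInterpolator:
    """Fit per-variable random intercept+slope models and predict at visit years.

    Near-noiseless data make the REML problem degenerate (residual variance at
    the boundary); in that case — or if the optimizer fails — the interpolator
    falls back to exact per-participant least-squares lines, which is the
    sigma^2 -> 0 limit of the BLUP.
    """

    def __init__(self, min_participants: int = 2):
        self.min_participants = min_participants

    def get_params(self, deep: bool = True) -> dict:
        return {"min_participants": self.min_participants}

    def set_params(self, **params) -> "ImagingInterpolator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, imaging: pd.DataFrame, y=None) -> "ImagingInterpolator":
        """``imaging``: long table (participant_id, time_months, variable, value)."""
        df = imaging.dropna(subset=["value"])
        self.models_: dict[str, dict] = {}
        for var, sub in df.groupby("variable"):
            t_years = sub["time_months"].to_numpy(dtype=float) / 12.0
            if len(np.unique(t_years)) < 2:
                raise ValueError(
                    f"imaging variable {var!r} observed at a single time point; "
                    "slope is unidentifiable")
            n_per = sub.groupby("participant_id").size()
            if (n_per >= 2).sum() < self.min_participants:
                raise ValueError(
                    f"imaging variable {var!r} needs >=2 time points for >=2 "
                    "participants")
            self.models_[var] = self._fit_one(sub, t_years)
        return self

    def _fit_one(self, sub: pd.DataFrame, t_years: np.ndarray) -> dict:
        y = sub["value"].to_numpy(dtype=float)
        groups = sub["participant_id"].to_numpy()
        X = np.column_stack([np.ones_like(t_years), t_years])
        per_lines, max_resid, scale = self._participant_lines(sub)
        if max_resid < 1e-8 * max(scale, 1e-12):
            # saturated noiseless case: exact per-participant lines
            return {"mode": "exact", "lines": per_lines}
        free = MixedLMParams.from_components(fe_params=np.ones(2),
                                             cov_re=np.eye(2))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups, exog_re=X)
                res = model.fit(free=free, reml=True, method="lbfgs")
            beta = np.asarray(res.fe_params)
            cov_re = np.asarray(res.cov_re) * 1.0
            sigma2 = float(res.scale)
            if not np.all(np.isfinite(beta)) or sigma2 <= 0:
                raise ValueError("degenerate mixed-model fit")
        except Exception:
            return {"mode": "exact", "lines": per_lines}
        effects = {}
        for pid, psub in sub.groupby("participant_id"):
            b = blup_random_effects(psub["time_months"].to_numpy(float) / 12.0,
                                    psub["value"].to_numpy(float),
                                    beta, cov_re, sigma2)
            effects[pid] = beta + b
        return {"mode": "mixed", "beta": beta, "cov_re": cov_re,
                "sigma2": sigma2, "lines": effects}

    @staticmethod
    def _participant_lines(sub: pd.DataFrame) -> tuple[dict, float, float]:
        lines, max_resid = {}, 0.0
        for pid, psub in sub.groupby("participant_id"):
            t = psub["time_months"].to_numpy(float) / 12.0
            y = psub["value"].to_numpy(float)
            if len(np.unique(t)) >= 2:
                coef, *_ = np.linalg.lstsq(
                    np.column_stack([np.ones_like(t), t]), y, rcond=None)
                resid = y - coef[0] - coef[1] * t
                max_resid = max(max_resid, float(np.max(np.abs(resid))))
            else:  # single observation: flat line through it
                coef = np.array([float(y.mean()), 0.0])
            lines[pid] = coef
        scale = float(np.std(sub["value"])) if len(sub) else 0.0
        return lines, max_resid, scale

    def predict(self, visit_years) -> pd.DataFrame:
        """Wide table: one row per participant, columns ``var@year``."""
        years = [int(t) for t in visit_years]
        cols = {}
        for var, model in self.models_.items():
            lines = model["lines"]
            pids = sorted(lines)
            coefs = np.array([lines[p] for p in pids])
            for t in years:
                cols[make_column(var, t)] = pd.Series(
                    coefs[:, 0] + coefs[:, 1] * t, index=pids)
        return pd.DataFrame(cols)


def interpolate_imaging(imaging: pd.DataFrame, visit_years) -> pd.DataFrame:
    """Fit the mixed model and return per-(participant, year) predictions."""
    interp = ImagingInterpolator().fit(imaging)
    return interp.predict(visit_years)
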
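"""In-silico investigation of a fitted network ensemble.

*Forward simulation* draws synthetic participants from the ensemble: for each
draw one network is taken (cycling uniformly), exogenous variables are
resampled jointly from the training rows, clamped variables are fixed with
do-semantics (their own local models severed), and every dependent variable is
sampled in topological order from its linear-Gaussian fragment.

*Disease-state perturbation* clamps a putative predictor at the 5th and 95th
percentile of the training data, simulates the endpoint posterior under each
state, subsamples both posteriors to the training-cohort size, and compares
them by a permutation test on the absolute difference of means.  P-values
below 0.05 are labelled significant and below 0.1 exploratory.

*Progression perturbation* simulates the whole time series of an outcome per
draw, fits an ordinary least-squares line of value on year per draw, keeps
only the slopes (intercepts are discarded), and applies the same subsampled
permutation machinery to the two slope distributions — a test of whether the
predictor changes the *rate* of progression rather than the level.

*Recall validation* clamps every baseline, genetic and treatment column at
each participant's observed values, propagates the ensemble-averaged
expectation to the endpoints, and reports per-endpoint R^2 against the
training values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortFrame, split_column
from .network import NetworkEnsemble

__all__ = [
    "ClampSpec", "PerturbationResult", "SlopeDistribution", "snp_clamp",
    "forward_simulate", "disease_state_perturbation",
    "progression_perturbation", "recall_validation",
]

SIGNIFICANT, EXPLORATORY = 0.05, 0.1


@dataclass(frozen=True)
class ClampSpec:
    """Do-intervention: hold listed variables fixed, sever their own parents."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"clamp value for {k!r} is not finite")


@dataclass
class SlopeDistribution:
    """Per-draw progression slopes under the two clamp states."""

    low: np.ndarray
    high: np.ndarray
    years: tuple[int, ...]


@dataclass
class PerturbationResult:
    predictor: str
    endpoint: str
    time_index: int | str | None
    low: np.ndarray
    high: np.ndarray
    effect: float  # mean(high state) - mean(low state)
    p_value: float
    n_permutations: int
    subsample_size: int
    clamp_low: dict[str, float] = field(default_factory=dict)
    clamp_high: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        if self.p_value < SIGNIFICANT:
            return "significant"
        if self.p_value < EXPLORATORY:
            return "exploratory"
        return "ns"


def snp_clamp(frame: CohortFrame, snp: str, dosage: float) -> dict[str, float]:
    """Coherent clamp values for all coding columns of one SNP.

    additive = dosage, dominant = min(dosage, 1), recessive = max(dosage-1, 0);
    exact for integer dosages, piecewise-linear in between (interpolated
    quantiles).
    """
    cols = [c for c, s in frame.snp_group.items() if s == snp]
    if not cols:
        raise KeyError(f"no coding columns for SNP {snp!r}")
    out = {}
    for c in cols:
        if c.endswith("_additive"):
            out[c] = float(dosage)
        elif c.endswith("_dominant"):
            out[c] = float(min(dosage, 1.0))
        elif c.endswith("_recessive"):
            out[c] = float(max(dosage - 1.0, 0.0))
        else:
            out[c] = float(dosage)
    return out


# ---------------------------------------------------------------------------
def _child_order(net, children: list[str]) -> list[str]:
    """Topological child order; the (time, name) order works whenever outcome
    parents strictly precede their children, the default constraint regime."""
    pos = {c: i for i, c in enumerate(children)}
    ok = all(pos.get(p, -1) < pos[c]
             for c in children for p in net.fragment_of[c].parents
             if p in pos)
    if ok:
        return children
    import networkx as nx

    g = net.graph()
    return [c for c in nx.topological_sort(g) if c in net.fragment_of]


def _sorted_children(ensemble: NetworkEnsemble) -> list[str]:
    children = set()
    for net in ensemble.networks:
        children.update(net.fragment_of)
    return sorted(children, key=lambda c: (split_column(c)[1] is not None,
                                           split_column(c)[1] or 0, c))


def forward_simulate(
    ensemble: NetworkEnsemble,
    frame: CohortFrame,
    clamp: ClampSpec | dict[str, float] | None = None,
    n_draws: int = 1024,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior draws of all frame columns under an optional do-clamp.

    Returns an ``n_draws x columns`` table pooled over the ensemble (draw i
    uses network ``i mod N``).  Exogenous unclamped variables are resampled
    jointly (whole training rows) so their empirical dependence — e.g.
    coherent SNP codings — is preserved.  Deterministic given ``seed``.
    """
    clamp_values = dict(clamp.values if isinstance(clamp, ClampSpec)
                        else (clamp or {}))
    unknown = [c for c in clamp_values if c not in frame.data.columns]
    if unknown:
        raise KeyError(f"clamped variables not in frame: {unknown}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    children = _sorted_children(ensemble)
    exog = [c for c in frame.columns if c not in children]
    out = {c: np.empty(n_draws) for c in frame.columns}
    net_of_draw = np.arange(n_draws) % ensemble.n_networks
    train = {c: frame.data[c].to_numpy(dtype=float) for c in frame.columns}
    n_rows = frame.n_participants
    for i, net in enumerate(ensemble.networks):
        sel = np.flatnonzero(net_of_draw == i)
        m = sel.size
        if m == 0:
            continue
        rows = rng.integers(0, n_rows, size=m)
        vals: dict[str, np.ndarray] = {}
        for c in exog:
            vals[c] = (np.full(m, clamp_values[c]) if c in clamp_values
                       else train[c][rows])
        for child in _child_order(net, children):
            if child in clamp_values:
                vals[child] = np.full(m, clamp_values[child])
                continue
            f = net.fragment_of[child]
            mu = np.full(m, f.intercept)
            for p, b in zip(f.parents, f.coefficients):
                mu += b * vals[p]
            vals[child] = mu + rng.normal(0.0, f.noise_sd, size=m)
        for c in frame.columns:
            out[c][sel] = vals[c]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
def _permutation_pvalue(low: np.ndarray, high: np.ndarray,
                        n_permutations: int, rng: np.random.Generator) -> float:
    """Add-one permutation p-value for |mean(high) - mean(low)|."""
    obs = abs(float(high.mean()) - float(low.mean()))
    pooled = np.concatenate([low, high])
    m = low.size
    mat = np.tile(pooled, (n_permutations, 1))
    rng.permuted(mat, axis=1, out=mat)
    stats = np.abs(mat[:, m:].mean(axis=1) - mat[:, :m].mean(axis=1))
    return (int(np.sum(stats >= obs)) + 1) / (n_permutations + 1)


def _clamp_states(frame: CohortFrame, predictor: str, quantiles):
    """Low/high clamp dictionaries for a predictor column or SNP name."""
    snps = set(frame.snp_group.values())
    if predictor in snps:
        base_col = next(c for c, s in frame.snp_group.items()
                        if s == predictor and c.endswith("_additive"))
    elif predictor in frame.snp_group:  # a coding column: perturb its SNP
        snp = frame.snp_group[predictor]
        base_col = next(c for c, s in frame.snp_group.items()
                        if s == snp and c.endswith("_additive"))
    elif predictor in frame.data.columns:
        base_col = None
    else:
        raise KeyError(f"predictor {predictor!r} not in frame")
    col = base_col or predictor
    lo, hi = np.quantile(frame.data[col].to_numpy(dtype=float), quantiles,
                         method="linear")
    if lo == hi:
        raise ValueError(
            f"degenerate perturbation: {predictor!r} has equal "
            f"{quantiles[0]:.0%}/{quantiles[1]:.0%} quantiles ({lo})")
    if base_col is not None:
        snp = frame.snp_group[base_col]
        return snp_clamp(frame, snp, lo), snp_clamp(frame, snp, hi)
    return {col: float(lo)}, {col: float(hi)}


def _subsample(x: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    if size > x.size:
        raise ValueError(f"cannot subsample {size} points from {x.size} draws; "
                         "increase n_draws")
    return x[rng.choice(x.size, size=size, replace=False)]


def disease_state_perturbation(
    ensemble: NetworkEnsemble,
    frame: CohortFrame,
    predictor: str,
    endpoint: str,
    quantiles=(0.05, 0.95),
    n_draws: int | None = None,
    n_permutations: int = 10_000,
    subsample_size: int | None = None,
    seed: int = 0,
) -> PerturbationResult:
    """Clamp ``predictor`` low/high and permutation-test the endpoint posteriors.

    The predictor is clamped at the empirical ``quantiles`` of the training
    column (a SNP is clamped coherently across its three codings using
    additive-dosage quantiles); each posterior is subsampled without
    replacement to the training-cohort size before the permutation test.
    """
    if endpoint not in frame.data.columns:
        raise KeyError(f"endpoint {endpoint!r} not in frame")
    clamp_lo, clamp_hi = _clamp_states(frame, predictor, quantiles)
    sub = subsample_size or frame.n_participants
    if n_draws is None:
        n_draws = max(1024, sub)
    ss = np.random.SeedSequence(seed)
    s_lo, s_hi, s_sub, s_perm = (int(s.generate_state(1)[0] % (2 ** 31))
                                 for s in ss.spawn(4))
    post_lo = forward_simulate(ensemble, frame, clamp_lo, n_draws, seed=s_lo)
    post_hi = forward_simulate(ensemble, frame, clamp_hi, n_draws, seed=s_hi)
    rng = np.random.default_rng(s_sub)
    low = _subsample(post_lo[endpoint].to_numpy(), sub, rng)
    high = _subsample(post_hi[endpoint].to_numpy(), sub, rng)
    p = _permutation_pvalue(low, high, n_permutations,
                            np.random.default_rng(s_perm))
    var, t = split_column(endpoint)
    return PerturbationResult(
        predictor=predictor, endpoint=var, time_index=t, low=low, high=high,
        effect=float(high.mean() - low.mean()), p_value=p,
        n_permutations=n_permutations, subsample_size=sub,
        clamp_low=clamp_lo, clamp_high=clamp_hi)


def progression_perturbation(
    ensemble: NetworkEnsemble,
    frame: CohortFrame,
    predictor: str,
    endpoint: str,
    years=None,
    quantiles=(0.05, 0.95),
    n_draws: int | None = None,
    n_permutations: int = 10_000,
    subsample_size: int | None = None,
    seed: int = 0,
) -> tuple[PerturbationResult, SlopeDistribution]:
    """Test whether ``predictor`` changes the *rate* of ``endpoint`` progression.

    ``endpoint`` is a time-varying outcome variable name (e.g. its columns are
    ``endpoint@4 .. endpoint@7``).  Each draw simulates the whole trajectory
    within one network, an OLS line of value on year is fitted per draw, and
    only the slopes are kept; the two slope distributions are then compared by
    the subsampled permutation test.
    """
    if years is None:
        years = frame.times_of(endpoint)
    years = tuple(int(t) for t in years)
    if len(years) < 3:
        raise ValueError(f"progression test needs >=3 time points, got {years}")
    cols = [f"{endpoint}@{t}" for t in years]
    missing = [c for c in cols if c not in frame.data.columns]
    if missing:
        raise KeyError(f"endpoint columns not in frame: {missing}")
    clamp_lo, clamp_hi = _clamp_states(frame, predictor, quantiles)
    sub = subsample_size or frame.n_participants
    if n_draws is None:
        n_draws = max(1024, sub)
    ss = np.random.SeedSequence(seed)
    s_lo, s_hi, s_sub, s_perm = (int(s.generate_state(1)[0] % (2 ** 31))
                                 for s in ss.spawn(4))
    t = np.asarray(years, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)

    def slopes(sim: pd.DataFrame) -> np.ndarray:
        Y = sim[cols].to_numpy()
        return (Y - Y.mean(axis=1, keepdims=True)) @ tc / denom

    slopes_lo = slopes(forward_simulate(ensemble, frame, clamp_lo, n_draws,
                                        seed=s_lo))
    slopes_hi = slopes(forward_simulate(ensemble, frame, clamp_hi, n_draws,
                                        seed=s_hi))
    rng = np.random.default_rng(s_sub)
    low = _subsample(slopes_lo, sub, rng)
    high = _subsample(slopes_hi, sub, rng)
    p = _permutation_pvalue(low, high, n_permutations,
                            np.random.default_rng(s_perm))
    result = PerturbationResult(
        predictor=predictor, endpoint=endpoint, time_index="slope",
        low=low, high=high, effect=float(high.mean() - low.mean()),
        p_value=p, n_permutations=n_permutations, subsample_size=sub,
        clamp_low=clamp_lo, clamp_high=clamp_hi)
    return result, SlopeDistribution(low=slopes_lo, high=slopes_hi, years=years)


# ---------------------------------------------------------------------------
def recall_validation(
    ensemble: NetworkEnsemble,
    frame: CohortFrame,
    endpoints: list[str] | None = None,
    clamp_roles=("baseline", "genetic", "genetic_pc", "intervention", "imaging"),
) -> pd.DataFrame:
    """Training-data recall: clamp each participant's exogenous data, read R^2.

    For every participant, all columns with a role in ``clamp_roles`` are
    clamped at that participant's observed values and the ensemble-averaged
    endpoint expectation is propagated through each network (the analytic mean
    of the forward simulation).  Returns per-endpoint R^2 between predicted
    means and observed values, alongside the in-sample R^2 of a direct OLS of
    the endpoint on the same clamped columns for comparison.
    """
    children = _sorted_children(ensemble)
    if endpoints is None:
        endpoints = children
    clamp_cols = [c for c in frame.columns if frame.roles[c] in clamp_roles]
    exog = [c for c in frame.columns if c not in children]
    n = frame.n_participants
    train = {c: frame.data[c].to_numpy(dtype=float) for c in frame.columns}
    preds = {e: np.zeros(n) for e in endpoints}
    for net in ensemble.networks:
        vals: dict[str, np.ndarray] = {}
        for c in exog:
            vals[c] = (train[c] if c in clamp_cols
                       else np.full(n, train[c].mean()))
        for child in _child_order(net, children):
            if child in clamp_cols:
                vals[child] = train[child]
                continue
            f = net.fragment_of[child]
            mu = np.full(n, f.intercept)
            for p, b in zip(f.parents, f.coefficients):
                mu += b * vals[p]
            vals[child] = mu
        for e in endpoints:
            preds[e] += vals[e]
    rows = []
    for e in endpoints:
        yhat = preds[e] / ensemble.n_networks
        y = train[e]
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else np.nan
        rows.append((e, r2, _direct_r2(frame, e, clamp_cols)))
    return pd.DataFrame(rows, columns=["endpoint", "r2", "direct_ols_r2"]
                        ).set_index("endpoint")


def _direct_r2(frame: CohortFrame, endpoint: str, predictor_cols) -> float:
    """In-sample R^2 of an OLS of the endpoint on the clamped columns."""
    y = frame.data[endpoint].to_numpy(dtype=float)
    X = frame.data[list(predictor_cols)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
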
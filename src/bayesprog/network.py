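"""Two-step ensemble learning of dynamic linear-Gaussian Bayesian networks.

Step one (*enumeration*) exhaustively lists and scores small local models
("fragments"): for every dependent variable, every admissible parent set with
at most ``cap`` non-SNP parents and at most one coding column per SNP.  Each
fragment is an ordinary least-squares linear-Gaussian model of the child on
its parents; its score is a regularized goodness-of-fit, higher is better:

    score = -( n * log(RSS / n) + (k + 2) * log n )            # -BIC
            - k * ( 2 * gamma * log p  +  log((1 - pi) / pi) )

with ``k`` parents out of ``p`` admissible candidates.  The first line is the
Bayesian information criterion of the local model; the optional second line
adds an EBIC-style multiplicity correction (``gamma``) and a Bernoulli
edge-inclusion prior (``pi``), both standard regularizers for structure
learning when many candidate parents compete at moderate sample size.

Step two (*optimization by sampling*) assembles whole acyclic networks by
Metropolis sampling over per-child fragment swaps, targeting probability
proportional to ``exp(total score / T)`` down a geometric temperature ladder
ending at T = 1, where networks are collected at a fixed thinning interval.
Edge frequency across the collected ensemble estimates the structural
posterior; thresholding it yields the consensus network.

Structural constraints: genetic, genetic-PC, baseline, intervention and
imaging columns are exogenous (never children); a time-indexed parent must
strictly precede its child, except that an intervention may explain a
same-year outcome (treatment at the time of assessment).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortFrame, split_column

__all__ = [
    "Fragment", "ConstraintSet", "Network", "NetworkEnsemble",
    "score_fragment", "enumerate_fragments", "build_ensemble",
    "exact_edge_posterior", "convergence_diagnostics", "consensus_network",
    "NetworkEnsembleLearner",
]

_RSS_FLOOR = 1e-30  # keeps log finite on (near-)noiseless planted data


@dataclass(frozen=True)
class Fragment:
    """One scored local model: ``child ~ intercept + coefficients . parents``."""

    child: str
    parents: tuple[str, ...]
    score: float
    intercept: float
    coefficients: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.child in self.parents:
            raise ValueError(f"fragment for {self.child} lists itself as parent")
        if not math.isfinite(self.score):
            raise ValueError("fragment score must be finite")

    def predict(self, values: dict[str, np.ndarray]) -> np.ndarray:
        out = np.asarray(self.intercept, dtype=float)
        for p, c in zip(self.parents, self.coefficients):
            out = out + c * values[p]
        return out


@dataclass
class ConstraintSet:
    """Admissibility rules for (parent, child) edges, derived from roles/times."""

    roles: dict[str, str]
    snp_group: dict[str, str] = field(default_factory=dict)
    cap: int = 4          # max non-SNP parents per child
    snp_cap: int = 2      # max distinct SNPs per child (one coding each)
    allow_same_time: bool = False  # permissive mode (cycle-stress tests)

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValueError("parent cap must be >= 1")

    @classmethod
    def from_frame(cls, frame: CohortFrame, **kw) -> "ConstraintSet":
        return cls(roles=dict(frame.roles), snp_group=dict(frame.snp_group), **kw)

    def is_dependent(self, column: str) -> bool:
        return self.roles[column] == "outcome"

    def allowed(self, parent: str, child: str) -> bool:
        if parent == child or not self.is_dependent(child):
            return False
        role = self.roles[parent]
        _, tp = split_column(parent)
        _, tc = split_column(child)
        if role in ("baseline", "genetic", "genetic_pc"):
            return True
        if role == "intervention":
            return tp is None or (tc is not None and tp <= tc)
        # imaging or outcome parents must strictly precede the child,
        # unless the permissive same-time mode is on (outcome parents only)
        if tp is None:
            return True
        if tc is None:
            return False
        if tp < tc:
            return True
        return self.allow_same_time and role == "outcome" and tp == tc

    def admissible_parents(self, child: str, columns) -> tuple[list[str], dict]:
        """(non-SNP candidates, SNP -> its admissible coding columns)."""
        non_snp, snp_options = [], {}
        for col in columns:
            if not self.allowed(col, child):
                continue
            if col in self.snp_group:
                snp_options.setdefault(self.snp_group[col], []).append(col)
            else:
                non_snp.append(col)
        return sorted(non_snp), {s: sorted(c) for s, c in sorted(snp_options.items())}


# ---------------------------------------------------------------------------
# scoring and enumeration
# ---------------------------------------------------------------------------
def score_fragment(
    frame: CohortFrame,
    child: str,
    parents,
    gamma: float = 0.0,
    edge_prior: float = 0.5,
    n_candidates: int | None = None,
) -> Fragment:
    """Least-squares fit of ``child`` on ``parents`` with regularized score.

    With the defaults (``gamma=0``, ``edge_prior=0.5``) the score is exactly
    the negated BIC, ``-(n log(RSS/n) + (k+2) log n)``; the learner passes
    stricter regularization (see module docstring).
    """
    parents = tuple(parents)
    y = frame.data[child].to_numpy(dtype=float)
    n = len(y)
    k = len(parents)
    if n <= k + 2:
        raise ValueError(f"need n > |parents| + 2 rows (n={n}, k={k})")
    X = np.column_stack([np.ones(n)] + [frame.data[p].to_numpy(float) for p in parents])
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"singular design for child {child!r}: parents {parents}")
    resid = y - X @ beta
    rss_n = max(float(resid @ resid) / n, _RSS_FLOOR)
    score = -(n * math.log(rss_n) + (k + 2) * math.log(n))
    if k and (gamma > 0 or edge_prior != 0.5):
        p_cand = max(int(n_candidates or k), 1)
        score -= k * (2.0 * gamma * math.log(max(p_cand, 2))
                      + math.log((1.0 - edge_prior) / edge_prior))
    return Fragment(child=child, parents=parents, score=score,
                    intercept=float(beta[0]),
                    coefficients=tuple(float(b) for b in beta[1:]),
                    noise_sd=math.sqrt(rss_n))


def enumerate_fragments(
    frame: CohortFrame,
    child: str,
    constraints: ConstraintSet,
    top_k: int | None = None,
    gamma: float = 0.0,
    edge_prior: float = 0.5,
    max_fragments: int = 2_000_000,
) -> list[Fragment]:
    """All admissible parent sets for ``child``, scored, best-first.

    Enumerates every subset of at most ``cap`` non-SNP parents combined with
    at most ``snp_cap`` SNPs (one coding column each), scores each by
    :func:`score_fragment`, and returns the ``top_k`` best.  Ties break toward
    fewer parents, then lexicographic parent ids.  Candidate sets whose design
    matrix is singular are skipped.
    """
    if not constraints.is_dependent(child):
        raise ValueError(f"{child!r} is not a dependent (outcome-role) column")
    non_snp, snp_options = constraints.admissible_parents(child, frame.columns)
    n_candidates = len(non_snp) + sum(len(v) for v in snp_options.values())

    snp_combos: list[tuple[str, ...]] = [()]
    snps = list(snp_options)
    for r in range(1, min(constraints.snp_cap, len(snps)) + 1):
        for chosen in itertools.combinations(snps, r):
            for coding in itertools.product(*(snp_options[s] for s in chosen)):
                snp_combos.append(tuple(coding))

    count = sum(math.comb(len(non_snp), r)
                for r in range(min(constraints.cap, len(non_snp)) + 1))
    if count * len(snp_combos) > max_fragments:
        raise ValueError(
            f"{count * len(snp_combos)} candidate fragments for {child!r} "
            f"exceeds max_fragments={max_fragments}; lower cap or top_k inputs")

    fragments: list[Fragment] = []
    for r in range(min(constraints.cap, len(non_snp)) + 1):
        for base in itertools.combinations(non_snp, r):
            for snp_part in snp_combos:
                parents = tuple(sorted(base + snp_part))
                try:
                    fragments.append(score_fragment(
                        frame, child, parents, gamma=gamma,
                        edge_prior=edge_prior, n_candidates=n_candidates))
                except ValueError:
                    continue  # singular design (e.g. redundant codings)
    if not fragments:
        fragments = [score_fragment(frame, child, (), gamma=gamma,
                                    edge_prior=edge_prior)]
    fragments.sort(key=lambda f: (-f.score, len(f.parents), f.parents))
    return fragments[:top_k] if top_k else fragments


# ---------------------------------------------------------------------------
# networks and ensembles
# ---------------------------------------------------------------------------
@dataclass
class Network:
    """One full model: a fragment per dependent variable."""

    fragment_of: dict[str, Fragment]

    @property
    def total_score(self) -> float:
        return sum(f.score for f in self.fragment_of.values())

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, f in self.fragment_of.items() for p in f.parents]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.fragment_of)
        g.add_edges_from(self.edges())
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph())


@dataclass
class NetworkEnsemble:
    """Sampled set of networks with trace and exact per-edge frequencies."""

    networks: list[Network]
    trace: list[float]
    burn_in_trace: list[float] = field(default_factory=list)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def edge_frequency(self) -> dict[tuple[str, str], float]:
        counts: dict[tuple[str, str], int] = {}
        for net in self.networks:
            for e in set(net.edges()):
                counts[e] = counts.get(e, 0) + 1
        return {e: c / len(self.networks) for e, c in counts.items()}

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "trace": list(self.trace),
            "burn_in_trace": list(self.burn_in_trace),
            "networks": [
                {c: {"parents": list(f.parents), "score": f.score,
                     "intercept": f.intercept,
                     "coefficients": list(f.coefficients),
                     "noise_sd": f.noise_sd}
                 for c, f in net.fragment_of.items()}
                for net in self.networks
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkEnsemble":
        payload = json.loads(Path(path).read_text())
        nets = [
            Network(fragment_of={
                c: Fragment(child=c, parents=tuple(d["parents"]),
                            score=d["score"], intercept=d["intercept"],
                            coefficients=tuple(d["coefficients"]),
                            noise_sd=d["noise_sd"])
                for c, d in net.items()})
            for net in payload["networks"]
        ]
        return cls(networks=nets, trace=payload["trace"],
                   burn_in_trace=payload.get("burn_in_trace", []))


def _union_may_cycle(fragment_lists: dict[str, list[Fragment]]) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(fragment_lists)
    for child, frags in fragment_lists.items():
        for f in frags:
            for p in f.parents:
                g.add_edge(p, child)
    return not nx.is_directed_acyclic_graph(g)


class _AssignmentState:
    """Current fragment assignment with incremental cycle checking."""

    def __init__(self, fragment_lists: dict[str, list[Fragment]],
                 may_cycle: bool):
        self.lists = fragment_lists
        self.children = sorted(fragment_lists)
        self.scores = {c: np.array([f.score for f in fragment_lists[c]])
                       for c in self.children}
        self.may_cycle = may_cycle
        self.idx: dict[str, int] = {}

    def creates_cycle(self, child: str, frag: Fragment) -> bool:
        if not self.may_cycle:
            return False
        g = nx.DiGraph()
        for c in self.children:
            f = (frag if c == child
                 else self.lists[c][self.idx[c]] if c in self.idx else None)
            if f is None:
                continue
            for p in f.parents:
                g.add_edge(p, c)
        return not nx.is_directed_acyclic_graph(g)

    def initialize(self, rng: np.random.Generator, max_attempts: int = 25) -> None:
        for _ in range(max_attempts):
            self.idx = {}
            order = list(self.children)
            rng.shuffle(order)
            ok = True
            for child in order:
                placed = False
                best_first = np.argsort(-self.scores[child])
                for j in best_first:
                    if not self.creates_cycle(child, self.lists[child][j]):
                        self.idx[child] = int(j)
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok:
                return
        raise RuntimeError("no acyclic fragment assignment found "
                           f"after {max_attempts} repair attempts")

    def total_score(self) -> float:
        return float(sum(self.scores[c][self.idx[c]] for c in self.children))

    def sweep(self, temperature: float, rng: np.random.Generator) -> None:
        for child in self.children:
            frags = self.lists[child]
            if len(frags) == 1:
                continue
            j = int(rng.integers(len(frags)))
            cur = self.idx[child]
            if j == cur:
                continue
            delta = self.scores[child][j] - self.scores[child][cur]
            if delta >= 0 or rng.random() < math.exp(delta / temperature):
                if not self.creates_cycle(child, frags[j]):
                    self.idx[child] = j

    def snapshot(self) -> Network:
        return Network(fragment_of={c: self.lists[c][self.idx[c]]
                                    for c in self.children})


def build_ensemble(
    fragment_lists: dict[str, list[Fragment]],
    n_networks: int = 1024,
    burn_in_sweeps: int = 200,
    thin: int = 3,
    n_temperatures: int = 8,
    max_temperature: float = 8.0,
    seed: int = 0,
) -> NetworkEnsemble:
    """Sample an ensemble of acyclic networks by per-child fragment swaps.

    Metropolis moves swap one child's fragment for another from its list,
    rejecting cycle-creating moves, targeting ``exp(total score / T)``.  A
    geometric temperature ladder from ``max_temperature`` down to T = 1 is
    traversed during burn-in; networks are then collected at T = 1 every
    ``thin`` sweeps.  Deterministic given ``seed``.
    """
    for child, frags in fragment_lists.items():
        if not frags:
            raise ValueError(f"dependent variable {child!r} has no fragments")
    rng = np.random.default_rng(seed)
    state = _AssignmentState(fragment_lists, _union_may_cycle(fragment_lists))
    state.initialize(rng)
    ladder = np.geomspace(max_temperature, 1.0, num=max(n_temperatures, 1))
    per_level = max(burn_in_sweeps // len(ladder), 1)
    burn_trace = []
    for T in ladder:
        for _ in range(per_level):
            state.sweep(float(T), rng)
            burn_trace.append(state.total_score())
    networks, trace = [], []
    for _ in range(n_networks):
        for _ in range(thin):
            state.sweep(1.0, rng)
        networks.append(state.snapshot())
        trace.append(state.total_score())
    return NetworkEnsemble(networks=networks, trace=trace,
                           burn_in_trace=burn_trace)


# ---------------------------------------------------------------------------
# exact small-scale posterior (independent enumeration oracle)
# ---------------------------------------------------------------------------
def exact_edge_posterior(
    fragment_lists: dict[str, list[Fragment]],
    limit: int = 5_000_000,
) -> dict[tuple[str, str], float]:
    """Exact edge marginals by exhaustive enumeration of acyclic assignments.

    Enumerates the full product space of per-child fragment choices, discards
    cyclic assignments, weights each survivor by ``exp(total score)`` and
    accumulates per-edge marginal probabilities.  Only feasible at desk scale;
    used as the independent reference for the sampling-based ensemble.
    """
    children = sorted(fragment_lists)
    sizes = [len(fragment_lists[c]) for c in children]
    total = math.prod(sizes)
    if total > limit:
        raise ValueError(f"{total} assignments exceed enumeration limit {limit}")
    max_score = sum(max(f.score for f in fragment_lists[c]) for c in children)
    weights: dict[tuple[int, ...], float] = {}
    z = 0.0
    for combo in itertools.product(*(range(s) for s in sizes)):
        frags = [fragment_lists[c][j] for c, j in zip(children, combo)]
        edge_set = [(p, c) for c, f in zip(children, frags) for p in f.parents]
        g = nx.DiGraph()
        g.add_edges_from(edge_set)
        if edge_set and not nx.is_directed_acyclic_graph(g):
            continue
        w = math.exp(sum(f.score for f in frags) - max_score)
        weights[combo] = w
        z += w
    marginals: dict[tuple[str, str], float] = {}
    for combo, w in weights.items():
        for c, j in zip(children, combo):
            for p in fragment_lists[c][j].parents:
                marginals[(p, c)] = marginals.get((p, c), 0.0) + w / z
    return marginals


# ---------------------------------------------------------------------------
# diagnostics and consensus
# ---------------------------------------------------------------------------
def convergence_diagnostics(trace, split_tol: float = 0.5,
                            autocorr_tol: float = 0.9, lag: int = 1) -> dict:
    """Stationarity checks on the total-score trace.

    Reports the split-half mean difference in units of the trace standard
    deviation and the lag-``lag`` autocorrelation; warns when either exceeds
    its threshold (drifting or poorly-mixing chains).  A constant trace is a
    converged degenerate case (autocorrelation reported as 0).
    """
    x = np.asarray(list(trace), dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    sd = float(np.std(x))
    half = x.size // 2
    diff = float(np.mean(x[half:]) - np.mean(x[:half])) if half else 0.0
    if sd == 0 or x.size <= lag:
        autocorr = 0.0
        rel_diff = 0.0
    else:
        xc = x - x.mean()
        autocorr = float(np.dot(xc[:-lag], xc[lag:]) / np.dot(xc, xc))
        rel_diff = abs(diff) / sd
    status = "pass" if (rel_diff <= split_tol and autocorr <= autocorr_tol) else "warn"
    return {"split_half_diff": diff, "split_half_diff_sd_units": rel_diff,
            "trace_sd": sd, "autocorrelation": autocorr, "lag": lag,
            "status": status}


def consensus_network(ensemble: NetworkEnsemble,
                      threshold: float = 0.30) -> pd.DataFrame:
    """Edges reaching ``frequency >= threshold`` (inclusive boundary).

    Returns (parent, child, frequency, mean_coefficient) sorted by descending
    frequency; the mean coefficient is averaged over the networks that contain
    the edge.
    """
    if not ensemble.networks:
        raise ValueError("empty ensemble")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    freq = ensemble.edge_frequency
    coef_sums: dict[tuple[str, str], list[float]] = {}
    for net in ensemble.networks:
        for child, f in net.fragment_of.items():
            for p, c in zip(f.parents, f.coefficients):
                coef_sums.setdefault((p, child), []).append(c)
    rows = [(p, c, f, float(np.mean(coef_sums[(p, c)])))
            for (p, c), f in freq.items() if f >= threshold]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows, columns=["parent", "child", "frequency",
                                       "mean_coefficient"])


def write_consensus(consensus: pd.DataFrame, out_dir: str | Path,
                    stem: str = "consensus") -> dict[str, Path]:
    """Emit the consensus network as TSV, GraphML and DOT."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"tsv": out / f"{stem}.tsv", "graphml": out / f"{stem}.graphml",
             "dot": out / f"{stem}.dot"}
    consensus.to_csv(paths["tsv"], sep="\t", index=False)
    g = nx.DiGraph()
    for _, row in consensus.iterrows():
        g.add_edge(row["parent"], row["child"], frequency=float(row["frequency"]),
                   mean_coefficient=float(row["mean_coefficient"]))
    nx.write_graphml(g, paths["graphml"])
    lines = ["digraph consensus {"]
    for _, row in consensus.iterrows():
        lines.append(f'  "{row["parent"]}" -> "{row["child"]}" '
                     f'[label="{row["frequency"]:.2f}"];')
    lines.append("}")
    paths["dot"].write_text("\n".join(lines) + "\n")
    return paths


# ---------------------------------------------------------------------------
class NetworkEnsembleLearner(BaseEstimator):
    """Fit-style wrapper: enumerate fragments, then sample a network ensemble.

    Parameters mirror :func:`enumerate_fragments` and :func:`build_ensemble`;
    fitted attributes are ``fragments_`` (per-child scored lists),
    ``ensemble_``, ``edge_frequency_`` and ``trace_``.
    """

    def __init__(self, cap: int = 4, snp_cap: int = 2, top_k: int | None = 64,
                 n_networks: int = 1024, gamma: float = 1.0,
                 edge_prior: float = 0.02, burn_in_sweeps: int = 200,
                 thin: int = 3, n_temperatures: int = 8,
                 max_temperature: float = 8.0, allow_same_time: bool = False,
                 random_state: int = 0):
        self.cap = cap
        self.snp_cap = snp_cap
        self.top_k = top_k
        self.n_networks = n_networks
        self.gamma = gamma
        self.edge_prior = edge_prior
        self.burn_in_sweeps = burn_in_sweeps
        self.thin = thin
        self.n_temperatures = n_temperatures
        self.max_temperature = max_temperature
        self.allow_same_time = allow_same_time
        self.random_state = random_state

    def fit(self, frame: CohortFrame, y=None) -> "NetworkEnsembleLearner":
        self.constraints_ = ConstraintSet.from_frame(
            frame, cap=self.cap, snp_cap=self.snp_cap,
            allow_same_time=self.allow_same_time)
        self.fragments_ = {
            child: enumerate_fragments(frame, child, self.constraints_,
                                       top_k=self.top_k, gamma=self.gamma,
                                       edge_prior=self.edge_prior)
            for child in frame.dependent_columns()
        }
        if not self.fragments_:
            raise ValueError("frame has no outcome-role columns to model")
        self.ensemble_ = build_ensemble(
            self.fragments_, n_networks=self.n_networks,
            burn_in_sweeps=self.burn_in_sweeps, thin=self.thin,
            n_temperatures=self.n_temperatures,
            max_temperature=self.max_temperature, seed=self.random_state)
        self.edge_frequency_ = self.ensemble_.edge_frequency
        self.trace_ = self.ensemble_.trace
        self.training_frame_ = frame
        return self

    def consensus(self, threshold: float = 0.30) -> pd.DataFrame:
        return consensus_network(self.ensemble_, threshold=threshold)

    def diagnostics(self, **kw) -> dict:
        return convergence_diagnostics(self.ensemble_.trace, **kw)
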
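"""Fragment scoring, enumeration, ensemble sampling and consensus."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

import bayesprog as bp
from bayesprog.network import (ConstraintSet, Fragment, Network,
                               build_ensemble, consensus_network,
                               convergence_diagnostics, enumerate_fragments,
                               exact_edge_posterior, score_fragment)
from conftest import make_frame


def random_frame(seed, n=80, n_parents=3):
    rng = np.random.default_rng(seed)
    cols = {f"x{j}": rng.normal(size=n) for j in range(n_parents)}
    cols["y@1"] = rng.normal(size=n)
    roles = {c: "baseline" for c in cols}
    roles["y@1"] = "outcome"
    return make_frame(cols, roles)


class TestScoreFragment:
    def test_empty_parent_set_closed_form(self):
        frame = random_frame(0)
        f = score_fragment(frame, "y@1", ())
        y = frame.data["y@1"].to_numpy()
        n = len(y)
        expected = -(n * math.log(np.var(y)) + 2 * math.log(n))
        assert f.score == pytest.approx(expected, rel=1e-12)

    def test_true_parent_beats_empty_set(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = 1.0 * x + rng.normal(size=500)
        frame = make_frame({"x": x, "y@1": y},
                           {"x": "baseline", "y@1": "outcome"})
        assert (score_fragment(frame, "y@1", ("x",)).score
                > score_fragment(frame, "y@1", ()).score)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_ols_bic_oracle(self, seed):
        frame = random_frame(seed)
        parents = ("x0", "x2")
        f = score_fragment(frame, "y@1", parents)
        X = sm.add_constant(frame.data[list(parents)].to_numpy())
        res = sm.OLS(frame.data["y@1"].to_numpy(), X).fit()
        n = len(frame.data)
        rss = float(res.ssr)
        oracle = -(n * math.log(rss / n) + (len(parents) + 2) * math.log(n))
        assert f.score == pytest.approx(oracle, abs=1e-8)
        np.testing.assert_allclose([f.intercept, *f.coefficients], res.params,
                                   atol=1e-10)

    def test_collinear_parents_error(self):
        frame = random_frame(2)
        frame.data["x_dup"] = frame.data["x0"]
        frame.roles["x_dup"] = "baseline"
        with pytest.raises(ValueError, match="singular"):
            score_fragment(frame, "y@1", ("x0", "x_dup"))

    def test_self_parent_forbidden(self):
        with pytest.raises(ValueError):
            Fragment(child="y", parents=("y",), score=0.0, intercept=0.0,
                     coefficients=(1.0,), noise_sd=1.0)


class TestEnumeration:
    def test_power_set_count_with_three_parents(self):
        frame = random_frame(3, n_parents=3)
        cons = ConstraintSet.from_frame(frame, cap=4)
        frags = enumerate_fragments(frame, "y@1", cons)
        assert len(frags) == 2 ** 3

    def test_binomial_count_with_cap_two(self):
        frame = random_frame(4, n_parents=10, n=120)
        cons = ConstraintSet.from_frame(frame, cap=2)
        frags = enumerate_fragments(frame, "y@1", cons)
        assert len(frags) == 1 + 10 + 45

    def test_at_most_one_coding_per_snp(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, 100).astype(float)
        frame = make_frame(
            {"rs1_additive": d, "rs1_dominant": (d >= 1).astype(float),
             "y@1": rng.normal(size=100)},
            {"rs1_additive": "genetic", "rs1_dominant": "genetic",
             "y@1": "outcome"},
            snp_group={"rs1_additive": "rs1", "rs1_dominant": "rs1"})
        cons = ConstraintSet.from_frame(frame, cap=2, snp_cap=2)
        frags = enumerate_fragments(frame, "y@1", cons)
        # empty, additive-only, dominant-only — never both codings
        assert len(frags) == 3
        for f in frags:
            assert len(f.parents) <= 1

    def test_temporal_and_role_constraints(self, default_frame):
        cons = ConstraintSet.from_frame(default_frame)
        assert cons.allowed("age", "moca@4")
        assert cons.allowed("moca@4", "moca@5")
        assert not cons.allowed("moca@5", "moca@4")
        assert not cons.allowed("moca@5", "moca@5")
        assert not cons.allowed("moca@4", "age")          # exogenous child
        assert not cons.allowed("updrs3@5", "bst1_additive")

    def test_intervention_may_explain_same_year_outcome(self):
        roles = {"rx@5": "intervention", "y@5": "outcome", "y@4": "outcome"}
        cons = ConstraintSet(roles=roles)
        assert cons.allowed("rx@5", "y@5")
        assert not cons.allowed("y@5", "rx@5")
        assert not cons.allowed("y@5", "y@4")

    def test_top_one_recovers_planted_single_parent(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            x = rng.normal(size=n)
            noise = {f"z{j}": rng.normal(size=n) for j in range(3)}
            y = 1.0 * x + rng.normal(size=n)
            frame = make_frame(
                {"x": x, **noise, "y@1": y},
                {"x": "baseline", **{k: "baseline" for k in noise},
                 "y@1": "outcome"})
            cons = ConstraintSet.from_frame(frame, cap=2)
            best = enumerate_fragments(frame, "y@1", cons, gamma=1.0,
                                       edge_prior=0.1)[0]
            hits += best.parents == ("x",)
        assert hits >= 95

    def test_no_admissible_parents_gives_intercept_only(self):
        frame = make_frame({"y@1": np.random.default_rng(6).normal(size=30)},
                           {"y@1": "outcome"})
        cons = ConstraintSet.from_frame(frame)
        frags = enumerate_fragments(frame, "y@1", cons)
        assert len(frags) == 1 and frags[0].parents == ()


def two_fragment_lists(s1=0.0, s2=1.0):
    f1 = Fragment(child="y", parents=("a",), score=s1, intercept=0.0,
                  coefficients=(1.0,), noise_sd=1.0)
    f2 = Fragment(child="y", parents=("b",), score=s2, intercept=0.0,
                  coefficients=(1.0,), noise_sd=1.0)
    return {"y": [f1, f2]}


class TestEnsembleSampling:
    def test_two_fragment_long_run_frequency_matches_softmax(self):
        lists = two_fragment_lists(0.0, 1.0)
        ens = build_ensemble(lists, n_networks=4096, thin=1, seed=0)
        freq = ens.edge_frequency[("a", "y")]
        target = math.exp(0.0) / (math.exp(0.0) + math.exp(1.0))
        se = math.sqrt(target * (1 - target) / 4096)
        assert abs(freq - target) <= 4 * se

    def test_every_network_passes_independent_audit(self, default_learner,
                                                    default_frame):
        cons = default_learner.constraints_
        for net in default_learner.ensemble_.networks[::16]:
            assert net.is_acyclic()
            for child, f in net.fragment_of.items():
                for p in f.parents:
                    assert cons.allowed(p, child)
                snps = [cons.snp_group[p] for p in f.parents
                        if p in cons.snp_group]
                assert len(snps) == len(set(snps))

    def test_edge_frequencies_match_exhaustive_enumeration(self):
        cfg = bp.null_cohort_config(n_participants=120, seed=2)
        frame = bp.frame_from_raw(bp.generate_cohort(cfg, seed=2))
        cons = ConstraintSet.from_frame(frame, cap=2)
        lists = {c: enumerate_fragments(frame, c, cons, gamma=1.0,
                                        edge_prior=0.1)
                 for c in frame.dependent_columns()}
        exact = exact_edge_posterior(lists)
        ens = build_ensemble(lists, n_networks=1024, seed=3)
        freq = ens.edge_frequency
        for e in set(exact) | set(freq):
            assert abs(exact.get(e, 0.0) - freq.get(e, 0.0)) <= 0.05

    def test_cycle_rejection_matches_exact_acyclic_posterior(self):
        # two mutually-admissible edges with hand-set scores: the cyclic
        # assignment (both edges) must be excluded, and frequencies must
        # match enumeration over the three acyclic assignments
        def frag(child, parents, score):
            return Fragment(child=child, parents=parents, score=score,
                            intercept=0.0,
                            coefficients=(1.0,) * len(parents), noise_sd=1.0)

        lists = {"u": [frag("u", (), 0.0), frag("u", ("v",), 2.0)],
                 "v": [frag("v", (), 0.0), frag("v", ("u",), 3.5)]}
        exact = exact_edge_posterior(lists)
        z = 1.0 + math.exp(2.0) + math.exp(3.5)
        assert exact[("u", "v")] == pytest.approx(math.exp(3.5) / z)
        assert exact[("v", "u")] == pytest.approx(math.exp(2.0) / z)
        ens = build_ensemble(lists, n_networks=4096, thin=2, seed=8)
        for net in ens.networks[::64]:
            assert net.is_acyclic()
        for e, p in exact.items():
            se = math.sqrt(p * (1 - p) / 4096)
            assert abs(ens.edge_frequency.get(e, 0.0) - p) <= 5 * se + 0.01

    def test_deterministic_given_seed(self):
        lists = two_fragment_lists()
        e1 = build_ensemble(lists, n_networks=64, seed=5)
        e2 = build_ensemble(lists, n_networks=64, seed=5)
        assert e1.trace == e2.trace
        assert e1.edge_frequency == e2.edge_frequency

    def test_json_round_trip(self, tmp_path):
        lists = two_fragment_lists()
        ens = build_ensemble(lists, n_networks=16, seed=1)
        path = tmp_path / "ens.json"
        ens.to_json(path)
        back = bp.NetworkEnsemble.from_json(path)
        assert back.edge_frequency == ens.edge_frequency
        assert back.trace == ens.trace


class TestDiagnostics:
    def test_constant_trace_passes_with_zero_autocorrelation(self):
        d = convergence_diagnostics([5.0] * 100)
        assert d["status"] == "pass"
        assert d["autocorrelation"] == 0.0

    def test_monotone_trace_warns(self):
        d = convergence_diagnostics(np.arange(100.0))
        assert d["status"] == "warn"

    def test_two_seeds_agree_on_mean_ensemble_score(self, default_frame):
        scores = []
        for seed in (21, 22):
            ln = bp.NetworkEnsembleLearner(n_networks=64,
                                           random_state=seed).fit(default_frame)
            scores.append(np.mean(ln.trace_))
        assert abs(scores[0] - scores[1]) <= 5.0


class TestConsensus:
    def test_boundary_inclusive_and_monotone(self):
        f_a = Fragment(child="y", parents=("a",), score=0.0, intercept=0.0,
                       coefficients=(2.0,), noise_sd=1.0)
        f_0 = Fragment(child="y", parents=(), score=0.0, intercept=0.0,
                       coefficients=(), noise_sd=1.0)
        nets = [Network(fragment_of={"y": f_a}) for _ in range(3)] + \
               [Network(fragment_of={"y": f_0}) for _ in range(7)]
        ens = bp.NetworkEnsemble(networks=nets, trace=[0.0] * 10)
        cons30 = consensus_network(ens, threshold=0.30)
        assert list(cons30["parent"]) == ["a"]
        assert cons30.iloc[0]["frequency"] == pytest.approx(0.3)
        assert cons30.iloc[0]["mean_coefficient"] == pytest.approx(2.0)
        cons50 = consensus_network(ens, threshold=0.50)
        assert set(map(tuple, cons50[["parent", "child"]].to_numpy())) <= \
            set(map(tuple, cons30[["parent", "child"]].to_numpy()))

    def test_always_present_edge_has_frequency_one(self, default_learner):
        cons = default_learner.consensus(0.3)
        top = cons.set_index(["parent", "child"])
        assert top.loc[("age", "moca@4"), "frequency"] == 1.0

    def test_threshold_validation(self, default_learner):
        with pytest.raises(ValueError):
            default_learner.consensus(0.0)
        with pytest.raises(ValueError):
            default_learner.consensus(1.5)


def test_score_monotone_in_true_parents_at_large_n():
    rng = np.random.default_rng(9)
    n = 2000
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 0.5 * x1 + 0.5 * x2 + rng.normal(size=n)
    frame = make_frame({"x1": x1, "x2": x2, "y@1": y},
                       {"x1": "baseline", "x2": "baseline", "y@1": "outcome"})
    s0 = score_fragment(frame, "y@1", ()).score
    s1 = score_fragment(frame, "y@1", ("x1",)).score
    s2 = score_fragment(frame, "y@1", ("x1", "x2")).score
    assert s0 < s1 < s2


def test_sklearn_param_interface(default_frame):
    ln = bp.NetworkEnsembleLearner(n_networks=8)
    params = ln.get_params()
    assert params["cap"] == 4 and params["edge_prior"] == 0.02
    ln.set_params(cap=2, n_networks=16).fit(default_frame)
    assert max(len(f.parents) for fr in ln.fragments_.values()
               for f in fr) <= 2 + 1  # cap on non-SNP parents + one SNP coding
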
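import math

import numpy as np
import pytest
from scipy import stats

from genechron.chronology import (
    CalibrationSet,
    CladeMinimum,
    ClockSettings,
    PosteriorTrace,
    PruningEngine,
    convergence_diagnostics,
    log_posterior,
    mcmc_date,
    summarize_chronogram,
)
from genechron.synthetic import simulate_alignment, simulate_dated_tree
from genechron.trees import DatedTree


@pytest.fixture(scope="module")
def topo5():
    return simulate_dated_tree(5, 1e-3, 4e-4, 3800.0, seed=55)


CAL = CalibrationSet(root_mean=3800.0, root_sd=200.0)


# ---------------------------------------------------------------------------
# the joint density
# ---------------------------------------------------------------------------

class TestLogPosterior:
    def test_valid_vs_violated_bounds(self, topo5):
        clock = ClockSettings(model="strict", prior_only=True)
        ages = {n.id: n.age for n in topo5.postorder() if not n.is_leaf}
        assert math.isfinite(log_posterior(topo5, None, ages, 1e-4, CAL, clock))
        # violate parent > child ordering
        bad = dict(ages)
        internal = [n for n in topo5.postorder()
                    if not n.is_leaf and n.parent is not None]
        bad[internal[0].id] = topo5.root_age + 1.0
        assert log_posterior(topo5, None, bad, 1e-4, CAL, clock) == -math.inf

    def test_hard_minimum_violation_is_minus_inf(self, topo5):
        node = next(n for n in topo5.postorder()
                    if not n.is_leaf and n.parent is not None)
        leaves = [l.label for l in node.leaves()]
        cal = CalibrationSet(3800.0, 200.0,
                             [CladeMinimum((leaves[0], leaves[-1]),
                                           node.age + 100.0)])
        clock = ClockSettings(model="strict", prior_only=True)
        ages = {n.id: n.age for n in topo5.postorder() if not n.is_leaf}
        assert log_posterior(topo5, None, ages, 1e-4, cal, clock) == -math.inf

    def test_two_leaf_likelihood_matches_jukes_cantor(self):
        tree = simulate_dated_tree(2, 1e-3, 0.0, 1000.0, seed=1)
        aln = simulate_alignment(tree, rate=1e-4, sites=1, seed=2)
        engine = PruningEngine(tree, aln, K=4)
        rate = 1e-4
        nodes = list(tree.postorder())
        subs = {i: rate * (n.parent.age - n.age)
                for i, n in enumerate(nodes) if n.parent is not None}
        got = engine.loglik(subs)
        # closed form: P(same site pattern) under the two-branch JC model
        d = rate * 2 * tree.root_age
        eps = math.exp(-4.0 / 3.0 * d)
        same = aln.matrix[0, 0] == aln.matrix[1, 0]
        p = (0.25 * (0.25 + 0.75 * eps) if same
             else 0.25 * (0.25 - 0.25 * eps))
        assert got == pytest.approx(math.log(p), rel=1e-9)

    def test_rate_time_rescaling_leaves_likelihood_unchanged(self, topo5):
        aln = simulate_alignment(topo5, rate=1e-4, sites=200, seed=3)
        engine = PruningEngine(topo5, aln, K=4)
        nodes = list(topo5.postorder())
        base = {i: 1e-4 * (n.parent.age - n.age)
                for i, n in enumerate(nodes) if n.parent is not None}
        # doubling the rate while halving every duration changes nothing
        assert engine.loglik(base) == pytest.approx(
            engine.loglik({i: (2 * 1e-4) * 0.5 * (nodes[i].parent.age - nodes[i].age)
                           for i in base}))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampler:
    def test_prior_only_root_matches_truncated_normal_mean(self, topo5):
        clock = ClockSettings(model="strict", cycles=4000, n_chains=1, seed=2,
                              prior_only=True)
        trace = mcmc_date(topo5, None, CAL, clock)[0]
        root = trace.post_burnin()[:, -1]
        # truncation at 0 is ~19 sd away: the mean is the normal mean
        se = root.std(ddof=1) / math.sqrt(len(root) / 20)  # crude ESS deflation
        assert abs(root.mean() - 3800.0) < 4 * max(se, 10.0)

    def test_every_sample_respects_bounds_and_ordering(self, topo5):
        node = next(n for n in topo5.postorder()
                    if not n.is_leaf and n.parent is not None)
        leaves = [l.label for l in node.leaves()]
        cal = CalibrationSet(3800.0, 200.0,
                             [CladeMinimum((leaves[0], leaves[-1]), 500.0)])
        clock = ClockSettings(model="ugam", cycles=600, n_chains=1, seed=3,
                              prior_only=True)
        trace = mcmc_date(topo5, None, cal, clock)[0]
        constrained = cal.resolve(topo5)
        idx = {nid: j for j, nid in enumerate(trace.node_ids)}
        for nid, min_age in constrained.items():
            assert (trace.ages[:, idx[nid]] >= min_age - 1e-9).all()
        for n in topo5.postorder():
            if n.is_leaf or n.parent is None:
                continue
            child_col = trace.ages[:, idx[n.id]]
            parent_col = trace.ages[:, idx[n.parent.id]]
            assert (parent_col > child_col).all()

    def test_streaming_determinism_doubling_cycles(self, topo5):
        aln = simulate_alignment(topo5, rate=1e-4, sites=100, seed=4)
        short = ClockSettings(model="strict", cycles=80, n_chains=1, seed=5)
        long = ClockSettings(model="strict", cycles=160, n_chains=1, seed=5)
        a = mcmc_date(topo5, aln, CAL, short)[0]
        b = mcmc_date(topo5, aln, CAL, long)[0]
        assert np.array_equal(a.ages, b.ages[:80])
        assert np.array_equal(a.rate, b.rate[:80])

    def test_prior_and_posterior_differ_on_root_age(self):
        """Sequence data must move the root posterior off the prior.

        A free global rate can absorb the absolute time scale, so the data
        inform the root only through interior calibration anchors: a
        prior-only run satisfies a clade minimum by floating that clade's
        relative height, while the data pin the height and transmit the
        bound to the root.  The check therefore anchors three mid-depth
        clades at their true ages (the idealized fossil minimum).
        """
        topo = simulate_dated_tree(10, 1e-3, 4e-4, 3800.0, seed=101)
        minima = []
        for node in sorted((n for n in topo.postorder()
                            if not n.is_leaf and n.parent is not None),
                           key=lambda n: -n.age):
            ls = [l.label for l in node.leaves()]
            if len(set(ls)) >= 2 and 0.3 < node.age / topo.root_age < 0.8:
                minima.append(CladeMinimum((ls[0], ls[-1]), round(node.age, 1)))
        cal = CalibrationSet(3800.0, 200.0, minima[:3])
        aln = simulate_alignment(topo, rate=1e-4, sites=2000, seed=6)
        prior_clock = ClockSettings(model="strict", cycles=2000, n_chains=1,
                                    seed=7, prior_only=True)
        post_clock = ClockSettings(model="strict", cycles=2000, n_chains=1, seed=7)
        prior_root = mcmc_date(topo, None, cal, prior_clock)[0].post_burnin()[:, -1]
        post_root = mcmc_date(topo, aln, cal, post_clock)[0].post_burnin()[:, -1]
        ks = stats.ks_2samp(prior_root, post_root).statistic
        assert ks > 0.1


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _trace_from(ages: np.ndarray, burnin=0.0) -> PosteriorTrace:
    n = ages.shape[0]
    return PosteriorTrace(node_ids=[f"n{j}" for j in range(ages.shape[1])],
                          ages=ages, rate=np.ones(n), multipliers=None,
                          log_posterior=np.zeros(n), burnin_frac=burnin)


class TestDiagnostics:
    def test_identical_traces_have_zero_maxdiff(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(1000, 50, size=(500, 3))
        diag = convergence_diagnostics(_trace_from(ages), _trace_from(ages.copy()))
        assert diag.maxdiff == 0.0

    def test_iid_draws_have_near_full_ess(self):
        rng = np.random.default_rng(1)
        a = _trace_from(rng.normal(0, 1, size=(5000, 1)))
        b = _trace_from(rng.normal(0, 1, size=(5000, 1)))
        diag = convergence_diagnostics(a, b)
        n_total = 10_000
        assert abs(diag.ess.iloc[0] - n_total) < 0.2 * n_total
        assert diag.passed

    def test_shifted_chains_fail_the_rule(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(2000, 1))
        b = rng.normal(3, 1, size=(2000, 1))
        diag = convergence_diagnostics(_trace_from(a), _trace_from(b))
        # independent empirical-CDF check of the KS statistic
        grid = np.linspace(-6, 9, 2001)
        ecdf_a = (a[:, 0, None] <= grid).mean(axis=0)
        ecdf_b = (b[:, 0, None] <= grid).mean(axis=0)
        assert diag.maxdiff == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=5e-3)
        assert diag.maxdiff > 0.3
        assert not diag.passed

    def test_trace_shorter_than_burnin_raises(self):
        ages = np.zeros((5, 1))
        with pytest.raises(ValueError):
            convergence_diagnostics(_trace_from(ages, burnin=1.0 - 1e-12),
                                    _trace_from(ages, burnin=1.0 - 1e-12))


# ---------------------------------------------------------------------------
# summarisation
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_constant_trace_gives_degenerate_intervals(self, topo5):
        ids = [n.id for n in topo5.postorder()
               if not n.is_leaf and n.parent is not None] + [topo5.root.id]
        ages_row = np.array([[topo5.node_by_id(i).age for i in ids]])
        trace = PosteriorTrace(node_ids=ids, ages=np.repeat(ages_row, 50, axis=0),
                               rate=np.ones(50), multipliers=None,
                               log_posterior=np.zeros(50), burnin_frac=0.2)
        tree, table = summarize_chronogram([trace], topo5)
        for nid in ids:
            row = table.loc[nid]
            assert row["mean_age"] == pytest.approx(topo5.node_by_id(nid).age)
            assert row["lo95"] == pytest.approx(row["hi95"])

    def test_intervals_match_independent_percentiles(self, topo5):
        clock = ClockSettings(model="strict", cycles=400, n_chains=2, seed=8,
                              prior_only=True)
        traces = mcmc_date(topo5, None, CAL, clock)
        _, table = summarize_chronogram(traces, topo5)
        pooled = np.vstack([t.post_burnin() for t in traces])
        for j, nid in enumerate(traces[0].node_ids):
            lo = np.percentile(pooled[:, j], 2.5)
            hi = np.percentile(pooled[:, j], 97.5)
            assert table.loc[nid, "lo95"] == pytest.approx(lo)
            assert table.loc[nid, "hi95"] == pytest.approx(hi)

    def test_newick_round_trip_matches_table(self, topo5):
        clock = ClockSettings(model="strict", cycles=300, n_chains=1, seed=9,
                              prior_only=True)
        traces = mcmc_date(topo5, None, CAL, clock)
        tree, table = summarize_chronogram(traces, topo5)
        reread = DatedTree.from_newick(tree.to_newick(decimals=8))
        for node in reread.postorder():
            if not node.is_leaf:
                assert node.age == pytest.approx(
                    table.loc[node.id, "mean_age"], abs=1e-6)

    def test_failed_diagnostics_require_override(self, topo5):
        import pandas as pd

        from genechron.chronology import Diagnostics

        clock = ClockSettings(model="strict", cycles=300, n_chains=1, seed=10,
                              prior_only=True)
        traces = mcmc_date(topo5, None, CAL, clock)
        bad = Diagnostics(ess=pd.Series({"n0": 5.0}), maxdiff=0.9)
        with pytest.raises(ValueError):
            summarize_chronogram(traces, topo5, diagnostics=bad)
        tree, _ = summarize_chronogram(traces, topo5, diagnostics=bad,
                                       override=True)
        tree.validate()
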
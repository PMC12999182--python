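"""Synthetic generator: stability, ground truth, determinism, moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import cardionet as cn
from cardionet.dag import ZeroLagDag
from cardionet.simulate import SimulationConfig


def test_independent_configuration_yields_uncoupled_series():
    """With all couplings zero and unit noise, cross-correlations stay at
    noise level (seeded; a max over 72 null correlations at N=300 sits
    near its 2.6-sigma band edge)."""
    s = cn.generate_subject(SimulationConfig(), seed=5)
    assert s.n_beats == 300
    x = s.values - s.values.mean(axis=0)
    x /= x.std(axis=0)
    n = len(x)
    worst = 0.0
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            for lag in range(6):
                r = x[: n - lag, a] @ x[lag:, b] / (n - lag)
                worst = max(worst, abs(r))
    assert worst < 0.15


def test_default_configs_return_300_beats():
    for cfg in (cn.default_rest_config(), cn.default_hut_config()):
        assert cn.generate_subject(cfg, seed=0).n_beats == 300


def test_autocovariance_matches_yule_walker_solution():
    """Long-run sample autocovariance agrees with the Lyapunov-equation truth.

    The reduced-form VAR implied by the REST config has autocovariance
    G(0) solving the discrete Lyapunov equation in companion form and
    G(k) = sum_j B_j G(k-j); the sample moments at N=1e5 must match.
    """
    cfg = cn.default_rest_config(n_samples=100_000)
    bmats, innov_cov = cfg.reduced_form()
    m, p = 4, len(bmats)
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.hstack(bmats)
    if p > 1:
        comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    q = np.zeros((m * p, m * p))
    q[:m, :m] = innov_cov
    big = linalg.solve_discrete_lyapunov(comp, q)
    gamma0 = big[:m, :m]
    gamma1 = (comp @ big)[:m, :m]  # lag-1 autocovariance E[x_n x_{n-1}^T]

    x = cn.generate_subject(cfg, seed=123).values
    x = x - x.mean(axis=0)
    n = len(x)
    s0 = x.T @ x / n
    s1 = x[1:].T @ x[:-1] / (n - 1)
    assert np.max(np.abs(s0 - gamma0)) < 0.02 * max(1.0, np.max(np.abs(gamma0)))
    assert np.max(np.abs(s1 - gamma1)) < 0.02 * max(1.0, np.max(np.abs(gamma1)))


def test_unstable_configuration_rejected():
    with pytest.raises(ValueError, match="spectral radius"):
        SimulationConfig(self_dynamics={"R": (1.05,), "H": (), "M": (), "C": ()})


def test_zero_lag_edge_outside_dag_rejected():
    with pytest.raises(ValueError, match="zero-lag"):
        SimulationConfig(linear_coupling=[("M", "R", 0, 0.3)])


def test_ground_truth_scan():
    cfg = cn.default_rest_config()
    gt = cn.ground_truth(cfg)
    expected = {(s, t) for s, t, _lag, _c in cfg.linear_coupling}
    assert set(gt.links()) == expected
    assert not gt.adjacency.values.diagonal().any()

    # all-zero couplings -> all-false adjacency
    gt0 = cn.ground_truth(SimulationConfig())
    assert not gt0.adjacency.values.any()

    # single added link flips exactly one entry
    cfg2 = cn.default_rest_config()
    cfg2 = SimulationConfig(
        linear_coupling=cfg2.linear_coupling + [("C", "H", 1, 0.1)],
        self_dynamics=dict(cfg2.self_dynamics),
        noise_sd=dict(cfg2.noise_sd),
    )
    gt2 = cn.ground_truth(cfg2)
    diff = gt2.adjacency.values ^ gt.adjacency.values
    assert diff.sum() == 1 and gt2.adjacency.loc["C", "H"]


def test_nonlinear_config_flags_quadratic_link():
    gt = cn.ground_truth(cn.nonlinear_rest_config())
    assert gt.adjacency.loc["R", "H"] and gt.nonlinear.loc["R", "H"]
    assert gt.nonlinear.values.sum() == 1


def test_cohort_determinism_and_seed_isolation():
    rest, hut = cn.default_rest_config(), cn.default_hut_config()
    c1 = cn.generate_cohort(rest, hut, 3, master_seed=99)
    c2 = cn.generate_cohort(rest, hut, 3, master_seed=99)
    for (r1, h1), (r2, h2) in zip(c1, c2):
        assert np.array_equal(r1.values, r2.values)
        assert np.array_equal(h1.values, h2.values)
    # subject i unchanged when the cohort grows
    c3 = cn.generate_cohort(rest, hut, 5, master_seed=99)
    for (r1, _), (r3, _) in zip(c1, c3):
        assert np.array_equal(r1.values, r3.values)
    # pairs carry matching ids and condition labels
    assert c1[0][0].condition == "REST" and c1[0][1].condition == "HUT"
    assert c1[2][0].subject_id == c1[2][1].subject_id


def test_cohort_degenerate_inputs_rejected():
    rest, hut = cn.default_rest_config(), cn.default_hut_config()
    with pytest.raises(ValueError, match="at least 2"):
        cn.generate_cohort(rest, hut, 1, master_seed=1)
    other = SimulationConfig(
        nodes=("A", "B"),
        dag=ZeroLagDag(node_order=("A", "B"), edges=frozenset()),
        self_dynamics={"A": (0.5,), "B": ()},
    )
    with pytest.raises(ValueError, match="share nodes"):
        cn.generate_cohort(rest, other, 3, master_seed=1)


def test_stationarity_of_accepted_configs():
    """First/second-half moments agree within 5 pooled standard errors."""
    cfg = cn.default_rest_config(n_samples=10_000)
    x = cn.generate_subject(cfg, seed=3).values
    half = len(x) // 2
    a, b = x[:half], x[half:]
    for j in range(x.shape[1]):
        se = np.sqrt(a[:, j].var() / half + b[:, j].var() / half)
        # crude correction for serial correlation (effective n smaller)
        assert abs(a[:, j].mean() - b[:, j].mean()) < 5 * se * 4
        assert abs(a[:, j].std() - b[:, j].std()) / b[:, j].std() < 0.2


def test_zero_lag_evaluation_order_invariance():
    """Any DAG-consistent evaluation order gives bitwise-identical output.

    With zero-lag edges only R->H and R->M, both H-before-M and
    M-before-H are valid topological orders; the realized series must not
    depend on which one the generator walks.
    """
    edges = frozenset({("R", "H"), ("R", "M")})
    dag_a = ZeroLagDag(node_order=("R", "H", "M", "C"), edges=edges)
    dag_b = ZeroLagDag(node_order=("R", "M", "H", "C"), edges=edges)
    kwargs = dict(
        linear_coupling=[("R", "H", 0, 0.4), ("R", "M", 0, 0.3), ("M", "H", 1, 0.3)],
        self_dynamics={"R": (0.0, -0.64), "H": (0.5,), "M": (0.5,), "C": (0.4,)},
    )
    sa = cn.generate_subject(SimulationConfig(dag=dag_a, **kwargs), seed=77)
    sb = cn.generate_subject(SimulationConfig(dag=dag_b, **kwargs), seed=77)
    assert np.array_equal(sa.values, sb.values)
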
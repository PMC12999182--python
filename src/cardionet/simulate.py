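"""Synthetic beat-to-beat cardiovascular network generator.

Generates seeded four-node (R, H, M, C) beat series from a stable extended
vector autoregression with known directed couplings — lagged and, along the
within-beat DAG R->H->M->C, instantaneous — plus optional nonlinear links
and a paired REST/HUT parameter shift.  The generator stands in for a human
cohort: it gives every downstream estimator a known ground-truth adjacency
to be scored against.

The default REST topology mimics the canonical short-term regulatory
pathways: respiratory sinus arrhythmia (R->H, partly within-beat), the
baroreflex (M->H, lagged), the mechanical feedforward (H->M, within-beat),
respiratory pumping on pressure (R->M), and the pressure/heart-period/
respiration influences on arterial compliance (M->C, H->C, R->C) with a
weak compliance-to-pressure feedback (C->M).  The HUT variant shifts these
coefficients the way orthostatic stress shifts sympatho-vagal balance:
vagally mediated links (R->H, H->C) are halved and pressure-related links
(M->H, R->M, C->M) are strengthened, so the paired group comparison has a
known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dag import DEFAULT_DAG, ZeroLagDag
from .series import BeatSeries

NONLINEAR_FORMS = ("quadratic", "threshold")

#: linear coupling entry: (source, target, lag, coefficient)
LinCoupling = tuple[str, str, int, float]
#: nonlinear coupling entry: (source, target, lag, form, coefficient)
NlCoupling = tuple[str, str, int, str, float]


@dataclass
class SimulationConfig:
    """Ground-truth generative model for one experimental condition.

    The implied recursive system must be stable: the spectral radius of the
    companion matrix of the reduced-form VAR (zero-lag effects solved out)
    is checked at construction and must be < 1.
    """

    nodes: tuple[str, ...] = ("R", "H", "M", "C")
    n_samples: int = 300
    linear_coupling: list[LinCoupling] = field(default_factory=list)
    nonlinear_coupling: list[NlCoupling] = field(default_factory=list)
    self_dynamics: dict[str, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    dag: ZeroLagDag = field(default_factory=lambda: DEFAULT_DAG)
    burn_in: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if set(self.nodes) != set(self.dag.node_order):
            raise ValueError("config nodes must match the DAG node set")
        self.linear_coupling = [
            (s, t, int(lag), float(c)) for s, t, lag, c in self.linear_coupling
        ]
        self.nonlinear_coupling = [
            (s, t, int(lag), form, float(c))
            for s, t, lag, form, c in self.nonlinear_coupling
        ]
        for s, t, lag, _c in self.linear_coupling:
            self._check_edge(s, t, lag)
        for s, t, lag, form, _c in self.nonlinear_coupling:
            self._check_edge(s, t, lag)
            if form not in NONLINEAR_FORMS:
                raise ValueError(f"unknown nonlinear form {form!r}")
        for node in self.nodes:
            self.self_dynamics.setdefault(node, ())
            self.self_dynamics[node] = tuple(float(a) for a in self.self_dynamics[node])
            self.noise_sd.setdefault(node, 1.0)
            if self.noise_sd[node] <= 0:
                raise ValueError(f"noise_sd[{node}] must be positive")
        if self.n_samples < MIN_SAMPLES:
            raise ValueError(f"n_samples must be at least {MIN_SAMPLES}")
        if self.burn_in < 500:
            raise ValueError("burn-in of at least 500 samples is required")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"unstable configuration: companion spectral radius {rho:.4f} >= 1"
            )

    def _check_edge(self, s: str, t: str, lag: int) -> None:
        if s not in self.nodes or t not in self.nodes:
            raise ValueError(f"coupling {s}->{t} uses unknown node")
        if s == t:
            raise ValueError(f"self-coupling {s}->{t} must use self_dynamics")
        if lag < 0:
            raise ValueError("coupling lag must be >= 0")
        if lag == 0 and not self.dag.allows(s, t):
            raise ValueError(
                f"zero-lag coupling {s}->{t} is not an edge of the zero-lag DAG"
            )

    # -- structural views -------------------------------------------------
    @property
    def max_lag(self) -> int:
        lags = [lag for _s, _t, lag, _c in self.linear_coupling]
        lags += [lag for _s, _t, lag, _f, _c in self.nonlinear_coupling]
        lags += [len(a) for a in self.self_dynamics.values()]
        return max(lags, default=1)

    def coefficient_matrices(self) -> list[np.ndarray]:
        """A_0..A_p with A_k[target, source] the lag-k linear coefficient."""
        m, p = len(self.nodes), self.max_lag
        idx = {n: i for i, n in enumerate(self.nodes)}
        mats = [np.zeros((m, m)) for _ in range(p + 1)]
        for s, t, lag, c in self.linear_coupling:
            mats[lag][idx[t], idx[s]] += c
        for node, coefs in self.self_dynamics.items():
            for k, a in enumerate(coefs, start=1):
                mats[k][idx[node], idx[node]] += a
        return mats

    def spectral_radius(self) -> float:
        """Companion spectral radius of the reduced-form (linear part) VAR."""
        mats = self.coefficient_matrices()
        m = len(self.nodes)
        p = len(mats) - 1
        inv = np.linalg.inv(np.eye(m) - mats[0])
        reduced = [inv @ a for a in mats[1:]]
        if p == 0:
            return 0.0
        comp = np.zeros((m * p, m * p))
        comp[:m, :] = np.hstack(reduced) if reduced else np.zeros((m, 0))
        if p > 1:
            comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def reduced_form(self) -> tuple[list[np.ndarray], np.ndarray]:
        """Reduced VAR matrices B_1..B_p and innovation covariance.

        Solving out the zero-lag effects gives X_n = sum_k B_k X_{n-k} + E_n
        with B_k = (I - A_0)^{-1} A_k and cov(E) = (I - A_0)^{-1} S (I - A_0)^{-T},
        S the diagonal matrix of squared innovation SDs.
        """
        mats = self.coefficient_matrices()
        m = len(self.nodes)
        inv = np.linalg.inv(np.eye(m) - mats[0])
        bmats = [inv @ a for a in mats[1:]]
        s = np.diag([self.noise_sd[n] ** 2 for n in self.nodes])
        return bmats, inv @ s @ inv.T


MIN_SAMPLES = 50


@dataclass(frozen=True)
class GroundTruth:
    """True directed adjacency of a simulated network.

    ``adjacency.loc[source, target]`` is True where any coupling (any lag,
    including 0) was configured; ``nonlinear.loc[source, target]`` flags
    links carrying a nonlinear term.
    """

    adjacency: pd.DataFrame
    nonlinear: pd.DataFrame

    def links(self) -> list[tuple[str, str]]:
        return [
            (s, t)
            for s in self.adjacency.index
            for t in self.adjacency.columns
            if self.adjacency.loc[s, t]
        ]

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.adjacency.index),
            "links": [
                {"source": s, "target": t, "nonlinear": bool(self.nonlinear.loc[s, t])}
                for s, t in self.links()
            ],
        }


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Scan the coupling lists into a boolean source-by-target adjacency."""
    nodes = list(config.nodes)
    adj = pd.DataFrame(False, index=nodes, columns=nodes)
    nl = pd.DataFrame(False, index=nodes, columns=nodes)
    for s, t, _lag, c in config.linear_coupling:
        if c != 0.0:
            adj.loc[s, t] = True
    for s, t, _lag, _form, c in config.nonlinear_coupling:
        if c != 0.0:
            adj.loc[s, t] = True
            nl.loc[s, t] = True
    np.fill_diagonal(adj.values, False)
    np.fill_diagonal(nl.values, False)
    return GroundTruth(adjacency=adj, nonlinear=nl)


def _nonlinear_transform(form: str, s: float) -> float:
    if form == "quadratic":
        # standardized square of a ~N(0,1) source: zero mean, unit variance
        return (s * s - 1.0) / np.sqrt(2.0)
    # threshold: saturating sign response
    return 1.0 if s > 0 else -1.0


def generate_subject(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    subject_id: str = "S00",
    condition: str = "REST",
) -> BeatSeries:
    """Simulate one subject-condition series from *config*.

    Zero-lag effects are realized by evaluating the node equations within
    each beat in the DAG's topological order; a burn-in (default 500
    samples) is discarded so the returned ``n_samples`` beats are free of
    initialization transients.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = config.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    total = config.burn_in + config.n_samples

    # per-target ingredient lists, resolved to integer indices once
    lin_in: dict[str, list[tuple[int, int, float]]] = {n: [] for n in nodes}
    for s, t, lag, c in config.linear_coupling:
        lin_in[t].append((idx[s], lag, c))
    nl_in: dict[str, list[tuple[int, int, str, float]]] = {n: [] for n in nodes}
    for s, t, lag, form, c in config.nonlinear_coupling:
        nl_in[t].append((idx[s], lag, form, c))

    eval_order = [n for n in config.dag.topological_order() if n in nodes]
    noise = rng.standard_normal((total, len(nodes)))
    for n in nodes:
        noise[:, idx[n]] *= config.noise_sd[n]

    x = np.zeros((total, len(nodes)))
    for n in range(total):
        for node in eval_order:
            j = idx[node]
            v = noise[n, j]
            for k, a in enumerate(config.self_dynamics[node], start=1):
                if n - k >= 0:
                    v += a * x[n - k, j]
            for si, lag, c in lin_in[node]:
                if n - lag >= 0:
                    v += c * x[n - lag, si]
            for si, lag, form, c in nl_in[node]:
                if n - lag >= 0:
                    v += c * _nonlinear_transform(form, x[n - lag, si])
            x[n, j] = v

    data = pd.DataFrame(x[config.burn_in :], columns=list(nodes))
    return BeatSeries(data, subject_id=subject_id, condition=condition)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

_REST_LINKS: list[LinCoupling] = [
    ("R", "H", 0, 0.4),  # respiratory sinus arrhythmia, within-beat part
    ("R", "H", 1, 0.3),  # ... lagged part
    ("M", "H", 1, 0.3),  # baroreflex
    ("H", "M", 0, 0.4),  # mechanical feedforward (Starling/runoff)
    ("R", "M", 1, 0.3),  # respiratory pumping on pressure
    ("M", "C", 0, 0.4),  # pressure dependence of compliance
    ("H", "C", 0, 0.3),  # heart-period effect on compliance, within-beat
    ("H", "C", 1, 0.3),  # ... lagged part
    ("R", "C", 0, 0.3),  # respiratory modulation of compliance
    ("C", "M", 1, 0.15),  # weak compliance-to-pressure feedback
]

# orthostatic stress: vagally mediated links halved, pressure links enhanced
_HUT_SHIFT = {
    ("R", "H", 0): 0.2,
    ("R", "H", 1): 0.15,
    ("H", "C", 0): 0.15,
    ("H", "C", 1): 0.15,
    ("M", "H", 1): 0.42,
    ("R", "M", 1): 0.45,
    ("C", "M", 1): 0.22,
}

_SELF = {
    # R: AR(2) oscillator near 0.25 cycles/beat (poles at radius 0.8, +-pi/2)
    "R": (0.0, -0.64),
    "H": (0.4,),
    "M": (0.4,),
    "C": (0.4,),
}

_NOISE = {"R": 1.0, "H": 0.8, "M": 0.8, "C": 0.8}


def default_rest_config(n_samples: int = 300) -> SimulationConfig:
    """Default supine-rest condition (linear couplings only)."""
    return SimulationConfig(
        n_samples=n_samples,
        linear_coupling=list(_REST_LINKS),
        self_dynamics=dict(_SELF),
        noise_sd=dict(_NOISE),
    )


def default_hut_config(n_samples: int = 300) -> SimulationConfig:
    """Default head-up-tilt condition: REST topology, shifted coefficients."""
    links = [
        (s, t, lag, _HUT_SHIFT.get((s, t, lag), c)) for s, t, lag, c in _REST_LINKS
    ]
    return SimulationConfig(
        n_samples=n_samples,
        linear_coupling=links,
        self_dynamics=dict(_SELF),
        noise_sd=dict(_NOISE),
    )


def nonlinear_rest_config(
    n_samples: int = 300, coefficient: float = 0.7
) -> SimulationConfig:
    """REST variant with the R->H link replaced by a quadratic coupling.

    The squared (standardized) source is uncorrelated with the source
    itself, so a linear estimator sees no R->H link while an entropy-based
    estimator does — the model-based vs model-free detection contrast.
    """
    links = [(s, t, lag, c) for s, t, lag, c in _REST_LINKS if (s, t) != ("R", "H")]
    return SimulationConfig(
        n_samples=n_samples,
        linear_coupling=links,
        nonlinear_coupling=[("R", "H", 1, "quadratic", coefficient)],
        self_dynamics=dict(_SELF),
        noise_sd=dict(_NOISE),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

JITTER_SD = 0.10  # multiplicative between-subject coefficient jitter
_MAX_REDRAWS = 100


def _coupling_keys(config: SimulationConfig) -> list[tuple]:
    keys = [("lin", s, t, lag) for s, t, lag, _c in config.linear_coupling]
    keys += [("nl", s, t, lag, f) for s, t, lag, f, _c in config.nonlinear_coupling]
    keys += [("self", n, k) for n in config.nodes for k in range(len(config.self_dynamics[n]))]
    return keys


def _jittered(config: SimulationConfig, mult: dict[tuple, float]) -> SimulationConfig:
    lin = [
        (s, t, lag, c * mult[("lin", s, t, lag)])
        for s, t, lag, c in config.linear_coupling
    ]
    nl = [
        (s, t, lag, f, c * mult[("nl", s, t, lag, f)])
        for s, t, lag, f, c in config.nonlinear_coupling
    ]
    self_dyn = {
        n: tuple(a * mult[("self", n, k)] for k, a in enumerate(config.self_dynamics[n]))
        for n in config.nodes
    }
    return replace(
        config,
        linear_coupling=lin,
        nonlinear_coupling=nl,
        self_dynamics=self_dyn,
        noise_sd=dict(config.noise_sd),
    )


def generate_cohort(
    rest: SimulationConfig,
    hut: SimulationConfig,
    n_subjects: int,
    master_seed: int,
) -> list[tuple[BeatSeries, BeatSeries]]:
    """Simulate a paired REST/HUT cohort with between-subject variability.

    Each subject draws one multiplicative jitter factor (sd 10%) per
    coupling coefficient, applied to *both* conditions, so the configured
    REST->HUT shift is preserved within subject.  Per-subject seeds are
    spawned deterministically from ``master_seed``: subject i's series do
    not change when ``n_subjects`` grows.  Unstable jittered draws are
    redrawn (at most 100 attempts).
    """
    if n_subjects < 2:
        raise ValueError("a paired cohort requires at least 2 subjects")
    if set(rest.nodes) != set(hut.nodes) or rest.dag != hut.dag:
        raise ValueError("REST and HUT configs must share nodes and zero-lag DAG")
    keys = sorted(set(_coupling_keys(rest)) | set(_coupling_keys(hut)))
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        jitter_ss, rest_ss, hut_ss = child.spawn(3)
        jitter_rng = np.random.default_rng(jitter_ss)
        for _attempt in range(_MAX_REDRAWS):
            mult = {k: 1.0 + JITTER_SD * jitter_rng.standard_normal() for k in keys}
            try:
                rest_i = _jittered(rest, mult)
                hut_i = _jittered(hut, mult)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"no stable coefficient draw found for subject {i} "
                f"after {_MAX_REDRAWS} attempts"
            )
        sid = f"S{i:02d}"
        cohort.append(
            (
                generate_subject(rest_i, rest_ss, subject_id=sid, condition="REST"),
                generate_subject(hut_i, hut_ss, subject_id=sid, condition="HUT"),
            )
        )
    return cohort
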
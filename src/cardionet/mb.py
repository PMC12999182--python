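"""Model-based (linear) conditional causality on extended VAR models.

The M observed processes are modelled by a vector autoregression whose lag
counter starts at zero: X_n = sum_{k=0..p} A_k X_{n-k} + U_n.  The lag-0
matrix A_0 carries only coefficients on the edges of the within-beat DAG,
which makes the simultaneous system recursive and identifiable
equation-by-equation by ordinary least squares.

Conditional Granger causality from source i to target j given the rest of
the network Z is the log ratio of restricted to unrestricted residual
variances, F = ln(lambda^2 / sigma^2), where the restricted regression for
X_j drops every term of X_i (lagged and, where DAG-permitted, zero-lag).
For jointly Gaussian processes this equals twice the conditional transfer
entropy, T = F / 2, which is the quantity reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import DEFAULT_DAG, ZeroLagDag
from .series import BeatSeries

DEFAULT_P_RANGE = range(1, 11)


@dataclass(frozen=True)
class MbLinkEstimate:
    """One directed-link estimate from the model-based approach."""

    source: str
    target: str
    conditioning: tuple[str, ...]
    F: float
    T: float
    sigma2_unrestricted: float
    sigma2_restricted: float
    order: int


def _design(
    x: np.ndarray,
    nodes: tuple[str, ...],
    target: str,
    regressors: tuple[str, ...],
    dag: ZeroLagDag,
    p: int,
    rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Build the OLS design for one target on a fixed sample window.

    Columns are the lag-1..p terms of every regressor node plus the lag-0
    terms of the target's DAG parents among the regressors (collider rule:
    zero-lag regressors are only DAG parents of the target).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    parents0 = set(dag.parents(target))
    cols, names = [], []
    for m in regressors:
        for k in range(1, p + 1):
            cols.append(x[rows - k, idx[m]])
            names.append((m, k))
    for m in regressors:
        if m in parents0:
            cols.append(x[rows, idx[m]])
            names.append((m, 0))
    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    y = x[rows, idx[target]]
    return X, y, names


def target_regression(
    series: BeatSeries,
    target: str,
    regressor_nodes: tuple[str, ...] | list[str],
    dag: ZeroLagDag | None = None,
    p: int = 2,
    rows: np.ndarray | None = None,
) -> tuple[float, dict[tuple[str, int], float]]:
    """OLS fit of one target equation; returns (residual variance, coefficients).

    The residual variance uses denominator N - p (the sample-window length),
    matching across restricted and unrestricted fits so their ratio is a
    valid variance comparison.
    """
    dag = dag or DEFAULT_DAG
    if p < 1:
        raise ValueError("model order p must be >= 1")
    x = series.values
    if rows is None:
        rows = np.arange(p, series.n_beats)
    X, y, names = _design(x, series.nodes, target, tuple(regressor_nodes), dag, p, rows)
    if X.shape[1] >= len(rows):
        raise ValueError(
            f"window of {len(rows)} samples cannot identify {X.shape[1]} coefficients"
        )
    sigma2, beta = _ols_variance(X, y)
    return sigma2, dict(zip(names, beta))


def _ols_variance(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    if X.shape[1] == 0:
        return float(np.mean(y**2)), np.empty(0)
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        cond = np.linalg.cond(X)
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns, "
            f"condition number {cond:.3g})"
        )
    resid = y - X @ beta
    return float(np.mean(resid**2)), beta


def select_order_aic(
    series: BeatSeries,
    dag: ZeroLagDag | None = None,
    p_range=DEFAULT_P_RANGE,
) -> int:
    """Akaike-optimal extended-VAR order on a common sample window.

    All candidate orders are scored on the same rows (p_max..N-1):
    AIC(p) = N_eff * ln det(Sigma_hat(p)) + 2 * n_free_coefficients, with
    Sigma_hat the residual covariance of the full unrestricted model.
    """
    dag = dag or DEFAULT_DAG
    p_range = list(p_range)
    if not p_range:
        raise ValueError("empty order range")
    nodes = series.nodes
    x = series.values
    p_max = max(p_range)
    rows = np.arange(p_max, series.n_beats)
    n_eff = len(rows)
    best_p, best_aic = None, np.inf
    for p in p_range:
        resid = np.empty((n_eff, len(nodes)))
        n_coef = 0
        for j, target in enumerate(nodes):
            X, y, names = _design(x, nodes, target, nodes, dag, p, rows)
            _s2, beta = _ols_variance(X, y)
            resid[:, j] = y - X @ beta
            n_coef += len(names)
        sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        aic = n_eff * logdet + 2 * n_coef
        if aic < best_aic:
            best_p, best_aic = p, aic
    if best_p is None:
        raise np.linalg.LinAlgError("no candidate order produced a valid fit")
    return best_p


def conditional_gc(
    series: BeatSeries,
    source: str,
    target: str,
    dag: ZeroLagDag | None = None,
    p: int = 2,
) -> MbLinkEstimate:
    """Extended conditional Granger causality source -> target given the rest.

    Restricted and unrestricted regressions share the identical sample
    window (rows p..N-1), so the restricted design is a column subset of
    the unrestricted one and F >= 0 is guaranteed by least squares.
    """
    dag = dag or DEFAULT_DAG
    if source == target:
        raise ValueError("source and target must differ")
    nodes = series.nodes
    rows = np.arange(p, series.n_beats)
    s2_u, _ = target_regression(series, target, nodes, dag, p, rows)
    restricted = tuple(n for n in nodes if n != source)
    s2_r, _ = target_regression(series, target, restricted, dag, p, rows)
    if s2_u <= 0:
        raise np.linalg.LinAlgError(
            f"unrestricted residual variance {s2_u} is not positive"
        )
    F = float(np.log(s2_r / s2_u))
    conditioning = tuple(n for n in nodes if n not in (source, target))
    return MbLinkEstimate(
        source=source,
        target=target,
        conditioning=conditioning,
        F=F,
        T=F / 2.0,
        sigma2_unrestricted=s2_u,
        sigma2_restricted=s2_r,
        order=p,
    )


def mb_network(
    series: BeatSeries,
    dag: ZeroLagDag | None = None,
    p_range=DEFAULT_P_RANGE,
    order: int | None = None,
) -> list[MbLinkEstimate]:
    """All M(M-1) directed-link estimates with one shared AIC-selected order."""
    dag = dag or DEFAULT_DAG
    p = order if order is not None else select_order_aic(series, dag, p_range)
    return [
        conditional_gc(series, i, j, dag, p)
        for j in series.nodes
        for i in series.nodes
        if i != j
    ]


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------


class ExtendedVAR:
    """Extended (zero-lag) vector autoregression for a beat series.

    Parameters
    ----------
    series
        :class:`BeatSeries` or DataFrame of beat-indexed node columns.
    dag
        Zero-lag DAG; defaults to the R->H->M->C convention.
    order
        Fixed model order; if None, :meth:`fit` selects it by AIC.
    """

    def __init__(
        self,
        series: BeatSeries | pd.DataFrame,
        dag: ZeroLagDag | None = None,
        order: int | None = None,
    ):
        if isinstance(series, pd.DataFrame):
            series = BeatSeries(series)
        self.series = series
        self.dag = dag or DEFAULT_DAG
        self.order = order

    def select_order(self, p_range=DEFAULT_P_RANGE) -> int:
        return select_order_aic(self.series, self.dag, p_range)

    def fit(self, p_range=DEFAULT_P_RANGE) -> "ExtendedVARResults":
        p = self.order if self.order is not None else self.select_order(p_range)
        nodes = self.series.nodes
        x = self.series.values
        rows = np.arange(p, self.series.n_beats)
        coef_mats = [np.zeros((len(nodes), len(nodes))) for _ in range(p + 1)]
        resid = np.empty((len(rows), len(nodes)))
        for j, target in enumerate(nodes):
            X, y, names = _design(x, nodes, target, nodes, self.dag, p, rows)
            _s2, beta = _ols_variance(X, y)
            resid[:, j] = y - X @ beta
            for (m, k), b in zip(names, beta):
                coef_mats[k][j, nodes.index(m)] = b
        sigma = resid.T @ resid / len(rows)
        return ExtendedVARResults(self, p, coef_mats, sigma, len(rows))


class ExtendedVARResults:
    """Fitted extended VAR: coefficients, residual covariance, causality."""

    def __init__(self, model, order, coefficients, resid_cov, nobs_effective):
        self.model = model
        self.order = order
        self.coefficients = coefficients  # A_0..A_p, [target, source]
        self.resid_cov = resid_cov
        self.nobs_effective = nobs_effective

    def conditional_gc(self, source: str, target: str) -> MbLinkEstimate:
        return conditional_gc(self.model.series, source, target, self.model.dag, self.order)

    def causality_network(self) -> pd.DataFrame:
        """Tidy table of all directed links (source, target, F, T, variances)."""
        ests = mb_network(self.model.series, self.model.dag, order=self.order)
        return pd.DataFrame(
            {
                "subject": self.model.series.subject_id,
                "condition": self.model.series.condition,
                "estimator": "mb",
                "source": [e.source for e in ests],
                "target": [e.target for e in ests],
                "F": [e.F for e in ests],
                "T": [e.T for e in ests],
                "order": self.order,
                "sigma2_unrestricted": [e.sigma2_unrestricted for e in ests],
                "sigma2_restricted": [e.sigma2_restricted for e in ests],
            }
        )

    def summary(self) -> str:
        net = self.causality_network()
        lines = [
            "Extended VAR conditional causality (model-based)",
            f"  subject: {self.model.series.subject_id}"
            f"  condition: {self.model.series.condition}",
            f"  order p = {self.order} (AIC), effective samples = {self.nobs_effective}",
            "",
            net[["source", "target", "F", "T"]].to_string(
                index=False, float_format=lambda v: f"{v:8.4f}"
            ),
        ]
        return "\n".join(lines)
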
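"""Surrogate-data significance testing of per-subject causality estimates.

A link estimate on 300-beat physiological series has no usable analytic
null, so significance is assessed against measure values recomputed on
artificially decoupled data:

* model-based path — every node column is replaced by an independent iAAFT
  surrogate, which preserves each series' amplitude distribution and
  (approximately) its power spectrum while destroying all cross-series
  dependence;
* model-free path — the target column is circularly time-shifted by a
  random amount (at least 20 beats) and all other columns are left
  untouched, destroying lagged source->target dependence while preserving
  every series exactly.

The observed measure is significant when it exceeds the 95th percentile of
the surrogate distribution (100 surrogates by default; percentiles use
linear interpolation between order statistics).  At cohort level the degree
of significance s is the percentage of subjects passing the test, binned
into none (< 25%), low (25-50%), medium (50-75%) and high (75-100%)
classes; the low class is conventionally read as not statistically
relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import DEFAULT_DAG, ZeroLagDag
from .series import BeatSeries
from . import mb, mf

_MAX_REDRAWS = 10


@dataclass(frozen=True)
class SurrogateConfig:
    """Settings of the per-subject surrogate test."""

    n_surrogates: int = 100
    percentile: float = 95.0
    method: str | None = None  # default: iaaft for mb, time_shift for mf
    min_shift: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be strictly between 0 and 100")
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")


@dataclass(frozen=True)
class LinkSignificance:
    """Observed measure vs its surrogate distribution for one link."""

    source: str
    target: str
    estimator: str
    observed: float
    surrogate_values: tuple[float, ...]
    threshold: float
    significant: bool


@dataclass(frozen=True)
class SignificanceSummary:
    """Cohort-level degree of significance for one link."""

    source: str
    target: str
    n_significant: int
    n_total: int
    s: float  # percentage
    significance_class: str


# ---------------------------------------------------------------------------
# surrogate generators
# ---------------------------------------------------------------------------


def iaaft_surrogate(
    column: np.ndarray,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Iterative amplitude-adjusted Fourier-transform surrogate of one series.

    Alternates substitution of the original amplitude spectrum with
    rank-ordered substitution of the original amplitudes, so the returned
    series has exactly the original value multiset and an amplitude
    spectrum matching the original within the convergence tolerance.
    Iteration stops when the rank permutation stabilizes, the relative
    spectrum error changes by less than ``tol``, or after ``max_iter``
    rounds.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("iaaft_surrogate expects a single column")
    if len(x) < 32:
        raise ValueError("need at least 32 samples for a spectrum-preserving surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    r = rng.permutation(x)
    prev_err = np.inf
    for _ in range(max_iter):
        # spectrum substitution: keep current phases, impose original amplitudes
        spec = np.fft.rfft(r)
        phase = np.angle(spec)
        y = np.fft.irfft(target_amp * np.exp(1j * phase), n=len(x))
        # amplitude substitution: rank-order the original values onto y
        ranks = np.argsort(np.argsort(y))
        r_new = sorted_x[ranks]
        err = np.linalg.norm(np.abs(np.fft.rfft(r_new)) - target_amp) / np.linalg.norm(
            target_amp
        )
        if np.array_equal(r_new, r) or abs(prev_err - err) < tol:
            r = r_new
            break
        r, prev_err = r_new, err
    return r


def time_shift_surrogate(
    column: np.ndarray,
    min_shift: int = 20,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Circular rotation by a uniform random shift in [min_shift, N - min_shift]."""
    x = np.asarray(column, dtype=float)
    n = len(x)
    if n <= 2 * min_shift:
        raise ValueError(f"series of {n} samples too short for min_shift={min_shift}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = int(rng.integers(min_shift, n - min_shift + 1))
    return np.roll(x, shift)


# ---------------------------------------------------------------------------
# per-link significance
# ---------------------------------------------------------------------------


def _mb_observed(series, source, target, dag, p) -> float:
    return mb.conditional_gc(series, source, target, dag, p).T


def _mf_observed(series, source, target, dag, rng, **mf_params) -> float:
    return mf.mf_cte(series, source, target, dag, seed=rng, **mf_params).T


def link_significance(
    estimator: str,
    series: BeatSeries,
    source: str,
    target: str,
    cfg: SurrogateConfig | None = None,
    dag: ZeroLagDag | None = None,
    p: int | None = None,
    mf_params: dict | None = None,
) -> LinkSignificance:
    """Surrogate significance of one directed link for one subject.

    Estimator parameters (``p`` for the model-based path; ``L``, ``k``,
    ``ns``, ``alpha`` in ``mf_params`` for the model-free path) are held
    fixed across the original series and every surrogate.
    """
    cfg = cfg or SurrogateConfig()
    dag = dag or DEFAULT_DAG
    rng = np.random.default_rng(cfg.seed)
    method = cfg.method or ("iaaft" if estimator == "mb" else "time_shift")
    mf_params = mf_params or {}

    if estimator == "mb":
        if p is None:
            p = mb.select_order_aic(series, dag)
        observed = _mb_observed(series, source, target, dag, p)
    elif estimator == "mf":
        observed = _mf_observed(series, source, target, dag, rng, **mf_params)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    values = []
    for _ in range(cfg.n_surrogates):
        for _redraw in range(_MAX_REDRAWS):
            try:
                surr = _surrogate_series(series, target, method, cfg, rng)
                if estimator == "mb":
                    values.append(_mb_observed(surr, source, target, dag, p))
                else:
                    values.append(_mf_observed(surr, source, target, dag, rng, **mf_params))
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        else:
            raise RuntimeError("surrogate estimation failed after 10 redraws")
    threshold = float(np.percentile(values, cfg.percentile))
    return LinkSignificance(
        source=source,
        target=target,
        estimator=estimator,
        observed=float(observed),
        surrogate_values=tuple(values),
        threshold=threshold,
        significant=bool(observed > threshold),
    )


def _surrogate_series(series, target, method, cfg, rng) -> BeatSeries:
    x = series.values.copy()
    nodes = series.nodes
    if method == "iaaft":
        for i in range(x.shape[1]):
            x[:, i] = iaaft_surrogate(x[:, i], rng)
    elif method == "time_shift":
        j = nodes.index(target)
        x[:, j] = time_shift_surrogate(x[:, j], cfg.min_shift, rng)
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    return series.with_values(x)


def network_significance(
    estimator: str,
    series: BeatSeries,
    cfg: SurrogateConfig | None = None,
    dag: ZeroLagDag | None = None,
    p: int | None = None,
    mf_params: dict | None = None,
) -> pd.DataFrame:
    """Surrogate significance of all M(M-1) links of one subject.

    The model-based path shares each iAAFT surrogate dataset across all
    links (the surrogate destroys every cross-dependence at once); the
    model-free path shares each target rotation across that target's
    sources.  Returns a tidy frame (source, target, observed, threshold,
    significant).
    """
    cfg = cfg or SurrogateConfig()
    dag = dag or DEFAULT_DAG
    rng = np.random.default_rng(cfg.seed)
    nodes = series.nodes
    mf_params = mf_params or {}
    pairs = [(i, j) for j in nodes for i in nodes if i != j]

    if estimator == "mb":
        if p is None:
            p = mb.select_order_aic(series, dag)
        observed = {
            (i, j): _mb_observed(series, i, j, dag, p) for i, j in pairs
        }
        surr_values = {pair: [] for pair in pairs}
        for _ in range(cfg.n_surrogates):
            surr = _surrogate_series(series, None, "iaaft", cfg, rng)
            for i, j in pairs:
                surr_values[(i, j)].append(_mb_observed(surr, i, j, dag, p))
    elif estimator == "mf":
        ests = mf.mf_network(series, dag, seed=rng, **mf_params)
        observed = {(e.source, e.target): e.T for e in ests}
        surr_values = {pair: [] for pair in pairs}
        for _ in range(cfg.n_surrogates):
            for target in nodes:
                surr = _surrogate_series(series, target, "time_shift", cfg, rng)
                engine = mf._make_engine(
                    surr, mf_params.get("L", mf.DEFAULT_L), mf_params.get("k", mf.DEFAULT_K), rng
                )
                emb = mf.nonuniform_embed(
                    surr, target, dag, seed=rng, _engine=engine, **mf_params
                )
                for source in nodes:
                    if source != target:
                        est = mf._link_from_embedding(
                            engine, emb, source, mf_params.get("k", mf.DEFAULT_K)
                        )
                        surr_values[(source, target)].append(est.T)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    rows = []
    for i, j in pairs:
        threshold = float(np.percentile(surr_values[(i, j)], cfg.percentile))
        rows.append(
            {
                "subject": series.subject_id,
                "condition": series.condition,
                "estimator": estimator,
                "source": i,
                "target": j,
                "observed": float(observed[(i, j)]),
                "threshold": threshold,
                "significant": bool(observed[(i, j)] > threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level degree of significance
# ---------------------------------------------------------------------------


def classify_significance(s: float) -> str:
    if s < 25.0:
        return "none"
    if s < 50.0:
        return "low"
    if s < 75.0:
        return "medium"
    return "high"


def significance_degree(
    flags, source: str = "", target: str = ""
) -> SignificanceSummary:
    """Cohort degree of significance s = 100 * n_significant / n_total."""
    flags = [bool(f) for f in flags]
    if not flags:
        raise ValueError("need at least one subject")
    n_sig = sum(flags)
    s = 100.0 * n_sig / len(flags)
    return SignificanceSummary(
        source=source,
        target=target,
        n_significant=n_sig,
        n_total=len(flags),
        s=s,
        significance_class=classify_significance(s),
    )


def significance_summary_table(significance: pd.DataFrame) -> pd.DataFrame:
    """Per-link significance degrees from a stacked per-subject table."""
    rows = []
    for (est, cond, i, j), grp in significance.groupby(
        ["estimator", "condition", "source", "target"], sort=True
    ):
        summ = significance_degree(grp["significant"], i, j)
        rows.append(
            {
                "estimator": est,
                "condition": cond,
                "source": i,
                "target": j,
                "n_significant": summ.n_significant,
                "n_total": summ.n_total,
                "s": summ.s,
                "class": summ.significance_class,
            }
        )
    return pd.DataFrame(rows)
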
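"""Model-free conditional transfer entropy (kNN estimator, non-uniform embedding).

Entropies are estimated with k-nearest-neighbour statistics under the
maximum (Chebyshev) norm, following the Kraskov-Stogbauer-Grassberger
scheme: the search radius is fixed per sample by the distance eps/2 to its
kth neighbour in the highest-dimensional joint space, and the lower
dimensional terms are obtained from strict range counts in the projected
spaces, combined through digamma functions:

    T = psi(k) + < psi(N_VjVz + 1) - psi(N_XjVjVz + 1) - psi(N_V + 1) >.

Process pasts are represented by non-uniformly embedded (node, lag)
components: starting from all candidates up to a maximum lag L (lag 0
offered only along the within-beat DAG), the candidate maximizing the
conditional mutual information with the present target is admitted iff its
CMI exceeds the 95th percentile of a shuffle null, and the search stops at
the first rejection.  The transfer entropy from a source is then the CMI
between the target's present and the admitted source components, given the
other admitted components; it is exactly zero when no source component was
admitted.  Estimates can be negative for weak couplings (estimator bias)
and are reported unclipped — significance is delegated to surrogate tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .dag import DEFAULT_DAG, ZeroLagDag
from .series import BeatSeries

DEFAULT_L = 10
DEFAULT_K = 10
DEFAULT_NS = 100
DEFAULT_ALPHA = 0.05
_JITTER = 1e-10
_BRUTE_MAX = 1500  # above this sample count, neighbour queries use a kd-tree


# ---------------------------------------------------------------------------
# general-purpose CMI estimator
# ---------------------------------------------------------------------------


def _as_block(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def cmi_knn(x, y, z=None, k: int = DEFAULT_K, rng: np.random.Generator | None = None) -> float:
    """Conditional mutual information I(x; y | z) in nats, KSG fixed-eps scheme.

    The kth-neighbour distance in the joint (x, y, z) space sets the search
    radius per sample; counts in the (x, z), (y, z) and z marginal spaces
    use a strictly-smaller-than comparison.  With ``z=None`` the estimate
    degrades to plain mutual information.  Inputs are expected standardized
    to unit variance; if ``rng`` is given, a uniform jitter of amplitude
    1e-10 breaks ties in discrete-valued inputs.
    """
    x, y = _as_block(x), _as_block(y)
    blocks = [x, y] + ([] if z is None else [_as_block(z)])
    n = x.shape[0]
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("all blocks must share the sample count")
    if n < 5 * k:
        raise ValueError(f"need at least 5k = {5 * k} samples, got {n}")
    if rng is not None:
        blocks = [b + rng.uniform(-_JITTER, _JITTER, size=b.shape) for b in blocks]
    x, y = blocks[0], blocks[1]
    zb = blocks[2] if len(blocks) == 3 else None

    if n <= _BRUTE_MAX:
        dx, dy = _cheb_matrix(x), _cheb_matrix(y)
        dz = _cheb_matrix(zb) if zb is not None else None
        return _cmi_from_matrices(dx, dy, dz, k)

    joint = np.hstack(blocks)
    tree = cKDTree(joint)
    eps_half = tree.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    r = np.nextafter(eps_half, 0.0)  # strict inequality at the radius
    xz = np.hstack([x, zb]) if zb is not None else x
    yz = np.hstack([y, zb]) if zb is not None else y
    n_xz = cKDTree(xz).query_ball_point(xz, r, p=np.inf, return_length=True) - 1
    n_yz = cKDTree(yz).query_ball_point(yz, r, p=np.inf, return_length=True) - 1
    if zb is not None:
        n_z = cKDTree(zb).query_ball_point(zb, r, p=np.inf, return_length=True) - 1
        term_z = np.mean(digamma(n_z + 1))
    else:
        term_z = digamma(n)
    return float(
        digamma(k) + term_z - np.mean(digamma(n_xz + 1)) - np.mean(digamma(n_yz + 1))
    )


def _cheb_matrix(block: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distances with +inf on the diagonal."""
    d = np.abs(block[:, None, 0] - block[None, :, 0])
    for c in range(1, block.shape[1]):
        np.maximum(d, np.abs(block[:, None, c] - block[None, :, c]), out=d)
    np.fill_diagonal(d, np.inf)
    return d


def _counts_numpy(dx, dy, dz, k: int):
    joint = np.maximum(dx, dy)
    if dz is not None:
        joint = np.maximum(joint, dz)
    eps_half = np.partition(joint, k - 1, axis=1)[:, k - 1]
    lim = eps_half[:, None]
    n_xz = ((np.maximum(dx, dz) if dz is not None else dx) < lim).sum(axis=1)
    n_yz = ((np.maximum(dy, dz) if dz is not None else dy) < lim).sum(axis=1)
    n_z = (dz < lim).sum(axis=1) if dz is not None else None
    return n_xz, n_yz, n_z


try:  # optional JIT kernel: same arithmetic, far less memory traffic
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _counts_jit(dx, dy, dz, k, has_z, px, py):  # pragma: no cover - thin kernel
        n = dx.shape[0]
        n_xz = np.empty(n, dtype=np.int64)
        n_yz = np.empty(n, dtype=np.int64)
        n_z = np.empty(n, dtype=np.int64)
        kbuf = np.empty(k)
        for a in range(n):
            xa = px[a]
            ya = py[a]
            # pass 1: kth smallest joint distance (diagonal is +inf)
            for i in range(k):
                kbuf[i] = np.inf
            for b in range(n):
                v = dx[xa, px[b]]
                w = dy[ya, py[b]]
                if w > v:
                    v = w
                if has_z:
                    w = dz[a, b]
                    if w > v:
                        v = w
                if v < kbuf[k - 1]:
                    i = k - 1
                    while i > 0 and kbuf[i - 1] > v:
                        kbuf[i] = kbuf[i - 1]
                        i -= 1
                    kbuf[i] = v
            eps = kbuf[k - 1]
            # pass 2: strict range counts in the projected spaces
            cx = cy = cz = 0
            for b in range(n):
                xv = dx[xa, px[b]]
                yv = dy[ya, py[b]]
                if has_z:
                    zv = dz[a, b]
                    if zv < eps:
                        cz += 1
                        if xv < eps:
                            cx += 1
                        if yv < eps:
                            cy += 1
                else:
                    if xv < eps:
                        cx += 1
                    if yv < eps:
                        cy += 1
            n_xz[a] = cx
            n_yz[a] = cy
            n_z[a] = cz
        return n_xz, n_yz, n_z

    _HAVE_NUMBA = True

    def _counts(dx, dy, dz, k, px=None, py=None):
        n = dx.shape[0]
        ident = np.arange(n)
        dummy = dx if dz is None else dz
        n_xz, n_yz, n_z = _counts_jit(
            dx,
            dy,
            dummy,
            k,
            dz is not None,
            ident if px is None else px,
            ident if py is None else py,
        )
        return n_xz, n_yz, (n_z if dz is not None else None)

except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _counts(dx, dy, dz, k, px=None, py=None):
        if px is not None:
            dx = dx[np.ix_(px, px)]
        if py is not None:
            dy = dy[np.ix_(py, py)]
        return _counts_numpy(dx, dy, dz, k)


def _cmi_from_matrices(
    dx,
    dy,
    dz,
    k: int,
    dg_table: np.ndarray | None = None,
    px: np.ndarray | None = None,
    py: np.ndarray | None = None,
) -> float:
    n = dx.shape[0]
    n_xz, n_yz, n_z = _counts(dx, dy, dz, k, px, py)
    if dg_table is None:
        dg_table = digamma(np.arange(1, n + 2))
    term_z = np.mean(dg_table[n_z]) if n_z is not None else dg_table[n - 1]
    return float(
        digamma(k) + term_z - np.mean(dg_table[n_xz]) - np.mean(dg_table[n_yz])
    )


# ---------------------------------------------------------------------------
# embedding machinery
# ---------------------------------------------------------------------------

Component = tuple[str, int]  # (node label, lag)


@dataclass(frozen=True)
class EmbeddingVector:
    """Admitted (node, lag) components of one target's embedding.

    ``selected`` preserves admission order; ``cmi_values`` and
    ``thresholds`` record the admitted candidates' scores and their shuffle
    thresholds for audit.
    """

    target: str
    selected: tuple[Component, ...]
    cmi_values: tuple[float, ...] = ()
    thresholds: tuple[float, ...] = ()

    def partition(self, source: str) -> tuple[tuple[Component, ...], tuple[Component, ...]]:
        """Split into (source components, remaining components)."""
        vi = tuple(c for c in self.selected if c[0] == source)
        rest = tuple(c for c in self.selected if c[0] != source)
        return vi, rest


def candidate_set(
    target: str, nodes: tuple[str, ...], dag: ZeroLagDag, L: int = DEFAULT_L
) -> list[Component]:
    """All (node, lag) candidates for one target up to maximum lag L.

    The initial lag is 0 for DAG-permitted zero-lag parents of the target
    and 1 otherwise; the target's own present value is never a candidate.
    """
    out: list[Component] = []
    for node in nodes:
        tau = 0 if (node != target and dag.allows(node, target)) else 1
        out.extend((node, lag) for lag in range(tau, L + 1))
    return out


class _EmbeddingEngine:
    """Cached pairwise-distance workspace for one standardized series.

    Every embedding component is a lag-shifted copy of one node column;
    its N_eff x N_eff Chebyshev distance matrix (diagonal +inf) is built
    once and combined by elementwise maxima, so candidate scans, shuffle
    nulls (row/column permutations of the cached matrices) and surrogate
    re-runs share almost all of the distance work.
    """

    def __init__(
        self,
        columns: dict[str, np.ndarray],
        L: int,
        k: int,
        rng: np.random.Generator,
    ):
        n = len(next(iter(columns.values())))
        self.rows = np.arange(L, n)
        self.k = k
        self.n_eff = len(self.rows)
        if self.n_eff < 5 * k:
            raise ValueError(
                f"embedding needs at least 5k = {5 * k} usable samples, got {self.n_eff}"
            )
        self.columns = {
            name: col + rng.uniform(-_JITTER, _JITTER, size=col.shape)
            for name, col in columns.items()
        }
        self._dm: dict[Component, np.ndarray] = {}
        self._dg = digamma(np.arange(1, self.n_eff + 2))

    def replaced(self, node: str, column: np.ndarray, rng: np.random.Generator) -> "_EmbeddingEngine":
        """New engine with one node column replaced (shares cached matrices)."""
        eng = object.__new__(_EmbeddingEngine)
        eng.rows, eng.k, eng.n_eff = self.rows, self.k, self.n_eff
        eng.columns = dict(self.columns)
        eng.columns[node] = column + rng.uniform(-_JITTER, _JITTER, size=column.shape)
        eng._dm = {c: m for c, m in self._dm.items() if c[0] != node}
        eng._dg = self._dg
        return eng

    def dm(self, comp: Component) -> np.ndarray:
        if comp not in self._dm:
            node, lag = comp
            v = self.columns[node][self.rows - lag]
            d = np.abs(v[:, None] - v[None, :])
            np.fill_diagonal(d, np.inf)
            self._dm[comp] = d
        return self._dm[comp]

    def block_dm(self, comps) -> np.ndarray | None:
        comps = list(comps)
        if not comps:
            return None
        d = self.dm(comps[0])
        for c in comps[1:]:
            d = np.maximum(d, self.dm(c))
        return d

    def cmi(self, d_target, d_cand, d_cond=None) -> float:
        return _cmi_from_matrices(d_target, d_cand, d_cond, self.k, self._dg)

    def shuffled_cmi(self, d_target, d_cand, d_cond, rng) -> float:
        """CMI with candidate and target samples independently permuted."""
        p1 = rng.permutation(self.n_eff)
        p2 = rng.permutation(self.n_eff)
        return _cmi_from_matrices(
            d_target, d_cand, d_cond, self.k, self._dg, px=p2, py=p1
        )


def _make_engine(series: BeatSeries, L: int, k: int, rng) -> _EmbeddingEngine:
    x = series.values
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be unit-variance standardized")
    cols = {
        n: (x[:, i] - x[:, i].mean()) / sd[i] for i, n in enumerate(series.nodes)
    }
    return _EmbeddingEngine(cols, L, k, rng)


def nonuniform_embed(
    series: BeatSeries,
    target: str,
    dag: ZeroLagDag | None = None,
    L: int = DEFAULT_L,
    k: int = DEFAULT_K,
    ns: int = DEFAULT_NS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
    _engine: _EmbeddingEngine | None = None,
) -> EmbeddingVector:
    """Greedy significance-gated selection of the target's embedding.

    At each step every remaining candidate is scored by its kNN CMI with
    the target's present given the current embedding; the maximizer is
    admitted iff its CMI exceeds the 100(1-alpha)th percentile of ``ns``
    shuffle-null CMIs (candidate and target samples permuted randomly and
    independently).  Selection stops at the first rejection.
    """
    dag = dag or DEFAULT_DAG
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    engine = _engine if _engine is not None else _make_engine(series, L, k, rng)
    candidates = candidate_set(target, series.nodes, dag, L)
    d_target = engine.dm((target, 0))
    d_cond = None
    selected: list[Component] = []
    values: list[float] = []
    thresholds: list[float] = []
    while candidates:
        scores = [engine.cmi(d_target, engine.dm(c), d_cond) for c in candidates]
        best = int(np.argmax(scores))
        d_best = engine.dm(candidates[best])
        null = [
            engine.shuffled_cmi(d_target, d_best, d_cond, rng) for _ in range(ns)
        ]
        threshold = float(np.percentile(null, 100.0 * (1.0 - alpha)))
        if scores[best] <= threshold:
            break
        selected.append(candidates.pop(best))
        values.append(float(scores[best]))
        thresholds.append(threshold)
        d_cond = d_best if d_cond is None else np.maximum(d_cond, d_best)
    return EmbeddingVector(
        target=target,
        selected=tuple(selected),
        cmi_values=tuple(values),
        thresholds=tuple(thresholds),
    )


@dataclass(frozen=True)
class MfLinkEstimate:
    """One directed-link estimate from the model-free approach."""

    source: str
    target: str
    T: float
    embedding: EmbeddingVector
    k: int

    @property
    def source_selected(self) -> bool:
        return any(c[0] == self.source for c in self.embedding.selected)


def _link_from_embedding(
    engine: _EmbeddingEngine, embedding: EmbeddingVector, source: str, k: int
) -> MfLinkEstimate:
    vi, rest = embedding.partition(source)
    if not vi:
        return MfLinkEstimate(source, embedding.target, 0.0, embedding, k)
    d_target = engine.dm((embedding.target, 0))
    t = engine.cmi(d_target, engine.block_dm(vi), engine.block_dm(rest))
    return MfLinkEstimate(source, embedding.target, float(t), embedding, k)


def mf_cte(
    series: BeatSeries,
    source: str,
    target: str,
    dag: ZeroLagDag | None = None,
    L: int = DEFAULT_L,
    k: int = DEFAULT_K,
    ns: int = DEFAULT_NS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> MfLinkEstimate:
    """Model-free conditional transfer entropy source -> target.

    The embedding is selected with the full candidate set (source
    included); T is the fixed-eps CMI between the target's present and the
    admitted source components given the other admitted components, and is
    exactly 0 when no source component was admitted.
    """
    dag = dag or DEFAULT_DAG
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    engine = _make_engine(series, L, k, rng)
    emb = nonuniform_embed(series, target, dag, L, k, ns, alpha, rng, _engine=engine)
    return _link_from_embedding(engine, emb, source, k)


def mf_network(
    series: BeatSeries,
    dag: ZeroLagDag | None = None,
    L: int = DEFAULT_L,
    k: int = DEFAULT_K,
    ns: int = DEFAULT_NS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> list[MfLinkEstimate]:
    """All M(M-1) directed links.

    The candidate set is always the full one, so the selected embedding is
    a function of the target alone; it is computed once per target and
    shared by that target's three sources (identical result, less work).
    """
    dag = dag or DEFAULT_DAG
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    engine = _make_engine(series, L, k, rng)
    out: list[MfLinkEstimate] = []
    for target in series.nodes:
        emb = nonuniform_embed(series, target, dag, L, k, ns, alpha, rng, _engine=engine)
        for source in series.nodes:
            if source != target:
                out.append(_link_from_embedding(engine, emb, source, k))
    return out


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------


class KnnCausality:
    """Model-free causality analysis of one beat series.

    Parameters mirror the estimation settings: maximum candidate lag ``L``,
    neighbour count ``k``, shuffle-null size ``ns`` and admission level
    ``alpha``.
    """

    def __init__(
        self,
        series: BeatSeries | pd.DataFrame,
        dag: ZeroLagDag | None = None,
        L: int = DEFAULT_L,
        k: int = DEFAULT_K,
        ns: int = DEFAULT_NS,
        alpha: float = DEFAULT_ALPHA,
    ):
        if isinstance(series, pd.DataFrame):
            series = BeatSeries(series)
        self.series = series
        self.dag = dag or DEFAULT_DAG
        self.L, self.k, self.ns, self.alpha = L, k, ns, alpha

    def fit(self, seed: int | np.random.Generator | None = None) -> "KnnCausalityResults":
        links = mf_network(
            self.series, self.dag, self.L, self.k, self.ns, self.alpha, seed
        )
        return KnnCausalityResults(self, links)


class KnnCausalityResults:
    def __init__(self, model: KnnCausality, links: list[MfLinkEstimate]):
        self.model = model
        self.links = links

    def link(self, source: str, target: str) -> MfLinkEstimate:
        for e in self.links:
            if e.source == source and e.target == target:
                return e
        raise KeyError((source, target))

    def causality_network(self) -> pd.DataFrame:
        s = self.model.series
        return pd.DataFrame(
            {
                "subject": s.subject_id,
                "condition": s.condition,
                "estimator": "mf",
                "source": [e.source for e in self.links],
                "target": [e.target for e in self.links],
                "T": [e.T for e in self.links],
                "embedding": [
                    ";".join(f"{n}-{lag}" for n, lag in e.embedding.selected)
                    for e in self.links
                ],
                "k": self.model.k,
            }
        )

    def summary(self) -> str:
        net = self.causality_network()
        lines = [
            "kNN conditional transfer entropy (model-free)",
            f"  subject: {self.model.series.subject_id}"
            f"  condition: {self.model.series.condition}",
            f"  L = {self.model.L}, k = {self.model.k}, "
            f"Ns = {self.model.ns}, alpha = {self.model.alpha}",
            "",
            net[["source", "target", "T", "embedding"]].to_string(
                index=False, float_format=lambda v: f"{v:8.4f}"
            ),
        ]
        return "\n".join(lines)
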
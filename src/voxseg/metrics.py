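"""Segmentation-quality metrics.

Two procedures quantify segmentation quality without ground truth:

* **Spurious co-expression.** For gene i let P_i be the set of cells with
  count ≥ 1. The conditional co-expression C_ij = |P_i ∩ P_j| / |P_j|
  inflates when transcripts bleed across cell boundaries. Gene pairs
  whose C_ij rises ≥ 1.5-fold between nuclear and deliberately expanded
  nuclear segmentation are labelled spurious; a segmentation method is
  then scored by its C_ij on those pairs relative to nuclear
  segmentation. Counts are first equalized by keeping cells with ≥ 50
  transcripts and redrawing each retained cell's vector from a
  Multinomial(50, observed proportions), which stops the metric being
  cheated by under-assignment or over-splitting.

* **Tumor proximity.** On the Delaunay graph of cell centroids with a
  chosen cell type made absorbing, the expected hitting time t = (I−Q)⁻¹1
  of a uniform random walk measures each cell's proximity to that type;
  dividing by the hitting time measured after a k-step background walk
  (local shuffling) normalizes away local composition.

Count-matrix orientation throughout this module: cells × genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay


def censored_log_proportions(counts: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Per-cell proportions floored at ``floor`` and log-transformed."""
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every cell must have a positive total count")
    P = X / totals[:, None]
    return np.log(np.maximum(P, floor))


def conditional_coexpression(counts: np.ndarray) -> np.ndarray:
    """C_ij = |P_i ∩ P_j| / |P_j| over cells×genes counts; columns with no
    expressing cell give C_·j = 0."""
    B = (np.asarray(counts) >= 1).astype(np.int64)
    N = B.T @ B  # N_ij = cells expressing both i and j
    nj = np.diag(N).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(nj[None, :] > 0, N / nj[None, :], 0.0)
    return C


def find_spurious_pairs(
    C_nuclear: np.ndarray, C_expanded: np.ndarray, fold_threshold: float = 1.5
):
    """Ordered gene pairs (i, j), i ≠ j, whose conditional co-expression
    inflates at least ``fold_threshold``-fold under expansion. Pairs with
    zero nuclear co-expression are excluded (the fold is undefined) and
    returned separately."""
    Cn = np.asarray(C_nuclear, dtype=float)
    Ce = np.asarray(C_expanded, dtype=float)
    off = ~np.eye(Cn.shape[0], dtype=bool)
    defined = (Cn > 0) & off
    spurious = defined & (np.log2(np.where(defined, Ce / np.where(Cn > 0, Cn, 1.0), 1.0))
                          >= np.log2(fold_threshold))
    undefined = off & (Cn == 0) & (Ce > 0)
    return list(zip(*np.nonzero(spurious))), list(zip(*np.nonzero(undefined)))


def downsample_counts(counts: np.ndarray, total: int = 50, rng=None):
    """Keep cells with at least ``total`` transcripts and redraw each kept
    cell from Multinomial(total, observed proportions); every output row
    sums to exactly ``total``. Returns (downsampled, kept row indices)."""
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(counts)
    sums = X.sum(axis=1)
    kept = np.flatnonzero(sums >= total)
    out = np.empty((len(kept), X.shape[1]), dtype=np.int64)
    for r, i in enumerate(kept):
        out[r] = rng.multinomial(total, X[i] / sums[i])
    return out, kept


@dataclass
class CoexpressionReport:
    ratios: np.ndarray  # per-pair C_method / C_nuclear
    pairs: list  # pairs actually scored
    excluded: list  # spurious pairs with zero nuclear co-expression
    quantiles: dict

    @property
    def median(self) -> float:
        return float(np.median(self.ratios)) if len(self.ratios) else np.nan


def relative_spurious_score(
    method_counts: np.ndarray, nuclear_counts: np.ndarray, spurious_pairs
) -> CoexpressionReport:
    """Per spurious pair, the method's conditional co-expression divided
    by the nuclear-segmentation rate (both on downsampled counts)."""
    if not len(spurious_pairs):
        raise ValueError("empty spurious-pair list")
    Cm = conditional_coexpression(method_counts)
    Cn = conditional_coexpression(nuclear_counts)
    ratios, used, excluded = [], [], []
    for i, j in spurious_pairs:
        if Cn[i, j] > 0:
            ratios.append(Cm[i, j] / Cn[i, j])
            used.append((i, j))
        else:
            excluded.append((i, j))
    ratios = np.asarray(ratios)
    qs = {q: float(np.quantile(ratios, q)) for q in (0.25, 0.5, 0.75)} if len(ratios) else {}
    return CoexpressionReport(ratios=ratios, pairs=used, excluded=excluded, quantiles=qs)


# ---------------------------------------------------------------------------
# absorbing random-walk proximity


@dataclass
class ProximityGraph:
    """Delaunay cell-neighborhood graph with an absorbing cell type.

    Transitions are uniform over Delaunay neighbors; absorbing nodes keep
    incoming edges but have none outgoing. ``indptr``/``indices`` hold
    the full undirected adjacency in CSR layout.
    """

    points: np.ndarray  # (n, 2)
    types: np.ndarray
    absorbing: np.ndarray  # (n,) bool
    indptr: np.ndarray
    indices: np.ndarray
    transient: np.ndarray  # node ids of transient cells
    Q: sparse.csr_matrix  # transient-to-transient transition block

    def degree(self, v: int) -> int:
        return self.indptr[v + 1] - self.indptr[v]


def delaunay_graph(centroids, types, absorbing_type, jitter_seed: int = 0) -> ProximityGraph:
    """Build the proximity graph from 2D centroids (x, y) and type labels."""
    pts = np.asarray(centroids, dtype=float)[:, :2]
    types = np.asarray(types)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 centroids")
    # deterministic jitter guards against collinear/cocircular degeneracy
    jit = np.random.default_rng(jitter_seed).normal(0, 1e-9, pts.shape)
    tri = Delaunay(pts + jit)
    nbr = [set() for _ in range(n)]
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                u, v = simplex[a], simplex[b]
                nbr[u].add(int(v))
                nbr[v].add(int(u))
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        indptr[v + 1] = indptr[v] + len(nbr[v])
    indices = np.concatenate([sorted(nbr[v]) for v in range(n)]).astype(np.int64)

    absorbing = types == absorbing_type
    transient = np.flatnonzero(~absorbing)
    tmap = -np.ones(n, dtype=np.int64)
    tmap[transient] = np.arange(len(transient))
    rows, cols, vals = [], [], []
    for ti, v in enumerate(transient):
        nbrs = indices[indptr[v] : indptr[v + 1]]
        if len(nbrs) == 0:
            continue
        p = 1.0 / len(nbrs)
        for w in nbrs:
            if tmap[w] >= 0:
                rows.append(ti)
                cols.append(tmap[w])
                vals.append(p)
    Q = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(transient), len(transient))
    )
    return ProximityGraph(
        points=pts,
        types=types,
        absorbing=absorbing,
        indptr=indptr,
        indices=indices,
        transient=transient,
        Q=Q,
    )


def expected_hitting_time(graph: ProximityGraph) -> np.ndarray:
    """Expected steps to absorption for each transient node (aligned with
    ``graph.transient``); ∞ where no absorbing node is reachable."""
    nt = len(graph.transient)
    t = np.full(nt, np.inf)
    if nt == 0:
        return t
    reachable = _reaches_absorbing(graph)
    if not reachable.any():
        return t
    Q = graph.Q[np.ix_(reachable, reachable)].tocsc()
    A = sparse.eye(int(reachable.sum()), format="csc") - Q
    t[reachable] = spsolve(A, np.ones(int(reachable.sum())))
    return t


def _reaches_absorbing(graph: ProximityGraph) -> np.ndarray:
    """Transient nodes with a directed path to an absorbing node."""
    n = len(graph.points)
    good = np.zeros(n, dtype=bool)
    frontier = list(np.flatnonzero(graph.absorbing))
    good[frontier] = True
    # walk edges backwards: any node adjacent to a good node is good
    # (transition graph follows full adjacency from transient nodes)
    while frontier:
        v = frontier.pop()
        for w in graph.indices[graph.indptr[v] : graph.indptr[v + 1]]:
            if not good[w] and not graph.absorbing[w]:
                good[w] = True
                frontier.append(int(w))
    return good[graph.transient]


def normalized_hitting_time(
    graph: ProximityGraph,
    k_steps: int = 10,
    repeats: int = 100,
    rng=None,
) -> dict:
    """Hitting times normalized by a k-step-walk background.

    Each transient cell is first sent on a k-step uniform random walk over
    the full undirected Delaunay graph — a local shuffle that preserves
    neighborhood composition, so absorbing cells are ordinary waypoints
    during the walk — and the background t̄_i is the mean hitting time at
    the walk's endpoint over ``repeats`` walks (0 when the endpoint is
    absorbing). Returns the raw ``t``, background ``t_background`` and
    ``relative`` = t / t̄, which is ≈ 1 under random spatial organization.
    (Terminating background walks at the first absorbing contact would
    instead give E[t̄] = t − E[min(k, absorption time)] by the optional-
    stopping identity, forcing every relative score above 1.)
    """
    if k_steps < 0 or repeats < 1:
        raise ValueError("k_steps must be ≥ 0 and repeats ≥ 1")
    rng = np.random.default_rng() if rng is None else rng
    t = expected_hitting_time(graph)
    nt = len(graph.transient)
    t_full = np.zeros(len(graph.points))
    t_full[graph.transient] = t

    pos = np.repeat(graph.transient, repeats)
    deg = np.diff(graph.indptr)
    for _ in range(k_steps):
        u = rng.random(len(pos))
        pos = graph.indices[graph.indptr[pos] + (u * deg[pos]).astype(np.int64)]
    endpoint_t = np.where(graph.absorbing[pos], 0.0, t_full[pos])
    t_bar = endpoint_t.reshape(nt, repeats).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(t_bar > 0, t / t_bar, np.inf)
    return {"t": t, "t_background": t_bar, "relative": rel}
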
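"""Small enumerable sampler configurations shared by tests.

The toys pair a tiny lattice with fixed expression parameters so the
chain's stationary distribution can be computed by exhaustive
enumeration, independently of the sampler's own likelihood code.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from voxseg.lattice import CellState, VoxelLattice
from voxseg.model import ModelParams, PriorConfig
from voxseg.sampler import BoundarySampler, SamplerConfig, Stage

TAU = np.array([[0.5, 0.05], [0.05, 0.5]])
TAU_BG = np.array([0.05, 0.05])


def _params(mu_vol: float) -> ModelParams:
    return ModelParams(
        tau_bg=TAU_BG.copy(),
        tau=TAU.copy(),
        alpha=np.ones((2, 1)),
        phi=np.zeros((2, 1)),
        h=1.0,
        pi=np.ones(1),
        z=np.zeros(2, dtype=int),
        mu_vol=np.array([mu_vol]),
        prec_vol=np.array([1.0]),
    )


def make_chain_toy(seed: int = 0, **cfg_kw) -> BoundarySampler:
    """6×1×1 lattice, two cells seeded at the ends, two genes.

    The proposal structure anchors each cell to its end voxel (no
    mismatch edge can ever target an end voxel whose face neighbor
    belongs to the same cell, and annihilation is prohibited), so the
    reachable states are exactly: cell 0 a run from the left, cell 1 a
    run from the right, unassigned space between.
    """
    lattice = VoxelLattice(np.zeros(3), np.ones(3), (6, 1, 1))
    lattice.state[:, 0, 0] = [0, -1, -1, -1, -1, 1]
    cells = CellState.from_lattice(lattice, 2)
    gene = np.array([0, 0, 1, 1])
    pos = np.array([[1.5, 0.5, 0.5], [2.5, 0.5, 0.5], [3.5, 0.5, 0.5], [4.5, 0.5, 0.5]])
    cfg = SamplerConfig(
        schedule=[Stage(4.0, 1, 1)], use_checkerboard=False, seed=seed, **cfg_kw
    )
    return BoundarySampler(
        lattice,
        cells,
        _params(math.log(3.0)),
        PriorConfig(k=1),
        gene,
        pos,
        np.full(4, -1),
        cfg,
        np.random.default_rng(seed),
    )


def chain_toy_posterior() -> dict:
    """Exhaustive posterior of the 6×1×1 toy over its reachable states,
    computed directly from the model's densities (scipy-free arithmetic,
    no sampler code)."""
    gene = [0, 0, 1, 1]
    tvox = [1, 2, 3, 4]
    mu, prec = math.log(3.0), 1.0
    states, ws = [], []
    for st in product([-1, 0, 1], repeat=6):
        occ0 = [i for i, v in enumerate(st) if v == 0]
        occ1 = [i for i, v in enumerate(st) if v == 1]
        if not occ0 or not occ1:
            continue
        if max(occ0) - min(occ0) + 1 != len(occ0):
            continue
        if max(occ1) - min(occ1) + 1 != len(occ1):
            continue
        if st[0] != 0 or st[5] != 1:
            continue
        lw = 0.0
        for c, occ in ((0, occ0), (1, occ1)):
            nu = float(len(occ))
            lw += -nu * TAU[:, c].sum()
            lv = math.log(nu)
            lw += -lv + 0.5 * math.log(prec / (2 * math.pi)) - 0.5 * prec * (lv - mu) ** 2
        for g, v in zip(gene, tvox):
            c = st[v]
            lw += math.log(TAU_BG[g] + (TAU[g, c] if c >= 0 else 0.0))
        states.append(st)
        ws.append(lw)
    ws = np.array(ws)
    p = np.exp(ws - ws.max())
    p /= p.sum()
    return dict(zip(states, p))


# -- 2D toy: articulation matters here ---------------------------------------

_COORDS_2D = [(x, y) for x in range(3) for y in range(2)]


def make_grid_toy(seed: int = 0, **cfg_kw) -> BoundarySampler:
    """3×2×1 lattice with two single-voxel cells at opposite corners; in
    2D the local-connectivity (articulation) rule genuinely constrains
    the chain."""
    lattice = VoxelLattice(np.zeros(3), np.ones(3), (3, 2, 1))
    lattice.state[:] = -1
    lattice.state[0, 0, 0] = 0
    lattice.state[2, 1, 0] = 1
    cells = CellState.from_lattice(lattice, 2)
    gene = np.array([0, 1])
    pos = np.array([[0.5, 1.5, 0.5], [2.5, 0.5, 0.5]])
    cfg = SamplerConfig(
        schedule=[Stage(4.0, 1, 1)], use_checkerboard=False, seed=seed, **cfg_kw
    )
    return BoundarySampler(
        lattice,
        cells,
        _params(math.log(2.0)),
        PriorConfig(k=1),
        gene,
        pos,
        np.full(2, -1),
        cfg,
        np.random.default_rng(seed),
    )


def _moore_nbrs_2d(p):
    x, y = p
    return [
        (x + dx, y + dy)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        if (dx, dy) != (0, 0) and 0 <= x + dx < 3 and 0 <= y + dy < 2
    ]


def _face_nbrs_2d(p):
    x, y = p
    return [q for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)) if 0 <= q[0] < 3 and 0 <= q[1] < 2]


def _moore_connected(occ) -> bool:
    occ = set(occ)
    if not occ:
        return False
    start = next(iter(occ))
    seen = {start}
    stack = [start]
    while stack:
        p = stack.pop()
        for q in _moore_nbrs_2d(p):
            if q in occ and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(occ)


def _local_ok(smap, j, label) -> bool:
    nbrs = [q for q in _moore_nbrs_2d(j) if smap[q] == label]
    return _moore_connected(nbrs) if nbrs else False


def _legal_moves(st):
    """All single-flip successors under the annihilation and
    local-connectivity rules (first-principles reimplementation)."""
    smap = dict(zip(_COORDS_2D, st))
    out = []
    for jidx, j in enumerate(_COORDS_2D):
        for i in _face_nbrs_2d(j):
            if smap[i] == smap[j]:
                continue
            for new in {smap[i], -1}:
                if new == smap[j]:
                    continue
                old = smap[j]
                if old >= 0:
                    if sum(1 for p in _COORDS_2D if smap[p] == old) == 1:
                        continue
                    if not _local_ok(smap, j, old):
                        continue
                if new >= 0 and not _local_ok(smap, j, new):
                    continue
                st2 = list(st)
                st2[jidx] = new
                out.append(tuple(st2))
    return out


def grid_toy_posterior() -> dict:
    """Posterior of the 3×2×1 toy restricted to the states reachable from
    its initial configuration."""
    tvox = {0: (0, 1), 1: (2, 0)}
    mu, prec = math.log(2.0), 1.0
    post = {}
    for st in product([-1, 0, 1], repeat=6):
        smap = dict(zip(_COORDS_2D, st))
        lw = 0.0
        ok = True
        for c in (0, 1):
            occ = [p for p in _COORDS_2D if smap[p] == c]
            if not occ or not _moore_connected(occ):
                ok = False
                break
            nu = float(len(occ))
            lw += -nu * TAU[:, c].sum()
            lv = math.log(nu)
            lw += -lv + 0.5 * math.log(prec / (2 * math.pi)) - 0.5 * prec * (lv - mu) ** 2
        if not ok:
            continue
        for g in (0, 1):
            c = smap[tvox[g]]
            lw += math.log(TAU_BG[g] + (TAU[g, c] if c >= 0 else 0.0))
        post[st] = lw

    start = (0, -1, -1, -1, -1, 1)
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for s2 in _legal_moves(s):
            if s2 not in seen:
                seen.add(s2)
                stack.append(s2)
    sup = {k: w for k, w in post.items() if k in seen}
    ws = np.array(list(sup.values()))
    p = np.exp(ws - ws.max())
    p /= p.sum()
    return dict(zip(sup, p))


def empirical_tv(sampler: BoundarySampler, posterior: dict, n_proposals: int) -> float:
    """Total-variation distance between the chain's empirical state
    frequencies and an enumerated posterior (mass on states outside the
    posterior's support counts fully)."""
    from collections import Counter

    cnt = Counter()
    for _ in range(n_proposals):
        prop = sampler.propose_flip(0)
        if prop is not None:
            sampler.evaluate_acceptance(prop)
        cnt[tuple(int(v) for v in sampler.st)] += 1
    tot = sum(cnt.values())
    tv = 0.5 * sum(abs(cnt.get(k, 0) / tot - p) for k, p in posterior.items())
    tv += 0.5 * sum(c / tot for k, c in cnt.items() if k not in posterior)
    return tv
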
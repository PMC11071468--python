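"""Metropolis–Hastings segmentation engine.

The sampler perturbs the voxel lattice with label-copy proposals drawn
uniformly from the mismatch-edge pool, occasionally proposing the
unassigned state instead ("bubble" moves, which make pocket formation and
popping mutually reversible). Each proposal is screened by three hard
rules before its probability is evaluated:

* a cell reduced to a single voxel is never changed (annihilation would
  be irreversible);
* a flip may not alter the local (Moore-neighborhood) connectivity of
  either affected cell — equivalently the same-label Moore neighbors of
  the flipped voxel must form exactly one connected component;
* the resulting layer of either affected cell may not exceed the
  perimeter bound ξ·raw ≤ b·2√(π·area).

Surviving proposals are accepted with the Metropolis–Hastings probability
min(1, exp(Δlog posterior) · q(σ|σ')/q(σ'|σ)), where the proposal-ratio
accounts for the pool-size change and the copy/bubble branch structure of
the reverse move. Temperature is fixed at 1.

Interleaved with boundary sweeps are full Gibbs parameter sweeps (model
module) and transcript-repositioning sweeps under the Normal-mixture
diffusion prior. Resolution doubles between schedule stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lattice as lat
from . import model as mdl
from .io import TranscriptTable
from .lattice import (
    MOORE_OFFSETS,
    UNASSIGNED,
    VON_NEUMANN_OFFSETS,
    XI_DEFAULT,
    CellState,
    CheckerboardSchedule,
    EdgePool,
    VoxelLattice,
    build_lattice,
    count_bitmask_components,
    double_resolution,
    initialize_from_nuclei,
    neighbor_matrix,
    voxels_of,
)
from .model import CountMatrix, ModelParams, PriorConfig

_INPLANE_IDS = [i for i, (dx, dy, dz) in enumerate(MOORE_OFFSETS) if dz == 0]


@dataclass
class RepositionConfig:
    """Transcript-diffusion prior and proposal kernel."""

    rho: float = 0.2  # weight of the wide diffusion component
    sigma_a: float = 4.0  # μm, wide component sd
    sigma_b: float = 0.5  # μm, narrow component sd
    proposal_sd_xy: float = 1.0  # μm, symmetric random-walk kernel
    proposal_sd_z: float = 0.5
    every_n_sweeps: int = 5


@dataclass
class Stage:
    voxel_xy: float  # μm
    z_layers: int
    sweeps: int


@dataclass
class SamplerConfig:
    b_factor: float = 1.3
    bubble_prob: float = 0.05
    p_nuc: float = 0.8
    reposition: RepositionConfig = field(default_factory=RepositionConfig)
    schedule: list[Stage] = field(
        default_factory=lambda: [Stage(4.0, 1, 200), Stage(2.0, 2, 200), Stage(1.0, 4, 200)]
    )
    bin_size_um: float | None = None  # None: calibrate from nuclei spacing
    seed: int = 0
    min_cell_transcripts: int = 10
    xi: float = XI_DEFAULT
    param_every_n_sweeps: int = 1
    init_param_sweeps: int = 20
    use_checkerboard: bool = True
    # validation-only switches; breaking either must break the
    # detailed-balance audit
    disable_q_ratio: bool = False
    disable_articulation: bool = False

    def __post_init__(self):
        if not (0.0 <= self.bubble_prob < 1.0):
            raise ValueError("bubble_prob must lie in [0, 1)")
        for a, b in zip(self.schedule, self.schedule[1:]):
            if not math.isclose(a.voxel_xy, 2.0 * b.voxel_xy):
                raise ValueError("schedule voxel sizes must halve between stages")
            if b.z_layers != 2 * a.z_layers:
                raise ValueError("schedule z_layers must double between stages")


@dataclass
class Proposal:
    source: int  # flat voxel index i
    target: int  # flat voxel index j
    new_state: int  # cell id or UNASSIGNED
    kind: str  # "copy" | "bubble"
    log_q_ratio: float = 0.0


@dataclass
class SegmentationResult:
    """Final segmentation: per-transcript assignments, counts over
    retained cells (≥ min_cell_transcripts), metadata and boundaries."""

    gene_names: list[str]
    gene: np.ndarray
    assignment: np.ndarray  # (M,) retained cell id, -1 otherwise
    status: np.ndarray  # (M,) "assigned" | "background" | "filtered"
    counts: CountMatrix  # genes × retained cells
    cell_ids: np.ndarray  # retained cell ids, column order of counts
    cell_meta: pd.DataFrame
    polygons: dict  # (cell_id, z_layer) -> list of (k, 2) rings, μm
    observed_positions: np.ndarray
    inferred_positions: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


class BoundarySampler:
    """Mutable sampler state: lattice + cells + parameters + transcripts,
    with the incremental caches the proposal loop needs.

    Drives three kinds of moves: boundary flips (``boundary_sweep``),
    Gibbs parameter updates (``parameter_sweep``) and transcript
    repositioning (``reposition_sweep``).
    """

    def __init__(
        self,
        lattice: VoxelLattice,
        cells: CellState,
        params: ModelParams,
        prior: PriorConfig,
        gene: np.ndarray,
        observed: np.ndarray,
        nuclear_cell: np.ndarray,
        cfg: SamplerConfig,
        rng: np.random.Generator,
    ):
        self.lattice = lattice
        self.cells = cells
        self.params = params
        self.prior = prior
        self.cfg = cfg
        self.rng = rng
        self.gene = np.asarray(gene, dtype=np.int64)
        self.observed = np.asarray(observed, dtype=float)
        self.inferred = self.observed.copy()
        self.nuclear_cell = np.asarray(nuclear_cell, dtype=np.int64)
        self.m = params.tau.shape[0]
        self.n = cells.n
        self._log_pnuc = math.log(cfg.p_nuc) - math.log1p(-cfg.p_nuc)
        self.accept_log: list[dict] = []
        self._rebuild_geometry()
        self.refresh_expression_caches()
        self._ubuf = rng.random(1 << 14)
        self._uptr = 0

    # -- geometry ---------------------------------------------------------
    def _rebuild_geometry(self):
        lattice = self.lattice
        self.st = lattice.state.reshape(-1)
        self.vn = neighbor_matrix(lattice.dims, VON_NEUMANN_OFFSETS)
        self.moore = neighbor_matrix(lattice.dims, MOORE_OFFSETS)
        nz = lattice.dims[2]
        self.z_of = (np.arange(lattice.n_voxels) % nz).astype(np.int64)
        if self.cfg.use_checkerboard:
            bs = self._bin_voxels()
            self.schedule = CheckerboardSchedule.build(lattice, bs)
        else:
            self.schedule = None
        self.pool = EdgePool(lattice, self.schedule)
        self.phase_flat = self.pool.phase_flat
        self.b_vol = lattice.voxel_volume
        self.tx_flat = lattice.flat(voxels_of(lattice, self.inferred))
        self._rebuild_voxel_tx()

    def _bin_voxels(self) -> int:
        um = self.cfg.bin_size_um if self.cfg.bin_size_um is not None else 40.0
        return max(2, int(round(um / self.lattice.voxel_size[0])))

    def _rebuild_voxel_tx(self):
        order = np.argsort(self.tx_flat, kind="stable")
        fs = self.tx_flat[order]
        cuts = np.flatnonzero(np.diff(fs)) + 1
        groups = np.split(order, cuts)
        self.voxel_tx = {int(fs[c]): g for c, g in zip(np.r_[0, cuts], groups)} if len(fs) else {}

    def refresh_expression_caches(self):
        """Per-cell total rates and log point-rates; call after any
        parameter change."""
        p = self.params
        self.T = p.tau.sum(axis=0)  # (n,)
        self.lt = np.column_stack(
            [np.log(p.tau_bg[:, None] + p.tau), np.log(p.tau_bg)]
        )  # (m, n+1); column n = background only
        self.muv = p.mu_vol[p.z]
        self.precv = p.prec_vol[p.z]

    # -- small helpers ----------------------------------------------------
    def _u(self) -> float:
        if self._uptr >= len(self._ubuf):
            self._ubuf = self.rng.random(1 << 14)
            self._uptr = 0
        v = self._ubuf[self._uptr]
        self._uptr += 1
        return v

    def _label_components(self, j: int, label: int) -> int:
        bits = 0
        st = self.st
        for o, f in enumerate(self.moore[j]):
            if f >= 0 and st[f] == label:
                bits |= 1 << o
        return count_bitmask_components(bits)

    def _vol_logprior(self, c: int, nu: float) -> float:
        lv = math.log(nu)
        prec = self.precv[c]
        return -lv + 0.5 * math.log(prec / (2.0 * math.pi)) - 0.5 * prec * (lv - self.muv[c]) ** 2

    def current_counts(self) -> CountMatrix:
        owner = self.st[self.tx_flat]
        return CountMatrix.from_assignments(self.gene, owner, self.m, self.n)

    def total_volume(self) -> float:
        return self.lattice.n_voxels * self.b_vol

    def log_posterior(self) -> float:
        """Full-state log posterior (likelihood + volume prior + nuclear
        prior), for trace diagnostics and audits."""
        counts = self.current_counts()
        ll = mdl.log_likelihood(
            self.cells.volume_um3, counts, self.params, self.total_volume()
        )
        for c in range(self.n):
            ll += self._vol_logprior(c, self.cells.voxel_count[c] * self.b_vol)
        lab = self.nuclear_cell
        has = lab >= 0
        match = self.st[self.tx_flat[has]] == lab[has]
        ll += float(match.sum()) * math.log(self.cfg.p_nuc)
        ll += float((~match).sum()) * math.log1p(-self.cfg.p_nuc)
        return ll

    # -- boundary proposals ----------------------------------------------
    def propose_flip(self, phase: int) -> Proposal | None:
        """Draw a uniform pool edge in ``phase`` and the copy/bubble
        branch; returns None when the phase pool is empty."""
        npool = self.pool.phase_size(phase)
        if npool == 0:
            return None
        i, j = self.pool.sample(phase, self._u())
        bubble = self.cfg.bubble_prob > 0 and self._u() < self.cfg.bubble_prob
        new = UNASSIGNED if bubble else int(self.st[i])
        return Proposal(i, j, new, "bubble" if bubble else "copy")

    def evaluate_acceptance(self, prop: Proposal) -> bool:
        """Screen, score and (on acceptance) apply one flip proposal."""
        j = prop.target
        st = self.st
        old = int(st[j])
        new = prop.new_state
        if new == old:
            return False
        cells = self.cells
        cfg = self.cfg

        # annihilation prohibition and local-connectivity preservation
        if old >= 0:
            if cells.voxel_count[old] == 1:
                return False
            if not cfg.disable_articulation and self._label_components(j, old) != 1:
                return False
        if new >= 0:
            if not cfg.disable_articulation and self._label_components(j, new) != 1:
                return False

        # perimeter bound on the affected layer
        zj = int(self.z_of[j])
        n_inb = 0
        cnt_old = 0
        cnt_new = 0
        for o in _INPLANE_IDS:
            f = self.moore[j, o]
            if f >= 0:
                n_inb += 1
                sf = st[f]
                if sf == old:
                    cnt_old += 1
                elif sf == new:
                    cnt_new += 1
        xi = cfg.xi
        bb = 2.0 * cfg.b_factor * math.sqrt(math.pi)
        # Layers already over the bound (possible right after a resolution
        # doubling, which inflates raw mismatch counts by more than the
        # bound's factor of two) may only move toward compliance; compliant
        # layers may never leave it.
        if old >= 0:
            raw_old_new = cells.layer_perimeter_raw[old, zj] - n_inb + 2 * cnt_old
            vol_old_new = cells.layer_volume[old, zj] - 1
            if vol_old_new > 0 and xi * raw_old_new > bb * math.sqrt(vol_old_new):
                raw_cur = cells.layer_perimeter_raw[old, zj]
                vol_cur = cells.layer_volume[old, zj]
                if raw_old_new * math.sqrt(vol_cur) > raw_cur * math.sqrt(vol_old_new):
                    return False
        if new >= 0:
            raw_new_new = cells.layer_perimeter_raw[new, zj] + n_inb - 2 * cnt_new
            vol_new_new = cells.layer_volume[new, zj] + 1
            if xi * raw_new_new > bb * math.sqrt(vol_new_new):
                raw_cur = cells.layer_perimeter_raw[new, zj]
                vol_cur = cells.layer_volume[new, zj]
                if vol_cur == 0 or raw_new_new * math.sqrt(vol_cur) > raw_cur * math.sqrt(
                    vol_new_new
                ):
                    return False

        # Δ log posterior
        d = self.delta_loglik(j, old, new)
        if old >= 0:
            nu = cells.voxel_count[old] * self.b_vol
            d += self._vol_logprior(old, nu - self.b_vol) - self._vol_logprior(old, nu)
        if new >= 0:
            nu = cells.voxel_count[new] * self.b_vol
            d += self._vol_logprior(new, nu + self.b_vol) - self._vol_logprior(new, nu)
        txs = self.voxel_tx.get(j)
        if txs is not None:
            for t in txs:
                lab = self.nuclear_cell[t]
                if lab >= 0:
                    if lab == new:
                        d += self._log_pnuc
                    elif lab == old:
                        d -= self._log_pnuc

        # proposal-density ratio
        if not cfg.disable_q_ratio:
            p_bub = cfg.bubble_prob
            ph = int(self.phase_flat[j])
            n_old_nb = 0
            n_new_nb = 0
            n_diff_old = 0
            n_diff_new = 0
            d_pool = 0
            for f in self.vn[j]:
                if f < 0:
                    continue
                sf = st[f]
                if sf == old:
                    n_old_nb += 1
                if sf == new:
                    n_new_nb += 1
                w = 1 + (self.phase_flat[f] == ph)
                if sf != old:
                    n_diff_old += 1
                    d_pool -= w
                if sf != new:
                    n_diff_new += 1
                    d_pool += w
            q_fwd = (1.0 - p_bub) * n_new_nb + (p_bub * n_diff_old if new < 0 else 0.0)
            q_rev = (1.0 - p_bub) * n_old_nb + (p_bub * n_diff_new if old < 0 else 0.0)
            if q_rev <= 0.0:
                return False
            npool = self.pool.phase_size(ph)
            prop.log_q_ratio = (
                math.log(q_rev) - math.log(q_fwd) + math.log(npool) - math.log(npool + d_pool)
            )
            d += prop.log_q_ratio

        if d < 0 and self._u() >= math.exp(d):
            return False

        self._apply_flip(j, old, new, zj)
        return True

    def delta_loglik(self, j: int, old: int, new: int) -> float:
        """Incremental Poisson point-process log-likelihood change of
        flipping voxel j from ``old`` to ``new``: only the two affected
        cells' exposure terms and the transcripts inside j contribute."""
        d = 0.0
        if old >= 0:
            d += self.b_vol * self.T[old]
        if new >= 0:
            d -= self.b_vol * self.T[new]
        txs = self.voxel_tx.get(j)
        if txs is not None:
            lt = self.lt
            oc = old if old >= 0 else self.m_col
            nc = new if new >= 0 else self.m_col
            for t in txs:
                g = self.gene[t]
                d += lt[g, nc] - lt[g, oc]
        return d

    def _apply_flip(self, j: int, old: int, new: int, zj: int):
        """Set voxel j to ``new`` and update pool and layer tallies."""
        cells = self.cells
        n_inb = 0
        cnt_old = 0
        cnt_new = 0
        st = self.st
        for o in _INPLANE_IDS:
            f = self.moore[j, o]
            if f >= 0:
                n_inb += 1
                sf = st[f]
                if sf == old:
                    cnt_old += 1
                elif sf == new:
                    cnt_new += 1
        st[j] = new
        self.pool.update_around(j)
        if old >= 0:
            cells.layer_volume[old, zj] -= 1
            cells.voxel_count[old] -= 1
            cells.layer_perimeter_raw[old, zj] += 2 * cnt_old - n_inb
        if new >= 0:
            cells.layer_volume[new, zj] += 1
            cells.voxel_count[new] += 1
            cells.layer_perimeter_raw[new, zj] += n_inb - 2 * cnt_new

    @property
    def m_col(self) -> int:
        return self.n  # background column index in self.lt

    def run_sweep_phase(self, phase: int) -> int:
        """One pass over the current pool of ``phase``; returns number of
        accepted flips."""
        accepted = 0
        n_props = self.pool.phase_size(phase)
        for _ in range(n_props):
            prop = self.propose_flip(phase)
            if prop is None:
                break
            if self.evaluate_acceptance(prop):
                accepted += 1
        return accepted

    def boundary_sweep(self) -> int:
        acc = 0
        n_phases = self.pool.n_phases
        for phase in range(n_phases):
            acc += self.run_sweep_phase(phase)
        return acc

    # -- parameter updates -------------------------------------------------
    def parameter_sweep(self, update_z: bool = True):
        counts = self.current_counts()
        volumes = self.cells.volume_um3
        mdl.gibbs_sweep(
            counts, volumes, self.params, self.prior, self.total_volume(), self.rng,
            update_z=update_z,
        )
        self.refresh_expression_caches()

    # -- transcript repositioning -----------------------------------------
    def _mixture_logprior(self, disp: np.ndarray, active) -> np.ndarray:
        """Normal-mixture diffusion prior log density of displacements
        from the observed positions, over the spatially active axes."""
        rc = self.cfg.reposition
        ndim = len(active)
        sq = (disp[:, active] ** 2).sum(axis=1)
        la = (
            math.log(rc.rho)
            - ndim * math.log(rc.sigma_a * math.sqrt(2 * math.pi))
            - sq / (2 * rc.sigma_a**2)
        )
        lb = (
            math.log1p(-rc.rho)
            - ndim * math.log(rc.sigma_b * math.sqrt(2 * math.pi))
            - sq / (2 * rc.sigma_b**2)
        )
        hi = np.maximum(la, lb)
        return hi + np.log(np.exp(la - hi) + np.exp(lb - hi))

    def reposition_sweep(self) -> int:
        """One vectorized Metropolis sweep over inferred transcript
        positions (independent given fixed boundaries)."""
        M = len(self.gene)
        if M == 0:
            return 0
        rc = self.cfg.reposition
        lattice = self.lattice
        active = [0, 1] + ([2] if self._z_extent() > 0 else [])
        sd = np.array([rc.proposal_sd_xy, rc.proposal_sd_xy, rc.proposal_sd_z])
        if 2 not in active:
            sd[2] = 0.0
        step = self.rng.standard_normal((M, 3)) * sd
        prop = self.inferred + step
        inb = np.all((prop >= lattice.origin) & (prop <= lattice.upper), axis=1)

        new_flat = np.where(
            inb, lattice.flat(voxels_of(lattice, np.where(inb[:, None], prop, 0.0))), -1
        )
        old_owner = self.st[self.tx_flat]
        new_owner = np.where(inb, self.st[np.maximum(new_flat, 0)], 0)

        col_old = np.where(old_owner >= 0, old_owner, self.m_col)
        col_new = np.where(new_owner >= 0, new_owner, self.m_col)
        d = self.lt[self.gene, col_new] - self.lt[self.gene, col_old]
        d += self._mixture_logprior(prop - self.observed, active)
        d -= self._mixture_logprior(self.inferred - self.observed, active)
        lab = self.nuclear_cell
        has = lab >= 0
        d[has] += self._log_pnuc * (
            (new_owner[has] == lab[has]).astype(float) - (old_owner[has] == lab[has])
        )
        acc = inb & (np.log(self.rng.random(M)) < d)
        self.inferred[acc] = prop[acc]
        self.tx_flat[acc] = new_flat[acc]
        if acc.any():
            self._rebuild_voxel_tx()
        return int(acc.sum())

    def propose_reposition(self, t: int) -> bool:
        """One Metropolis update of a single transcript's latent position
        (the sweep is the vectorized form of this move)."""
        rc = self.cfg.reposition
        lattice = self.lattice
        active = [0, 1] + ([2] if self._z_extent() > 0 else [])
        sd = np.array([rc.proposal_sd_xy, rc.proposal_sd_xy, rc.proposal_sd_z])
        if 2 not in active:
            sd[2] = 0.0
        prop = self.inferred[t] + self.rng.standard_normal(3) * sd
        if np.any(prop < lattice.origin) or np.any(prop > lattice.upper):
            return False
        new_flat = int(lattice.flat(voxels_of(lattice, prop[None, :])[0]))
        old_owner = int(self.st[self.tx_flat[t]])
        new_owner = int(self.st[new_flat])
        col_old = old_owner if old_owner >= 0 else self.m_col
        col_new = new_owner if new_owner >= 0 else self.m_col
        g = self.gene[t]
        d = self.lt[g, col_new] - self.lt[g, col_old]
        d += float(self._mixture_logprior((prop - self.observed[t])[None, :], active)[0])
        d -= float(self._mixture_logprior((self.inferred[t] - self.observed[t])[None, :], active)[0])
        lab = self.nuclear_cell[t]
        if lab >= 0:
            d += self._log_pnuc * (float(new_owner == lab) - float(old_owner == lab))
        if d < 0 and math.log(self.rng.random()) >= d:
            return False
        self.inferred[t] = prop
        if new_flat != self.tx_flat[t]:
            self.tx_flat[t] = new_flat
            self._rebuild_voxel_tx()
        return True

    def _z_extent(self) -> float:
        return float(self.observed[:, 2].max() - self.observed[:, 2].min()) if len(self.observed) else 0.0

    # -- resolution schedule ----------------------------------------------
    def double(self):
        self.lattice, self.cells = double_resolution(self.lattice, self.n)
        self._rebuild_geometry()

    # -- perimeter repair ---------------------------------------------------
    def _violating_layers(self) -> list[tuple[int, int]]:
        xi = self.cfg.xi
        bb = 2.0 * self.cfg.b_factor * math.sqrt(math.pi)
        lv = self.cells.layer_volume
        lp = self.cells.layer_perimeter_raw
        bad = (lv > 0) & (xi * lp > bb * np.sqrt(np.maximum(lv, 1)))
        return [(int(c), int(z)) for c, z in zip(*np.nonzero(bad))]

    def repair_perimeters(self, max_passes: int = 200) -> bool:
        """Deterministic local search restoring the perimeter bound.

        Refining the lattice inflates raw mismatch counts by more than the
        bound's factor of 2, so freshly doubled (or freshly initialized)
        states can violate the constraint that the sampler otherwise
        preserves. This greedily applies single-voxel boundary-smoothing
        flips that strictly reduce a violating layer's perimeter-to-√area
        ratio, subject to the same connectivity/annihilation rules and
        without pushing any other layer out of compliance. Returns True
        when every layer complies.
        """
        for _ in range(max_passes):
            viol = self._violating_layers()
            if not viol:
                return True
            improved = False
            for c, z in viol:
                if self._improve_layer(c, z) or self._remove_layer_island(c, z):
                    improved = True
            if not improved:
                return False
        return not self._violating_layers()

    def _remove_layer_island(self, c: int, z: int) -> bool:
        """Detach a small in-plane island of layer (c, z) — 3D-connected
        cells may hold disconnected in-plane fragments whose perimeter
        cost no single-voxel move can repair — provided the cell stays
        connected and the layer's ratio strictly improves."""
        from scipy import ndimage

        state = self.lattice.state
        mask2d = state[:, :, z] == c
        comp, ncomp = ndimage.label(mask2d, structure=np.ones((3, 3), bool))
        if ncomp < 2:
            return False
        sizes = ndimage.sum_labels(mask2d, comp, index=np.arange(1, ncomp + 1))
        raw0 = self.cells.layer_perimeter_raw[c, z]
        vol0 = self.cells.layer_volume[c, z]
        ratio0 = raw0 / math.sqrt(vol0)
        nz = self.lattice.dims[2]
        ny = self.lattice.dims[1]
        for k in np.argsort(sizes)[:-1]:  # smallest first, never the largest
            island = comp == (k + 1)
            trial = state[:, :, z].copy()
            trial[island] = UNASSIGNED
            raw1 = int(lat._layer_perimeters(np.where(trial == c, 0, UNASSIGNED)
                                             .astype(np.int32)[:, :, None], 1)[0, 0])
            vol1 = int(vol0 - island.sum())
            if vol1 <= 0 or raw1 / math.sqrt(vol1) >= ratio0:
                continue
            cell_mask = state == c
            cell_mask[:, :, z][island] = False
            if not cell_mask.any():
                continue
            _, nc3 = ndimage.label(cell_mask, structure=np.ones((3, 3, 3), bool))
            if nc3 != 1:
                continue
            for x, y in zip(*np.nonzero(island)):
                j = (x * ny + y) * nz + z
                self._apply_flip(int(j), c, UNASSIGNED, z)
            return True
        return False

    def _improve_layer(self, c: int, z: int) -> bool:
        """First-improvement smoothing flip for layer (c, z); True if one
        was applied."""
        st = self.st
        cells = self.cells
        raw0 = cells.layer_perimeter_raw[c, z]
        vol0 = cells.layer_volume[c, z]
        ratio0 = raw0 / math.sqrt(vol0)
        xi = self.cfg.xi
        bb = 2.0 * self.cfg.b_factor * math.sqrt(math.pi)

        members = np.flatnonzero((st == c) & (self.z_of == z))
        candidates: list[tuple[int, int]] = []  # (j, new_state)
        seen = set()
        for j in members:
            candidates.append((int(j), UNASSIGNED))
            for f in self.vn[j]:
                if f >= 0 and st[f] != c and self.z_of[f] == z and f not in seen:
                    seen.add(int(f))
                    candidates.append((int(f), c))
        for j, new in candidates:
            old = int(st[j])
            if old == new:
                continue
            if old >= 0:
                if cells.voxel_count[old] == 1 or self._label_components(j, old) != 1:
                    continue
            if new >= 0 and self._label_components(j, new) != 1:
                continue
            n_inb = 0
            cnt_old = 0
            cnt_new = 0
            for o in _INPLANE_IDS:
                f = self.moore[j, o]
                if f >= 0:
                    n_inb += 1
                    sf = st[f]
                    if sf == old:
                        cnt_old += 1
                    elif sf == new:
                        cnt_new += 1
            # effect on layer (c, z)
            if new == c:
                raw1 = raw0 + n_inb - 2 * cnt_new
                vol1 = vol0 + 1
            else:  # removal from c
                raw1 = raw0 + 2 * cnt_old - n_inb
                vol1 = vol0 - 1
            if vol1 <= 0 or raw1 / math.sqrt(vol1) >= ratio0:
                continue
            # the counterpart cell's layer must stay compliant or improve
            other = old if new == c else -1
            if other >= 0:
                o_raw = cells.layer_perimeter_raw[other, z] + 2 * cnt_old - n_inb
                o_vol = cells.layer_volume[other, z] - 1
                o_ok_now = xi * cells.layer_perimeter_raw[other, z] <= bb * math.sqrt(
                    cells.layer_volume[other, z]
                )
                if o_vol > 0 and xi * o_raw > bb * math.sqrt(o_vol):
                    if o_ok_now or o_raw * math.sqrt(
                        cells.layer_volume[other, z]
                    ) >= cells.layer_perimeter_raw[other, z] * math.sqrt(o_vol):
                        continue
            self._apply_flip(j, old, new, z)
            return True
        return False

    def audit(self) -> list[str]:
        return lat.audit_state(self.lattice, self.cells)


# ---------------------------------------------------------------------------
# top-level pipeline


def run(
    table: TranscriptTable,
    cfg: SamplerConfig | None = None,
    prior: PriorConfig | None = None,
    return_state: bool = False,
):
    """Segment a transcript table end to end.

    Initializes cells from the nuclear labels at the coarsest scheduled
    resolution, then alternates boundary, parameter and repositioning
    sweeps, doubling resolution between stages, and finalizes counts,
    metadata and boundary polygons. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SamplerConfig()
    prior = prior or PriorConfig()
    rng = np.random.default_rng(cfg.seed)
    sampler = initialize(table, cfg, prior, rng)
    for si, stage in enumerate(cfg.schedule):
        if si > 0:
            sampler.double()
        sampler.repair_perimeters()
        acc_total = 0
        for sweep in range(stage.sweeps):
            acc_total += sampler.boundary_sweep()
            if (sweep + 1) % cfg.param_every_n_sweeps == 0:
                sampler.parameter_sweep()
            if (sweep + 1) % cfg.reposition.every_n_sweeps == 0:
                sampler.reposition_sweep()
        sampler.accept_log.append(
            {
                "stage": si,
                "voxel_xy": sampler.lattice.voxel_size[0],
                "accepted": acc_total,
                "pool": len(sampler.pool),
            }
        )
    result = finalize(sampler, table, cfg)
    return (result, sampler) if return_state else result


def initialize(
    table: TranscriptTable, cfg: SamplerConfig, prior: PriorConfig, rng: np.random.Generator
) -> BoundarySampler:
    stage0 = cfg.schedule[0]
    lattice = build_lattice(table.observed, stage0.voxel_xy, stage0.z_layers)
    vox = voxels_of(lattice, table.observed)
    cells, kept = initialize_from_nuclei(lattice, vox, table.nuclear)
    # original nuclear label -> cell id
    remap = {int(l): c for c, l in enumerate(kept)}
    nuc_cell = np.array([remap.get(int(l), -1) for l in table.nuclear], dtype=np.int64)
    if cfg.bin_size_um is None and cfg.use_checkerboard:
        cfg.bin_size_um = _calibrate_bin_um(table, nuc_cell)
    params = ModelParams.initial(table.m, cells.n, prior, rng)
    sampler = BoundarySampler(
        lattice, cells, params, prior, table.gene, table.observed, nuc_cell, cfg, rng
    )
    params.z = mdl.initial_components(sampler.current_counts(), prior.k, rng)
    for i in range(cfg.init_param_sweeps):
        # adapt α, β to the initial partition before resampling z
        sampler.parameter_sweep(update_z=i >= cfg.init_param_sweeps // 2)
    return sampler


def _calibrate_bin_um(table: TranscriptTable, nuc_cell: np.ndarray) -> float:
    """Checkerboard bin edge from nuclei spacing: at least twice the 90th
    percentile nearest-neighbor distance between nuclei centroids."""
    from scipy.spatial import cKDTree

    has = nuc_cell >= 0
    if not has.any():
        return 40.0
    cents = (
        pd.DataFrame(
            {"c": nuc_cell[has], "x": table.observed[has, 0], "y": table.observed[has, 1]}
        )
        .groupby("c")
        .mean()
        .to_numpy()
    )
    if len(cents) < 2:
        return 40.0
    dist, _ = cKDTree(cents).query(cents, k=2)
    return float(max(8.0, 2.0 * np.percentile(dist[:, 1], 90)))


def finalize(
    sampler: BoundarySampler, table: TranscriptTable, cfg: SamplerConfig
) -> SegmentationResult:
    """Build the result from the sampler's final state: counts over cells
    with at least ``min_cell_transcripts`` transcripts, transcript-weighted
    centroids, and per-layer boundary polygons traced from the raster."""
    owner = sampler.st[sampler.tx_flat]  # (M,) cell id or -1
    n = sampler.n
    per_cell = np.bincount(owner[owner >= 0], minlength=n)
    retained = np.flatnonzero(per_cell >= cfg.min_cell_transcripts)
    keep_mask = np.isin(owner, retained) & (owner >= 0)

    status = np.where(owner < 0, "background", np.where(keep_mask, "assigned", "filtered"))
    assignment = np.where(keep_mask, owner, -1)

    col = {c: i for i, c in enumerate(retained)}
    X = np.zeros((sampler.m, len(retained)), dtype=np.int64)
    gm = sampler.gene[keep_mask]
    cm = np.array([col[c] for c in owner[keep_mask]], dtype=np.int64)
    if len(gm):
        np.add.at(X, (gm, cm), 1)
    X_bg = np.bincount(sampler.gene[owner < 0], minlength=sampler.m).astype(np.int64)
    counts = CountMatrix(X, X_bg)

    meta_rows = []
    for c in retained:
        sel = assignment == c
        cent = sampler.inferred[sel].mean(axis=0)
        meta_rows.append(
            {
                "cell": int(c),
                "centroid_x": cent[0],
                "centroid_y": cent[1],
                "centroid_z": cent[2],
                "volume_um3": float(sampler.cells.voxel_count[c] * sampler.b_vol),
                "component": int(sampler.params.z[c]),
                "n_transcripts": int(per_cell[c]),
            }
        )
    cell_meta = pd.DataFrame(
        meta_rows,
        columns=[
            "cell",
            "centroid_x",
            "centroid_y",
            "centroid_z",
            "volume_um3",
            "component",
            "n_transcripts",
        ],
    )

    polygons = trace_polygons(sampler.lattice, retained)
    return SegmentationResult(
        gene_names=list(table.gene_names),
        gene=sampler.gene,
        assignment=assignment,
        status=status,
        counts=counts,
        cell_ids=retained,
        cell_meta=cell_meta,
        polygons=polygons,
        observed_positions=sampler.observed,
        inferred_positions=sampler.inferred,
    )


def trace_polygons(lattice: VoxelLattice, cell_ids) -> dict:
    """Exterior rings of each cell's per-layer voxel mask, in μm."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    out = {}
    ox, oy = lattice.origin[0], lattice.origin[1]
    vx, vy = lattice.voxel_size[0], lattice.voxel_size[1]
    for c in cell_ids:
        xs, ys, zs = np.nonzero(lattice.state == c)
        for z in np.unique(zs):
            sel = zs == z
            boxes = [
                box(ox + x * vx, oy + y * vy, ox + (x + 1) * vx, oy + (y + 1) * vy)
                for x, y in zip(xs[sel], ys[sel])
            ]
            geom = unary_union(boxes)
            polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
            rings = [np.asarray(p.exterior.coords) for p in polys]
            out[(int(c), int(z))] = rings
    return out
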
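"""Voxel-lattice geometry and cell-state bookkeeping.

Space is discretized into an axis-aligned grid of voxels. Every voxel is
either unassigned (state ``UNASSIGNED`` = -1) or owned by exactly one cell
(states ``0..n-1``), so the lattice state is a partition of space. The
sampler perturbs this state by copying labels across voxel faces; this
module provides the geometry, the incremental per-cell tallies (layer
volumes and mismatch-count perimeters), the mismatch-edge proposal pool,
and the checkerboard schedule that groups proposals into non-interacting
phases.

Conventions: 0-based voxel indices, half-open voxel intervals ``[lo, hi)``
per axis (points on the outer boundary clamp to the last voxel), μm units
throughout. Proposal edges use von Neumann (face) adjacency; connectivity
and perimeter use Moore adjacency (26 in 3D, 8 in-plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

UNASSIGNED = -1

# 26-connectivity structuring element for component labelling
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# offsets
VON_NEUMANN_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)
MOORE_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)
INPLANE_MOORE_OFFSETS = np.array(
    [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)],
    dtype=np.int64,
)

#: Perceived-perimeter scaling constant: multiplying the raw in-plane
#: Moore-mismatch count by ``XI_DEFAULT`` gives a length in voxel edge
#: units. Fitted once by ``calibrate_xi`` on rasterized disks (radius
#: 10–100 voxels) regressed against the true circle perimeter 2πr.
XI_DEFAULT = 0.32437


class LatticeError(ValueError):
    pass


@dataclass
class VoxelLattice:
    """A rectangular voxel grid with per-voxel cell-ownership state."""

    origin: np.ndarray  # (3,) μm
    voxel_size: np.ndarray  # (3,) μm per voxel along x, y, z
    dims: tuple[int, int, int]
    state: np.ndarray = field(default=None)  # int32, shape dims

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise LatticeError("voxel_size must be strictly positive")
        if self.state is None:
            self.state = np.full(self.dims, UNASSIGNED, dtype=np.int32)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, μm³."""
        return float(np.prod(self.voxel_size))

    @property
    def upper(self) -> np.ndarray:
        return self.origin + np.asarray(self.dims) * self.voxel_size

    # -- flat index helpers ------------------------------------------------
    def flat(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        nx, ny, nz = self.dims
        return (idx[..., 0] * ny + idx[..., 1]) * nz + idx[..., 2]

    def unflat(self, f):
        nx, ny, nz = self.dims
        f = np.asarray(f)
        z = f % nz
        xy = f // nz
        return np.stack([xy // ny, xy % ny, z], axis=-1)

    def copy(self) -> "VoxelLattice":
        return VoxelLattice(
            self.origin.copy(), self.voxel_size.copy(), self.dims, self.state.copy()
        )


def build_lattice(positions: np.ndarray, voxel_size_xy, z_layers: int) -> VoxelLattice:
    """Construct an all-unassigned lattice covering a transcript cloud.

    ``voxel_size_xy`` gives the in-plane voxel edge length (scalar or
    (vx, vy)); the z axis is split into exactly ``z_layers`` layers
    spanning the z-coordinate range. A flat (zero z-extent) cloud gets a
    nominal 1 μm slab thickness so that voxel volumes stay finite.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise LatticeError("empty transcript table")
    if not np.all(np.isfinite(positions)):
        raise LatticeError("non-finite transcript coordinates")
    vs = np.atleast_1d(np.asarray(voxel_size_xy, dtype=float))
    vx, vy = (vs[0], vs[0]) if vs.size == 1 else (vs[0], vs[1])
    if vx <= 0 or vy <= 0 or z_layers < 1:
        raise LatticeError("voxel size and z_layers must be positive")
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    ext = hi - lo
    nx = max(1, int(np.ceil(ext[0] / vx - 1e-9)))
    ny = max(1, int(np.ceil(ext[1] / vy - 1e-9)))
    z_ext = ext[2] if ext[2] > 0 else 1.0
    vz = z_ext / z_layers
    return VoxelLattice(lo, np.array([vx, vy, vz]), (nx, ny, int(z_layers)))


def voxel_of(lattice: VoxelLattice, point) -> tuple[int, int, int]:
    """Voxel index containing ``point`` (half-open intervals, outer
    boundary clamps to the last voxel). Raises outside the bounding box."""
    p = np.asarray(point, dtype=float)
    if np.any(p < lattice.origin - 1e-9) or np.any(p > lattice.upper + 1e-9):
        raise LatticeError(f"point {p} outside lattice bounds")
    idx = np.floor((p - lattice.origin) / lattice.voxel_size).astype(int)
    idx = np.minimum(idx, np.asarray(lattice.dims) - 1)
    idx = np.maximum(idx, 0)
    return tuple(int(i) for i in idx)


def voxels_of(lattice: VoxelLattice, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`voxel_of`; returns an (M, 3) int array."""
    p = np.asarray(points, dtype=float)
    idx = np.floor((p - lattice.origin) / lattice.voxel_size).astype(np.int64)
    np.clip(idx, 0, np.asarray(lattice.dims) - 1, out=idx)
    return idx


def moore_neighbors(lattice: VoxelLattice, j) -> list[tuple[int, int, int]]:
    """In-bounds Moore (26-)neighbors of voxel ``j``, excluding ``j``."""
    j = np.asarray(j)
    nb = j + MOORE_OFFSETS
    ok = np.all((nb >= 0) & (nb < np.asarray(lattice.dims)), axis=1)
    return [tuple(int(v) for v in row) for row in nb[ok]]


def is_local_articulation(lattice: VoxelLattice, j, label: int) -> bool:
    """Whether changing voxel ``j``'s membership in ``label`` alters the
    number of connected components of that cell within j's Moore
    neighborhood (plus j).

    Because j is Moore-adjacent to every voxel of its own neighborhood,
    this reduces to: the same-label Moore neighbors of j form exactly one
    Moore-connected component. An empty neighbor set also counts as
    articulating (the voxel is the cell's whole local presence).
    """
    if label == UNASSIGNED:
        raise ValueError("articulation test is undefined for the unassigned state")
    st = lattice.state
    nbs = [nb for nb in moore_neighbors(lattice, j) if st[nb] == label]
    return _n_moore_components(nbs) != 1


def _n_moore_components(coords: list[tuple[int, int, int]]) -> int:
    """Number of Moore-connected components among a small coordinate set."""
    m = len(coords)
    if m == 0:
        return 0
    seen = [False] * m
    ncomp = 0
    for s in range(m):
        if seen[s]:
            continue
        ncomp += 1
        stack = [s]
        seen[s] = True
        while stack:
            a = stack.pop()
            ax, ay, az = coords[a]
            for t in range(m):
                if not seen[t]:
                    tx, ty, tz = coords[t]
                    if abs(ax - tx) <= 1 and abs(ay - ty) <= 1 and abs(az - tz) <= 1:
                        seen[t] = True
                        stack.append(t)
    return ncomp


# ---------------------------------------------------------------------------
# cell-state tallies


@dataclass
class CellState:
    """Per-cell voxel tallies kept incrementally in sync with the lattice.

    ``layer_volume[c, z]`` counts the voxels of cell c in z-layer z and
    ``layer_perimeter_raw[c, z]`` the in-plane Moore mismatch count
    Σ_{i∈V_zc} |N2(i) ∩ V_z ∩ ¬V_c| that, scaled by ξ, approximates the
    perceived perimeter of that layer.
    """

    n: int
    layer_volume: np.ndarray  # (n, nz) int64
    layer_perimeter_raw: np.ndarray  # (n, nz) int64
    voxel_count: np.ndarray  # (n,) int64
    voxel_volume: float
    voxel_xy: float

    @property
    def volume_um3(self) -> np.ndarray:
        return self.voxel_count * self.voxel_volume

    @classmethod
    def from_lattice(cls, lattice: VoxelLattice, n: int) -> "CellState":
        nz = lattice.dims[2]
        lv = _layer_volumes(lattice.state, n)
        lp = _layer_perimeters(lattice.state, n)
        return cls(
            n=n,
            layer_volume=lv,
            layer_perimeter_raw=lp,
            voxel_count=lv.sum(axis=1),
            voxel_volume=lattice.voxel_volume,
            voxel_xy=float(lattice.voxel_size[0]),
        )

    def voxels_of_cell(self, lattice: VoxelLattice, c: int) -> np.ndarray:
        return np.argwhere(lattice.state == c)


def _layer_volumes(state: np.ndarray, n: int) -> np.ndarray:
    nz = state.shape[2]
    lv = np.zeros((n, nz), dtype=np.int64)
    for z in range(nz):
        sl = state[:, :, z]
        counts = np.bincount(sl[sl >= 0].ravel(), minlength=n)
        lv[:, z] = counts[:n]
    return lv


def _layer_perimeters(state: np.ndarray, n: int) -> np.ndarray:
    """Raw per-cell, per-layer in-plane Moore mismatch counts, from scratch."""
    nx, ny, nz = state.shape
    lp = np.zeros((n, nz), dtype=np.int64)
    for dx, dy in INPLANE_MOORE_OFFSETS:
        # neighbor state shifted by (dx, dy); out-of-bounds never counted
        xs = slice(max(dx, 0), nx + min(dx, 0))
        xn = slice(max(-dx, 0), nx + min(-dx, 0))
        ys = slice(max(dy, 0), ny + min(dy, 0))
        yn = slice(max(-dy, 0), ny + min(-dy, 0))
        own = state[xs, ys, :]
        nbr = state[xn, yn, :]
        mism = (own >= 0) & (nbr != own)
        if not mism.any():
            continue
        cells = own[mism]
        zs = np.broadcast_to(np.arange(nz), own.shape)[mism]
        np.add.at(lp, (cells, zs), 1)
    return lp


def layer_perimeter(cells: CellState, c: int, z: int, xi: float = XI_DEFAULT) -> float:
    """Perceived perimeter of cell ``c``'s z-layer, in μm."""
    return xi * float(cells.layer_perimeter_raw[c, z]) * cells.voxel_xy


def perimeter_bound_ok(
    cells: CellState, c: int, z: int, b_factor: float = 1.3, xi: float = XI_DEFAULT
) -> bool:
    """Compactness constraint: the layer's perceived perimeter may exceed
    that of a circle of equal area by at most the factor ``b_factor``."""
    vol = cells.layer_volume[c, z]
    if vol == 0:
        return True
    area = vol * cells.voxel_xy**2
    perim = xi * cells.layer_perimeter_raw[c, z] * cells.voxel_xy
    return perim <= b_factor * 2.0 * np.sqrt(np.pi * area)


def calibrate_xi(radii=range(10, 101, 10)) -> float:
    """Fit the perceived-perimeter constant ξ on rasterized disks.

    Counts raw in-plane mismatches for disks of the given radii (in voxel
    units) and regresses the true perimeter 2πr on the raw count through
    the origin.
    """
    raws, true = [], []
    for r in radii:
        raws.append(disk_raw_mismatches(r))
        true.append(2 * np.pi * r)
    raws = np.asarray(raws, dtype=float)
    true = np.asarray(true, dtype=float)
    return float((raws * true).sum() / (raws * raws).sum())


def disk_raw_mismatches(r: int) -> int:
    """Raw in-plane mismatch count for a rasterized disk of radius ``r``
    voxels (margin chosen so the lattice boundary plays no role)."""
    n = 2 * r + 5
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= r**2
    state = np.where(mask, 0, UNASSIGNED).astype(np.int32)[:, :, None]
    return int(_layer_perimeters(state, 1)[0, 0])


# ---------------------------------------------------------------------------
# nuclear initialization


def initialize_from_nuclei(
    lattice: VoxelLattice, voxel_idx: np.ndarray, nuclear_label: np.ndarray
) -> tuple[CellState, np.ndarray]:
    """Seed the lattice from per-transcript nuclear labels.

    Each voxel holding at least one nuclear-labelled transcript is assigned
    to the label with the plurality of its nuclear transcripts; ties are
    broken by the larger count of that label's transcripts in the voxel's
    Moore neighborhood, then by the smaller label id. Labels are remapped
    to contiguous cell ids 0..n-1; labels left without any voxel are
    dropped. If a label's voxels are disconnected only its largest
    Moore-connected component is kept, so every resulting cell is
    non-empty and connected.

    Returns the cell state and the array of original label values indexed
    by new cell id.
    """
    nuclear_label = np.asarray(nuclear_label)
    labelled = nuclear_label >= 0
    if not labelled.any():
        raise LatticeError("no nuclear-labelled transcripts")
    vi = np.asarray(voxel_idx)[labelled]
    labs = nuclear_label[labelled]
    flat = lattice.flat(vi)

    # per-(voxel, label) counts
    per_voxel: dict[int, dict[int, int]] = {}
    for f, l in zip(flat.tolist(), labs.tolist()):
        per_voxel.setdefault(f, {}).setdefault(l, 0)
        per_voxel[f][l] += 1

    def nbhood_count(f: int, lab: int) -> int:
        j = lattice.unflat(f)
        total = per_voxel.get(f, {}).get(lab, 0)
        for nb in moore_neighbors(lattice, j):
            total += per_voxel.get(int(lattice.flat(np.asarray(nb))), {}).get(lab, 0)
        return total

    assigned: dict[int, int] = {}
    for f, cnts in per_voxel.items():
        best = max(cnts.values())
        cands = sorted(l for l, c in cnts.items() if c == best)
        if len(cands) > 1:
            nbc = {l: nbhood_count(f, l) for l in cands}
            top = max(nbc.values())
            cands = sorted(l for l in cands if nbc[l] == top)
        assigned[f] = cands[0]

    kept_labels = sorted(set(assigned.values()))
    remap = {l: i for i, l in enumerate(kept_labels)}
    lattice.state[:] = UNASSIGNED
    for f, l in assigned.items():
        lattice.state[tuple(lattice.unflat(f))] = remap[l]

    # prune disconnected labels to their largest component
    for c in range(len(kept_labels)):
        mask = lattice.state == c
        comp, ncomp = ndimage.label(mask, structure=_STRUCT26)
        if ncomp > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, ncomp + 1))
            keep = 1 + int(np.argmax(sizes))
            lattice.state[mask & (comp != keep)] = UNASSIGNED

    # a label may now be empty only if pruning could remove everything,
    # which it cannot (largest component is kept); but plurality may have
    # produced empty labels before remap — those were already excluded.
    cells = CellState.from_lattice(lattice, len(kept_labels))
    return cells, np.asarray(kept_labels)


# ---------------------------------------------------------------------------
# resolution doubling


def double_resolution(lattice: VoxelLattice, n_cells: int) -> tuple[VoxelLattice, CellState]:
    """Split every voxel into its 8 children, preserving every cell's
    spatial region (and hence its volume in μm³); tallies are recomputed."""
    st = lattice.state
    st2 = np.repeat(np.repeat(np.repeat(st, 2, axis=0), 2, axis=1), 2, axis=2)
    nx, ny, nz = lattice.dims
    lat2 = VoxelLattice(
        lattice.origin.copy(), lattice.voxel_size / 2.0, (2 * nx, 2 * ny, 2 * nz), st2
    )
    return lat2, CellState.from_lattice(lat2, n_cells)


# ---------------------------------------------------------------------------
# proposal pool and checkerboard schedule


@dataclass
class CheckerboardSchedule:
    """Four-phase (sub-quadrant) partition of the voxels.

    Voxels whose bins have even/odd parity along x and y fall into phases
    0..3; with the bin edge at least twice the largest plausible cell
    diameter, two proposals in the same phase can never touch the same
    cell.
    """

    bin_size: int
    phase_flat: np.ndarray  # (n_voxels,) uint8, phase of each flat voxel index

    @classmethod
    def build(cls, lattice: VoxelLattice, bin_size: int) -> "CheckerboardSchedule":
        if bin_size < 2:
            raise LatticeError("bin_size must be at least 2 voxels")
        nx, ny, nz = lattice.dims
        x = np.arange(nx)
        y = np.arange(ny)
        px = (x // bin_size) % 2
        py = (y // bin_size) % 2
        phase2d = (px[:, None] + 2 * py[None, :]).astype(np.uint8)
        phase = np.repeat(phase2d[:, :, None], nz, axis=2)
        return cls(bin_size=bin_size, phase_flat=phase.reshape(-1))

    def phase_voxels(self, phase: int) -> np.ndarray:
        return np.nonzero(self.phase_flat == phase)[0]


class EdgePool:
    """The mismatch-edge proposal pool, split by the target voxel's phase.

    Holds every ordered von-Neumann-adjacent voxel pair (i, j) with
    σ_i ≠ σ_j, supporting O(1) uniform sampling and O(1) add/remove so the
    sampler can keep it exact across accepted flips.
    """

    def __init__(self, lattice: VoxelLattice, schedule: CheckerboardSchedule | None = None):
        self.lattice = lattice
        nv = lattice.n_voxels
        if schedule is None:
            self.phase_flat = np.zeros(nv, dtype=np.uint8)
            self.n_phases = 1
        else:
            self.phase_flat = schedule.phase_flat
            self.n_phases = 4
        self.edges: list[list[tuple[int, int]]] = [[] for _ in range(self.n_phases)]
        self.pos: dict[tuple[int, int], tuple[int, int]] = {}
        self._neighbors_flat = neighbor_matrix(lattice.dims, VON_NEUMANN_OFFSETS)
        self.rebuild()

    def rebuild(self):
        for lst in self.edges:
            lst.clear()
        self.pos.clear()
        st = self.lattice.state.reshape(-1)
        nbrs = self._neighbors_flat
        mism = (st[:, None] != st[nbrs]) & (nbrs >= 0)
        for i, j in zip(*np.nonzero(mism)):
            self._add((int(i), int(nbrs[i, j])))

    def _add(self, e: tuple[int, int]):
        if e in self.pos:
            return
        ph = int(self.phase_flat[e[1]])
        lst = self.edges[ph]
        self.pos[e] = (ph, len(lst))
        lst.append(e)

    def _remove(self, e: tuple[int, int]):
        loc = self.pos.pop(e, None)
        if loc is None:
            return
        ph, k = loc
        lst = self.edges[ph]
        last = lst[-1]
        lst[k] = last
        if last != e:
            self.pos[last] = (ph, k)
        lst.pop()

    def __len__(self):
        return len(self.pos)

    def phase_size(self, phase: int) -> int:
        return len(self.edges[phase])

    def sample(self, phase: int, u: float) -> tuple[int, int]:
        lst = self.edges[phase]
        return lst[int(u * len(lst))]

    def update_around(self, j_flat: int):
        """Re-derive pool membership of every edge incident to voxel j
        after its state changed."""
        st = self.lattice.state.reshape(-1)
        sj = st[j_flat]
        for nb in self._neighbors_flat[j_flat]:
            if nb < 0:
                continue
            if st[nb] != sj:
                self._add((nb, j_flat))
                self._add((j_flat, nb))
            else:
                self._remove((nb, j_flat))
                self._remove((j_flat, nb))

    def contains(self, e: tuple[int, int]) -> bool:
        return e in self.pos


def neighbor_matrix(dims: tuple[int, int, int], offsets: np.ndarray) -> np.ndarray:
    """(N, n_offsets) flat-index neighbor table, -1 where out of bounds."""
    nx, ny, nz = dims
    coords = np.indices((nx, ny, nz)).reshape(3, -1)  # (3, N)
    mat = np.full((coords.shape[1], len(offsets)), -1, dtype=np.int64)
    for o, (dx, dy, dz) in enumerate(offsets):
        x = coords[0] + dx
        y = coords[1] + dy
        z = coords[2] + dz
        ok = (x >= 0) & (x < nx) & (y >= 0) & (y < ny) & (z >= 0) & (z < nz)
        mat[ok, o] = (x[ok] * ny + y[ok]) * nz + z[ok]
    return mat


# Moore-offset adjacency bitmasks: bit j set in MOORE_ADJ[i] when offsets i
# and j are themselves Moore-adjacent; used for fast local component counts.
MOORE_ADJ = tuple(
    int(sum(1 << j for j, oj in enumerate(MOORE_OFFSETS) if np.abs(oi - oj).max() <= 1 and i != j))
    for i, oi in enumerate(MOORE_OFFSETS)
)


def count_bitmask_components(bits: int, adj=MOORE_ADJ) -> int:
    """Connected components among a set of Moore offsets given as a bitmask."""
    ncomp = 0
    while bits:
        ncomp += 1
        frontier = bits & -bits  # lowest set bit
        comp = 0
        while frontier:
            comp |= frontier
            grow = 0
            f = frontier
            while f:
                b = f & -f
                f ^= b
                grow |= adj[b.bit_length() - 1]
            frontier = grow & bits & ~comp
        bits &= ~comp
    return ncomp


def checkerboard_phases(lattice: VoxelLattice, bin_size: int) -> CheckerboardSchedule:
    return CheckerboardSchedule.build(lattice, bin_size)


# ---------------------------------------------------------------------------
# audits


def audit_state(lattice: VoxelLattice, cells: CellState) -> list[str]:
    """Recompute every cached tally and structural invariant from scratch;
    returns a list of violation descriptions (empty when consistent)."""
    problems = []
    st = lattice.state
    n = cells.n
    if st.max(initial=UNASSIGNED) >= n or st.min(initial=UNASSIGNED) < UNASSIGNED:
        problems.append("state values out of range")
    lv = _layer_volumes(st, n)
    if not np.array_equal(lv, cells.layer_volume):
        problems.append("layer_volume cache mismatch")
    if not np.array_equal(lv.sum(axis=1), cells.voxel_count):
        problems.append("voxel_count cache mismatch")
    lp = _layer_perimeters(st, n)
    if not np.array_equal(lp, cells.layer_perimeter_raw):
        problems.append("layer_perimeter cache mismatch")
    for c in range(n):
        mask = st == c
        if not mask.any():
            problems.append(f"cell {c} empty")
            continue
        _, ncomp = ndimage.label(mask, structure=_STRUCT26)
        if ncomp != 1:
            problems.append(f"cell {c} has {ncomp} Moore components")
    return problems
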
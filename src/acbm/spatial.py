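"""3D geometry: occupancy mesh, random motion, neighbour search, placement.

The environment is a cube meshed into 1 µm elements; cells claim elements
according to their shape (sphere for cocci, capsule for bacilli) and two
cells never share an element. Metabolite packages are point objects with no
footprint and are held in a flat array store with a per-step cKDTree index.

Random directions follow the published construction
``d = (cos φ cos θ, cos φ sin θ, sin φ)`` with φ, θ ~ U[0, 2π). Note that
this is *not* uniform on the sphere: |d_z| = |sin φ| has an arcsine-law
density, so polar directions are over-represented relative to a uniform
spherical distribution. The construction is kept deliberately, bias and all,
because the motion model is defined by it.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_types import CellSpec

ELEMENT_EDGE_UM = 1.0


# ---------------------------------------------------------------------------
# Directions and velocities
# ---------------------------------------------------------------------------

def random_direction(rng: np.random.Generator) -> np.ndarray:
    """Unit vector from two angles φ, θ ~ U[0, 2π) (see module note on bias)."""
    phi = rng.uniform(0.0, 2.0 * math.pi)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return direction_from_angles(phi, theta)


def direction_from_angles(phi: float, theta: float) -> np.ndarray:
    return np.array(
        [
            math.cos(phi) * math.cos(theta),
            math.cos(phi) * math.sin(theta),
            math.sin(phi),
        ]
    )


def random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Vectorised draw of ``n`` directions with the same construction."""
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.stack(
        [np.cos(phi) * np.cos(theta), np.cos(phi) * np.sin(theta), np.sin(phi)],
        axis=1,
    )


def velocity(direction: np.ndarray, speed_um_per_h: float) -> np.ndarray:
    """Velocity vector in µm/h; ‖v‖ equals the speed."""
    if speed_um_per_h < 0:
        raise ValueError("speed must be non-negative")
    return np.asarray(direction, dtype=float) * speed_um_per_h


def reflect_positions(pos: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Fold positions back into [0, dims] by mirror reflection at the walls."""
    dims = np.asarray(dims, dtype=float)
    p = np.mod(pos, 2.0 * dims)
    return np.where(p > dims, 2.0 * dims - p, p)


def wrap_positions(pos: np.ndarray, dims: np.ndarray) -> np.ndarray:
    return np.mod(pos, np.asarray(dims, dtype=float))


def apply_boundary(pos: np.ndarray, dims: Sequence[float], boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return wrap_positions(pos, np.asarray(dims))
    return reflect_positions(pos, np.asarray(dims))


# ---------------------------------------------------------------------------
# Occupancy mesh
# ---------------------------------------------------------------------------

class OccupancyGrid:
    """Sparse 1 µm occupancy mesh: element (i, j, k) → agent id."""

    def __init__(self, dims_um: Sequence[float]):
        self.dims_um = tuple(float(d) for d in dims_um)
        self.shape = tuple(int(round(d / ELEMENT_EDGE_UM)) for d in self.dims_um)
        self._cells: dict[tuple[int, int, int], int] = {}

    def in_bounds(self, el: tuple[int, int, int]) -> bool:
        return all(0 <= e < n for e, n in zip(el, self.shape))

    def owner(self, el: tuple[int, int, int]) -> Optional[int]:
        return self._cells.get(el)

    def is_free(self, el: tuple[int, int, int], for_agent: Optional[int] = None) -> bool:
        owner = self._cells.get(el)
        return owner is None or owner == for_agent

    def claim(self, elements: Iterable[tuple[int, int, int]], agent_id: int) -> None:
        for el in elements:
            owner = self._cells.get(el)
            if owner is not None and owner != agent_id:
                raise ValueError(f"element {el} already owned by agent {owner}")
            self._cells[el] = agent_id

    def release(self, elements: Iterable[tuple[int, int, int]], agent_id: int) -> None:
        for el in elements:
            if self._cells.get(el) == agent_id:
                del self._cells[el]

    def occupied_count(self) -> int:
        return len(self._cells)

    def element_center(self, el: tuple[int, int, int]) -> np.ndarray:
        return np.array(el, dtype=float) + 0.5

    def containing_element(self, position: np.ndarray) -> tuple[int, int, int]:
        return tuple(
            min(int(math.floor(p)), n - 1)
            for p, n in zip(np.maximum(position, 0.0), self.shape)
        )


def occupied_elements(
    center: np.ndarray,
    spec: CellSpec,
    direction: Optional[np.ndarray] = None,
    grid: Optional[OccupancyGrid] = None,
) -> frozenset:
    """Mesh elements claimed by a cell of this shape at ``center``.

    Cocci claim every element whose center lies within ``radius_um`` of the
    cell center; bacilli claim elements within ``radius_um`` of the axis
    segment (capsule of total length ``length_um``) oriented along
    ``direction``. The element containing the center is always included, so
    the footprint is never empty. Elements outside the mesh may be returned;
    the move logic treats them as blocked.
    """
    c = np.asarray(center, dtype=float)
    r = spec.radius_um
    if spec.shape == "bacilli":
        if direction is None:
            raise ValueError("bacilli need an orientation")
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        d = d / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        half = max(0.0, spec.length_um / 2.0 - r)
        a, b = c - half * d, c + half * d
    else:
        a = b = c

    lo = np.floor(np.minimum(a, b) - r - 0.5).astype(int)
    hi = np.floor(np.maximum(a, b) + r + 0.5).astype(int)
    out = set()
    ab = b - a
    ab2 = float(ab @ ab)
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                p = np.array([i + 0.5, j + 0.5, k + 0.5])
                if ab2 == 0.0:
                    d2 = float((p - a) @ (p - a))
                else:  # distance to segment
                    t = float(np.clip((p - a) @ ab / ab2, 0.0, 1.0))
                    q = a + t * ab
                    d2 = float((p - q) @ (p - q))
                if d2 <= r * r:
                    out.add((i, j, k))
    out.add(tuple(int(math.floor(x)) for x in c))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def _commit_move(agent, spec, grid: OccupancyGrid, new_pos, new_dir, boundary) -> bool:
    if boundary == "periodic":
        els = frozenset(
            tuple(e % n for e, n in zip(el, grid.shape))
            for el in occupied_elements(new_pos, spec, new_dir)
        )
    else:
        els = occupied_elements(new_pos, spec, new_dir)
        if not all(grid.in_bounds(el) for el in els):
            return False
    if not all(grid.is_free(el, agent.id) for el in els):
        return False
    grid.release(agent.occupied, agent.id)
    grid.claim(els, agent.id)
    agent.occupied = els
    agent.position = np.asarray(new_pos, dtype=float)
    agent.direction = np.asarray(new_dir, dtype=float)
    return True


def try_move(
    agent,
    spec: CellSpec,
    grid: OccupancyGrid,
    rng: np.random.Generator,
    dt_min: float,
    speed_um_per_h: float,
    boundary: str = "reflective",
    max_retries: int = 10,
) -> bool:
    """Random move: displacement = velocity × Δt; redraw on collision.

    Up to ``max_retries`` directions are drawn; if all destinations are
    blocked (occupied elements or, for reflective walls, a footprint poking
    outside the mesh) the agent stays put, which is a valid outcome.
    """
    step = speed_um_per_h * dt_min / 60.0
    dims = np.asarray(grid.dims_um)
    for _ in range(max_retries):
        d = random_direction(rng)
        cand = apply_boundary(agent.position + d * step, dims, boundary)
        if _commit_move(agent, spec, grid, cand, d, boundary):
            return True
    return False


def directed_move(
    agent,
    spec: CellSpec,
    grid: OccupancyGrid,
    target: np.ndarray,
    dt_min: float,
    speed_um_per_h: float,
    boundary: str = "reflective",
) -> bool:
    """Move toward ``target`` at the configured speed, capped at the target.

    Blocked destinations leave the agent in place (it may still eat from
    where it stands).
    """
    dims = np.asarray(grid.dims_um)
    delta = np.asarray(target, dtype=float) - agent.position
    if boundary == "periodic":  # head for the nearest image of the target
        delta = np.mod(delta + dims / 2.0, dims) - dims / 2.0
    dist = float(np.linalg.norm(delta))
    if dist == 0.0:
        return True
    step = min(speed_um_per_h * dt_min / 60.0, dist)
    d = delta / dist
    # if the destination is occupied, stop short of the blocker: back off
    # along the path in element-sized decrements
    back = 0
    while step > 0 and back < 8:
        cand = apply_boundary(agent.position + d * step, dims, boundary)
        if _commit_move(agent, spec, grid, cand, d, boundary):
            return True
        step -= ELEMENT_EDGE_UM
        back += 1
    return False


# ---------------------------------------------------------------------------
# Package store and spatial queries
# ---------------------------------------------------------------------------

class PackageStore:
    """Flat-array registry of metabolite packages with a per-step KD-tree.

    Packages are points; they never claim mesh elements. The index is built
    once per scheduler step (`build_index`); queries post-filter by liveness
    and metabolite so results stay exact as packages are consumed mid-step.
    Packages added after `build_index` become searchable the next step.
    """

    _CHUNK = 4096

    def __init__(self, met_ids: Sequence[str], periodic_dims: Optional[Sequence[float]] = None):
        self.met_ids = list(met_ids)
        self.met_code = {m: i for i, m in enumerate(self.met_ids)}
        self.periodic_dims = (
            np.asarray(periodic_dims, dtype=float) if periodic_dims is not None else None
        )
        n0 = self._CHUNK
        self.positions = np.empty((n0, 3), dtype=float)
        self.n = np.zeros(n0, dtype=float)
        self.met = np.zeros(n0, dtype=np.int16)
        self.alive = np.zeros(n0, dtype=bool)
        self.size = 0
        self._tree: Optional[cKDTree] = None
        self._tree_ids: Optional[np.ndarray] = None

    def _grow(self, need: int) -> None:
        cap = len(self.n)
        if self.size + need <= cap:
            return
        new_cap = max(cap * 2, self.size + need + self._CHUNK)
        for name in ("positions", "n", "met", "alive"):
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[: self.size] = arr[: self.size]
            setattr(self, name, new)

    def add(self, metabolite: str, position: np.ndarray, n: float) -> int:
        self._grow(1)
        i = self.size
        self.positions[i] = position
        self.n[i] = n
        self.met[i] = self.met_code[metabolite]
        self.alive[i] = n > 0
        self.size += 1
        return i

    def add_many(self, metabolite: str, positions: np.ndarray, n_each: float) -> None:
        k = len(positions)
        if k == 0:
            return
        self._grow(k)
        sl = slice(self.size, self.size + k)
        self.positions[sl] = positions
        self.n[sl] = n_each
        self.met[sl] = self.met_code[metabolite]
        self.alive[sl] = n_each > 0
        self.size += k

    # -- totals -------------------------------------------------------------
    def total_molecules(self, metabolite: str) -> float:
        code = self.met_code[metabolite]
        m = self.alive[: self.size] & (self.met[: self.size] == code)
        return float(self.n[: self.size][m].sum())

    def live_count(self) -> int:
        return int(self.alive[: self.size].sum())

    # -- motion -------------------------------------------------------------
    def move_all(
        self,
        rng: np.random.Generator,
        speed_um_per_h: float,
        dt_min: float,
        dims: Sequence[float],
        boundary: str = "reflective",
    ) -> None:
        idx = np.flatnonzero(self.alive[: self.size])
        if len(idx) == 0:
            return
        d = random_directions(rng, len(idx))
        step = speed_um_per_h * dt_min / 60.0
        moved = self.positions[idx] + d * step
        self.positions[idx] = apply_boundary(moved, dims, boundary)

    # -- queries ------------------------------------------------------------
    def build_index(self) -> None:
        ids = np.flatnonzero(self.alive[: self.size])
        self._tree_ids = ids
        if len(ids) == 0:
            self._tree = None
        elif self.periodic_dims is not None:
            pos = np.mod(self.positions[ids], self.periodic_dims)
            self._tree = cKDTree(pos, boxsize=self.periodic_dims)
        else:
            self._tree = cKDTree(self.positions[ids])

    def _dist2(self, center: np.ndarray, ids: np.ndarray) -> np.ndarray:
        delta = np.abs(self.positions[ids] - center)
        if self.periodic_dims is not None:
            delta = np.minimum(delta, self.periodic_dims - delta)
        return (delta**2).sum(axis=1)

    def _candidates(self, center: np.ndarray, radius: float) -> np.ndarray:
        if self._tree is None:
            return np.empty(0, dtype=int)
        center = np.asarray(center, dtype=float)
        if self.periodic_dims is not None:
            center = np.mod(center, self.periodic_dims)
        local = self._tree.query_ball_point(center, radius)
        ids = self._tree_ids[np.asarray(local, dtype=int)]
        return ids[self.alive[ids]]  # drop packages consumed since index build

    def nearest(
        self, center: np.ndarray, radius: float, codes: frozenset
    ) -> Optional[int]:
        """Index of the nearest consumable package within ``radius``.

        Exact: equals a brute-force scan; ties broken by lowest package id.
        """
        ids = self._candidates(center, radius)
        ids = ids[np.isin(self.met[ids], list(codes))] if len(ids) else ids
        if len(ids) == 0:
            return None
        d2 = self._dist2(np.asarray(center, dtype=float), ids)
        order = np.lexsort((ids, d2))
        return int(ids[order[0]])

    def in_radius(self, center: np.ndarray, radius: float, codes: frozenset) -> np.ndarray:
        """Ids of consumable packages within ``radius``, sorted (distance, id)."""
        ids = self._candidates(center, radius)
        if len(ids):
            ids = ids[np.isin(self.met[ids], list(codes))]
        if len(ids) == 0:
            return ids
        d2 = self._dist2(np.asarray(center, dtype=float), ids)
        return ids[np.lexsort((ids, d2))]

    def debit(self, ids: np.ndarray, amount: float) -> float:
        """Remove up to ``amount`` molecules from packages in the given order.

        Returns the amount actually removed. Emptied packages die; partially
        consumed packages keep their position (excess stays at the source).
        """
        left = amount
        taken = 0.0
        for i in ids:
            if left <= 0:
                break
            take = min(self.n[i], left)
            self.n[i] -= take
            left -= take
            if self.n[i] < 1.0:  # molecules are discrete: absorb the residue
                take += self.n[i]
                self.n[i] = 0.0
                self.alive[i] = False
            taken += take
        return taken

    def compact(self) -> None:
        live = self.alive[: self.size]
        if live.all():
            return
        k = int(live.sum())
        self.positions[:k] = self.positions[: self.size][live]
        self.n[:k] = self.n[: self.size][live]
        self.met[:k] = self.met[: self.size][live]
        self.alive[:k] = True
        self.alive[k : self.size] = False
        self.size = k
        self._tree = None
        self._tree_ids = None


def uniform_positions(
    rng: np.random.Generator, n: int, dims: Sequence[float]
) -> np.ndarray:
    dims = np.asarray(dims, dtype=float)
    return rng.uniform(0.0, 1.0, (n, 3)) * dims


def positions_in_sphere(
    rng: np.random.Generator, n: int, center: np.ndarray, radius: float
) -> np.ndarray:
    """Uniform points within a sphere (for secretion placement)."""
    d = rng.normal(size=(n, 3))
    d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-300)
    r = radius * rng.uniform(0.0, 1.0, (n, 1)) ** (1.0 / 3.0)
    return np.asarray(center, dtype=float) + d * r
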
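"""Voxel-grid Monte Carlo light transport on 2-D imaging-plane slices.

Photon packets are launched from a surface source travelling into depth and
tracked through a heterogeneous absorption map with isotropic scattering
(similarity relation mu_s = mu_s' / (1 - g), g = 0 by default). Fluence is
scored per voxel with an energy-deposition estimator (path-length estimator
available, auto-selected when mu_a vanishes anywhere). Fluence contribution
maps (FCMs) record, per target voxel, the fraction of photons reaching the
target that traversed each other voxel.

Each scan slice is treated as an independent 2-D (x, z) problem; full 3-D
transport is out of scope.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .grid import GridSpec

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_MAX_EVENTS = 10_000_000  # per-photon safety cap


# --------------------------------------------------------------------------
# source specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpec:
    """Illumination geometry on the top (z = 0) surface, aimed into depth.

    ``geometry``: 'line' spans the full lateral width, 'pencil' is a point
    source at ``position_mm`` (default: lateral center), 'slab' has finite
    ``width_mm`` centered at ``position_mm``.
    """

    geometry: str = "line"
    position_mm: float | None = None
    width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("line", "pencil", "slab"):
            raise ValueError(f"unknown source geometry {self.geometry!r}")
        if self.geometry == "slab" and not (self.width_mm and self.width_mm > 0):
            raise ValueError("slab source requires width_mm > 0")

    def launch_window_cm(self, grid: GridSpec) -> tuple[float, float]:
        """(x0, width) of the launch interval in cm."""
        lx = grid.nx * grid.spacing_cm
        if self.geometry == "line":
            return 0.0, lx
        pos = lx / 2 if self.position_mm is None else self.position_mm / 10.0
        if self.geometry == "pencil":
            return pos, 0.0
        w = self.width_mm / 10.0
        return pos - w / 2, w

    def key(self) -> tuple:
        return (self.geometry, self.position_mm, self.width_mm)


# --------------------------------------------------------------------------
# numba transport kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _transport_fluence(mua, mus, dx, src_x0, src_w, n_photons, seed,
                       dep, plen):
    """One batch of photon packets; tallies deposition and path length.

    Returns the weight ledger (deposited, exited, roulette-killed,
    roulette-gained) for conservation checks.
    """
    np.random.seed(seed)
    nx, nz = mua.shape
    lx = nx * dx
    lz = nz * dx
    eps = 1e-9
    eps_hop = 1e-6 * dx
    w_dep = 0.0
    w_exit = 0.0
    w_kill = 0.0
    w_gain = 0.0
    for _ in range(n_photons):
        x = src_x0 + np.random.random() * src_w
        if x >= lx:
            x = lx - eps
        if x < 0.0:
            x = eps
        z = eps
        ux = 0.0
        uz = 1.0
        w = 1.0
        s = -np.log(np.random.random() + 1e-300)
        events = 0
        while True:
            events += 1
            if events > _MAX_EVENTS:
                w_kill += w
                break
            ix = int(np.floor(x / dx))
            iz = int(np.floor(z / dx))
            if ix < 0 or ix >= nx or iz < 0 or iz >= nz:
                w_exit += w
                break
            mut = mua[ix, iz] + mus
            if ux > 1e-12:
                dbx = ((ix + 1) * dx - x) / ux
            elif ux < -1e-12:
                dbx = (ix * dx - x) / ux
            else:
                dbx = 1e30
            if uz > 1e-12:
                dbz = ((iz + 1) * dx - z) / uz
            elif uz < -1e-12:
                dbz = (iz * dx - z) / uz
            else:
                dbz = 1e30
            db = min(dbx, dbz)
            hop = db + eps_hop
            if mut * db < s or mut == 0.0:
                # traverse to the voxel boundary
                plen[ix, iz] += w * db
                s -= mut * db
                if s < 0.0:
                    s = 0.0
                x += ux * hop
                z += uz * hop
            else:
                # interaction inside this voxel
                step = s / mut
                plen[ix, iz] += w * step
                x += ux * step
                z += uz * step
                dw = w * mua[ix, iz] / mut
                dep[ix, iz] += dw
                w_dep += dw
                w -= dw
                if w <= 0.0:
                    break
                theta = 2.0 * np.pi * np.random.random()
                ux = np.cos(theta)
                uz = np.sin(theta)
                s = -np.log(np.random.random() + 1e-300)
                if w < ROULETTE_THRESHOLD:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w_gain += w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                        w /= ROULETTE_SURVIVAL
                    else:
                        w_kill += w
                        break
    return w_dep, w_exit, w_kill, w_gain


@njit(cache=True)
def _transport_visits(mua, mus, dx, src_x0, src_w, n_photons, seed,
                      target, counts_row, acc_mode, counts, visits):
    """One batch with per-photon distinct-voxel traversal recording.

    acc_mode 0: single-target mode — photons that traversed flat voxel
    ``target`` add their visit set to ``counts_row`` (length n_plane);
    returns the number of hits.
    acc_mode 1: bank mode — every photon adds the outer product of its
    visit set to ``counts`` (n_plane x n_plane) and increments ``visits``.
    """
    np.random.seed(seed)
    nx, nz = mua.shape
    n_plane = nx * nz
    lx = nx * dx
    lz = nz * dx
    eps = 1e-9
    eps_hop = 1e-6 * dx
    stamp = np.full(n_plane, -1, dtype=np.int64)
    vlist = np.empty(n_plane, dtype=np.int64)
    hits = 0
    for ph in range(n_photons):
        x = src_x0 + np.random.random() * src_w
        if x >= lx:
            x = lx - eps
        if x < 0.0:
            x = eps
        z = eps
        ux = 0.0
        uz = 1.0
        w = 1.0
        s = -np.log(np.random.random() + 1e-300)
        m = 0
        hit_target = False
        events = 0
        while True:
            events += 1
            if events > _MAX_EVENTS:
                break
            ix = int(np.floor(x / dx))
            iz = int(np.floor(z / dx))
            if ix < 0 or ix >= nx or iz < 0 or iz >= nz:
                break
            flat = ix * nz + iz
            if stamp[flat] != ph:
                stamp[flat] = ph
                vlist[m] = flat
                m += 1
                if flat == target:
                    hit_target = True
            mut = mua[ix, iz] + mus
            if ux > 1e-12:
                dbx = ((ix + 1) * dx - x) / ux
            elif ux < -1e-12:
                dbx = (ix * dx - x) / ux
            else:
                dbx = 1e30
            if uz > 1e-12:
                dbz = ((iz + 1) * dx - z) / uz
            elif uz < -1e-12:
                dbz = (iz * dx - z) / uz
            else:
                dbz = 1e30
            db = min(dbx, dbz)
            hop = db + eps_hop
            if mut * db < s or mut == 0.0:
                s -= mut * db
                if s < 0.0:
                    s = 0.0
                x += ux * hop
                z += uz * hop
            else:
                step = s / mut
                x += ux * step
                z += uz * step
                w *= mus / mut
                if w <= 0.0:
                    break
                theta = 2.0 * np.pi * np.random.random()
                ux = np.cos(theta)
                uz = np.sin(theta)
                s = -np.log(np.random.random() + 1e-300)
                if w < ROULETTE_THRESHOLD:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        break
        if acc_mode == 0:
            if hit_target:
                hits += 1
                for i in range(m):
                    counts_row[vlist[i]] += 1
        else:
            for i in range(m):
                vi = vlist[i]
                visits[vi] += 1
                row = counts[vi]
                for j in range(m):
                    row[vlist[j]] += 1
    return hits


# --------------------------------------------------------------------------
# fluence simulation
# --------------------------------------------------------------------------

@dataclass
class FluenceMap:
    """Per-slice fluence estimate, normalized per launched unit energy.

    ``phi_deposition`` carries the energy-deposition-scored estimate of the
    same batch stream. It is statistically noisier than the path-length
    estimate (absorption events are sparse where mu_a is small) and is the
    right input for forming measurement-like signals, whose intrinsic shot
    noise carries information about weak absorbers.
    """

    phi: np.ndarray
    se: np.ndarray
    n_photons: int
    seed: int
    estimator: str
    ledger: dict = field(default_factory=dict)
    phi_deposition: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.phi)) or np.any(self.phi < 0):
            raise ValueError("fluence must be finite and >= 0")


def _batch_seeds(seed: int, n_batches: int, salt: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), salt])
    return ss.generate_state(n_batches).astype(np.int64) % (2**31 - 1)


def simulate_fluence(
    mu_a: np.ndarray,
    mu_s_prime: float,
    spacing_mm: float,
    source: SourceSpec,
    n_photons: int,
    seed: int,
    n_batches: int = 8,
    estimator: str = "auto",
    g: float = 0.0,
) -> FluenceMap:
    """Monte Carlo fluence on one (x, z) slice.

    The returned ``phi`` has units 1/cm^2 per unit delivered energy; ``se``
    is the per-voxel standard error estimated from batch-to-batch variance.
    """
    mu_a = np.ascontiguousarray(mu_a, dtype=np.float64)
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if mu_s_prime < 0 or not (0.0 <= g < 1.0):
        raise ValueError("invalid scattering parameters")
    mus = mu_s_prime / (1.0 - g)
    if estimator == "auto":
        estimator = "pathlength" if np.any(mu_a == 0) else "deposition"
    if estimator == "deposition" and np.all(mu_a + mus == 0):
        raise ValueError(
            "all-zero mu_t slice: no interactions possible; "
            "use the path-length estimator"
        )
    dx = spacing_mm / 10.0
    nx, nz = mu_a.shape
    grid = GridSpec(dims=(nx, nz, 1), spacing_mm=spacing_mm)
    src_x0, src_w = source.launch_window_cm(grid)
    n_batches = min(n_batches, n_photons)
    per_batch = np.full(n_batches, n_photons // n_batches)
    per_batch[: n_photons % n_batches] += 1
    seeds = _batch_seeds(seed, n_batches, 0x5F1)
    phis = np.empty((n_batches, nx, nz))
    ledger = {"launched": float(n_photons), "deposited": 0.0, "exited": 0.0,
              "roulette_killed": 0.0, "roulette_gained": 0.0}
    vox_area = dx * dx
    dep_total = np.zeros((nx, nz))
    for b in range(n_batches):
        dep = np.zeros((nx, nz))
        plen = np.zeros((nx, nz))
        w_dep, w_exit, w_kill, w_gain = _transport_fluence(
            mu_a, mus, dx, src_x0, src_w, int(per_batch[b]), int(seeds[b]),
            dep, plen)
        ledger["deposited"] += w_dep
        ledger["exited"] += w_exit
        ledger["roulette_killed"] += w_kill
        ledger["roulette_gained"] += w_gain
        dep_total += dep
        if estimator == "deposition":
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = dep / (mu_a * vox_area)
            phi[mu_a == 0] = 0.0
        else:
            phi = plen / vox_area
        phis[b] = phi / per_batch[b]
    phi = np.average(phis, axis=0, weights=per_batch)
    if n_batches > 1:
        se = phis.std(axis=0, ddof=1) / np.sqrt(n_batches)
    else:
        se = np.zeros_like(phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_dep = dep_total / (mu_a * vox_area * n_photons)
    phi_dep[mu_a == 0] = 0.0
    return FluenceMap(phi=phi, se=se, n_photons=n_photons, seed=seed,
                      estimator=estimator, ledger=ledger,
                      phi_deposition=phi_dep)


def homogeneous_fluence(
    grid: GridSpec,
    source: SourceSpec,
    mu_a_background: float = 0.1,
    mu_s_prime: float = 1.5,
    n_photons: int = 1_000_000,
    seed: int = 0,
    **kwargs,
) -> FluenceMap:
    """Fluence on a uniform slice (the homogeneous-assumption baseline)."""
    mu_a = np.full(grid.plane_shape, float(mu_a_background))
    return simulate_fluence(mu_a, mu_s_prime, grid.spacing_mm, source,
                            n_photons, seed, **kwargs)


# --------------------------------------------------------------------------
# fluence contribution maps
# --------------------------------------------------------------------------

class FcmQuotaError(RuntimeError):
    """Raised when the target-hit quota cannot be met within the batch cap."""

    def __init__(self, target, achieved: int, quota: int):
        self.achieved = achieved
        self.quota = quota
        super().__init__(
            f"FCM target {target}: achieved {achieved} of {quota} "
            f"required photon hits within the batch cap"
        )


@dataclass
class FCM:
    """Fluence contribution map for one target voxel.

    ``values[v']`` is the fraction of photons that traversed the target and
    also traversed v'; values lie in [0, 1] with values[target] == 1.
    """

    target: tuple[int, int]
    values: np.ndarray
    n_target_hits: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("FCM values must lie in [0, 1]")


def simulate_fcm(
    target_voxel: tuple[int, int],
    source: SourceSpec,
    grid: GridSpec,
    mu_a_background: float = 0.1,
    mu_s_prime: float = 1.5,
    min_target_hits: int = 10_000,
    seed: int = 0,
    batch_photons: int = 100_000,
    max_batches: int = 100,
    g: float = 0.0,
) -> FCM:
    """FCM for a single target voxel in homogeneous background tissue.

    Photons are launched in batches until at least ``min_target_hits``
    distinct photons have traversed the target voxel. Each photon's traversal
    of a voxel is counted once, regardless of re-entries.
    """
    ix, iz = target_voxel
    if not (0 <= ix < grid.nx and 0 <= iz < grid.nz):
        raise ValueError(f"target {target_voxel} outside grid plane")
    if min_target_hits < 1:
        raise ValueError("min_target_hits must be >= 1")
    mu_a = np.full(grid.plane_shape, float(mu_a_background))
    mus = mu_s_prime / (1.0 - g)
    dx = grid.spacing_cm
    src_x0, src_w = source.launch_window_cm(grid)
    flat = grid.plane_flat_index(ix, iz)
    counts_row = np.zeros(grid.n_plane, dtype=np.int64)
    seeds = _batch_seeds(seed, max_batches, 0xFC3)
    dummy = np.zeros((1, 1), dtype=np.int64)
    hits = 0
    for b in range(max_batches):
        hits += _transport_visits(mu_a, mus, dx, src_x0, src_w,
                                  int(batch_photons), int(seeds[b]),
                                  int(flat), counts_row, 0, dummy,
                                  dummy[0])
        if hits >= min_target_hits:
            break
    if hits < min_target_hits:
        raise FcmQuotaError(target_voxel, hits, min_target_hits)
    values = (counts_row / hits).reshape(grid.plane_shape)
    return FCM(target=(ix, iz), values=values, n_target_hits=hits)


@dataclass
class FcmBank:
    """FCMs for every imaging-plane voxel of a fixed hardware setup.

    ``counts[v, v']`` counts photons that traversed both plane voxels (flat
    row-major indices, x-major); ``visits[v]`` counts photons traversing v.
    """

    grid: GridSpec
    counts: np.ndarray
    visits: np.ndarray
    setup_hash: str
    meta: dict = field(default_factory=dict)

    @property
    def n_fcms(self) -> int:
        return self.grid.n_plane

    def fcm(self, target_voxel: tuple[int, int]) -> FCM:
        ix, iz = target_voxel
        flat = int(self.grid.plane_flat_index(ix, iz))
        v = int(self.visits[flat])
        if v == 0:
            raise FcmQuotaError(target_voxel, 0, 1)
        values = (self.counts[flat] / v).reshape(self.grid.plane_shape)
        return FCM(target=(ix, iz), values=values, n_target_hits=v)

    def fcm_matrix(self) -> np.ndarray:
        """(n_plane, n_plane) matrix of FCM values, one row per target."""
        vis = np.maximum(self.visits.astype(np.float64), 1.0)
        return self.counts / vis[:, None]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip",
                             compression_opts=1)
            f.create_dataset("visits", data=self.visits)
            f.attrs["setup_hash"] = self.setup_hash
            f.attrs["dims"] = self.grid.dims
            f.attrs["spacing_mm"] = self.grid.spacing_mm
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path, expected_hash: str | None = None) -> "FcmBank":
        with h5py.File(path, "r") as f:
            setup_hash = str(f.attrs["setup_hash"])
            if expected_hash is not None and setup_hash != expected_hash:
                raise ValueError(
                    f"FCM bank setup hash mismatch: file has {setup_hash}, "
                    f"expected {expected_hash}; refusing to load"
                )
            grid = GridSpec(dims=tuple(int(d) for d in f.attrs["dims"]),
                            spacing_mm=float(f.attrs["spacing_mm"]))
            return cls(grid=grid, counts=f["counts"][()],
                       visits=f["visits"][()], setup_hash=setup_hash,
                       meta=json.loads(f.attrs["meta"]))


def setup_hash(grid: GridSpec, source: SourceSpec, mu_a_background: float,
               mu_s_prime: float, min_target_hits: int, seed: int,
               batch_photons: int, g: float = 0.0) -> str:
    key = repr((grid.dims, grid.spacing_mm, source.key(), mu_a_background,
                mu_s_prime, min_target_hits, seed, batch_photons, g))
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def precompute_fcm_bank(
    grid: GridSpec,
    source: SourceSpec,
    mu_a_background: float = 0.1,
    mu_s_prime: float = 1.5,
    min_target_hits: int = 10_000,
    seed: int = 0,
    batch_photons: int = 100_000,
    max_batches: int = 100,
    g: float = 0.0,
) -> FcmBank:
    """Generate the FCM bank for a hardware setup (one FCM per plane voxel).

    All plane voxels share the photon stream: each photon contributes its
    distinct-visit set to every voxel it traversed, which is equivalent to
    (but far cheaper than) independent per-target runs. Batches are launched
    until every plane voxel has at least ``min_target_hits`` traversals or
    the batch cap is reached (then the shortfall is reported in ``meta``).
    """
    mu_a = np.full(grid.plane_shape, float(mu_a_background))
    mus = mu_s_prime / (1.0 - g)
    dx = grid.spacing_cm
    src_x0, src_w = source.launch_window_cm(grid)
    n_plane = grid.n_plane
    counts = np.zeros((n_plane, n_plane), dtype=np.int64)
    visits = np.zeros(n_plane, dtype=np.int64)
    seeds = _batch_seeds(seed, max_batches, 0xBA4C)
    dummy_row = np.zeros(1, dtype=np.int64)
    used = 0
    for b in range(max_batches):
        _transport_visits(mu_a, mus, dx, src_x0, src_w, int(batch_photons),
                          int(seeds[b]), -1, dummy_row, 1, counts, visits)
        used += 1
        if visits.min() >= min_target_hits:
            break
    min_vis = int(visits.min())
    if min_vis < min_target_hits:
        warnings.warn(
            f"FCM bank: minimum per-voxel traversal count {min_vis} below "
            f"quota {min_target_hits} after {used} batches", stacklevel=2)
    shash = setup_hash(grid, source, mu_a_background, mu_s_prime,
                       min_target_hits, seed, batch_photons, g)
    meta = {
        "mu_a_background": mu_a_background,
        "mu_s_prime": mu_s_prime,
        "g": g,
        "source": list(source.key()),
        "min_target_hits": min_target_hits,
        "batch_photons": batch_photons,
        "batches_used": used,
        "min_visits": min_vis,
        "seed": seed,
    }
    return FcmBank(grid=grid, counts=counts, visits=visits,
                   setup_hash=shash, meta=meta)
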
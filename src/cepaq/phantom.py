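"""In-silico vascular tissue phantoms.

Generates voxel volumes of optical properties containing tubular "vessels"
whose centerlines follow a seeded random walk, with uniform-randomly sampled
geometry and absorption per dataset design, and a hemoglobin-based spectral
absorption model for the multispectral oxygenation dataset.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec

M_HEMOGLOBIN_G_PER_MOL = 64500.0
LN10 = np.log(10.0)

#: random-walk bounds: per-vessel step scale eta ~ U(0, ETA_MAX),
#: per-step component a ~ U(-A_MAX_MM, A_MAX_MM)
ETA_MAX = 0.2
A_MAX_MM = 0.2


# --------------------------------------------------------------------------
# blood optics
# --------------------------------------------------------------------------

def _load_extinction_table() -> np.ndarray:
    ref = importlib.resources.files("cepaq.data").joinpath("hb_extinction.tsv")
    with ref.open("rb") as fh:
        return np.loadtxt(fh, comments="#")


@dataclass(frozen=True)
class BloodOpticsModel:
    """Hemoglobin absorption model.

    ``extinction_table`` columns: wavelength [nm], molar extinction of HbO2
    and of Hb [cm^-1/M, decadic]. Concentration ``c_hb`` in g/L.
    """

    c_hb: float = 150.0
    bvf_background: float = 0.005
    bvf_vessel: float = 1.0
    extinction_table: np.ndarray = field(default_factory=_load_extinction_table)

    def __post_init__(self) -> None:
        tab = np.asarray(self.extinction_table, dtype=float)
        if tab.ndim != 2 or tab.shape[1] != 3:
            raise ValueError("extinction table must have 3 columns")
        if np.any(tab[:, 1:] <= 0):
            raise ValueError("extinction values must be > 0")
        if tab[0, 0] > 750.0 or tab[-1, 0] < 850.0:
            raise ValueError("extinction table must cover 750-850 nm")
        object.__setattr__(self, "extinction_table", tab)

    def extinction(self, wavelength_nm: float) -> tuple[float, float]:
        """Interpolated (eps_HbO2, eps_Hb) at ``wavelength_nm``."""
        tab = self.extinction_table
        lo, hi = tab[0, 0], tab[-1, 0]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside table range [{lo}, {hi}]"
            )
        eps_hbo2 = float(np.interp(wavelength_nm, tab[:, 0], tab[:, 1]))
        eps_hb = float(np.interp(wavelength_nm, tab[:, 0], tab[:, 2]))
        return eps_hbo2, eps_hb


def blood_mu_a(
    wavelength_nm: float,
    so2: float,
    model: BloodOpticsModel | None = None,
    bvf: float = 1.0,
) -> float:
    """Absorption coefficient [cm^-1] of blood-perfused tissue.

    mu_a = bvf * ln(10) * (c_hb / M_hb) * (so2*eps_HbO2 + (1-so2)*eps_Hb),
    with decadic molar extinction coefficients.
    """
    if model is None:
        model = BloodOpticsModel()
    if not (0.0 <= so2 <= 1.0):
        raise ValueError(f"so2 must be in [0, 1], got {so2}")
    eps_hbo2, eps_hb = model.extinction(wavelength_nm)
    molar = model.c_hb / M_HEMOGLOBIN_G_PER_MOL
    return bvf * LN10 * molar * (so2 * eps_hbo2 + (1.0 - so2) * eps_hb)


def background_offset(model: BloodOpticsModel | None = None,
                      target_mu_a: float = 0.1,
                      reference_wavelength_nm: float = 800.0,
                      reference_so2: float = 0.5) -> float:
    """Constant baseline added to background absorption in spectral volumes.

    Calibrated once so that background mu_a is ~``target_mu_a`` at the
    reference wavelength, keeping the multispectral background consistent
    with the 0.1 cm^-1 monospectral background.
    """
    if model is None:
        model = BloodOpticsModel()
    blood = blood_mu_a(reference_wavelength_nm, reference_so2, model,
                       bvf=model.bvf_background)
    return target_mu_a - blood


# --------------------------------------------------------------------------
# vessels
# --------------------------------------------------------------------------

@dataclass
class VesselPath:
    """Random-walk vessel: lateral wander points plus a propagation axis.

    ``points`` are the raw walk positions (mm). The raster centerline is the
    walk extruded along ``direction`` at one grid spacing per step, see
    :meth:`centerline`.
    """

    points: np.ndarray  # (n+1, 3) mm, axis order (x, z, y)
    eta: float
    radius_mm: float
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if not (0.0 <= self.eta < ETA_MAX):
            raise ValueError(f"eta must be in [0, {ETA_MAX}), got {self.eta}")
        if not self.radius_mm > 0:
            raise ValueError("vessel radius must be > 0")
        steps = np.diff(self.points, axis=0)
        if steps.size and np.abs(steps).max() > self.eta * A_MAX_MM + 1e-12:
            raise ValueError("walk step exceeds eta * a bound")

    def centerline(self, step_mm: float) -> np.ndarray:
        """Walk points extruded along ``direction``, one step per point."""
        n = len(self.points)
        drift = np.outer(np.arange(n) * step_mm, self.direction)
        return self.points + drift


def random_walk_vessel(
    seed,
    n_steps: int,
    start_point,
    start_direction=(0.0, 0.0, 1.0),
    radius_mm: float = 3.0,
) -> VesselPath:
    """Sample a vessel path: r_i = r_{i-1} + eta * a.

    ``eta`` is drawn once per vessel from U(0, 0.2); each component of ``a``
    is redrawn per step from U(-0.2, 0.2) mm. The walk itself carries no
    deterministic drift; propagation along ``start_direction`` is applied at
    raster time (one grid spacing per step).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    eta = rng.uniform(0.0, ETA_MAX)
    a = rng.uniform(-A_MAX_MM, A_MAX_MM, size=(n_steps, 3))
    points = np.empty((n_steps + 1, 3))
    points[0] = np.asarray(start_point, dtype=float)
    np.cumsum(eta * a, axis=0, out=points[1:])
    points[1:] += points[0]
    return VesselPath(points=points, eta=eta, radius_mm=radius_mm,
                      direction=np.asarray(start_direction, dtype=float))


def rasterize_vessels(paths: list[VesselPath], grid: GridSpec) -> np.ndarray:
    """Label volume: 0 = background, i = inside vessel ``paths[i-1]``.

    A voxel belongs to a vessel iff its center lies within the vessel radius
    of any centerline segment. Later vessels overwrite earlier ones where
    they overlap.
    """
    labels = np.zeros(grid.dims, dtype=np.int32)
    sp = grid.spacing_mm
    centers = grid.voxel_centers_mm()
    for vid, path in enumerate(paths, start=1):
        pts = path.centerline(sp)
        r = path.radius_mm
        touched = False
        for p0, p1 in zip(pts[:-1], pts[1:]):
            lo = np.minimum(p0, p1) - r
            hi = np.maximum(p0, p1) + r
            idx = []
            for ax in range(3):
                i0 = max(int(np.floor(lo[ax] / sp - 0.5)), 0)
                i1 = min(int(np.ceil(hi[ax] / sp - 0.5)) + 1, grid.dims[ax])
                if i0 >= i1:
                    idx = None
                    break
                idx.append((i0, i1))
            if idx is None:
                continue
            (x0, x1), (z0, z1), (y0, y1) = idx
            cx = centers[0][x0:x1][:, None, None]
            cz = centers[1][z0:z1][None, :, None]
            cy = centers[2][y0:y1][None, None, :]
            d = _dist_to_segment(cx, cz, cy, p0, p1)
            inside = d <= r
            if inside.any():
                touched = True
                labels[x0:x1, z0:z1, y0:y1][inside] = vid
        if not touched:
            warnings.warn(
                f"vessel {vid} lies entirely outside the grid", stacklevel=2
            )
    return labels


def _dist_to_segment(cx, cz, cy, p0, p1):
    """Distance from broadcast voxel-center coordinates to segment p0-p1."""
    d = p1 - p0
    dd = float(d @ d)
    vx, vz, vy = cx - p0[0], cz - p0[1], cy - p0[2]
    if dd == 0.0:
        return np.sqrt(vx * vx + vz * vz + vy * vy)
    t = (vx * d[0] + vz * d[1] + vy * d[2]) / dd
    t = np.clip(t, 0.0, 1.0)
    ex = vx - t * d[0]
    ez = vz - t * d[1]
    ey = vy - t * d[2]
    return np.sqrt(ex * ex + ez * ez + ey * ey)


# --------------------------------------------------------------------------
# tissue volumes
# --------------------------------------------------------------------------

@dataclass
class TissueVolume:
    """Ground-truth optical property volume.

    ``mu_a`` is the (blurred) absorption map [cm^-1]. For multispectral
    volumes ``mu_a_by_wavelength`` holds one map per wavelength and ``mu_a``
    aliases the 800 nm map (or the first wavelength if 800 nm is absent).
    """

    grid: GridSpec
    mu_a: np.ndarray
    labels: np.ndarray
    mu_s_prime: float = 1.5
    gamma: float = 1.0
    so2: float | None = None
    mu_a_by_wavelength: dict[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.mu_a.shape != self.grid.dims:
            raise ValueError("mu_a shape does not match grid")
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime < 0:
            raise ValueError("mu_s_prime must be >= 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.so2 is not None and not (0.0 <= self.so2 <= 1.0):
            raise ValueError("so2 must be in [0, 1]")

    def absorption(self, wavelength_nm: float | None = None) -> np.ndarray:
        if wavelength_nm is None:
            return self.mu_a
        if self.mu_a_by_wavelength is None:
            raise ValueError("volume has no spectral absorption maps")
        try:
            return self.mu_a_by_wavelength[wavelength_nm]
        except KeyError:
            raise KeyError(f"no absorption map at {wavelength_nm} nm") from None


def assign_optics(
    labels: np.ndarray,
    grid: GridSpec,
    vessel_mu_a,
    background_mu_a: float,
    mu_s_prime: float = 1.5,
    gamma: float = 1.0,
    blur_sigma_mm: float = 0.6,
    so2: float | None = None,
) -> TissueVolume:
    """Build a TissueVolume from a label mask.

    ``vessel_mu_a`` is a scalar applied to all vessels or a mapping
    ``{vessel id: mu_a}``. The absorption map is Gaussian blurred with
    ``blur_sigma_mm`` (reflective boundaries) to approximate partial-volume
    effects; the labels are left crisp.
    """
    if blur_sigma_mm < 0:
        raise ValueError("blur_sigma_mm must be >= 0")
    mu_a = np.full(labels.shape, float(background_mu_a))
    if np.isscalar(vessel_mu_a):
        mu_a[labels > 0] = float(vessel_mu_a)
    else:
        for vid, val in vessel_mu_a.items():
            mu_a[labels == vid] = float(val)
    mu_a = _blur(mu_a, blur_sigma_mm, grid)
    return TissueVolume(grid=grid, mu_a=mu_a, labels=labels,
                        mu_s_prime=mu_s_prime, gamma=gamma, so2=so2)


def _blur(mu_a: np.ndarray, blur_sigma_mm: float, grid: GridSpec) -> np.ndarray:
    if blur_sigma_mm == 0:
        return mu_a
    return gaussian_filter(mu_a, sigma=blur_sigma_mm / grid.spacing_mm,
                           mode="reflect")


# --------------------------------------------------------------------------
# dataset designs
# --------------------------------------------------------------------------

#: hard bounds any design must respect
_BOUNDS = {
    "vessel_radius_mm": (0.5, 6.0),
    "vessel_mu_a": (1.0, 12.0),
    "vessel_count": (1, 7),
    "background_mu_a": (1e-4, 0.2),
}
# the fixed single-value designs sit slightly outside the varied ranges
_FIXED_OK = {"vessel_mu_a": {4.7}, "background_mu_a": {0.1}}


@dataclass(frozen=True)
class DatasetSpec:
    """Design of one experimental dataset (uniform sampling bounds)."""

    name: str
    vessel_radius_mm: tuple[float, float] = (3.0, 3.0)
    vessel_mu_a: tuple[float, float] = (4.7, 4.7)
    vessel_count: tuple[int, int] = (1, 1)
    background_mu_a: tuple[float, float] = (0.1, 0.1)
    n_train: int = 150
    n_val: int = 25
    n_test: int = 25
    wavelengths: tuple[float, ...] = ()
    test_so2_levels: tuple[float, ...] = ()
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        for key in ("vessel_radius_mm", "vessel_mu_a", "background_mu_a",
                    "vessel_count"):
            lo, hi = getattr(self, key)
            if lo > hi:
                raise ValueError(f"{key}: lower bound exceeds upper bound")
            blo, bhi = _BOUNDS[key]
            fixed_ok = lo == hi and lo in _FIXED_OK.get(key, ())
            if not fixed_ok and not (blo <= lo and hi <= bhi):
                raise ValueError(
                    f"{key} range ({lo}, {hi}) outside design bounds "
                    f"({blo}, {bhi})"
                )
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("item counts must be >= 0")

    @property
    def multispectral(self) -> bool:
        return len(self.wavelengths) > 0

    def scaled(self, n_train=None, n_val=None, n_test=None,
               grid=None) -> "DatasetSpec":
        """Copy with reduced item counts (parameter ranges untouched)."""
        return DatasetSpec(
            name=self.name,
            vessel_radius_mm=self.vessel_radius_mm,
            vessel_mu_a=self.vessel_mu_a,
            vessel_count=self.vessel_count,
            background_mu_a=self.background_mu_a,
            n_train=self.n_train if n_train is None else n_train,
            n_val=self.n_val if n_val is None else n_val,
            n_test=self.n_test if n_test is None else n_test,
            wavelengths=self.wavelengths,
            test_so2_levels=self.test_so2_levels,
            grid=self.grid if grid is None else grid,
        )


def standard_datasets() -> dict[str, DatasetSpec]:
    """The seven standard dataset designs."""
    ds = {
        "DSbase": DatasetSpec(name="DSbase"),
        "DSradius": DatasetSpec(name="DSradius",
                                vessel_radius_mm=(0.5, 6.0)),
        "DSabsorb": DatasetSpec(name="DSabsorb", vessel_mu_a=(1.0, 12.0)),
        "DSvessel": DatasetSpec(name="DSvessel", vessel_count=(1, 7)),
        "DSbackground": DatasetSpec(name="DSbackground",
                                    background_mu_a=(1e-4, 0.2)),
        "DSmulti": DatasetSpec(name="DSmulti",
                               vessel_radius_mm=(0.5, 6.0),
                               vessel_mu_a=(1.0, 12.0),
                               vessel_count=(1, 7),
                               background_mu_a=(1e-4, 0.2),
                               n_train=400),
        "DSoxy": DatasetSpec(name="DSoxy",
                             vessel_radius_mm=(2.3, 4.0),
                             n_train=240, n_val=0, n_test=11,
                             wavelengths=(750.0, 800.0, 850.0),
                             test_so2_levels=tuple(np.round(
                                 np.arange(11) * 0.1, 10))),
    }
    return ds


def _sample_item(spec: DatasetSpec, rng: np.random.Generator,
                 split: str, index: int) -> dict:
    """Sample all free parameters of one dataset item."""
    n_vessels = int(rng.integers(spec.vessel_count[0],
                                 spec.vessel_count[1] + 1))
    rec = {
        "dataset": spec.name,
        "split": split,
        "index": index,
        "n_vessels": n_vessels,
        "background_mu_a": float(rng.uniform(*spec.background_mu_a)),
        "vessels": [],
    }
    nx, nz, _ = spec.grid.dims
    sp = spec.grid.spacing_mm
    for _ in range(n_vessels):
        radius = float(rng.uniform(*spec.vessel_radius_mm))
        mu_a = float(rng.uniform(*spec.vessel_mu_a))
        # start uniformly in the imaging plane with one-radius margin
        mx = min(radius, nx * sp / 2 - sp)
        mz = min(radius, nz * sp / 2 - sp)
        x0 = float(rng.uniform(mx, nx * sp - mx))
        z0 = float(rng.uniform(mz, nz * sp - mz))
        rec["vessels"].append({
            "radius_mm": radius,
            "mu_a": mu_a,
            "start_xz_mm": (x0, z0),
            "walk_seed": int(rng.integers(0, 2**31 - 1)),
        })
    if spec.multispectral:
        if split == "test" and spec.test_so2_levels:
            rec["so2"] = float(
                spec.test_so2_levels[index % len(spec.test_so2_levels)])
        else:
            rec["so2"] = float(rng.uniform(0.0, 1.0))
    return rec


def build_manifest(spec: DatasetSpec, seed: int) -> list[dict]:
    """Deterministic manifest of all items and their sampled parameters.

    Each split draws from its own seeded stream, so e.g. shrinking the
    training split never changes which test items are generated.
    """
    manifest = []
    for si, (split, n) in enumerate((("train", spec.n_train),
                                     ("val", spec.n_val),
                                     ("test", spec.n_test))):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE9A, si]))
        for i in range(n):
            manifest.append(_sample_item(spec, rng, split, i))
    return manifest


def realize_item(rec: dict, spec: DatasetSpec,
                 blood_model: BloodOpticsModel | None = None,
                 blur_sigma_mm: float = 0.6) -> TissueVolume:
    """Materialize the TissueVolume described by one manifest record."""
    grid = spec.grid
    paths = []
    vessel_mu_a = {}
    for i, v in enumerate(rec["vessels"], start=1):
        x0, z0 = v["start_xz_mm"]
        path = random_walk_vessel(v["walk_seed"], n_steps=grid.ny - 1,
                                  start_point=(x0, z0, grid.spacing_mm / 2),
                                  radius_mm=v["radius_mm"])
        paths.append(path)
        vessel_mu_a[i] = v["mu_a"]
    labels = rasterize_vessels(paths, grid)
    if not spec.multispectral:
        return assign_optics(labels, grid, vessel_mu_a,
                             rec["background_mu_a"],
                             blur_sigma_mm=blur_sigma_mm)
    if blood_model is None:
        blood_model = BloodOpticsModel()
    so2 = rec["so2"]
    offset = background_offset(blood_model)
    maps = {}
    for lam in spec.wavelengths:
        vessel = blood_mu_a(lam, so2, blood_model, bvf=blood_model.bvf_vessel)
        bg = blood_mu_a(lam, so2, blood_model,
                        bvf=blood_model.bvf_background) + offset
        mu_a = np.full(grid.dims, bg)
        mu_a[labels > 0] = vessel
        maps[lam] = _blur(mu_a, blur_sigma_mm, grid)
    ref = 800.0 if 800.0 in maps else spec.wavelengths[0]
    return TissueVolume(grid=grid, mu_a=maps[ref], labels=labels,
                        so2=so2, mu_a_by_wavelength=maps)


def iter_items(spec: DatasetSpec, seed: int, split: str | None = None,
               blood_model: BloodOpticsModel | None = None):
    """Yield (record, TissueVolume) pairs for a dataset (optionally one split)."""
    for rec in build_manifest(spec, seed):
        if split is not None and rec["split"] != split:
            continue
        yield rec, realize_item(rec, spec, blood_model=blood_model)
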
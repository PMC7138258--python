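"""Training-set assembly, tree-ensemble fluence regression and inversion.

Labels are the fluence correction phi_c = phi / phi_h (ratio of the true
per-slice fluence to the homogeneous-assumption fluence), or blood
oxygenation for the functional variant. Background voxels are undersampled
to a 1:1 ROI/background ratio before training. The regressor is a
100-tree random forest with library defaults otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import pasignal
from .hardware import HardwareSetup
from .phantom import TissueVolume

N_REGRESSORS = 100
N_SLICES = 5


@dataclass
class SliceBatch:
    """Everything extracted from the equidistant slices of one volume.

    Flattened x-major over (slice, plane voxel): features (n, f), fluence
    correction labels, ROI/vessel flags, signal, reference fluence and the
    validity mask (phi and phi_h strictly positive).
    """

    features: np.ndarray
    phi_c: np.ndarray
    roi: np.ndarray
    vessel: np.ndarray
    signal: np.ndarray
    phi: np.ndarray
    valid: np.ndarray
    slice_indices: np.ndarray
    so2: float | None = None


def process_volume(
    volume: TissueVolume,
    setup: HardwareSetup,
    n_photons: int,
    seed: int,
    noise_level: int = 0,
    n_slices: int = N_SLICES,
    wavelength: float | None = None,
) -> SliceBatch:
    """Simulate, form signal and encode CIs for one volume's slice set."""
    grid = volume.grid
    slices = grid.equidistant_slices(n_slices)
    phi_h = setup.phi_h_flat()
    mu_a_vol = volume.absorption(wavelength)
    feats, phic, roi, vessel, sig, phis, valid = [], [], [], [], [], [], []
    ss = np.random.SeedSequence([seed, 0x51])
    child = ss.generate_state(2 * len(slices)) % (2**31 - 1)
    for j, iy in enumerate(slices):
        mu_a = np.ascontiguousarray(mu_a_vol[:, :, iy])
        fm = setup.simulate_slice(mu_a, n_photons, int(child[2 * j]))
        # the measured signal keeps the shot noise of discrete absorption
        # events (its statistics encode weak absorbers); labels and the
        # reference fluence use the low-variance estimate
        phi_meas = (fm.phi_deposition if fm.phi_deposition is not None
                    else fm.phi)
        s = pasignal.forward_signal(mu_a, phi_meas, setup.scale_k,
                                    setup.gamma)
        s = pasignal.apply_noise(s, noise_level, int(child[2 * j + 1]))
        feats.append(setup.encoder.encode_slice(s))
        phi = fm.phi.reshape(-1)
        ok = (phi > 0) & (phi_h > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = np.where(ok, phi / np.where(phi_h > 0, phi_h, 1.0), 0.0)
        phic.append(pc)
        valid.append(ok)
        labels = volume.labels[:, :, iy]
        roi.append(pasignal.roi_mask(labels, s.reshape(grid.plane_shape),
                                     setup.background_stats).reshape(-1))
        vessel.append((labels > 0).reshape(-1))
        sig.append(s.reshape(-1))
        phis.append(phi)
    return SliceBatch(
        features=np.concatenate(feats),
        phi_c=np.concatenate(phic),
        roi=np.concatenate(roi),
        vessel=np.concatenate(vessel),
        signal=np.concatenate(sig),
        phi=np.concatenate(phis),
        valid=np.concatenate(valid),
        slice_indices=slices,
        so2=volume.so2,
    )


@dataclass
class TrainingSet:
    """Balanced, labeled CI feature matrix ready for the regressor."""

    features: np.ndarray
    labels: np.ndarray
    roi: np.ndarray
    label_type: str
    ci_config_hash: str
    provenance: dict = field(default_factory=dict)
    n_before_balancing: int = 0

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if self.label_type == "fluence_correction" and np.any(
                self.labels <= 0):
            raise ValueError("fluence correction labels must be > 0")


def balance_samples(roi: np.ndarray, seed: int) -> np.ndarray:
    """Indices achieving a 1:1 ROI/background ratio (never drops ROI).

    Background (non-ROI) samples are randomly undersampled to the ROI
    count; raises if there are no ROI samples at all.
    """
    roi = np.asarray(roi, dtype=bool)
    roi_idx = np.flatnonzero(roi)
    bg_idx = np.flatnonzero(~roi)
    if roi_idx.size == 0:
        raise ValueError("no ROI samples: cannot balance the training set")
    rng = np.random.default_rng(seed)
    take = min(roi_idx.size, bg_idx.size)
    bg_take = rng.choice(bg_idx, size=take, replace=False)
    return np.sort(np.concatenate([roi_idx, bg_take]))


def subsample_balanced(roi: np.ndarray, max_samples: int,
                       seed: int) -> np.ndarray:
    """Equal-count random subsample of ROI and background indices.

    Used to bound forest fitting time at large training scales while
    keeping the 1:1 class ratio; assumes the set is already balanced.
    """
    roi = np.asarray(roi, dtype=bool)
    half = max_samples // 2
    rng = np.random.default_rng(seed)
    parts = []
    for mask in (roi, ~roi):
        idx = np.flatnonzero(mask)
        if idx.size > half:
            idx = rng.choice(idx, size=half, replace=False)
        parts.append(idx)
    return np.sort(np.concatenate(parts))


def make_training_set(
    items,
    setup: HardwareSetup,
    n_photons: int,
    seed: int,
    noise_level: int = 0,
    n_slices: int = N_SLICES,
    balance: bool = True,
    max_samples: int | None = None,
) -> TrainingSet:
    """Assemble the fluence-correction training set from dataset items.

    ``items`` yields (record, TissueVolume) pairs (monospectral). CIs are
    extracted from ``n_slices`` equidistant slices per volume and labeled
    with phi_c; invalid voxels (zero fluence) are dropped, then background
    is undersampled 1:1 against the ROI.
    """
    feats, labels, roi = [], [], []
    n_items = 0
    n_cis = 0
    for i, (rec, vol) in enumerate(items):
        batch = process_volume(vol, setup, n_photons,
                               seed=_item_seed(seed, i),
                               noise_level=noise_level, n_slices=n_slices)
        n_cis += len(batch.features)
        ok = batch.valid
        feats.append(batch.features[ok])
        labels.append(batch.phi_c[ok])
        roi.append(batch.roi[ok])
        n_items += 1
    features = np.concatenate(feats)
    labels = np.concatenate(labels)
    roi = np.concatenate(roi)
    n_before = len(labels)
    if balance:
        keep = balance_samples(roi, seed=_item_seed(seed, -1))
        features, labels, roi = features[keep], labels[keep], roi[keep]
    if max_samples is not None and len(labels) > max_samples:
        keep = subsample_balanced(roi, max_samples, seed=_item_seed(seed, -2))
        features, labels, roi = features[keep], labels[keep], roi[keep]
    return TrainingSet(
        features=features, labels=labels, roi=roi,
        label_type="fluence_correction",
        ci_config_hash=setup.ci_config.config_hash(),
        provenance={"n_items": n_items, "n_slices": n_slices,
                    "n_photons": n_photons, "noise_level": noise_level,
                    "seed": seed, "n_cis_generated": n_cis},
        n_before_balancing=n_before,
    )


def _item_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, 0x17E, index + 10])
               .generate_state(1)[0] % (2**31 - 1))


@dataclass
class RegressorModel:
    """Trained tree ensemble plus the metadata needed for safe reuse."""

    forest: RandomForestRegressor
    label_type: str
    ci_config_hash: str
    n_trees: int
    label_range: tuple[float, float]
    label_transform: str = "identity"
    provenance: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray,
                ci_config_hash: str | None = None) -> np.ndarray:
        """Predict in the original label space (transform undone)."""
        if (ci_config_hash is not None
                and ci_config_hash != self.ci_config_hash):
            raise ValueError(
                "CI config hash mismatch between model and features; "
                "refusing to predict")
        pred = self.forest.predict(features)
        if self.label_transform == "log":
            pred = np.exp(pred)
        return pred

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "RegressorModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a RegressorModel")
        return model


def train_regressor(training_set: TrainingSet,
                    n_trees: int = N_REGRESSORS,
                    seed: int = 0,
                    label_transform: str | None = None) -> RegressorModel:
    """Fit the random forest (library defaults apart from tree count).

    Strictly positive ratio labels (fluence correction) are regressed in
    log space by default: leaf averaging then acts geometrically, which
    suits their multiplicative dynamic range. Predictions are returned in
    the original space either way.
    """
    if len(training_set.features) == 0:
        raise ValueError("empty training set")
    if label_transform is None:
        label_transform = ("log" if training_set.label_type
                           == "fluence_correction" else "identity")
    y = training_set.labels
    if label_transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive labels")
        y = np.log(y)
    elif label_transform != "identity":
        raise ValueError(f"unknown label transform {label_transform!r}")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1)
    forest.fit(training_set.features, y)
    return RegressorModel(
        forest=forest,
        label_type=training_set.label_type,
        ci_config_hash=training_set.ci_config_hash,
        n_trees=n_trees,
        label_range=(float(training_set.labels.min()),
                     float(training_set.labels.max())),
        label_transform=label_transform,
        provenance=dict(training_set.provenance, train_seed=seed),
    )


def predict_fluence(model: RegressorModel, features: np.ndarray,
                    phi_h_at_voxel: np.ndarray,
                    ci_config_hash: str | None = None) -> np.ndarray:
    """phi_hat = predicted fluence correction * phi_h, strictly positive."""
    if model.label_type != "fluence_correction":
        raise ValueError(
            f"model predicts {model.label_type!r}, not fluence correction")
    phi_c = model.predict(features, ci_config_hash=ci_config_hash)
    return phi_c * np.asarray(phi_h_at_voxel)


def reconstruct_absorption(signal: np.ndarray, phi_hat: np.ndarray,
                           gamma: float, scale_k: float):
    """Invert the signal model: mu_a = S / (k * Gamma * phi_hat).

    Returns (mu_a_hat, clipped) where ``clipped`` flags voxels whose signal
    sits at the range bound and is therefore unreliable.
    """
    signal = np.asarray(signal, dtype=float)
    phi_hat = np.asarray(phi_hat, dtype=float)
    if signal.shape != phi_hat.shape:
        raise ValueError("signal and fluence estimate must share the grid")
    if np.any(phi_hat <= 0):
        raise ValueError("fluence estimate must be strictly positive")
    mu_a_hat = signal / (scale_k * gamma * phi_hat)
    clipped = signal >= pasignal.SIGNAL_MAX
    return mu_a_hat, clipped
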
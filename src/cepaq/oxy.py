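"""Blood oxygenation estimation from multispectral stacks.

Three estimators: non-negative spectral unmixing of the raw signal,
unmixing of the fluence-corrected (estimated-absorption) signal, and direct
functional regression on concatenated per-wavelength context images. All
estimators are evaluated on the same voxel set for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .phantom import BloodOpticsModel, blood_mu_a
from .regress import RegressorModel, predict_fluence


def reference_spectra(wavelengths, model: BloodOpticsModel | None = None
                      ) -> np.ndarray:
    """Absorption spectra matrix A: rows = wavelengths, columns = (HbO2, Hb).

    Built from the same extinction table used for phantom generation so the
    forward and inverse spectral models are consistent.
    """
    if model is None:
        model = BloodOpticsModel()
    a = np.array([
        [blood_mu_a(lam, 1.0, model), blood_mu_a(lam, 0.0, model)]
        for lam in sorted(wavelengths)
    ])
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("reference spectra matrix is rank deficient")
    return a


def nnls_unmix(b: np.ndarray, a: np.ndarray):
    """Solve argmin ||Ax - b|| s.t. x >= 0; return (x, so2).

    so2 = x_HbO2 / (x_HbO2 + x_Hb); NaN when both abundances vanish.
    """
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise ValueError("reference spectra matrix is rank deficient")
    x, _ = nnls(a, b)
    total = x.sum()
    so2 = x[0] / total if total > 0 else np.nan
    return x, so2


def unmix_so2(measurements: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Row-wise NNLS unmixing; measurements shape (n, n_wavelengths)."""
    measurements = np.atleast_2d(measurements)
    out = np.empty(len(measurements))
    for i, b in enumerate(measurements):
        _, out[i] = nnls_unmix(b, a)
    return out


def mip_select(signal: np.ndarray, axis: int = 1) -> tuple:
    """Per projection line, the argmax voxel along ``axis`` (ties: lowest).

    Returns an index tuple addressing one voxel per line, usable to index
    arrays of the same shape.
    """
    signal = np.asarray(signal)
    am = np.argmax(signal, axis=axis)
    idx = list(np.indices(am.shape))
    idx.insert(axis, am)
    return tuple(idx)


@dataclass
class So2Map:
    """Oxygenation estimates on an evaluated voxel set."""

    so2: np.ndarray
    method: str
    eval_description: str = ""
    undefined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.so2 = np.asarray(self.so2, dtype=float)
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.so2)
        ok = self.so2[~self.undefined]
        if ok.size and (ok.min() < -1e-9 or ok.max() > 1 + 1e-9):
            raise ValueError("defined so2 values must lie in [0, 1]")


def estimate_so2(
    mode: str,
    signals: dict[float, np.ndarray],
    eval_idx: np.ndarray,
    spectra: np.ndarray | None = None,
    fluence_models: dict[float, RegressorModel] | None = None,
    features: dict[float, np.ndarray] | None = None,
    phi_h: np.ndarray | None = None,
    scale_k: float = 1.0,
    gamma: float = 1.0,
    functional_model: RegressorModel | None = None,
    functional_features: np.ndarray | None = None,
    eval_description: str = "",
) -> So2Map:
    """Oxygenation on a fixed voxel set by one of the three estimators.

    ``signals`` maps wavelength to the flat signal array of one slice;
    ``eval_idx`` selects the evaluated voxels (identical across modes by
    construction). For ``ce_unmix`` the per-wavelength fluence regressors
    correct each signal to an absorption estimate before unmixing; for
    ``functional`` the concatenated-CI regressor predicts so2 directly.
    """
    wavelengths = sorted(signals)
    if mode in ("raw_unmix", "ce_unmix"):
        if spectra is None:
            raise ValueError(f"{mode} requires the reference spectra matrix")
        if mode == "raw_unmix":
            meas = np.stack([signals[lam][eval_idx] for lam in wavelengths],
                            axis=1)
        else:
            if not (fluence_models and features and phi_h is not None):
                raise ValueError(
                    "ce_unmix requires per-wavelength fluence models, "
                    "features and phi_h")
            missing = [lam for lam in wavelengths if lam not in fluence_models]
            if missing:
                raise ValueError(f"missing fluence model for {missing} nm")
            cols = []
            for lam in wavelengths:
                phi_hat = predict_fluence(fluence_models[lam],
                                          features[lam][eval_idx],
                                          phi_h[eval_idx])
                cols.append(signals[lam][eval_idx]
                            / (scale_k * gamma * phi_hat))
            meas = np.stack(cols, axis=1)
        so2 = unmix_so2(meas, spectra)
        return So2Map(so2=so2, method=mode, eval_description=eval_description)
    if mode == "functional":
        if functional_model is None or functional_features is None:
            raise ValueError("functional mode requires a trained so2 model")
        if functional_model.label_type != "so2":
            raise ValueError("functional model must be labeled with so2")
        so2 = functional_model.predict(functional_features[eval_idx])
        return So2Map(so2=np.clip(so2, 0.0, 1.0), method=mode,
                      eval_description=eval_description)
    raise ValueError(f"unknown mode {mode!r}")
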
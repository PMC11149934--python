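"""Covariance estimation, LCMV spatial filtering, pseudo-T modulation maps
and virtual-electrode extraction.

The LCMV filter passes unit gain from a target voxel while minimising
output variance: w = C^-1 L eta / (eta^T L^T C^-1 L eta).  The source
orientation eta is the tangential direction maximising beamformer output
power (equivalently, minimising eta^T L^T C^-1 L eta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .containers import EpochSet
from .forward import LeadField, tangential_basis
from .preprocess import bandpass_filter

logger = logging.getLogger(__name__)


@dataclass
class CovarianceModel:
    """Data covariance with Tikhonov regularisation.

    C_reg = C + mu * lambda_max * I, with mu the regularisation fraction
    (default 5% of the largest eigenvalue of the unregularised matrix).
    """

    C: np.ndarray
    mu: float = 0.05
    band: tuple[float, float] | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        lam_max = float(np.linalg.eigvalsh(self.C)[-1])
        self.C_reg = self.C + self.mu * lam_max * np.eye(self.C.shape[0])
        self._cho = sla.cho_factor(self.C_reg)

    def solve(self, B: np.ndarray) -> np.ndarray:
        """C_reg^-1 B."""
        return sla.cho_solve(self._cho, B)


def regularized_covariance(
    epochs: EpochSet,
    band: tuple[float, float] | None = None,
    window: tuple[float, float] | None = None,
    mu: float = 0.05,
) -> CovarianceModel:
    """Covariance over concatenated kept trials, optionally band-filtered
    and restricted to an epoch-relative time window."""
    data = epochs.kept
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite data in covariance window")
    if band is not None:
        data = bandpass_filter(data, epochs.fs, band[0], band[1], axis=-1)
    if window is not None:
        data = data[:, :, epochs.window_slice(window)]
    X = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    n_ch, n_samp = X.shape
    if n_samp < 5 * n_ch:
        logger.warning("covariance from only %d samples for %d channels", n_samp, n_ch)
    C = np.cov(X)
    return CovarianceModel(C=np.atleast_2d(C), mu=mu, band=band, window=window)


@dataclass
class VoxelWeights:
    w: np.ndarray          # (n_channels,)
    eta: np.ndarray        # unit 3-vector source orientation
    ok: bool = True


def lcmv_weights(
    L_voxel: np.ndarray,
    cov: CovarianceModel,
    basis: np.ndarray | None = None,
    point: np.ndarray | None = None,
    origin: np.ndarray | None = None,
) -> VoxelWeights:
    """LCMV weights for one voxel.

    ``L_voxel`` is (n_channels, 3).  The orientation is restricted to the
    tangential plane (radial sources are silent in the sphere) and chosen
    to maximise the unit-gain output power; its sign is fixed so the
    largest-magnitude component of eta is positive.
    """
    if basis is None:
        if point is None:
            raise ValueError("need either a tangential basis or the voxel point")
        basis = tangential_basis(point, origin)[0]
    Lt = L_voxel @ basis                      # (n_channels, 2)
    scale = np.linalg.norm(Lt)
    if not np.isfinite(scale) or scale < 1e-30:
        return VoxelWeights(w=np.zeros(L_voxel.shape[0]), eta=np.zeros(3), ok=False)
    CiLt = cov.solve(Lt)
    M = Lt.T @ CiLt                            # 2x2, symmetric positive definite
    evals, evecs = np.linalg.eigh(M)
    if evals[0] <= 1e-12 * evals[-1]:
        return VoxelWeights(w=np.zeros(L_voxel.shape[0]), eta=np.zeros(3), ok=False)
    # unit-gain output power is 1 / (eta^T M eta): smallest eigenvalue wins
    eta2 = evecs[:, 0]
    eta = basis @ eta2
    if eta[np.argmax(np.abs(eta))] < 0:
        eta = -eta
        eta2 = -eta2
    denom = float(eta2 @ M @ eta2)
    w = (CiLt @ eta2) / denom
    return VoxelWeights(w=w, eta=eta, ok=True)


@dataclass
class PseudoTMap:
    points: np.ndarray       # (V, 3)
    t: np.ndarray            # (V,) pseudo-T values; NaN where unlocalizable
    ok: np.ndarray           # (V,) bool
    band: tuple[float, float]
    window_active: tuple[float, float]
    window_control: tuple[float, float]

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(np.abs(self.t)))

    @property
    def peak_point(self) -> np.ndarray:
        return self.points[self.peak_index]

    def peak_in_roi(
        self, center: np.ndarray | None = None, radius: float | None = None
    ) -> np.ndarray:
        """Location of max |T| within a spherical region of interest
        (default: the whole grid).  Mirrors restricting the peak search to
        an anatomical region such as left sensorimotor cortex."""
        if center is None or radius is None:
            return self.peak_point
        d = np.linalg.norm(self.points - np.asarray(center, float), axis=1)
        sel = (d <= radius) & self.ok
        if not sel.any():
            raise ValueError("no localizable voxel inside the region of interest")
        tt = np.where(sel, np.abs(self.t), np.nan)
        return self.points[int(np.nanargmax(tt))]


def pseudo_t_map(
    epochs: EpochSet,
    leadfield: LeadField,
    band: tuple[float, float] = (13.0, 30.0),
    window_active: tuple[float, float] = (0.3, 0.8),
    window_control: tuple[float, float] = (2.5, 3.0),
    mu: float = 0.05,
) -> PseudoTMap:
    """Voxelwise normalised power contrast between task windows.

    Weights come from the band-limited covariance over all kept data; per
    voxel, window powers P = w^T C_win w give
    T = (P_a - P_c) / (P_a + P_c), bounded in [-1, 1].
    """
    cov, covs_win = window_covariances(
        epochs, band, (window_active, window_control), mu=mu
    )
    return pseudo_t_from_covariances(
        leadfield, cov, covs_win[0], covs_win[1],
        band=band, window_active=window_active, window_control=window_control,
    )


def window_covariances(
    epochs: EpochSet,
    band: tuple[float, float],
    windows: tuple[tuple[float, float], ...],
    mu: float = 0.05,
) -> tuple[CovarianceModel, list[np.ndarray]]:
    """Band-limited whole-experiment covariance plus per-window covariances
    (shared by coarse and refined pseudo-T grids)."""
    for win in windows:
        epochs.window_slice(win)  # validates
    data = bandpass_filter(epochs.kept, epochs.fs, band[0], band[1], axis=-1)
    X_all = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    cov = CovarianceModel(C=np.cov(X_all), mu=mu, band=band)
    covs_win = []
    for win in windows:
        seg = data[:, :, epochs.window_slice(win)]
        covs_win.append(np.cov(seg.transpose(1, 0, 2).reshape(seg.shape[1], -1)))
    return cov, covs_win


def pseudo_t_from_covariances(
    leadfield: LeadField,
    cov: CovarianceModel,
    C_active: np.ndarray,
    C_control: np.ndarray,
    band: tuple[float, float] = (13.0, 30.0),
    window_active: tuple[float, float] = (0.3, 0.8),
    window_control: tuple[float, float] = (2.5, 3.0),
) -> PseudoTMap:
    """Pseudo-T map from precomputed band and window covariances."""
    covs_win = [C_active, C_control]
    _, bases = leadfield.tangential()
    V = leadfield.n_voxels
    t = np.full(V, np.nan)
    ok = np.zeros(V, dtype=bool)
    for v in range(V):
        vw = lcmv_weights(leadfield.L[v], cov, basis=bases[v])
        if not vw.ok:
            continue
        P_a = float(vw.w @ covs_win[0] @ vw.w)
        P_c = float(vw.w @ covs_win[1] @ vw.w)
        if P_a + P_c <= 0:
            continue
        t[v] = (P_a - P_c) / (P_a + P_c)
        ok[v] = True
    if not ok.any():
        raise RuntimeError("no localizable voxel in pseudo-T map")
    return PseudoTMap(
        points=leadfield.points,
        t=t,
        ok=ok,
        band=band,
        window_active=window_active,
        window_control=window_control,
    )


@dataclass
class VirtualElectrode:
    """Beamformer-projected source time course at one location."""

    epochs: np.ndarray       # (n_kept_trials, n_samples)
    fs: float
    window: tuple[float, float]
    point: np.ndarray
    eta: np.ndarray
    fingers: list[str]

    @property
    def concatenated(self) -> np.ndarray:
        return self.epochs.reshape(-1)

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.epochs.shape[1]) / self.fs


def virtual_electrode(
    epochs: EpochSet,
    leadfield_voxel: np.ndarray,
    point: np.ndarray,
    cov: CovarianceModel,
    origin: np.ndarray | None = None,
) -> VirtualElectrode:
    """Project kept epochs through the LCMV filter at one voxel.

    The covariance should be broadband (whole-experiment), per the
    source-reconstruction convention used for time-course extraction.
    """
    vw = lcmv_weights(leadfield_voxel, cov, point=point, origin=origin)
    if not vw.ok:
        raise RuntimeError("requested virtual-electrode voxel is unlocalizable")
    ve = np.einsum("c,tcs->ts", vw.w, epochs.kept)
    return VirtualElectrode(
        epochs=ve,
        fs=epochs.fs,
        window=epochs.window,
        point=np.asarray(point, float),
        eta=vw.eta,
        fingers=epochs.kept_fingers,
    )
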
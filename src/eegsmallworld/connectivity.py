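"""Histogram-based normalized mutual information between channel pairs.

For two sampled signals X and Y the mutual information is estimated by
binning each signal into ``n_bins`` equal-width bins spanning its own
[min, max] within the epoch (default 100 bins per axis, a 100 x 100
joint histogram) and computing

    MI(X, Y) = sum_xy P_XY(x, y) * log2( P_XY(x, y) / (P_X(x) P_Y(y)) )

in bits, with 0*log(0) terms contributing zero. The normalized MI

    nMI(X, Y) = MI(X, Y) / (H(X) + H(Y))

is bounded by [0, 1] (in fact by 0.5, since MI <= min(H_X, H_Y)), which
makes values comparable across subjects and bands. A subject-level
connectivity matrix is the arithmetic mean of the per-epoch matrices.

The histogram estimator is positively biased for independent finite
samples; callers that need debiased absolute values can subtract a
surrogate estimate obtained by shuffling one signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochedBandData


class ConnectivityError(ValueError):
    pass


@dataclass
class HistogramEstimate:
    """Joint/marginal histogram probabilities and the entropies and MI
    (all in bits) derived from them."""

    n_bins: int
    marginal_px: np.ndarray
    marginal_py: np.ndarray
    joint_pxy: np.ndarray
    entropy_x: float
    entropy_y: float
    mi: float


@dataclass
class ConnectivityMatrix:
    """Symmetric (n_channels, n_channels) normalized-MI matrix with zero
    diagonal, averaged over ``n_epochs_averaged`` epochs."""

    values: np.ndarray
    band: str
    subject_id: str = ""
    n_epochs_averaged: int = 1

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConnectivityError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ConnectivityError("diagonal must be zero")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(off < 0) or np.any(off > 1):
            raise ConnectivityError("off-diagonal values must lie in [0, 1]")


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index of each sample over the signal's own
    [min, max]; a constant signal maps to a single occupied bin."""
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(x.shape, dtype=np.intp)
    idx = ((x - lo) * (n_bins / (hi - lo))).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return idx


def _mi_from_joint_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    hxy = _entropy_bits(pxy.ravel())
    # MI = H(X) + H(Y) - H(X,Y); algebraically identical to the double
    # sum over cells but avoids 0/0 handling cell by cell.
    mi = max(hx + hy - hxy, 0.0)
    return px, py, pxy, hx, hy, mi


def histogram_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 100) -> HistogramEstimate:
    """Histogram MI estimate between two equal-length sample vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ConnectivityError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ConnectivityError("need at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConnectivityError("non-finite samples")
    if n_bins < 1:
        raise ConnectivityError("n_bins must be positive")
    xi = _bin_indices(x, n_bins)
    yi = _bin_indices(y, n_bins)
    counts = np.bincount(xi * n_bins + yi, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    px, py, pxy, hx, hy, mi = _mi_from_joint_counts(counts.astype(float))
    return HistogramEstimate(
        n_bins=n_bins, marginal_px=px, marginal_py=py, joint_pxy=pxy,
        entropy_x=hx, entropy_y=hy, mi=mi,
    )


def normalized_mi(est: HistogramEstimate) -> float:
    """MI / (H(X) + H(Y)), clipped into [0, 1]; defined as 0 when both
    signals are constant (both entropies zero)."""
    denom = est.entropy_x + est.entropy_y
    if denom <= 0:
        return 0.0
    return float(np.clip(est.mi / denom, 0.0, 1.0))


def _epoch_nmi_matrix(epoch: np.ndarray, n_bins: int) -> np.ndarray:
    n_ch, n_samp = epoch.shape
    if n_samp < 2:
        raise ConnectivityError("epoch too short for MI estimation")
    idx = np.empty((n_ch, n_samp), dtype=np.intp)
    ent = np.empty(n_ch)
    for c in range(n_ch):
        idx[c] = _bin_indices(epoch[c], n_bins)
        p = np.bincount(idx[c], minlength=n_bins) / n_samp
        ent[c] = _entropy_bits(p)
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        row_i = idx[i] * n_bins
        for j in range(i + 1, n_ch):
            counts = np.bincount(row_i + idx[j], minlength=n_bins * n_bins)
            hxy = _entropy_bits(counts / n_samp)
            mi = max(ent[i] + ent[j] - hxy, 0.0)
            denom = ent[i] + ent[j]
            out[i, j] = out[j, i] = min(mi / denom, 1.0) if denom > 0 else 0.0
    return out


def epoch_connectivity(
    epochs: EpochedBandData | list[np.ndarray],
    n_bins: int = 100,
    subject_id: str = "",
    band: str | None = None,
) -> ConnectivityMatrix:
    """Normalized-MI matrix per epoch, averaged into one subject-level
    symmetric matrix with zero diagonal."""
    if isinstance(epochs, EpochedBandData):
        epoch_list = epochs.epochs
        band_name = band if band is not None else epochs.band.name
    else:
        epoch_list = list(epochs)
        band_name = band or ""
    if len(epoch_list) < 1:
        raise ConnectivityError("need at least one epoch")
    acc = None
    for e in epoch_list:
        m = _epoch_nmi_matrix(np.atleast_2d(np.asarray(e, dtype=float)), n_bins)
        acc = m if acc is None else acc + m
    result = ConnectivityMatrix(
        values=acc / len(epoch_list),
        band=band_name,
        subject_id=subject_id,
        n_epochs_averaged=len(epoch_list),
    )
    result.validate()
    return result
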
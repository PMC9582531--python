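"""Spectral-PCA artifact attenuation.

The subject's all-condition average gait ERSP is rearranged into
observations = (channel, phase-bin) pairs by variables = frequency bins,
mean-centered and decomposed with PCA.  The component with the greatest
eigenvalue (the dominant spectral shape, assumed non-neural) is rejected;
back-projection through the remaining components defines a symmetric,
idempotent projector W that is re-applied unchanged to condition-specific
ERSPs so the attenuation cannot introduce condition differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitgpm.timefreq import GaitERSP


@dataclass
class SpcaModel:
    eigenvectors: np.ndarray   # (n_freq, n_freq), columns sorted by decreasing eigenvalue
    eigenvalues: np.ndarray    # (n_freq,), non-increasing
    mean: np.ndarray           # (n_freq,) variable means of the fitting data
    projector: np.ndarray      # (n_freq, n_freq): span of all but the first component
    freqs_hz: np.ndarray
    n_removed: int = 1

    def explained_fraction_first(self) -> float:
        total = float(self.eigenvalues.sum())
        return float(self.eigenvalues[0] / total) if total > 0 else 0.0


def _as_observations(ersp: GaitERSP) -> np.ndarray:
    n_ch, n_f, n_p = ersp.values_db.shape
    return ersp.values_db.transpose(0, 2, 1).reshape(n_ch * n_p, n_f)


def fit_spca(ersp_all: GaitERSP) -> SpcaModel:
    """PCA over the frequency dimension of the all-condition average ERSP."""
    X = _as_observations(ersp_all)
    if not np.all(np.isfinite(X)):
        raise ValueError("ERSP must be finite")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 frequency bins")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD for numerical stability; eigenvalues of the covariance follow
    _, s, Vt = np.linalg.svd(Xc, full_matrices=True)
    n_obs = X.shape[0]
    eigvals = np.zeros(X.shape[1])
    eigvals[:len(s)] = s ** 2 / max(n_obs - 1, 1)
    if (eigvals > 0).sum() < 2:
        raise ValueError("rank-deficient spectra: fewer than 2 nonzero eigenvalues")
    V = Vt.T
    W = V[:, 1:] @ V[:, 1:].T
    return SpcaModel(V, eigvals, mean, W, ersp_all.freqs_hz.copy())


def apply_spca(model: SpcaModel, ersp: GaitERSP) -> GaitERSP:
    """Project out the rejected spectral component; shape preserved.

    Each observation's spectrum is centered with the *fitting* means,
    multiplied by the projector, and un-centered, so the same weighting is
    applied to averaged and condition-specific ERSPs alike.
    """
    if len(model.freqs_hz) != len(ersp.freqs_hz) or np.any(model.freqs_hz != ersp.freqs_hz):
        raise ValueError("frequency grid mismatch between model and ERSP")
    X = _as_observations(ersp)
    Y = (X - model.mean) @ model.projector + model.mean
    n_ch, n_f, n_p = ersp.values_db.shape
    vals = Y.reshape(n_ch, n_p, n_f).transpose(0, 2, 1)
    return GaitERSP(vals, ersp.freqs_hz.copy(), list(ersp.ch_names),
                    ersp.n_cycles, ersp.condition)
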
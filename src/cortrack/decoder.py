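"""Backward-model stimulus reconstruction (decoding TRF).

The decoder is a linear map from multichannel EEG at a window of time lags
back to the stimulus envelope:

    s_hat(t) = sum_n sum_tau d(t + tau, n) g(tau, n)

with ``g`` estimated by ridge regression on the lagged design matrix D:

    g = (D'D + lambda I)^{-1} D' s

Model selection follows the nested leave-one-out scheme: an outer LOO over
epochs separates training from test; an inner LOO inside each training set
picks the ridge parameter lambda by mean inner-fold Pearson correlation;
the winning lambda is refit on the whole training set and the refit model
reconstructs the held-out epoch.  Accuracy is the Pearson correlation
between the reconstruction and the true envelope.

Conventions (fixed and documented):

* lag bounds are ``floor(t_min*fs)`` .. ``floor(t_max*fs)`` inclusive, so
  the canonical window [-0.2 s, +0.35 s] at 64 Hz gives shifts -13..22,
  i.e. 36 shifts including zero;
* design-matrix columns are channel-major then lag, out-of-epoch samples
  zero-filled;
* EEG channels and envelopes are z-scored per epoch before fitting
  (Pearson scoring is invariant to this);
* lambda ties break toward the larger (more regularized) value;
* stacking training epochs never bridges lags across epoch boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "LagWindow",
    "EEGEpoch",
    "DecoderModel",
    "ReconstructionResult",
    "lag_grid",
    "build_lagged_matrix",
    "ridge_fit",
    "reconstruct",
    "score",
    "nested_loo_decode",
    "DEFAULT_LAMBDA_GRID",
]

#: Ridge-parameter grid used when the caller does not supply one.
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-6, 7))


@dataclass(frozen=True)
class LagWindow:
    """An inclusive grid of integer sample shifts tau."""

    t_min: float
    t_max: float
    fs: float
    shifts: np.ndarray = field(repr=False, default=None)

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)


def lag_grid(t_min: float, t_max: float, fs: float) -> LagWindow:
    """Build the lag window for a decoder.

    Bounds are floored: ``floor(t_min*fs) .. floor(t_max*fs)`` inclusive.
    This is the convention under which [-0.2, 0.35] s at 64 Hz yields
    exactly 36 shifts (-13 .. 22) including the zero shift.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    lo = int(math.floor(t_min * fs + 1e-9))
    hi = int(math.floor(t_max * fs + 1e-9))
    shifts = np.arange(lo, hi + 1, dtype=int)
    return LagWindow(t_min=t_min, t_max=t_max, fs=fs, shifts=shifts)


@dataclass
class EEGEpoch:
    """One epoch of multichannel EEG: a channels x time matrix."""

    data: np.ndarray
    fs: float
    subject_id: object = None
    stimulus_id: object = None
    presentation: int | None = None
    epoch_index: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEGEpoch.data must be channels x time")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEGEpoch.data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]


@dataclass
class DecoderModel:
    """A fitted reconstruction filter g(tau, n) with its ridge parameter."""

    g: np.ndarray  # lags x channels
    lag_window: LagWindow
    lam: float
    training_epoch_ids: list = field(default_factory=list)

    @property
    def coef_vector(self) -> np.ndarray:
        """g flattened channel-major then lag, matching the design matrix."""
        return self.g.T.ravel()


@dataclass
class ReconstructionResult:
    """Reconstruction of one held-out epoch and its accuracy."""

    reconstruction: np.ndarray
    accuracy: float
    lambda_selected: float
    test_epoch_id: object = None
    model: DecoderModel | None = None


def build_lagged_matrix(data: np.ndarray, lag_window: LagWindow) -> np.ndarray:
    """Time x (channels * n_shifts) lagged design matrix.

    Column (n, tau) holds d(t + tau, n); samples outside the epoch are
    zero.  Columns are ordered channel-major then lag (all lags of channel
    0 first, ascending tau).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    n_ch, n_t = data.shape
    shifts = lag_window.shifts
    D = np.zeros((n_t, n_ch * len(shifts)))
    for c in range(n_ch):
        for j, tau in enumerate(shifts):
            col = c * len(shifts) + j
            if tau >= 0:
                D[: n_t - tau, col] = data[c, tau:]
            else:
                D[-tau:, col] = data[c, : n_t + tau]
    return D


def ridge_fit(D: np.ndarray, s: np.ndarray, lam: float) -> np.ndarray:
    """Solve (D'D + lam I) g = D's by a stable positive-definite solve.

    At lam = 0 on a full-column-rank design this is ordinary least
    squares; a rank-deficient design with lam = 0 falls back to the
    minimum-norm solution with a warning.  Returns the flat coefficient
    vector (channel-major then lag ordering).
    """
    D = np.asarray(D, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite inputs")
    if D.shape[0] != s.shape[0]:
        raise ValueError("row count of D must match length of s")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    A = D.T @ D
    b = D.T @ s
    A[np.diag_indices_from(A)] += lam
    try:
        return linalg.solve(A, b, assume_a="pos")
    except linalg.LinAlgError:
        if lam == 0.0:
            warnings.warn(
                "rank-deficient design with lambda=0; returning the "
                "minimum-norm least-squares solution",
                stacklevel=2,
            )
            return linalg.lstsq(D, s)[0]
        raise


def _as_model(coefs: np.ndarray, lag_window: LagWindow, n_channels: int, lam: float, ids=None) -> DecoderModel:
    g = coefs.reshape(n_channels, lag_window.n_shifts).T
    return DecoderModel(g=g, lag_window=lag_window, lam=lam, training_epoch_ids=list(ids or []))


def reconstruct(epoch: EEGEpoch | np.ndarray, model: DecoderModel) -> np.ndarray:
    """Apply a decoder: s_hat = D @ vec(g), same length as the epoch."""
    data = epoch.data if isinstance(epoch, EEGEpoch) else np.asarray(epoch, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[0] != model.g.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    D = build_lagged_matrix(data, model.lag_window)
    return D @ model.coef_vector


def score(reconstruction: np.ndarray, original: np.ndarray) -> float:
    """Pearson correlation between reconstructed and original envelopes."""
    x = np.asarray(reconstruction, dtype=float)
    y = np.asarray(original, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant trace")
    return float(stats.pearsonr(x, y)[0])


def _zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def nested_loo_decode(
    pairs,
    lag_window: LagWindow,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    zscore: bool = True,
) -> list[ReconstructionResult]:
    """Outer LOO over epochs with an inner LOO selecting lambda.

    Parameters
    ----------
    pairs
        Sequence of ``(eeg, envelope)`` where ``eeg`` is channels x time
        (or an :class:`EEGEpoch`) and ``envelope`` a matching 1-D trace
        (or :class:`~cortrack.envelope.EnvelopeTrace`).
    lag_window
        Shared lag grid.
    lambda_grid
        Candidate ridge parameters; ties in mean inner-fold correlation
        break toward the larger lambda.

    Returns one :class:`ReconstructionResult` per epoch — a study with 32
    epochs yields 32 models per participant.
    """
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must not be empty")
    if len(pairs) < 3:
        raise ValueError("need at least 3 epochs for nested LOO")

    eegs, envs, ids = [], [], []
    for k, (eeg, env) in enumerate(pairs):
        data = eeg.data if isinstance(eeg, EEGEpoch) else np.asarray(eeg, dtype=float)
        if data.ndim == 1:
            data = data[None, :]
        samples = getattr(env, "samples", env)
        samples = np.asarray(samples, dtype=float)
        if data.shape[1] != samples.size:
            raise ValueError(f"epoch {k}: EEG and envelope lengths differ")
        if zscore:
            data = _zscore(data, axis=1)
            samples = _zscore(samples)
        eegs.append(data)
        envs.append(samples)
        eid = getattr(eeg, "epoch_index", None)
        ids.append(eid if eid is not None else k)
    n_channels = eegs[0].shape[0]
    if any(e.shape[0] != n_channels for e in eegs):
        raise ValueError("all epochs must share a channel count")

    # Per-epoch sufficient statistics; stacking epochs sums them.
    Ds = [build_lagged_matrix(e, lag_window) for e in eegs]
    grams = [D.T @ D for D in Ds]
    moments = [D.T @ s for D, s in zip(Ds, envs)]
    total_gram = np.sum(grams, axis=0)
    total_moment = np.sum(moments, axis=0)

    m = len(pairs)
    results = []
    for i in range(m):
        train = [j for j in range(m) if j != i]
        if lambda_grid.size == 1 or len(train) < 2:
            best_lam = float(lambda_grid[-1])
        else:
            mean_r = np.zeros(lambda_grid.size)
            train_gram = total_gram - grams[i]
            train_moment = total_moment - moments[i]
            for j in train:
                A = train_gram - grams[j]
                b = train_moment - moments[j]
                w, U = linalg.eigh(A)
                w = np.clip(w, 0.0, None)
                Ub = U.T @ b
                for li, lam in enumerate(lambda_grid):
                    g = U @ (Ub / (w + lam))
                    shat = Ds[j] @ g
                    if np.ptp(shat) == 0:
                        continue
                    mean_r[li] += score(shat, envs[j])
            mean_r /= len(train)
            # argmax with ties toward larger lambda
            best_lam = float(lambda_grid[np.flatnonzero(mean_r >= mean_r.max() - 1e-12)[-1]])
        A = total_gram - grams[i]
        b = total_moment - moments[i]
        A = A.copy()
        A[np.diag_indices_from(A)] += best_lam
        coefs = linalg.solve(A, b, assume_a="pos")
        model = _as_model(coefs, lag_window, n_channels, best_lam, ids=[ids[j] for j in train])
        shat = Ds[i] @ coefs
        results.append(
            ReconstructionResult(
                reconstruction=shat,
                accuracy=score(shat, envs[i]),
                lambda_selected=best_lam,
                test_epoch_id=ids[i],
                model=model,
            )
        )
    return results
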
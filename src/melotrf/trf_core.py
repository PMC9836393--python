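"""Time-expanded deconvolution regression (TRF / regression evoked response).

A set of impulse regressors on the neural sampling grid is expanded into a
design matrix whose column blocks are time-shifted copies of each regressor
(lags t_min..t_max).  Ordinary least squares on the valid rows then yields a
lag-resolved kernel per regressor per channel — the temporal response
function.  Predictive performance is measured by fivefold cross-validated
Pearson correlation between predicted and recorded signal, and competing
regression models are compared with paired t-tests under Bonferroni-Holm
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, signal, stats

__all__ = [
    "NeuralRecording",
    "ImpulseRegressors",
    "DesignMatrix",
    "TRFModel",
    "CVResult",
    "bandpass",
    "time_expand",
    "fit_ols",
    "fit_ridge",
    "cv_predictive_r",
    "select_channels",
    "holm_adjust",
    "compare_models",
    "context_sweep",
]


@dataclass
class NeuralRecording:
    """Multichannel neural time series with a per-sample bad mask."""

    data: np.ndarray  # (n_channels, n_samples)
    srate: float
    bad_mask: np.ndarray | None = None  # True = bad sample
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.srate <= 0:
            raise ValueError("srate must be > 0")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (self.data.shape[1],):
            raise ValueError("bad_mask length must equal n_samples")
        if not np.all(np.isfinite(self.data[:, ~self.bad_mask])):
            raise ValueError("data must be finite on good samples")
        if not self.channel_ids:
            self.channel_ids = [f"ch{c:02d}" for c in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ImpulseRegressors:
    """Per-note feature values placed at note-onset samples."""

    matrix: np.ndarray  # (n_samples, n_features)
    names: list[str]
    srate: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be samples x features matching names")


@dataclass
class DesignMatrix:
    """Time-expanded regressor matrix with lag axis and valid-row mask."""

    matrix: np.ndarray  # (n_samples, n_regressors * n_lags)
    t_min: float
    t_max: float
    srate: float
    names: list[str]
    valid: np.ndarray  # (n_samples,) bool

    @property
    def n_lags(self) -> int:
        return round((self.t_max - self.t_min) * self.srate) + 1

    @property
    def lag_samples(self) -> np.ndarray:
        start = round(self.t_min * self.srate)
        return np.arange(start, start + self.n_lags)

    @property
    def lag_times(self) -> np.ndarray:
        return self.lag_samples / self.srate

    def columns_for_lags(self, lo: float, hi: float) -> np.ndarray:
        """Flat column indices whose lag time lies in [lo, hi]."""
        in_win = (self.lag_times >= lo - 1e-9) & (self.lag_times <= hi + 1e-9)
        lag_idx = np.where(in_win)[0]
        cols = []
        for f in range(len(self.names)):
            cols.extend(f * self.n_lags + lag_idx)
        return np.asarray(cols, dtype=int)


@dataclass
class TRFModel:
    """Estimated lag-resolved coefficients per regressor per channel."""

    coefficients: np.ndarray  # (n_regressors, n_lags, n_channels)
    lag_times: np.ndarray
    intercept: np.ndarray  # (n_channels,)
    names: list[str]
    method: str = "ols"
    alpha: float = 0.0

    def kernel(self, name: str) -> np.ndarray:
        """(n_lags, n_channels) kernel of one regressor."""
        return self.coefficients[self.names.index(name)]


@dataclass
class CVResult:
    """Cross-validated predictive correlations for one regression model."""

    r: np.ndarray  # (n_folds, n_channels)
    channel_ids: list[str]
    model_label: str = "model"
    selected: np.ndarray | None = None  # bool (n_channels,)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (np.any(finite < -1 - 1e-9) or np.any(finite > 1 + 1e-9)):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def channel_summary(self) -> np.ndarray:
        """Median r across folds, per channel."""
        return np.nanmedian(self.r, axis=0)

    def summary_r(self, selected: np.ndarray | None = None) -> float:
        """Median across folds, then mean across (selected) channels."""
        sel = selected if selected is not None else self.selected
        per_chan = self.channel_summary
        if sel is not None:
            per_chan = per_chan[np.asarray(sel, dtype=bool)]
        return float(np.mean(per_chan))


# ---------------------------------------------------------------------------
# Filtering and design construction
# ---------------------------------------------------------------------------


def bandpass(rec: NeuralRecording, lo: float, hi: float) -> NeuralRecording:
    """Zero-phase (forward-backward) FIR band-pass filter.

    The FIR is a Hamming-windowed design whose length scales with the lower
    edge (3 cycles of ``lo``); the bad mask is dilated by the filter
    half-length on each side to absorb edge smearing.
    """
    if not 0 < lo < hi < rec.srate / 2:
        raise ValueError(f"invalid band [{lo}, {hi}] at srate {rec.srate}")
    numtaps = int(3 * rec.srate / lo) | 1  # odd
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rec.srate)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    half = numtaps // 2
    dilated = rec.bad_mask.copy()
    idx = np.where(rec.bad_mask)[0]
    for i in idx:
        dilated[max(0, i - half) : i + half + 1] = True
    return NeuralRecording(
        data=filtered, srate=rec.srate, bad_mask=dilated, channel_ids=rec.channel_ids
    )


def time_expand(regs: ImpulseRegressors, t_min: float, t_max: float,
                bad_mask: np.ndarray | None = None) -> DesignMatrix:
    """Build the time-expanded design matrix.

    Column (f, l) at row s holds regressor f at sample s - lag_l (zero-padded
    at the edges), so a least-squares fit of the expanded matrix is exactly a
    deconvolution.  Rows whose sample is flagged bad are marked invalid.
    """
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    n_samples, n_feat = regs.matrix.shape
    srate = regs.srate
    start = round(t_min * srate)
    n_lags = round((t_max - t_min) * srate) + 1
    if n_lags > n_samples:
        raise ValueError("lag span longer than recording")
    X = np.zeros((n_samples, n_feat * n_lags))
    for li, lag in enumerate(range(start, start + n_lags)):
        if lag >= 0:
            src = slice(0, n_samples - lag)
            dst = slice(lag, n_samples)
        else:
            src = slice(-lag, n_samples)
            dst = slice(0, n_samples + lag)
        for f in range(n_feat):
            X[dst, f * n_lags + li] = regs.matrix[src, f]
    valid = np.ones(n_samples, dtype=bool)
    if bad_mask is not None:
        valid &= ~np.asarray(bad_mask, dtype=bool)
    return DesignMatrix(
        matrix=X, t_min=t_min, t_max=t_max, srate=srate,
        names=list(regs.names), valid=valid,
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _solve_ls(X: np.ndarray, Y: np.ndarray, allow_rank_deficient: bool,
              names: Sequence[str], n_lags: int) -> np.ndarray:
    beta, _, rank, _ = linalg.lstsq(X, Y, lapack_driver="gelsd")
    if rank < X.shape[1] and not allow_rank_deficient:
        # name the regressors contributing near-dependent columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad_cols = piv[rank:]
        bad_regs = sorted({names[(c - 1) // n_lags] for c in bad_cols if c > 0})
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns involve regressors {bad_regs}; "
            "pass allow_rank_deficient=True for a pseudo-inverse fit"
        )
    return beta


def fit_ols(
    M: DesignMatrix,
    rec: NeuralRecording,
    allow_rank_deficient: bool = False,
    rows: np.ndarray | None = None,
) -> TRFModel:
    """Per-channel least squares on the valid rows of the design.

    Solved with an SVD-based least-squares routine (never an explicit normal
    -equation inverse).  An intercept column is always included and reported
    separately.
    """
    use = M.valid if rows is None else (M.valid & rows)
    X = M.matrix[use]
    Y = rec.data[:, use].T
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(
            f"only {X.shape[0]} valid rows for {X.shape[1] + 1} columns"
        )
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    beta = _solve_ls(Xi, Y, allow_rank_deficient, M.names, M.n_lags)
    coef = beta[1:].reshape(len(M.names), M.n_lags, rec.n_channels)
    return TRFModel(
        coefficients=coef, lag_times=M.lag_times, intercept=beta[0],
        names=list(M.names),
        method="ols" if not allow_rank_deficient else "ols-pinv",
    )


def _ridge_beta(X: np.ndarray, Y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge solution with an unpenalized intercept (first column)."""
    n, p = X.shape
    Xi = np.column_stack([np.ones(n), X])
    if alpha == 0:
        beta, *_ = linalg.lstsq(Xi, Y, lapack_driver="gelsd")
        return beta
    A = Xi.T @ Xi
    pen = np.eye(p + 1) * alpha
    pen[0, 0] = 0.0
    return linalg.solve(A + pen, Xi.T @ Y, assume_a="pos")


def fit_ridge(
    M: DesignMatrix,
    rec: NeuralRecording,
    alphas: Sequence[float] = (0.0, 0.1, 1.0, 10.0, 100.0),
    n_inner_folds: int = 3,
) -> TRFModel:
    """Ridge regression with the penalty chosen by inner cross-validation.

    ``alphas`` must include 0 so that plain OLS is always a candidate; the
    inner CV uses contiguous blocks of the valid rows and picks the alpha
    with the lowest mean held-out squared error.
    """
    alphas = list(alphas)
    if 0.0 not in alphas:
        raise ValueError("alphas must include 0 (the OLS solution)")
    use = np.where(M.valid)[0]
    X = M.matrix[use]
    Y = rec.data[:, use].T
    bounds = np.linspace(0, len(use), n_inner_folds + 1).astype(int)
    sse = np.zeros(len(alphas))
    for i in range(n_inner_folds):
        test = np.zeros(len(use), dtype=bool)
        test[bounds[i] : bounds[i + 1]] = True
        Xtr, Ytr, Xte, Yte = X[~test], Y[~test], X[test], Y[test]
        for ai, alpha in enumerate(alphas):
            beta = _ridge_beta(Xtr, Ytr, alpha)
            pred = np.column_stack([np.ones(Xte.shape[0]), Xte]) @ beta
            sse[ai] += float(((pred - Yte) ** 2).sum())
    best = alphas[int(np.argmin(sse))]
    beta = _ridge_beta(X, Y, best)
    coef = beta[1:].reshape(len(M.names), M.n_lags, rec.n_channels)
    return TRFModel(
        coefficients=coef, lag_times=M.lag_times, intercept=beta[0],
        names=list(M.names), method="ridge", alpha=best,
    )


# ---------------------------------------------------------------------------
# Cross-validated predictive performance
# ---------------------------------------------------------------------------


def _fold_masks(M: DesignMatrix, n_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous time-block folds.

    Training rows within one lag span of a fold boundary are dropped so that
    no training row's lag window overlaps held-out data.
    """
    n = M.matrix.shape[0]
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    guard = M.n_lags
    folds = []
    for i in range(n_folds):
        test = np.zeros(n, dtype=bool)
        test[bounds[i] : bounds[i + 1]] = True
        train = ~test
        lo = max(0, bounds[i] - guard)
        hi = min(n, bounds[i + 1] + guard)
        train[lo : bounds[i]] = False
        train[bounds[i + 1] : hi] = False
        folds.append((train & M.valid, test & M.valid))
    return folds


def cv_predictive_r(
    M: DesignMatrix,
    rec: NeuralRecording,
    n_folds: int = 5,
    window: tuple[float, float] = (0.0, 0.6),
    method: str = "ols",
    alphas: Sequence[float] = (0.0, 0.1, 1.0, 10.0, 100.0),
    model_label: str = "model",
    return_betas: bool = False,
) -> CVResult | tuple[CVResult, list[np.ndarray]]:
    """Fivefold cross-validated predictive correlation per channel.

    Folds are contiguous 20% time blocks.  The model is fit on training rows
    over the full lag window; predictions on the held-out rows use only the
    design columns whose lag lies in ``window`` (default 0-0.6 s).  Channel
    data are z-scored with training-row statistics only.  The per-fold score
    is the Pearson r between predicted and observed signal over the
    concatenated test rows of that fold.
    """
    folds = _fold_masks(M, n_folds)
    win_cols = M.columns_for_lags(*window)
    r = np.full((n_folds, rec.n_channels), np.nan)
    betas: list[np.ndarray] = []
    for fi, (train, test) in enumerate(folds):
        if not test.any() or not train.any():
            raise ValueError(f"fold {fi} has no valid rows")
        Xtr = M.matrix[train]
        Xte = M.matrix[test][:, win_cols]
        mu = rec.data[:, train].mean(axis=1, keepdims=True)
        sd = rec.data[:, train].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Ytr = ((rec.data[:, train] - mu) / sd).T
        Yte = ((rec.data[:, test] - mu) / sd).T
        Xi = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
        if method == "ols":
            beta, *_ = linalg.lstsq(Xi, Ytr, lapack_driver="gelsd")
        elif method == "ridge":
            alist = list(alphas)
            if 0.0 not in alist:
                raise ValueError("alphas must include 0")
            # nested inner CV on the training block
            bounds = np.linspace(0, Xtr.shape[0], 4).astype(int)
            sse = np.zeros(len(alist))
            for i in range(3):
                inner = np.zeros(Xtr.shape[0], dtype=bool)
                inner[bounds[i] : bounds[i + 1]] = True
                for ai, alpha in enumerate(alist):
                    b = _ridge_beta(Xtr[~inner], Ytr[~inner], alpha)
                    pr = np.column_stack(
                        [np.ones(inner.sum()), Xtr[inner]]
                    ) @ b
                    sse[ai] += float(((pr - Ytr[inner]) ** 2).sum())
            beta = _ridge_beta(Xtr, Ytr, alist[int(np.argmin(sse))])
        else:
            raise ValueError(f"unknown method {method!r}")
        betas.append(beta)
        pred = beta[0][None, :] + Xte @ beta[1:][win_cols]
        for c in range(rec.n_channels):
            ps = pred[:, c].std()
            ys = Yte[:, c].std()
            if ps == 0 or ys == 0:
                r[fi, c] = 0.0
            else:
                r[fi, c] = np.corrcoef(pred[:, c], Yte[:, c])[0, 1]
    result = CVResult(
        r=r, channel_ids=list(rec.channel_ids), model_label=model_label
    )
    return (result, betas) if return_betas else result


def select_channels(onset_cv: CVResult, quantile: float = 2 / 3) -> np.ndarray:
    """Channels whose summary r lies strictly above the given quantile.

    When a tie makes the strict rule select nothing (e.g. all channels
    equal), all channels are kept and a warning is issued.
    """
    per_chan = onset_cv.channel_summary
    if per_chan.size < 3:
        raise ValueError("need at least 3 channels for selection")
    thresh = np.quantile(per_chan, quantile)
    sel = per_chan > thresh
    if not sel.any():
        warnings.warn(
            "strict quantile rule selected no channels; keeping all",
            stacklevel=2,
        )
        sel = np.ones_like(sel, dtype=bool)
    return sel


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_models(
    results: Mapping[str, Sequence[CVResult]],
    pairs: Sequence[tuple[str, str]] | None = None,
    selected: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Paired comparison of regression models across simulated participants.

    ``results[label]`` holds one CVResult per participant, evaluated on
    identical folds.  For each (a, b) pair the per-participant difference in
    summary r is tested with a paired t-test; p-values are Holm-adjusted
    across all pairs and Cohen's d is the mean/SD of the paired differences.
    A zero-SD difference yields NaN statistics (reported as degenerate).
    """
    labels = list(results)
    n_participants = {len(v) for v in results.values()}
    if len(n_participants) != 1:
        raise ValueError("all models need the same number of participants")
    n = n_participants.pop()
    if n < 2:
        raise ValueError("need >= 2 participants for paired tests")
    if pairs is None:
        pairs = [(a, labels[0]) for a in labels[1:]]
    summaries = {
        lab: np.array(
            [
                cv.summary_r(selected[i] if selected is not None else None)
                for i, cv in enumerate(cvs)
            ]
        )
        for lab, cvs in results.items()
    }
    rows = []
    for a, b in pairs:
        diff = summaries[a] - summaries[b]
        sd = diff.std(ddof=1)
        if sd == 0:
            t_stat, p, d = (0.0, 1.0, 0.0) if np.allclose(diff, 0) else (
                np.nan, np.nan, np.nan)
        else:
            t_stat, p = stats.ttest_rel(summaries[a], summaries[b])
            d = diff.mean() / sd
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_delta_r": float(diff.mean()),
                "sd_delta_r": float(sd),
                "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "cohens_d": float(d) if np.isfinite(d) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = holm_adjust(out.loc[mask, "p"].to_numpy())
    out["p_holm"] = adj
    return out


def context_sweep(
    evaluations: Mapping[int, tuple],
    base_cvs: Sequence[CVResult],
    surprise_cvs: Mapping[int, Sequence[CVResult]],
    selected: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tabulate music accuracy and neural Δr as a function of context length.

    ``evaluations[k]`` is the (table, per_composition, overall) triple from
    :func:`evaluate_model` at context length k; ``base_cvs`` the per-
    participant CV of the regression model without surprise; and
    ``surprise_cvs[k]`` the per-participant CV with the k-context surprise
    regressor added.  Returns one row per k with the music accuracy and the
    mean Δr (surprise minus base) across participants.
    """
    base = np.array(
        [
            cv.summary_r(selected[i] if selected is not None else None)
            for i, cv in enumerate(base_cvs)
        ]
    )
    rows = []
    for k in sorted(surprise_cvs):
        full = np.array(
            [
                cv.summary_r(selected[i] if selected is not None else None)
                for i, cv in enumerate(surprise_cvs[k])
            ]
        )
        overall = evaluations[k][2] if k in evaluations else {}
        rows.append(
            {
                "context_length": k,
                "accuracy": overall.get("accuracy", np.nan),
                "median_surprise": overall.get("median_surprise", np.nan),
                "mean_delta_r": float((full - base).mean()),
                "mean_r_full": float(full.mean()),
                "mean_r_base": float(base.mean()),
            }
        )
    return pd.DataFrame(rows)
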
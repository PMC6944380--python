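"""Analysis of reaching sessions: windowed system identification of the
inverse model, error metrics, exponential learning-curve fits, and
recovery of the learner's parameters from a trial log.

Metrics
-------
Given the true interface map ``H`` and a movement set (a trailing window
of r trials with body matrix ``Q`` (S x r) and target matrix ``U``
(K x r)):

* ``G_est = Q U^T (U U^T)^-1`` — least-squares inverse-model estimate;
* ``RE`` — reaching error: spectral norm of ``E = H Q - U`` (windowed
  variant) or the per-trial L2 norm ``|p - u|`` (per-trial variant);
* ``IME = |H G - I|`` — inverse-model error (spectral);
* ``dG = |G_n - G_{n-1}| / |G_{n-1}|`` — convergence of the inverse
  estimate;
* ``FME = |H - H_hat| / |H|`` and ``PE = |p - H_hat q|`` — forward-model
  and prediction errors (simulation-only: they need the internal
  forward estimate).

Learning curves of RE and IME are summarised by exponential fits
``a exp(-lambda n) + c``; the decay rate ``lambda_RE`` identifies the
inverse-model learning rate ``eta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit, minimize

from .interface_map import InterfaceMap
from .learning_dynamics import LearnerParams, SessionResult, run_session

__all__ = [
    "MovementWindow",
    "LearningCurves",
    "ExpFit",
    "ModelFitResult",
    "RankDeficientWindowError",
    "movement_windows",
    "estimate_inverse",
    "reaching_error",
    "per_trial_reaching_error",
    "inverse_model_error",
    "delta_G",
    "forward_model_error",
    "prediction_error",
    "compute_learning_curves",
    "fit_exponential",
    "fit_model_params",
    "r_squared",
    "trials_to_criterion",
]

DEFAULT_WINDOW = 12
COND_THRESHOLD = 1e12
#: Fixed evaluation seeds for the stochastic fitting cost; recorded in
#: result payloads so fits are reproducible bit for bit.
FIT_SEEDS = tuple(range(11, 19))


class RankDeficientWindowError(np.linalg.LinAlgError):
    """The target matrix of a movement set is (numerically) rank deficient."""


@dataclass(frozen=True)
class MovementWindow:
    """One movement set: the r trials ending at trial ``end_trial``."""

    Q: np.ndarray  # S x r body matrix
    U: np.ndarray  # K x r target matrix
    end_trial: int

    def __post_init__(self) -> None:
        if self.Q.shape[1] != self.U.shape[1]:
            raise ValueError("Q and U must be column-aligned by trial")
        if self.r < self.U.shape[0]:
            raise ValueError("window shorter than the cursor dimension")

    @property
    def r(self) -> int:
        return self.Q.shape[1]


def _log_arrays(log: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    qcols = sorted(
        (c for c in log.columns if c.startswith("q") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    q = log[qcols].to_numpy(dtype=float)
    u = log[["u_x", "u_y"]].to_numpy(dtype=float)
    p = log[["p_x", "p_y"]].to_numpy(dtype=float)
    return q, u, p


def movement_windows(
    log: pd.DataFrame, r: int = DEFAULT_WINDOW
) -> Iterator[MovementWindow]:
    """Iterate the trailing movement sets of a trial log."""
    q, u, _ = _log_arrays(log)
    if len(q) < r:
        raise ValueError(f"log holds {len(q)} trials, fewer than the window r={r}")
    for end in range(r - 1, len(q)):
        yield MovementWindow(
            Q=q[end - r + 1 : end + 1].T, U=u[end - r + 1 : end + 1].T, end_trial=end
        )


def estimate_inverse(
    win: MovementWindow, cond_threshold: float = COND_THRESHOLD
) -> np.ndarray:
    """Least-squares inverse-model estimate ``G = Q U^T (U U^T)^-1``.

    A window whose target matrix is numerically rank deficient (condition
    number of ``U U^T`` above ``cond_threshold``) falls back to the
    pseudo-inverse with a warning; randomised blocks make this rare but
    possible at window edges.
    """
    UUt = win.U @ win.U.T
    if np.linalg.cond(UUt) > cond_threshold:
        warnings.warn(
            f"rank-deficient target window ending at trial {win.end_trial}; "
            "using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        return win.Q @ np.linalg.pinv(win.U)
    return np.linalg.solve(UUt, win.U @ win.Q.T).T


def reaching_error(imap: InterfaceMap, win: MovementWindow) -> float:
    """Windowed reaching error: spectral norm of ``E = H Q + origin - U``."""
    E = imap.apply(win.Q) - win.U
    return float(np.linalg.norm(E, 2))


def per_trial_reaching_error(p: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per-trial L2 reaching error ``|p - u|`` for arrays of endpoints."""
    return np.linalg.norm(np.atleast_2d(p) - np.atleast_2d(u), axis=1)


def inverse_model_error(imap: InterfaceMap, G: np.ndarray) -> float:
    """``IME = |H G - I_K|`` (spectral norm)."""
    K = imap.K
    return float(np.linalg.norm(imap.H @ G - np.eye(K), 2))


def delta_G(G_n: np.ndarray, G_prev: np.ndarray, denominator: str = "prev") -> float:
    """Relative change ``|G_n - G_prev| / |G_denominator|`` in spectral
    norm; ``denominator`` selects the previous (default) or current
    estimate."""
    if G_n.shape != G_prev.shape:
        raise ValueError("G_n and G_prev must have the same shape")
    den = np.linalg.norm(G_prev if denominator == "prev" else G_n, 2)
    if den == 0:
        raise ZeroDivisionError("denominator inverse-model norm is zero")
    return float(np.linalg.norm(G_n - G_prev, 2) / den)


def forward_model_error(imap: InterfaceMap, H_hat: np.ndarray) -> float:
    """``FME = |H - H_hat| / |H|`` (spectral norms)."""
    hn = imap.spectral_norm()
    if hn == 0:
        raise ZeroDivisionError("interface map has zero norm")
    return float(np.linalg.norm(imap.H - np.asarray(H_hat), 2) / hn)


def prediction_error(p: np.ndarray, H_hat: np.ndarray, q: np.ndarray) -> float:
    """``PE = |p - H_hat q|`` (L2)."""
    return float(np.linalg.norm(np.asarray(p) - np.asarray(H_hat) @ np.asarray(q)))


@dataclass
class LearningCurves:
    """Per-trial and windowed learning-curve series of one session.

    Windowed series (``re_spectral``, ``re_mean``, ``ime``, ``dg``,
    ``sigma_res``) are indexed by the 0-based end trial of each window,
    ``n = r-1 .. N-1``.  ``fme`` and ``pe`` are per-trial and only
    available when the internal state trajectory is known (simulation).
    """

    n: np.ndarray
    re_spectral: np.ndarray
    re_mean: np.ndarray
    ime: np.ndarray
    dg: np.ndarray
    sigma_res: np.ndarray
    r: int
    pe: np.ndarray | None = None
    fme: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "n": self.n,
            "re_spectral": self.re_spectral,
            "re_mean": self.re_mean,
            "ime": self.ime,
            "dg": self.dg,
            "sigma_res": self.sigma_res,
        }
        if self.pe is not None:
            d["pe"] = self.pe[self.n]
            d["fme"] = self.fme[self.n]
        return pd.DataFrame(d)


def _window_view(arr: np.ndarray, r: int) -> np.ndarray:
    # (N, d) -> (N - r + 1, d, r) trailing windows
    return sliding_window_view(arr, r, axis=0)


def compute_learning_curves(
    log: pd.DataFrame,
    imap: InterfaceMap,
    r: int = DEFAULT_WINDOW,
    session: SessionResult | None = None,
    dg_denominator: str = "prev",
) -> LearningCurves:
    """All windowed metrics of a trial log, plus per-trial FME/PE when
    the generating session (with its state trajectory) is supplied."""
    q, u, p = _log_arrays(log)
    N = len(q)
    if N < r + 1:
        raise ValueError("log too short for windowed analysis")
    Qw = _window_view(q, r)  # (nw, S, r)
    Uw = _window_view(u, r)  # (nw, K, r)
    # Windowed least-squares inverse estimates, vectorised over windows.
    UUt = np.einsum("wkr,wlr->wkl", Uw, Uw)
    G_est = np.einsum("wsr,wkr,wkl->wsl", Qw, Uw, np.linalg.inv(UUt))
    resid = Qw - np.einsum("wsk,wkr->wsr", G_est, Uw)
    K = imap.K
    sigma_res = np.sqrt(np.mean(resid**2, axis=(1, 2)) * r / (r - K))
    e_trial = per_trial_reaching_error(p, u)
    re_mean = np.convolve(e_trial, np.ones(r) / r, mode="valid")
    Ew = np.einsum("ks,wsr->wkr", imap.H, Qw) + imap.origin[None, :, None] - Uw
    re_spec = np.linalg.norm(Ew, ord=2, axis=(1, 2))
    ime = np.array([inverse_model_error(imap, G) for G in G_est])
    dg = np.full(len(G_est), np.nan)
    for i in range(1, len(G_est)):
        try:
            dg[i] = delta_G(G_est[i], G_est[i - 1], denominator=dg_denominator)
        except ZeroDivisionError:
            pass
    pe = fme = None
    if session is not None:
        pe = np.array([rec.prediction_error for rec in session.records])
        fme = np.array(
            [forward_model_error(imap, H) for H in session.H_hat_traj[1:]]
        )
    return LearningCurves(
        n=np.arange(r - 1, N),
        re_spectral=re_spec,
        re_mean=re_mean,
        ime=ime,
        dg=dg,
        sigma_res=sigma_res,
        r=r,
        pe=pe,
        fme=fme,
    )


def trials_to_criterion(
    re_series: np.ndarray, n_index: np.ndarray, threshold: float = 1.0
) -> int | None:
    """First trial at which the windowed reaching error drops below
    ``threshold`` (cm); ``None`` if it never does."""
    hits = np.nonzero(re_series < threshold)[0]
    return int(n_index[hits[0]]) if len(hits) else None


@dataclass(frozen=True)
class ExpFit:
    """Exponential learning-curve fit ``a exp(-lambda n) + c``."""

    a: float
    lam: float
    c: float
    r2: float
    stderr: tuple[float, float, float]
    degenerate: bool = False  # amplitude ~ 0: lambda is unidentifiable


def fit_exponential(series: np.ndarray, n_index: np.ndarray | None = None) -> ExpFit:
    """Bounded nonlinear least squares of ``a exp(-lambda n) + c`` with
    a, lambda, c >= 0.

    A (near-)constant series yields ``a ~ 0`` and is flagged degenerate
    rather than raising: the decay rate is then meaningless.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 points for an exponential fit")
    if (y < 0).any():
        raise ValueError("series must be non-negative")
    n = np.arange(len(y)) if n_index is None else np.asarray(n_index, dtype=float)

    def model(t, a, lam, c):
        return a * np.exp(-lam * t) + c

    a0 = max(y[0] - y[-1], 1e-12)
    c0 = max(y[-1], 1e-12)
    lam0 = 2.0 / max(n[-1] - n[0], 1.0)
    try:
        popt, pcov = curve_fit(
            model,
            n,
            y,
            p0=[a0, lam0, c0],
            bounds=([0.0, 0.0, 0.0], [np.inf, 2.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - optimizer pathology
        raise RuntimeError(f"exponential fit did not converge: {err}") from err
    a, lam, c = (float(v) for v in popt)
    yhat = model(n, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else 0.0
    with np.errstate(invalid="ignore"):
        se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    degenerate = a < 1e-8 * max(1.0, float(np.max(y)))
    return ExpFit(a=a, lam=lam, c=c, r2=r2, stderr=se, degenerate=degenerate)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination ``1 - SSres/SStot``; may be negative
    for a model worse than the mean.  Raises on a constant ``y``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must have equal length >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("y is constant: R^2 is undefined (SStot = 0)")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / sst


# ---------------------------------------------------------------------------
# (epsilon, sigma) recovery from a trial log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFitResult:
    """Outcome of the (epsilon, sigma) search.

    ``cost`` is the minimised trajectory-discrepancy cost; ``forward_cost``
    is the cumulative forward-model error sum(|H - H_hat(n)|/|H|) of the
    fitted model, averaged over the evaluation seeds.
    """

    epsilon: float
    sigma: float
    cost: float
    forward_cost: float
    eta: float
    seeds: tuple[int, ...]
    n_evals: int


def _summaries(
    q: np.ndarray, e_norm: np.ndarray, Pw: np.ndarray, Uw: np.ndarray, r: int, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean reaching error and windowed residual-noise estimate."""
    wre = np.convolve(e_norm, np.ones(r) / r, mode="valid")
    Qw = _window_view(q, r)  # (nw, S, r)
    G_est = np.einsum("wsr,wrk->wsk", Qw, Pw)
    resid = Qw - np.einsum("wsk,wkr->wsr", G_est, Uw)
    sig = np.sqrt(np.mean(resid**2, axis=(1, 2)) * r / (r - K))
    return wre, sig


def fit_model_params(
    trial_log: pd.DataFrame,
    imap: InterfaceMap,
    eta_fixed: float,
    box: tuple[tuple[float, float], tuple[float, float]] = ((0.01, 0.5), (0.1, 1.5)),
    seeds: Sequence[int] = FIT_SEEDS,
    r: int = DEFAULT_WINDOW,
    sigma_weight: float = 5.0,
    starts: Sequence[tuple[float, float]] = ((0.08, 0.5), (0.2, 0.8), (0.35, 1.1)),
    maxfev: int = 100,
) -> ModelFitResult:
    """Recover the forward learning rate and exploration noise of the
    learner that produced ``trial_log``.

    The model (with ``eta_fixed`` and candidate epsilon, sigma) is
    simulated on the log's own target sequence from the default naive
    initialisation — zero forward estimate, small random inverse model
    drawn per evaluation seed, matching the generative convention — and
    compared to the log through two summary curves: the windowed mean
    reaching error and the windowed residual-noise estimate (the
    root-mean-square residual of the movement-set least squares, an
    observable proxy for sigma).  The cost is the mean squared
    discrepancy between the *seed-averaged* model curves and the
    observed ones (estimating the initial state from the log instead
    overfits the subject's early noise and biases epsilon low); it is
    minimised by multi-start Nelder-Mead over the bounded box.

    Raises ``ValueError`` if the log covers fewer than two movement sets.
    """
    if eta_fixed < 0:
        raise ValueError("eta_fixed must be >= 0")
    q_log, u_log, p_log = _log_arrays(trial_log)
    if len(q_log) < r + 1:
        raise ValueError("trial log must cover at least two movement sets")
    K, S = imap.H.shape
    targets = list(u_log)
    # Precompute per-window projectors of the (fixed) target sequence.
    Uw = _window_view(u_log, r)  # (nw, K, r)
    UUt = np.einsum("wkr,wlr->wkl", Uw, Uw)
    Pw = np.einsum("wrk,wkl->wrl", Uw.transpose(0, 2, 1), np.linalg.inv(UUt))
    wre_obs, sig_obs = _summaries(
        q_log, per_trial_reaching_error(p_log, u_log), Pw, Uw, r, K
    )
    (e_lo, e_hi), (s_lo, s_hi) = box
    n_evals = 0

    def simulate(eps: float, sig: float, seed: int) -> SessionResult:
        params = LearnerParams(eta=eta_fixed, epsilon=eps, sigma=sig, seed=seed)
        return run_session(imap, targets, params)

    def cost(x: np.ndarray) -> float:
        nonlocal n_evals
        eps, sig = float(x[0]), float(x[1])
        if not (e_lo <= eps <= e_hi and s_lo <= sig <= s_hi):
            return 1e6
        n_evals += 1
        wres, sigs = [], []
        for sd in seeds:
            res = simulate(eps, sig, sd)
            q_m = np.array([rec.q for rec in res.records])
            e_m = np.array([rec.reaching_error for rec in res.records])
            wre_m, sig_m = _summaries(q_m, e_m, Pw, Uw, r, K)
            wres.append(wre_m)
            sigs.append(sig_m)
        return float(
            np.mean((np.mean(wres, axis=0) - wre_obs) ** 2)
            + sigma_weight * np.mean((np.mean(sigs, axis=0) - sig_obs) ** 2)
        )

    best = None
    for x0 in starts:
        out = minimize(
            cost,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options=dict(xatol=1e-3, fatol=1e-4, maxfev=maxfev),
        )
        if best is None or out.fun < best.fun:
            best = out
    if best is None:  # pragma: no cover
        raise RuntimeError("no optimizer start succeeded")
    eps_hat, sig_hat = float(best.x[0]), float(best.x[1])
    eps_hat = min(max(eps_hat, e_lo), e_hi)
    sig_hat = min(max(sig_hat, s_lo), s_hi)
    fwd = 0.0
    for sd in seeds:
        res = simulate(eps_hat, sig_hat, sd)
        fwd += sum(forward_model_error(imap, H) for H in res.H_hat_traj[1:])
    return ModelFitResult(
        epsilon=eps_hat,
        sigma=sig_hat,
        cost=float(best.fun),
        forward_cost=fwd / len(seeds),
        eta=eta_fixed,
        seeds=tuple(seeds),
        n_evals=n_evals,
    )
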
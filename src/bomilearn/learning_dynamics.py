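"""Coupled forward/inverse internal-model learning dynamics.

The learner controls a cursor through a fixed linear interface ``p = Hq``
that it does not know.  Its state is a pair of internal models: a forward
estimate ``H_hat`` (K x S) predicting cursor motion from body signals, and
an inverse model ``G`` (S x K) producing body signals for a desired cursor
target.  On trial ``n`` the learner

1. plans an action ``q = G u + xi`` with exploratory Gaussian noise ``xi``
   (i.i.d. N(0, sigma^2) per component),
2. observes the realised cursor endpoint ``p = H q + origin`` and the
   reaching error ``e = p - u``,
3. updates the forward estimate down the gradient of the squared
   prediction error  1/2 |p - H_hat q|^2:

       H_hat <- H_hat + eps (p - H_hat q) q^T,

4. updates the inverse model down the gradient of the squared reaching
   error, using the *pre-update* forward estimate in place of the unknown
   true map:

       G <- G - eta H_hat^T e u^T.

Both processes run concurrently (the default); a two-phase variant first
trains the forward model on aimless motor babbling, then the inverse
model on reaching with the forward estimate frozen.

Step-size safeguard
-------------------
The forward update contracts the prediction-error component along ``q``
by the factor ``1 - eps |q|^2``.  Once the learner reaches 5 cm targets,
``|q|`` is of order 1/|H| and ``eps |q|^2`` exceeds the stability limit 2
for learning rates in the empirically observed range, so the raw update
diverges.  ``step_trial`` therefore applies the gradient with an
effective step ``min(eps, kappa/|q|^2)`` (kappa = 1.5 by default): the
literal gradient step whenever it is stable, and a normalised (projection
-type) step beyond the stability limit.  The gradient direction is never
altered.  Set ``forward_step_clip=None`` to recover the raw update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .interface_map import InterfaceMap
from .protocol import TargetSequence

__all__ = [
    "LearnerParams",
    "LearnerState",
    "TrialRecord",
    "SessionResult",
    "DivergenceError",
    "default_init_state",
    "plan_action",
    "update_forward",
    "update_inverse",
    "step_trial",
    "run_session",
    "run_two_phase",
]

#: Default scale of the random initial inverse model (per entry, body
#: units per cm).  Small enough that the initial cursor barely moves, so
#: the initial reaching error is approximately the target distance.
DEFAULT_G0_SCALE: float = 0.05


class DivergenceError(RuntimeError):
    """The learning state exceeded the divergence bound."""

    def __init__(self, trial: int, quantity: str, norm: float):
        self.trial = trial
        self.quantity = quantity
        self.norm = norm
        super().__init__(
            f"learning diverged at trial {trial}: |{quantity}| = {norm:.3g}"
        )


@dataclass(frozen=True)
class LearnerParams:
    """Scalar learning rates and exploration noise of one learner.

    eta
        Inverse-model learning rate (1/trial).
    epsilon
        Forward-model learning rate.
    sigma
        Standard deviation of the exploratory noise added to each body
        signal component (body units).
    forward_step_clip
        Safeguard constant kappa for the forward step (see module
        docstring); ``None`` disables the safeguard.
    """

    eta: float
    epsilon: float
    sigma: float
    seed: int = 0
    forward_step_clip: float | None = 1.5

    def __post_init__(self) -> None:
        if self.eta < 0 or self.epsilon < 0 or self.sigma < 0:
            raise ValueError("eta, epsilon and sigma must be non-negative")


@dataclass(frozen=True)
class LearnerState:
    """Forward estimate, inverse model and trial counter: the learning
    state.  For S = 8 body signals and a K = 2 cursor this is a
    2x8 + 8x2 = 32-dimensional state space."""

    H_hat: np.ndarray
    G: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        H_hat = np.asarray(self.H_hat, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if H_hat.shape != G.T.shape:
            raise ValueError(
                f"H_hat {H_hat.shape} and G {G.shape} have inconsistent shapes"
            )
        if not (np.isfinite(H_hat).all() and np.isfinite(G).all()):
            raise ValueError("learning state contains non-finite entries")
        object.__setattr__(self, "H_hat", H_hat)
        object.__setattr__(self, "G", G)

    @property
    def dim(self) -> int:
        """Dimension of the combined learning state space."""
        return self.H_hat.size + self.G.size


@dataclass(frozen=True)
class TrialRecord:
    """Everything observed on one reaching iteration."""

    n: int
    u: np.ndarray
    xi: np.ndarray
    q: np.ndarray
    p: np.ndarray
    p_pred: np.ndarray
    e: np.ndarray

    @property
    def reaching_error(self) -> float:
        return float(np.linalg.norm(self.e))

    @property
    def prediction_error(self) -> float:
        return float(np.linalg.norm(self.p - self.p_pred))


@dataclass
class SessionResult:
    """Trial records plus the full state trajectory of one session."""

    records: list[TrialRecord]
    H_hat_traj: np.ndarray  # (n+1, K, S), includes the initial state
    G_traj: np.ndarray  # (n+1, S, K)
    params: LearnerParams
    stopped_at: int | None = None  # trial index where the stop rule fired
    phase: np.ndarray | None = None  # per-trial phase label for two-phase runs

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self, sequence: TargetSequence | None = None) -> pd.DataFrame:
        """Trial log with the standard CSV schema
        (n, block, target_id, u_x, u_y, q1..qS, p_x, p_y, e_norm)."""
        S = self.records[0].q.shape[0]
        rows = {
            "n": [r.n for r in self.records],
            "block": (
                sequence.block_index[: len(self.records)]
                if sequence is not None
                else np.zeros(len(self.records), dtype=int)
            ),
            "target_id": (
                sequence.target_id[: len(self.records)]
                if sequence is not None
                else np.full(len(self.records), -1)
            ),
            "u_x": [r.u[0] for r in self.records],
            "u_y": [r.u[1] for r in self.records],
        }
        for j in range(S):
            rows[f"q{j + 1}"] = [r.q[j] for r in self.records]
        rows["p_x"] = [r.p[0] for r in self.records]
        rows["p_y"] = [r.p[1] for r in self.records]
        rows["e_norm"] = [r.reaching_error for r in self.records]
        return pd.DataFrame(rows)


def default_init_state(
    S: int,
    K: int,
    rng: np.random.Generator,
    g0_scale: float = DEFAULT_G0_SCALE,
) -> LearnerState:
    """Naive initial state: zero forward estimate and a small random
    inverse model (entries i.i.d. N(0, g0_scale^2)), so the initial
    reaching error is approximately the target distance."""
    return LearnerState(
        H_hat=np.zeros((K, S)), G=g0_scale * rng.standard_normal((S, K)), n=0
    )


def plan_action(
    state: LearnerState,
    u: np.ndarray,
    params: LearnerParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the body action ``q = G u + xi``, with a fresh noise draw
    ``xi ~ N(0, sigma^2 I)`` per trial."""
    u = np.asarray(u, dtype=float)
    S = state.G.shape[0]
    xi = params.sigma * rng.standard_normal(S)
    return state.G @ u + xi, xi


def update_forward(
    H_hat: np.ndarray, q: np.ndarray, p: np.ndarray, epsilon: float
) -> np.ndarray:
    """One gradient step on the squared prediction error:
    ``H_hat + epsilon (p - H_hat q) q^T``."""
    H_hat = np.asarray(H_hat, dtype=float)
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (np.isfinite(H_hat).all() and np.isfinite(q).all() and np.isfinite(p).all()):
        raise ValueError("non-finite input to update_forward")
    return H_hat + epsilon * np.outer(p - H_hat @ q, q)


def update_inverse(
    G: np.ndarray, H_hat: np.ndarray, e: np.ndarray, u: np.ndarray, eta: float
) -> np.ndarray:
    """One gradient step on the squared reaching error, with the forward
    estimate standing in for the true map:  ``G - eta H_hat^T e u^T``."""
    G = np.asarray(G, dtype=float)
    H_hat = np.asarray(H_hat, dtype=float)
    e = np.asarray(e, dtype=float)
    u = np.asarray(u, dtype=float)
    if not all(np.isfinite(a).all() for a in (G, H_hat, e, u)):
        raise ValueError("non-finite input to update_inverse")
    return G - eta * np.outer(H_hat.T @ e, u)


def _effective_forward_step(
    epsilon: float, q: np.ndarray, clip: float | None
) -> float:
    if clip is None:
        return epsilon
    return min(epsilon, clip / (1e-12 + float(q @ q)))


def step_trial(
    state: LearnerState,
    imap: InterfaceMap,
    u: np.ndarray,
    params: LearnerParams,
    rng: np.random.Generator,
) -> tuple[LearnerState, TrialRecord]:
    """One reaching trial of the concurrent dynamics.

    Order of evaluation: action and noise from the current inverse model;
    cursor endpoint and reaching error from the true interface; forward
    update from the prediction error; inverse update using the
    *pre-update* forward estimate.
    """
    u = np.asarray(u, dtype=float)
    q, xi = plan_action(state, u, params, rng)
    p = imap.apply(q)
    e = p - u
    p_pred = state.H_hat @ q
    step = _effective_forward_step(params.epsilon, q, params.forward_step_clip)
    H_hat_next = update_forward(state.H_hat, q, p, step)
    G_next = update_inverse(state.G, state.H_hat, e, u, params.eta)
    rec = TrialRecord(n=state.n, u=u, xi=xi, q=q, p=p, p_pred=p_pred, e=e)
    return LearnerState(H_hat=H_hat_next, G=G_next, n=state.n + 1), rec


def _check_divergence(state: LearnerState, bound: float, trial: int) -> None:
    gn = float(np.linalg.norm(state.G))
    hn = float(np.linalg.norm(state.H_hat))
    if not (np.isfinite(gn) and np.isfinite(hn)):
        raise DivergenceError(trial, "state", float("inf"))
    if gn > bound:
        raise DivergenceError(trial, "G", gn)
    if hn > bound:
        raise DivergenceError(trial, "H_hat", hn)


def run_session(
    imap: InterfaceMap,
    targets: TargetSequence | Sequence[np.ndarray],
    params: LearnerParams,
    init: LearnerState | None = None,
    stop_rule: str = "fixed",
    stop_threshold: float | None = None,
    stop_window: int = 12,
    divergence_factor: float = 1e6,
    rng: np.random.Generator | None = None,
) -> SessionResult:
    """Iterate ``step_trial`` over a target sequence.

    stop_rule
        ``"fixed"`` runs every trial; ``"plateau"`` stops once the
        trailing-``stop_window`` mean of the per-trial reaching-error norm
        falls below ``stop_threshold`` (default: the protocol's target
        radius, or 1 cm), after which performance is considered at
        plateau.
    divergence_factor
        Abort with :class:`DivergenceError` if |G| or |H_hat| exceeds
        ``divergence_factor`` times max(1, initial norm).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seq = list(targets.targets) if isinstance(targets, TargetSequence) else list(targets)
    K, S = imap.H.shape
    state = default_init_state(S, K, rng) if init is None else init
    if stop_threshold is None:
        stop_threshold = (
            targets.config.target_radius if isinstance(targets, TargetSequence) else 1.0
        )
    bound = divergence_factor * max(
        1.0, float(np.linalg.norm(state.G)), float(np.linalg.norm(state.H_hat))
    )
    records: list[TrialRecord] = []
    H_traj = [state.H_hat.copy()]
    G_traj = [state.G.copy()]
    stopped_at = None
    recent: list[float] = []
    for i, u in enumerate(seq):
        state, rec = step_trial(state, imap, u, params, rng)
        _check_divergence(state, bound, i)
        records.append(rec)
        H_traj.append(state.H_hat.copy())
        G_traj.append(state.G.copy())
        recent.append(rec.reaching_error)
        if len(recent) > stop_window:
            recent.pop(0)
        if (
            stop_rule == "plateau"
            and len(recent) == stop_window
            and float(np.mean(recent)) < stop_threshold
        ):
            stopped_at = i
            break
    return SessionResult(
        records=records,
        H_hat_traj=np.array(H_traj),
        G_traj=np.array(G_traj),
        params=params,
        stopped_at=stopped_at,
    )


def run_two_phase(
    imap: InterfaceMap,
    targets: TargetSequence | Sequence[np.ndarray],
    params: LearnerParams,
    init: LearnerState | None = None,
    babble_trials: int = 200,
    babble_sd: float = 1.0,
    divergence_factor: float = 1e6,
    rng: np.random.Generator | None = None,
) -> SessionResult:
    """Sequential (two-phase) variant of the learning dynamics.

    Phase 1 ("motor babbling"): body vectors are drawn i.i.d.
    N(0, babble_sd^2 I); only the forward model is updated, the inverse
    model is untouched.  Phase 2: reaching trials in which only the
    inverse model is updated, with the phase-1 forward estimate frozen.
    """
    if babble_trials < 1:
        raise ValueError("babble_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seq = list(targets.targets) if isinstance(targets, TargetSequence) else list(targets)
    K, S = imap.H.shape
    state = default_init_state(S, K, rng) if init is None else init
    bound = divergence_factor * max(
        1.0, float(np.linalg.norm(state.G)), float(np.linalg.norm(state.H_hat))
    )
    records: list[TrialRecord] = []
    H_traj = [state.H_hat.copy()]
    G_traj = [state.G.copy()]
    phase = []
    for i in range(babble_trials):
        q = babble_sd * rng.standard_normal(S)
        p = imap.apply(q)
        p_pred = state.H_hat @ q
        step = _effective_forward_step(params.epsilon, q, params.forward_step_clip)
        H_next = update_forward(state.H_hat, q, p, step)
        records.append(
            TrialRecord(
                n=state.n, u=np.zeros(K), xi=q, q=q, p=p, p_pred=p_pred, e=p
            )
        )
        state = LearnerState(H_hat=H_next, G=state.G, n=state.n + 1)
        _check_divergence(state, bound, i)
        H_traj.append(state.H_hat.copy())
        G_traj.append(state.G.copy())
        phase.append(1)
    frozen_H_hat = state.H_hat
    for i, u in enumerate(seq):
        u = np.asarray(u, dtype=float)
        q, xi = plan_action(state, u, params, rng)
        p = imap.apply(q)
        e = p - u
        G_next = update_inverse(state.G, frozen_H_hat, e, u, params.eta)
        records.append(
            TrialRecord(
                n=state.n, u=u, xi=xi, q=q, p=p, p_pred=frozen_H_hat @ q, e=e
            )
        )
        state = LearnerState(H_hat=frozen_H_hat, G=G_next, n=state.n + 1)
        _check_divergence(state, bound, babble_trials + i)
        H_traj.append(state.H_hat.copy())
        G_traj.append(state.G.copy())
        phase.append(2)
    return SessionResult(
        records=records,
        H_hat_traj=np.array(H_traj),
        G_traj=np.array(G_traj),
        params=params,
        phase=np.array(phase),
    )
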
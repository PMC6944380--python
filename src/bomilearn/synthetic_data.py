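"""Synthetic subjects: calibration babbling sets, subject-specific
interface maps and complete reaching sessions generated by the learning
dynamics themselves.

The generator emulates the statistical structure the analysis assumes:

* an 8-channel "motor babbling" recording whose first two principal
  components capture about 73% of the variance (the default eigenvalue
  spectrum is proportional to 45, 28, 8, 7, 5, 3, 2, 2, summing to 100,
  in a random orthonormal channel frame);
* the centre-out protocol (6 targets at 5 cm, 6 blocks x 9 repetitions);
* trial-by-trial learner behaviour produced by the concurrent
  forward/inverse dynamics, with subject-level parameters in the
  empirically observed ranges (sigma in [0.65, 0.83], epsilon in
  [0.15, 0.25], eta in [0.006, 0.036]).

Optional measurement noise is applied to the *logged* body signals only,
never inside the learner's loop: the learner's noise xi is exploratory
(part of the action), not sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interface_map import CalibrationSet, InterfaceMap, build_map_pca, normalize_workspace
from .learning_dynamics import LearnerParams, SessionResult, run_session
from .protocol import ProtocolConfig, TargetSequence, generate_targets

__all__ = [
    "SubjectSpec",
    "SyntheticSubject",
    "DEFAULT_BABBLE_SPECTRUM",
    "SUBJECT_PRESETS",
    "generate_calibration",
    "generate_subject",
    "make_cohort",
    "write_trial_log",
    "read_trial_log",
]

#: Default babbling eigenvalue spectrum (arbitrary units; the top two
#: components hold 73% of the total).
DEFAULT_BABBLE_SPECTRUM: tuple[float, ...] = (45.0, 28.0, 8.0, 7.0, 5.0, 3.0, 2.0, 2.0)

#: Representative subject-level parameter sets (sigma, epsilon, eta)
#: spanning the empirically observed range of interface learners.
SUBJECT_PRESETS: dict[str, tuple[float, float, float]] = {
    "S1": (0.7335, 0.1774, 0.036),
    "S2": (0.6587, 0.2463, 0.010),
    "S3": (0.7395, 0.1924, 0.015),
    "S4": (0.7241, 0.2178, 0.016),
    "S5": (0.8278, 0.1540, 0.021),
    "S6": (0.7794, 0.1937, 0.029),
}

_PARAM_RANGES = {"sigma": (0.65, 0.83), "epsilon": (0.15, 0.25), "eta": (0.006, 0.036)}


@dataclass(frozen=True)
class SubjectSpec:
    """Recipe for one synthetic subject."""

    params: LearnerParams
    babble_spectrum: tuple[float, ...] = DEFAULT_BABBLE_SPECTRUM
    measurement_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        spec = np.asarray(self.babble_spectrum, dtype=float)
        if (spec <= 0).any() or (np.diff(spec) > 0).any():
            raise ValueError("babble_spectrum must be positive and descending")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    """A complete synthetic data set with its generating ground truth."""

    spec: SubjectSpec
    calibration: CalibrationSet
    imap: InterfaceMap
    sequence: TargetSequence
    session: SessionResult  # ground-truth trajectory lives here
    trial_log: pd.DataFrame = field(repr=False)  # logged data (maybe noisy)


def generate_calibration(
    seed: int | np.random.Generator = 0,
    S: int = 8,
    M: int = 5000,
    sample_rate: float = 75.0,
    spectrum: tuple[float, ...] = DEFAULT_BABBLE_SPECTRUM,
    cutoff_hz: float = 1.0,
    mean_sd: float = 1.0,
) -> CalibrationSet:
    """Simulate a motor-babbling recording.

    Latent coordinates follow independent stationary AR(1) processes
    (first-order low-pass, ``cutoff_hz`` at ``sample_rate``), scaled to
    the requested eigenvalue spectrum and rotated into a random
    orthonormal channel frame; a random mean posture is added.  The
    smoothing makes the "dance" physically plausible; the sample
    covariance spectrum is unaffected in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.asarray(spectrum, dtype=float)
    if len(lam) != S:
        raise ValueError(f"spectrum must have S={S} entries")
    a = float(np.exp(-2.0 * np.pi * cutoff_hz / sample_rate))
    innov = np.sqrt(1.0 - a * a)
    z = np.empty((S, M))
    z[:, 0] = rng.standard_normal(S)
    w = rng.standard_normal((S, M - 1))
    for t in range(1, M):  # unit-variance stationary AR(1)
        z[:, t] = a * z[:, t - 1] + innov * w[:, t - 1]
    frame, _ = np.linalg.qr(rng.standard_normal((S, S)))
    signals = frame @ (np.sqrt(lam)[:, None] * z)
    signals += mean_sd * rng.standard_normal(S)[:, None]
    return CalibrationSet(signals=signals, sample_rate=sample_rate)


def generate_subject(
    spec: SubjectSpec, cfg: ProtocolConfig | None = None, K: int = 2
) -> SyntheticSubject:
    """Build a subject: calibration -> PCA map -> normalised workspace ->
    full reaching session run by the learning dynamics."""
    cfg = cfg or ProtocolConfig(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    cal = generate_calibration(rng, spectrum=spec.babble_spectrum)
    imap = normalize_workspace(build_map_pca(cal, K=K))
    # Simulated sessions live in the task frame: centre at the origin.
    imap = InterfaceMap(
        H=imap.H, origin=np.zeros(K), variance_share=imap.variance_share,
        eigenvalues=imap.eigenvalues,
    )
    seq = generate_targets(cfg)
    session = run_session(imap, seq, spec.params, rng=rng)
    log = session.to_frame(seq)
    if spec.measurement_noise_sd > 0:
        qcols = [c for c in log.columns if c.startswith("q") and c[1:].isdigit()]
        noise = spec.measurement_noise_sd * rng.standard_normal(
            (len(log), len(qcols))
        )
        log[qcols] = log[qcols].to_numpy() + noise
    return SyntheticSubject(
        spec=spec, calibration=cal, imap=imap, sequence=seq, session=session,
        trial_log=log,
    )


def make_cohort(
    n_subjects: int,
    master_seed: int = 0,
    cfg: ProtocolConfig | None = None,
    measurement_noise_sd: float = 0.0,
) -> list[SyntheticSubject]:
    """Generate ``n_subjects`` subjects with parameters sampled uniformly
    within the declared ranges; per-subject seeds are derived
    deterministically from ``master_seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        seed = int(rng.integers(0, 2**31 - 1))
        draw = {k: rng.uniform(*v) for k, v in _PARAM_RANGES.items()}
        params = LearnerParams(
            eta=draw["eta"], epsilon=draw["epsilon"], sigma=draw["sigma"], seed=seed
        )
        spec = SubjectSpec(
            params=params, measurement_noise_sd=measurement_noise_sd, seed=seed
        )
        sub_cfg = cfg or ProtocolConfig(seed=seed)
        out.append(generate_subject(spec, sub_cfg))
    return out


def write_trial_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
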
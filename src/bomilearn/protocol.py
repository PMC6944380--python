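"""Centre-out reaching protocol.

The training session presents targets on a circle around the screen
centre.  Targets are presented in randomised blocks: within each cycle of
``n_targets`` consecutive trials every target appears exactly once, in a
freshly drawn permutation, so a target never repeats before all others
have been visited.  The default session is 6 blocks x 9 repetitions x 6
targets = 324 centre-out movements.

Return-to-centre movements are generated by the apparatus but excluded
from the learning-trial index: the centre target is ``u = 0``, for which
the inverse-model update vanishes identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProtocolConfig", "TargetSequence", "generate_targets", "windowed"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Session geometry and block structure.

    ``blind_duration`` (s) is the initial feedback-free phase of each
    trial; the model is endpoint-level so it is metadata only.
    """

    n_targets: int = 6
    radius: float = 5.0  # cm, distance of targets from the centre
    target_radius: float = 1.0  # cm, acceptance radius of a target
    n_blocks: int = 6
    reps_per_block: int = 9
    blind_duration: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_blocks", "reps_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.radius > self.target_radius > 0:
            raise ValueError("need radius > target_radius > 0")

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.n_blocks * self.reps_per_block

    @property
    def trials_per_block(self) -> int:
        return self.n_targets * self.reps_per_block


@dataclass(frozen=True)
class TargetSequence:
    """The ordered centre-out targets of one session.

    ``targets`` has shape ``(n_trials, 2)`` in cm, task frame with the
    origin at the screen centre; ``target_id`` and ``block_index`` label
    each trial.
    """

    targets: np.ndarray
    target_id: np.ndarray
    block_index: np.ndarray
    config: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __len__(self) -> int:
        return len(self.target_id)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": np.arange(len(self)),
                "block": self.block_index,
                "target_id": self.target_id,
                "u_x": self.targets[:, 0],
                "u_y": self.targets[:, 1],
            }
        )


def target_positions(cfg: ProtocolConfig) -> np.ndarray:
    """The ``n_targets`` peripheral target positions, shape (n_targets, 2).

    Target k sits at angle k * 360/n_targets degrees, counterclockwise
    from +x, at distance ``radius`` from the origin.
    """
    k = np.arange(cfg.n_targets)
    ang = 2.0 * np.pi * k / cfg.n_targets
    return cfg.radius * np.column_stack([np.cos(ang), np.sin(ang)])


def generate_targets(cfg: ProtocolConfig | None = None) -> TargetSequence:
    """Generate the randomised-block centre-out target sequence.

    Reproducible: the same ``cfg.seed`` yields the identical sequence.
    """
    cfg = cfg or ProtocolConfig()
    rng = np.random.default_rng(cfg.seed)
    positions = target_positions(cfg)
    n_cycles = cfg.n_blocks * cfg.reps_per_block
    ids = np.concatenate([rng.permutation(cfg.n_targets) for _ in range(n_cycles)])
    blocks = np.repeat(np.arange(cfg.n_blocks), cfg.trials_per_block)
    return TargetSequence(
        targets=positions[ids], target_id=ids, block_index=blocks, config=cfg
    )


def windowed(series: Sequence | np.ndarray, r: int = 12) -> Iterator:
    """Trailing windows of length ``r`` ("movement sets"), shifted by one.

    The window ending at trial ``n`` contains items ``n-r+1 .. n``; the
    first window ends at index ``r-1``.  With the default protocol and
    r = 12 each window holds on average two trials per target.
    """
    if r < 1:
        raise ValueError("window length r must be >= 1")
    n = len(series)
    if n < r:
        raise ValueError(f"series of length {n} is shorter than the window r={r}")
    if isinstance(series, np.ndarray):
        for end in range(r, n + 1):
            yield series[end - r : end]
    else:
        for end in range(r, n + 1):
            yield series[end - r : end]
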
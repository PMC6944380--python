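"""Construction of the body-to-cursor interface map.

A body-machine interface (BoMI) reads an S-dimensional vector of body
signals ``q`` (here: planar coordinates of upper-body markers) and maps it
to a K-dimensional cursor position ``p = H q + origin`` with ``K < S``.
The linear map ``H`` is calibrated per subject from a "motor babbling"
recording: principal component analysis of the free-movement covariance
picks the K highest-variance directions of body motion as the rows of H,
so that the user's most comfortable movements span the screen.

After calibration the map is adjusted to the task workspace: rotated,
scaled and offset so the resting posture sits at the screen centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationSet",
    "InterfaceMap",
    "DegenerateCalibrationError",
    "DEFAULT_WORKSPACE_NORM",
    "build_map_pca",
    "adjust_map",
    "normalize_workspace",
]

#: Default spectral norm of the adjusted map, in cm per body-signal unit.
#: With targets at 5 cm and randomised target directions, the linearised
#: per-trial contraction of the reaching error is eta * |u|^2 * |H H^T| / 2
#: (the factor 1/2 is the angular average of the rank-one projector
#: u u^T / |u|^2), so |H| = sqrt(2)/5 makes the fitted exponential decay
#: rate of the reaching error approximately equal to eta.
DEFAULT_WORKSPACE_NORM: float = float(np.sqrt(2.0) / 5.0)


class DegenerateCalibrationError(ValueError):
    """Raised when a calibration set carries no usable variance."""


@dataclass(frozen=True)
class CalibrationSet:
    """A motor-babbling recording, organised as an S x M signal matrix.

    Parameters
    ----------
    signals
        Array of shape ``(S, M)``: S body-signal channels, M time samples.
    sample_rate
        Acquisition rate in samples per second.
    """

    signals: np.ndarray
    sample_rate: float = 75.0

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signals must be a 2-D (S, M) array")
        S, M = sig.shape
        if S < 1 or M <= S:
            raise ValueError(f"need more samples than channels, got S={S}, M={M}")
        if not np.isfinite(sig).all():
            raise ValueError("signals contain non-finite values")
        object.__setattr__(self, "signals", sig)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def save_csv(self, path: str | Path) -> None:
        """Write one row per time sample (S columns) plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.signals.T, delimiter=",")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"sample_rate": self.sample_rate}))

    @classmethod
    def load_csv(cls, path: str | Path) -> "CalibrationSet":
        path = Path(path)
        signals = np.loadtxt(path, delimiter=",").T
        sidecar = path.with_suffix(path.suffix + ".json")
        rate = 75.0
        if sidecar.exists():
            rate = float(json.loads(sidecar.read_text())["sample_rate"])
        return cls(signals=signals, sample_rate=rate)


@dataclass(frozen=True)
class InterfaceMap:
    """The fixed K x S body-to-cursor map plus workspace metadata.

    ``H`` is in cm per body-signal unit; ``origin`` (cm) is added to
    ``H q`` so the average calibration posture maps to the screen centre.
    ``variance_share`` is the fraction of calibration variance captured by
    the K retained principal components.
    """

    H: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    variance_share: float = 1.0
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if not np.isfinite(H).all():
            raise ValueError("H contains non-finite values")
        K, S = H.shape
        if K >= S:
            raise ValueError(f"interface map must reduce dimension, got K={K}, S={S}")
        origin = self.origin
        origin = np.zeros(K) if origin is None else np.asarray(origin, dtype=float)
        if origin.shape != (K,):
            raise ValueError(f"origin must have shape ({K},)")
        if not 0.0 < self.variance_share <= 1.0 + 1e-12:
            raise ValueError("variance_share must lie in (0, 1]")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "origin", origin)

    @property
    def K(self) -> int:
        return self.H.shape[0]

    @property
    def S(self) -> int:
        return self.H.shape[1]

    def apply(self, q: np.ndarray) -> np.ndarray:
        """Cursor position ``p = H q + origin`` for one or many body vectors."""
        q = np.asarray(q, dtype=float)
        if q.ndim == 1:
            return self.H @ q + self.origin
        return (self.H @ q) + self.origin[:, None]

    def spectral_norm(self) -> float:
        return float(np.linalg.norm(self.H, 2))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "H": self.H.tolist(),
            "origin": self.origin.tolist(),
            "variance_share": self.variance_share,
        }
        if self.eigenvalues is not None:
            payload["eigenvalues"] = np.asarray(self.eigenvalues).tolist()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InterfaceMap":
        d = json.loads(Path(path).read_text())
        eig = d.get("eigenvalues")
        return cls(
            H=np.array(d["H"], dtype=float),
            origin=np.array(d["origin"], dtype=float),
            variance_share=float(d["variance_share"]),
            eigenvalues=None if eig is None else np.array(eig, dtype=float),
        )


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    # PCA eigenvector signs are arbitrary; flip each so its largest-magnitude
    # component is positive, which makes the decomposition deterministic.
    out = vectors.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def build_map_pca(cal: CalibrationSet, K: int = 2) -> InterfaceMap:
    """Build the interface map from the K leading principal components.

    The rows of ``H`` are the unit-norm eigenvectors of the sample
    covariance of the calibration signals, ordered by decreasing
    eigenvalue.  The channel means are folded into ``origin`` so the
    average babbling posture maps to the screen centre.

    Raises
    ------
    DegenerateCalibrationError
        If the calibration signals carry (numerically) zero total variance.
    ValueError
        If ``K`` is not smaller than the number of channels.
    """
    S = cal.n_channels
    if not 1 <= K < S:
        raise ValueError(f"K must satisfy 1 <= K < S={S}, got {K}")
    mean = cal.signals.mean(axis=1)
    cov = np.cov(cal.signals)
    total = float(np.trace(cov))
    if not total > 0.0:
        raise DegenerateCalibrationError(
            "calibration signals have zero variance; the recording is unusable"
        )
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    H = _fix_eigenvector_signs(evecs[:, :K].T)
    share = float(evals[:K].sum() / total)
    return InterfaceMap(
        H=H,
        origin=-H @ mean,
        variance_share=min(share, 1.0),
        eigenvalues=evals,
    )


def adjust_map(
    imap: InterfaceMap,
    rotation: float = 0.0,
    scale: float = 1.0,
    origin: np.ndarray | None = None,
) -> InterfaceMap:
    """Workspace adjustment: rotate (degrees, counterclockwise), scale
    and re-offset the map, mirroring the user-customisation phase in which
    origin, orientation and scaling of the task space are chosen.

    Only ``K = 2`` maps support a rotation angle.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    H = imap.H
    if rotation != 0.0:
        if imap.K != 2:
            raise ValueError("rotation is only defined for 2-D cursor maps")
        a = np.deg2rad(rotation)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        H = R @ H
    H = scale * H
    new_origin = imap.origin if origin is None else np.asarray(origin, dtype=float)
    return replace(imap, H=H, origin=new_origin)


def normalize_workspace(
    imap: InterfaceMap, target_norm: float = DEFAULT_WORKSPACE_NORM
) -> InterfaceMap:
    """Rescale the map so its spectral norm equals ``target_norm``.

    The subjects' hand-tuned scalings are not published, so simulations use
    a fixed, reproducible convention instead (see DEFAULT_WORKSPACE_NORM).
    """
    if target_norm <= 0:
        raise ValueError("target_norm must be positive")
    norm = imap.spectral_norm()
    if norm == 0.0:
        raise ValueError("cannot normalize a zero map")
    return replace(imap, H=imap.H * (target_norm / norm))
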
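"""First-PC / center-of-mass extraction and motion-onset detection.

The informational content of multi-sensor body motion is summarized by
the first principal component of the pooled sensor coordinates
(excluding the finger); its near-equal loadings make it act as a
center-of-mass motion.  Motion onset is the first time the speed of a
channel exceeds a threshold (0.05 cm/s in this paradigm); the defending
player's response additionally requires motion in the same direction as
the attacking player's reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "FirstPC",
    "velocity",
    "first_pc",
    "center_of_mass",
    "detect_onset",
    "blocker_response",
]

ONSET_SPEED_CM_S = 0.05


@dataclass
class FirstPC:
    """First principal component of pooled sensor coordinates.

    ``loadings`` is the unit component vector over sensor-coordinate
    columns; ``percent`` maps ``"<sensor>_<axis>"`` to the squared
    loading in percent (the coordinate's contribution to the PC);
    ``projection`` is the per-sample score.  ``fallback`` flags
    rank-deficient input where the center-of-mass x-axis was used
    instead.
    """

    loadings: Optional[np.ndarray]
    percent: dict[str, float]
    projection: np.ndarray
    sensors: list[str]
    fallback: bool = False
    explained_fraction: float = float("nan")


def velocity(pos: np.ndarray, rate: float) -> np.ndarray:
    """First-difference velocity, assigned to the later sample.

    For a position series of n samples returns n-1 velocity values; the
    k-th value belongs to time ``t0 + (k+1)/rate``.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 samples for a velocity")
    return np.diff(pos, axis=0) * rate


def _body_sensors(trial, exclude: Sequence[str]) -> list[str]:
    return [s for s in trial.sensors if s not in exclude]


def first_pc(trial, exclude: Sequence[str] = ("finger",)) -> FirstPC:
    """First principal component of the pooled body-sensor coordinates.

    Coordinates (three per sensor) are the variables, time samples the
    observations.  The projection sign is fixed toward the reach
    direction: the net displacement of the projected series is made
    positive.  Rank-deficient (zero-variance) input falls back to the
    center-of-mass motion axis, flagged in the result.
    """
    sensors = _body_sensors(trial, exclude)
    if len(sensors) < 2:
        raise ValueError(f"need at least 2 sensors after excluding {exclude}")
    X = np.column_stack([trial.pos[s] for s in sensors])  # (n, 3*len)
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 0):
        com = center_of_mass(trial, exclude=exclude)
        return FirstPC(
            loadings=None, percent={}, projection=com[:, 0] - com[0, 0],
            sensors=sensors, fallback=True,
        )
    pca = PCA(n_components=1, svd_solver="full")
    proj = pca.fit_transform(Xc)[:, 0]
    w = pca.components_[0]
    if proj[-1] - proj[0] < 0:  # sign convention: toward the reach
        proj = -proj
        w = -w
    axes = "xyz"
    percent = {
        f"{s}_{axes[a]}": float(100.0 * w[3 * i + a] ** 2)
        for i, s in enumerate(sensors)
        for a in range(3)
    }
    return FirstPC(
        loadings=w, percent=percent, projection=proj, sensors=sensors,
        explained_fraction=float(pca.explained_variance_ratio_[0]),
    )


def center_of_mass(trial, exclude: Sequence[str] = ("finger",)) -> np.ndarray:
    """Unweighted mean of the body-sensor positions, per sample."""
    sensors = _body_sensors(trial, exclude)
    if not sensors:
        raise ValueError("no body sensors left after exclusion")
    return np.mean([trial.pos[s] for s in sensors], axis=0)


def detect_onset(
    pos: np.ndarray,
    rate: float,
    threshold: float = ONSET_SPEED_CM_S,
    t0: float = 0.0,
) -> Optional[float]:
    """First time the speed of a position series exceeds ``threshold``.

    ``pos`` may be 1-D or (n, d); speed is the Euclidean norm of the
    first-difference velocity, assigned to the later sample.  Returns
    None if the speed never exceeds the threshold.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    v = velocity(pos, rate)
    speed = np.linalg.norm(v, axis=1)
    idx = np.flatnonzero(speed > threshold)
    if idx.size == 0:
        return None
    return t0 + (idx[0] + 1) / rate


def blocker_response(
    pos: np.ndarray,
    attacker_direction: int,
    rate: float,
    threshold: float = ONSET_SPEED_CM_S,
    axis: int = 0,
    t0: float = 0.0,
) -> Optional[float]:
    """First time the signed target-axis velocity matches the attack.

    The response is the first sample where the velocity component along
    the target axis exceeds ``threshold`` in the same direction as the
    attacking player's motion (``attacker_direction`` is +/-1).
    """
    if attacker_direction not in (-1, 1):
        raise ValueError("attacker_direction must be +/-1")
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    v = velocity(pos, rate)[:, axis]
    idx = np.flatnonzero(v * attacker_direction > threshold)
    if idx.size == 0:
        return None
    return t0 + (idx[0] + 1) / rate
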
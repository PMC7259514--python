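"""Fold-transition (saddle-node) trajectory simulation and matched controls.

The minimal model of a noisy fold transition is

    dx/dt = y + x**2 + xi(t),        dy/dt = epsilon,

where ``x`` is the fast variable (the observed signal), ``y`` the slow
control parameter ("decision momentum"), and ``xi`` uncorrelated noise.
For ``y < 0`` the fast dynamics have a stable fixed point at
``-sqrt(-y)``; when ``y`` crosses zero the fixed points annihilate and
``x`` escapes.  The saturating variant used for on-screen dot stimuli is

    dx/dt = y + a*x**2 - x**3 + gamma*xi(t),

whose post-transition plateau is set by the quadratic coefficient ``a``.

Integration is an explicit Euler update per readout step, with the noise
term added once per readout as ``gamma * xi_k`` (the equations are treated
as a discrete map at the readout rate, not as a continuum SDE with
``sqrt(dt)``-scaled increments).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Trajectory",
    "stable_branch",
    "simulate_fold_minimal",
    "simulate_fold_exp3",
    "simulate_heaviside_control",
    "detrend",
    "generate_exp3_ensemble",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a fold-transition simulation.

    Attributes
    ----------
    a : float
        Quadratic coefficient; sets the post-transition plateau of the
        saturating (cubic) model.
    gamma : float
        Noise amplitude multiplying the per-readout noise draw.
    epsilon : float
        Drift rate of the slow variable, per second.  The admissible
        band at the default readout step is set by two constraints: the
        per-readout Euler map must stay stable at the deepest
        pre-transition branch (epsilon below ~750/s for transition
        times up to 0.7 s), and the pre-transition lag-1 autocorrelation
        baseline should start at or below zero so that the detector
        threshold crossing is a genuine rise (epsilon above ~530/s).
        The default sits inside that band.
    dt : float
        Readout step in seconds.
    duration : float
        Total simulated time in seconds; the trajectory has
        ``round(duration / dt)`` readouts.
    tstar_range : tuple of float
        (min, max) of the uniform draw for the transition time, seconds.
    noise_kind : {"gaussian", "uniform"}
        Per-readout noise distribution: standard normal, or uniform on
        [-1, 1].
    cubic : bool
        Include the saturating ``-x**3`` term.
    seed : int or None
        Seed for the ensemble-level random generator.
    x_bound_factor : float
        Overflow guard: integration clamps at ``|x| = x_bound_factor *
        max(|a|, 1)`` and records the clamp time as the escape time.
    """

    a: float = 4.0
    gamma: float = 0.063
    epsilon: float = 600.0
    dt: float = 0.010
    duration: float = 1.5
    tstar_range: tuple[float, float] = (0.350, 0.700)
    noise_kind: str = "gaussian"
    cubic: bool = True
    seed: Optional[int] = None
    x_bound_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        lo, hi = self.tstar_range
        if lo > hi:
            raise ValueError(f"tstar_range min {lo} exceeds max {hi}")
        if self.duration < hi:
            raise ValueError(
                f"duration {self.duration} shorter than tstar_range max {hi}"
            )
        if self.noise_kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")

    @property
    def n_readouts(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def x_bound(self) -> float:
        return self.x_bound_factor * max(abs(self.a), 1.0)


@dataclass
class Trajectory:
    """A simulated 1-D trajectory with its latent slow variable and truth.

    ``kind`` is ``"fold"`` for fold-transition simulations and
    ``"heaviside"`` for the step-plus-noise controls.  ``tstar_true`` is
    the time at which the latent slow variable crosses zero (fold) or the
    step time (control); NaN when the slow variable never crosses within
    the simulated span.
    """

    t: np.ndarray
    x: np.ndarray
    tstar_true: float
    direction: int = 1
    kind: str = "fold"
    y: Optional[np.ndarray] = None
    escape_time: Optional[float] = None
    cfg: Optional[SimConfig] = None
    detrended: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +/-1, got {self.direction}")
        if self.kind not in ("fold", "heaviside"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def pre_transition_mask(self) -> np.ndarray:
        """Boolean mask of samples strictly before the transition time."""
        if not np.isfinite(self.tstar_true):
            return np.ones_like(self.t, dtype=bool)
        return self.t < self.tstar_true


def _draw_noise(rng: np.random.Generator, n: int, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return rng.standard_normal(n)
    return rng.uniform(-1.0, 1.0, n)


def stable_branch(y: np.ndarray, a: float, cubic: bool) -> np.ndarray:
    """Quasi-static stable fixed point ``x_s(y)`` of the fast dynamics.

    For the minimal model this is ``-sqrt(-y)``; for the saturating model
    it is the negative-side root of ``y + a x^2 - x^3 = 0`` (found by
    vectorized Newton iteration from the small-|y| asymptote).  For
    ``y >= 0`` no static branch exists and 0 is returned, the limit of
    the branch as ``y -> 0-``.
    """
    y = np.asarray(y, dtype=float)
    xs = np.zeros_like(y)
    neg = y < 0
    if not np.any(neg):
        return xs
    yn = y[neg]
    if not cubic:
        xs[neg] = -np.sqrt(-yn)
        return xs
    x = -np.sqrt(-yn / a)  # small-|y| asymptote of the stable root
    for _ in range(60):
        f = yn + a * x**2 - x**3
        fp = 2.0 * a * x - 3.0 * x**2
        step = f / np.where(np.abs(fp) > 1e-300, fp, 1e-300)
        x = x - step
        if np.max(np.abs(step)) < 1e-13:
            break
    xs[neg] = x
    return xs


def _integrate(
    x0: float,
    y_series: np.ndarray,
    cfg: SimConfig,
    rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, Optional[float]]:
    """Euler-integrate the fast variable along a given slow-variable path.

    Returns the trajectory and the escape (clamp) time, or None if the
    overflow bound was never reached.
    """
    n = y_series.size
    t = np.arange(n) * cfg.dt
    x = np.empty(n)
    x[0] = x0
    bound = cfg.x_bound
    if rng is not None and cfg.gamma > 0:
        noise = cfg.gamma * _draw_noise(rng, n, cfg.noise_kind)
    else:
        noise = np.zeros(n)
    escape_time: Optional[float] = None
    for k in range(n - 1):
        xk = x[k]
        drift = y_series[k] + cfg.a * xk * xk - xk**3 if cfg.cubic else y_series[k] + xk * xk
        xn = xk + cfg.dt * drift + noise[k + 1]
        if abs(xn) >= bound:
            x[k + 1 :] = np.sign(xn) * bound
            escape_time = t[k + 1]
            break
        x[k + 1] = xn
    return x, escape_time


def integrate_fast(
    x0: float,
    y_series: np.ndarray,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate the fast variable along an arbitrary slow-variable path.

    Useful for held or custom schedules of ``y`` (for example, probing
    the post-transition plateau by holding ``y`` at a small positive
    constant).  The transition time is flagged at the first zero
    crossing of ``y``, NaN if there is none.
    """
    y_series = np.asarray(y_series, dtype=float)
    if rng is None and cfg.gamma > 0:
        rng = np.random.default_rng(cfg.seed)
    x, escape = _integrate(float(x0), y_series, cfg, rng)
    t = np.arange(y_series.size) * cfg.dt
    crossings = np.flatnonzero((y_series[:-1] < 0) & (y_series[1:] >= 0))
    tstar = float(t[crossings[0] + 1]) if crossings.size else float("nan")
    return Trajectory(
        t=t, x=x, y=y_series, tstar_true=tstar, kind="fold",
        escape_time=escape, cfg=cfg,
    )


def simulate_fold_minimal(
    cfg: SimConfig,
    y0: float,
    x0: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate the minimal fold model ``dx/dt = y + x^2 + xi(t)``.

    Parameters
    ----------
    cfg : SimConfig
        Must have ``cubic=False``.  ``gamma`` scales the noise; the slow
        drift uses ``cfg.epsilon`` unless ``y0 >= 0`` makes it moot.
    y0 : float
        Initial value of the slow variable; must be negative for a
        pre-transition static state to exist.
    x0 : float, optional
        Initial fast value; defaults to the stable root ``-sqrt(-y0)``.
    rng : numpy Generator, optional
        Noise source; defaults to a generator seeded from ``cfg.seed``.

    Notes
    -----
    The transition time is flagged where ``y`` first crosses zero
    (``-y0 / epsilon``); NaN if that lies outside the simulated span.
    """
    if cfg.cubic:
        raise ValueError("simulate_fold_minimal requires cfg.cubic=False")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_readouts
    t = np.arange(n) * cfg.dt
    y_series = y0 + cfg.epsilon * t
    if x0 is None:
        if y0 >= 0:
            raise ValueError("y0 must be negative when x0 is not given")
        x0 = -np.sqrt(-y0)
    x, escape = _integrate(x0, y_series, cfg, rng)
    tstar = -y0 / cfg.epsilon if cfg.epsilon > 0 else float("inf")
    if not (t[0] <= tstar <= t[-1]):
        tstar = float("nan")
    return Trajectory(
        t=t, x=x, y=y_series, tstar_true=tstar, direction=1, kind="fold",
        escape_time=escape, cfg=cfg,
    )


def _simulate_fold_raw(
    cfg: SimConfig, tstar: float, rng: Optional[np.random.Generator]
) -> Trajectory:
    n = cfg.n_readouts
    t = np.arange(n) * cfg.dt
    y_series = cfg.epsilon * (t - tstar)
    x0 = float(stable_branch(np.array([y_series[0]]), cfg.a, cfg.cubic)[0])
    x, escape = _integrate(x0, y_series, cfg, rng)
    return Trajectory(
        t=t, x=x, y=y_series, tstar_true=float(tstar), direction=1,
        kind="fold", escape_time=escape, cfg=cfg,
    )


def detrend(traj: Trajectory) -> Trajectory:
    """Remove the quasi-static trend so pre-transition motion hovers at 0.

    Subtracts the stable-branch solution ``x_s(y(t))`` (zero once ``y``
    has crossed), then a constant offset equal to the mean pre-transition
    residual, so that before the transition the signal fluctuates around
    the origin while the post-transition ramp is preserved up to that
    constant.  Requires the latent slow variable.
    """
    if traj.kind != "fold":
        raise ValueError("detrend applies to fold trajectories only")
    if traj.y is None or traj.cfg is None:
        raise ValueError("detrend requires the latent slow variable and cfg")
    pre = traj.pre_transition_mask()
    if pre.sum() < 2:
        raise ValueError("trajectory too short before the transition to detrend")
    trend = stable_branch(traj.y, traj.cfg.a, traj.cfg.cubic)
    resid = traj.x - trend
    offset = float(resid[pre].mean())
    out = replace(traj)
    out.x = resid - offset
    out.detrended = True
    out.meta = dict(traj.meta, detrend_offset=offset)
    return out


def simulate_fold_exp3(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    tstar: Optional[float] = None,
    direction: Optional[int] = None,
) -> Trajectory:
    """Simulate one saturating fold-transition dot trajectory.

    Draws the transition time uniformly from ``cfg.tstar_range``, starts
    the slow variable at ``-epsilon * tstar`` so it crosses zero at the
    transition, integrates with per-readout noise, detrends, and mirrors
    the trajectory with a random sign to randomize motion direction.
    """
    if not cfg.cubic:
        raise ValueError("simulate_fold_exp3 requires cfg.cubic=True")
    if cfg.a <= 0:
        raise ValueError("simulate_fold_exp3 requires cfg.a > 0")
    if cfg.epsilon <= 0:
        raise ValueError("simulate_fold_exp3 requires cfg.epsilon > 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if tstar is None:
        tstar = float(rng.uniform(*cfg.tstar_range))
    traj = _simulate_fold_raw(cfg, tstar, rng)
    traj = detrend(traj)
    if direction is None:
        direction = int(rng.choice([-1, 1]))
    traj.x = traj.x * direction
    traj.direction = int(direction)
    return traj


def simulate_heaviside_control(
    tstar: float,
    amplitude: float,
    noise_amp: float,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    direction: Optional[int] = None,
) -> Trajectory:
    """Step-plus-noise control: ``x(t) = amplitude * H(t - tstar) + xi(t)``.

    ``xi`` is zero-mean uniform noise of half-width ``noise_amp`` added
    independently at every readout, so the control carries no serial
    correlation before (or after) the step.  The whole trajectory is
    mirrored by a random sign, as for the fold simulations.
    """
    if noise_amp < 0:
        raise ValueError("noise_amp must be non-negative")
    if not (0 <= tstar <= cfg.duration):
        raise ValueError("tstar must lie within the configured duration")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_readouts
    t = np.arange(n) * cfg.dt
    x = amplitude * (t >= tstar).astype(float)
    if noise_amp > 0:
        x = x + rng.uniform(-noise_amp, noise_amp, n)
    if direction is None:
        direction = int(rng.choice([-1, 1]))
    direction = int(direction)
    return Trajectory(
        t=t, x=x * direction, tstar_true=float(tstar), direction=direction,
        kind="heaviside", cfg=cfg, meta={"noise_amp": float(noise_amp)},
    )


def generate_exp3_ensemble(
    cfg: SimConfig, n_per_arm: int
) -> list[tuple[Trajectory, Trajectory]]:
    """Generate matched fold / Heaviside-control trajectory pairs.

    The fold arm is simulated first; each control reuses its partner's
    transition time, and the control noise half-width is set from the
    fold arm's mean pre-transition fluctuation amplitude (standard
    deviation times sqrt(3), matching the variance of a uniform draw).
    Seeds are spawned deterministically from ``cfg.seed``.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be at least 1")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * n_per_arm)
    folds = [
        simulate_fold_exp3(cfg, rng=np.random.default_rng(children[i]))
        for i in range(n_per_arm)
    ]
    pre_sd = [float(np.std(f.x[f.pre_transition_mask()], ddof=1)) for f in folds]
    noise_amp = float(np.mean(pre_sd)) * np.sqrt(3.0)
    pairs = []
    for i, f in enumerate(folds):
        ctrl = simulate_heaviside_control(
            f.tstar_true, cfg.a, noise_amp, cfg,
            rng=np.random.default_rng(children[n_per_arm + i]),
        )
        pairs.append((f, ctrl))
    return pairs


# ---------------------------------------------------------------------------
# Trajectory file format: delimited text with a JSON metadata header line.

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with a ``#``-prefixed JSON metadata line."""
    meta = {
        "tstar_true": None if not np.isfinite(traj.tstar_true) else traj.tstar_true,
        "direction": traj.direction,
        "kind": traj.kind,
        "escape_time": traj.escape_time,
        "detrended": traj.detrended,
        "cfg": asdict(traj.cfg) if traj.cfg is not None else None,
        "meta": {k: v for k, v in traj.meta.items()},
    }
    cols = {"time_s": traj.t, "x": traj.x}
    if traj.y is not None:
        cols["y"] = traj.y
    buf = io.StringIO()
    pd.DataFrame(cols).to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write(buf.getvalue())


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing JSON metadata header line")
        meta = json.loads(header.lstrip("#").strip())
        df = pd.read_csv(fh)
    cfg = None
    if meta.get("cfg") is not None:
        d = dict(meta["cfg"])
        d["tstar_range"] = tuple(d["tstar_range"])
        cfg = SimConfig(**d)
    tstar = meta.get("tstar_true")
    traj = Trajectory(
        t=df["time_s"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy() if "y" in df.columns else None,
        tstar_true=float("nan") if tstar is None else float(tstar),
        direction=int(meta.get("direction", 1)),
        kind=meta.get("kind", "fold"),
        escape_time=meta.get("escape_time"),
        cfg=cfg,
        detrended=bool(meta.get("detrended", False)),
        meta=meta.get("meta", {}),
    )
    return traj
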
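"""Simulation of dynamic GRN models and training-data generation.

Training data are noise-free model outputs: each trajectory samples the
solution of a model's ODE system on an evenly spaced grid of
``n_points`` (200 by default) over ``[0, t_end]``.  The *sparse* dataset
uses starting set 1 only; the *detailed* dataset uses all five starting
sets.  Integration failures (solver breakdown, non-finite state, or a
blow-up beyond a threshold — routine events for S-system candidates
with negative kinetic orders) are returned as flagged trajectories, not
exceptions, so a reverse-engineering run can convert them to
worst-fitness candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cases import starting_sets
from .models import GRNModel

#: Default number of sample points per trajectory.
N_POINTS = 200

#: Default time horizon: about six degradation time constants at k = 0.3,
#: long enough to capture the transient and the approach to steady state.
T_END = 20.0


@dataclass(frozen=True)
class IntegrationSettings:
    """Adaptive-integration controls for trajectory generation."""

    t_end: float = T_END
    n_points: int = N_POINTS
    rtol: float = 1e-7
    atol: float = 1e-9
    blowup: float = 1e6

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")

    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)


@dataclass
class Trajectory:
    """One time series: a time grid and a (p, N) concentration matrix."""

    label: object
    t: np.ndarray
    x: np.ndarray
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape[0] != self.t.shape[0]:
            raise ValueError("time grid and data matrix row count differ")

    @property
    def n_genes(self) -> int:
        return self.x.shape[1]

    @property
    def n_points(self) -> int:
        return self.x.shape[0]


@dataclass
class TimeSeriesSet:
    """A collection of trajectories sharing one sampling layout."""

    trajectories: list[Trajectory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trajectories:
            t0 = self.trajectories[0].t
            for tr in self.trajectories[1:]:
                if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
                    raise ValueError(
                        "all trajectories in a set must share the time grid"
                    )

    @property
    def n_genes(self) -> int:
        return self.trajectories[0].n_genes

    @property
    def all_success(self) -> bool:
        return all(tr.success for tr in self.trajectories)

    def subset(self, labels) -> "TimeSeriesSet":
        keep = [tr for tr in self.trajectories if tr.label in set(labels)]
        return TimeSeriesSet(keep, dict(self.meta))

    # -- CSV dialect: series_id,time,X1..XN -------------------------------

    def to_frame(self, gene_names=None) -> pd.DataFrame:
        names = (list(gene_names) if gene_names is not None
                 else [f"X{i}" for i in range(1, self.n_genes + 1)])
        frames = []
        for tr in self.trajectories:
            df = pd.DataFrame(tr.x, columns=names)
            df.insert(0, "time", tr.t)
            df.insert(0, "series_id", tr.label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path, gene_names=None) -> None:
        self.to_frame(gene_names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesSet":
        df = pd.read_csv(path)
        required = {"series_id", "time"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns series_id,time,...")
        genes = [c for c in df.columns if c not in required]
        trajectories = []
        for label, grp in df.groupby("series_id", sort=False):
            trajectories.append(Trajectory(
                label=label,
                t=grp["time"].to_numpy(),
                x=grp[genes].to_numpy(),
            ))
        return cls(trajectories, meta={"genes": genes})

    def write_meta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.meta, fh, indent=2)


def integrate(model: GRNModel, x0, settings: IntegrationSettings | None = None,
              label=None) -> Trajectory:
    """Integrate a model's ODE system on the settings' sample grid.

    Never raises for dynamical failures: a trajectory whose integration
    breaks down, leaves the finite range, or crosses the blow-up
    threshold comes back with ``success=False`` and the partial data
    padded with the last finite state.
    """
    settings = settings or IntegrationSettings()
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_genes,):
        raise ValueError(
            f"x0 has shape {x0.shape}, expected ({model.n_genes},)"
        )
    grid = settings.grid()

    def rhs(t, x):
        return model.rate(x, guarded=True)

    def blown(t, x):
        return settings.blowup - np.max(np.abs(x))

    blown.terminal = True
    blown.direction = -1

    try:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            sol = solve_ivp(rhs, (0.0, settings.t_end), x0, method="RK45",
                            t_eval=grid, rtol=settings.rtol,
                            atol=settings.atol, events=blown)
    except (FloatingPointError, ValueError, OverflowError) as exc:
        return Trajectory(label, grid,
                          np.full((len(grid), model.n_genes), np.nan),
                          success=False, message=f"integrator error: {exc}")

    x = np.full((len(grid), model.n_genes), np.nan)
    got = sol.y.T.shape[0]
    x[:got] = sol.y.T
    ok = sol.success and got == len(grid) and np.all(np.isfinite(x)) \
        and np.max(np.abs(x)) <= settings.blowup
    if not ok:
        # pad with last finite row so downstream shapes stay intact
        finite_rows = np.where(np.all(np.isfinite(x), axis=1))[0]
        if len(finite_rows):
            x[finite_rows[-1] + 1:] = x[finite_rows[-1]]
        x = np.nan_to_num(x, nan=0.0, posinf=settings.blowup,
                          neginf=-settings.blowup)
        msg = sol.message if not sol.success else "blow-up guard triggered"
        return Trajectory(label, grid, x, success=False, message=msg)
    return Trajectory(label, grid, x)


def _dataset(model: GRNModel, sets, settings: IntegrationSettings,
             density: str) -> TimeSeriesSet:
    trajectories = [
        integrate(model, np.asarray(s.x0), settings, label=s.label)
        for s in sets
    ]
    meta = {"method": model.method, "density": density,
            "t_end": settings.t_end, "n_points": settings.n_points,
            "starting_sets": [s.label for s in sets]}
    return TimeSeriesSet(trajectories, meta)


def generate_sparse(model: GRNModel,
                    settings: IntegrationSettings | None = None,
                    x0=None) -> TimeSeriesSet:
    """One trajectory from starting set 1 (or a caller-supplied x0)."""
    settings = settings or IntegrationSettings()
    if x0 is not None:
        sets = [type(starting_sets()[0])(1, tuple(np.asarray(x0)))]
    else:
        if model.n_genes != 5:
            raise ValueError("built-in starting sets are for 5-gene models; "
                             "pass x0 explicitly")
        sets = [starting_sets()[0]]
    return _dataset(model, sets, settings, "sparse")


def generate_detailed(model: GRNModel,
                      settings: IntegrationSettings | None = None
                      ) -> TimeSeriesSet:
    """Five trajectories from starting sets 1-5, in order."""
    settings = settings or IntegrationSettings()
    if model.n_genes != 5:
        raise ValueError("detailed datasets use the five built-in "
                         "5-gene starting sets")
    return _dataset(model, starting_sets(), settings, "detailed")


def add_noise(data: TimeSeriesSet, sigma: float,
              rng: np.random.Generator | int | None = None
              ) -> TimeSeriesSet:
    """Multiplicative Gaussian observation noise (extension hook).

    The study datasets are noise-free model outputs; this helper is
    provided for robustness experiments and is never applied by
    default.  Each value is multiplied by ``1 + sigma * eps`` with
    standard-normal ``eps``; results are clipped at zero.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    noisy = [
        Trajectory(tr.label, tr.t.copy(),
                   np.maximum(tr.x * (1.0 + sigma * rng.standard_normal(
                       tr.x.shape)), 0.0),
                   success=tr.success, message=tr.message)
        for tr in data.trajectories
    ]
    meta = dict(data.meta)
    meta["noise_sigma"] = sigma
    return TimeSeriesSet(noisy, meta)


def perturb_input(model: GRNModel) -> tuple[GRNModel, GRNModel]:
    """The two input-perturbed variants of a reference model.

    The network input gene X1 has no regulators, so changing its
    degradation constant k_1 (beta_1 for the S-system) changes the
    stimulus the rest of the network sees: 0.1 raises the X1 level
    (increased input), 0.5 lowers it (decreased input).
    """
    return (model.with_degradation(1, 0.1),
            model.with_degradation(1, 0.5))


def perturb_initial(x0, gene: int, factor: float) -> np.ndarray:
    """Multiply one gene's initial concentration by ``factor``."""
    x0 = np.asarray(x0, dtype=float).copy()
    if not (1 <= gene <= len(x0)):
        raise IndexError(f"gene index {gene} out of range 1..{len(x0)}")
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    x0[gene - 1] *= factor
    return x0
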
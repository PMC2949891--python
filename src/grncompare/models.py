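"""The three continuous rate-law formalisms for dynamic GRN models.

Each formalism describes an N-gene network with N coupled ODEs for the
gene-product concentrations X_i:

ANN (recurrent-network rate law)
    dX_i/dt = v_i * f(sum_j w_ij X_j - theta_i) - k_i X_i
    with f a sigmoid transfer function (logistic by default).  Additive
    input processing (logical OR); production bounded in (0, v_i).

S-system (SS, power-law kinetics)
    dX_i/dt = alpha_i * prod_j X_j^g_ij - beta_i * prod_j X_j^h_ij
    Multiplicative input processing; unbounded rates; negative kinetic
    orders introduce singularities as a concentration approaches zero.

GRLOT (general rate law of transcription, Hill-type)
    dX_i/dt = v_i * prod_j Ki_j^n_j / (I_j^n_j + Ki_j^n_j)
                  * prod_k A_k^n_k / (A_k^n_k + Ka_k^n_k)  -  k_i X_i
    One saturating factor in (0, 1) per regulator; activator and
    inhibitor factors are complementary forms.

All rate functions are vectorized over leading axes: ``state`` may be
shaped ``(N,)`` or ``(..., N)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .topology import ACTIVATING, INHIBITING, GRNTopology

MethodTag = Literal["ANN", "SS", "GRLOT"]
METHODS: tuple[MethodTag, ...] = ("ANN", "SS", "GRLOT")

#: Floor applied to power-law bases so fractional exponents of (numerically)
#: non-positive concentrations stay real while preserving blow-up behavior.
POWER_FLOOR = 1e-12


def logistic(x: np.ndarray) -> np.ndarray:
    """Standard logistic sigmoid 1 / (1 + exp(-x)), overflow-safe."""
    # clipping at +-500 keeps exp finite without changing the double-
    # precision result (the sigmoid saturates far earlier)
    return 1.0 / (1.0 + np.exp(-np.clip(np.asarray(x, dtype=float),
                                        -500.0, 500.0)))


#: Swappable sigmoid used by the ANN rate law.
SIGMOID: Callable[[np.ndarray], np.ndarray] = logistic


class SingularityError(ArithmeticError):
    """A non-positive concentration met a negative kinetic order."""


def _check_state(state: np.ndarray, n: int) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != n:
        raise ValueError(
            f"state has {state.shape[-1]} genes, parameters expect {n}"
        )
    return state


@dataclass
class ANNParams:
    """Parameters of the recurrent-network rate law.

    v: maximal expression rates (conc/time), theta: external inputs,
    k: first-order degradation rates (1/time), w: N x N connection
    weights (row i = influences on gene i).
    """

    v: np.ndarray
    w: np.ndarray
    theta: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = self.v.shape[0]
        if self.w.shape != (n, n) or self.theta.shape != (n,) or \
                self.k.shape != (n,):
            raise ValueError("ANN parameter dimensions are inconsistent")
        if np.any(self.v < 0) or np.any(self.theta < 0):
            raise ValueError("v and theta must be non-negative")
        if np.any(self.k <= 0):
            raise ValueError("degradation rates k must be positive")

    @property
    def n_genes(self) -> int:
        return self.v.shape[0]

    def to_dict(self) -> dict:
        return {"v": self.v.tolist(), "w": self.w.tolist(),
                "theta": self.theta.tolist(), "k": self.k.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ANNParams":
        return cls(np.array(d["v"]), np.array(d["w"]),
                   np.array(d["theta"]), np.array(d["k"]))


@dataclass
class SSParams:
    """Parameters of the S-system power law.

    alpha/beta: activation/degradation rate constants; g/h: N x N
    production/degradation kinetic orders (sign encodes effect).
    """

    alpha: np.ndarray
    beta: np.ndarray
    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.alpha.shape[0]
        if self.beta.shape != (n,) or self.g.shape != (n, n) or \
                self.h.shape != (n, n):
            raise ValueError("SS parameter dimensions are inconsistent")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive")

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    def to_dict(self) -> dict:
        return {"alpha": self.alpha.tolist(), "beta": self.beta.tolist(),
                "g": self.g.tolist(), "h": self.h.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SSParams":
        return cls(np.array(d["alpha"]), np.array(d["beta"]),
                   np.array(d["g"]), np.array(d["h"]))


@dataclass(frozen=True)
class Regulator:
    """One Hill-type regulatory input of a GRLOT gene.

    ``n`` is the (non-negative) Hill exponent; ``K`` the half-saturation
    concentration; ``role`` selects the activator or inhibitor form.
    """

    source: int
    role: Literal["activator", "inhibitor"]
    n: float
    K: float

    def __post_init__(self) -> None:
        if self.role not in ("activator", "inhibitor"):
            raise ValueError(f"unknown regulator role {self.role!r}")
        if self.K <= 0:
            raise ValueError("half-saturation constant K must be positive")


@dataclass
class GRLOTParams:
    """Parameters of the general rate law of transcription."""

    v: np.ndarray
    k: np.ndarray
    regulators: dict[int, list[Regulator]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = self.v.shape[0]
        if self.k.shape != (n,):
            raise ValueError("GRLOT parameter dimensions are inconsistent")
        if np.any(self.v < 0):
            raise ValueError("v must be non-negative")
        if np.any(self.k <= 0):
            raise ValueError("degradation rates k must be positive")
        for target, regs in self.regulators.items():
            if not (1 <= target <= n):
                raise ValueError(f"regulator target {target} out of range")
            sources = [r.source for r in regs]
            if len(set(sources)) != len(sources):
                raise ValueError(
                    f"duplicate regulator source for gene {target}"
                )

    @property
    def n_genes(self) -> int:
        return self.v.shape[0]

    def to_dict(self) -> dict:
        return {
            "v": self.v.tolist(),
            "k": self.k.tolist(),
            "regulators": {
                str(t): [[r.source, r.role, r.n, r.K] for r in regs]
                for t, regs in sorted(self.regulators.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRLOTParams":
        regs = {
            int(t): [Regulator(int(s), role, float(n), float(K))
                     for s, role, n, K in lst]
            for t, lst in d["regulators"].items()
        }
        return cls(np.array(d["v"]), np.array(d["k"]), regs)


MethodParams = ANNParams | SSParams | GRLOTParams


# ---------------------------------------------------------------------------
# Rate laws


def ann_rate(state: np.ndarray, params: ANNParams,
             sigmoid: Callable[[np.ndarray], np.ndarray] | None = None
             ) -> np.ndarray:
    """Right-hand side of the ANN ODE system at ``state``."""
    x = _check_state(state, params.n_genes)
    f = sigmoid if sigmoid is not None else SIGMOID
    drive = x @ params.w.T - params.theta
    return params.v * f(drive) - params.k * x


def _powprod(x: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """prod_j base_j^orders_ij with the base floored at POWER_FLOOR."""
    base = np.maximum(x, POWER_FLOOR)
    # log-domain product: orders rows may be dense or mostly zero
    return np.exp(np.log(base) @ orders.T)


def ss_rate(state: np.ndarray, params: SSParams) -> np.ndarray:
    """Right-hand side of the S-system at ``state``.

    Raises :class:`SingularityError` when any X_j <= 0 is paired with a
    negative kinetic order (the power-law singularity), even though the
    numerical evaluation floors the base at ``POWER_FLOOR``.
    """
    x = _check_state(state, params.n_genes)
    nonpos = x <= 0
    if np.any(nonpos):
        neg_order = (params.g < 0) | (params.h < 0)
        if np.any(nonpos[..., None, :] & neg_order):
            raise SingularityError(
                "non-positive concentration raised to a negative "
                "kinetic order"
            )
    return (params.alpha * _powprod(x, params.g)
            - params.beta * _powprod(x, params.h))


def ss_rate_guarded(state: np.ndarray, params: SSParams) -> np.ndarray:
    """S-system right-hand side without the singularity exception.

    Bases are floored at ``POWER_FLOOR``; the resulting (possibly huge)
    rates are returned as-is so blow-up guards downstream can flag the
    trajectory.  Used inside integrators and EA fitness evaluation.
    """
    x = _check_state(state, params.n_genes)
    return (params.alpha * _powprod(x, params.g)
            - params.beta * _powprod(x, params.h))


def hill_activation(x: np.ndarray, n: float, K: float) -> np.ndarray:
    """Activator factor X^n / (X^n + K^n), in (0, 1); 0.5 at X = K."""
    xn = np.power(np.maximum(x, POWER_FLOOR), n)
    return xn / (xn + K ** n)


def hill_inhibition(x: np.ndarray, n: float, K: float) -> np.ndarray:
    """Inhibitor factor K^n / (X^n + K^n), complement of activation."""
    xn = np.power(np.maximum(x, POWER_FLOOR), n)
    return K ** n / (xn + K ** n)


def grlot_rate(state: np.ndarray, params: GRLOTParams) -> np.ndarray:
    """Right-hand side of the GRLOT ODE system at ``state``."""
    x = _check_state(state, params.n_genes)
    if np.any(x < 0):
        raise ValueError(
            "GRLOT rate law is defined for non-negative concentrations"
        )
    production = np.broadcast_to(params.v, x.shape).copy()
    for target, regs in params.regulators.items():
        factor = np.ones(x.shape[:-1])
        for r in regs:
            xs = x[..., r.source - 1]
            if r.role == "activator":
                factor = factor * hill_activation(xs, r.n, r.K)
            else:
                factor = factor * hill_inhibition(xs, r.n, r.K)
        production[..., target - 1] = params.v[target - 1] * factor
    return production - params.k * x


def count_parameters(method: MethodTag, n_genes: int) -> int:
    """Fully dense parameter count of a method for an N-gene network.

    ANN: N(N+3) (w matrix + v, theta, k); SS: N(2N+2) (g, h matrices +
    alpha, beta); GRLOT: N(2N+1) (n, K per possible regulator + v, k ...
    one shared rate and one degradation constant per gene).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if method == "ANN":
        return n_genes * (n_genes + 3)
    if method == "SS":
        return n_genes * (2 * n_genes + 2)
    if method == "GRLOT":
        return n_genes * (2 * n_genes + 1)
    raise ValueError(f"unknown method tag {method!r}")


# ---------------------------------------------------------------------------
# Dynamic GRN model = structure + parameters


_PARAM_CLASSES = {"ANN": ANNParams, "SS": SSParams, "GRLOT": GRLOTParams}


@dataclass
class GRNModel:
    """A dynamic GRN model: method tag, topology and matching parameters."""

    method: MethodTag
    topology: GRNTopology
    params: MethodParams

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not isinstance(self.params, _PARAM_CLASSES[self.method]):
            raise TypeError(
                f"{self.method} model requires "
                f"{_PARAM_CLASSES[self.method].__name__}"
            )
        if self.params.n_genes != self.topology.n_genes:
            raise ValueError("parameter dimensions do not match topology")
        self._validate_mask()

    def _validate_mask(self) -> None:
        mask = self.topology.mask()
        if self.method == "ANN":
            if np.any(self.params.w[~mask] != 0):
                raise ValueError("ANN w entries outside topology must be 0")
        elif self.method == "SS":
            if np.any(self.params.g[~mask] != 0):
                raise ValueError("SS g entries outside topology must be 0")
        else:
            for target, regs in self.params.regulators.items():
                for r in regs:
                    edge = self.topology.edge(r.source, target)
                    if edge is None:
                        raise ValueError(
                            f"GRLOT regulator {r.source}->{target} has no "
                            "topology edge"
                        )
                    expected = (ACTIVATING if r.role == "activator"
                                else INHIBITING)
                    if edge.sign != expected:
                        raise ValueError(
                            f"regulator role of {r.source}->{target} "
                            "contradicts the edge sign"
                        )

    @property
    def n_genes(self) -> int:
        return self.topology.n_genes

    def rate(self, state: np.ndarray, *, guarded: bool = False
             ) -> np.ndarray:
        """Evaluate dX/dt at ``state`` with this model's rate law."""
        if self.method == "ANN":
            return ann_rate(state, self.params)
        if self.method == "SS":
            fn = ss_rate_guarded if guarded else ss_rate
            return fn(state, self.params)
        return grlot_rate(state, self.params)

    def degradation_rates(self) -> np.ndarray:
        """Per-gene first-order degradation constants (beta_i for SS)."""
        return self.params.beta if self.method == "SS" else self.params.k

    def with_degradation(self, gene: int, value: float) -> "GRNModel":
        """Copy of the model with gene's k_i (beta_i for SS) replaced."""
        d = self.to_dict()
        key = "beta" if self.method == "SS" else "k"
        d["params"][key][gene - 1] = value
        return GRNModel.from_dict(d)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_genes": self.n_genes,
            "edges": self.topology.to_dict()["edges"],
            "params": self.params.to_dict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GRNModel":
        topo = GRNTopology.from_dict(
            {"n_genes": d["n_genes"], "edges": d["edges"]}
        )
        params = _PARAM_CLASSES[d["method"]].from_dict(d["params"])
        return cls(d["method"], topo, params)

    @classmethod
    def from_json(cls, source) -> "GRNModel":
        """Parse a model from a JSON string or a path to a JSON file."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
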
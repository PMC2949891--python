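"""Parameter-vector encodings for reverse engineering.

A codec maps between a method's structured parameters and the flat
real-valued vectors the evolutionary algorithm works on.  The network
structure is fixed during inference: only parameters belonging to
edges of the static topology (plus the per-gene scalars) are free, so
masked entries never appear in a vector.  The same canonical ordering
defines the vectors compared by the inferential-power measure.

Canonical order, per gene k (ascending), then concatenated:

* ANN:   v_k, theta_k, k_k, then w_kj for regulator sources j ascending
* SS:    alpha_k, beta_k, then g_kj (j ascending), then h_kk
* GRLOT: v_k, k_k, then (n_kj, K_kj) per regulator source j ascending

The S-system degradation kinetic orders are searched on the diagonal
only (each gene's own degradation exponent); off-diagonal h entries
stay zero, matching the constructed reference models.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .models import (ANNParams, GRLOTParams, GRNModel, MethodTag,
                     POWER_FLOOR, Regulator, SIGMOID, SSParams)
from .topology import ACTIVATING, GRNTopology

#: Positive floor for degradation constants when materializing a model
#: from a vector whose search interval includes zero.
_RATE_FLOOR = 1e-9


@dataclass(frozen=True)
class ParameterBounds:
    """Per-method, per-symbol search intervals for the EA.

    Defaults: ANN w in [-15, 15], v in [0, 3], theta in [0, 7],
    k in [0, 2]; SS kinetic orders g, h in [-3, 3], rate constants
    alpha, beta in [0, 15]; GRLOT exponents in [0, 7] for
    activator-role and [-5, 5] for inhibitor-role regulators,
    half-saturation K in [1e-3, 40], k in [0, 2].
    """

    ann_w: tuple[float, float] = (-15.0, 15.0)
    ann_v: tuple[float, float] = (0.0, 3.0)
    ann_theta: tuple[float, float] = (0.0, 7.0)
    ann_k: tuple[float, float] = (0.0, 2.0)
    ss_alpha: tuple[float, float] = (0.0, 15.0)
    ss_beta: tuple[float, float] = (0.0, 15.0)
    ss_g: tuple[float, float] = (-3.0, 3.0)
    ss_h: tuple[float, float] = (-3.0, 3.0)
    grlot_n_activator: tuple[float, float] = (0.0, 7.0)
    grlot_n_inhibitor: tuple[float, float] = (-5.0, 5.0)
    grlot_K: tuple[float, float] = (1e-3, 40.0)
    grlot_k: tuple[float, float] = (0.0, 2.0)
    # maximal-rate interval shared with the ANN method's v
    grlot_v: tuple[float, float] = (0.0, 3.0)


# ---------------------------------------------------------------------------
# Batched per-gene rate evaluators (population along the leading axis)


class _AnnNode:
    def __init__(self, V, m, self_col):
        self.v, self.theta, self.kk = V[:, 0], V[:, 1], V[:, 2]
        self.w = V[:, 3:3 + m]
        self.self_col = self_col
        self.m = m

    def rate(self, x, xs_row):
        xs = _with_self(x, xs_row, self.self_col, self.m)
        drive = (self.w * xs).sum(-1) - self.theta
        return self.v * SIGMOID(drive) - self.kk * x


class _SsNode:
    def __init__(self, V, m, self_col):
        self.alpha, self.beta = V[:, 0], V[:, 1]
        self.g = V[:, 2:2 + m]
        self.hkk = V[:, 2 + m]
        self.self_col = self_col
        self.m = m

    def rate(self, x, xs_row):
        xs = _with_self(x, xs_row, self.self_col, self.m)
        base = np.maximum(xs, POWER_FLOOR)
        prod = np.exp((self.g * np.log(base)).sum(-1))
        own = np.maximum(x, POWER_FLOOR)
        return self.alpha * prod - self.beta * own ** self.hkk


class _GrlotNode:
    def __init__(self, V, m, self_col, roles):
        self.v, self.kk = V[:, 0], V[:, 1]
        self.n = V[:, 2:2 + 2 * m:2]
        self.K = V[:, 3:3 + 2 * m:2]
        self.roles = roles
        self.self_col = self_col
        self.m = m

    def rate(self, x, xs_row):
        xs = _with_self(x, xs_row, self.self_col, self.m)
        prod = self.v.copy() if self.m else self.v
        if self.m:
            base = np.maximum(xs, POWER_FLOOR)
            xn = base ** self.n
            Kn = np.maximum(self.K, POWER_FLOOR) ** self.n
            act = xn / (xn + Kn)
            factors = np.where(self.roles, act, 1.0 - act)
            prod = self.v * factors.prod(-1)
        return prod - self.kk * x


def _with_self(x, xs_row, self_col, m):
    """Inject the gene's own evolving level into its regulator row."""
    if self_col is None:
        return xs_row
    xs = np.broadcast_to(xs_row, np.shape(x) + (m,)).copy()
    xs[..., self_col] = x
    return xs


# ---------------------------------------------------------------------------
# Node codec


class NodeCodec:
    """Vector layout for the node model of one gene."""

    def __init__(self, method: MethodTag, topology: GRNTopology, gene: int,
                 bounds: ParameterBounds | None = None):
        if not (1 <= gene <= topology.n_genes):
            raise ValueError(f"gene index {gene} out of range")
        self.method = method
        self.topology = topology
        self.gene = gene
        self.bounds = bounds or ParameterBounds()
        regs = topology.regulators_of(gene)
        self.sources = [e.source for e in regs]
        self.signs = [e.sign for e in regs]
        self.self_col = (self.sources.index(gene)
                         if gene in self.sources else None)
        b = self.bounds
        m = len(self.sources)
        if method == "ANN":
            self.names = [f"v[{gene}]", f"theta[{gene}]", f"k[{gene}]"] + \
                [f"w[{gene},{s}]" for s in self.sources]
            intervals = [b.ann_v, b.ann_theta, b.ann_k] + [b.ann_w] * m
        elif method == "SS":
            self.names = [f"alpha[{gene}]", f"beta[{gene}]"] + \
                [f"g[{gene},{s}]" for s in self.sources] + \
                [f"h[{gene},{gene}]"]
            intervals = [b.ss_alpha, b.ss_beta] + [b.ss_g] * m + [b.ss_h]
        elif method == "GRLOT":
            self.names = [f"v[{gene}]", f"k[{gene}]"]
            intervals = [b.grlot_v, b.grlot_k]
            for s, sg in zip(self.sources, self.signs):
                self.names += [f"n[{gene},{s}]", f"K[{gene},{s}]"]
                n_int = (b.grlot_n_activator if sg == ACTIVATING
                         else b.grlot_n_inhibitor)
                intervals += [n_int, b.grlot_K]
        else:
            raise ValueError(f"unknown method tag {method!r}")
        self.lower = np.array([lo for lo, _ in intervals])
        self.upper = np.array([hi for _, hi in intervals])
        self.dim = len(self.names)

    def decode_batch(self, V: np.ndarray):
        V = np.atleast_2d(np.asarray(V, dtype=float))
        m = len(self.sources)
        if self.method == "ANN":
            return _AnnNode(V, m, self.self_col)
        if self.method == "SS":
            return _SsNode(V, m, self.self_col)
        roles = np.array([sg == ACTIVATING for sg in self.signs])
        return _GrlotNode(V, m, self.self_col, roles)

    def encode(self, model: GRNModel) -> np.ndarray:
        """Extract this gene's free parameters from a model."""
        if model.method != self.method:
            raise ValueError("model method does not match codec")
        p = model.params
        k0 = self.gene - 1
        if self.method == "ANN":
            return np.array([p.v[k0], p.theta[k0], p.k[k0]] +
                            [p.w[k0, s - 1] for s in self.sources])
        if self.method == "SS":
            return np.array([p.alpha[k0], p.beta[k0]] +
                            [p.g[k0, s - 1] for s in self.sources] +
                            [p.h[k0, k0]])
        regs = {r.source: r for r in p.regulators.get(self.gene, [])}
        vec = [p.v[k0], p.k[k0]]
        for s in self.sources:
            r = regs[s]
            vec += [r.n, r.K]
        return np.array(vec)


# ---------------------------------------------------------------------------
# Batched whole-network rate evaluators


class _AnnNet:
    """Whole-network rate; state X shaped (..., P, N)."""

    def __init__(self, W, v, theta, kk):
        self.W, self.v, self.theta, self.kk = W, v, theta, kk

    def rate(self, X):
        drive = np.einsum("pij,...pj->...pi", self.W, X) - self.theta
        return self.v * SIGMOID(drive) - self.kk * X


class _SsNet:
    def __init__(self, G, H, alpha, beta):
        self.G, self.H, self.alpha, self.beta = G, H, alpha, beta

    def rate(self, X):
        logx = np.log(np.maximum(X, POWER_FLOOR))
        prod_g = np.exp(np.einsum("pij,...pj->...pi", self.G, logx))
        prod_h = np.exp(np.einsum("pij,...pj->...pi", self.H, logx))
        return self.alpha * prod_g - self.beta * prod_h


class _GrlotNet:
    def __init__(self, v, kk, edges):
        # edges: list of (target0, source0, is_activator, n (P,), K (P,))
        self.v, self.kk, self.edges = v, kk, edges

    def rate(self, X):
        production = np.broadcast_to(self.v, X.shape).copy()
        base = np.maximum(X, POWER_FLOOR)
        for t0, s0, act, n, K in self.edges:
            xn = base[..., s0] ** n
            Kn = np.maximum(K, POWER_FLOOR) ** n
            f = xn / (xn + Kn)
            production[..., t0] *= f if act else (1.0 - f)
        return production - self.kk * X


class NetworkCodec:
    """Concatenation of the N node codecs of one method/topology."""

    def __init__(self, method: MethodTag, topology: GRNTopology,
                 bounds: ParameterBounds | None = None):
        self.method = method
        self.topology = topology
        self.bounds = bounds or ParameterBounds()
        self.nodes = [NodeCodec(method, topology, g, self.bounds)
                      for g in range(1, topology.n_genes + 1)]
        self.slices = []
        start = 0
        for nc in self.nodes:
            self.slices.append(slice(start, start + nc.dim))
            start += nc.dim
        self.dim = start
        self.names = [nm for nc in self.nodes for nm in nc.names]
        self.lower = np.concatenate([nc.lower for nc in self.nodes])
        self.upper = np.concatenate([nc.upper for nc in self.nodes])

    def encode(self, model: GRNModel) -> np.ndarray:
        """Canonical free-parameter vector of a model (masked zeros excluded)."""
        return np.concatenate([nc.encode(model) for nc in self.nodes])

    def decode_batch(self, V: np.ndarray):
        V = np.atleast_2d(np.asarray(V, dtype=float))
        n = self.topology.n_genes
        P = V.shape[0]
        if self.method == "ANN":
            W = np.zeros((P, n, n))
            v = np.empty((P, n))
            theta = np.empty((P, n))
            kk = np.empty((P, n))
            for nc, sl in zip(self.nodes, self.slices):
                blk = V[:, sl]
                g0 = nc.gene - 1
                v[:, g0], theta[:, g0], kk[:, g0] = \
                    blk[:, 0], blk[:, 1], blk[:, 2]
                for i, s in enumerate(nc.sources):
                    W[:, g0, s - 1] = blk[:, 3 + i]
            return _AnnNet(W, v, theta, kk)
        if self.method == "SS":
            G = np.zeros((P, n, n))
            H = np.zeros((P, n, n))
            alpha = np.empty((P, n))
            beta = np.empty((P, n))
            for nc, sl in zip(self.nodes, self.slices):
                blk = V[:, sl]
                g0 = nc.gene - 1
                alpha[:, g0], beta[:, g0] = blk[:, 0], blk[:, 1]
                for i, s in enumerate(nc.sources):
                    G[:, g0, s - 1] = blk[:, 2 + i]
                H[:, g0, g0] = blk[:, 2 + len(nc.sources)]
            return _SsNet(G, H, alpha, beta)
        v = np.empty((P, n))
        kk = np.empty((P, n))
        edges = []
        for nc, sl in zip(self.nodes, self.slices):
            blk = V[:, sl]
            g0 = nc.gene - 1
            v[:, g0], kk[:, g0] = blk[:, 0], blk[:, 1]
            for i, (s, sg) in enumerate(zip(nc.sources, nc.signs)):
                edges.append((g0, s - 1, sg == ACTIVATING,
                              blk[:, 2 + 2 * i], blk[:, 3 + 2 * i]))
        return _GrlotNet(v, kk, edges)

    def build_model(self, vector: np.ndarray) -> GRNModel:
        """Materialize a GRNModel from a flat parameter vector."""
        vector = np.asarray(vector, dtype=float)
        n = self.topology.n_genes
        if self.method == "ANN":
            v = np.empty(n)
            theta = np.empty(n)
            kk = np.empty(n)
            W = np.zeros((n, n))
            for nc, sl in zip(self.nodes, self.slices):
                blk = vector[sl]
                g0 = nc.gene - 1
                v[g0], theta[g0], kk[g0] = blk[0], blk[1], blk[2]
                for i, s in enumerate(nc.sources):
                    W[g0, s - 1] = blk[3 + i]
            params = ANNParams(v=v, w=W, theta=np.maximum(theta, 0.0),
                               k=np.maximum(kk, _RATE_FLOOR))
        elif self.method == "SS":
            alpha = np.empty(n)
            beta = np.empty(n)
            G = np.zeros((n, n))
            H = np.zeros((n, n))
            for nc, sl in zip(self.nodes, self.slices):
                blk = vector[sl]
                g0 = nc.gene - 1
                alpha[g0], beta[g0] = blk[0], blk[1]
                for i, s in enumerate(nc.sources):
                    G[g0, s - 1] = blk[2 + i]
                H[g0, g0] = blk[2 + len(nc.sources)]
            params = SSParams(alpha=np.maximum(alpha, 0.0),
                              beta=np.maximum(beta, _RATE_FLOOR),
                              g=G, h=H)
        else:
            v = np.empty(n)
            kk = np.empty(n)
            regulators: dict[int, list[Regulator]] = {}
            for nc, sl in zip(self.nodes, self.slices):
                blk = vector[sl]
                g0 = nc.gene - 1
                v[g0], kk[g0] = blk[0], blk[1]
                regs = []
                for i, (s, sg) in enumerate(zip(nc.sources, nc.signs)):
                    role = "activator" if sg == ACTIVATING else "inhibitor"
                    regs.append(Regulator(
                        s, role, float(blk[2 + 2 * i]),
                        float(max(blk[3 + 2 * i], POWER_FLOOR))))
                if regs:
                    regulators[nc.gene] = regs
            params = GRLOTParams(v=np.maximum(v, 0.0),
                                 k=np.maximum(kk, _RATE_FLOOR),
                                 regulators=regulators)
        return GRNModel(self.method, self.topology, params)
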
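"""Reference case-study networks.

Cases A-C are hand-constructed 5-gene networks with printed parameters
for all three formalisms:

* **A** — a four-step activation cascade X1 -> X2 -> X3 -> X4 -> X5 with
  constant signal propagation (identical interaction strengths).
* **B** — a cascade with signal branching (X2 activates X3 and X4) and
  co-regulation (X3 and X4 both activate X5), both asymmetric.
* **C** — case B plus a positive feedback loop X3 -> X2 and a negative
  feedback loop X5 -| X2.

Gene X1 has no regulators in all three cases; it acts as the network
input, decaying from its initial concentration.  All constructed models
share a uniform degradation rate of 0.3 (beta_i in the S-system) and an
S-system degradation kinetic order of 1 on the diagonal only.

Cases D (3-gene oscillator, ANN) and E (5-gene power-law benchmark, SS)
come from the literature with fixed topologies but parameter values that
must be supplied by the user.  Case F is the synthetic-yeast network of
Cantone et al.; only the time-series preprocessing contract is
implemented here (the data are external).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .models import (ANNParams, GRLOTParams, GRNModel, MethodTag, Regulator,
                     SSParams)
from .topology import ACTIVATING, INHIBITING, GRNTopology

CaseId = Literal["A", "B", "C", "D", "E", "F"]

#: Uniform degradation rate of all constructed case A-C models.
DEGRADATION = 0.3

CANTONE_GENES = ("CBF1", "GAL4", "SWI5", "GAL80", "ASH1")


class UnsupportedCombinationError(ValueError):
    """Requested (case, method) pair has no printed parameter values."""


@dataclass(frozen=True)
class StartingSet:
    """One of the five initial-concentration vectors for cases A-C."""

    label: int
    x0: tuple[float, ...]


_STARTING_SETS = (
    StartingSet(1, (0.8, 0.1, 0.1, 0.1, 0.1)),
    StartingSet(2, (0.8, 0.1, 0.1, 0.3, 0.5)),
    StartingSet(3, (0.5, 0.5, 0.2, 0.1, 0.1)),
    StartingSet(4, (0.4, 0.8, 0.2, 0.2, 0.2)),
    StartingSet(5, (0.5, 0.2, 0.8, 0.8, 0.2)),
)


def starting_sets() -> tuple[StartingSet, ...]:
    """The five printed initial-condition sets, in order."""
    return _STARTING_SETS


# ---------------------------------------------------------------------------
# Topologies

_CASCADE = [(1, 2, ACTIVATING), (2, 3, ACTIVATING),
            (3, 4, ACTIVATING), (4, 5, ACTIVATING)]

_BRANCHED = [(1, 2, ACTIVATING), (2, 3, ACTIVATING), (2, 4, ACTIVATING),
             (3, 5, ACTIVATING), (4, 5, ACTIVATING)]

_FEEDBACK = _BRANCHED + [(3, 2, ACTIVATING), (5, 2, INHIBITING)]

_CASE_D_EDGES = [(1, 2, ACTIVATING), (2, 3, ACTIVATING),
                 (2, 1, ACTIVATING), (3, 1, INHIBITING)]

# 5-gene power-law benchmark wiring: a cascade X1 -> X2 -> X3 -> X4 -> X5
# with X3 activating X1 and X5 inhibiting X1's production; the inhibitory
# dependency is the documented source of singular dynamics.
_CASE_E_EDGES = [(3, 1, ACTIVATING), (5, 1, INHIBITING),
                 (1, 2, ACTIVATING), (2, 3, ACTIVATING),
                 (3, 4, ACTIVATING), (4, 5, ACTIVATING)]


def case_topology(case_id: CaseId) -> GRNTopology:
    """Fixed signed structure of a case study."""
    if case_id == "A":
        return GRNTopology.from_tuples(5, _CASCADE)
    if case_id == "B":
        return GRNTopology.from_tuples(5, _BRANCHED)
    if case_id in ("C", "F"):
        # Case F shares the 5-gene size; its true wiring (regulator chains
        # and feedback loops of the synthetic yeast network) is only needed
        # when fitting, where all within-topology signs are free.  We use
        # the case-C structure as the default mask for case F fits.
        return GRNTopology.from_tuples(5, _FEEDBACK)
    if case_id == "D":
        return GRNTopology.from_tuples(3, _CASE_D_EDGES)
    if case_id == "E":
        return GRNTopology.from_tuples(5, _CASE_E_EDGES)
    raise ValueError(f"unknown case id {case_id!r}")


# ---------------------------------------------------------------------------
# Printed parameter tables for cases A-C
#
# Entries are (target gene, source gene) -> value; degradation and the
# remaining scalars are uniform within a case.

_ANN_TABLE = {
    # case: (theta, {(target, source): w})
    "A": (4.0, {(2, 1): 5.0, (3, 2): 5.0, (4, 3): 5.0, (5, 4): 5.0}),
    "B": (4.5, {(2, 1): 7.0, (3, 2): 6.0, (4, 2): 4.0,
                (5, 3): 4.0, (5, 4): 6.0}),
    "C": (4.5, {(2, 1): 7.0, (3, 2): 6.0, (4, 2): 4.0,
                (5, 3): 4.0, (5, 4): 6.0, (2, 3): 7.0, (2, 5): -8.0}),
}

_SS_TABLE = {
    "A": {(2, 1): 2.0, (3, 2): 2.0, (4, 3): 2.0, (5, 4): 2.0},
    "B": {(2, 1): 1.5, (3, 2): 2.0, (4, 2): 3.0, (5, 3): 2.0, (5, 4): 3.0},
    "C": {(2, 1): 1.5, (3, 2): 2.0, (4, 2): 3.0, (5, 3): 2.0, (5, 4): 3.0,
          (2, 3): 0.6, (2, 5): -0.3},
}

_GRLOT_TABLE = {
    # (target, source): (n, K); sign of the topology edge fixes the role.
    "A": {(2, 1): (1.5, 1.1), (3, 2): (1.5, 1.1),
          (4, 3): (1.5, 1.1), (5, 4): (1.5, 1.1)},
    "B": {(2, 1): (1.5, 0.8), (3, 2): (2.5, 0.5), (4, 2): (1.5, 0.8),
          (5, 3): (1.5, 0.8), (5, 4): (2.5, 0.5)},
    "C": {(2, 1): (1.5, 0.8), (3, 2): (2.5, 0.5), (4, 2): (1.5, 0.8),
          (5, 3): (1.5, 0.8), (5, 4): (2.5, 0.5),
          (2, 3): (3.5, 0.1), (2, 5): (1.5, 2.0)},
}


def build_case(case_id: CaseId, method: MethodTag,
               params: dict | None = None) -> GRNModel:
    """Construct a reference dynamic GRN model for a case study.

    Cases A-C are fully specified for all three methods.  Cases D and E
    require ``params`` (their literature values are not bundled): pass a
    parameter dictionary in the ``GRNModel.to_dict()["params"]`` layout.
    """
    if case_id in ("A", "B", "C"):
        topo = case_topology(case_id)
        n = topo.n_genes
        if method == "ANN":
            theta, wmap = _ANN_TABLE[case_id]
            w = np.zeros((n, n))
            for (t, s), val in wmap.items():
                w[t - 1, s - 1] = val
            p = ANNParams(v=np.ones(n), w=w,
                          theta=np.full(n, theta),
                          k=np.full(n, DEGRADATION))
        elif method == "SS":
            g = np.zeros((n, n))
            for (t, s), val in _SS_TABLE[case_id].items():
                g[t - 1, s - 1] = val
            alpha = np.ones(n)
            alpha[0] = 0.0  # X1 is the network input: no production
            p = SSParams(alpha=alpha, beta=np.full(n, DEGRADATION),
                         g=g, h=np.eye(n))
        elif method == "GRLOT":
            topo_signs = {(e.source, e.target): e.sign for e in topo.edges}
            regs: dict[int, list[Regulator]] = {}
            for (t, s), (hill_n, K) in _GRLOT_TABLE[case_id].items():
                role = ("activator"
                        if topo_signs[(s, t)] == ACTIVATING else "inhibitor")
                regs.setdefault(t, []).append(Regulator(s, role, hill_n, K))
            v = np.ones(n)
            v[0] = 0.0
            p = GRLOTParams(v=v, k=np.full(n, DEGRADATION),
                            regulators={t: sorted(r, key=lambda x: x.source)
                                        for t, r in regs.items()})
        else:
            raise ValueError(f"unknown method tag {method!r}")
        return GRNModel(method, topo, p)

    if case_id == "D":
        if method != "ANN" or params is None:
            raise UnsupportedCombinationError(
                "case D is an ANN model; literature parameters required "
                "(pass params={'v':..., 'w':..., 'theta':..., 'k':...})"
            )
        return GRNModel("ANN", case_topology("D"),
                        ANNParams.from_dict(params))
    if case_id == "E":
        if method != "SS" or params is None:
            raise UnsupportedCombinationError(
                "case E is an S-system model; literature parameters "
                "required (pass params={'alpha':..., 'beta':..., "
                "'g':..., 'h':...})"
            )
        return GRNModel("SS", case_topology("E"), SSParams.from_dict(params))
    raise UnsupportedCombinationError(
        f"case {case_id!r} with method {method!r} has no printed parameters"
    )


def case_d_variants(params: dict) -> tuple[GRNModel, GRNModel]:
    """The two 3-gene ANN variants differing only in theta_1.

    The first has theta_1 = 3.0 (non-oscillatory regime), the second
    theta_1 = 1.0 (oscillatory regime).  All other parameters are taken
    from ``params`` unchanged.
    """
    out = []
    for theta1 in (3.0, 1.0):
        p = {key: list(val) if not isinstance(val, list) else list(val)
             for key, val in params.items()}
        p["theta"] = list(p["theta"])
        p["theta"][0] = theta1
        out.append(build_case("D", "ANN", params=p))
    return out[0], out[1]


class FormatError(ValueError):
    """A user-supplied time-series file violates the expected layout."""


def load_cantone_series(path, series: str = "switch-on"):
    """Load a Cantone-style yeast time-series CSV.

    Expects a ``time`` column in minutes plus the five gene columns
    CBF1, GAL4, SWI5, GAL80, ASH1.  Rows are restricted to the window
    (10, 100] minutes: the first 10-minute interval covers the medium
    shift and is excluded, and the system is externally perturbed after
    100 minutes.

    Returns a :class:`~grncompare.simulate.TimeSeriesSet` with one
    trajectory labelled by ``series``.
    """
    from .simulate import TimeSeriesSet, Trajectory

    if series not in ("switch-on", "switch-off"):
        raise ValueError("series must be 'switch-on' or 'switch-off'")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    cols = {c.strip(): c for c in df.columns}
    time_col = cols.get("time") or cols.get("Time")
    if time_col is None:
        raise FormatError(f"{path}: missing 'time' column")
    missing = [gname for gname in CANTONE_GENES if gname not in cols]
    if missing:
        raise FormatError(f"{path}: missing gene columns {missing}")
    t = df[time_col].to_numpy(dtype=float)
    if len(t) == 0:
        raise FormatError(f"{path}: no data rows")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must increase monotonically")
    keep = (t > 10.0) & (t <= 100.0)
    if not np.any(keep):
        raise FormatError(f"{path}: no rows in the (10, 100] minute window")
    x = df[[cols[gname] for gname in CANTONE_GENES]].to_numpy(dtype=float)
    traj = Trajectory(label=series, t=t[keep], x=x[keep])
    return TimeSeriesSet(trajectories=[traj],
                         meta={"source": str(path), "series": series,
                               "genes": list(CANTONE_GENES)})
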
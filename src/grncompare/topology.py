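"""Static gene-regulatory-network structure.

A static GRN model records only *which* genes regulate which, and whether
each interaction activates or inhibits the target.  Gene indices are
1-based throughout the public API, matching the X1..XN naming convention
used for small network case studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

Sign = Literal["activating", "inhibiting"]

ACTIVATING: Sign = "activating"
INHIBITING: Sign = "inhibiting"


@dataclass(frozen=True)
class Edge:
    """One directed regulatory interaction ``source -> target``."""

    source: int
    target: int
    sign: Sign

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATING, INHIBITING):
            raise ValueError(f"unknown edge sign {self.sign!r}")


@dataclass(frozen=True)
class GRNTopology:
    """Signed, directed regulatory structure of an ``n_genes`` network.

    Self-edges are permitted; at most one edge per ordered (source, target)
    pair.  Gene indices run from 1 to ``n_genes``.
    """

    n_genes: int
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            for idx in (e.source, e.target):
                if not (1 <= idx <= self.n_genes):
                    raise ValueError(
                        f"gene index {idx} outside [1, {self.n_genes}]"
                    )
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge for pair {key}")
            seen.add(key)

    @classmethod
    def from_tuples(
        cls, n_genes: int, edges: Iterable[tuple[int, int, Sign]]
    ) -> "GRNTopology":
        return cls(n_genes, frozenset(Edge(s, t, sg) for s, t, sg in edges))

    def regulators_of(self, target: int) -> list[Edge]:
        """Incoming edges of ``target``, sorted by source index."""
        return sorted(
            (e for e in self.edges if e.target == target),
            key=lambda e: e.source,
        )

    def edge(self, source: int, target: int) -> Edge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def mask(self) -> np.ndarray:
        """Boolean N x N matrix, ``mask[i-1, j-1]`` true iff edge j -> i."""
        m = np.zeros((self.n_genes, self.n_genes), dtype=bool)
        for e in self.edges:
            m[e.target - 1, e.source - 1] = True
        return m

    def sign_matrix(self) -> np.ndarray:
        """Signed adjacency: +1 activation, -1 inhibition, 0 no edge."""
        m = np.zeros((self.n_genes, self.n_genes), dtype=int)
        for e in self.edges:
            m[e.target - 1, e.source - 1] = 1 if e.sign == ACTIVATING else -1
        return m

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "edges": sorted(
                [e.source, e.target, e.sign] for e in self.edges
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNTopology":
        return cls.from_tuples(
            d["n_genes"], [(s, t, sg) for s, t, sg in d["edges"]]
        )
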
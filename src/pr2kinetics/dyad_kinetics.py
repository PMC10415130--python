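"""Sixteen-state dinucleotide (dyad) mutation kinetics on the tesseract graph.

The 16 ordered dyads (5'->3' dinucleotides, "AC" == ApC) form the nodes of a
hypercube-like network in which each directed edge substitutes one of the two
positions, giving 16 x 2 x 3 = 96 directed edges.  Under the no-strand-bias
(NSB) assumption an edge and the edge between the reverse complements of its
endpoints carry the same rate (e.g. ApC->ApT pairs with GpT->ApT), reducing
the 96 rates to 48 equivalence classes.

Whatever the 48 NSB rates are, the stationary dyad contents always collapse
into 10 classes:

    [AA=TT], [AC=GT], [AG=CT], [CA=TG], [GA=TC], [CC=GG], [CG], [GC], [AT], [TA]

— each dyad matching its reverse complement, i.e. parity (PR-2) at the dyad
level.  With context-independent rates (each edge carrying the singleton rate
of its mutating position) the classes merge further into just three values:
the outer square of the singleton NSB equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .rate_model import BASES, RateSet, SymmetricRateSet
from .singleton_kinetics import DegenerateSystemError, IntegrationError

__all__ = [
    "DYADS",
    "DyadComposition",
    "DyadNetwork",
    "reverse_complement",
    "enumerate_edges",
    "nsb_edge_partner",
    "nsb_edge_classes",
    "build_dyad_network",
    "context_independent_network",
    "evolve_dyads",
    "DyadTrajectory",
    "stationary_dyads",
    "equilibrium_classes",
    "context_independent_equilibrium",
    "EQ6_CLASSES",
]

#: The 16 ordered dyads, alphabetical.
DYADS = tuple(a + b for a, b in product(BASES, repeat=2))
_DYAD_INDEX = {d: i for i, d in enumerate(DYADS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The ten stationary-content classes of an NSB dyad network: each dyad is
#: grouped with its reverse complement.
EQ6_CLASSES = (
    frozenset({"AA", "TT"}),
    frozenset({"AC", "GT"}),
    frozenset({"AG", "CT"}),
    frozenset({"CA", "TG"}),
    frozenset({"GA", "TC"}),
    frozenset({"CC", "GG"}),
    frozenset({"CG"}),
    frozenset({"GC"}),
    frozenset({"AT"}),
    frozenset({"TA"}),
)


def reverse_complement(dyad: str) -> str:
    """Complement then reverse: "AC" -> "GT"."""
    return "".join(_COMPLEMENT[b] for b in reversed(dyad))


def enumerate_edges() -> list[tuple[str, str]]:
    """All 96 directed single-position substitution edges (source, target)."""
    edges = []
    for d in DYADS:
        for pos in (0, 1):
            for alt in BASES:
                if alt != d[pos]:
                    target = d[:pos] + alt + d[pos + 1:]
                    edges.append((d, target))
    return edges


def nsb_edge_partner(edge: tuple[str, str]) -> tuple[str, str]:
    """The NSB partner edge: the same mutation seen on the complementary strand.

    An edge (d1 -> d2) pairs with (revcomp(d1) -> revcomp(d2)); the pairing is
    an involution with no fixed points.
    """
    s, t = edge
    return (reverse_complement(s), reverse_complement(t))


def nsb_edge_classes() -> list[frozenset[tuple[str, str]]]:
    """The 48 unordered {edge, partner} classes, deterministically ordered."""
    seen = set()
    classes = []
    for edge in enumerate_edges():
        partner = nsb_edge_partner(edge)
        cls = frozenset({edge, partner})
        if cls not in seen:
            seen.add(cls)
            classes.append(cls)
    return classes


@dataclass(frozen=True)
class DyadComposition:
    """Fractional contents of the 16 dyads, summing to one."""

    contents: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.contents) != set(DYADS):
            raise ValueError("DyadComposition needs exactly the 16 dyads")
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError("dyad contents must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"dyad contents must sum to 1, got {vec.sum()!r}")
        object.__setattr__(self, "contents", dict(self.contents))

    def __getitem__(self, dyad: str) -> float:
        return self.contents[dyad]

    def as_array(self) -> np.ndarray:
        return np.array([self.contents[d] for d in DYADS], dtype=float)

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "DyadComposition":
        return cls(dict(zip(DYADS, map(float, vec))))

    @classmethod
    def uniform(cls) -> "DyadComposition":
        return cls.from_array(np.full(16, 1 / 16))

    def marginal_first(self) -> np.ndarray:
        """Singleton composition of the first position, (A, C, G, T) order."""
        vec = self.as_array().reshape(4, 4)
        return vec.sum(axis=1)

    def marginal_second(self) -> np.ndarray:
        vec = self.as_array().reshape(4, 4)
        return vec.sum(axis=0)


@dataclass(frozen=True)
class DyadNetwork:
    """The dyad mutation network: 96 directed edges with rate constants.

    ``nsb`` records whether the rates were supplied per NSB class, in which
    case both edges of every class carry the shared value.
    """

    rates: Mapping[tuple[str, str], float]
    nsb: bool = False

    def __post_init__(self) -> None:
        expected = set(enumerate_edges())
        got = set(self.rates)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise ValueError(
                f"dyad network needs exactly the 96 substitution edges; "
                f"missing (first 5)={missing}, unexpected (first 5)={extra}"
            )
        for edge, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"negative rate on edge {edge}")
        if self.nsb:
            for edge in expected:
                partner = nsb_edge_partner(edge)
                if abs(self.rates[edge] - self.rates[partner]) > 1e-12:
                    raise ValueError(f"NSB network has unequal class rates on {edge}/{partner}")
        object.__setattr__(self, "rates", dict(self.rates))

    def generator(self) -> np.ndarray:
        """The 16x16 generator (row = target, column = source; columns sum to 0)."""
        M = np.zeros((16, 16))
        for (s, t), rate in self.rates.items():
            M[_DYAD_INDEX[t], _DYAD_INDEX[s]] += rate
        np.fill_diagonal(M, M.diagonal() - M.sum(axis=0))
        return M


def build_dyad_network(
    rates: Mapping[tuple[str, str], float] | Mapping[frozenset, float],
    nsb: bool = False,
) -> DyadNetwork:
    """Build the network from per-edge rates (nsb=False, 96 entries) or
    per-class rates (nsb=True, 48 entries keyed by frozenset of the two edges).
    """
    if nsb:
        classes = nsb_edge_classes()
        if set(rates) != set(classes):
            raise ValueError(
                f"NSB network needs rates for exactly the 48 edge classes, got {len(rates)}"
            )
        edge_rates = {}
        for cls in classes:
            for edge in cls:
                edge_rates[edge] = float(rates[cls])
        return DyadNetwork(edge_rates, nsb=True)
    return DyadNetwork({k: float(v) for k, v in rates.items()}, nsb=False)


def context_independent_network(r: RateSet) -> DyadNetwork:
    """Dyad network whose every edge carries the singleton rate of its mutating
    position, ignoring the neighbour base."""
    rates = {}
    for s, t in enumerate_edges():
        pos = 0 if s[0] != t[0] else 1
        rates[(s, t)] = r[s[pos] + t[pos]]
    nsb = False
    try:
        from .rate_model import nsb_reduce
        nsb_reduce(r, tolerance=1e-12)
        nsb = True
    except Exception:
        pass
    return DyadNetwork(rates, nsb=nsb)


@dataclass(frozen=True)
class DyadTrajectory:
    """Recorded time course of dyad contents: times (T,), contents (T, 16)."""

    times: np.ndarray
    contents: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        contents = np.asarray(self.contents, dtype=float)
        if contents.shape != (times.size, 16):
            raise ValueError("contents must be (n_times, 16)")
        if np.any(np.abs(contents.sum(axis=1) - 1.0) > 1e-7):
            raise ValueError("dyad contents must sum to 1 along the trajectory")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "contents", contents)

    @property
    def final(self) -> DyadComposition:
        return DyadComposition.from_array(self.contents[-1])


def evolve_dyads(
    net: DyadNetwork,
    d0: DyadComposition,
    horizon: float,
    record_times: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> DyadTrajectory:
    """Integrate the 16-state linear ODE d(contents)/dt = M contents."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if record_times is None:
        times = np.linspace(0.0, horizon, 200)
    else:
        times = np.asarray(record_times, dtype=float)
        if times[0] != 0:
            times = np.concatenate([[0.0], times])
    M = net.generator()
    sol = solve_ivp(
        lambda _t, y: M @ y,
        (0.0, float(times[-1])),
        d0.as_array(),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"dyad ODE integration failed: {sol.message}")
    return DyadTrajectory(sol.t, sol.y.T)


def stationary_dyads(net: DyadNetwork, tol: float = 1e-10) -> DyadComposition:
    """Stationary dyad contents from the generator's null space (the oracle
    route, independent of time integration)."""
    M = net.generator()
    ns = null_space(M, rcond=tol)
    if ns.shape[1] != 1:
        raise DegenerateSystemError(
            f"dyad network has a {ns.shape[1]}-dimensional stationary space"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if np.any(v < -1e-8):
        raise DegenerateSystemError("null-space vector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return DyadComposition.from_array(v / v.sum())


def equilibrium_classes(net: DyadNetwork, tol: float = 1e-6) -> list[frozenset[str]]:
    """Partition the 16 dyads by stationary content, grouped within ``tol``.

    For any NSB network this returns the ten reverse-complement classes; for
    generic unconstrained rates the stationary values generically do not
    coincide and 16 singleton classes come back.
    """
    eq = stationary_dyads(net)
    order = sorted(DYADS, key=lambda d: eq[d])
    groups: list[list[str]] = [[order[0]]]
    for dyad in order[1:]:
        if abs(eq[dyad] - eq[groups[-1][0]]) <= tol:
            groups[-1].append(dyad)
        else:
            groups.append([dyad])
    return [frozenset(g) for g in groups]


def context_independent_equilibrium(s: SymmetricRateSet) -> DyadComposition:
    """Closed-form dyad equilibrium for context-independent NSB rates.

    AT-class dyads (AA, TT, AT, TA) take (i+m)^2 / 4(i+j+m+n)^2, GC-class
    dyads (CC, GG, CG, GC) take (j+n)^2 / 4(i+j+m+n)^2, and the eight mixed
    dyads take the cross term (i+m)(j+n) / 4(i+j+m+n)^2 — i.e. the outer
    square of the singleton equilibrium.
    """
    denom = s.i + s.j + s.m + s.n
    if denom <= 0:
        raise DegenerateSystemError("i + j + m + n must be positive")
    at = (s.i + s.m) / (2 * denom)
    gc = (s.j + s.n) / (2 * denom)
    per_base = {"A": at, "T": at, "C": gc, "G": gc}
    return DyadComposition({d: per_base[d[0]] * per_base[d[1]] for d in DYADS})


def write_dyad_rates(net: DyadNetwork, path: str | Path) -> None:
    """Write the 96 edge rates as TSV: source_dyad, target_dyad, rate."""
    rows = [(s, t, net.rates[(s, t)]) for s, t in sorted(net.rates)]
    pd.DataFrame(rows, columns=["source_dyad", "target_dyad", "rate"]).to_csv(
        path, sep="\t", index=False
    )


def read_dyad_rates(path: str | Path, nsb: bool = False) -> DyadNetwork:
    """Read edge rates from TSV (source_dyad, target_dyad, rate)."""
    df = pd.read_csv(path, sep="\t")
    rates = {(str(r.source_dyad), str(r.target_dyad)): float(r.rate) for r in df.itertuples()}
    net = DyadNetwork(rates, nsb=False)
    if nsb:
        # re-tag after verifying pairing
        return DyadNetwork(rates, nsb=True)
    return net


def write_dyad_trajectory(traj: DyadTrajectory, path: str | Path) -> None:
    """Write a dyad trajectory as 17-column TSV (time_byr + 16 dyads)."""
    df = pd.DataFrame(traj.contents, columns=list(DYADS))
    df.insert(0, "time_byr", traj.times)
    df.to_csv(path, sep="\t", index=False)
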
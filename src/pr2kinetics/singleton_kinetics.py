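"""Four-state mutational kinetics of genomic base content.

The genome-averaged base composition C = (C_A, C_C, C_G, C_T) evolves under
the linear ODE dC/dt = M C, where M is the generator built from the 12
directed mutation rate constants: the off-diagonal entry in row u, column s is
k_{s->u}, and each diagonal entry is minus the total outgoing rate of its
column's base, so every column of M sums to zero and total content is
conserved.

Under the no-strand-bias (NSB) reduction the system is fully solvable at
equilibrium:

    C_A = C_T = (i + m) / (2 (i + j + m + n))
    C_G = C_C = (j + n) / (2 (i + j + m + n))

which exhibits the C_A = C_T and C_G = C_C intra-strand parity (PR-2) and ties
the equilibrium G+C content to the rates through

    (n + j) / (i + m) = C_GC / (1 - C_GC).

Besides the general integrator (`evolve`, stiff-capable `solve_ivp`) the
module provides the exact eigendecomposition propagator used for large
ensembles, a dedicated NSB-form integrator for cross-checking, and the
null-space stationary composition as an independent long-time oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .rate_model import BASES, RATE_KEYS, RateSet, SymmetricRateSet

__all__ = [
    "BaseComposition",
    "Trajectory",
    "build_rate_matrix",
    "evolve",
    "evolve_nsb",
    "nsb_equilibrium",
    "gc_equilibrium_curve",
    "stationary_composition",
    "LinearPropagator",
    "EnsemblePropagator",
    "evolve_ensemble",
    "default_time_grid",
    "write_trajectory",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default integrator tolerances (see docs/methods.md).
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12


@dataclass(frozen=True)
class BaseComposition:
    """Fractional base contents, summing to one."""

    C_A: float
    C_C: float
    C_G: float
    C_T: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError(f"base contents must lie in [0, 1], got {vec}")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"base contents must sum to 1, got {vec.sum()!r}")

    def as_array(self) -> np.ndarray:
        """Contents in (A, C, G, T) order."""
        return np.array([self.C_A, self.C_C, self.C_G, self.C_T], dtype=float)

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "BaseComposition":
        a, c, g, t = (float(x) for x in vec)
        return cls(a, c, g, t)

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @property
    def gc_content(self) -> float:
        return self.C_G + self.C_C


@dataclass(frozen=True)
class Trajectory:
    """A recorded time course of base compositions.

    ``times`` are strictly increasing, start at 0, in byr; ``compositions`` is
    an (n_times, 4) array in (A, C, G, T) order with rows summing to ~1.
    """

    times: np.ndarray
    compositions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        comps = np.asarray(self.compositions, dtype=float)
        if times.ndim != 1 or comps.shape != (times.size, 4):
            raise ValueError("times must be 1-D and compositions (n_times, 4)")
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(np.abs(comps.sum(axis=1) - 1.0) > 1e-7):
            raise ValueError("trajectory compositions must sum to 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "compositions", comps)

    def at(self, index: int) -> BaseComposition:
        return BaseComposition.from_array(self.compositions[index])

    @property
    def final(self) -> BaseComposition:
        return self.at(-1)


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver's message."""


class DegenerateSystemError(ValueError):
    """The rate system has no unique stationary composition."""


def build_rate_matrix(r: RateSet) -> np.ndarray:
    """Build the 4x4 generator M with columns indexed by source base.

    ``M[u, s] = k_{s->u}`` for u != s (row = target, column = source, both in
    (A, C, G, T) order); diagonals make every column sum to zero, so
    ``dC/dt = M @ C`` conserves total content.
    """
    M = np.zeros((4, 4))
    for code in RATE_KEYS:
        s, u = code[0], code[1]
        M[_BASE_INDEX[u], _BASE_INDEX[s]] += r[code]
    np.fill_diagonal(M, M.diagonal() - M.sum(axis=0))
    return M


def default_time_grid(horizon: float, n: int = 1000, t_min_fraction: float = 1e-4) -> np.ndarray:
    """t=0 plus ``n`` log-spaced points from ``t_min_fraction*horizon`` to ``horizon``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    grid = np.geomspace(t_min_fraction * horizon, horizon, n)
    return np.concatenate([[0.0], grid])


def evolve(
    r: RateSet,
    c0: BaseComposition,
    horizon: float,
    record_times: Sequence[float] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Numerically evolve dC/dt = M C up to ``horizon`` byr.

    Uses a stiff-capable LSODA integrator; the recorded grid defaults to
    :func:`default_time_grid`.  Raises :class:`IntegrationError` on solver
    failure.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if record_times is None:
        times = default_time_grid(horizon)
    else:
        times = np.asarray(record_times, dtype=float)
        if times[0] != 0:
            times = np.concatenate([[0.0], times])
    M = build_rate_matrix(r)
    sol = solve_ivp(
        lambda _t, c: M @ c,
        (0.0, float(times[-1])),
        c0.as_array(),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T)


def evolve_nsb(
    s: SymmetricRateSet,
    c0: BaseComposition,
    horizon: float,
    record_times: Sequence[float] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the six-rate NSB system written directly in its reduced form.

    dC_A/dt = i C_C + l C_T + m C_G - (j + l + n) C_A, and cyclic companions.
    Kept as a separate right-hand side so the reduced formulation can be
    cross-checked against the general 12-rate integrator.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if record_times is None:
        times = default_time_grid(horizon)
    else:
        times = np.asarray(record_times, dtype=float)
        if times[0] != 0:
            times = np.concatenate([[0.0], times])
    i, j, k, l, m, n = s.i, s.j, s.k, s.l, s.m, s.n

    def rhs(_t: float, c: np.ndarray) -> list[float]:
        ca, cc, cg, ct = c
        return [
            i * cc + l * ct + m * cg - (j + l + n) * ca,
            j * ca + n * ct + k * cg - (i + m + k) * cc,
            n * ca + k * cc + j * ct - (m + i + k) * cg,
            l * ca + i * cg + m * cc - (l + n + j) * ct,
        ]

    sol = solve_ivp(rhs, (0.0, float(times[-1])), c0.as_array(), t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T)


def nsb_equilibrium(s: SymmetricRateSet) -> BaseComposition:
    """Closed-form NSB equilibrium contents.

    C_A = C_T = (i+m)/(2(i+j+m+n)); C_G = C_C = (j+n)/(2(i+j+m+n)).  The k and
    l rates (the intra-pair C<->G and A<->T exchanges) drop out.
    """
    denom = s.i + s.j + s.m + s.n
    if denom <= 0:
        raise DegenerateSystemError("i + j + m + n must be positive for a unique equilibrium")
    at = (s.i + s.m) / (2 * denom)
    gc = (s.j + s.n) / (2 * denom)
    return BaseComposition(at, gc, gc, at)


def gc_equilibrium_curve(s: SymmetricRateSet) -> float:
    """Equilibrium G+C content from the rate ratio (n+j)/(i+m).

    Solves (n+j)/(i+m) = C_GC / (1 - C_GC), i.e. returns
    (n+j)/(n+j+i+m); independent of the k and l rates.  If i+m = 0 with
    n+j > 0 the limiting value 1 is returned.
    """
    nj = s.n + s.j
    im = s.i + s.m
    if im == 0:
        if nj == 0:
            raise DegenerateSystemError("all of i, j, m, n are zero")
        return 1.0
    return nj / (nj + im)


def stationary_composition(r: RateSet, tol: float = 1e-10) -> BaseComposition:
    """Stationary composition as the normalized null space of the generator.

    Serves as the independent long-time oracle for `evolve`.  Raises
    :class:`DegenerateSystemError` when the null space is not one-dimensional
    (reducible networks have ambiguous long-time limits that depend on the
    initial composition).
    """
    M = build_rate_matrix(r)
    ns = null_space(M, rcond=tol)
    if ns.shape[1] != 1:
        raise DegenerateSystemError(
            f"rate network has a {ns.shape[1]}-dimensional stationary space; "
            "the long-time composition depends on the initial state"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if np.any(v < -1e-8):
        raise DegenerateSystemError("null-space vector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return BaseComposition.from_array(v / v.sum())


class LinearPropagator:
    """Exact solution of dC/dt = M C via eigendecomposition.

    For a single rate set this evaluates C(t) = V exp(L t) V^{-1} C(0) at
    arbitrary times — the closed-form solution of the linear system, used for
    crossing-time refinement and as the engine behind ensemble runs.
    """

    def __init__(self, r: RateSet, c0: BaseComposition):
        M = build_rate_matrix(r)
        self._eigvals, V = np.linalg.eig(M)
        self._V = V
        self._coeffs = np.linalg.solve(V, c0.as_array().astype(complex))

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Composition(s) at time(s) ``t``; shape (..., 4)."""
        t = np.asarray(t, dtype=float)
        phases = np.exp(np.multiply.outer(t, self._eigvals))  # (..., 4)
        out = (phases * self._coeffs) @ self._V.T
        return np.real(out)


class EnsemblePropagator:
    """Exact batched solution of many independent 4-state linear systems.

    Eigendecomposes every generator once; compositions at arbitrary times are
    then closed-form, which is what makes 10^5-replicate ensembles and
    vectorized crossing-time bisection cheap.
    """

    def __init__(self, rate_vectors: np.ndarray, c0: np.ndarray):
        rate_vectors = np.asarray(rate_vectors, dtype=float)
        self.n = rate_vectors.shape[0]
        c0 = np.asarray(c0, dtype=float)
        if c0.ndim == 1:
            c0 = np.broadcast_to(c0, (self.n, 4))
        M = _build_matrices(rate_vectors)
        self._eigvals, self._V = np.linalg.eig(M)  # (n,4), (n,4,4)
        self._coeffs = np.linalg.solve(self._V, c0.astype(complex)[..., None])[..., 0]  # (n,4)

    def at_times(self, t: np.ndarray, index: np.ndarray | None = None) -> np.ndarray:
        """Compositions at per-replicate times ``t`` (shape (m,)).

        ``index`` selects a subset of replicates (default: all, so ``t`` must
        have length n).  Returns (m, 4).
        """
        t = np.asarray(t, dtype=float)
        lam = self._eigvals if index is None else self._eigvals[index]
        coeffs = self._coeffs if index is None else self._coeffs[index]
        V = self._V if index is None else self._V[index]
        phases = np.exp(lam * t[:, None])  # (m,4)
        return np.real(np.einsum("mk,mk,mik->mi", phases, coeffs, V))

    def at_grid(self, times: np.ndarray, chunk: int = 2000) -> np.ndarray:
        """Compositions on a shared time grid; returns (n, T, 4)."""
        times = np.asarray(times, dtype=float)
        out = np.empty((self.n, times.size, 4))
        for start in range(0, self.n, chunk):
            stop = min(start + chunk, self.n)
            phases = np.exp(self._eigvals[start:stop, None, :] * times[None, :, None])
            out[start:stop] = np.real(
                np.einsum(
                    "btk,bk,bik->bti",
                    phases,
                    self._coeffs[start:stop],
                    self._V[start:stop],
                )
            )
        return out

    def stationary(self) -> np.ndarray:
        """Per-replicate stationary compositions (n, 4) from the zero mode.

        Assumes each generator has a unique zero eigenvalue (generic strictly
        positive rates); the eigenvector of the eigenvalue closest to zero is
        normalized to sum one.
        """
        idx = np.argmin(np.abs(self._eigvals), axis=1)
        v = np.real(self._V[np.arange(self.n), :, idx])  # (n, 4)
        sums = v.sum(axis=1, keepdims=True)
        return v / sums


def evolve_ensemble(
    rate_vectors: np.ndarray,
    c0: np.ndarray,
    times: np.ndarray,
    chunk: int = 2000,
) -> np.ndarray:
    """Exactly evolve many independent 4-state systems on a shared time grid.

    Parameters
    ----------
    rate_vectors : (n, 12) array in :data:`~pr2kinetics.rate_model.RATE_KEYS`
        order.
    c0 : (4,) or (n, 4) initial compositions in (A, C, G, T) order.
    times : (T,) evaluation times, byr.
    chunk : replicates processed per batch (memory bound).

    Returns
    -------
    (n, T, 4) array of compositions.
    """
    prop = EnsemblePropagator(rate_vectors, c0)
    return prop.at_grid(np.asarray(times, dtype=float), chunk=chunk)


def _build_matrices(rate_vectors: np.ndarray) -> np.ndarray:
    """Stack of generator matrices for (n, 12) rate vectors."""
    n = rate_vectors.shape[0]
    M = np.zeros((n, 4, 4))
    for idx, code in enumerate(RATE_KEYS):
        s, u = _BASE_INDEX[code[0]], _BASE_INDEX[code[1]]
        M[:, u, s] = rate_vectors[:, idx]
    diag = -M.sum(axis=1)
    M[:, np.arange(4), np.arange(4)] = diag
    return M


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV: time_byr, C_A, C_C, C_G, C_T."""
    df = pd.DataFrame(traj.compositions, columns=["C_A", "C_C", "C_G", "C_T"])
    df.insert(0, "time_byr", traj.times)
    df.to_csv(path, sep="\t", index=False)
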
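"""Seeded Monte Carlo generation of rate sets and initial compositions.

Three rate-sampling protocols back the ensemble studies:

``uniform_unconstrained``
    Twelve independent draws from U(0, upper), with the upper bound computed
    from the packaged human table as (CT/GA mean) + m x (CT/GA sd) — the
    largest strand-symmetry-averaged rate — for multiplier m.  At m = 1 the
    bound is 1.109 + 0.690 = 1.799 per byr.

``truncnorm_individual``
    Twelve draws from zero-truncated normals centred at the 12 individual
    human means with sd scaled by m.

``truncnorm_symmetric``
    Six draws from zero-truncated normals centred at the strand-symmetry-
    averaged means (sd scaled by m), expanded to 12 rates via the NSB map.

Initial compositions come as the flat 0.25 genome, randomly constrained
draws, or the four extreme-skew corners.  All sampling is reproducible from a
single master seed via `numpy.random.SeedSequence` child streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .rate_model import (
    NSB_SYMBOLS,
    RATE_KEYS,
    RateSet,
    TABLE1_INDIVIDUAL,
    TABLE1_SYMMETRIC,
)
from .singleton_kinetics import BaseComposition

__all__ = [
    "SamplingScheme",
    "InitScheme",
    "uniform_upper_bound",
    "sample_rates",
    "sample_rate_vectors",
    "sample_initial",
    "CORNER_SKEW_COMPOSITIONS",
]

_SYMMETRIC_BY_LABEL = {e.label: e for e in TABLE1_SYMMETRIC}
_INDIVIDUAL_BY_LABEL = {e.label: e for e in TABLE1_INDIVIDUAL}

RATE_MODES = ("uniform_unconstrained", "truncnorm_individual", "truncnorm_symmetric")
INIT_MODES = ("uniform_quarter", "random_constrained", "corner_skews")


def uniform_upper_bound(multiplier: float = 1.0) -> float:
    """Upper bound of the unconstrained uniform range.

    (CT/GA mean) + multiplier x (CT/GA sd) from the packaged symmetric table:
    1.799 at multiplier 1.
    """
    entry = _SYMMETRIC_BY_LABEL["CT/GA"]
    return entry.mean + multiplier * entry.sd


@dataclass(frozen=True)
class SamplingScheme:
    """A rate-sampling protocol: mode, sd multiplier and master seed."""

    mode: str = "uniform_unconstrained"
    multiplier: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in RATE_MODES:
            raise ValueError(f"mode must be one of {RATE_MODES}, got {self.mode!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class InitScheme:
    """An initial-composition protocol.

    ``random_constrained`` samples the first two bases (in a random order)
    uniformly within ``base_range`` and splits the remainder between the other
    two, so the four always sum to one; infeasible draws (remainder < 0) are
    resampled.  The per-base allowed range defaults to [0.1, 0.4].
    """

    mode: str = "uniform_quarter"
    seed: int = 1
    base_range: tuple[float, float] = (0.1, 0.4)

    def __post_init__(self) -> None:
        if self.mode not in INIT_MODES:
            raise ValueError(f"mode must be one of {INIT_MODES}, got {self.mode!r}")
        lo, hi = self.base_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("base_range must satisfy 0 <= lo < hi <= 1")


#: Compositions (A, C, G, T) hitting the four extreme (gc_skew, at_skew)
#: corners; the split between the two nonzero bases is underdetermined and
#: fixed at 0.5/0.5.
CORNER_SKEW_COMPOSITIONS: dict[tuple[int, int], BaseComposition] = {
    (1, 1): BaseComposition(0.5, 0.0, 0.5, 0.0),    # only A and G: skews (+1, +1)
    (-1, 1): BaseComposition(0.5, 0.5, 0.0, 0.0),   # only A and C: skews (-1, +1)
    (1, -1): BaseComposition(0.0, 0.0, 0.5, 0.5),   # only G and T: skews (+1, -1)
    (-1, -1): BaseComposition(0.0, 0.5, 0.0, 0.5),  # only C and T: skews (-1, -1)
}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def sample_rate_vectors(scheme: SamplingScheme, n: int) -> np.ndarray:
    """Sample ``n`` rate sets as an (n, 12) array in RATE_KEYS order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(scheme.seed)
    m = scheme.multiplier
    if scheme.mode == "uniform_unconstrained":
        upper = uniform_upper_bound(m)
        return rng.uniform(0.0, upper, size=(n, 12))
    if scheme.mode == "truncnorm_individual":
        out = np.empty((n, 12))
        for idx, code in enumerate(RATE_KEYS):
            entry = _INDIVIDUAL_BY_LABEL[code]
            out[:, idx] = _truncnorm_draws(rng, entry.mean, m * entry.sd, n)
        return out
    # truncnorm_symmetric: six draws, NSB-expanded
    out = np.empty((n, 12))
    col_of = {code: i for i, code in enumerate(RATE_KEYS)}
    for symbol, (a, b) in NSB_SYMBOLS.items():
        entry = _SYMMETRIC_BY_LABEL[f"{a}/{b}"]
        draws = _truncnorm_draws(rng, entry.mean, m * entry.sd, n)
        out[:, col_of[a]] = draws
        out[:, col_of[b]] = draws
    return out


def _truncnorm_draws(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Zero-truncated normal draws (truncation at 0 only, no upper bound)."""
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def sample_rates(scheme: SamplingScheme, n: int) -> list[RateSet]:
    """Sample ``n`` :class:`RateSet` objects (wrapper over the array sampler)."""
    return [RateSet.from_vector(row) for row in sample_rate_vectors(scheme, n)]


def sample_initial(scheme: InitScheme, n: int) -> list[BaseComposition]:
    """Sample ``n`` initial compositions under the given protocol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme.mode == "uniform_quarter":
        return [BaseComposition.uniform() for _ in range(n)]
    if scheme.mode == "corner_skews":
        corners = list(CORNER_SKEW_COMPOSITIONS.values())
        return [corners[i % 4] for i in range(n)]
    # random_constrained
    rng = _rng(scheme.seed)
    lo, hi = scheme.base_range
    out: list[BaseComposition] = []
    while len(out) < n:
        first, second = rng.uniform(lo, hi, size=2)
        remainder = 1.0 - first - second
        if remainder < 0:
            continue  # infeasible draw; resample
        third = rng.uniform(0.0, remainder)
        fourth = remainder - third
        values = [first, second, third, fourth]
        order = rng.permutation(4)
        comp = np.empty(4)
        comp[order] = values
        out.append(BaseComposition.from_array(comp))
    return out


def sample_initial_vectors(scheme: InitScheme, n: int) -> np.ndarray:
    """Initial compositions as an (n, 4) array in (A, C, G, T) order."""
    return np.array([c.as_array() for c in sample_initial(scheme, n)])
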
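"""Domain types for base-mutation rate constants.

A genome-averaged substitution process among {A, C, G, T} is described by 12
directed rate constants ``k_{s->u}`` (per site per billion years, byr).  Under
the no-strand-bias (NSB) assumption each mutation proceeds at the same rate on
both strands of a dsDNA, which — via Watson–Crick complementarity — forces six
pairwise equalities and leaves six independent rates, conventionally written
``i, j, k, l, m, n``:

    i = k_CA = k_GT      j = k_AC = k_TG      k = k_CG = k_GC
    l = k_AT = k_TA      m = k_CT = k_GA      n = k_AG = k_TC

This module packages the human-genome rate-constant table used throughout the
simulations (Trek-derived means and standard deviations, both the 12
individual rates and the 6 strand-symmetry-averaged rates), the linear
frequency-to-rate conversion, and the NSB reduction/expansion maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BASES",
    "RATE_KEYS",
    "NSB_PAIRS",
    "NSB_SYMBOLS",
    "TREK_SCALING",
    "RateSet",
    "SymmetricRateSet",
    "RateTableEntry",
    "TABLE1_INDIVIDUAL",
    "TABLE1_SYMMETRIC",
    "table1_individual_means",
    "table1_symmetric_means",
    "frequency_to_rate",
    "nsb_reduce",
    "nsb_expand",
    "read_rate_table",
    "write_rate_table",
]

BASES = ("A", "C", "G", "T")

#: The 12 ordered source->target mutation codes, alphabetical.
RATE_KEYS = (
    "AC", "AG", "AT",
    "CA", "CG", "CT",
    "GA", "GC", "GT",
    "TA", "TC", "TG",
)

#: NSB symbol -> the pair of mutation codes it equates.
#: The symbol letters follow the conventional six-rate notation; note that the
#: third symbol "k" (= k_CG = k_GC) is distinct from the generic use of k for
#: any rate constant.
NSB_SYMBOLS: dict[str, tuple[str, str]] = {
    "i": ("CA", "GT"),
    "j": ("AC", "TG"),
    "k": ("CG", "GC"),
    "l": ("AT", "TA"),
    "m": ("CT", "GA"),
    "n": ("AG", "TC"),
}

#: The six NSB pairs in symbol order (i, j, k, l, m, n).
NSB_PAIRS = tuple(NSB_SYMBOLS.values())

#: Linear conversion from a dimensionless mutation frequency to a rate
#: constant in per-site-per-byr units (regression through the origin against
#: Trek-derived human rates).  Overridable at call sites.
TREK_SCALING = 2.831


class SymmetryViolationError(ValueError):
    """A rate set violates an NSB pairwise equality beyond tolerance."""


@dataclass(frozen=True)
class RateSet:
    """The 12 directed mutation rate constants, per site per byr.

    Access rates with :meth:`__getitem__` using two-character codes
    ("CT" is the C->T rate).
    """

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.rates)
        if keys != set(RATE_KEYS):
            missing = sorted(set(RATE_KEYS) - keys)
            extra = sorted(keys - set(RATE_KEYS))
            raise ValueError(
                f"RateSet needs exactly the 12 mutation codes; "
                f"missing={missing}, unexpected={extra}"
            )
        for code, value in self.rates.items():
            if value < 0:
                raise ValueError(f"rate {code} is negative: {value}")
        object.__setattr__(self, "rates", dict(self.rates))

    def __getitem__(self, code: str) -> float:
        return self.rates[code]

    def as_vector(self) -> list[float]:
        """Rates in :data:`RATE_KEYS` order."""
        return [self.rates[c] for c in RATE_KEYS]

    @classmethod
    def from_vector(cls, values: Iterable[float]) -> "RateSet":
        values = list(values)
        if len(values) != 12:
            raise ValueError(f"expected 12 rates, got {len(values)}")
        return cls(dict(zip(RATE_KEYS, map(float, values))))


@dataclass(frozen=True)
class SymmetricRateSet:
    """The six NSB-reduced rates (i, j, k, l, m, n), per site per byr."""

    i: float
    j: float
    k: float
    l: float
    m: float
    n: float

    def __post_init__(self) -> None:
        for name in "ijklmn":
            if getattr(self, name) < 0:
                raise ValueError(f"NSB rate {name} is negative")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in "ijklmn"}


@dataclass(frozen=True)
class RateTableEntry:
    """One row of the packaged rate table: a mutation label, mean and sd."""

    label: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError(f"negative mean/sd for {self.label}")


# Packaged human-genome rate constants (per site per byr): the 12 individual
# rates and, below, the strand-symmetry-averaged six.  Both blocks are
# independent literals — the averaged block is NOT recomputed from the upper
# one (the source estimates differ in the last digit for some pairs).
TABLE1_INDIVIDUAL: tuple[RateTableEntry, ...] = (
    RateTableEntry("AC", 0.198, 0.100),
    RateTableEntry("TG", 0.199, 0.098),
    RateTableEntry("AG", 0.679, 0.553),
    RateTableEntry("TC", 0.875, 0.824),
    RateTableEntry("AT", 0.210, 0.111),
    RateTableEntry("TA", 0.216, 0.132),
    RateTableEntry("CA", 0.371, 0.505),
    RateTableEntry("GT", 0.269, 0.139),
    RateTableEntry("CG", 0.304, 0.158),
    RateTableEntry("GC", 0.238, 0.117),
    RateTableEntry("CT", 1.173, 0.894),
    RateTableEntry("GA", 1.044, 0.387),
)

TABLE1_SYMMETRIC: tuple[RateTableEntry, ...] = (
    RateTableEntry("AC/TG", 0.198, 0.099),
    RateTableEntry("AG/TC", 0.753, 0.673),
    RateTableEntry("AT/TA", 0.212, 0.119),
    RateTableEntry("CA/GT", 0.322, 0.378),
    RateTableEntry("CG/GC", 0.273, 0.144),
    RateTableEntry("CT/GA", 1.109, 0.690),
)


def table1_individual_means() -> RateSet:
    """The packaged 12 individual human rate means as a :class:`RateSet`."""
    return RateSet({e.label: e.mean for e in TABLE1_INDIVIDUAL})


def table1_symmetric_means() -> SymmetricRateSet:
    """The packaged strand-symmetry-averaged means as a :class:`SymmetricRateSet`."""
    by_pair = {e.label: e.mean for e in TABLE1_SYMMETRIC}
    values = {}
    for symbol, (a, b) in NSB_SYMBOLS.items():
        label = f"{a}/{b}"
        values[symbol] = by_pair[label]
    return SymmetricRateSet(**values)


def frequency_to_rate(f: float, scaling: float = TREK_SCALING) -> float:
    """Convert a mutation frequency to a rate constant (per site per byr).

    The conversion is linear through the origin, ``k = scaling * f``, with the
    packaged default ``scaling`` of 2.831 from the Trek calibration.
    """
    if f < 0:
        raise ValueError(f"mutation frequency must be non-negative, got {f}")
    return scaling * f


def nsb_reduce(r: RateSet, tolerance: float = 1e-9) -> SymmetricRateSet:
    """Collapse a 12-rate set to the six NSB rates.

    Each pair of rates that NSB equates must agree to the given *relative*
    tolerance; the reduced value is the pair mean.

    Raises
    ------
    SymmetryViolationError
        naming the offending pair, if any pair deviates beyond tolerance.
    """
    values = {}
    for symbol, (a, b) in NSB_SYMBOLS.items():
        va, vb = r[a], r[b]
        scale = max(abs(va), abs(vb))
        if scale > 0 and abs(va - vb) / scale > tolerance:
            raise SymmetryViolationError(
                f"NSB pair {a}/{b} violated: k_{a}={va} vs k_{b}={vb} "
                f"(relative deviation {abs(va - vb) / scale:.3g} > {tolerance:g})"
            )
        values[symbol] = 0.5 * (va + vb)
    return SymmetricRateSet(**values)


def nsb_expand(s: SymmetricRateSet) -> RateSet:
    """Expand six NSB rates into the full 12-rate set (exact pair equality)."""
    rates = {}
    for symbol, (a, b) in NSB_SYMBOLS.items():
        value = getattr(s, symbol)
        rates[a] = value
        rates[b] = value
    return RateSet(rates)


def read_rate_table(path: str | Path) -> list[RateTableEntry]:
    """Read a rate table from TSV with required header (mutation, mean, sd)."""
    df = pd.read_csv(path, sep="\t")
    required = {"mutation", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"rate table must have columns {sorted(required)}, got {list(df.columns)}")
    return [RateTableEntry(str(row.mutation), float(row.mean), float(row.sd)) for row in df.itertuples()]


def write_rate_table(entries: Iterable[RateTableEntry], path: str | Path) -> None:
    """Write rate-table entries as TSV (mutation, mean, sd)."""
    df = pd.DataFrame(
        [(e.label, e.mean, e.sd) for e in entries],
        columns=["mutation", "mean", "sd"],
    )
    df.to_csv(path, sep="\t", index=False)
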
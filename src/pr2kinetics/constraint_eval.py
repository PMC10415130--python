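"""The twelve generalized mutation-rate constraint equations.

Symbolic regression over the PR-2-compliant region of unconstrained kinetic
simulations yields, for each of the 12 directed mutation rates, a simple
linear form over the remaining 11 rates plus an intercept — a set of
interrelations more permissive than the strict no-strand-bias pairwise
equalities, yet still predictive of PR-2 compliance within 4.28 byr.  The
forms are packaged verbatim (coefficients as printed, to 1-2 significant
figures, so every derived check carries a tolerance):

    k_ag = -0.6 (k_cg - k_gc + k_at - k_ta + k_ct - 1.3 k_tc - k_ga - 0.6)
    ... (and 11 companions; see :data:`CONSTRAINT_FORMS`).

The module evaluates the predictions, scores rate sets by their residuals,
reports the NSB pairwise residuals, and compares species rate sets against
the equilibrium G+C curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .rate_model import NSB_SYMBOLS, RATE_KEYS, RateSet, SymmetricRateSet
from .singleton_kinetics import gc_equilibrium_curve

__all__ = [
    "ConstraintForm",
    "CONSTRAINT_FORMS",
    "predict_rates",
    "predict_rates_array",
    "constraint_residuals",
    "residual_norms_array",
    "nsb_residuals",
    "species_vs_gc_curve",
]


@dataclass(frozen=True)
class ConstraintForm:
    """One constraint: target = outer * (sum inner_coeffs[u] * k_u + inner_const).

    Stored in the factored shape in which the equations are printed; the
    expanded linear coefficients come from :meth:`expanded`.
    """

    target: str
    outer: float
    inner_coeffs: Mapping[str, float]
    inner_const: float

    def __post_init__(self) -> None:
        if self.target in self.inner_coeffs:
            raise ValueError(f"form for {self.target} must not reference itself")
        unknown = set(self.inner_coeffs) - set(RATE_KEYS)
        if unknown:
            raise ValueError(f"unknown rate codes {unknown}")
        object.__setattr__(self, "inner_coeffs", dict(self.inner_coeffs))

    def expanded(self) -> tuple[dict[str, float], float]:
        """(linear coefficients over the 11 other rates, intercept)."""
        coeffs = {u: self.outer * c for u, c in self.inner_coeffs.items()}
        return coeffs, self.outer * self.inner_const

    def predict(self, r: RateSet) -> float:
        coeffs, intercept = self.expanded()
        return sum(c * r[u] for u, c in coeffs.items()) + intercept


# The 12 packaged forms, transcribed in their printed factored shape.
# Lowercase two-letter symbols map to source->target codes (k_ag == k_{A->G}).
CONSTRAINT_FORMS: dict[str, ConstraintForm] = {
    form.target: form
    for form in (
        ConstraintForm("AG", -0.6, {"CG": 1, "GC": -1, "AT": 1, "TA": -1,
                                    "CT": 1, "TC": -1.3, "GA": -1}, -0.6),
        ConstraintForm("GA", 0.7, {"CG": 1, "GC": -1, "AT": 1, "TA": -1,
                                   "CT": 1, "TC": -1, "AG": 1}, 0.1),
        ConstraintForm("TC", 0.8, {"CG": 0.7, "GC": -1, "AT": 0.8, "TA": -1,
                                   "AG": 1, "GA": -0.8, "CT": 1}, 0.4),
        ConstraintForm("CT", -0.8, {"CG": 1, "GC": -1, "AT": 0.8, "TA": -1,
                                    "AG": 1, "GA": -1, "CA": 0.1, "TC": -1}, -0.3),
        ConstraintForm("AC", -0.8, {"GC": 1, "CG": -1, "AT": 1, "TA": -1,
                                    "GT": 1, "TG": -1, "CA": -1}, -0.3),
        ConstraintForm("CA", 0.8, {"GC": 1, "CG": -1, "AT": 1, "TA": -1,
                                   "GT": 1, "TG": -1, "AC": 1}, 0.2),
        ConstraintForm("GT", -0.8, {"GC": 1, "CG": -1, "AT": 1, "TA": -1,
                                    "TG": -1, "AC": 1, "CA": -1}, -0.2),
        ConstraintForm("TG", 0.8, {"GC": 1, "CG": -1, "AT": 1, "TA": -1,
                                   "GT": 1, "AC": 1, "CA": -1}, 0.1),
        ConstraintForm("AT", -0.5, {"TA": -2, "CT": 1, "TC": -1, "AG": 1,
                                    "GA": -1, "GT": 1, "TG": -1, "AC": 1,
                                    "CA": -1}, -0.5),
        ConstraintForm("TA", 0.5, {"AT": 2, "CT": 1, "TC": -1, "AG": 1,
                                   "GA": -1, "GT": 1, "TG": -1, "AC": 1,
                                   "CA": -1}, -0.1),
        ConstraintForm("GC", -0.4, {"CG": -2, "TC": 1, "CT": -1, "GA": 1,
                                    "AG": -1, "GT": 1, "TG": -1, "AC": 1,
                                    "CA": -1}, -0.06),
        ConstraintForm("CG", 0.4, {"GC": 2, "TC": 1, "CT": -1, "GA": 1,
                                   "AG": -1, "GT": 1, "TG": -1, "AC": 1,
                                   "CA": -1}, 0.9),
    )
}

# Precomputed expanded coefficient matrix: predicted = rates @ _COEF.T + _INTERCEPT,
# rows in RATE_KEYS order for both targets and sources.
_COEF = np.zeros((12, 12))
_INTERCEPT = np.zeros(12)
for _t, _form in CONSTRAINT_FORMS.items():
    _row = RATE_KEYS.index(_t)
    _coeffs, _b = _form.expanded()
    for _u, _c in _coeffs.items():
        _COEF[_row, RATE_KEYS.index(_u)] = _c
    _INTERCEPT[_row] = _b


def predict_rates(r: RateSet) -> dict[str, tuple[float, float]]:
    """Per-target (actual, predicted) pairs under the constraint forms."""
    return {t: (r[t], form.predict(r)) for t, form in CONSTRAINT_FORMS.items()}


def predict_rates_array(rate_vectors: np.ndarray) -> np.ndarray:
    """Vectorized predictions: (n, 12) rates -> (n, 12) predictions, both in
    RATE_KEYS order."""
    rate_vectors = np.asarray(rate_vectors, dtype=float)
    return rate_vectors @ _COEF.T + _INTERCEPT


def constraint_residuals(r: RateSet) -> tuple[dict[str, float], float]:
    """Signed residuals (actual - predicted) per target plus their 2-norm."""
    pairs = predict_rates(r)
    residuals = {t: actual - predicted for t, (actual, predicted) in pairs.items()}
    norm = float(np.sqrt(sum(v * v for v in residuals.values())))
    return residuals, norm


def residual_norms_array(rate_vectors: np.ndarray) -> np.ndarray:
    """Aggregate constraint-residual 2-norm for each of n rate vectors."""
    rate_vectors = np.asarray(rate_vectors, dtype=float)
    res = rate_vectors - predict_rates_array(rate_vectors)
    return np.linalg.norm(res, axis=1)


def nsb_residuals(r: RateSet) -> dict[str, dict[str, float]]:
    """Per-NSB-pair ratio and absolute difference.

    Zero denominators are reported as ``ratio = nan`` with a flag.
    """
    out = {}
    for symbol, (a, b) in NSB_SYMBOLS.items():
        va, vb = r[a], r[b]
        out[f"{a}/{b}"] = {
            "ratio": va / vb if vb > 0 else float("nan"),
            "difference": abs(va - vb),
            "zero_denominator": float(vb == 0),
        }
    return out


def species_vs_gc_curve(
    species_rates: Sequence[SymmetricRateSet],
    observed_gc: Sequence[float],
) -> list[dict[str, float]]:
    """Deviation of each species' observed G+C from its equilibrium value.

    The equilibrium G+C content implied by the species' six NSB rates (via
    the (n+j)/(i+m) relation) is compared with the observed genomic G+C;
    returns per-species signed deviation (observed - equilibrium) and
    absolute percent deviation.
    """
    if len(species_rates) != len(observed_gc):
        raise ValueError("species_rates and observed_gc must have equal length")
    out = []
    for s, gc in zip(species_rates, observed_gc):
        eq = gc_equilibrium_curve(s)
        deviation = gc - eq
        out.append(
            {
                "equilibrium_gc": eq,
                "observed_gc": float(gc),
                "deviation": deviation,
                "abs_percent_deviation": 100.0 * abs(deviation) / eq if eq > 0 else float("inf"),
            }
        )
    return out
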
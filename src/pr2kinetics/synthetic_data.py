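"""Synthetic genomes and labelled rate-set ensembles for offline testing.

Every pipeline stage — FASTA counting, skew/tolerance analysis, kinetic
evolution, NSB diagnostics and constraint scoring — can be exercised without
any genome download.  Genomes are i.i.d. (optionally first-order Markov)
random sequences whose expected base fractions realise a requested
(gc_content, gc_skew, at_skew) triple:

    C_G = gc (1 + gc_skew) / 2      C_C = gc (1 - gc_skew) / 2
    C_A = (1 - gc)(1 + at_skew) / 2  C_T = (1 - gc)(1 - at_skew) / 2

Rate ensembles come with ground-truth labels: exactly NSB-symmetric, NSB
rates perturbed by a controlled relative factor, sets solved to satisfy a
subset of the generalized constraint forms, or adversarial sets with large
strand-bias residuals.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constraint_eval import CONSTRAINT_FORMS
from .rate_model import BASES, NSB_PAIRS, RATE_KEYS, RateSet
from .sampling import SamplingScheme, sample_rate_vectors

__all__ = [
    "composition_from_targets",
    "make_genome",
    "write_fasta",
    "LabelledRateSet",
    "make_rate_ensemble",
]

ENSEMBLE_KINDS = ("nsb_exact", "nsb_perturbed", "constraint_conforming", "adversarial")


def composition_from_targets(gc_content: float, gc_skew: float, at_skew: float) -> np.ndarray:
    """Base probabilities (A, C, G, T) realising the target content and skews."""
    probs = np.array(
        [
            (1 - gc_content) * (1 + at_skew) / 2,  # A
            gc_content * (1 - gc_skew) / 2,        # C
            gc_content * (1 + gc_skew) / 2,        # G
            (1 - gc_content) * (1 - at_skew) / 2,  # T
        ]
    )
    if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 1e-9:
        raise ValueError(
            f"targets (gc={gc_content}, gc_skew={gc_skew}, at_skew={at_skew}) "
            "yield invalid base probabilities"
        )
    return probs


def make_genome(
    length: int,
    gc_content: float = 0.5,
    gc_skew: float = 0.0,
    at_skew: float = 0.0,
    seed: int = 1,
    markov_correlation: float = 0.0,
) -> str:
    """A random sequence with the requested expected composition.

    With ``markov_correlation`` r in [0, 1) the sequence is first-order
    Markov: each base repeats the previous one with probability r and is an
    independent draw otherwise, leaving the single-base marginals unchanged
    while correlating neighbours (useful for sliding-vs-segmentation dyad
    tests).  r = 0 gives the i.i.d. default.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= markov_correlation < 1):
        raise ValueError("markov_correlation must be in [0, 1)")
    probs = composition_from_targets(gc_content, gc_skew, at_skew)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.choice(4, size=length, p=probs)
    if markov_correlation > 0:
        repeat = rng.random(length) < markov_correlation
        repeat[0] = False
        for pos in np.flatnonzero(repeat):
            draws[pos] = draws[pos - 1]
    alphabet = np.array(list(BASES))
    return "".join(alphabet[draws])


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as a plain FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


@dataclass(frozen=True)
class LabelledRateSet:
    """A rate set with its generating kind and construction parameters."""

    rates: RateSet
    kind: str
    epsilon: float = 0.0
    conforming_targets: tuple[str, ...] = ()


def make_rate_ensemble(
    kind: str,
    n: int,
    seed: int = 1,
    epsilon: float = 0.1,
    conforming_targets: Sequence[str] = ("AG",),
    base_scheme: SamplingScheme | None = None,
) -> list[LabelledRateSet]:
    """Generate ``n`` labelled rate sets of the requested kind.

    - ``nsb_exact``: six symmetric draws expanded, so every NSB pair ratio is
      exactly 1.
    - ``nsb_perturbed``: exact sets whose pair members are multiplied by
      (1 + eps/2) and (1 - eps/2), bounding each pair ratio near
      (1 + eps/2)/(1 - eps/2).
    - ``constraint_conforming``: random sets re-solved so the chosen subset of
      constraint forms holds to ~1e-9 (a linear solve in the target rates);
      draws yielding negative solved rates are resampled and an error is
      raised if none succeed.
    - ``adversarial``: exact sets with one member of every pair scaled up
      tenfold, giving large strand-bias residuals.
    """
    if kind not in ENSEMBLE_KINDS:
        raise ValueError(f"kind must be one of {ENSEMBLE_KINDS}, got {kind!r}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if base_scheme is None:
        base_scheme = SamplingScheme(mode="truncnorm_symmetric", multiplier=1.0, seed=seed)

    if kind in ("nsb_exact", "nsb_perturbed", "adversarial"):
        scheme = SamplingScheme(mode="truncnorm_symmetric",
                                multiplier=base_scheme.multiplier, seed=seed)
        vectors = sample_rate_vectors(scheme, n)
        out = []
        for vec in vectors:
            rates = dict(zip(RATE_KEYS, vec))
            if kind == "nsb_perturbed":
                for a, b in NSB_PAIRS:
                    rates[a] *= 1 + epsilon / 2
                    rates[b] *= 1 - epsilon / 2
            elif kind == "adversarial":
                for a, _b in NSB_PAIRS:
                    rates[a] *= 10.0
            out.append(
                LabelledRateSet(RateSet(rates), kind,
                                epsilon=epsilon if kind == "nsb_perturbed" else 0.0)
            )
        return out

    # constraint_conforming
    targets = tuple(conforming_targets)
    unknown = set(targets) - set(CONSTRAINT_FORMS)
    if unknown:
        raise ValueError(f"unknown constraint targets {unknown}")
    scheme = SamplingScheme(mode="uniform_unconstrained",
                            multiplier=base_scheme.multiplier, seed=seed)
    out = []
    attempts = 0
    max_attempts = 200 * n
    draw_iter = iter(sample_rate_vectors(scheme, max_attempts))
    while len(out) < n:
        try:
            vec = next(draw_iter)
        except StopIteration:
            raise RuntimeError(
                f"constraint solve infeasible: produced {len(out)}/{n} non-negative "
                f"solutions in {max_attempts} attempts"
            )
        attempts += 1
        solved = _solve_conforming(vec, targets)
        if solved is not None:
            out.append(
                LabelledRateSet(RateSet.from_vector(solved), kind,
                                conforming_targets=targets)
            )
    return out


def _solve_conforming(vec: np.ndarray, targets: Sequence[str]) -> np.ndarray | None:
    """Solve the target rates so their constraint forms hold exactly.

    The forms are linear, so with non-target rates frozen this is a small
    linear system in the target rates.  Returns None if any solved rate is
    negative (infeasible draw).
    """
    idx = {code: i for i, code in enumerate(RATE_KEYS)}
    t_idx = [idx[t] for t in targets]
    A = np.eye(len(targets))
    b = np.zeros(len(targets))
    for row, t in enumerate(targets):
        coeffs, intercept = CONSTRAINT_FORMS[t].expanded()
        b[row] = intercept
        for u, c in coeffs.items():
            if u in targets:
                A[row, list(targets).index(u)] -= c
            else:
                b[row] += c * vec[idx[u]]
    try:
        solution = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    if np.any(solution < 0):
        return None
    out = vec.copy()
    out[t_idx] = solution
    return out
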
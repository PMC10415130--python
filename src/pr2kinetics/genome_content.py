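"""Base and dyad content counting from FASTA, with skew and tolerance utilities.

Counts are strand-specific: only the forward strand as recorded in the FASTA
is tallied (intra-strand parity is precisely a single-strand statement).
Case is ignored, so soft-masked (lowercase) stretches count identically to
unmasked sequence.  Ambiguity symbols (N and friends) are skipped and
tallied; a dyad spanning a skipped symbol is not counted, and dyad counting
restarts after it (the contiguous-segment rule), in both the sliding
(overlapping) and segmentation (non-overlapping, frame starting at the first
position of each contiguous segment) modes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dyad_kinetics import DYADS
from .pr2_metrics import SkewPair, ToleranceBox
from .rate_model import BASES

__all__ = [
    "GenomeCounts",
    "count_sequence",
    "count_genome",
    "genome_skews",
    "kingdom_tolerance",
    "deduplicate_species",
    "write_counts_table",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class GenomeCounts:
    """Exact base and dyad counts for one sequence (or a pooled set)."""

    sequence_id: str
    base_counts: Mapping[str, int]
    dyad_counts: Mapping[str, int]
    length: int
    skipped: int
    dyad_mode: str = "sliding"

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_counts", dict(self.base_counts))
        object.__setattr__(self, "dyad_counts", dict(self.dyad_counts))

    @property
    def counted_length(self) -> int:
        return self.length - self.skipped

    @property
    def gc_content(self) -> float:
        counted = self.counted_length
        return (self.base_counts["G"] + self.base_counts["C"]) / counted if counted else float("nan")

    def pooled_with(self, other: "GenomeCounts") -> "GenomeCounts":
        if self.dyad_mode != other.dyad_mode:
            raise ValueError("cannot pool counts from different dyad modes")
        return GenomeCounts(
            sequence_id=f"{self.sequence_id}+{other.sequence_id}",
            base_counts={b: self.base_counts[b] + other.base_counts[b] for b in BASES},
            dyad_counts={d: self.dyad_counts[d] + other.dyad_counts[d] for d in DYADS},
            length=self.length + other.length,
            skipped=self.skipped + other.skipped,
            dyad_mode=self.dyad_mode,
        )


def count_sequence(seq: str, sequence_id: str = "", dyad_mode: str = "sliding") -> GenomeCounts:
    """Count bases and dyads in one sequence string.

    ``dyad_mode`` is "sliding" (all overlapping dimers) or "segmentation"
    (non-overlapping dimers, frame restarting at each contiguous segment).
    """
    if dyad_mode not in ("sliding", "segmentation"):
        raise ValueError(f"dyad_mode must be 'sliding' or 'segmentation', got {dyad_mode!r}")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    base_counts = dict(zip(BASES, np.bincount(codes[valid], minlength=4).tolist()))
    dyad_counts = {d: 0 for d in DYADS}
    if codes.size >= 2:
        pair_valid = valid[:-1] & valid[1:]
        if dyad_mode == "segmentation" and valid.any():
            # keep every other valid pair within each contiguous valid run
            segment_starts = valid & np.concatenate([[True], ~valid[:-1]])
            run_id = np.cumsum(segment_starts) - 1
            position_in_run = np.arange(codes.size) - np.flatnonzero(segment_starts)[run_id]
            pair_valid = pair_valid & (position_in_run[:-1] % 2 == 0)
        pair_codes = codes[:-1][pair_valid] * 4 + codes[1:][pair_valid]
        counts = np.bincount(pair_codes, minlength=16)
        for i, d in enumerate(DYADS):
            dyad_counts[d] = int(counts[i])
    return GenomeCounts(
        sequence_id=sequence_id,
        base_counts=base_counts,
        dyad_counts=dyad_counts,
        length=int(codes.size),
        skipped=int((~valid).sum()),
        dyad_mode=dyad_mode,
    )


def _open_fasta(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_genome(
    fasta_path: str | Path, dyad_mode: str = "sliding"
) -> tuple[list[GenomeCounts], GenomeCounts]:
    """Count all records in a FASTA file (plain or gzip).

    Returns (per-record counts, pooled whole-file counts).  Raises on an
    unreadable or empty file; an empty record yields zero counts.
    """
    per_record: list[GenomeCounts] = []
    with _open_fasta(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            per_record.append(count_sequence(str(record.seq), record.id, dyad_mode))
    if not per_record:
        raise IOError(f"no FASTA records found in {fasta_path}")
    pooled = per_record[0]
    for counts in per_record[1:]:
        pooled = pooled.pooled_with(counts)
    pooled = GenomeCounts(
        sequence_id="pooled",
        base_counts=pooled.base_counts,
        dyad_counts=pooled.dyad_counts,
        length=pooled.length,
        skipped=pooled.skipped,
        dyad_mode=dyad_mode,
    )
    return per_record, pooled


def genome_skews(counts: GenomeCounts) -> SkewPair:
    """(gc_skew, at_skew) from integer counts; zero denominators are flagged."""
    g, c = counts.base_counts["G"], counts.base_counts["C"]
    a, t = counts.base_counts["A"], counts.base_counts["T"]
    degenerate = (g + c) == 0 or (a + t) == 0
    gc = (g - c) / (g + c) if g + c else 0.0
    at = (a - t) / (a + t) if a + t else 0.0
    return SkewPair(gc, at, degenerate)


def kingdom_tolerance(
    counts: Iterable[GenomeCounts], labels: Iterable[str]
) -> dict[str, ToleranceBox]:
    """Per-label skew tolerance boxes: mean +/- 1 sample sd of each skew axis.

    Requires at least two genomes per label; a label whose genomes all share
    identical skews has sd 0 and raises (a degenerate box has no width).
    """
    rows: dict[str, list[SkewPair]] = {}
    for c, label in zip(counts, labels):
        rows.setdefault(label, []).append(genome_skews(c))
    out = {}
    for label, pairs in rows.items():
        if len(pairs) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 genomes")
        gc = np.array([p.gc_skew for p in pairs])
        at = np.array([p.at_skew for p in pairs])
        gc_sd = float(gc.std(ddof=1))
        at_sd = float(at.std(ddof=1))
        if gc_sd == 0 or at_sd == 0:
            raise ValueError(f"label {label!r} has zero skew spread; box would be degenerate")
        out[label] = ToleranceBox(label, float(gc.mean()), gc_sd, float(at.mean()), at_sd)
    return out


def deduplicate_species(metadata: pd.DataFrame, species_column: str = "species") -> pd.DataFrame:
    """Keep the first occurring row per species name (cohort de-duplication)."""
    if species_column not in metadata.columns:
        raise ValueError(f"metadata lacks column {species_column!r}")
    return metadata.drop_duplicates(subset=species_column, keep="first").reset_index(drop=True)


def write_counts_table(counts: Iterable[GenomeCounts], path: str | Path) -> None:
    """Write per-record counts, skews and G+C content as TSV."""
    rows = []
    for c in counts:
        s = genome_skews(c)
        rows.append(
            {
                "sequence_id": c.sequence_id,
                **{f"n_{b}": c.base_counts[b] for b in BASES},
                "length": c.length,
                "skipped": c.skipped,
                "gc_content": c.gc_content,
                "gc_skew": s.gc_skew,
                "at_skew": s.at_skew,
                **{f"dyad_{d}": c.dyad_counts[d] for d in DYADS},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
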
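"""Sequence-divergence metrics computed from a gapped pairwise alignment.

Five variables summarize how far two aligned protein sequences have
diverged:

* **PNI** — percent sequence non-identity, ``(1 - N_iden/N_algn) * 100``;
* **SNG** — standardized number of gaps, ``100 * N_gap / N_algn``, where a
  "gap" is one maximal run of ``'-'`` in either row regardless of length;
* **PNS** — percent sequence non-similarity, ``100 * N_ns / N_algn``, where
  a column is non-similar when its residue pair scores zero or negative in
  the BLOSUM45 matrix;
* **LSNG** — length-weighted SNG, ``(100/N_algn) * sum_i N_i * a_i``, with
  ``N_i`` the number of gap runs of length ``i`` and ``a_i`` the relative
  flank-shift weight of a length-``i`` indel (see
  :mod:`strucdiv.indel_weight`);
* **PC** — Poisson-correction distance, ``-ln(1 - PNI/100)``, correcting
  percent non-identity for multiple substitutions per site.

``N_algn`` counts columns with residues in both rows; gap columns never
contribute. Gap runs touching the alignment termini are counted like
internal ones, since the alignment covers only the matched region of two
domains. Columns containing an ambiguous residue (B, Z, X, U, O, J) count
toward ``N_algn`` but are classified non-identical and non-similar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

from Bio.Align import substitution_matrices

from .alignment_model import GAP, STANDARD_AA, AlignedPair
from .errors import UndefinedMetricError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .indel_weight import IndelWeightModel

DEFAULT_MATRIX_NAME = "BLOSUM45"


def load_substitution_matrix(source: str | Path = DEFAULT_MATRIX_NAME):
    """Load a substitution score matrix.

    ``source`` is either the name of a matrix distributed with Biopython
    (default ``"BLOSUM45"``) or a path to a file in NCBI square-matrix text
    format.
    """
    source = str(source)
    if Path(source).is_file():
        return substitution_matrices.read(source)
    return substitution_matrices.load(source)


@dataclass(frozen=True)
class SequenceSimilarity:
    """The five divergence metrics of one aligned pair.

    Invariants: ``pns <= pni`` (identical pairs score positively in
    BLOSUM45, so non-similar implies non-identical); ``lsng >= sng`` (all
    gap-length weights are >= 1); ``pc >= pni/100`` (convexity of
    ``-ln(1-p)``).
    """

    pni: float
    sng: float
    pns: float
    lsng: float
    pc: float


@dataclass(frozen=True)
class GapRun:
    """One maximal run of gap characters in one alignment row."""

    row: str  # "a" or "b"
    start: int  # 0-based column index
    length: int

    def __post_init__(self) -> None:
        if self.row not in ("a", "b"):
            raise ValidationError(f"gap-run row must be 'a' or 'b', got {self.row!r}")
        if self.length < 1:
            raise ValidationError(f"gap-run length must be >= 1, got {self.length}")


def _runs_in_row(seq: str, label: str) -> list[GapRun]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append(GapRun(label, start, i - start))
            start = None
    if start is not None:
        runs.append(GapRun(label, start, len(seq) - start))
    return runs


def gap_runs(pair: AlignedPair) -> list[GapRun]:
    """All maximal gap runs in either row, sorted by (row, start).

    Terminal runs are included. The run count is the alignment's ``N_gap``.
    """
    return _runs_in_row(pair.row_a, "a") + _runs_in_row(pair.row_b, "b")


def _aligned_columns(pair: AlignedPair) -> list[tuple[str, str]]:
    cols = [
        (ca, cb)
        for ca, cb in zip(pair.row_a, pair.row_b)
        if ca != GAP and cb != GAP
    ]
    if not cols:
        raise UndefinedMetricError("no aligned columns; metrics undefined")
    return cols


def compute_pni(pair: AlignedPair) -> float:
    """Percent sequence non-identity: ``(1 - N_iden/N_algn) * 100``.

    A column is identical only when both residues are the same standard
    amino acid.
    """
    cols = _aligned_columns(pair)
    n_iden = sum(1 for ca, cb in cols if ca == cb and ca in STANDARD_AA)
    # algebraically (1 - N_iden/N_algn)*100; the subtraction-first form keeps
    # the result an exact ratio of integers times 100
    return 100.0 * (len(cols) - n_iden) / len(cols)


def compute_sng(pair: AlignedPair) -> float:
    """Standardized number of gaps: ``100 * N_gap / N_algn``.

    Counts gap runs irrespective of their length.
    """
    n_algn = len(_aligned_columns(pair))
    return 100.0 * len(gap_runs(pair)) / n_algn


def _column_is_nonsimilar(ca: str, cb: str, matrix) -> bool:
    if ca not in STANDARD_AA or cb not in STANDARD_AA:
        # ambiguity policy: ambiguous residues are conservatively non-similar
        return True
    return matrix[ca, cb] <= 0


def compute_pns(pair: AlignedPair, matrix=None) -> float:
    """Percent sequence non-similarity: ``100 * N_ns / N_algn``.

    ``N_ns`` counts aligned columns whose residue pair scores zero or
    negative in ``matrix`` (BLOSUM45 by default).
    """
    if matrix is None:
        matrix = load_substitution_matrix()
    cols = _aligned_columns(pair)
    n_ns = sum(1 for ca, cb in cols if _column_is_nonsimilar(ca, cb, matrix))
    return 100.0 * n_ns / len(cols)


def compute_lsng(pair: AlignedPair, weights: "IndelWeightModel") -> float:
    """Length-weighted gap density: ``(100/N_algn) * sum_i N_i * a_i``.

    Each gap run of length L contributes the weight ``a_L = f(L)/f(1)`` of
    the fitted flank-shift curve; a run of length 1 contributes exactly 1,
    so LSNG >= SNG always.
    """
    n_algn = len(_aligned_columns(pair))
    # summing in sorted-length order makes the value exactly symmetric
    # under row exchange
    lengths = sorted(run.length for run in gap_runs(pair))
    total = sum(weights.weight(L) for L in lengths)
    return 100.0 * total / n_algn


def compute_pc(pni: float) -> float:
    """Poisson-correction distance ``-ln(1 - PNI/100)`` (substitutions/site)."""
    if not 0.0 <= pni < 100.0:
        raise UndefinedMetricError(
            f"Poisson correction requires 0 <= PNI < 100, got {pni} (saturated)"
        )
    return -math.log(1.0 - pni / 100.0)


def compute_all_metrics(
    pair: AlignedPair, matrix=None, weights: "IndelWeightModel | None" = None
) -> SequenceSimilarity:
    """All five metrics of one pair, consistent with the single-metric calls.

    Without a weight model, LSNG falls back to unit weights (i.e. SNG).
    """
    if matrix is None:
        matrix = load_substitution_matrix()
    pni = compute_pni(pair)
    sng = compute_sng(pair)
    pns = compute_pns(pair, matrix)
    lsng = compute_lsng(pair, weights) if weights is not None else sng
    return SequenceSimilarity(pni=pni, sng=sng, pns=pns, lsng=lsng, pc=compute_pc(pni))
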
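"""Domain types and file I/O for pairwise structure-alignment data.

The analysis consumes four kinds of input:

* pairwise structure-alignment record tables (TSV) summarizing each
  structural comparison: RMSD (Å), Z-score, P-score, aligned-residue count
  and SCOP-style superfamily/family labels;
* structure-based pairwise sequence alignments (2-record gapped FASTA);
* genome-presence matrices (superfamily x genome booleans with a
  domain-of-life label per genome) plus per-domain structure metadata;
* indel-flank samples (indel length L, flank RMSD) used to fit the
  gap-length weight curve.

All tables are UTF-8 TSV with a header row; floats use '.' as the decimal
separator and are written at full round-trip precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, RowError, SchemaError, ValidationError

#: The 20 standard amino acids (one-letter codes).
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguous / non-standard residue codes tolerated in alignments.
AMBIGUOUS_AA = frozenset("BZXUOJ")

GAP = "-"

#: First five SCOP structural classes: all-alpha, all-beta, alpha/beta
#: (parallel beta sheets), alpha+beta (segregated), multi-domain (alpha&beta).
SCOP_CLASSES = ("a", "b", "c", "d", "e")

DOMAINS_OF_LIFE = ("eukaryote", "bacterium", "archaeon")

ALIGNMENT_TABLE_COLUMNS = (
    "id_a",
    "id_b",
    "superfamily",
    "family_a",
    "family_b",
    "rmsd",
    "z_score",
    "p_score",
    "n_algn",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped sequences from one pairwise alignment.

    Rows are strings over the amino-acid alphabet plus ``'-'``. No column may
    be gapped in both rows, and at least one column must hold residues in
    both rows (otherwise every divergence metric is undefined).
    """

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValidationError(
                f"aligned rows differ in length: {len(self.row_a)} vs {len(self.row_b)}"
            )
        if len(self.row_a) == 0:
            raise ValidationError("empty alignment")
        allowed = STANDARD_AA | AMBIGUOUS_AA | {GAP}
        for name, row in (("row_a", self.row_a), ("row_b", self.row_b)):
            bad = set(row) - allowed
            if bad:
                raise ValidationError(f"{name} contains invalid symbols: {sorted(bad)}")
        n_aligned = 0
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValidationError("column gapped in both rows")
            if ca != GAP and cb != GAP:
                n_aligned += 1
        if n_aligned == 0:
            raise ValidationError("alignment has no column with residues in both rows")

    def __len__(self) -> int:
        return len(self.row_a)

    @property
    def n_aligned_columns(self) -> int:
        """Number of columns holding residues in both rows (N_algn)."""
        return sum(
            1 for ca, cb in zip(self.row_a, self.row_b) if ca != GAP and cb != GAP
        )

    def swapped(self) -> "AlignedPair":
        """The same alignment with the two rows exchanged."""
        return AlignedPair(self.id_b, self.id_a, self.row_b, self.row_a)


@dataclass
class AlignmentRecord:
    """One pairwise structural comparison between two protein domains.

    ``rmsd`` is the root mean square deviation of superposed C-alpha
    positions in Å; ``z_score`` the Gaussian-statistics significance of the
    structural match; ``p_score`` the negative log10 of the alignment
    P-value (may be <= 0); ``n_algn`` the number of aligned residue pairs
    (gap columns excluded).
    """

    id_a: str
    id_b: str
    superfamily_id: str
    family_a: str
    family_b: str
    rmsd: float
    z_score: float
    p_score: float
    n_algn: int
    pair: AlignedPair | None = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValidationError(f"self-comparison record: {self.id_a}")
        if self.rmsd < 0:
            raise ValidationError(f"rmsd must be >= 0, got {self.rmsd}")
        if self.z_score < 0:
            raise ValidationError(f"z_score must be >= 0, got {self.z_score}")
        if self.n_algn < 1:
            raise ValidationError(f"n_algn must be >= 1, got {self.n_algn}")
        if self.pair is not None and self.pair.n_aligned_columns != self.n_algn:
            raise ValidationError(
                f"n_algn={self.n_algn} does not match the pair's "
                f"{self.pair.n_aligned_columns} aligned columns"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """Structure metadata for one SCOP domain."""

    domain_id: str
    superfamily_id: str
    family_id: str
    scop_class: str
    method: str

    def __post_init__(self) -> None:
        if self.scop_class not in SCOP_CLASSES:
            raise ValidationError(
                f"scop_class must be one of {SCOP_CLASSES}, got {self.scop_class!r}"
            )
        if self.method not in ("xray", "other"):
            raise ValidationError(f"method must be 'xray' or 'other', got {self.method!r}")


@dataclass
class PresenceMatrix:
    """Boolean superfamily x genome occurrence matrix.

    Every genome carries a domain-of-life label (eukaryote / bacterium /
    archaeon); ancient-superfamily selection thresholds the presence
    fraction within each of the three groups separately.
    """

    superfamily_ids: list[str]
    genome_ids: list[str]
    domain_of_life: list[str]
    present: np.ndarray  # bool, shape (n_superfamilies, n_genomes)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.superfamily_ids), len(self.genome_ids)):
            raise ValidationError(
                f"presence matrix shape {self.present.shape} does not match "
                f"{len(self.superfamily_ids)} superfamilies x {len(self.genome_ids)} genomes"
            )
        if len(self.domain_of_life) != len(self.genome_ids):
            raise ValidationError("one domain-of-life label required per genome")
        for label in self.domain_of_life:
            if label not in DOMAINS_OF_LIFE:
                raise ValidationError(
                    f"unknown domain-of-life label {label!r}; expected one of {DOMAINS_OF_LIFE}"
                )

    def presence_fraction(self, superfamily_id: str, domain: str) -> float:
        """Fraction of genomes of one domain of life containing the superfamily."""
        i = self.superfamily_ids.index(superfamily_id)
        mask = np.array([d == domain for d in self.domain_of_life])
        if not mask.any():
            raise ValidationError(f"no genomes labelled {domain!r}")
        return float(self.present[i, mask].mean())


@dataclass(frozen=True)
class IndelFlankSample:
    """One (indel length L, flank-region RMSD) observation."""

    length: int
    rmsd: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"indel length must be >= 1, got {self.length}")
        if self.rmsd < 0:
            raise ValidationError(f"flank rmsd must be >= 0, got {self.rmsd}")


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_float(value: str, column: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {column}={value!r} as a number", line=line) from None


def _parse_int(value: str, column: str, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {column}={value!r} as an integer", line=line) from None


# ---------------------------------------------------------------------------
# Alignment-record tables
# ---------------------------------------------------------------------------


def read_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    """Read a TSV of pairwise structural-alignment records.

    The header must name the nine schema columns
    ``id_a id_b superfamily family_a family_b rmsd z_score p_score n_algn``.
    Row order is preserved. Raises :class:`SchemaError` for a missing
    column, :class:`RowError` (with the 1-based file line) for an
    unparsable numeric cell, and :class:`ValidationError` for an invariant
    violation such as a negative RMSD.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ALIGNMENT_TABLE_COLUMNS, path)
    records: list[AlignmentRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        records.append(
            AlignmentRecord(
                id_a=row.id_a,
                id_b=row.id_b,
                superfamily_id=row.superfamily,
                family_a=row.family_a,
                family_b=row.family_b,
                rmsd=_parse_float(row.rmsd, "rmsd", line),
                z_score=_parse_float(row.z_score, "z_score", line),
                p_score=_parse_float(row.p_score, "p_score", line),
                n_algn=_parse_int(row.n_algn, "n_algn", line),
            )
        )
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records as TSV in the fixed nine-column schema order.

    Floats are written with :func:`repr`, i.e. the shortest decimal string
    that round-trips exactly (always at least the value's full precision).
    """
    path = Path(path)
    lines = ["\t".join(ALIGNMENT_TABLE_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.id_a,
                    r.id_b,
                    r.superfamily_id,
                    r.family_a,
                    r.family_b,
                    repr(float(r.rmsd)),
                    repr(float(r.z_score)),
                    repr(float(r.p_score)),
                    str(int(r.n_algn)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Aligned pairs (pairwise FASTA)
# ---------------------------------------------------------------------------


def read_aligned_pair(path: str | Path) -> AlignedPair:
    """Read a pairwise-aligned FASTA file with exactly two equal-length records.

    Sequence IDs are the FASTA headers up to the first whitespace.
    """
    path = Path(path)
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if len(seqs) != 2:
        raise FormatError(f"{path}: expected exactly 2 FASTA records, found {len(seqs)}")
    a, b = seqs
    if len(a.seq) != len(b.seq):
        raise FormatError(
            f"{path}: aligned rows differ in length ({len(a.seq)} vs {len(b.seq)})"
        )
    return AlignedPair(a.id, b.id, str(a.seq).upper(), str(b.seq).upper())


def write_aligned_pair(pair: AlignedPair, path: str | Path) -> None:
    """Write an AlignedPair as 2-record gapped FASTA."""
    records = [
        SeqRecord(Seq(pair.row_a), id=pair.id_a, description=""),
        SeqRecord(Seq(pair.row_b), id=pair.id_b, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Presence matrices
# ---------------------------------------------------------------------------


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a superfamily x genome presence table.

    Layout: header row ``superfamily<TAB>genome ids...``; second row
    ``domain_of_life<TAB>labels...``; then one 0/1 row per superfamily.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "superfamily":
        raise SchemaError(f"{path}: first column must be 'superfamily'")
    if len(df) == 0 or df.iloc[0, 0] != "domain_of_life":
        raise SchemaError(f"{path}: second file line must carry the domain_of_life labels")
    genome_ids = list(df.columns[1:])
    domain_of_life = [str(x) for x in df.iloc[0, 1:]]
    body = df.iloc[1:]
    superfamily_ids = [str(x) for x in body.iloc[:, 0]]
    present = np.zeros((len(superfamily_ids), len(genome_ids)), dtype=bool)
    for i, (_, row) in enumerate(body.iterrows()):
        for j, genome in enumerate(genome_ids):
            cell = row[genome]
            if cell not in ("0", "1"):
                raise RowError(
                    f"presence cell must be 0 or 1, got {cell!r}", line=i + 3
                )
            present[i, j] = cell == "1"
    return PresenceMatrix(superfamily_ids, genome_ids, domain_of_life, present)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(["superfamily", *matrix.genome_ids])]
    lines.append("\t".join(["domain_of_life", *matrix.domain_of_life]))
    for i, sf in enumerate(matrix.superfamily_ids):
        lines.append("\t".join([sf, *("1" if v else "0" for v in matrix.present[i])]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Indel-flank samples
# ---------------------------------------------------------------------------


def read_flank_samples(path: str | Path) -> list[IndelFlankSample]:
    """Read (length, rmsd) flank-shift samples from TSV with those headers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("length", "rmsd"), path)
    samples = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        samples.append(
            IndelFlankSample(
                length=_parse_int(row.length, "length", line),
                rmsd=_parse_float(row.rmsd, "rmsd", line),
            )
        )
    return samples


def write_flank_samples(samples: Iterable[IndelFlankSample], path: str | Path) -> None:
    path = Path(path)
    lines = ["length\trmsd"]
    for s in samples:
        lines.append(f"{s.length}\t{repr(float(s.rmsd))}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("domain_id", "superfamily", "family", "scop_class", "method")


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Read per-domain metadata (superfamily, family, SCOP class, method)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    return [
        DomainAnnotation(
            domain_id=row.domain_id,
            superfamily_id=row.superfamily,
            family_id=row.family,
            scop_class=row.scop_class,
            method=row.method,
        )
        for row in df.itertuples(index=False)
    ]


def write_domain_annotations(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> None:
    path = Path(path)
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for a in annotations:
        lines.append(
            "\t".join([a.domain_id, a.superfamily_id, a.family_id, a.scop_class, a.method])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
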
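"""Species-paired multiple sequence alignments.

Each chain brings its own MSA whose first record is the query. After
reading, the alignment is reduced to the query's match columns, so MSA
column index equals query position throughout the package. One
representative row is kept per species (highest ungapped identity to the
query, first occurrence on ties). Two MSAs are paired on their shared
species; rows covering less than 50% of either protein's surface
positions are excluded, and surface/interface columns with more than 50%
gaps among the remaining rows are dropped from scoring.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

from ._alphabet import encode_rows
from .errors import MsaFormatError, NoPairedRowsError, NoSpeciesLabelsError

DEFAULT_SPECIES_REGEX = r"OX=(\d+)"
QUERY_SENTINEL = "__query__"
GAP_CHARS = set("-.")


@dataclass
class SpeciesMSA:
    """One protein's alignment with a single representative per species.

    ``sequences`` are aligned to query coordinates: every row has the
    same length as ``query_sequence`` and column *i* is query position
    *i*. The query itself is row 0 with identity 1.0.
    """

    query_sequence: str
    species: list[str]
    sequences: list[str]
    identities: list[float]
    n_unlabeled: int = 0

    @property
    def depth(self) -> int:
        return len(self.species)

    def row_for(self, species_id: str) -> str:
        return self.sequences[self.species.index(species_id)]


@dataclass
class PairedMSA:
    """Species-matched concatenation of two alignments.

    Column provenance: columns ``0..len1-1`` are protein 1 query
    positions, columns ``len1..len1+len2-1`` are protein 2 positions.
    ``dropped_columns`` holds ``(protein, query_position)`` pairs removed
    by the gap filter; their metric contributions are skipped downstream.
    """

    rows: list[tuple[str, str, str]]  # (species, seq1, seq2)
    len1: int
    len2: int
    dropped_columns: set[tuple[int, int]] = field(default_factory=set)
    matrix: np.ndarray = field(default=None, repr=False)  # (n, len1+len2) uint8

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = encode_rows([s1 + s2 for _, s1, s2 in self.rows])

    @property
    def n_msa(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return self.len1 + self.len2

    @property
    def column_provenance(self) -> list[tuple[int, int]]:
        return [(1, q) for q in range(self.len1)] + [
            (2, q) for q in range(self.len2)
        ]

    def column_index(self, protein: int, query_pos: int) -> int:
        length = self.len1 if protein == 1 else self.len2
        if not 0 <= query_pos < length:
            raise IndexError(
                f"query position {query_pos} out of range for protein {protein}"
            )
        return query_pos if protein == 1 else self.len1 + query_pos

    def is_retained(self, protein: int, query_pos: int) -> bool:
        return (protein, query_pos) not in self.dropped_columns

    def to_fasta(self) -> str:
        """Concatenated paired alignment with species prefixes."""
        out = []
        for sp, s1, s2 in self.rows:
            out.append(f">{sp}|paired\n{s1}{s2}")
        return "\n".join(out) + "\n"


def _read_records(
    source: str | Path | IO[str], fmt: str
) -> list[tuple[str, str]]:
    fmt = fmt.lower()
    try:
        if fmt == "stockholm":
            aln = AlignIO.read(source, "stockholm")
            return [(rec.description or rec.id, str(rec.seq)) for rec in aln]
        if fmt in ("fasta", "a3m"):
            recs = list(SeqIO.parse(source, "fasta"))
            return [(rec.description or rec.id, str(rec.seq)) for rec in recs]
    except (ValueError, OSError) as exc:
        raise MsaFormatError(f"cannot read {fmt} alignment: {exc}") from exc
    raise MsaFormatError(f"unknown MSA format: {fmt!r}")


def _strip_a3m_inserts(seq: str) -> str:
    # lowercase letters are insert states relative to the query; '.' is
    # an insert gap — both are removed so rows align to match columns
    return "".join(c for c in seq if not (c.islower() or c == "."))


def _identity(row: str, query: str) -> float:
    n = sum(a == b for a, b in zip(row, query) if b not in GAP_CHARS)
    return n / len(query)


def read_msa(
    msa_file: str | Path | IO[str],
    format: str = "fasta",
    species_regex: str = DEFAULT_SPECIES_REGEX,
) -> SpeciesMSA:
    """Read an alignment and keep one representative row per species.

    The first record is the query. Headers are matched against
    ``species_regex`` (first capture group = species label); non-query
    rows without a label are dropped and counted. Representative per
    species: highest ungapped identity to the query, first in file on
    ties.
    """
    records = _read_records(msa_file, format)
    if not records:
        raise MsaFormatError("alignment contains no sequences")
    if format.lower() == "a3m":
        records = [(h, _strip_a3m_inserts(s)) for h, s in records]
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise MsaFormatError("alignment rows have inconsistent lengths")

    query_header, query_row = records[0]
    keep_cols = [i for i, c in enumerate(query_row) if c not in GAP_CHARS]
    if not keep_cols:
        raise MsaFormatError("query row is all gaps")

    def reduce(seq: str) -> str:
        return "".join(seq[i].upper() for i in keep_cols)

    query = reduce(query_row)
    pattern = re.compile(species_regex)

    rows: list[tuple[str, str, float]] = []  # (species, seq, identity)
    n_unlabeled = 0
    for k, (header, seq) in enumerate(records):
        m = pattern.search(header)
        if m is None:
            if k == 0:
                species = QUERY_SENTINEL
            else:
                n_unlabeled += 1
                continue
        else:
            species = m.group(1)
        reduced = reduce(seq)
        ident = 1.0 if k == 0 else _identity(reduced, query)
        rows.append((species, reduced, ident))

    if len(records) > 1 and n_unlabeled == len(records) - 1 and pattern.search(
        query_header
    ) is None:
        raise NoSpeciesLabelsError(
            "no species labels: species_regex matched no header"
        )

    best: dict[str, tuple[str, float]] = {}
    order: list[str] = []
    for species, seq, ident in rows:
        if species not in best:
            best[species] = (seq, ident)
            order.append(species)
        elif ident > best[species][1]:
            best[species] = (seq, ident)

    return SpeciesMSA(
        query_sequence=query,
        species=order,
        sequences=[best[s][0] for s in order],
        identities=[best[s][1] for s in order],
        n_unlabeled=n_unlabeled,
    )


def _coverage(seq: str, positions: Sequence[int]) -> float:
    if len(positions) == 0:
        return 1.0
    ok = sum(seq[p] not in GAP_CHARS for p in positions)
    return ok / len(positions)


def _gap_filter(
    rows: list[tuple[str, str, str]],
    len1: int,
    len2: int,
    scope1: Sequence[int],
    scope2: Sequence[int],
) -> set[tuple[int, int]]:
    """Columns (within scope) whose gap fraction exceeds 50%."""
    dropped: set[tuple[int, int]] = set()
    if not rows:
        return dropped
    n = len(rows)
    for protein, scope, getter in (
        (1, scope1, lambda r: r[1]),
        (2, scope2, lambda r: r[2]),
    ):
        for q in scope:
            gaps = sum(getter(r)[q] in GAP_CHARS for r in rows)
            if gaps / n > 0.5:
                dropped.add((protein, q))
    return dropped


def pair_msas(
    msa1: SpeciesMSA,
    msa2: SpeciesMSA,
    surface1: Iterable[int] | None = None,
    surface2: Iterable[int] | None = None,
) -> PairedMSA:
    """Pair two alignments on shared species and apply the 50% filters.

    ``surface1``/``surface2`` are query positions (surface plus
    interface residues). A row is kept iff it covers at least 50% of the
    surface positions of *both* proteins; afterwards any in-scope column
    with more than 50% gaps among kept rows is dropped. Without surface
    sets, coverage and gap scope default to all query positions.
    """
    scope1 = sorted(surface1) if surface1 is not None else list(
        range(len(msa1.query_sequence))
    )
    scope2 = sorted(surface2) if surface2 is not None else list(
        range(len(msa2.query_sequence))
    )
    idx2 = {s: i for i, s in enumerate(msa2.species)}
    rows: list[tuple[str, str, str]] = []
    for i, sp in enumerate(msa1.species):
        j = idx2.get(sp)
        if j is None:
            continue
        s1, s2 = msa1.sequences[i], msa2.sequences[j]
        if _coverage(s1, scope1) >= 0.5 and _coverage(s2, scope2) >= 0.5:
            rows.append((sp, s1, s2))
    if not rows:
        raise NoPairedRowsError("no paired rows: empty species intersection")
    dropped = _gap_filter(
        rows, len(msa1.query_sequence), len(msa2.query_sequence), scope1, scope2
    )
    return PairedMSA(
        rows=rows,
        len1=len(msa1.query_sequence),
        len2=len(msa2.query_sequence),
        dropped_columns=dropped,
    )


def pair_homodimer(
    msa: SpeciesMSA, surface: Iterable[int] | None = None
) -> PairedMSA:
    """Self-pairing for homodimers: each row is paired with itself.

    Depth equals the row-filtered MSA depth; the same coverage and
    column-gap filters apply. ``surface`` should contain the union of
    surface/interface positions of both chains (same query coordinates).
    """
    scope = sorted(surface) if surface is not None else list(
        range(len(msa.query_sequence))
    )
    rows = [
        (sp, seq, seq)
        for sp, seq in zip(msa.species, msa.sequences)
        if _coverage(seq, scope) >= 0.5
    ]
    if not rows:
        raise NoPairedRowsError("no paired rows: all rows below coverage")
    dropped = _gap_filter(
        rows, len(msa.query_sequence), len(msa.query_sequence), scope, scope
    )
    return PairedMSA(
        rows=rows,
        len1=len(msa.query_sequence),
        len2=len(msa.query_sequence),
        dropped_columns=dropped,
    )
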
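"""Readers/writers for the formats the pipeline touches.

FASTA handling is built on Biopython's SeqIO; tabular inputs go through
pandas with an explicit column schema. Secondary-structure strings use the
standard dot-bracket notation: '(' opens a base pair, ')' closes it, '.'
marks an unpaired base. Only pseudoknot-free (purely nested) structures
are accepted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the expected format; message names the offender."""


class StructureError(ValueError):
    """A dot-bracket string is unbalanced, crossing, or empty."""


class SchemaError(ValueError):
    """A tabular file does not match the declared column schema."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with its declared alphabet.

    Sequences are stored uppercase. ``alphabet`` is ``"rna"`` (A/C/G/U,
    as in miRBase mature entries) or ``"dna"`` (A/C/G/T/N, as in ESTs).
    """

    id: str
    sequence: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.alphabet not in ("rna", "dna"):
            raise FormatError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        allowed = RNA_ALPHABET if self.alphabet == "rna" else DNA_ALPHABET
        seq = self.sequence.upper()
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                f"for alphabet {self.alphabet}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def as_rna(self) -> "SequenceRecord":
        if self.alphabet == "rna":
            return self
        return SequenceRecord(
            self.id, self.sequence.replace("T", "U"), "rna", self.description
        )

    def as_dna(self) -> "SequenceRecord":
        if self.alphabet == "dna":
            return self
        return SequenceRecord(
            self.id, self.sequence.replace("U", "T"), "dna", self.description
        )


@dataclass(frozen=True)
class DotBracket:
    """A validated pseudoknot-free secondary structure string."""

    structure: str
    pairs: tuple = field(default=())

    @property
    def length(self) -> int:
        return len(self.structure)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_table(self) -> dict:
        """Map 0-based position -> 0-based partner for every paired base."""
        table = {}
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table


def validate_dotbracket(s: str) -> DotBracket:
    """Validate a dot-bracket string, reporting the first violation.

    Raises :class:`StructureError` on empty input, characters outside
    ``(.)``, or unbalanced brackets. Nested brackets cannot cross by
    construction of the stack check, so any balanced string is accepted.
    """
    if not s:
        raise StructureError("empty structure string")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(s):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"illegal character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[0]}")
    return DotBracket(s, tuple(sorted(pairs)))


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "rna":
        return seq.replace("T", "U")
    return seq.replace("U", "T")


def read_fasta(path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``alphabet`` may be ``"rna"``, ``"dna"`` or ``"auto"`` (detect from
    the presence of U vs T over the whole file; ambiguous files default
    to dna). U<->T are normalized to the declared alphabet and lowercase
    is uppercased. Duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FormatError(f"{path}: empty or not FASTA")
    if alphabet == "auto":
        joined = "".join(str(r.seq).upper() for r in raw)
        alphabet = "rna" if ("U" in joined and "T" not in joined) else "dna"
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for r in raw:
        if r.id in seen:
            raise FormatError(f"{path}: duplicate id {r.id!r}")
        seen.add(r.id)
        desc = r.description[len(r.id):].strip() if r.description else ""
        try:
            records.append(
                SequenceRecord(r.id, _normalize(str(r.seq), alphabet), alphabet, desc)
            )
        except FormatError as e:
            raise FormatError(f"{path}: {e}") from e
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a header-carrying TSV and coerce columns to a schema.

    ``schema`` maps column name -> dtype (``float``, ``int`` or ``str``).
    Missing columns, unparseable cells and missing numeric cells raise
    :class:`SchemaError` naming the row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: cannot parse TSV ({e})") from e
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = {}
    for col, dtype in schema.items():
        series = df[col]
        if dtype is str:
            if series.isna().any():
                row = int(series.isna().idxmax())
                raise SchemaError(f"{path}: empty cell at row {row}, column {col!r}")
            out[col] = series
            continue
        coerced = pd.to_numeric(series, errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            bad = series.iloc[row]
            raise SchemaError(
                f"{path}: unparseable value {bad!r} at row {row}, column {col!r}"
            )
        out[col] = coerced.astype(dtype)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def records_to_fasta_str(records: Sequence[SequenceRecord]) -> str:
    buf = io.StringIO()
    for r in records:
        header = f">{r.id} {r.description}".strip()
        buf.write(header + "\n")
        for i in range(0, len(r.sequence), 60):
            buf.write(r.sequence[i:i + 60] + "\n")
    return buf.getvalue()
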
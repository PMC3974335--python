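"""Sequence containers and FASTA / Stockholm / TSV input-output.

A family is a named, ordered collection of protein sequences
(:class:`FamilyDataset`); it is the unit every other module operates on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from ._scoring import AA_X

logger = logging.getLogger(__name__)

_ALPHABET = set(AA_X)
#: Ambiguity / non-standard codes accepted on input and mapped to X.
_AMBIGUOUS = set("BZJUO")
_STRIP = set("*-.")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter alphabet plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class FamilyDataset:
    """Ordered, uniquely identified members of one protein family."""

    family_id: str
    members: list[ProteinSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")
        seen: set[str] = set()
        for m in self.members:
            if m.id in seen:
                raise ValueError(f"duplicate sequence id {m.id!r}")
            seen.add(m.id)
        self._index = {m.id: m for m in self.members}

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def mean_length(self) -> float:
        return sum(m.length for m in self.members) / len(self.members)

    def get(self, seq_id: str) -> ProteinSequence:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.members)

    def subset(self, ids: Iterable[str], family_id: str | None = None) -> "FamilyDataset":
        """New dataset restricted to ``ids``, in the given order."""
        return FamilyDataset(
            family_id or self.family_id, [self._index[i] for i in ids]
        )


def clean_residues(raw: str, seq_id: str = "?") -> str:
    """Uppercase, strip gap/stop characters, map ambiguity codes to X."""
    out: list[str] = []
    mapped: set[str] = set()
    for ch in raw.upper():
        if ch in _STRIP or ch.isspace():
            continue
        if ch in _AMBIGUOUS:
            mapped.add(ch)
            ch = "X"
        if ch not in _ALPHABET:
            raise ValueError(f"sequence {seq_id!r}: invalid residue {ch!r}")
        out.append(ch)
    if mapped:
        logger.warning(
            "sequence %s: mapped ambiguous residue(s) %s to X",
            seq_id, ",".join(sorted(mapped)),
        )
    return "".join(out)


def read_fasta(
    path: str | Path,
    family_id: str | None = None,
    allow_empty: bool = False,
) -> FamilyDataset | None:
    """Read a multi-FASTA file into a :class:`FamilyDataset`.

    The id token is the header up to the first whitespace. Lowercase
    letters are uppercased, ``*`` and gap characters stripped, ambiguity
    codes (B, Z, J, U, O) mapped to X with a logged warning.

    With ``allow_empty=True`` an empty file returns ``None`` instead of
    raising (used by the query-scan path).
    """
    path = Path(path)
    members: list[ProteinSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        token = record.id
        if token in seen:
            raise ValueError(f"duplicate FASTA header token {token!r}")
        seen.add(token)
        members.append(ProteinSequence(token, clean_residues(str(record.seq), token)))
    if not members:
        if allow_empty:
            return None
        raise ValueError(f"no sequences in {path}")
    return FamilyDataset(family_id or path.stem, members)


def write_fasta(dataset: FamilyDataset | Sequence[ProteinSequence], path: str | Path) -> Path:
    """Write sequences as FASTA, 60 residues per line."""
    members = list(dataset.members if isinstance(dataset, FamilyDataset) else dataset)
    if not members:
        raise ValueError("nothing to write")
    path = Path(path)
    with open(path, "w") as fh:
        for m in members:
            fh.write(f">{m.id}\n")
            for i in range(0, m.length, 60):
                fh.write(m.residues[i : i + 60] + "\n")
    return path


def write_stockholm(
    alignment: Sequence[tuple[str, str]], path: str | Path
) -> Path:
    """Write (id, aligned-row) pairs as minimal Stockholm 1.0."""
    rows = list(alignment)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0][1])
    for name, row in rows:
        if len(row) != width:
            raise ValueError(f"ragged alignment row {name!r}")
    path = Path(path)
    name_w = max(len(name) for name, _ in rows)
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n\n")
        for name, row in rows:
            fh.write(f"{name:<{name_w}} {row}\n")
        fh.write("//\n")
    return path
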
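"""Readers and writers for the pipeline's external tables.

Everything the pipeline touches on disk is plain text: a documented TSV
schema for peptide-level phosphopeptide quantification (one row per
quantified peptide observation in one condition), standard FASTA for
protein sequences, GMT for annotation term sets, and a two/three-column
edge list for protein--protein interactions.

Peptide table schema (tab-separated, one header line)::

    condition?  peptide  protein_id  mod_positions  abundance  reliability?

``mod_positions`` is a semicolon-joined list of site tokens such as
``S25;T31`` giving the phosphorylated residue and its 1-based position
within the protein.  ``condition`` may instead be supplied by the caller
(one file per condition); ``reliability`` is an optional score in [0, 1].
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Residues that can carry the phosphate group in this pipeline.
PHOSPHO_RESIDUES = ("S", "T", "Y")

#: Default condition labels of the five-condition starvation/restimulation
#: design: non-treated, serum-starved, amino-acid-starved, leucine
#: restimulated, all-amino-acid restimulated.
DEFAULT_CONDITIONS = ("NT", "SS", "AAS", "LeuS", "AllS")

_THREE_TO_ONE = {"Ser": "S", "Thr": "T", "Tyr": "Y"}
_SITE_TOKEN_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)$")

REQUIRED_PEPTIDE_COLUMNS = ("peptide", "protein_id", "mod_positions", "abundance")


class SchemaError(ValueError):
    """An input file violates the documented schema (e.g. missing column)."""


class UnsupportedResidueError(ValueError):
    """A site token names a residue outside the S/T/Y phospho-acceptor set."""


@dataclass(frozen=True)
class RowError:
    """A malformed data row, reported with its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


def parse_site_token(token: str) -> tuple[str, int]:
    """Parse a site token such as ``Ser25``, ``S25`` or ``Tyr187``.

    Returns the one-letter residue code and the 1-based position.  Both
    three-letter (``Ser``/``Thr``/``Tyr``) and one-letter (``S``/``T``/``Y``)
    spellings are accepted and normalized to one letter.
    """
    m = _SITE_TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse site token {token!r}")
    raw, pos = m.group(1), int(m.group(2))
    residue = _THREE_TO_ONE.get(raw.capitalize(), raw.upper())
    if residue not in PHOSPHO_RESIDUES:
        raise UnsupportedResidueError(
            f"residue {raw!r} in token {token!r} is not one of S/T/Y"
        )
    if pos < 1:
        raise ValueError(f"position must be >= 1 in token {token!r}")
    return residue, pos


@dataclass(frozen=True, order=True)
class SiteKey:
    """A protein-anchored residue-level phosphosite.

    The canonical text form is ``<protein_id>:<residue><position>``,
    e.g. ``chx:102173139:S25``.  Note that accessions themselves may
    contain colons; parsing splits on the *last* colon.
    """

    protein_id: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise UnsupportedResidueError(
                f"residue {self.residue!r} is not one of S/T/Y"
            )
        if self.position < 1:
            raise ValueError("site position must be >= 1")
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")

    def __str__(self) -> str:
        return f"{self.protein_id}:{self.residue}{self.position}"

    @property
    def token(self) -> str:
        """The ``S25``-style residue+position token."""
        return f"{self.residue}{self.position}"

    @classmethod
    def from_string(cls, text: str) -> "SiteKey":
        protein_id, _, token = text.rpartition(":")
        if not protein_id:
            raise ValueError(f"cannot parse site key {text!r}")
        residue, position = parse_site_token(token)
        return cls(protein_id=protein_id, residue=residue, position=position)


@dataclass(frozen=True)
class PhosphoPeptideRecord:
    """One quantified phosphopeptide observation in one condition.

    A single peptide may carry several phosphosites; ``mod_positions`` and
    ``residues`` are parallel, strictly increasing lists.  Abundance is a
    non-negative intensity in arbitrary units (only ratios are interpreted
    downstream).
    """

    condition: str
    peptide: str
    protein_id: str
    mod_positions: tuple[int, ...]
    residues: tuple[str, ...]
    abundance: float
    reliability: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mod_positions", tuple(self.mod_positions))
        object.__setattr__(self, "residues", tuple(self.residues))
        if len(self.mod_positions) != len(self.residues) or not self.mod_positions:
            raise ValueError("mod_positions and residues must be parallel, non-empty")
        if any(b <= a for a, b in zip(self.mod_positions, self.mod_positions[1:])):
            raise ValueError("mod_positions must be strictly increasing")
        for r in self.residues:
            if r not in PHOSPHO_RESIDUES:
                raise UnsupportedResidueError(f"residue {r!r} is not one of S/T/Y")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if self.reliability is not None and not (0.0 <= self.reliability <= 1.0):
            raise ValueError("reliability must lie in [0, 1]")

    @property
    def sites(self) -> tuple[SiteKey, ...]:
        return tuple(
            SiteKey(self.protein_id, res, pos)
            for pos, res in zip(self.mod_positions, self.residues)
        )


def _format_mod_positions(record: PhosphoPeptideRecord) -> str:
    return ";".join(f"{r}{p}" for r, p in zip(record.residues, record.mod_positions))


def _parse_mod_positions(text: str) -> tuple[tuple[int, ...], tuple[str, ...]]:
    positions: list[int] = []
    residues: list[str] = []
    for token in text.split(";"):
        residue, pos = parse_site_token(token)
        positions.append(pos)
        residues.append(residue)
    return tuple(positions), tuple(residues)


def read_peptide_table(
    path: str | Path, condition: str | None = None
) -> tuple[list[PhosphoPeptideRecord], list[RowError]]:
    """Read a peptide quantification TSV.

    Returns ``(records, errors)``: well-formed rows in file order plus
    row-level errors (with 1-based line numbers) for malformed rows.  A
    missing required column raises :class:`SchemaError` immediately.
    ``condition`` overrides / stands in for the file's condition column.
    """
    path = Path(path)
    records: list[PhosphoPeptideRecord] = []
    errors: list[RowError] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for col in REQUIRED_PEPTIDE_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        if condition is None and "condition" not in header:
            raise SchemaError(
                f"{path} has no 'condition' column and no condition was given"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                cond = condition if condition is not None else row["condition"]
                positions, residues = _parse_mod_positions(row["mod_positions"])
                rel_text = (row.get("reliability") or "").strip()
                records.append(
                    PhosphoPeptideRecord(
                        condition=cond,
                        peptide=row["peptide"].strip().upper(),
                        protein_id=row["protein_id"].strip(),
                        mod_positions=positions,
                        residues=residues,
                        abundance=float(row["abundance"]),
                        reliability=float(rel_text) if rel_text else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))
    if errors:
        logger.warning("%s: %d malformed row(s) skipped", path, len(errors))
    return records, errors


def write_peptide_table(
    records: Iterable[PhosphoPeptideRecord], path: str | Path
) -> None:
    """Write records to the documented TSV schema (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["condition", "peptide", "protein_id", "mod_positions", "abundance", "reliability"]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.condition,
                    rec.peptide,
                    rec.protein_id,
                    _format_mod_positions(rec),
                    repr(rec.abundance),
                    "" if rec.reliability is None else repr(rec.reliability),
                ]
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{protein_id: sequence}``.

    The ID is the first whitespace-delimited token of the header; duplicate
    IDs raise :class:`SchemaError`; an empty file yields an empty mapping
    with a warning.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise SchemaError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT annotation file into ``{term: member set}``.

    GMT lines are ``term <TAB> description <TAB> member1 <TAB> member2 ...``;
    the description column is ignored.  An empty file yields an empty
    mapping with a warning.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with path.open() as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            terms[fields[0]] = {m for m in fields[2:] if m}
    if not terms:
        warnings.warn(f"GMT file {path} contains no terms", stacklevel=2)
    return terms


def write_gmt(
    term_sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as handle:
        for term, members in term_sets.items():
            desc = descriptions.get(term, "na")
            handle.write("\t".join([term, desc, *sorted(members)]) + "\n")


Edge = tuple[str, str, float | None]


def read_edge_list(path: str | Path) -> list[Edge]:
    """Read an undirected edge list (two IDs per line, optional third score).

    Self-loops are dropped; duplicate edges (either orientation) are
    collapsed to the first occurrence.  Lines starting with ``#`` and a
    leading header line naming non-numeric weights are skipped.
    """
    path = Path(path)
    edges: list[Edge] = []
    seen: set[frozenset[str]] = set()
    with path.open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            a, b = fields[0], fields[1]
            weight: float | None = None
            if len(fields) >= 3 and fields[2]:
                try:
                    weight = float(fields[2])
                except ValueError:
                    continue  # header line such as "protein_a  protein_b  score"
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            edges.append((a, b, weight))
    if not edges:
        warnings.warn(f"edge list {path} contains no edges", stacklevel=2)
    return edges


def write_edge_list(edges: Iterable[Edge | Sequence], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for edge in edges:
            a, b = edge[0], edge[1]
            weight = edge[2] if len(edge) > 2 else None
            if weight is None:
                handle.write(f"{a}\t{b}\n")
            else:
                handle.write(f"{a}\t{b}\t{weight}\n")
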
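"""File formats: multi-FASTA, PHYLIP square distance matrix, Newick.

FASTA parsing goes through Biopython's SeqIO; PHYLIP matrices follow the
classic layout (taxon count header, rows of 10-character name field plus
whitespace-separated reals, 6 printed decimals) with a relaxed
whitespace-split reader fallback.  Newick lives in :mod:`acsphylo.phylo`
and is re-exported here.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
from Bio import SeqIO

from .distance import DistanceMatrix
from .errors import FormatError
from .index import SequenceRecord
from .phylo import PhyloTree, parse_newick, write_newick

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_phylip",
    "write_phylip",
    "read_newick",
    "write_newick_file",
    "parse_newick",
    "write_newick",
]

PathLike = Union[str, Path]

PHYLIP_NAME_WIDTH = 10


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a multi-FASTA file; record name = first header token, residues uppercased."""
    records: List[SequenceRecord] = []
    seen = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # e.g. sequence data before any '>' header
        raise FormatError(f"{path}: not a FASTA file ({exc})") from None
    for rec in parsed:
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty name")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _phylip_names(taxa: Sequence[str]) -> List[str]:
    """Render names into the 10-character field; suffix on truncation collisions."""
    out: List[str] = []
    seen = set()
    for name in taxa:
        short = name[:PHYLIP_NAME_WIDTH]
        if short in seen:
            i = 2
            while True:
                tag = f"~{i}"
                candidate = short[: PHYLIP_NAME_WIDTH - len(tag)] + tag
                if candidate not in seen:
                    short = candidate
                    break
                i += 1
        seen.add(short)
        out.append(short)
    return out


def write_phylip(m: DistanceMatrix, path: PathLike) -> None:
    """Write a square PHYLIP distance matrix (6 decimals)."""
    names = _phylip_names(m.taxa)
    with open(path, "w") as fh:
        fh.write(f"{len(m.taxa)}\n")
        for name, row in zip(names, m.d):
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name:<{PHYLIP_NAME_WIDTH}} {vals}\n")


def read_phylip(path: PathLike) -> DistanceMatrix:
    """Read a square PHYLIP matrix, tolerating strict and relaxed name fields."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: first line must be the taxon count") from None
    rows = lines[1:]
    if len(rows) != count:
        raise FormatError(f"{path}: header says {count} taxa but found {len(rows)} rows")
    taxa: List[str] = []
    values = np.empty((count, count), dtype=float)
    for i, line in enumerate(rows):
        tokens = line.split()
        if len(tokens) == count + 1:
            name, vals = tokens[0], tokens[1:]
        else:  # strict dialect: fixed-width name field (may contain spaces)
            name = line[:PHYLIP_NAME_WIDTH].strip()
            vals = line[PHYLIP_NAME_WIDTH:].split()
        if not name:
            raise FormatError(f"{path}: row {i + 1} has no taxon name")
        if len(vals) != count:
            raise FormatError(
                f"{path}: row {name!r} has {len(vals)} values, expected {count}"
            )
        taxa.append(name)
        try:
            values[i] = [float(v) for v in vals]
        except ValueError:
            raise FormatError(f"{path}: non-numeric value in row {name!r}") from None
    return DistanceMatrix(taxa, values)


def read_newick(path: PathLike) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick_file(t: PhyloTree, path: PathLike) -> None:
    Path(path).write_text(write_newick(t) + "\n")
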
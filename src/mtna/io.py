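"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ and Newick go through Biopython; tables are tab-separated with
``#``-prefixed provenance headers. gzip is handled transparently by file
extension for sequence formats.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqParseError(ValueError):
    """Raised when a FASTQ file is malformed; message names file and line."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(name, sequence), ...]``."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ (Sanger Phred+33) into ``[(name, sequence, quality), ...]``.

    Raises :class:`FastqParseError` naming the offending line on truncated
    or malformed records.
    """
    out: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                out.append((rec.id, str(rec.seq), qual))
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ record near line {4 * len(out) + 1}: {exc}"
            ) from exc
    return out


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {name}")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a tab-separated table, skipping ``#`` provenance headers."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """Write a tab-separated table with an optional ``#`` provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_newick(path_or_string):
    """Parse a Newick tree (Bio.Phylo); internal node labels become supports."""
    text = path_or_string
    try:
        is_file = Path(str(text)).exists()
    except OSError:  # e.g. a long Newick string passed directly
        is_file = False
    if is_file:
        with open(text) as fh:
            text = fh.read()
    return Phylo.read(_io.StringIO(str(text)), "newick")


def write_newick(tree, path=None) -> str:
    """Serialize a Bio.Phylo tree to Newick; returns the string."""
    buf = _io.StringIO()
    Phylo.write(tree, buf, "newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")


def phred_string(length: int, quality: int = 40) -> str:
    """Constant Phred+33 quality string (the pipeline never uses qualities)."""
    return chr(quality + 33) * length


__all__ = [
    "FastqParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "read_newick",
    "write_newick",
    "write_json",
    "phred_string",
]
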
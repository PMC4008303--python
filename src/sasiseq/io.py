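"""FASTA/FASTQ I/O and run-parameter sidecars.

FASTA goes through Biopython; FASTQ uses a strict positional four-line
reader so that truncation errors can name the offending line and '@' at the
start of a quality line cannot derail parsing.  Every artifact the CLI
writes gets a JSON sidecar recording the full parameters and seed that
produced it.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_sidecar",
    "read_sidecar",
]

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Duplicate ids, an empty file, or characters outside ACGTN are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    if not recs:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) from a FASTQ file (gzip by
    suffix), strictly four lines per record by position.

    Malformed or truncated records raise with the 1-based line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}:{lineno}: truncated record (fewer than 4 lines)")
            lineno += 3
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}:{lineno}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield header[1:].rstrip("\n").split()[0], seq, qual


def write_sidecar(artifact_path: str | Path, params: dict) -> Path:
    """Write ``<artifact>.json`` recording parameters sufficient to
    regenerate the artifact bit-exactly."""
    artifact_path = Path(artifact_path)
    side = artifact_path.with_suffix(artifact_path.suffix + ".json")
    side.write_text(json.dumps(params, indent=2, default=str) + "\n")
    return side


def read_sidecar(artifact_path: str | Path) -> dict:
    artifact_path = Path(artifact_path)
    side = artifact_path.with_suffix(artifact_path.suffix + ".json")
    return json.loads(side.read_text())
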
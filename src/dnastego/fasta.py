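"""FASTA reading and writing with an explicit alphabet policy.

Covers and stego sequences travel as single-record FASTA.  Real genomic
records routinely contain lowercase (soft-masked) and ambiguous (N)
bases; lowercase is always raised to uppercase, and what happens to
non-ACGT symbols is the caller's choice:

* ``"strict"`` — reject the record (the default: a stego pipeline must
  not silently alter the cover it will later have to reproduce);
* ``"drop"`` — remove them and log how many were removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import FastaError

__all__ = ["FastaRecord", "read_fasta", "write_fasta"]

log = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class FastaRecord:
    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FastaError("FASTA record needs a non-empty identifier")


def read_fasta(
    path: str | Path, policy: str = "strict", record: int | str | None = None
) -> FastaRecord:
    """Read one record from a FASTA file.

    By default the first record is used and any further records trigger
    a warning; ``record`` selects another by 0-based index or by id.
    """
    if policy not in ("strict", "drop"):
        raise FastaError(f"unknown sanitize policy {policy!r}")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise FastaError(f"{path}: cannot read FASTA: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    if record is None:
        if len(records) > 1:
            log.warning(
                "%s: %d records; using the first (%s)",
                path,
                len(records),
                records[0].id,
            )
        chosen = records[0]
    elif isinstance(record, int):
        try:
            chosen = records[record]
        except IndexError:
            raise FastaError(f"{path}: no record with index {record}") from None
    else:
        by_id = {r.id: r for r in records}
        if record not in by_id:
            raise FastaError(f"{path}: no record with id {record!r}")
        chosen = by_id[record]
    seq = str(chosen.seq).upper()
    bad = [c for c in set(seq) if c not in _VALID]
    if bad:
        if policy == "strict":
            raise FastaError(
                f"{path}: record {chosen.id} contains non-ACGT symbols "
                f"{sorted(bad)} (use the drop policy to remove them)"
            )
        n_before = len(seq)
        seq = "".join(c for c in seq if c in _VALID)
        log.info(
            "%s: dropped %d non-ACGT symbols from record %s",
            path,
            n_before - len(seq),
            chosen.id,
        )
    return FastaRecord(identifier=chosen.id, sequence=seq)


def write_fasta(record: FastaRecord, path: str | Path, width: int = 70) -> None:
    """Write a single-record FASTA file, wrapping the sequence at ``width``."""
    if width < 1:
        raise FastaError(f"line width must be >= 1, got {width}")
    if not record.sequence:
        log.warning("writing empty sequence for record %s", record.identifier)
    lines = [f">{record.identifier}"]
    seq = record.sequence
    lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")
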
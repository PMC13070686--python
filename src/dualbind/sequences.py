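"""Protein sequence records, affinity records, and FASTA/CSV input-output.

A :class:`ProteinSequence` is a validated amino-acid string with a chain role
(antibody or antigen) and optional CDR span annotations.  An
:class:`AffinityRecord` pairs one antibody with one antigen and a pK_D label
(pK_D = -log10 of the dissociation constant in molar units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import VALID_AA


class SequenceValidationError(ValueError):
    """Raised when a sequence or its annotations violate the domain contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """One protein chain.

    Parameters
    ----------
    id:
        Record identifier (FASTA header id or table key).
    residues:
        Amino-acid string.  The twenty canonical letters are always valid;
        the ambiguity/nonstandard letters X, B, Z, U, O are accepted and
        handled by embedding providers as "unknown" residues.
    chain_role:
        ``"antibody"`` or ``"antigen"``.
    cdr_spans:
        Optional half-open ``(start, end)`` intervals marking CDR loops,
        sorted and non-overlapping, within ``[0, len)``.
    """

    id: str
    residues: str
    chain_role: str
    cdr_spans: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r}: empty residue string")
        for pos, letter in enumerate(self.residues):
            if letter not in VALID_AA:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: invalid residue {letter!r} at position {pos}"
                )
        if self.chain_role not in ("antibody", "antigen"):
            raise SequenceValidationError(
                f"sequence {self.id!r}: chain_role must be 'antibody' or 'antigen', "
                f"got {self.chain_role!r}"
            )
        if self.cdr_spans is not None:
            object.__setattr__(self, "cdr_spans", tuple(tuple(s) for s in self.cdr_spans))
            prev_end = 0
            for start, end in self.cdr_spans:
                if not (0 <= start < end <= len(self.residues)):
                    raise SequenceValidationError(
                        f"sequence {self.id!r}: CDR span ({start}, {end}) outside "
                        f"[0, {len(self.residues)})"
                    )
                if start < prev_end:
                    raise SequenceValidationError(
                        f"sequence {self.id!r}: CDR spans overlap or are unsorted"
                    )
                prev_end = end

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AffinityRecord:
    """One antibody-antigen pair with a pK_D label."""

    antibody: ProteinSequence
    antigen: ProteinSequence
    pkd: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.pkd):
            raise SequenceValidationError(
                f"pair ({self.antibody.id}, {self.antigen.id}): pkd must be finite"
            )
        if not (3.0 <= self.pkd <= 15.0):
            warnings.warn(
                f"pair ({self.antibody.id}, {self.antigen.id}): pkd {self.pkd:.3g} "
                "outside the typical 3-15 range",
                stacklevel=2,
            )


def parse_cdr_spans(text: str | None) -> tuple[tuple[int, int], ...] | None:
    """Parse ``"start-end;start-end"`` (0-based, half-open) CDR annotation."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return None
    spans = []
    for chunk in str(text).split(";"):
        start_s, _, end_s = chunk.partition("-")
        spans.append((int(start_s), int(end_s)))
    return tuple(spans)


def format_cdr_spans(spans: Sequence[tuple[int, int]] | None) -> str:
    if not spans:
        return ""
    return ";".join(f"{s}-{e}" for s, e in spans)


def read_fasta(path: str | Path, chain_role: str) -> list[ProteinSequence]:
    """Read a multi-record FASTA file; the description line is parsed for id only."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper(), chain_role=chain_role))
    return records


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


PAIR_CSV_COLUMNS = ["antibody_id", "antigen_id", "antibody_seq", "antigen_seq", "pkd", "cdr_spans"]


def read_pairs_csv(path: str | Path) -> list[AffinityRecord]:
    """Read the pair-affinity CSV (antibody_id, antigen_id, antibody_seq,
    antigen_seq, pkd[, cdr_spans])."""
    df = pd.read_csv(path, dtype={"cdr_spans": str})
    required = {"antibody_id", "antigen_id", "antibody_seq", "antigen_seq", "pkd"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        spans = parse_cdr_spans(getattr(row, "cdr_spans", None))
        ab = ProteinSequence(
            id=str(row.antibody_id), residues=str(row.antibody_seq),
            chain_role="antibody", cdr_spans=spans,
        )
        ag = ProteinSequence(id=str(row.antigen_id), residues=str(row.antigen_seq), chain_role="antigen")
        records.append(AffinityRecord(antibody=ab, antigen=ag, pkd=float(row.pkd)))
    return records


def write_pairs_csv(path: str | Path, records: Iterable[AffinityRecord]) -> None:
    rows = [
        {
            "antibody_id": r.antibody.id,
            "antigen_id": r.antigen.id,
            "antibody_seq": r.antibody.residues,
            "antigen_seq": r.antigen.residues,
            "pkd": r.pkd,
            "cdr_spans": format_cdr_spans(r.antibody.cdr_spans),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PAIR_CSV_COLUMNS).to_csv(path, index=False)
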
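"""Aligned amino-acid sequences keyed by label.

Rows are stored upper-cased over the alphabet of 20 residues plus gap
'-', unknown 'X' and stop '*' (the last three are missing data for the
likelihood and parsimony engines).  FASTA I/O goes through Biopython.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_INDEX, MISSING_CHARS, encode_sequence

_VALID = set(AA_INDEX) | set(MISSING_CHARS)


class MSAError(ValueError):
    pass


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into an ordered label -> sequence map.

    ``source`` is a path or a string of FASTA text.  Wrapped lines are
    joined; '*' stop symbols are tolerated.  Empty input and duplicate
    headers are errors.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = StringIO(source)
    else:
        handle = open(source)
    out: dict[str, str] = {}
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise MSAError(f"duplicate FASTA header {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise MSAError("no sequences found in FASTA input")
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=label, description="") for label, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


class MSA:
    """Immutable-ish multiple sequence alignment of peptides."""

    def __init__(self, rows: dict[str, str]):
        if not rows:
            raise MSAError("alignment has no rows")
        self.rows: dict[str, str] = {}
        ncols = None
        for label, seq in rows.items():
            if not label:
                raise MSAError("row with empty label")
            seq = seq.upper()
            if ncols is None:
                ncols = len(seq)
            elif len(seq) != ncols:
                raise MSAError(
                    f"row {label!r} has length {len(seq)}, expected {ncols}"
                )
            bad = set(seq) - _VALID
            if bad:
                raise MSAError(f"row {label!r} contains invalid symbols {sorted(bad)}")
            self.rows[label] = seq
        self.n_cols = ncols or 0

    # ------------------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __getitem__(self, label: str) -> str:
        return self.rows[label]

    def __contains__(self, label: str) -> bool:
        return label in self.rows

    @classmethod
    def from_fasta(cls, source) -> "MSA":
        return cls(read_fasta(source))

    def to_fasta(self, path) -> None:
        write_fasta(self.rows, path)

    def encoded(self, order: list[str] | None = None) -> np.ndarray:
        """(n_rows, n_cols) int8 state matrix, missing = -1."""
        labels = order if order is not None else self.labels
        return np.vstack([encode_sequence(self.rows[l]) for l in labels])

    def select_columns(self, mask) -> "MSA":
        idx = np.flatnonzero(np.asarray(mask)) if np.asarray(mask).dtype == bool else list(mask)
        return MSA({l: "".join(s[i] for i in idx) for l, s in self.rows.items()})

    def subset(self, labels) -> "MSA":
        return MSA({l: self.rows[l] for l in labels})

    def drop(self, labels) -> "MSA":
        gone = set(labels)
        return MSA({l: s for l, s in self.rows.items() if l not in gone})

    def concat(self, other: "MSA") -> "MSA":
        """Column-wise concatenation over the shared label set."""
        if set(self.rows) != set(other.rows):
            raise MSAError("cannot concatenate alignments over different label sets")
        return MSA({l: self.rows[l] + other.rows[l] for l in self.rows})
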
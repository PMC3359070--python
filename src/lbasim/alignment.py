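"""Gap-free DNA alignments and their FASTA / relaxed-PHYLIP I/O.

Sequences are held as a taxa x sites uint8 matrix with the fixed base
encoding A=0, C=1, G=2, T=3.  The study simulates no indels, so gaps and
ambiguity codes are rejected everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["BASES", "Alignment", "read_alignment", "write_alignment"]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass
class Alignment:
    """Ordered taxon labels plus a (n_taxa, n_sites) uint8 base matrix."""

    labels: list
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match the label count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if self.data.size and self.data.max() > 3:
            raise ValueError("base codes must be in 0..3 (A,C,G,T)")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        row = self.data[self.labels.index(label)]
        return _BASE_ARR[row].tobytes().decode()

    @classmethod
    def from_strings(cls, pairs) -> "Alignment":
        labels, rows = [], []
        length = None
        for label, seq in pairs:
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"row {label!r} has length {len(seq)}, expected {length}"
                )
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            row = np.full(codes.shape, 255, dtype=np.uint8)
            for base, code in _CODE.items():
                row[codes == ord(base)] = code
            bad = np.nonzero(row == 255)[0]
            if bad.size:
                raise ValueError(
                    f"row {label!r} column {bad[0] + 1}: "
                    f"symbol {seq[bad[0]]!r} is not one of A,C,G,T"
                )
            labels.append(label)
            rows.append(row)
        return cls(labels, np.vstack(rows) if rows else np.zeros((0, 0), np.uint8))

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.data.shape == other.data.shape
            and bool(np.all(self.data == other.data))
        )


_FORMATS = {"fasta": "fasta", "phylip": "phylip-relaxed"}


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    records = [
        SeqRecord(Seq(alignment.sequence(lab)), id=lab, description="")
        for lab in alignment.labels
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), _FORMATS[format])


def read_alignment(source, format: str | None = None) -> Alignment:
    """Read FASTA or relaxed PHYLIP; the format is sniffed when not given."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    if format is None:
        format = "fasta" if text.lstrip().startswith(">") else "phylip"
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    try:
        msa = AlignIO.read(io.StringIO(text), _FORMATS[format])
    except ValueError as exc:
        raise ValueError(f"could not parse {format} alignment: {exc}") from exc
    if format == "phylip":
        header = text.split("\n", 1)[0].split()
        n_taxa, n_sites = int(header[0]), int(header[1])
        if n_taxa != len(msa) or n_sites != msa.get_alignment_length():
            raise ValueError(
                f"phylip header declares {n_taxa} x {n_sites} but the matrix "
                f"is {len(msa)} x {msa.get_alignment_length()}"
            )
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence headers: {dup}")
    return Alignment.from_strings((rec.id, str(rec.seq)) for rec in msa)
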
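"""Multiple sequence alignments over amino-acid or codon alphabets.

Sequences are held as an integer matrix (taxa x columns); gaps and
ambiguity codes are encoded as ``MISSING`` (-1) and treated as fully
missing data by the likelihood machinery.  Codon alignments are stored
one column per codon over the 61 sense codons of the standard genetic
code; in-frame stop codons are rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from ._aa_data import AA_ORDER

MISSING = -1

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))
# 61 sense codons in TCAG-major order (the conventional codon-model order)
_NT_ORDER = "TCAG"
CODONS = tuple(
    a + b + c
    for a in _NT_ORDER
    for b in _NT_ORDER
    for c in _NT_ORDER
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_TO_AA = tuple(_STANDARD_TABLE.forward_table[c] for c in CODONS)

_AMBIG_NT = set("NRYSWKMBDHV-?.")


class AlignmentError(ValueError):
    """Raised for malformed alignment inputs."""


@dataclass
class Alignment:
    """Integer-encoded alignment over AA20 or CODON61.

    Attributes
    ----------
    taxa : list of str
    matrix : (n_taxa, n_columns) int array; MISSING (-1) marks gaps/ambiguity
    alphabet : "aa" or "codon"
    reference : designated reference taxon for position reporting
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str
    reference: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.alphabet not in ("aa", "codon"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        self.matrix = np.asarray(self.matrix, dtype=np.int16)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxon count")
        if self.reference is not None and self.reference not in self.taxa:
            raise AlignmentError(f"reference taxon {self.reference!r} not in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_states(self) -> int:
        return 20 if self.alphabet == "aa" else 61

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_columns) mask of missing entries."""
        return self.matrix == MISSING

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in keep]
        ref = self.reference if self.reference in keep else None
        return Alignment(list(keep), self.matrix[idx], self.alphabet,
                         reference=ref, gene=self.gene)

    def reference_positions(self) -> np.ndarray:
        """1-based ungapped position in the reference taxon per column (0 = gap)."""
        if self.reference is None:
            raise AlignmentError("no reference taxon designated")
        row = self.row(self.reference)
        pos = np.cumsum(row != MISSING)
        pos[row == MISSING] = 0
        return pos

    def to_amino_acids(self) -> "Alignment":
        """Translate a codon alignment to amino acids (standard code)."""
        if self.alphabet != "codon":
            raise AlignmentError("alignment is not in codon mode")
        lut = np.array([AA_INDEX[a] for a in CODON_TO_AA], dtype=np.int16)
        out = np.full_like(self.matrix, MISSING)
        ok = self.matrix != MISSING
        out[ok] = lut[self.matrix[ok]]
        return Alignment(list(self.taxa), out, "aa",
                         reference=self.reference, gene=self.gene)

    # --------------------------------------------------------------- io

    @classmethod
    def from_sequences(cls, records: Sequence[tuple[str, str]], alphabet: str,
                       reference: Optional[str] = None,
                       gene: Optional[str] = None) -> "Alignment":
        if not records:
            raise AlignmentError("no sequences found")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            detail = ", ".join(f"{n}={len(s)}" for n, s in records)
            raise AlignmentError(f"ragged rows (unequal lengths): {detail}")
        (length,) = lengths
        taxa = [name for name, _ in records]
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon names in alignment")
        if alphabet == "aa":
            matrix = np.array(
                [[AA_INDEX.get(ch, MISSING) for ch in seq.upper()]
                 for _, seq in records], dtype=np.int16)
        elif alphabet == "codon":
            if length % 3 != 0:
                raise AlignmentError(
                    f"codon alignment length {length} not divisible by 3")
            ncod = length // 3
            matrix = np.empty((len(taxa), ncod), dtype=np.int16)
            for i, (name, seq) in enumerate(records):
                s = seq.upper().replace("U", "T")
                for j in range(ncod):
                    codon = s[3 * j:3 * j + 3]
                    if codon in STOP_CODONS:
                        raise AlignmentError(
                            f"in-frame stop codon {codon} in taxon {name!r} "
                            f"at codon index {j + 1}")
                    if codon in CODON_INDEX:
                        matrix[i, j] = CODON_INDEX[codon]
                    elif any(ch in _AMBIG_NT or ch not in "ACGT" for ch in codon):
                        matrix[i, j] = MISSING
                    else:  # pragma: no cover - unreachable with standard code
                        matrix[i, j] = MISSING
        else:
            raise AlignmentError(f"unknown alphabet {alphabet!r}")
        return cls(taxa, matrix, alphabet, reference=reference, gene=gene)

    @classmethod
    def read(cls, path: str | os.PathLike, alphabet: str,
             fmt: Optional[str] = None, reference: Optional[str] = None,
             gene: Optional[str] = None) -> "Alignment":
        """Read FASTA or relaxed PHYLIP into an :class:`Alignment`."""
        path = os.fspath(path)
        if fmt is None:
            with open(path) as fh:
                first = fh.readline()
            fmt = "fasta" if first.startswith(">") else "phylip-relaxed"
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, fmt)]
        if gene is None:
            gene = os.path.splitext(os.path.basename(path))[0]
        return cls.from_sequences(records, alphabet, reference=reference, gene=gene)

    def write_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for i, taxon in enumerate(self.taxa):
                fh.write(f">{taxon}\n{self.row_str(i)}\n")

    def row_str(self, i: int) -> str:
        if self.alphabet == "aa":
            return "".join(
                AA_ORDER[s] if s != MISSING else "-" for s in self.matrix[i])
        return "".join(
            CODONS[s] if s != MISSING else "---" for s in self.matrix[i])


def read_alignment(path: str | os.PathLike, alphabet: str, **kw) -> Alignment:
    """Read an alignment file (FASTA or relaxed PHYLIP)."""
    return Alignment.read(path, alphabet, **kw)
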
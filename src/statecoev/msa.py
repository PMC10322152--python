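"""Multiple sequence alignment ingestion, gap filtering and sequence weighting.

An alignment is the entry point of the coevolution pipeline: sequences are
read as-is (round-trip safe), columns with too many gaps are masked out, and
each sequence receives a weight 1/k where k is the number of alignment members
(including itself) at or above the identity threshold.  The sum of weights is
the effective sequence count M_eff, i.e. the number of non-redundant sequences
at the chosen identity level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, EmptyInputError

#: Ordered 21-letter alphabet; gap first so that index 0 always means "gap".
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
GAP_INDEX = 0
Q = len(ALPHABET)

# Non-standard / ambiguous residues are treated as gaps when encoding.
_ENCODE = np.full(128, GAP_INDEX, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("-")] = GAP_INDEX
_ENCODE[ord(".")] = GAP_INDEX


def encode_sequences(sequences: list[str], alphabet: str = ALPHABET) -> np.ndarray:
    """Encode aligned sequences to an (N, L) int8 matrix over ``alphabet``.

    With the default alphabet, case is ignored and any symbol outside the 20
    standard amino acids (B, Z, X, U, O, J, ...) maps to the gap state.
    """
    if alphabet == ALPHABET:
        arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
        return _ENCODE[arr].reshape(len(sequences), -1)
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    arr = lut[np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({chr(b) for b in np.frombuffer(
            "".join(sequences).encode("ascii"), dtype=np.uint8)[arr < 0]})
        raise AlignmentFormatError(f"symbols {bad} not in alphabet {alphabet!r}")
    return arr.reshape(len(sequences), -1)


@dataclass
class MultipleAlignment:
    """Aligned sequences with a column mask and per-sequence weights.

    ``column_mask`` marks the columns kept for analysis (True = kept);
    ``weights`` are in (0, 1] and sum to the effective sequence count M_eff.
    """

    sequences: list[str]
    ids: list[str]
    column_mask: np.ndarray = None
    weights: np.ndarray = None
    subfamily: str = ""
    gap_threshold: float = field(default=None, repr=False)

    def __post_init__(self):
        if not self.sequences:
            raise EmptyInputError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}")
        if self.column_mask is None:
            self.column_mask = np.ones(self.length, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
        if self.weights is None:
            self.weights = np.ones(self.n_sequences)
        else:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def meff(self) -> float:
        """Effective number of non-redundant sequences, sum of weights."""
        return float(self.weights.sum())

    @property
    def kept_columns(self) -> np.ndarray:
        """Original (0-based) indices of the unmasked columns."""
        return np.flatnonzero(self.column_mask)

    def encoded(self, masked: bool = True) -> np.ndarray:
        """Integer matrix over the 21-letter alphabet (kept columns only by default)."""
        enc = encode_sequences(self.sequences)
        return enc[:, self.column_mask] if masked else enc


def read_alignment(path, format: str = "fasta") -> MultipleAlignment:
    """Read a FASTA or Stockholm alignment with unit weights, all columns kept."""
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise AlignmentFormatError(f"unsupported format {format!r}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    try:
        if format == "fasta":
            # AlignIO's fasta reader does not verify equal lengths; go through
            # SeqIO and let MultipleAlignment enforce the invariant.
            records = list(SeqIO.parse(path, "fasta"))
        else:
            records = list(AlignIO.read(path, "stockholm"))
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no records in {path}")
    return MultipleAlignment(
        sequences=[str(r.seq) for r in records],
        ids=[r.id for r in records],
        subfamily=path.stem,
    )


def write_alignment(aln: MultipleAlignment, path, format: str = "fasta") -> None:
    """Write the alignment; sequences are emitted byte-identically."""
    records = [SeqRecord(Seq(s), id=i, description="")
               for s, i in zip(aln.sequences, aln.ids)]
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
    elif format == "stockholm":
        AlignIO.write(MultipleSeqAlignment(records), path, "stockholm")
    else:
        raise AlignmentFormatError(f"unsupported format {format!r}")


def filter_gap_columns(aln: MultipleAlignment,
                       max_gap_fraction: float = 0.2) -> MultipleAlignment:
    """Mask columns with strictly more than ``max_gap_fraction`` gaps.

    Recomputed from the raw sequences, so the operation is idempotent and the
    original column indices stay available for mapping back to structures.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    enc = encode_sequences(aln.sequences)
    gap_fraction = (enc == GAP_INDEX).mean(axis=0)
    mask = gap_fraction <= max_gap_fraction
    return replace(aln, column_mask=mask, gap_threshold=max_gap_fraction)


def pairwise_identity_counts(enc: np.ndarray, threshold: float) -> np.ndarray:
    """For each sequence, the number of sequences (incl. itself) with
    pairwise identity >= threshold.

    Identity is computed over mutually non-gap positions; a pair with no
    comparable position has identity 0.
    """
    n = enc.shape[0]
    nongap = enc != GAP_INDEX
    counts = np.zeros(n, dtype=np.int64)
    # O(N^2 L) but vectorized one row at a time to bound memory.
    for i in range(n):
        both = nongap[i] & nongap
        comparable = both.sum(axis=1)
        same = ((enc[i] == enc) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(comparable > 0, same / np.maximum(comparable, 1), 0.0)
        ident[i] = 1.0
        counts[i] = int((ident >= threshold).sum())
    return counts


def compute_weights(aln: MultipleAlignment,
                    identity_threshold: float = 0.8) -> MultipleAlignment:
    """Assign w_n = 1 / |{m : id(n, m) >= threshold}| on the masked columns.

    M_eff = sum of weights then counts sequences with less than
    ``identity_threshold`` mutual identity: all-distinct sequences each get
    weight 1, exact duplicates share a single unit of weight.
    """
    enc = aln.encoded(masked=True)
    counts = pairwise_identity_counts(enc, identity_threshold)
    return replace(aln, weights=1.0 / counts)
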
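"""DNA sequences, secondary structures, one-hot encodings, and truncation.

Sequences are single-stranded DNA over {A,C,G,T}, positions counted 1-based
from the 5' end. Secondary structure is dot-bracket: matched parentheses are
base pairs, dots unpaired. The built-in folder is a Nussinov base-pair
maximizer (non-crossing pairings, hairpin loops of at least ``min_loop``
unpaired bases); an externally predicted dot-bracket can be supplied anywhere
a structure is consumed, so thermodynamic folders remain pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
STRUCT_ALPHABET = "()."
DEFAULT_MAX_LEN = 100

#: Watson-Crick complements; GT wobble is added only when requested.
_WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


class AlphabetError(ValueError):
    """A character outside the permitted alphabet was encountered."""


class SizingError(ValueError):
    """An input does not fit the configured maximum length."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence (5'->3')."""

    bases: str

    def __post_init__(self):
        if not self.bases:
            raise AlphabetError("empty sequence")
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise AlphabetError(f"illegal characters {sorted(bad)} (alphabet ACGT)")
        if len(self.bases) > DEFAULT_MAX_LEN:
            raise SizingError(
                f"sequence length {len(self.bases)} exceeds maximum {DEFAULT_MAX_LEN}"
            )

    def __len__(self):
        return len(self.bases)

    def __str__(self):
        return self.bases


@dataclass(frozen=True)
class DotBracket:
    """A balanced, non-crossing dot-bracket string."""

    marks: str

    def __post_init__(self):
        if not self.marks:
            raise AlphabetError("empty structure")
        depth = 0
        for c in self.marks:
            if c not in STRUCT_ALPHABET:
                raise AlphabetError(f"illegal structure mark {c!r}")
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unmatched ')' in dot-bracket")
        if depth != 0:
            raise ValueError("unmatched '(' in dot-bracket")

    def __len__(self):
        return len(self.marks)

    def __str__(self):
        return self.marks

    def pairs(self) -> set[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples with i < j."""
        stack: list[int] = []
        out: set[tuple[int, int]] = set()
        for i, c in enumerate(self.marks):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.add((stack.pop(), i))
        return out


@dataclass
class EncodedSequence:
    """Padded one-hot encodings of a sequence and/or its structure.

    ``seq_onehot`` is L_max x 4 (columns A,C,G,T), ``struct_onehot`` is
    L_max x 3 (columns '(', ')', '.'), ``mask`` marks real positions.
    """

    seq_onehot: np.ndarray
    struct_onehot: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class PrimerSpec:
    """Forward and reverse primer sequences flanking a library insert."""

    forward: NucleotideSequence
    reverse: NucleotideSequence


@dataclass
class TruncationResult:
    sequence: NucleotideSequence
    left_trim: int
    right_trim: int
    warning: Optional[str] = None


def _check_len(n: int, max_len: int) -> None:
    if n > max_len:
        raise SizingError(f"length {n} exceeds max_len {max_len}")


def onehot_sequence(seq: NucleotideSequence | str, max_len: int = DEFAULT_MAX_LEN) -> EncodedSequence:
    """One-hot encode a sequence into an L_max x 4 matrix (columns A,C,G,T)."""
    s = str(seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(seq))
    _check_len(len(s), max_len)
    mat = np.zeros((max_len, 4))
    mask = np.zeros(max_len)
    for i, c in enumerate(s):
        mat[i, ALPHABET.index(c)] = 1.0
        mask[i] = 1.0
    return EncodedSequence(seq_onehot=mat, struct_onehot=np.zeros((max_len, 3)), mask=mask)


def onehot_structure(db: DotBracket | str, max_len: int = DEFAULT_MAX_LEN) -> EncodedSequence:
    """One-hot encode a dot-bracket into an L_max x 3 matrix (columns '(' ')' '.')."""
    d = str(db if isinstance(db, DotBracket) else DotBracket(db))
    _check_len(len(d), max_len)
    mat = np.zeros((max_len, 3))
    mask = np.zeros(max_len)
    for i, c in enumerate(d):
        mat[i, STRUCT_ALPHABET.index(c)] = 1.0
        mask[i] = 1.0
    return EncodedSequence(seq_onehot=np.zeros((max_len, 4)), struct_onehot=mat, mask=mask)


def encode_pair(seq, db, max_len: int = DEFAULT_MAX_LEN) -> EncodedSequence:
    """Joint sequence + structure encoding sharing one mask."""
    es = onehot_sequence(seq, max_len)
    st = onehot_structure(db, max_len)
    if not np.array_equal(es.mask, st.mask):
        raise SizingError("sequence and structure lengths differ")
    es.struct_onehot = st.struct_onehot
    return es


def decode_onehot(matrix: np.ndarray, mask: np.ndarray) -> NucleotideSequence:
    """Argmax-decode an L x 4 matrix back to a sequence.

    Ties resolve to the lexicographically first base (column order A,C,G,T).
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite values in decode input")
    keep = np.asarray(mask, dtype=bool)
    if not keep.any():
        raise AlphabetError("empty mask: nothing to decode")
    idx = np.argmax(matrix[keep], axis=1)  # np.argmax takes the first max -> A<C<G<T
    return NucleotideSequence("".join(ALPHABET[i] for i in idx))


def decode_structure_onehot(matrix: np.ndarray, mask: np.ndarray) -> DotBracket:
    """Argmax-decode an L x 3 matrix to a dot-bracket; falls back to all-dots
    if the argmax string is unbalanced (decoder outputs are unconstrained)."""
    keep = np.asarray(mask, dtype=bool)
    if not keep.any():
        raise AlphabetError("empty mask: nothing to decode")
    idx = np.argmax(np.asarray(matrix, dtype=float)[keep], axis=1)
    marks = "".join(STRUCT_ALPHABET[i] for i in idx)
    try:
        return DotBracket(marks)
    except ValueError:
        return DotBracket("." * len(marks))


def _pairable(a: str, b: str, wobble: bool) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return wobble and (a, b) in _WOBBLE_PAIRS


def fold_structure(seq: NucleotideSequence | str, min_loop: int = 3, wobble: bool = False) -> DotBracket:
    """Nussinov base-pair maximization with a minimum hairpin loop.

    Dynamic program over intervals; traceback is deterministic: within an
    interval, the 5'-most base is paired whenever pairing it attains the
    optimum, to the 5'-most partner that does so.
    """
    s = str(seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(seq))
    n = len(s)
    N = np.zeros((n + 1, n + 1), dtype=int)  # N[i][j] over s[i..j] inclusive, 0-based
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(s[i], s[k], wobble):
                    inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + rest + 1)
            N[i][j] = best
    marks = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _pairable(s[i], s[k], wobble):
                inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                rest = N[k + 1][j] if k + 1 <= j else 0
                if inner + rest + 1 == N[i][j]:
                    marks[i], marks[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return DotBracket("".join(marks))


FolderFn = Callable[[str], DotBracket]


def primer_refine(
    seq: NucleotideSequence | str,
    primers: PrimerSpec,
    folder: Optional[FolderFn] = None,
) -> TruncationResult:
    """Trim flanks down to the minimal core preserving the global fold.

    Bases are removed greedily outside-in from the 5' then 3' end; a trim is
    accepted only while the core, refolded in isolation, reproduces exactly
    the base-pair set of the full-length fold. Sequences lacking
    the primer regions (exact match at both ends) are returned unchanged with
    a warning, as are trims that would empty the core.
    """
    s = str(seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(seq))
    fold = folder or (lambda x: fold_structure(x))
    fwd, rev = str(primers.forward), str(primers.reverse)
    if not fwd or not rev:
        raise ValueError("both primers required for truncation")
    if not (s.startswith(fwd) and s.endswith(rev)):
        return TruncationResult(NucleotideSequence(s), 0, 0, warning="primers not found; unchanged")

    full_pairs = fold(s).pairs()

    def core_ok(lo: int, hi: int) -> bool:  # core = s[lo:hi]
        if hi - lo < 1:
            return False
        # the global structure must survive: every base pair of the
        # full-length fold stays inside the core and is reproduced exactly
        # when the core is refolded in isolation
        if any(i < lo or j >= hi for i, j in full_pairs):
            return False
        wanted = {(i - lo, j - lo) for i, j in full_pairs}
        return fold(s[lo:hi]).pairs() == wanted

    lo, hi = 0, len(s)
    progressed = True
    while progressed:
        progressed = False
        while hi - lo > 1 and core_ok(lo + 1, hi):
            lo += 1
            progressed = True
        while hi - lo > 1 and core_ok(lo, hi - 1):
            hi -= 1
            progressed = True
    if hi - lo < 1:
        return TruncationResult(NucleotideSequence(s), 0, 0, warning="truncation would empty core")
    return TruncationResult(NucleotideSequence(s[lo:hi]), lo, len(s) - hi)


# -- plain-text formats ------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) tuples."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) records as wrapped FASTA (60 columns)."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_structure_sidecar(path) -> list[tuple[str, str, str]]:
    """Read the 'ID<TAB>SEQ<TAB>DOTBRACKET' sidecar format."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, s, db = line.split("\t")
            out.append((name, s, db))
    return out


def write_structure_sidecar(path, rows: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, s, db in rows:
            fh.write(f"{name}\t{s}\t{db}\n")
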
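"""Target chemistry: SMILES graphs, matrices, fingerprints, sandwich tensors.

The parser covers the organic-subset SMILES grammar (heavy atoms, branches,
ring closures, bond orders -, =, #, aromatic lowercase normalized to order
1.5) — enough for the steroid-family targets this package models. It is the
reference implementation; a full cheminformatics backend can be adapted in
wherever a :class:`MolecularGraph` is consumed, and bit-compatibility of
fingerprints is explicitly not promised across backends.

The "sandwich" tensor stacks [target distance | sequence structure one-hot |
target adjacency] into a 3 x S x S array, mirroring how an aptamer wraps its
small-molecule target between structural context on both sides.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .seqstruct import EncodedSequence

ORGANIC_ATOMS = ["Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I"]
AROMATIC_ATOMS = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}
BOND_ORDERS = {"-": 1.0, "=": 2.0, "#": 3.0}
AROMATIC_ORDER = 1.5


class SmilesParseError(ValueError):
    """Raised with the offending token and its 0-based position."""

    def __init__(self, token: str, position: int, reason: str = "unsupported token"):
        self.token, self.position = token, position
        super().__init__(f"{reason} {token!r} at position {position}")


@dataclass
class MolecularGraph:
    """Heavy-atom graph; bond endpoints are 1-based atom indices."""

    atoms: list[str]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.atoms)


@dataclass
class TargetMatrices:
    adjacency: np.ndarray
    distance: np.ndarray
    n: int


@dataclass
class FingerprintBits:
    bits: np.ndarray
    radius: int
    n_bits: int


@dataclass
class SandwichTensor:
    """3 x S x S array; slab order [distance, structure, adjacency]."""

    slabs: np.ndarray
    size: int


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse subset SMILES into a heavy-atom molecular graph."""
    atoms: list[str] = []
    bonds: list[tuple[int, int, float]] = []
    aromatic_atoms: set[int] = set()
    prev: int | None = None  # 1-based index of the previous atom
    pending: float | None = None
    stack: list[int | None] = []
    rings: dict[str, tuple[int, float | None]] = {}
    i = 0
    n = len(smiles)
    while i < n:
        c = smiles[i]
        if c in BOND_ORDERS:
            pending = BOND_ORDERS[c]
            i += 1
            continue
        if c == "(":
            if prev is None:
                raise SmilesParseError(c, i, "branch before any atom:")
            stack.append(prev)
            i += 1
            continue
        if c == ")":
            if not stack:
                raise SmilesParseError(c, i, "unmatched branch close:")
            prev = stack.pop()
            i += 1
            continue
        if c.isdigit():
            if prev is None:
                raise SmilesParseError(c, i, "ring closure before any atom:")
            if c in rings:
                other, order0 = rings.pop(c)
                if pending is not None:
                    order = pending
                elif order0 is not None:
                    order = order0
                elif other in aromatic_atoms and prev in aromatic_atoms:
                    order = AROMATIC_ORDER
                else:
                    order = 1.0
                bonds.append((other, prev, order))
            else:
                rings[c] = (prev, pending)
            pending = None
            i += 1
            continue
        # atom token: try two-character symbols first
        sym = None
        aromatic = False
        for cand in ("Cl", "Br"):
            if smiles.startswith(cand, i):
                sym = cand
                break
        if sym is None:
            if c in AROMATIC_ATOMS:
                sym, aromatic = AROMATIC_ATOMS[c], True
            elif c in {"B", "C", "N", "O", "P", "S", "F", "I"}:
                sym = c
            else:
                raise SmilesParseError(c, i)
        atoms.append(sym)
        idx = len(atoms)
        if aromatic:
            aromatic_atoms.add(idx)
        if prev is not None:
            order = pending if pending is not None else (AROMATIC_ORDER if aromatic else 1.0)
            bonds.append((prev, idx, order))
        pending = None
        prev = idx
        i += len(sym)
    if stack:
        raise SmilesParseError("(", n - 1, "unclosed branch:")
    if rings:
        d = next(iter(rings))
        raise SmilesParseError(d, n - 1, "unclosed ring bond:")
    if not atoms:
        raise SmilesParseError(smiles or "", 0, "no atoms in:")
    return MolecularGraph(atoms=atoms, bonds=bonds)


def adjacency_matrix(g: MolecularGraph) -> np.ndarray:
    A = np.zeros((g.n, g.n))
    for i, j, _ in g.bonds:
        A[i - 1, j - 1] = 1.0
        A[j - 1, i - 1] = 1.0
    return A


def distance_matrix(g: MolecularGraph) -> np.ndarray:
    """Topological distances: shortest-path bond counts between atoms."""
    A = adjacency_matrix(g)
    if g.n == 1:
        return np.zeros((1, 1))
    D = shortest_path(A, method="D", unweighted=True)
    if np.isinf(D).any():
        raise ValueError("disconnected molecular graph has no finite distance matrix")
    return D


def target_matrices(g: MolecularGraph) -> TargetMatrices:
    return TargetMatrices(adjacency=adjacency_matrix(g), distance=distance_matrix(g), n=g.n)


_HASH_SEED = 0x5EED  # fixed fingerprint hashing seed, recorded in run configs


def _stable_hash(payload: tuple, seed: int = _HASH_SEED) -> int:
    h = hashlib.blake2b(repr((seed, payload)).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big")


def morgan_fingerprint(g: MolecularGraph, radius: int = 2, n_bits: int = 2048) -> FingerprintBits:
    """Circular (ECFP-style) fingerprint by iterative neighborhood hashing.

    Atom identifiers start from (element, degree, bond-order sum) invariants
    and are refined ``radius`` times by hashing the sorted (bond order,
    neighbor identifier) multiset. All identifiers from every radius are
    folded into ``n_bits`` with a fixed seed, so the bits are invariant to
    the input order of atoms.
    """
    if g.n == 0:
        raise ValueError("empty molecule")
    nbrs: dict[int, list[tuple[float, int]]] = {i: [] for i in range(1, g.n + 1)}
    for i, j, order in g.bonds:
        nbrs[i].append((order, j))
        nbrs[j].append((order, i))
    ids = {
        a: _stable_hash((g.atoms[a - 1], len(nbrs[a]), sum(o for o, _ in nbrs[a])))
        for a in range(1, g.n + 1)
    }
    all_ids = set(ids.values())
    for _ in range(radius):
        new_ids = {}
        for a in range(1, g.n + 1):
            if not nbrs[a]:  # environment cannot grow; keep the identifier
                new_ids[a] = ids[a]
                continue
            env = tuple(sorted((order, ids[b]) for order, b in nbrs[a]))
            new_ids[a] = _stable_hash((ids[a], env))
        ids = new_ids
        all_ids.update(ids.values())
    bits = np.zeros(n_bits)
    for ident in all_ids:
        bits[ident % n_bits] = 1.0
    return FingerprintBits(bits=bits, radius=radius, n_bits=n_bits)


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    ab = float(np.sum(a.bits * b.bits))
    union = float(np.sum(np.clip(a.bits + b.bits, 0, 1)))
    return ab / union if union else 1.0


def build_sandwich(enc: EncodedSequence, tm: TargetMatrices, S: int) -> SandwichTensor:
    """Assemble the 3-slab spatial encoding [distance | structure | adjacency]."""
    if tm.n == 0:
        raise ValueError("target has no atoms")
    L = int(enc.mask.sum())
    if S < max(tm.n, L, 3):
        raise ValueError(f"sandwich size {S} too small for n={tm.n}, L={L}")
    slabs = np.zeros((3, S, S))
    slabs[0, : tm.n, : tm.n] = tm.distance
    slabs[1, : enc.struct_onehot.shape[0], :3] = enc.struct_onehot[:S, :]
    slabs[2, : tm.n, : tm.n] = tm.adjacency
    return SandwichTensor(slabs=slabs, size=S)


def read_targets_tsv(path) -> list[tuple[int, str, str]]:
    """Read the targets file: 'class_id<TAB>name<TAB>SMILES' per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, name, smi = line.split("\t")
            out.append((int(cid), name, smi))
    return out


def write_targets_tsv(path, rows) -> None:
    with open(path, "w") as fh:
        for cid, name, smi in rows:
            fh.write(f"{cid}\t{name}\t{smi}\n")
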
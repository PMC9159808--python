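"""Molecular holograms: fragment enumeration, canonical keys, CRC bin hashing.

A hologram is a fixed-length integer vector counting every connected
vertex-induced subgraph (fragment) of a molecule whose atom count lies in a
configured size window.  Each fragment is reduced to a canonical key string
under a set of *distinction* flags controlling which atom/bond properties
enter fragment identity:

    A — atom aromaticity
    B — bond orders
    C — connection (the atom's heavy-atom degree in the PARENT molecule)
    D — donor/acceptor classification
    H — hydrogens included as explicit graph nodes

Element symbol and formal charge always participate.  Keys are hashed into
bins 1..L with CRC-32 (IEEE polynomial) modulo the hologram length L.
Internal consistency — not bit-compatibility with any proprietary
implementation — is the contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .molecule_io import StandardizedMolecule, _is_acceptor, _is_donor

__all__ = [
    "ALLOWED_LENGTHS",
    "HologramConfig",
    "FragmentKey",
    "Hologram",
    "EnumerationCapExceeded",
    "enumerate_fragments",
    "canonical_fragment_key",
    "hash_to_bin",
    "build_hologram",
    "hologram_matrix",
]

ALLOWED_LENGTHS = frozenset({53, 59, 61, 71, 83, 97, 151, 199, 257, 307, 353, 401})

VALID_DISTINCTIONS = frozenset("ABCDH")


@dataclass(frozen=True)
class HologramConfig:
    """Fragment size window, distinction flags, and hologram length.

    The default configuration (size 5-8, distinctions {A, C}, L=353) is
    the best-performing combination of the reference study.
    """

    min_atoms: int = 5
    max_atoms: int = 8
    distinctions: frozenset[str] = frozenset({"A", "C"})
    length_L: int = 353
    enumeration_cap: int = 2_000_000

    def __post_init__(self) -> None:
        if not 1 <= self.min_atoms <= self.max_atoms <= 11:
            raise ValueError(
                f"require 1 <= min_atoms <= max_atoms <= 11, got "
                f"[{self.min_atoms}, {self.max_atoms}]"
            )
        if self.length_L not in ALLOWED_LENGTHS:
            raise ValueError(f"length_L must be one of {sorted(ALLOWED_LENGTHS)}")
        flags = frozenset(self.distinctions)
        if not flags <= VALID_DISTINCTIONS:
            raise ValueError(f"unknown distinction flags: {sorted(flags - VALID_DISTINCTIONS)}")
        object.__setattr__(self, "distinctions", flags)

    def to_dict(self) -> dict:
        return {
            "min_atoms": self.min_atoms,
            "max_atoms": self.max_atoms,
            "distinctions": "".join(sorted(self.distinctions)),
            "length_L": self.length_L,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HologramConfig":
        return cls(
            min_atoms=int(d["min_atoms"]),
            max_atoms=int(d["max_atoms"]),
            distinctions=frozenset(d["distinctions"]),
            length_L=int(d["length_L"]),
        )


@dataclass(frozen=True)
class FragmentKey:
    """Canonical string identity of one fragment occurrence."""

    key: str
    atom_count: int


@dataclass
class Hologram:
    """Integer count vector over bins 1..L (stored 0-indexed)."""

    bins: np.ndarray
    total_fragments: int


class EnumerationCapExceeded(RuntimeError):
    """Raised when a molecule's connected-subgraph count exceeds the cost cap."""


# ---------------------------------------------------------------------------
# parent graph construction


class _ParentGraph:
    """Flat adjacency view of a molecule with per-node label strings."""

    __slots__ = ("n", "adj", "labels", "edge_labels", "atom_indices")

    def __init__(self, n: int):
        self.n = n
        self.adj: list[list[int]] = [[] for _ in range(n)]
        self.labels: list[str] = [""] * n
        self.edge_labels: dict[tuple[int, int], str] = {}
        self.atom_indices: list[int] = list(range(n))


def _atom_label(atom: Chem.Atom, flags: frozenset[str]) -> str:
    parts = [atom.GetSymbol(), str(atom.GetFormalCharge())]
    if "A" in flags:
        parts.append("ar" if atom.GetIsAromatic() else "al")
    if "C" in flags:
        heavy_deg = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        parts.append(f"c{heavy_deg}")
    if "D" in flags:
        parts.append(("D" if _is_donor(atom) else "-") + ("A" if _is_acceptor(atom) else "-"))
    return ",".join(parts)


def _build_parent_graph(mol: StandardizedMolecule, flags: frozenset[str]) -> _ParentGraph:
    rdmol = mol.mol
    if "H" in flags:
        rdmol = Chem.AddHs(rdmol)
    n = rdmol.GetNumAtoms()
    g = _ParentGraph(n)
    for atom in rdmol.GetAtoms():
        g.labels[atom.GetIdx()] = _atom_label(atom, flags)
    use_bond_order = "B" in flags
    for bond in rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        g.adj[i].append(j)
        g.adj[j].append(i)
        label = f"{bond.GetBondTypeAsDouble():g}" if use_bond_order else "-"
        g.edge_labels[(i, j) if i < j else (j, i)] = label
    return g


# ---------------------------------------------------------------------------
# canonical fragment keys (refinement + individualization on the subgraph)


def _refine(colors: list, adj: list[list[int]], elab: list[list[str]]) -> list[int]:
    """Iterative color refinement; returns integer colors (stable partition)."""
    k = len(colors)
    # normalize incoming colors to ints by sorted rank
    order = sorted(set(colors), key=repr)
    rank = {c: i for i, c in enumerate(order)}
    cur = [rank[c] for c in colors]
    n_colors = len(order)
    while True:
        sigs = [
            (cur[v], tuple(sorted((elab[v][idx], cur[u]) for idx, u in enumerate(adj[v]))))
            for v in range(k)
        ]
        uniq = sorted(set(sigs))
        if len(uniq) == n_colors:
            return cur
        srank = {s: i for i, s in enumerate(uniq)}
        cur = [srank[s] for s in sigs]
        n_colors = len(uniq)


def _serialize(order: list[int], labels: list[str], adj: list[list[int]], elab: list[list[str]]) -> str:
    pos = {v: i for i, v in enumerate(order)}
    node_part = ";".join(labels[v] for v in order)
    edges = []
    for v in order:
        for idx, u in enumerate(adj[v]):
            if pos[v] < pos[u]:
                edges.append((pos[v], pos[u], elab[v][idx]))
    edges.sort()
    edge_part = ";".join(f"{a}-{b}:{l}" for a, b, l in edges)
    return node_part + "|" + edge_part


def _canon_search(
    colors: list, labels: list[str], adj: list[list[int]], elab: list[list[str]]
) -> str:
    colors = _refine(colors, adj, elab)
    k = len(colors)
    cells: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        order = sorted(range(k), key=lambda v: colors[v])
        return _serialize(order, labels, adj, elab)
    best = None
    for v in target:
        branched = list(colors)
        branched[v] = -1 - branched[v]  # individualize: fresh, deterministic color
        s = _canon_search(branched, labels, adj, elab)
        if best is None or s < best:
            best = s
    return best


def _fragment_key_from_subset(subset: Sequence[int], parent: _ParentGraph) -> FragmentKey:
    k = len(subset)
    local = {v: i for i, v in enumerate(subset)}
    labels = [parent.labels[v] for v in subset]
    if k == 1:
        return FragmentKey(key=labels[0] + "|", atom_count=1)
    adj: list[list[int]] = [[] for _ in range(k)]
    elab: list[list[str]] = [[] for _ in range(k)]
    for v in subset:
        iv = local[v]
        for u in parent.adj[v]:
            iu = local.get(u)
            if iu is not None:
                adj[iv].append(iu)
                e = (v, u) if v < u else (u, v)
                elab[iv].append(parent.edge_labels[e])
    key = _canon_search(list(labels), labels, adj, elab)
    return FragmentKey(key=key, atom_count=k)


def canonical_fragment_key(
    mol: StandardizedMolecule, atoms: Iterable[int], distinctions: Iterable[str] = ("A", "C")
) -> FragmentKey:
    """Canonical key of the vertex-induced subgraph on ``atoms``.

    Atom indices refer to the heavy-atom molecule (or the H-explicit
    molecule when flag H is active).  The key is invariant to atom
    relabeling; a disconnected subset raises ``ValueError``.
    """
    flags = frozenset(distinctions)
    if not flags <= VALID_DISTINCTIONS:
        raise ValueError(f"unknown distinction flags: {sorted(flags - VALID_DISTINCTIONS)}")
    parent = _build_parent_graph(mol, flags)
    subset = list(dict.fromkeys(atoms))
    if not subset:
        raise ValueError("empty atom subset")
    if any(not 0 <= a < parent.n for a in subset):
        raise ValueError("atom index out of range")
    # connectivity check by BFS within the subset
    in_set = set(subset)
    seen = {subset[0]}
    stack = [subset[0]]
    while stack:
        v = stack.pop()
        for u in parent.adj[v]:
            if u in in_set and u not in seen:
                seen.add(u)
                stack.append(u)
    if len(seen) != len(subset):
        raise ValueError("subgraph is disconnected")
    return _fragment_key_from_subset(subset, parent)


# ---------------------------------------------------------------------------
# connected-subgraph enumeration (ESU with exclusive neighborhoods)


def _enumerate_subsets(
    adj: list[list[int]], min_atoms: int, max_atoms: int, cap: int
) -> list[tuple[int, ...]]:
    """All connected vertex-induced subgraphs with size in [min, max].

    Wernicke-style enumeration: each subgraph is emitted exactly once, at
    the recursion rooted at its smallest vertex.
    """
    n = len(adj)
    out: list[tuple[int, ...]] = []

    def extend(sub: list[int], ext: list[int], closed: set[int], start: int) -> None:
        if len(sub) >= min_atoms:
            out.append(tuple(sub))
            if len(out) > cap:
                raise EnumerationCapExceeded(
                    f"more than {cap} fragments enumerated; raise enumeration_cap "
                    f"or narrow the size window"
                )
        if len(sub) == max_atoms:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_nodes = [u for u in adj[w] if u > start and u not in closed]
            closed.update(new_nodes)
            sub.append(w)
            extend(sub, ext + new_nodes, closed, start)
            sub.pop()
            closed.difference_update(new_nodes)

    for start in range(n):
        ext0 = [u for u in adj[start] if u > start]
        extend([start], ext0, set([start] + ext0), start)
    return out


def enumerate_fragments(
    mol: StandardizedMolecule, config: HologramConfig
) -> list[FragmentKey]:
    """Enumerate every fragment occurrence of ``mol`` under ``config``.

    Returns one :class:`FragmentKey` per occurrence (duplicates reflect
    multiple occurrences of the same fragment).  Linear, branched, and
    cyclic fragments are all covered since every connected vertex-induced
    subgraph in the size window is visited.
    """
    if mol.num_heavy_atoms == 0:
        raise ValueError(f"molecule {mol.id!r} has no heavy atoms")
    parent = _build_parent_graph(mol, config.distinctions)
    subsets = _enumerate_subsets(
        parent.adj, config.min_atoms, config.max_atoms, config.enumeration_cap
    )
    return [_fragment_key_from_subset(s, parent) for s in subsets]


# ---------------------------------------------------------------------------
# hashing and hologram assembly


def hash_to_bin(key: FragmentKey, L: int) -> int:
    """Map a fragment key to a bin index in 1..L via CRC-32 (IEEE) mod L."""
    if not key.key:
        raise ValueError("empty fragment key")
    return zlib.crc32(key.key.encode("utf-8")) % L + 1


def build_hologram(occurrences: Sequence[FragmentKey], L: int) -> Hologram:
    """Accumulate fragment occurrences into an L-bin hologram."""
    if L not in ALLOWED_LENGTHS:
        raise ValueError(f"L must be one of {sorted(ALLOWED_LENGTHS)}")
    bins = np.zeros(L, dtype=np.int64)
    for occ in occurrences:
        bins[hash_to_bin(occ, L) - 1] += 1
    return Hologram(bins=bins, total_fragments=len(occurrences))


def hologram_matrix(
    mols: Sequence[StandardizedMolecule],
    config: HologramConfig,
    skip_errors: bool = False,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Stack per-molecule holograms into an (n_molecules, L) count matrix.

    Returns ``(matrix, ids, failures)`` where ``failures`` lists
    ``(id, reason)`` pairs.  Any enumeration failure aborts the run unless
    ``skip_errors`` is set, in which case the offending row is dropped.
    """
    if not mols:
        raise ValueError("empty molecule list")
    rows = []
    ids = []
    failures: list[tuple[str, str]] = []
    for m in mols:
        try:
            occ = enumerate_fragments(m, config)
        except (ValueError, EnumerationCapExceeded) as exc:
            if not skip_errors:
                raise RuntimeError(f"hologram failed for molecule {m.id!r}: {exc}") from exc
            failures.append((m.id, str(exc)))
            continue
        rows.append(build_hologram(occ, config.length_L).bins)
        ids.append(m.id)
    if not rows:
        raise RuntimeError("no molecule produced a hologram")
    return np.vstack(rows), ids, failures
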
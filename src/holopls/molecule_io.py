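"""Reading, standardization, fingerprinting, and diversity splitting of molecules.

Standardization keeps the largest covalent fragment (counterion removal),
counts implicit hydrogens, and produces a canonical serialization that is
invariant to input atom ordering.  Diversity splitting is greedy MaxMin on
Tanimoto distances over hashed circular fingerprints (radius 3, i.e. a
diameter-6 circular environment, 2048 bits by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedMolecule",
    "CircularFingerprint",
    "SplitResult",
    "RejectedRecord",
    "LoadResult",
    "load_molecules",
    "standardize",
    "circular_fingerprint",
    "tanimoto_distance",
    "maxmin_diverse_select",
    "write_rejects_report",
]


@dataclass(frozen=True)
class StandardizedMolecule:
    """A standardized heavy-atom molecule.

    ``mol`` is the backing RDKit molecule (largest fragment, implicit
    hydrogens); ``canonical_smiles`` is its order-invariant serialization.
    """

    id: str
    mol: Chem.Mol
    canonical_smiles: str

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def graph(self) -> nx.Graph:
        """Heavy-atom graph with element/charge/aromaticity/degree annotations."""
        g = nx.Graph()
        for atom in self.mol.GetAtoms():
            g.add_node(
                atom.GetIdx(),
                element=atom.GetSymbol(),
                formal_charge=atom.GetFormalCharge(),
                aromatic=atom.GetIsAromatic(),
                heavy_degree=sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1),
                num_h=atom.GetTotalNumHs(),
                donor=_is_donor(atom),
                acceptor=_is_acceptor(atom),
            )
        for bond in self.mol.GetBonds():
            g.add_edge(
                bond.GetBeginAtomIdx(),
                bond.GetEndAtomIdx(),
                order=bond.GetBondTypeAsDouble(),
                aromatic=bond.GetIsAromatic(),
            )
        return g


def _is_donor(atom: Chem.Atom) -> bool:
    """H-bond donor: N or O carrying at least one hydrogen."""
    return atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() > 0


def _is_acceptor(atom: Chem.Atom) -> bool:
    """H-bond acceptor: any N or O (simple Lipinski-style rule)."""
    return atom.GetSymbol() in ("N", "O")


@dataclass(frozen=True)
class CircularFingerprint:
    id: str
    on_bits: frozenset[int]
    radius: int = 3
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if any(not 0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("bit indices must lie in [0, n_bits)")


@dataclass
class RejectedRecord:
    id: str
    line_no: int
    reason: str


@dataclass
class LoadResult:
    molecules: list[StandardizedMolecule]
    rejects: list[RejectedRecord] = field(default_factory=list)


@dataclass
class SplitResult:
    """Outcome of MaxMin diversity selection."""

    selected_ids: list[str]
    remaining_ids: list[str]
    min_distance_trace: list[float]


def standardize(raw: Chem.Mol, mol_id: str = "") -> StandardizedMolecule:
    """Standardize a parsed molecule.

    Keeps the largest covalent fragment by heavy-atom count (ties broken
    by the lexicographically smallest canonical SMILES), sanitizes, and
    computes the canonical serialization.
    """
    if raw is None:
        raise ValueError("cannot standardize a null molecule")
    frags = Chem.GetMolFrags(raw, asMols=True, sanitizeFrags=False)
    if not frags:
        raise ValueError(f"molecule {mol_id!r} is empty after fragment splitting")
    best = None
    best_key = None
    for frag in frags:
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        key = (-frag.GetNumHeavyAtoms(), Chem.MolToSmiles(frag))
        if best_key is None or key < best_key:
            best, best_key = frag, key
    if best is None or best.GetNumHeavyAtoms() == 0:
        raise ValueError(f"molecule {mol_id!r} has no sanitizable heavy-atom fragment")
    return StandardizedMolecule(id=mol_id, mol=best, canonical_smiles=Chem.MolToSmiles(best))


def load_molecules(path: str | Path, fmt: str | None = None) -> LoadResult:
    """Load and standardize molecules from a .smi or .sdf file.

    ``fmt`` defaults to the file extension.  Input order is preserved;
    unparsable records are collected in ``rejects`` (and logged) rather
    than silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("smi", "sdf"):
        raise ValueError(f"unsupported format {fmt!r}; expected 'smi' or 'sdf'")

    result = LoadResult(molecules=[])
    if fmt == "smi":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"line{line_no}"
                raw = Chem.MolFromSmiles(smiles)
                if raw is None:
                    logger.warning("line %d (%s): unparsable SMILES %r", line_no, mol_id, smiles)
                    result.rejects.append(RejectedRecord(mol_id, line_no, "unparsable SMILES"))
                    continue
                try:
                    result.molecules.append(standardize(raw, mol_id))
                except ValueError as exc:
                    logger.warning("line %d (%s): %s", line_no, mol_id, exc)
                    result.rejects.append(RejectedRecord(mol_id, line_no, str(exc)))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for rec_no, raw in enumerate(supplier, start=1):
            if raw is None:
                logger.warning("SDF record %d: unparsable", rec_no)
                result.rejects.append(RejectedRecord(f"record{rec_no}", rec_no, "unparsable record"))
                continue
            mol_id = raw.GetProp("_Name") if raw.HasProp("_Name") and raw.GetProp("_Name") else f"record{rec_no}"
            try:
                result.molecules.append(standardize(raw, mol_id))
            except ValueError as exc:
                logger.warning("SDF record %d (%s): %s", rec_no, mol_id, exc)
                result.rejects.append(RejectedRecord(mol_id, rec_no, str(exc)))
    return result


def write_rejects_report(rejects: Sequence[RejectedRecord], path: str | Path) -> None:
    """Write the rejects report CSV (columns: id, line_no, reason)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "line_no", "reason"])
        for rec in rejects:
            writer.writerow([rec.id, rec.line_no, rec.reason])


def circular_fingerprint(
    mol: StandardizedMolecule, radius: int = 3, n_bits: int = 2048
) -> CircularFingerprint:
    """Hashed circular (Morgan) fingerprint of the standardized molecule."""
    if n_bits < 64:
        raise ValueError(f"n_bits must be >= 64, got {n_bits}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol.mol)
    return CircularFingerprint(
        id=mol.id, on_bits=frozenset(bv.GetOnBits()), radius=radius, n_bits=n_bits
    )


def tanimoto_distance(a: CircularFingerprint, b: CircularFingerprint) -> float:
    """1 - |A∩B| / |A∪B|.  Two empty fingerprints have distance 0 (logged)."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        logger.info("both fingerprints empty (%s, %s): distance 0 by convention", a.id, b.id)
        return 0.0
    return 1.0 - len(a.on_bits & b.on_bits) / union


def maxmin_diverse_select(
    fps: Sequence[CircularFingerprint], n_select: int, seed: int = 0
) -> SplitResult:
    """Greedy MaxMin diversity selection on Tanimoto distances.

    The first pick is a seeded-random index into the population; each
    subsequent pick maximizes the minimum Tanimoto distance to the
    already-selected set, breaking ties by input order.  Deterministic
    for a fixed seed and input order.
    """
    import random

    n = len(fps)
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}], got {n_select}")
    first = random.Random(seed).randrange(n)
    selected = [first]
    trace: list[float] = []
    # min distance from each candidate to the selected set, updated incrementally
    min_dist = [tanimoto_distance(fps[i], fps[first]) for i in range(n)]
    min_dist[first] = float("-inf")
    while len(selected) < n_select:
        best = max(range(n), key=lambda i: (min_dist[i], -i))
        trace.append(min_dist[best])
        selected.append(best)
        min_dist[best] = float("-inf")
        for i in range(n):
            if min_dist[i] > float("-inf"):
                d = tanimoto_distance(fps[i], fps[best])
                if d < min_dist[i]:
                    min_dist[i] = d
    chosen = set(selected)
    return SplitResult(
        selected_ids=[fps[i].id for i in selected],
        remaining_ids=[fps[i].id for i in range(n) if i not in chosen],
        min_distance_trace=trace,
    )
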
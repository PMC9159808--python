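"""Atomic contribution mapping from PLS coefficients over hologram bins.

Every fragment occurrence is generated in turn; each atom in the fragment
receives the PLS coefficient of the fragment's bin divided by the number
of atoms in the fragment.  Per-atom scores accumulate over all
occurrences containing the atom, so the sum over atoms equals the sum of
per-occurrence coefficients exactly.  Colliding fragments share a bin
coefficient by construction of the hologram; no de-collision is
attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .hologram import HologramConfig, _build_parent_graph, _enumerate_subsets, _fragment_key_from_subset, hash_to_bin
from .molecule_io import StandardizedMolecule
from .plsda import PLSDAModel

__all__ = ["AtomContributionMap", "atomic_contributions", "annotate", "write_contributions_csv"]


@dataclass
class AtomContributionMap:
    """Per-heavy-atom contribution scores and their total."""

    id: str
    scores: np.ndarray
    total: float


def atomic_contributions(
    mol: StandardizedMolecule, model: PLSDAModel, config: HologramConfig
) -> AtomContributionMap:
    """Spread per-occurrence bin coefficients uniformly over fragment atoms.

    The model must have been trained on holograms of the same
    configuration: the model's input width must equal ``config.length_L``.
    Original-scale coefficients are used; bins dropped during auto-scaling
    contribute zero.  Scores are reported on heavy atoms (explicit
    hydrogens from flag H fold into their occurrence's heavy members).
    """
    if model.n_features_in != config.length_L:
        raise ValueError(
            f"config mismatch: model expects {model.n_features_in} bins but "
            f"config has L={config.length_L}"
        )
    coef = np.zeros(config.length_L)
    coef[model.kept_columns] = model.coefficients_original

    parent = _build_parent_graph(mol, config.distinctions)
    n_heavy = mol.num_heavy_atoms
    scores = np.zeros(n_heavy)
    total = 0.0
    subsets = _enumerate_subsets(
        parent.adj, config.min_atoms, config.max_atoms, config.enumeration_cap
    )
    for subset in subsets:
        key = _fragment_key_from_subset(subset, parent)
        c = coef[hash_to_bin(key, config.length_L) - 1]
        total += c
        share = c / key.atom_count
        for a in subset:
            if a < n_heavy:  # explicit hydrogens (H flag) carry no own score
                scores[a] += share
    return AtomContributionMap(id=mol.id, scores=scores, total=total)


def annotate(mol: StandardizedMolecule, cmap: AtomContributionMap) -> Chem.Mol:
    """Return a copy of the molecule with per-atom contribution properties.

    Scores are stored as the atom property ``contribution`` (full
    precision via repr) and as a molecule-level property list, so an SDF
    round-trip preserves them exactly.
    """
    if len(cmap.scores) != mol.num_heavy_atoms:
        raise ValueError(
            f"score vector length {len(cmap.scores)} != heavy-atom count {mol.num_heavy_atoms}"
        )
    out = Chem.Mol(mol.mol)
    for atom in out.GetAtoms():
        atom.SetProp("contribution", repr(float(cmap.scores[atom.GetIdx()])))
    out.SetProp("atom_contributions", ";".join(repr(float(s)) for s in cmap.scores))
    out.SetProp("contribution_total", repr(float(cmap.total)))
    if mol.id:
        out.SetProp("_Name", mol.id)
    return out


def write_contributions_csv(maps: list[AtomContributionMap], path: str | Path) -> None:
    """CSV with one row per (molecule, atom): id, atom_index, score."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "atom_index", "score"])
        for m in maps:
            for idx, s in enumerate(m.scores):
                writer.writerow([m.id, idx, repr(float(s))])
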
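"""Seeded synthetic molecule sets and surrogate descriptor tables.

Class-1 molecules are decorated aromatic scaffolds (biphenyl, quinoline,
chromene); class-0 molecules are decorated aliphatic / small polar
scaffolds.  This plants fragment-level signal that a hologram PLS-DA
pipeline can recover.  A surrogate scalar descriptor is drawn from
class-shifted Gaussians whose Bayes boundary sits at -0.1 by
construction, so the fixed threshold rule is meaningful on synthetic
data (a design convenience, not a claim about real descriptor values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .molecule_io import StandardizedMolecule, standardize

__all__ = ["FixtureSpec", "FixtureData", "generate_labeled_smiles", "generate_descriptor_table", "write_dataset"]

POSITIVE_SCAFFOLDS = (
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
    "c1ccc2ncccc2c1",  # quinoline
    "C1=Cc2ccccc2OC1",  # 2H-chromene
)
NEGATIVE_SCAFFOLDS = (
    "C1CCCCC1",  # cyclohexane
    "C1COCCN1",  # morpholine
    "CCCCCC",  # n-hexane
    "CCOCC",  # diethyl ether
    "CCCCO",  # n-butanol
)

# substituents as chains of atomic numbers, attached by single bonds
_SUBSTITUENTS: tuple[tuple[int, ...], ...] = (
    (6,),  # methyl
    (6, 6),  # ethyl
    (8,),  # hydroxyl
    (7,),  # amino
    (9,),  # fluoro
    (17,),  # chloro
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic dataset generator."""

    n_per_class: int = 200
    positive_scaffolds: tuple[str, ...] = POSITIVE_SCAFFOLDS
    negative_scaffolds: tuple[str, ...] = NEGATIVE_SCAFFOLDS
    decoration_rate: float = 0.6
    max_decorations: int = 3
    label_noise: float = 0.05
    mu_pos: float = 0.4
    mu_neg: float = -0.6
    sigma: float = 0.35
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        for name in ("decoration_rate", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for smi in (*self.positive_scaffolds, *self.negative_scaffolds):
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid scaffold SMILES: {smi!r}")


@dataclass
class FixtureData:
    """Generated molecules plus labels, keyed by identifier."""

    smiles: list[tuple[str, str]]  # (smiles, id) in emission order
    labels: dict[str, int]
    true_classes: dict[str, int] = field(default_factory=dict)


def _decorate(mol: Chem.Mol, rng: np.random.Generator, n_decor: int) -> Chem.Mol:
    """Attach up to n_decor random single-bonded substituents to carbons with free valence."""
    rw = Chem.RWMol(mol)
    for _ in range(n_decor):
        Chem.SanitizeMol(rw)
        sites = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
        ]
        if not sites:
            break
        target = sites[int(rng.integers(len(sites)))]
        chain = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        prev = target
        for z in chain:
            idx = rw.AddAtom(Chem.Atom(int(z)))
            rw.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
    Chem.SanitizeMol(rw)
    return rw.GetMol()


def generate_labeled_smiles(spec: FixtureSpec) -> FixtureData:
    """Generate the labeled SMILES set; fully deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    labels: dict[str, int] = {}
    true_classes: dict[str, int] = {}
    counter = 0
    for cls, scaffolds in ((1, spec.positive_scaffolds), (0, spec.negative_scaffolds)):
        for _ in range(spec.n_per_class):
            scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
            n_decor = int(rng.binomial(spec.max_decorations, spec.decoration_rate))
            mol = _decorate(Chem.MolFromSmiles(scaffold), rng, n_decor)
            smiles = Chem.MolToSmiles(mol)
            mol_id = f"m{counter:05d}"
            counter += 1
            label = cls
            if rng.random() < spec.label_noise:
                label = 1 - label
            records.append((smiles, mol_id))
            labels[mol_id] = label
            true_classes[mol_id] = cls
    return FixtureData(smiles=records, labels=labels, true_classes=true_classes)


def generate_descriptor_table(spec: FixtureSpec, data: FixtureData) -> pd.DataFrame:
    """Surrogate descriptor table keyed by the emitted labels.

    ``BV12_DRY_surrogate`` is Normal(mu_pos, sigma) for label 1 and
    Normal(mu_neg, sigma) for label 0 (Bayes boundary at the midpoint,
    -0.1 under the defaults).  ``LogP_surrogate`` is a nuisance column
    with heavy class overlap.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = [mol_id for _, mol_id in data.smiles]
    unknown = [i for i in ids if i not in data.labels]
    if unknown:
        raise ValueError(f"ids without labels: {unknown[:5]}")
    y = np.array([data.labels[i] for i in ids])
    mu = np.where(y == 1, spec.mu_pos, spec.mu_neg)
    surrogate = rng.normal(mu, spec.sigma)
    nuisance = rng.normal(np.where(y == 1, 2.6, 2.2), 1.5)
    return pd.DataFrame(
        {"id": ids, "BV12_DRY_surrogate": surrogate, "LogP_surrogate": nuisance}
    )


def standardized_molecules(data: FixtureData) -> list[StandardizedMolecule]:
    """Parse and standardize the generated SMILES records."""
    return [
        standardize(Chem.MolFromSmiles(smi), mol_id) for smi, mol_id in data.smiles
    ]


def write_dataset(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write molecules.smi, labels.csv, and descriptors.csv into ``outdir``.

    Output bytes are a pure function of the spec (floats rendered with
    repr, which round-trips exactly).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_labeled_smiles(spec)
    table = generate_descriptor_table(spec, data)

    smi_path = outdir / "molecules.smi"
    with open(smi_path, "w") as fh:
        for smi, mol_id in data.smiles:
            fh.write(f"{smi} {mol_id}\n")

    labels_path = outdir / "labels.csv"
    with open(labels_path, "w") as fh:
        fh.write("id,label\n")
        for _, mol_id in data.smiles:
            fh.write(f"{mol_id},{data.labels[mol_id]}\n")

    desc_path = outdir / "descriptors.csv"
    with open(desc_path, "w") as fh:
        fh.write("id,BV12_DRY_surrogate,LogP_surrogate\n")
        for _, row in table.iterrows():
            fh.write(f"{row['id']},{row['BV12_DRY_surrogate']!r},{row['LogP_surrogate']!r}\n")

    return {"smi": smi_path, "labels": labels_path, "descriptors": desc_path}
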
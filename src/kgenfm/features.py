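"""Structural featurization of drugs and proteins.

Proteins are described by CTD descriptors: for each of seven physicochemical
properties the 20 standard residues are partitioned into three classes, and
the descriptor records the class Composition (3 values), the Transition
frequencies between unordered class pairs (3 values), and the Distribution
of each class along the chain (positions of the first, 25%, 50%, 75% and
last occurrence, scaled by sequence length; 15 values) — 21 per property,
147 in total.

Drugs are described by hashed circular (Morgan) fingerprints computed from
SMILES.  The chemistry backend is pluggable and a precomputed feature table
always bypasses it, so pipelines can run on synthetic fingerprint tables
without a cheminformatics dependency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from Bio import SeqIO

from .errors import FeaturizationError, ParseError

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Seven-property / three-class residue partitions (Dubchak-style CTD groupings).
# Each property's three classes cover the 20 standard residues exactly once;
# enforced at import by _check_groups().
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

CTD_LENGTH = 7 * 21  # 3 composition + 3 transition + 15 distribution per property


def _check_groups() -> None:
    for prop, classes in CTD_GROUPS.items():
        pooled = "".join(classes)
        if sorted(pooled) != sorted(STANDARD_RESIDUES):
            raise AssertionError(f"CTD grouping for {prop} does not partition the residues")


_check_groups()


def ctd_descriptors(sequence: str) -> np.ndarray:
    """147-dimensional Composition/Transition/Distribution descriptor.

    Distribution slots use the position of the ceil(q * n_g)-th occurrence of
    the class for q in {0.25, 0.5, 0.75}, bracketed by the first and last
    occurrence, all divided by the sequence length; absent classes yield 0.
    """
    n = len(sequence)
    if n < 2:
        raise FeaturizationError(f"sequence too short ({n} residues; need >= 2)")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in STANDARD_RESIDUES:
            raise FeaturizationError(f"non-standard residue {ch!r} at position {i + 1}")

    out: list[float] = []
    for prop, classes in CTD_GROUPS.items():
        cls_of = {}
        for g, members in enumerate(classes):
            for ch in members:
                cls_of[ch] = g
        labels = np.array([cls_of[ch] for ch in seq])
        # Composition
        counts = np.bincount(labels, minlength=3)
        out.extend(counts / n)
        # Transition over unordered class pairs (0,1), (0,2), (1,2)
        a, b = labels[:-1], labels[1:]
        for g, h in ((0, 1), (0, 2), (1, 2)):
            t = np.sum((a == g) & (b == h)) + np.sum((a == h) & (b == g))
            out.append(t / (n - 1))
        # Distribution: first / 25% / 50% / 75% / last occurrence per class
        for g in range(3):
            pos = np.flatnonzero(labels == g) + 1  # 1-based
            if len(pos) == 0:
                out.extend([0.0] * 5)
                continue
            ng = len(pos)
            slots = [pos[0]]
            for q in (0.25, 0.5, 0.75):
                slots.append(pos[math.ceil(q * ng) - 1])
            slots.append(pos[-1])
            out.extend(s / n for s in slots)
    vec = np.array(out, float)
    assert vec.shape == (CTD_LENGTH,)
    return vec


def _rdkit_backend(smiles: str, radius: int, n_bits: int) -> np.ndarray:
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.int8)


def circular_fingerprint(
    smiles: str,
    radius: int = 2,
    n_bits: int = 2048,
    backend: Callable[[str, int, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Hashed circular-substructure bit vector (Morgan fingerprint).

    Deterministic: identical input gives identical bits.  ``backend`` may
    replace the default RDKit implementation (same signature).
    """
    if radius < 0 or n_bits < 8:
        raise ValueError(f"invalid fingerprint parameters radius={radius}, n_bits={n_bits}")
    backend = backend or _rdkit_backend
    bits = np.asarray(backend(smiles, radius, n_bits))
    if bits.shape != (n_bits,):
        raise FeaturizationError(
            f"backend returned shape {bits.shape}, expected ({n_bits},)"
        )
    return bits


@dataclass
class FeatureTable:
    """Fixed-width real vectors keyed by entity id."""

    vectors: dict[str, np.ndarray]
    block_name: str
    width: int

    def __post_init__(self) -> None:
        for e, v in self.vectors.items():
            v = np.asarray(v, float)
            if v.shape != (self.width,):
                raise ValueError(f"{self.block_name}: {e} has width {v.shape}, want {self.width}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{self.block_name}: non-finite values for {e}")
            self.vectors[e] = v

    def matrix(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.stack([self.vectors[e] for e in ids])
        except KeyError as exc:
            raise FeaturizationError(
                f"no {self.block_name} features for entity {exc.args[0]!r}"
            ) from None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# block={self.block_name}\twidth={self.width}\n")
            for e in sorted(self.vectors):
                vals = "\t".join(repr(float(v)) for v in self.vectors[e])
                fh.write(f"{e}\t{vals}\n")


def read_feature_table(path: str | Path, block_name: str | None = None) -> FeatureTable:
    """Read a feature-table TSV written by :meth:`FeatureTable.write_tsv`."""
    vectors: dict[str, np.ndarray] = {}
    width = None
    name = block_name or "features"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("# block="):
            fields = dict(part.split("=", 1) for part in first[2:].split("\t"))
            name = block_name or fields["block"]
            width = int(fields["width"])
        elif first and not first.startswith("#"):
            parts = first.split("\t")
            width = len(parts) - 1
            vectors[parts[0]] = np.array(parts[1:], float)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if width is None:
                width = len(parts) - 1
            if len(parts) != width + 1:
                raise ParseError(f"{path}:{lineno}: expected {width + 1} fields, got {len(parts)}")
            vectors[parts[0]] = np.array(parts[1:], float)
    return FeatureTable(vectors=vectors, block_name=name, width=width or 0)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_smiles(path: str | Path) -> dict[str, str]:
    """2-column TSV (id <TAB> smiles) -> id -> SMILES map."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            out[parts[0]] = parts[1]
    return out


def protein_feature_table(sequences: dict[str, str]) -> FeatureTable:
    """CTD descriptors for a set of sequences."""
    vecs = {}
    for pid, seq in sequences.items():
        try:
            vecs[pid] = ctd_descriptors(seq)
        except FeaturizationError as exc:
            raise FeaturizationError(f"{pid}: {exc}") from None
    return FeatureTable(vectors=vecs, block_name="protein-structure", width=CTD_LENGTH)


def drug_feature_table(
    smiles: dict[str, str],
    radius: int = 2,
    n_bits: int = 2048,
    backend: Callable[[str, int, int], np.ndarray] | None = None,
) -> FeatureTable:
    """Circular fingerprints for a set of SMILES.

    A drug with no SMILES (and no precomputed row elsewhere) is a hard error:
    silent zero-vectors would corrupt training.
    """
    vecs = {}
    for did, smi in smiles.items():
        try:
            vecs[did] = circular_fingerprint(smi, radius, n_bits, backend).astype(float)
        except FeaturizationError as exc:
            raise FeaturizationError(f"{did}: {exc}") from None
    return FeatureTable(vectors=vecs, block_name="drug-structure", width=n_bits)
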
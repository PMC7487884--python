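"""Attribute features and pair-feature assembly.

Every drug and protein node gets a 64-dimensional *attribute* vector
describing the molecule itself, to sit alongside the 64-dimensional
*behaviour* vector learned from the association network:

* proteins -- the conjoint-triad descriptor: the 20 amino acids are
  collapsed into 4 side-chain polarity groups, every overlapping 3-mer is
  mapped to one of 4^3 = 64 group triples, and the vector holds the
  occurrence frequency of each triple (non-negative, sums to 1);
* drugs -- a Morgan (circular, radius-2) fingerprint folded to 64 bits,
  or any precomputed binary fingerprint OR-folded to 64 bits.

A node's combined representation is the 128-dim concatenation
``attribute || behaviour``; a drug-protein pair is the 256-dim ordered
concatenation ``drug(128) || protein(128)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AssemblyError,
    ConfigError,
    DegenerateSequenceError,
    ParseError,
    StructureError,
)

ATTRIBUTE_DIM = 64
NODE_DIM = 128
PAIR_DIM = 256

#: Amino-acid side-chain polarity groups (conjoint-triad reduced alphabet):
#: 0 = Arg/Lys/His, 1 = Gly/Cys/Ser/Gln/Thr/Asn/Tyr,
#: 2 = Ala/Ile/Trp/Val/Leu/Phe/Pro/Met, 3 = Glu/Asp.
REDUCED_ALPHABET: dict[str, int] = {}
for _letters, _group in (("RKH", 0), ("GCSQTNY", 1), ("AIWVLFPM", 2), ("ED", 3)):
    for _aa in _letters:
        REDUCED_ALPHABET[_aa] = _group


def classify_residue(aa: str) -> int:
    """Group index 0-3 of one amino-acid letter; KeyError-free contract.

    Non-standard letters (B, J, O, U, X, Z, gaps) return -1; the triad
    encoder skips windows containing them.
    """
    if len(aa) != 1:
        raise ConfigError(f"expected a single residue letter, got {aa!r}")
    return REDUCED_ALPHABET.get(aa.upper(), -1)


@dataclass
class AttributeVector:
    """A 64-dim intrinsic descriptor owned by one drug or protein."""

    values: np.ndarray
    owner: str
    kind: str  # 'protein' or 'drug'
    skipped_windows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (ATTRIBUTE_DIM,):
            raise AssemblyError(
                f"attribute vector for {self.owner!r} has shape "
                f"{self.values.shape}, expected ({ATTRIBUTE_DIM},)"
            )


def triad_index(g1: int, g2: int, g3: int) -> int:
    """Bijection from a group triple to 0..63 (base-4 encoding, 16*g1+4*g2+g3)."""
    return 16 * g1 + 4 * g2 + g3


def conjoint_triad_vector(sequence: str, owner: str = "") -> AttributeVector:
    """Sliding-window 3-mer frequency vector over the reduced alphabet.

    Windows containing a non-standard residue are skipped and excluded
    from the denominator; their count is reported on the returned vector.
    """
    groups = [classify_residue(aa) for aa in sequence]
    counts = np.zeros(ATTRIBUTE_DIM)
    skipped = 0
    for k in range(len(groups) - 2):
        g1, g2, g3 = groups[k], groups[k + 1], groups[k + 2]
        if g1 < 0 or g2 < 0 or g3 < 0:
            skipped += 1
            continue
        counts[triad_index(g1, g2, g3)] += 1
    total = counts.sum()
    if total == 0:
        raise DegenerateSequenceError(
            f"sequence {owner or sequence[:12]!r} has fewer than 3 usable residues"
        )
    if skipped:
        warnings.warn(
            f"{owner or 'sequence'}: skipped {skipped} 3-mer window(s) with "
            "non-standard residues",
            stacklevel=2,
        )
    return AttributeVector(counts / total, owner, "protein", skipped)


def fold_bits(bits: Sequence[int] | np.ndarray, n_bits: int = ATTRIBUTE_DIM) -> np.ndarray:
    """OR-fold a binary vector onto ``n_bits`` positions (bit j -> j mod n).

    Every input bit influences exactly one output position; folding an
    ``n_bits``-long input is the identity.
    """
    bits = np.asarray(bits)
    if bits.ndim != 1 or bits.size < n_bits:
        raise ConfigError(f"need a 1-d bit vector of length >= {n_bits}")
    if not np.isin(bits, (0, 1)).all():
        raise ConfigError("fingerprint vector must be binary")
    out = np.zeros(n_bits, dtype=np.uint8)
    for start in range(0, bits.size, n_bits):
        block = bits[start : start + n_bits]
        out[: block.size] |= block.astype(np.uint8)
    return out


def drug_attribute_vector(structure: str | Sequence[int] | np.ndarray, owner: str = "") -> AttributeVector:
    """64-bit drug fingerprint from a SMILES string or a precomputed vector.

    The SMILES path computes a radius-2 Morgan fingerprint (1024 bits) and
    OR-folds it to 64; it is the only code touching the chemistry toolkit,
    so pipelines fed precomputed fingerprints never import it.
    """
    if isinstance(structure, str):
        bits = _morgan_bits(structure)
    else:
        bits = np.asarray(structure)
    return AttributeVector(fold_bits(bits).astype(float), owner, "drug")


def _morgan_bits(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol)


@dataclass
class NodeFeature:
    """attribute(64) || behaviour(64) = combined(128) for one node."""

    owner: str
    attribute: np.ndarray
    behavior: np.ndarray
    combined: np.ndarray


def assemble_node_feature(attr: AttributeVector, behavior: np.ndarray, owner: str | None = None) -> NodeFeature:
    """Concatenate attribute and behaviour vectors, attribute first."""
    behavior = np.asarray(behavior, dtype=float)
    owner = owner if owner is not None else attr.owner
    if attr.owner and owner and attr.owner != owner:
        raise AssemblyError(f"owner mismatch: {attr.owner!r} vs {owner!r}")
    if behavior.shape != (ATTRIBUTE_DIM,):
        raise AssemblyError(
            f"behaviour vector for {owner!r} has shape {behavior.shape}, "
            f"expected ({ATTRIBUTE_DIM},)"
        )
    return NodeFeature(owner, attr.values, behavior, np.concatenate([attr.values, behavior]))


@dataclass
class FeatureMatrix:
    """Labelled drug-protein pair rows and their feature matrix."""

    pairs: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray | None

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.X.shape[1])])
        df.insert(0, "drug_id", [d for d, _ in self.pairs])
        df.insert(1, "protein_id", [p for _, p in self.pairs])
        df.insert(2, "label", self.y if self.y is not None else np.nan)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f")]
        y = None if df["label"].isna().all() else df["label"].to_numpy(dtype=int)
        return cls(
            list(zip(df["drug_id"], df["protein_id"])),
            df[feat_cols].to_numpy(dtype=float),
            y,
        )


def assemble_pair_matrix(
    pairs: Iterable[tuple[str, str, int | None]],
    node_features: Mapping[str, NodeFeature | np.ndarray],
) -> FeatureMatrix:
    """Stack per-pair rows ``drug_vec || protein_vec`` in the given order.

    Fails closed, reporting every pair endpoint missing from
    ``node_features``.  Accepts plain vectors or :class:`NodeFeature`.
    """
    pairs = list(pairs)
    missing = sorted(
        {n for d, p, _ in pairs for n in (d, p) if n not in node_features}
    )
    if missing:
        raise AssemblyError("missing node features for: " + ", ".join(missing))

    def vec(name: str) -> np.ndarray:
        f = node_features[name]
        return f.combined if isinstance(f, NodeFeature) else np.asarray(f, dtype=float)

    rows = [np.concatenate([vec(d), vec(p)]) for d, p, _ in pairs]
    labels = [lab for _, _, lab in pairs]
    y = None if any(lab is None for lab in labels) else np.asarray(labels, dtype=int)
    return FeatureMatrix([(d, p) for d, p, _ in pairs], np.asarray(rows), y)


# ---------------------------------------------------------------------------
# file I/O: FASTA sequences and fingerprint / SMILES tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (standard FASTA)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """``drug_id<TAB>bitstring`` rows into binary vectors."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not set(parts[1]) <= {"0", "1"}:
                raise ParseError(f"{path}: line {lineno}: expected 'id<TAB>bitstring'")
            out[parts[0]] = np.frombuffer(parts[1].encode(), dtype=np.uint8) - ord("0")
    return out


def write_fingerprints(fps: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in fps:
            fh.write(name + "\t" + "".join(str(int(b)) for b in fps[name]) + "\n")


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``drug_id,smiles``."""
    df = pd.read_csv(path)
    if not {"drug_id", "smiles"} <= set(df.columns):
        raise ParseError(f"{path}: need columns drug_id,smiles")
    return dict(zip(df["drug_id"], df["smiles"]))
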
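"""Synthetic data with the statistical structure the pipeline assumes.

The generator plants a block (module) structure over all five node types
and lets that structure show up in three places, each independently
switchable:

* the association network -- a planted-partition (SBM-like) graph over
  the eight association classes: node pairs in the same block are linked
  with probability ``p_in``, across blocks with ``p_out``;
* protein sequences and drug fingerprints -- each block biases one
  reduced-alphabet group / one set of fingerprint bits, so attribute
  vectors carry the block signal when ``signal_mode`` is ``sequence`` or
  ``both`` and are exchangeable in ``network`` mode;
* drug-target labels -- same-block drug-protein pairs interact with
  probability ``base_rate * lift``, others with ``base_rate``, then every
  pair's label is flipped with probability ``label_noise``.

Blocks are assigned round-robin within each node type, so block sizes are
balanced and the planted pair counts are stable across seeds.  No claim
of biological realism is made: the construction gives the behaviour
features a recoverable signal because shared neighbourhoods are exactly
what second-order proximity encodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .features import REDUCED_ALPHABET, write_fasta, write_fingerprints
from .network import NETWORK_CLASSES, ASSOCIATION_CLASSES, HeteroGraph, write_edge_tables

_TYPE_PREFIX = {
    "drug": "drug",
    "protein": "prot",
    "lncRNA": "lnc",
    "miRNA": "mir",
    "disease": "dis",
}

SIGNAL_MODES = ("network", "sequence", "both")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Node counts scale the five-type mix down to 260 nodes; ``p_in/p_out``
    of 0.25/0.02 give a strongly assortative network; planted interactions
    are (nearly) module-determined: every same-block drug-protein pair
    interacts (``base_rate * lift = 1``) against a 1% cross-block
    background, observed through 5% label noise.
    """

    n_drugs: int = 30
    n_proteins: int = 80
    n_lncrna: int = 40
    n_mirna: int = 50
    n_disease: int = 60
    n_blocks: int = 3
    p_in: float = 0.25
    p_out: float = 0.02
    signal_mode: str = "both"
    label_noise: float = 0.05
    base_rate: float = 0.01
    lift: float = 100.0
    signal_strength: float = 0.5
    min_seq_length: int = 150
    max_seq_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_drugs, self.n_proteins, self.n_lncrna, self.n_mirna, self.n_disease)
        if any(c < 1 for c in counts):
            raise ConfigError("all node counts must be >= 1")
        if self.n_blocks < 2:
            raise ConfigError("n_blocks must be >= 2")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ConfigError("need 0 <= p_out <= p_in <= 1")
        if self.signal_mode not in SIGNAL_MODES:
            raise ConfigError(f"signal_mode must be one of {SIGNAL_MODES}")
        if not 0 <= self.label_noise < 0.5:
            raise ConfigError("label_noise must be in [0, 0.5)")
        if self.lift < 1:
            raise ConfigError("lift must be >= 1")
        if not 0 <= self.base_rate * self.lift <= 1 or not 0 <= self.base_rate <= 1:
            raise ConfigError("interaction probabilities must lie in [0, 1]")
        if self.min_seq_length < 3 or self.max_seq_length < self.min_seq_length:
            raise ConfigError("sequence length range must be >= 3 and ordered")

    def type_counts(self) -> dict[str, int]:
        return {
            "drug": self.n_drugs,
            "protein": self.n_proteins,
            "lncRNA": self.n_lncrna,
            "miRNA": self.n_mirna,
            "disease": self.n_disease,
        }


@dataclass
class SyntheticTruth:
    """Planted ground truth: block per node and the pre-noise DTI pairs."""

    blocks: dict[str, int]
    true_pairs: set[tuple[str, str]] = field(default_factory=set)


def _derive_seed(seed: int, salt: int) -> int:
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(salt)) % np.uint64(2**31 - 1))


def _node_names(config: SyntheticConfig) -> dict[str, list[str]]:
    return {
        t: [f"{_TYPE_PREFIX[t]}_{i:03d}" for i in range(n)]
        for t, n in config.type_counts().items()
    }


def _block_labels(config: SyntheticConfig) -> dict[str, int]:
    """Round-robin block assignment within each node type (balanced)."""
    blocks: dict[str, int] = {}
    for names in _node_names(config).values():
        for i, name in enumerate(names):
            blocks[name] = i % config.n_blocks
    return blocks


def generate_network(config: SyntheticConfig) -> tuple[HeteroGraph, SyntheticTruth]:
    """Planted-partition heterogeneous network over the eight edge classes."""
    rng = np.random.default_rng(_derive_seed(config.seed, 11))
    names = _node_names(config)
    blocks = _block_labels(config)
    g = HeteroGraph()
    for t, node_list in names.items():
        for name in node_list:
            g.add_node(name, t)
    for cls in NETWORK_CLASSES:
        src_t, dst_t = ASSOCIATION_CLASSES[cls]
        src_names, dst_names = names[src_t], names[dst_t]
        b_src = np.array([blocks[n] for n in src_names])
        b_dst = np.array([blocks[n] for n in dst_names])
        same = b_src[:, None] == b_dst[None, :]
        p = np.where(same, config.p_in, config.p_out)
        draw = rng.random(p.shape) < p
        if src_t == dst_t:
            draw = np.triu(draw, k=1)  # unordered pairs once, no self-loops
        for i, j in zip(*np.nonzero(draw)):
            g.add_edge(src_names[i], dst_names[j])
    return g, SyntheticTruth(blocks)


def generate_sequences(
    names: list[str],
    blocks: Mapping[str, int],
    signal_strength: float,
    seed: int,
    min_length: int = 150,
    max_length: int = 400,
) -> dict[str, str]:
    """Random amino-acid sequences with a block-biased group composition.

    With strength ``s``, a residue is drawn from the block's favoured
    reduced-alphabet group with probability ``s`` and uniformly from all
    20 letters otherwise; ``s = 0`` makes blocks exchangeable.
    """
    if min_length < 3:
        raise ConfigError("sequences must be at least 3 residues long")
    rng = np.random.default_rng(seed)
    letters = np.array(sorted(REDUCED_ALPHABET))
    group_of = np.array([REDUCED_ALPHABET[aa] for aa in letters])
    out: dict[str, str] = {}
    for name in names:
        favoured = blocks[name] % 4
        in_group = group_of == favoured
        p = np.full(len(letters), (1.0 - signal_strength) / len(letters))
        p[in_group] += signal_strength / in_group.sum()
        length = int(rng.integers(min_length, max_length + 1))
        out[name] = "".join(rng.choice(letters, size=length, p=p))
    return out


def generate_drug_bits(
    names: list[str],
    blocks: Mapping[str, int],
    signal_strength: float,
    seed: int,
    n_bits: int = 64,
    baseline: float = 0.1,
) -> dict[str, np.ndarray]:
    """64-bit fingerprints with block-biased bit probabilities.

    Block ``b`` owns the 8-bit window starting at ``8b mod n_bits``; those
    bits fire with probability ``baseline + 0.8 * signal_strength``
    (capped at 0.95), all others at ``baseline``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in names:
        p = np.full(n_bits, baseline)
        start = (8 * blocks[name]) % n_bits
        idx = (np.arange(8) + start) % n_bits
        p[idx] = min(0.95, baseline + 0.8 * signal_strength)
        out[name] = (rng.random(n_bits) < p).astype(np.uint8)
    return out


def plant_dti_labels(
    truth: SyntheticTruth,
    drugs: list[str],
    proteins: list[str],
    base_rate: float,
    lift: float,
    noise: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], int]]:
    """Block-determined interaction labels with symmetric flip noise.

    Returns the observed positives and the full observed label map over
    the drug x protein grid; ``truth.true_pairs`` records the pre-noise
    interacting pairs for evaluation.
    """
    if lift < 1:
        raise ConfigError("lift must be >= 1")
    p_same = base_rate * lift
    if not (0 <= base_rate <= 1 and 0 <= p_same <= 1):
        raise ConfigError("interaction probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    positives: list[tuple[str, str]] = []
    labels: dict[tuple[str, str], int] = {}
    truth.true_pairs = set()
    for d in drugs:
        for p in proteins:
            prob = p_same if truth.blocks[d] == truth.blocks[p] else base_rate
            y = int(rng.random() < prob)
            if y:
                truth.true_pairs.add((d, p))
            if rng.random() < noise:
                y = 1 - y
            labels[(d, p)] = y
            if y:
                positives.append((d, p))
    return positives, labels


@dataclass
class SyntheticDataset:
    """Everything one end-to-end run needs, fully determined by its config."""

    config: SyntheticConfig
    graph: HeteroGraph
    truth: SyntheticTruth
    sequences: dict[str, str]
    fingerprints: dict[str, np.ndarray]
    positives: list[tuple[str, str]]
    labels: dict[tuple[str, str], int]


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Network, sequences, fingerprints and planted labels in one bundle."""
    config = config or SyntheticConfig()
    graph, truth = generate_network(config)
    names = _node_names(config)
    seq_strength = config.signal_strength if config.signal_mode in ("sequence", "both") else 0.0
    sequences = generate_sequences(
        names["protein"],
        truth.blocks,
        seq_strength,
        _derive_seed(config.seed, 23),
        config.min_seq_length,
        config.max_seq_length,
    )
    fingerprints = generate_drug_bits(
        names["drug"], truth.blocks, seq_strength, _derive_seed(config.seed, 37)
    )
    positives, labels = plant_dti_labels(
        truth,
        names["drug"],
        names["protein"],
        config.base_rate,
        config.lift,
        config.label_noise,
        _derive_seed(config.seed, 53),
    )
    return SyntheticDataset(config, graph, truth, sequences, fingerprints, positives, labels)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Edge-table TSVs, proteins.fasta, drugs.fp.tsv, pairs.csv, truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edge_tables(dataset.graph, out_dir)
    write_fasta(dataset.sequences, out_dir / "proteins.fasta")
    write_fingerprints(dataset.fingerprints, out_dir / "drugs.fp.tsv")
    with open(out_dir / "pairs.csv", "w") as fh:
        fh.write("drug_id,protein_id,label\n")
        for (d, p), y in sorted(dataset.labels.items()):
            fh.write(f"{d},{p},{y}\n")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "config": asdict(dataset.config),
                "blocks": dataset.truth.blocks,
                "true_pairs": sorted(list(p) for p in dataset.truth.true_pairs),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
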
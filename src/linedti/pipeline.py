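"""Glue between the network, embedding, feature and model stages.

These helpers assemble the per-node vector maps the experiments consume:
attribute vectors from sequences/structures, behaviour vectors from one
network embedding (with a warned zero-vector fallback for molecules
absent from the network, which is what makes the new-drug protocol
possible), and the labelled pair matrix with its once-per-study sampled
negative set.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError
from .features import (
    ATTRIBUTE_DIM,
    assemble_pair_matrix,
    conjoint_triad_vector,
    drug_attribute_vector,
    FeatureMatrix,
)
from .line import LineConfig, LineModelState, train_line
from .model import CVReport, cross_validate, sample_negative_pairs
from .network import HeteroGraph


def attribute_vector_map(
    sequences: Mapping[str, str],
    structures: Mapping[str, object],
) -> dict[str, np.ndarray]:
    """64-dim attribute vector per molecule: triads for proteins, bits for drugs."""
    out: dict[str, np.ndarray] = {}
    for name, seq in sequences.items():
        out[name] = conjoint_triad_vector(seq, owner=name).values
    for name, structure in structures.items():
        out[name] = drug_attribute_vector(structure, owner=name).values
    return out


def behavior_vector_map(
    graph: HeteroGraph,
    line_config: LineConfig | None = None,
    names: Iterable[str] | None = None,
    state: LineModelState | None = None,
) -> dict[str, np.ndarray]:
    """64-dim behaviour vector per node from a (possibly shared) embedding.

    Requested ``names`` missing from the network get a zero vector with a
    warning -- they have no association context to embed.
    """
    if state is None:
        state = train_line(graph, line_config or LineConfig())
    out = state.as_mapping()
    if names is not None:
        dim = state.vertex_vectors.shape[1]
        missing = sorted(set(names) - set(out))
        if missing:
            warnings.warn(
                f"{len(missing)} node(s) absent from the network get zero "
                f"behaviour vectors: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        for name in missing:
            out[name] = np.zeros(dim)
    return out


def node_vector_map(
    attr: Mapping[str, np.ndarray],
    behav: Mapping[str, np.ndarray],
    mode: str = "both",
    names: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-node vectors for one feature mode: attribute, behavior, or both."""
    if mode not in ("attribute", "behavior", "both"):
        raise ConfigError(f"unknown feature mode {mode!r}")
    names = sorted(names) if names is not None else sorted(set(attr) | set(behav))
    out = {}
    for name in names:
        if mode == "attribute":
            out[name] = np.asarray(attr[name], dtype=float)
        elif mode == "behavior":
            out[name] = np.asarray(behav[name], dtype=float)
        else:
            out[name] = np.concatenate([attr[name], behav[name]])
    return out


def build_labeled_pairs(
    positives: Iterable[tuple[str, str]],
    drugs: Iterable[str],
    proteins: Iterable[str],
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Positives plus an equal-sized sampled negative set, labelled 1/0."""
    positives = list(positives)
    negatives = sample_negative_pairs(positives, drugs, proteins, seed=seed)
    return [(d, p, 1) for d, p in positives] + [(d, p, 0) for d, p in negatives]


def build_feature_matrix(
    graph: HeteroGraph,
    sequences: Mapping[str, str],
    structures: Mapping[str, object],
    labeled_pairs: Iterable[tuple[str, str, int]],
    line_config: LineConfig | None = None,
    mode: str = "both",
    state: LineModelState | None = None,
) -> FeatureMatrix:
    """End-to-end pair features for labelled drug-protein pairs."""
    labeled_pairs = list(labeled_pairs)
    attr = attribute_vector_map(sequences, structures)
    names = {n for d, p, _ in labeled_pairs for n in (d, p)}
    behav = behavior_vector_map(graph, line_config=line_config, names=names, state=state)
    vectors = node_vector_map(attr, behav, mode=mode, names=names)
    return assemble_pair_matrix(labeled_pairs, vectors)


def evaluate_pipeline(
    dataset,
    seed: int = 0,
    classifier_name: str = "random_forest",
    mode: str = "both",
    k: int = 5,
    line_config: LineConfig | None = None,
) -> CVReport:
    """Embed, featurise and cross-validate one synthetic (or real) dataset.

    ``dataset`` needs ``graph``, ``sequences``, ``fingerprints`` and
    ``positives`` attributes (see :class:`linedti.synthetic.SyntheticDataset`).
    """
    drugs = dataset.graph.nodes_of_type("drug")
    proteins = dataset.graph.nodes_of_type("protein")
    labeled = build_labeled_pairs(dataset.positives, drugs, proteins, seed=seed)
    if line_config is None:
        line_config = LineConfig(seed=seed)
    matrix = build_feature_matrix(
        dataset.graph, dataset.sequences, dataset.fingerprints, labeled,
        line_config=line_config, mode=mode,
    )
    return cross_validate(matrix, k=k, classifier_name=classifier_name, seed=seed)
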
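"""Per-drug target ranking with the new-drug (hold-out) protocol.

To score candidate targets for a query drug as if it were new, every
known interaction of that drug is removed from the training pairs, the
network used for behaviour embedding is stripped of the query drug's
drug-protein edges (the leakage guard), the classifier is retrained, and
all candidate proteins are scored and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import assemble_pair_matrix
from .line import LineConfig
from .model import make_classifier
from .network import HeteroGraph
from .pipeline import (
    attribute_vector_map,
    behavior_vector_map,
    build_labeled_pairs,
    node_vector_map,
)


@dataclass
class RankedTargets:
    """Top-k candidate targets for one drug, scores non-increasing."""

    drug: str
    rows: list[tuple[str, float, int]]  # (protein, score, rank from 1)
    k: int
    zero_behavior: set[str] = field(default_factory=set)
    embedding_graph: HeteroGraph | None = None

    def to_frame(self, truth: Mapping[str, str] | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [r for _, _, r in self.rows],
                "protein_id": [p for p, _, _ in self.rows],
                "score": [s for _, s, _ in self.rows],
                "evidence": [
                    (truth or {}).get(p, "") for p, _, _ in self.rows
                ],
            }
        )

    def to_csv(self, path: str | Path, truth: Mapping[str, str] | None = None) -> None:
        self.to_frame(truth).to_csv(path, index=False)


def strip_drug_edges(
    graph: HeteroGraph, drug: str, all_edges: bool = False
) -> HeteroGraph:
    """Copy of ``graph`` without the drug's drug-protein edges.

    With ``all_edges=True`` every edge incident to the drug is removed;
    the default keeps non-protein context (disease links), matching the
    new-drug framing in which a drug without known targets still has
    other associations.
    """
    g = graph.copy()
    if drug not in g:
        return g
    for nbr in list(g.neighbors(drug)):
        if all_edges or g.node_type(nbr) == "protein":
            g.remove_edge(drug, nbr)
    return g


def rank_targets(
    drug: str,
    positives: Iterable[tuple[str, str]],
    candidates: Iterable[str],
    graph: HeteroGraph,
    sequences: Mapping[str, str],
    structures: Mapping[str, object],
    seed: int = 0,
    k: int = 10,
    line_config: LineConfig | None = None,
    classifier_name: str = "random_forest",
    remove_all_drug_edges: bool = False,
) -> RankedTargets:
    """Score and rank candidate proteins for one (held-out) query drug.

    Training pairs are all positives not involving the query drug plus an
    equal number of sampled negatives over the remaining drugs.  Ties are
    broken by protein identifier so permuting the candidate order cannot
    change the table.  Candidates absent from the embedding network are
    still scored (zero behaviour vector) and flagged.
    """
    if drug not in structures:
        raise ConfigError(f"query drug {drug!r} has no attribute information")
    candidates = sorted(set(candidates))
    if not candidates:
        raise ConfigError("candidate protein set is empty")

    train_pos = [(d, p) for d, p in positives if d != drug]
    train_drugs = sorted({d for d, _ in train_pos})
    train_prots = sorted({p for _, p in train_pos} | set(candidates))
    labeled = build_labeled_pairs(train_pos, train_drugs, train_prots, seed=seed)

    pruned = strip_drug_edges(graph, drug, all_edges=remove_all_drug_edges)
    attr = attribute_vector_map(sequences, structures)
    names = {n for d, p, _ in labeled for n in (d, p)} | {drug} | set(candidates)
    if line_config is None:
        line_config = LineConfig(seed=seed)
    behav = behavior_vector_map(pruned, line_config=line_config, names=names)
    vectors = node_vector_map(attr, behav, mode="both", names=names)

    matrix = assemble_pair_matrix(labeled, vectors)
    clf = make_classifier(classifier_name, seed=seed)
    clf.fit(matrix.X, matrix.y)
    pos_col = list(clf.classes_).index(1)

    query = assemble_pair_matrix([(drug, p, None) for p in candidates], vectors)
    scores = clf.predict_proba(query.X)[:, pos_col]

    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    top = order[: min(k, len(candidates))]
    rows = [(candidates[i], float(scores[i]), r + 1) for r, i in enumerate(top)]
    zero_behavior = {p for p in candidates if p not in pruned or pruned.degree(p) == 0}
    return RankedTargets(drug, rows, k, zero_behavior, pruned)
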
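"""Hierarchical clustering of compounds by Spearman correlation across species.

Compounds are the objects, species replicate-mean profiles the observations.
The distance is ``d = 1 - rho`` (Spearman rank correlation, ties mid-ranked;
constant columns get rho := 0 against everything), the tree is agglomerative
with average linkage (UPGMA) by default, and the cut into ``k`` clusters is
labeled with letters (A, B, ... in dendrogram leaf order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .datamodel import EmissionMatrix, ValidationError

__all__ = ["ClusterAssignment", "spearman_distance_matrix", "cluster_compounds"]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, str]  # compound_id -> cluster letter
    linkage: np.ndarray     # scipy linkage matrix
    k: int
    leaf_order: tuple[str, ...]

    def members(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for cid, letter in self.labels.items():
            out.setdefault(letter, []).append(cid)
        return {k: tuple(v) for k, v in out.items()}


def _letter(i: int) -> str:
    """A..Z, then AA, AB, ... for trees with more than 26 clusters."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def spearman_distance_matrix(matrix: EmissionMatrix) -> pd.DataFrame:
    """Compound x compound distance ``1 - rho`` over species-mean profiles.

    Rank correlation makes the distances invariant to any strictly monotone
    transform of an emission column.  Columns that are constant across species
    have undefined rank correlation; their rho is set to 0 (distance 1) against
    every other compound, keeping the matrix complete.
    """
    means = matrix.species_means().to_numpy()
    if means.shape[0] < 3:
        raise ValidationError("Spearman clustering needs >= 3 species")
    ranks = np.apply_along_axis(rankdata, 0, means)  # mid-ranks for ties
    sd = ranks.std(axis=0)
    ok = sd > 0
    n = matrix.n_compounds
    rho = np.zeros((n, n))
    if ok.sum() >= 2:
        rho[np.ix_(ok, ok)] = np.corrcoef(ranks[:, ok], rowvar=False)
    np.fill_diagonal(rho, 1.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    ids = list(matrix.compound_ids)
    return pd.DataFrame(d, index=ids, columns=ids)


def cluster_compounds(distances: pd.DataFrame, k: int = 17,
                      linkage: str = "average") -> ClusterAssignment:
    """Agglomerate on the distance matrix and cut into exactly ``k`` clusters.

    Letters are assigned in dendrogram leaf order: the cluster containing the
    left-most leaf is A, the next new cluster encountered is B, and so on —
    so the lettering is invariant to compound input order up to relabeling.
    """
    n = distances.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    condensed = squareform(distances.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    order = hierarchy.leaves_list(Z)
    letter_of_cluster: dict[int, str] = {}
    for leaf in order:
        c = int(flat[leaf])
        if c not in letter_of_cluster:
            letter_of_cluster[c] = _letter(len(letter_of_cluster))
    ids = list(distances.index)
    labels = {ids[i]: letter_of_cluster[int(flat[i])] for i in range(n)}
    return ClusterAssignment(labels=labels, linkage=Z, k=k,
                             leaf_order=tuple(ids[i] for i in order))


def write_cluster_table(assignment: ClusterAssignment, path: str | Path) -> None:
    df = pd.DataFrame(sorted(assignment.labels.items()),
                      columns=["compound_id", "cluster_letter"])
    Path(path).write_text(df.to_csv(sep="\t", index=False, lineterminator="\n"),
                          encoding="utf-8", newline="\n")


def write_tree_json(assignment: ClusterAssignment, path: str | Path) -> None:
    payload = {
        "k": assignment.k,
        "leaf_order": list(assignment.leaf_order),
        "merges": [[int(a), int(b), float(h), int(c)]
                   for a, b, h, c in assignment.linkage],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8", newline="\n")
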
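"""Post-run analysis: USF distances among references, UPGMA dendrogram,
OIU abundance, and evaluation against external ground-truth labels.

The distance between two references is their mean directional USF count
scaled by the maximal pairwise count, ``d = ((u_ij + u_ji)/2) / max_u``;
the complementary quantity ``1 - d`` is reported as a similarity.  UPGMA
(unweighted pair group method with arithmetic mean) on these distances
yields an ultrametric dendrogram: the closest pair of clusters is merged at
height d/2 and inter-cluster distances are updated as size-weighted means.
Ties are broken toward the lexicographically smallest member id so the tree
is independent of input order.

Evaluation consumes externally supplied operational-taxonomic-unit (OTU)
labels per strain: a sample spectrum assigned to a reference from a strain
of the same OTU is a true positive, otherwise a false positive.  Precision
is TP/(TP+FP) and the dereplication ratio is #OTUs / #references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dereplicate import DereplicationResult
from .io import MetadataTable
from .usf import USFMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "EvaluationReport",
    "usf_distance_matrix",
    "upgma_tree",
    "to_newick",
    "abundance_table",
    "evaluate",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric reference-to-reference distances in [0, 1], zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(v) != 0) or np.any(v < 0) or np.any(v > 1):
            raise ValueError("distances must be in [0, 1] with zero diagonal")

    @property
    def similarity(self) -> np.ndarray:
        """Complement 1 - d: identical references score 1."""
        sim = 1.0 - self.values
        np.fill_diagonal(sim, 1.0)
        return sim

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric dendrogram (leaf iff no children)."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        return [n for c in self.children for n in c.leaf_names()]


@dataclass(frozen=True)
class EvaluationReport:
    n_true_positive: int
    n_false_positive: int
    precision: float
    n_otus: int
    n_references: int
    dereplication_ratio: float


def usf_distance_matrix(usf: USFMatrix, references: Sequence[str]) -> DistanceMatrix:
    """Scaled symmetric USF distance among references.

    Directional counts are symmetrized by their arithmetic mean and divided
    by the maximum over all reference pairs; all zero counts (max 0) give an
    all-zero matrix.
    """
    refs = list(references)
    if len(refs) < 2:
        raise ValueError("need at least 2 references for a distance matrix")
    n = len(refs)
    u = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = 0.5 * (usf.value(refs[i], refs[j]) + usf.value(refs[j], refs[i]))
            u[i, j] = u[j, i] = m
    max_u = u.max()
    d = u / max_u if max_u > 0 else u
    return DistanceMatrix(ids=refs, values=d)


def upgma_tree(dist: DistanceMatrix) -> TreeNode:
    """Agglomerate a :class:`DistanceMatrix` into an ultrametric dendrogram.

    Merge height is half the merged inter-cluster distance; new distances
    are size-weighted arithmetic means of the merged clusters' distances.
    """
    nodes: list[TreeNode] = [TreeNode(0.0, name=i) for i in dist.ids]
    sizes = [1] * len(nodes)
    min_ids = [i for i in dist.ids]
    d = dist.values.astype(float).copy()
    active = list(range(len(nodes)))

    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        pair = (active[0], active[1])
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                lo, hi = sorted((min_ids[i], min_ids[j]))
                key = (d[i, j], lo, hi)
                if best is None or key < best:
                    best = key
                    pair = (i, j)
        i, j = pair
        if min_ids[j] < min_ids[i]:
            i, j = j, i
        height = d[i, j] / 2.0
        merged = TreeNode(height=height, children=(nodes[i], nodes[j]))
        # size-weighted mean distance to every other active cluster
        for k in active:
            if k in (i, j):
                continue
            d_new = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
            d[i, k] = d[k, i] = d_new
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.remove(j)
    return nodes[active[0]]


def _escape_newick(name: str) -> str:
    if any(c in name for c in " ()[]:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, parent_height: float) -> str:
    length = parent_height - node.height
    if node.is_leaf:
        return f"{_escape_newick(node.name or '')}:{length:g}"
    inner = ",".join(_newick_node(c, node.height) for c in node.children)
    return f"({inner}):{length:g}"


def to_newick(tree: TreeNode) -> str:
    """Serialize a dendrogram to Newick with branch lengths."""
    if tree.is_leaf:
        return f"{_escape_newick(tree.name or '')}:0;"
    inner = ",".join(_newick_node(c, tree.height) for c in tree.children)
    return f"({inner});"


def abundance_table(result: DereplicationResult) -> pd.DataFrame:
    """Per-OIU member counts and fractions of all spectra in the run.

    Only good-quality members are counted here, so fractions sum to <= 1;
    low-quality spectra (which may match several references) are reported
    separately by ``low_quality_abundance``.
    """
    total = len(result.quality)
    rows = [
        {
            "reference_id": ref,
            "n_members": len(members),
            "fraction": len(members) / total,
        }
        for ref, members in result.oius.items()
    ]
    return pd.DataFrame(rows)


def low_quality_abundance(result: DereplicationResult) -> pd.DataFrame:
    """Low-quality matches per reference, counted both ways.

    ``n_low_all`` counts a spectrum toward every reference it matched above
    the Dice threshold; ``n_low_best`` only toward its best-Dice reference.
    """
    all_counts = {r: 0 for r in result.references}
    best_counts = {r: 0 for r in result.references}
    for hits in result.low_quality_matches.values():
        for ref, _ in hits:
            all_counts[ref] += 1
        if hits:
            best_ref = max(hits, key=lambda h: (h[1], h[0]))[0]
            best_counts[best_ref] += 1
    return pd.DataFrame(
        {
            "reference_id": list(result.references),
            "n_low_all": [all_counts[r] for r in result.references],
            "n_low_best": [best_counts[r] for r in result.references],
        }
    )


def evaluate(
    result: DereplicationResult,
    otu_labels: Mapping[str, str],
    metadata: MetadataTable | None = None,
) -> EvaluationReport:
    """Score a run against ground-truth OTU labels per strain.

    Sample spectra are the assigned non-reference green spectra; a sample is
    a true positive iff its strain and its reference's strain carry the same
    OTU label.  The dereplication ratio divides the number of OTUs present
    in the dataset by the number of references produced.
    """
    meta = metadata if metadata is not None else result.metadata
    if meta is None:
        raise ValueError("evaluation needs a metadata table with strain labels")

    def otu_of(sid: str) -> str:
        strain = meta.strain_of(sid)
        if strain not in otu_labels:
            raise KeyError(f"no OTU label for strain {strain!r}")
        return str(otu_labels[strain])

    tp = fp = 0
    for sid, ref in result.assignments.items():
        if sid == ref:
            continue
        if otu_of(sid) == otu_of(ref):
            tp += 1
        else:
            fp += 1
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    otus = {otu_of(sid) for sid in result.quality}
    n_refs = len(result.references)
    return EvaluationReport(
        n_true_positive=tp,
        n_false_positive=fp,
        precision=precision,
        n_otus=len(otus),
        n_references=n_refs,
        dereplication_ratio=len(otus) / n_refs,
    )
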
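"""Taxonomy-based copy-number baseline.

Training lineages and labels build a hierarchical tree whose root is the
prokaryote domain and whose tips are terminal taxa; each node's value is the
unweighted mean of its child taxa's values (sequences that share a terminal
taxon are pooled by mean first). A query lineage descends the tree and takes
the value of the deepest matched node, so unassigned or novel ranks fall back
to the closest known ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxonNode:
    name: str
    rank: str
    children: dict[str, "TaxonNode"] = field(default_factory=dict)
    value: float = float("nan")
    n_leaves: int = 0
    _labels: list[float] = field(default_factory=list)  # terminal taxa only


def _is_assigned(name) -> bool:
    return not (name is None or (isinstance(name, float) and np.isnan(name))
                or str(name).strip() in ("", "NA", "na", "nan"))


def build_taxonomy_tree(
    lineages: Sequence[Sequence[str]],
    labels: Sequence[float],
    leaf_weighted: bool = False,
) -> TaxonNode:
    """Build the lineage tree and aggregate values bottom-up.

    By default an internal node's value is the plain mean of its child taxa
    (a genus of 100 species and a genus of 1 weigh equally at the family
    level); ``leaf_weighted`` switches to a per-sequence-weighted mean.
    Name collisions across different parents stay distinct: nodes are keyed
    by their full path.
    """
    if len(lineages) != len(labels):
        raise ValueError("lineages and labels must align")
    root = TaxonNode(name="root", rank="root")
    for lineage, label in zip(lineages, labels):
        if not any(_is_assigned(t) for t in lineage):
            raise ValueError("empty lineage")
        node = root
        for rank, name in zip(RANKS, lineage):
            if not _is_assigned(name):
                break
            name = str(name)
            if name not in node.children:
                node.children[name] = TaxonNode(name=name, rank=rank)
            node = node.children[name]
        node._labels.append(float(label))

    def aggregate(node: TaxonNode) -> None:
        for child in node.children.values():
            aggregate(child)
        own = np.mean(node._labels) if node._labels else None
        if node.children:
            if leaf_weighted:
                total = sum(c.value * c.n_leaves for c in node.children.values())
                count = sum(c.n_leaves for c in node.children.values())
                if own is not None:
                    total += own * len(node._labels)
                    count += len(node._labels)
                node.value = total / count
                node.n_leaves = count
            else:
                vals = [c.value for c in node.children.values()]
                if own is not None:
                    vals.append(own)
                node.value = float(np.mean(vals))
                node.n_leaves = sum(c.n_leaves for c in node.children.values()) + len(node._labels)
        else:
            node.value = float(own)
            node.n_leaves = len(node._labels)

    aggregate(root)
    return root


def query_lineage(root: TaxonNode, lineage: Sequence[str]) -> float:
    """Predicted copies/genome for a query lineage.

    Descends rank by rank while names match; the deepest matched node's value
    is returned (the domain/root mean if nothing matches). Never fails.
    """
    node = root
    for name in lineage:
        if not _is_assigned(name):
            break
        child = node.children.get(str(name))
        if child is None:
            break
        node = child
    return node.value


def export_table(root: TaxonNode) -> pd.DataFrame:
    """Flatten the tree to a (rank, taxon path, value, n_leaves) table."""
    rows = []

    def walk(node: TaxonNode, path: tuple[str, ...]) -> None:
        if node.rank != "root":
            rows.append({
                "rank": node.rank,
                "path": ";".join(path),
                "value": node.value,
                "n_leaves": node.n_leaves,
            })
        for child in node.children.values():
            walk(child, (*path, child.name))

    walk(root, ())
    return pd.DataFrame(rows)


def read_lineage_tsv(path) -> tuple[list[str], list[list[str]]]:
    """Read a lineage TSV (id + the seven ranks; empty cells = unassigned)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("id", *RANKS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ids = df["id"].tolist()
    lineages = df[list(RANKS)].values.tolist()
    return ids, lineages
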
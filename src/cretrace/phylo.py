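"""Labeled phylogeny handling and lineage activity tracing.

A :class:`PhyloTree` wraps a rooted dendropy tree whose internal nodes all
carry labels (named ancestors, e.g. "Anc239"): every downstream semantic —
lineage paths, per-edge activity step changes, derived mutations — refers to
ancestors by name, so unlabeled internal nodes are an error. Activities are
reporter-assay means with standard errors per node; step changes are log2
fold-changes between a node and its immediately prior ancestor along a
root-to-leaf path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import PhyloError
from .seqmut import (
    AlignmentPair,
    MutationEvent,
    RECONSTITUTION,
    Sequence,
    enumerate_mutations,
    GAP,
)


class PhyloTree:
    """Rooted tree with unique, fully labeled nodes."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        self._nodes: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise PhyloError(
                    "tree contains an unlabeled internal node; all nodes "
                    "must carry names (e.g. Anc239)"
                )
            label = label.replace(" ", "_")
            if label in self._nodes:
                raise PhyloError(f"duplicate node label {label!r}")
            labels.append(label)
            self._nodes[label] = node
            node._cretrace_label = label  # cached for reverse lookup
        self._labels = labels

    @classmethod
    def from_newick(cls, source: str | Path, is_path: bool = True) -> "PhyloTree":
        kwargs = dict(
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        try:
            if is_path:
                tree = dendropy.Tree.get(path=str(source), **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
            msg = str(exc)
            if "Duplicate" in msg or "duplicate" in msg:
                raise PhyloError(f"duplicate node label in tree: {msg}") from exc
            raise PhyloError(f"malformed newick: {msg}") from exc
        return cls(tree)

    def to_newick(self, path: str | Path) -> None:
        self._tree.write(path=str(path), schema="newick", unquoted_underscores=True)

    @property
    def root_label(self) -> str:
        return self._tree.seed_node._cretrace_label

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    @property
    def leaf_labels(self) -> list[str]:
        return [n._cretrace_label for n in self._tree.leaf_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._nodes[label]
        except KeyError:
            raise PhyloError(f"node {label!r} not in tree") from None

    def parent(self, label: str) -> Optional[str]:
        p = self.node(label).parent_node
        return None if p is None else p._cretrace_label

    def children(self, label: str) -> list[str]:
        return [c._cretrace_label for c in self.node(label).child_nodes()]

    def descendants(self, label: str) -> list[str]:
        node = self.node(label)
        return [
            n._cretrace_label
            for n in node.preorder_iter()
            if n is not node
        ]

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                out.append((node._cretrace_label, child._cretrace_label))
        return out


@dataclass(frozen=True)
class LineagePath:
    """Ordered node labels from an ancestor down to a leaf."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise PhyloError("empty lineage path")

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))


def lineage_path(tree: PhyloTree, leaf: str, from_node: Optional[str] = None) -> LineagePath:
    """Root-to-leaf chain of node labels (optionally from a named ancestor)."""
    node = tree.node(leaf)
    chain = []
    while node is not None:
        chain.append(node._cretrace_label)
        node = node.parent_node
    chain.reverse()
    if from_node is None:
        return LineagePath(tuple(chain))
    if from_node not in chain:
        raise PhyloError(f"{from_node!r} is not an ancestor of {leaf!r}")
    return LineagePath(tuple(chain[chain.index(from_node):]))


@dataclass
class NodeActivity:
    """Per-node activity summary: mean, standard error, replicate count."""

    values: dict[str, tuple[float, float, int]]

    def mu(self, label: str) -> Optional[float]:
        v = self.values.get(label)
        return None if v is None else v[0]

    def sigma(self, label: str) -> Optional[float]:
        v = self.values.get(label)
        return None if v is None else v[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeActivity":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            {
                str(r.node): (float(r.mu), float(r.sigma), int(r.n))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tmu\tsigma\tn\n")
            for node in sorted(self.values):
                mu, sigma, n = self.values[node]
                fh.write(f"{node}\t{mu:.6g}\t{sigma:.6g}\t{n}\n")


@dataclass(frozen=True)
class StepChange:
    """Activity log2 fold-change along one parent->child edge.

    ``log2_fc`` is None (sentinel) when either node's activity is missing,
    zero, or below the inactivity floor.
    """

    parent: str
    child: str
    log2_fc: Optional[float]
    derived_mutations: tuple[str, ...] = ()


def step_changes(
    path: LineagePath,
    act: NodeActivity,
    floor: float = 0.0,
) -> list[StepChange]:
    """One step change per consecutive path pair with defined activities.

    Nodes with activity <= ``floor`` are treated as inactive and excluded
    from ratios (log2 against zero or background is never computed). The
    defined steps telescope: their log2_fc values over a contiguous run sum
    to log2(last/first).
    """
    out = []
    for parent, child in path.edges:
        mu_p, mu_c = act.mu(parent), act.mu(child)
        if mu_p is None or mu_c is None or mu_p <= floor or mu_c <= floor:
            out.append(StepChange(parent, child, None))
        else:
            out.append(StepChange(parent, child, math.log2(mu_c / mu_p)))
    return out


def top_step_changes(steps: Iterable[StepChange], k: int) -> list[StepChange]:
    """The k edges with the largest log2 gains.

    Stable sort: ties keep path order, so a path of all-zero changes
    returns its first k edges. Undefined steps are excluded.
    """
    if k < 1:
        raise PhyloError("k must be >= 1")
    defined = [s for s in steps if s.log2_fc is not None]
    return sorted(defined, key=lambda s: -s.log2_fc)[:k]


def derived_mutations(
    msa: Mapping[str, str],
    node_x: str,
    predecessor: str,
    extant: str,
) -> list[MutationEvent]:
    """Mutations newly present in ``node_x`` that are retained in ``extant``.

    All three sequences must be rows of a shared MSA. The predecessor and
    node_x rows are compared column-wise (indel runs merged as in pairwise
    enumeration); an event is returned iff node_x's derived state equals the
    extant state over the event's columns. Column coordinates refer to the
    shared MSA.
    """
    for name in (node_x, predecessor, extant):
        if name not in msa:
            raise PhyloError(f"sequence for node {name!r} missing from MSA")
    row_p, row_x, row_e = msa[predecessor], msa[node_x], msa[extant]
    # build the pairwise alignment implied by the MSA rows (drop dual-gap columns)
    keep = [i for i in range(len(row_p)) if not (row_p[i] == GAP and row_x[i] == GAP)]
    sub_p = "".join(row_p[i] for i in keep)
    sub_x = "".join(row_x[i] for i in keep)
    pair = AlignmentPair(
        a=Sequence(id=predecessor, residues=sub_p.replace(GAP, "") or "A"),
        b=Sequence(id=node_x, residues=sub_x.replace(GAP, "") or "A"),
        aligned_a=sub_p,
        aligned_b=sub_x,
        score=0.0,
        params=RECONSTITUTION,
    )
    events = enumerate_mutations(pair)
    retained = []
    for ev in events:
        c0 = keep[ev.column_start]
        c1 = keep[ev.column_start + ev.n_columns - 1] + 1
        if row_x[c0:c1] == row_e[c0:c1]:
            retained.append(
                MutationEvent(
                    id=ev.id, kind=ev.kind, column_start=c0, ref_pos=ev.ref_pos,
                    from_allele=ev.from_allele, to_allele=ev.to_allele,
                )
            )
    return retained


def clade_summary(
    tree: PhyloTree,
    act: NodeActivity,
    identities: Mapping[str, float],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-clade activity and identity-vs-activity correlation table.

    For each clade (taxonomic order, typically): counts of ancestral and
    extant nodes with data, activity distribution summaries, and Spearman
    rho between percent sequence identity and activity (average ranks for
    ties; undefined, reported as NaN, for clades with fewer than 3 points
    or constant input).
    """
    leaves = set(tree.leaf_labels)
    rows = []
    clades = sorted(set(grouping.values()))
    for clade in clades:
        members = [n for n, c in grouping.items() if c == clade]
        with_data = [n for n in members if act.mu(n) is not None]
        acts = np.array([act.mu(n) for n in with_data])
        n_extant = sum(1 for n in with_data if n in leaves)
        pair = [
            (identities[n], act.mu(n))
            for n in with_data
            if n in identities
        ]
        if len(pair) >= 3:
            ident, a = map(np.array, zip(*pair))
            if np.ptp(ident) == 0 or np.ptp(a) == 0:
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(ident, a).statistic)
        else:
            rho = float("nan")
        rows.append(
            {
                "clade": clade,
                "n_total": len(members),
                "n_ancestral": len(with_data) - n_extant,
                "n_extant": n_extant,
                "activity_mean": float(acts.mean()) if acts.size else float("nan"),
                "activity_median": float(np.median(acts)) if acts.size else float("nan"),
                "activity_max": float(acts.max()) if acts.size else float("nan"),
                "spearman_rho": rho,
            }
        )
    return pd.DataFrame(rows)


def step_changes_to_tsv(steps: Iterable[StepChange], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\tlog2_fc\tderived_mutations\n")
        for s in steps:
            fc = "NA" if s.log2_fc is None else f"{s.log2_fc:.6g}"
            muts = ",".join(s.derived_mutations) if s.derived_mutations else "."
            fh.write(f"{s.parent}\t{s.child}\t{fc}\t{muts}\n")


def read_grouping(path: str | Path) -> dict[str, str]:
    """Two-column TSV (node, clade) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "clade"], comment="#")
    return {str(r.node): str(r.clade) for r in df.itertuples()}
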
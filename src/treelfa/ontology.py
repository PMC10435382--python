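"""Disease-ontology trees used as the structural prior for topics.

The tree is supplied as a two-column child/parent table (the format used for
ICD-10 subtrees).  A reserved token in the parent column — ``"root"`` by
default — marks top-level nodes.  Nodes that never appear as a parent are
leaves; any node may be flagged as an observed disease code, and internal
nodes that are not themselves codes (e.g. ICD-10 chapter headers) are retained
because they still carry indicator variables in the topic prior.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

ROOT = "root"


class TreeError(ValueError):
    """Structural problem in a child/parent table (cycle, orphan, duplicate)."""


@dataclass
class OntologyTree:
    """A rooted ontology tree over disease codes.

    Parameters
    ----------
    nodes
        All non-root node identifiers in topological order (parents before
        children, children in file order).
    parent_of
        Map node -> parent identifier; top-level nodes map to :data:`ROOT`.
    is_code
        Map node -> True if the node is an observed disease code (a column of
        the diagnosis matrix).
    code_order
        The fixed column ordering of the S codes, matching the diagnosis
        matrix.  Defaults to the order codes appear in ``nodes``.
    """

    nodes: list[str]
    parent_of: dict[str, str]
    is_code: dict[str, bool]
    code_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.code_order:
            self.code_order = [n for n in self.nodes if self.is_code[n]]
        self.children_of: dict[str, list[str]] = {n: [] for n in self.nodes}
        self.children_of[ROOT] = []
        for n in self.nodes:
            self.children_of[self.parent_of[n]].append(n)
        self.node_index = {n: i for i, n in enumerate(self.nodes)}
        self.code_index = {c: i for i, c in enumerate(self.code_order)}

    @property
    def n_nodes(self) -> int:
        """Number of non-root nodes (each carries an indicator variable)."""
        return len(self.nodes)

    @property
    def n_codes(self) -> int:
        return len(self.code_order)

    @property
    def depth(self) -> int:
        d = 0
        for n in self.nodes:
            k, p = 1, self.parent_of[n]
            while p != ROOT:
                k += 1
                p = self.parent_of[p]
            d = max(d, k)
        return d

    def parent_index(self) -> list[int]:
        """Index of each node's parent in ``nodes`` (-1 for the root)."""
        return [
            -1 if self.parent_of[n] == ROOT else self.node_index[self.parent_of[n]]
            for n in self.nodes
        ]

    def code_node_index(self) -> list[int]:
        """For each code (in ``code_order``), its position in ``nodes``."""
        return [self.node_index[c] for c in self.code_order]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"code": self.nodes, "parent": [self.parent_of[n] for n in self.nodes]}
        )

    def save(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def parse_tree(
    table,
    codes: list[str] | None = None,
    root_token: str = ROOT,
) -> OntologyTree:
    """Parse and validate a two-column child/parent table.

    ``table`` may be a DataFrame, a path, or a file-like object holding
    tab- or comma-delimited text (header optional, auto-detected).  The first
    column lists every node, the second its parent; the reserved
    ``root_token`` marks top-level nodes.

    ``codes`` optionally restricts which nodes are observed disease codes (in
    diagnosis-matrix column order).  By default every non-root node is a code;
    nodes present in the tree but absent from ``codes`` are retained with
    ``is_code=False``.
    """
    df = _read_table(table)
    children = df.iloc[:, 0].astype(str).tolist()
    parents = df.iloc[:, 1].astype(str).tolist()

    seen: set[str] = set()
    for c in children:
        if c in seen:
            raise TreeError(f"duplicate child entry: {c!r}")
        seen.add(c)
    if root_token in seen:
        raise TreeError(f"root token {root_token!r} listed as a child")

    parent_of = dict(zip(children, parents))
    for c, p in parent_of.items():
        if p != root_token and p not in seen:
            raise TreeError(f"orphan parent: node {c!r} references unknown {p!r}")

    # Topological order: parents before children, children in file order.
    order: list[str] = []
    placed = {root_token}
    pending = list(children)
    while pending:
        progressed = False
        rest = []
        for c in pending:
            if parent_of[c] in placed:
                order.append(c)
                placed.add(c)
                progressed = True
            else:
                rest.append(c)
        if not progressed:
            cycle = _find_cycle(rest, parent_of)
            raise TreeError(f"cycle detected: {' -> '.join(cycle)}")
        pending = rest

    if codes is None:
        is_code = {n: True for n in order}
        code_order: list[str] = []
    else:
        missing = [c for c in codes if c not in placed]
        if missing:
            raise TreeError(f"codes absent from tree: {missing}")
        is_code = {n: n in set(codes) for n in order}
        code_order = list(codes)

    parent_of = {
        n: (ROOT if parent_of[n] == root_token else parent_of[n]) for n in order
    }
    return OntologyTree(order, parent_of, is_code, code_order)


def flatten_tree(tree: OntologyTree) -> OntologyTree:
    """Re-attach every code directly under the root (the flatLFA prior).

    Non-code internal nodes are dropped: on a star tree they carry no
    information.  ``code_order`` is preserved exactly, so a model trained on
    the flattened tree sees the same data columns.  Idempotent.
    """
    codes = list(tree.code_order)
    return OntologyTree(
        nodes=codes,
        parent_of={c: ROOT for c in codes},
        is_code={c: True for c in codes},
        code_order=codes,
    )


def build_sim_tree() -> OntologyTree:
    """The fixed three-layer benchmark tree: root, 5 branch nodes, 15 leaves.

    All 20 non-root nodes are observed disease codes.  Branch nodes are named
    ``N1..N5`` and their children ``Ni-1..Ni-3``.
    """
    rows = []
    for i in range(1, 6):
        rows.append((f"N{i}", ROOT))
        for j in range(1, 4):
            rows.append((f"N{i}-{j}", f"N{i}"))
    return parse_tree(pd.DataFrame(rows, columns=["code", "parent"]))


def _read_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise TreeError("tree table needs two columns (code, parent)")
        return table.iloc[:, :2]
    if isinstance(table, (list, tuple)):
        return pd.DataFrame(table, columns=["code", "parent"])
    if hasattr(table, "read"):
        text = table.read()
    else:
        with open(table, "rt", encoding="utf-8") as fh:
            text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].lower().split(sep)
    header = 0 if first[0].strip() in {"code", "child", "node"} else None
    return pd.read_csv(io.StringIO(text), sep=sep, header=header, dtype=str)


def _find_cycle(nodes, parent_of):
    start = nodes[0]
    seen, cur = [], start
    while cur not in seen:
        seen.append(cur)
        cur = parent_of[cur]
    i = seen.index(cur)
    return seen[i:] + [cur]
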
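"""Time-scaled trees: Newick I/O, fossil date-range time-scaling, tip tables.

Age convention used throughout the package: ages are in Ma before present
(larger = older); a tree's ``root_age`` is the age of the root node, and a
tip's age is ``root_age - root_to_tip_path_length``.  Durations (branch
lengths, elapsed time) are in Myr.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

import dendropy
import pandas as pd

__all__ = [
    "TimeTree",
    "TipRange",
    "TipAnnotation",
    "TreeValidationError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "timescale",
    "write_tip_table",
    "read_tip_table",
]

TIP_TABLE_COLUMNS = ["tip_label", "fad", "lad", "group", "n_occ"]


class TreeValidationError(ValueError):
    """A tree or tip table violates a structural invariant."""


class NewickParseError(ValueError):
    """The Newick string could not be parsed."""


@dataclass(frozen=True)
class TipRange:
    """First/last appearance dates of a tip taxon, in Ma (FAD is older)."""

    tip_label: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if self.fad < self.lad:
            raise TreeValidationError(
                f"tip {self.tip_label!r}: fad ({self.fad}) must be >= lad ({self.lad})"
            )


@dataclass(frozen=True)
class TipAnnotation:
    """Clade-group label and fossil occurrence count for one tip."""

    tip_label: str
    group_label: str
    n_occ: int

    def __post_init__(self) -> None:
        if self.n_occ < 1:
            raise TreeValidationError(
                f"tip {self.tip_label!r}: n_occ must be >= 1, got {self.n_occ}"
            )


class TimeTree:
    """A rooted tree with branch lengths in Myr anchored at a root age (Ma).

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique tip
    labels and non-negative branch lengths, and carries the root age so tip
    ages are well defined.
    """

    def __init__(self, tree: dendropy.Tree, root_age: float | None = None):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise TreeValidationError("every tip must be labelled")
        dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
            if edge.length < -1e-12:
                raise TreeValidationError(
                    f"negative branch length {edge.length} above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
        self._tip_labels = labels
        self._depths: dict[str, float] = {}
        for leaf in tree.leaf_node_iter():
            self._depths[leaf.taxon.label] = leaf.distance_from_root()
        if root_age is None:
            root_age = max(self._depths.values()) if self._depths else 0.0
        self.root_age = float(root_age)

    # -- basic accessors -------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def path_length(self, tip_label: str) -> float:
        """Root-to-tip path length (Myr)."""
        try:
            return self._depths[tip_label]
        except KeyError:
            raise KeyError(f"unknown tip label {tip_label!r}") from None

    def tip_age(self, tip_label: str) -> float:
        """Age of the tip in Ma before present."""
        return self.root_age - self.path_length(tip_label)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def find_tip(self, tip_label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == tip_label:
                return leaf
        raise KeyError(f"unknown tip label {tip_label!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:g})"


def parse_newick(
    text: str,
    root_age: float | None = None,
    require_branch_lengths: bool = True,
) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Parameters
    ----------
    text:
        Newick string for a single rooted tree.
    root_age:
        Age of the root in Ma.  When omitted the oldest root-to-tip path is
        used, i.e. the deepest tip is placed at 0 Ma.
    require_branch_lengths:
        When True (default) every non-root edge must carry a length; set to
        False to read bare topologies destined for :func:`timescale`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "column", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed Newick string{where}: {exc}") from exc
    if dtree.seed_node is None or not any(dtree.leaf_node_iter()):
        raise NewickParseError("tree has no tips")
    if require_branch_lengths:
        missing = [
            e.head_node
            for e in dtree.preorder_edge_iter()
            if e.head_node is not dtree.seed_node and e.length is None
        ]
        if missing:
            raise NewickParseError(
                f"{len(missing)} edge(s) lack branch lengths; pass "
                "require_branch_lengths=False to read a bare topology"
            )
    return TimeTree(dtree, root_age=root_age)


def write_newick(tree: TimeTree) -> str:
    """Serialize to a single-line Newick string with branch lengths."""
    return tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


def _range_map(ranges: Iterable[TipRange]) -> dict[str, TipRange]:
    out: dict[str, TipRange] = {}
    for r in ranges:
        if r.tip_label in out:
            raise TreeValidationError(f"duplicate range for tip {r.tip_label!r}")
        out[r.tip_label] = r
    return out


def timescale(
    tree: TimeTree,
    ranges: Iterable[TipRange],
    mode: str = "shortest",
    min_branch: float = 1.0,
) -> TimeTree:
    """Date a topology against tip appearance ranges.

    ``mode="shortest"`` places every tip at its first appearance date (FAD);
    ``mode="longest"`` places every tip at its last appearance date (LAD).
    In both modes an internal node is dated ``min_branch`` older than the
    oldest of (its children's assigned ages, the FADs of its descendant
    tips): a clade can never be younger than its oldest fossil, so node ages
    are anchored by FADs regardless of where the tips themselves are dated.
    This makes the two modes share internal node ages and bracket total tree
    length from below (shortest) and above (longest).

    Any branch lengths already on ``tree`` are ignored; only the topology is
    used.  The result satisfies ``root_age - path_length(tip) == tip date``.
    """
    if mode not in ("shortest", "longest"):
        raise ValueError(f"mode must be 'shortest' or 'longest', got {mode!r}")
    if min_branch <= 0:
        raise ValueError(f"min_branch must be > 0, got {min_branch}")
    rmap = _range_map(ranges)
    missing = [lbl for lbl in tree.tip_labels if lbl not in rmap]
    if missing:
        raise TreeValidationError(f"missing date ranges for tips: {sorted(missing)}")

    src = tree.dendropy_tree
    clone = src.clone(depth=1)
    age: dict[int, float] = {}
    for node in clone.postorder_node_iter():
        if node.is_leaf():
            r = rmap[node.taxon.label]
            age[id(node)] = r.fad if mode == "shortest" else r.lad
            node._max_desc_fad = r.fad
        else:
            kids = node.child_nodes()
            node._max_desc_fad = max(k._max_desc_fad for k in kids)
            oldest = max(max(age[id(k)] for k in kids), node._max_desc_fad)
            age[id(node)] = oldest + min_branch
    for node in clone.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age[id(node.parent_node)] - age[id(node)]
        del node._max_desc_fad
    clone.seed_node.edge.length = None
    return TimeTree(clone, root_age=age[id(clone.seed_node)])


def write_tip_table(
    path_or_buf,
    ranges: Iterable[TipRange],
    annotations: Iterable[TipAnnotation],
    tree: TimeTree | None = None,
) -> None:
    """Write the per-tip table (tip_label, fad, lad, group, n_occ) as TSV.

    When ``tree`` is given, rows are written in tree tip order and every
    tree tip must be covered; otherwise rows follow the range order.
    """
    rmap = _range_map(ranges)
    amap: dict[str, TipAnnotation] = {}
    for a in annotations:
        if a.tip_label in amap:
            raise TreeValidationError(f"duplicate annotation for tip {a.tip_label!r}")
        amap[a.tip_label] = a
    labels = tree.tip_labels if tree is not None else list(rmap)
    missing = [l for l in labels if l not in rmap or l not in amap]
    if missing:
        raise TreeValidationError(
            f"tips lacking a range or annotation: {sorted(missing)}"
        )
    rows = [
        {
            "tip_label": lbl,
            "fad": rmap[lbl].fad,
            "lad": rmap[lbl].lad,
            "group": amap[lbl].group_label,
            "n_occ": amap[lbl].n_occ,
        }
        for lbl in labels
    ]
    df = pd.DataFrame(rows, columns=TIP_TABLE_COLUMNS)
    header = "# per-tip table: tip_label, fad (Ma), lad (Ma), group, n_occ\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header)
        df.to_csv(path_or_buf, sep="\t", index=False)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)


def read_tip_table(path_or_buf) -> tuple[list[TipRange], list[TipAnnotation]]:
    """Read a tip table written by :func:`write_tip_table`."""
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    missing = set(TIP_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise TreeValidationError(f"tip table missing columns: {sorted(missing)}")
    ranges = [
        TipRange(str(r.tip_label), float(r.fad), float(r.lad))
        for r in df.itertuples(index=False)
    ]
    annotations = [
        TipAnnotation(str(r.tip_label), str(r.group), int(r.n_occ))
        for r in df.itertuples(index=False)
    ]
    return ranges, annotations
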
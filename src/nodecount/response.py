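"""Per-tip response extraction: node counts, elapsed time, sampling covariate.

The response variable of the regression is ``n_nodes``: the number of
internal nodes (speciation events) on the path from the root to each tip,
with the root itself counted, so the minimum is 1.  ``time`` is the elapsed
duration (Myr) from the root to the tip.  ``log_n_occ`` is the natural log
of the tip's fossil occurrence count, the sampling covariate.
"""

from __future__ import annotations

import io
from typing import Iterable

import numpy as np
import pandas as pd

from .tree_io import TimeTree, TipAnnotation, TreeValidationError

__all__ = [
    "count_nodes",
    "elapsed_time",
    "build_response_table",
    "write_response_table",
    "read_response_table",
]

RESPONSE_COLUMNS = ["tip_label", "n_nodes", "time", "group", "n_occ", "log_n_occ"]


def count_nodes(tree: TimeTree, tip_label: str) -> int:
    """Number of internal nodes, root included, on the root-to-tip path.

    Equals the number of edges on that path; a polytomy counts as a single
    node.  Minimum value is 1 (a tip hanging directly off the root).
    """
    node = tree.find_tip(tip_label)
    count = 0
    while node.parent_node is not None:
        count += 1
        node = node.parent_node
    return count


def elapsed_time(tree: TimeTree, tip_label: str) -> float:
    """Root-to-tip path length in Myr."""
    return tree.path_length(tip_label)


def build_response_table(
    tree: TimeTree, annotations: Iterable[TipAnnotation]
) -> pd.DataFrame:
    """One row per tip: n_nodes, time, group, n_occ, log_n_occ.

    Every tip must have exactly one annotation with ``n_occ >= 1`` (the
    natural log of the occurrence count is used without any offset, so a
    zero count is rejected rather than silently shifted).
    """
    amap: dict[str, TipAnnotation] = {}
    for a in annotations:
        if a.tip_label in amap:
            raise TreeValidationError(f"duplicate annotation for tip {a.tip_label!r}")
        amap[a.tip_label] = a
    missing = [lbl for lbl in tree.tip_labels if lbl not in amap]
    if missing:
        raise TreeValidationError(f"tips lacking an annotation: {sorted(missing)}")

    rows = []
    for lbl in tree.tip_labels:
        a = amap[lbl]
        if a.n_occ < 1:
            raise TreeValidationError(
                f"tip {lbl!r}: n_occ must be >= 1 for the log covariate"
            )
        rows.append(
            {
                "tip_label": lbl,
                "n_nodes": count_nodes(tree, lbl),
                "time": elapsed_time(tree, lbl),
                "group": a.group_label,
                "n_occ": a.n_occ,
                "log_n_occ": float(np.log(a.n_occ)),
            }
        )
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    assert (df["n_nodes"] >= 1).all()
    assert (df["time"] >= -1e-9).all()
    return df


def write_response_table(path_or_buf, table: pd.DataFrame) -> None:
    """Serialize a response table as TSV with a documenting header line."""
    header = (
        "# response table: tip_label, n_nodes (root-to-tip node count, root "
        "included), time (Myr from root), group, n_occ, log_n_occ (natural log)\n"
    )
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header)
        table.to_csv(path_or_buf, sep="\t", index=False)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)


def read_response_table(path_or_buf) -> pd.DataFrame:
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise TreeValidationError(f"response table missing columns: {sorted(missing)}")
    return df[RESPONSE_COLUMNS]
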
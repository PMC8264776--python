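"""Average-rank aggregation of per-algorithm ranked edge lists.

The union of edges across the input lists forms the rows of an edge x
method rank matrix. An edge absent from a method's list is charged that
method's worst present rank plus one, so absence is penalized rather
than rewarded. Each edge's ranks are averaged and the averages
re-ranked (ascending, smaller mean = more confident) to produce the
consensus list, truncated to the top K.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import RankedEdgeList


def build_rank_matrix(lists: Sequence[RankedEdgeList]) -> pd.DataFrame:
    """Edge x method matrix of integer ranks over the union of edges.

    Index: (regulator, target) MultiIndex; columns: method tags.
    Missing entries are filled with (worst rank in that column) + 1.
    """
    if len(lists) < 2:
        raise ValidationError("rank aggregation needs at least 2 edge lists")
    tags = [el.method for el in lists]
    if len(set(tags)) != len(tags):
        raise ValidationError(f"duplicate method tag(s) among inputs: {tags}")
    columns = {}
    for el in lists:
        df = el.edges
        dup = df.duplicated(subset=["regulator", "target"])
        if dup.any():
            raise ValidationError(f"duplicate edge within list {el.method!r}")
        columns[el.method] = pd.Series(
            df["rank"].to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [df["regulator"], df["target"]], names=["regulator", "target"]
            ),
        )
    matrix = pd.DataFrame(columns)
    fill = {tag: len(lists[i]) + 1 for i, tag in enumerate(tags)}
    for tag in tags:
        matrix[tag] = matrix[tag].fillna(fill[tag])
    return matrix.astype(int).sort_index()


def aggregate_ranks(rank_matrix: pd.DataFrame, top_k: int) -> RankedEdgeList:
    """Mean-rank consensus; final ranks 1..min(K, #edges).

    The consensus score is the negated mean rank so that "score
    descending" coincides with "rank ascending". Ties in mean rank are
    broken lexicographically by (regulator, target).
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    means = rank_matrix.mean(axis=1)
    df = means.rename("mean_rank").reset_index()
    df = df.sort_values(
        ["mean_rank", "regulator", "target"], ascending=[True, True, True],
        kind="mergesort",
    ).head(top_k).reset_index(drop=True)
    out = pd.DataFrame(
        {
            "regulator": df["regulator"],
            "target": df["target"],
            "score": -df["mean_rank"],
            "rank": np.arange(1, len(df) + 1),
        }
    )
    return RankedEdgeList(method="consensus", edges=out)


def consensus_network(lists: Sequence[RankedEdgeList], top_k: int) -> RankedEdgeList:
    """Convenience wrapper: build the rank matrix and aggregate."""
    return aggregate_ranks(build_rank_matrix(lists), top_k)
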
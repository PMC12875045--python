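"""Hypergeometric over-representation analysis (ORA) over GMT gene sets.

Given a query protein list, a gene-set collection and a background
universe (here: all genes encoding proteins detected in the merged EV
proteome), each term is tested with the upper hypergeometric tail

    p = P(X >= k),  X ~ Hypergeom(M = |universe|, K = |term ∩ universe|,
                                  N = |query|)

with BH adjustment across tested terms. Defaults mirror the standard
clusterProfiler-style parameters: p-value cutoff 0.05, q-value cutoff
0.20, term sizes restricted to [15, 500] after intersection with the
universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora"]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members...

    Duplicate members within a set are deduplicated; a line with fewer
    than three fields is a parse error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields")
            name, description, *members = parts
            sets[name] = {m for m in members if m}
            desc[name] = description
    return GeneSetCollection(
        sets=sets, descriptions=desc,
        universe=set(universe) if universe is not None else None,
    )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    query,
    collection: GeneSetCollection,
    universe=None,
    min_size: int = 15,
    max_size: int = 500,
    p_cut: float = 0.05,
    q_cut: float = 0.20,
) -> pd.DataFrame:
    """Over-representation analysis of a query set against a collection.

    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe and those outside [min_size, max_size]
    excluded before testing. Returns one row per *tested* term with
    set_size, query_size, overlap k, p, BH q, members, and a ``reported``
    flag marking terms passing both p < p_cut and q < q_cut.
    """
    uni = set(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("a non-empty background universe is required")
    query = set(query)
    stray = query - uni
    if stray:
        warnings.warn(f"{len(stray)} query gene(s) outside the universe dropped")
        query &= uni
    M, N = len(uni), len(query)

    rows = []
    for name, members in collection.sets.items():
        inside = members & uni
        K = len(inside)
        if not min_size <= K <= max_size:
            continue
        overlap = sorted(inside & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "term": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": K,
                "query_size": N,
                "overlap": k,
                "p": min(p, 1.0),
                "members": "/".join(overlap),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=["term", "description", "set_size", "query_size", "overlap",
                 "p", "members"],
    )
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["reported"] = (res["p"] < p_cut) & (res["q"] < q_cut)
        res = res.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        res["q"] = []
        res["reported"] = []
    return res
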
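"""Hypergeometric gene-set enrichment (classic and DAVID-modified).

For a target set of size n1 drawn from a universe of N genes and an
annotation set of size n2 with overlap x, the classic one-tailed Fisher
exact p-value is the hypergeometric upper tail P(overlap >= x).  The
DAVID-style modification substitutes x -> x - 1 and n1 -> n1 - 1, which
is more conservative (a single-gene overlap is never significant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = ["fisher_p", "fisher_p_modified", "enrich", "read_gmt"]


def _check(N: int, n1: int, n2: int, x: int) -> None:
    if not (0 <= x <= min(n1, n2) and max(n1, n2) <= N):
        raise ValueError(f"invalid counts: N={N}, n1={n1}, n2={n2}, x={x}")


def fisher_p(N: int, n1: int, n2: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(overlap >= x)."""
    _check(N, n1, n2, x)
    return float(stats.hypergeom.sf(x - 1, N, n1, n2))


def fisher_p_modified(N: int, n1: int, n2: int, x: int) -> float:
    """DAVID-modified p: classic p evaluated at (x - 1, n1 - 1); x=0 -> 1."""
    _check(N, n1, n2, x)
    if x == 0:
        return 1.0
    return fisher_p(N, n1 - 1, n2, x - 1)


@dataclass
class EnrichmentRecord:
    name: str
    N: int
    n1: int
    n2: int
    x: int
    p_classic: float
    p_modified: float


def enrich(
    target,
    collection: dict,
    universe_size: int,
    p_max: float = 0.05,
    min_overlap: int = 2,
    top: int = 10,
) -> pd.DataFrame:
    """Rank annotation sets overlapping the target gene set.

    ``collection`` maps set name -> iterable of gene ids.  Sets are kept
    when the modified p-value is <= ``p_max`` and the overlap is at least
    ``min_overlap``, ranked by overlap size descending (ties: modified p
    ascending, then name), and the top entries returned.
    """
    target = set(target)
    n1 = len(target)
    records = []
    for name, members in collection.items():
        members = set(members)
        n2 = len(members)
        if n2 == 0 or n2 > universe_size:
            continue
        x = len(target & members)
        rec = EnrichmentRecord(
            name=name,
            N=universe_size,
            n1=n1,
            n2=n2,
            x=x,
            p_classic=fisher_p(universe_size, n1, n2, x) if n1 else 1.0,
            p_modified=fisher_p_modified(universe_size, n1, n2, x) if n1 else 1.0,
        )
        records.append(rec)
    table = pd.DataFrame([vars(r) for r in records])
    if table.empty:
        return pd.DataFrame(
            columns=["name", "N", "n1", "n2", "x", "p_classic", "p_modified", "rank"]
        )
    kept = table[(table["p_modified"] <= p_max) & (table["x"] >= min_overlap)]
    kept = kept.sort_values(
        ["x", "p_modified", "name"], ascending=[False, True, True], kind="stable"
    ).head(top)
    kept = kept.reset_index(drop=True)
    kept["rank"] = kept.index + 1
    return kept


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name, description, members per line."""
    collection: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
        collection[parts[0]] = set(g for g in parts[2:] if g)
    return collection
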
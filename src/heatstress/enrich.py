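"""Over-representation analysis against user-supplied gene sets.

Given a query feature list, a background, and a GMT collection, each term is
scored by fold enrichment ES = (k/n)/(K/N) and a hypergeometric upper-tail
p-value P(X >= k), then filtered by the reporting rules used throughout this
pipeline: term size K < 500, overlap k >= 4, ES > 2, p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from heatstress.util import ConfigurationError


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> members) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ConfigurationError("term names must be unique")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (term, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {line[:80]!r}")
        term, description, *members = parts
        if term in sets:
            raise ConfigurationError(f"duplicate GMT term {term!r}")
        sets[term] = frozenset(m for m in members if m)
        descriptions[term] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([term, collection.descriptions.get(term, "")] + sorted(members))
        for term, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def overrepresentation(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    background: Iterable[str],
    max_term_size: int = 500,
    min_overlap: int = 4,
    min_es: float = 2.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation with term filters.

    ``passed_filters`` is the conjunction K < max_term_size (strict), k >=
    min_overlap, ES > min_es (strict), p < max_p (strict). Term sizes K are
    computed against the supplied background; the query must be a subset of
    the background.
    """
    query_set = set(query)
    bg = set(background)
    if not collection:
        raise ConfigurationError("gene-set collection is empty")
    stray = query_set - bg
    if stray:
        raise ConfigurationError(
            f"query ids absent from background: {sorted(stray)[:10]}"
        )
    sets = collection.sets if isinstance(collection, GeneSetCollection) else {
        term: frozenset(m) for term, m in collection.items()
    }
    N = len(bg)
    n = len(query_set)
    rows = []
    for term, members in sets.items():
        in_bg = members & bg
        K = len(in_bg)
        k = len(in_bg & query_set)
        es = (k / n) / (K / N) if K > 0 and n > 0 else 0.0
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        p = min(p, 1.0)
        passed = (K < max_term_size) and (k >= min_overlap) and (es > min_es) \
            and (p < max_p)
        rows.append(
            {
                "term": term,
                "K": K,
                "k": k,
                "n": n,
                "N": N,
                "es": es,
                "p": p,
                "passed_filters": passed,
            }
        )
    return pd.DataFrame(rows).set_index("term")
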
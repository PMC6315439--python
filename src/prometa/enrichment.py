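"""Local gene-set over-representation analysis.

Replaces web-service calls with file-driven statistics: Fisher/hypergeometric
upper tail, the EASE-style jackknifed variant (one gene removed from the
overlap before taking the tail), a binomial upper tail with q = K/N, and
Benjamini–Hochberg adjustment. Terms are flat symbol sets from a GMT file;
no ontology graph is traversed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

METHODS = ("hypergeometric", "ease", "binomial")


@dataclass
class GeneSetCollection:
    """Named terms mapping to member-symbol sets over a background universe."""

    name: str
    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id} has no members")
            if not members <= self.background:
                raise ValueError(f"term {term_id} has members outside the background")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int           # overlap count
    n: int           # query size (within background)
    K: int           # term size
    N: int           # background size
    p_raw: float
    p_adjusted: float
    method: str
    overlap_symbols: list[str] = field(default_factory=list)


def read_gmt(
    path: str | Path,
    background: Optional[Iterable[str]] = None,
    name: Optional[str] = None,
) -> GeneSetCollection:
    """Parse a GMT file (``term_id<TAB>description<TAB>symbol...``).

    Symbols are uppercased and deduplicated within a term. The background
    defaults to the union of all members; an explicit background restricts
    every term to it.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term_id, description = fields[0], fields[1]
            members = frozenset(s.strip().upper() for s in fields[2:] if s.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term_id} has no members")
            terms[term_id] = (description, members)
    if not terms:
        raise ValueError(f"{path}: empty GMT file")

    if background is None:
        bg = frozenset().union(*(m for _, m in terms.values()))
    else:
        bg = frozenset(str(s).strip().upper() for s in background)
        restricted = {}
        for term_id, (desc, members) in terms.items():
            inside = members & bg
            if inside:
                restricted[term_id] = (desc, inside)
        terms = restricted
    return GeneSetCollection(name=name or path.stem, terms=terms, background=bg)


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, K={K}, n={n}")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) — the Fisher exact upper tail.

    N is the background size, K the term size, n the query size, k the
    observed overlap. Computed in log space by scipy for stability.
    """
    _check_margins(k, K, n, N)
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """EASE-style conservative tail: one gene removed from the overlap.

    Equals the hypergeometric upper tail evaluated at k - 1 on the same
    margins, so it is never smaller than the plain tail; k = 1 gives 1.
    """
    _check_margins(k, K, n, N)
    if k < 1:
        raise ValueError("ease_score requires k >= 1")
    return hypergeom_upper_tail(k - 1, K, n, N)


def binomial_upper_tail(k: int, n: int, q: float) -> float:
    """P(X >= k) for X ~ Binomial(n, q), q typically K/N."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n; got k={k}, n={n}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"need 0 <= q <= 1; got q={q}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.binom.sf(k - 1, n, q)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1].tolist()


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    method: str = "hypergeometric",
    min_term_overlap: int = 3,
    alpha: float = 0.05,
    filter_on: Optional[str] = None,
) -> list[EnrichmentRecord]:
    """Over-representation of ``query`` in each term of ``collection``.

    Only terms overlapping the query in at least ``min_term_overlap``
    symbols are tested; BH runs across exactly the tested terms. The
    significance filter uses raw p for hypergeometric/EASE (DAVID-style
    convention) and adjusted p for binomial (Reactome-style), unless
    ``filter_on`` overrides with ``"raw"`` or ``"adjusted"``. Query symbols
    outside the background are dropped with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if filter_on not in (None, "raw", "adjusted"):
        raise ValueError(f"filter_on must be 'raw' or 'adjusted', got {filter_on!r}")
    if filter_on is None:
        filter_on = "adjusted" if method == "binomial" else "raw"

    query_set = {str(s).strip().upper() for s in query}
    dropped = query_set - collection.background
    if dropped:
        warnings.warn(
            f"{len(dropped)} query symbols outside the background were dropped",
            stacklevel=2,
        )
    query_set &= collection.background
    if not query_set:
        raise ValueError("query is empty after restriction to the background")

    n = len(query_set)
    N = len(collection.background)
    tested: list[EnrichmentRecord] = []
    for term_id in sorted(collection.terms):
        term_name, members = collection.terms[term_id]
        overlap = sorted(query_set & members)
        k, K = len(overlap), len(members)
        if k < min_term_overlap:
            continue
        if method == "hypergeometric":
            p = hypergeom_upper_tail(k, K, n, N)
        elif method == "ease":
            p = ease_score(k, K, n, N)
        else:
            p = binomial_upper_tail(k, n, K / N)
        tested.append(
            EnrichmentRecord(
                term_id=term_id, term_name=term_name, k=k, n=n, K=K, N=N,
                p_raw=p, p_adjusted=p, method=method, overlap_symbols=overlap,
            )
        )
    if not tested:
        return []
    adjusted = bh_adjust([r.p_raw for r in tested])
    for rec, adj in zip(tested, adjusted):
        rec.p_adjusted = max(adj, rec.p_raw)  # BH never reports below raw
    kept = [
        r for r in tested
        if (r.p_raw if filter_on == "raw" else r.p_adjusted) <= alpha
    ]
    kept.sort(key=lambda r: (r.p_raw, r.term_id))
    return kept


def merge_redundant_terms(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Merge terms with identical overlap-symbol sets into one record.

    The merged record keeps the statistics (and term_id) of the smallest-p
    member and concatenates the term names with " / ". Input order is
    preserved by first appearance of each overlap set.
    """
    groups: dict[frozenset[str], list[EnrichmentRecord]] = {}
    order: list[frozenset[str]] = []
    for rec in records:
        key = frozenset(rec.overlap_symbols)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    merged: list[EnrichmentRecord] = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            merged.append(members[0])
            continue
        best = min(members, key=lambda r: (r.p_raw, r.term_id))
        merged.append(
            EnrichmentRecord(
                term_id=best.term_id,
                term_name=" / ".join(r.term_name for r in members),
                k=best.k, n=best.n, K=best.K, N=best.N,
                p_raw=best.p_raw, p_adjusted=best.p_adjusted,
                method=best.method, overlap_symbols=list(best.overlap_symbols),
            )
        )
    return merged
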
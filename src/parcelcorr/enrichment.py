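"""Gene-set overrepresentation analysis (ORA).

Given a list of reliable features from a PLS component (positive or
negative sets, tested separately) and a user-supplied GMT collection,
each set is tested for enrichment with the hypergeometric upper tail
against a reference universe of all analysed features, with BH-FDR
across the collection and a top-10 reporting view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .correspondence import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 2000


@dataclass
class GeneSetCollection:
    """Named feature sets plus the reference universe.

    Sets are intersected with the universe at construction; sets that
    become empty are dropped with their names logged.
    """

    sets: dict
    universe: tuple
    source: str = ""

    def __post_init__(self):
        universe = set(self.universe)
        cleaned, dropped = {}, []
        for name, members in self.sets.items():
            inter = sorted(set(members) & universe)
            if inter:
                cleaned[name] = tuple(inter)
            else:
                dropped.append(name)
        if dropped:
            logger.info("dropped %d set(s) empty after universe intersection: %s",
                        len(dropped), dropped[:10])
        self.sets = cleaned
        self.universe = tuple(sorted(universe))


@dataclass
class ORAResult:
    set_name: str
    overlap: int
    set_size_in_universe: int
    hits: int
    universe_size: int
    expected: float
    enrichment_ratio: float
    p: float
    q: float = None


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a set are counted once.  When ``universe``
    is not given, the union of all set members serves as the universe
    (callers analysing PLS output should pass the full analysed feature
    list instead).
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected name, description "
                    f"and at least one member, got {line!r}")
            name = fields[0]
            members = tuple(dict.fromkeys(f for f in fields[2:] if f))
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            sets[name] = members
    if universe is None:
        universe = sorted({m for members in sets.values() for m in members})
    return GeneSetCollection(sets=sets, universe=tuple(universe),
                             source=str(path))


def overrepresentation_test(interest, collection: GeneSetCollection,
                            min_set_size: int = DEFAULT_MIN_SET_SIZE,
                            max_set_size: int = DEFAULT_MAX_SET_SIZE):
    """Hypergeometric upper-tail enrichment of an interest list per set.

    ``p = P[overlap >= observed]`` for drawing ``hits`` features from a
    universe of size N containing the set; BH-FDR across all tested
    sets; results sorted by q then p.  Interest features outside the
    universe are logged and dropped.
    """
    universe = set(collection.universe)
    interest = list(dict.fromkeys(interest))
    outside = [f for f in interest if f not in universe]
    if outside:
        logger.info("dropped %d interest feature(s) outside the universe: %s",
                    len(outside), outside[:10])
    interest_set = set(interest) & universe
    if not interest_set:
        raise ValueError("interest list is empty (after universe intersection)")
    N = len(universe)
    hits = len(interest_set)
    results = []
    for name, members in collection.sets.items():
        K = len(members)
        if not (min_set_size <= K <= max_set_size):
            logger.info("set %r skipped by size filter (size %d)", name, K)
            continue
        k = len(interest_set & set(members))
        expected = hits * K / N
        results.append(ORAResult(
            set_name=name, overlap=k, set_size_in_universe=K, hits=hits,
            universe_size=N, expected=expected,
            enrichment_ratio=(k / expected) if expected > 0 else float("nan"),
            p=float(hypergeom.sf(k - 1, N, K, hits)),
        ))
    if not results:
        return results
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    results.sort(key=lambda r: (r.q, r.p))
    return results


def top_results(results, n: int = 10):
    """The n most significant sets (the reporting convention)."""
    return results[:n]
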
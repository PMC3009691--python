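"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the production code paths: the clustering oracle
recomputes every inter-cluster maximum from the original matrix instead
of using the Lance-Williams update, and the matcher oracle enumerates
substring realizations recursively instead of compiling a regex.
"""

from __future__ import annotations

import math

from enzpat.patterns import Gap, Literal, Pattern, ResidueClass

# ---------------------------------------------------------------------------
# Complete-linkage clustering


def canonical_tree(node):
    """Order-independent nested-tuple form of a ClusterNode tree."""
    if node.is_leaf:
        return ("L", next(iter(node.members)))
    children = tuple(sorted(canonical_tree(c) for c in node.children))
    return ("I", node.merge_evalue, children)


def oracle_complete_linkage(entries, ids, cutoff):
    """O(n^3)-per-merge complete linkage from scratch.

    Returns (partition, canonical trees): the partition as a set of
    frozensets over all ids (singletons included) and the set of
    canonical multi-leaf trees.
    """
    d0 = {frozenset((e.id_a, e.id_b)): e.distance for e in entries}
    clusters = [(frozenset({i}), ("L", i)) for i in sorted(set(ids))]
    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                members_i, _ = clusters[i]
                members_j, _ = clusters[j]
                dist = max(
                    d0.get(frozenset((a, b)), math.inf)
                    for a in members_i
                    for b in members_j
                )
                if dist > cutoff:
                    continue
                tie = tuple(sorted((min(members_i), min(members_j))))
                key = (dist, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        (dist, _), i, j = best
        members_i, canon_i = clusters[i]
        members_j, canon_j = clusters[j]
        merged = (
            members_i | members_j,
            ("I", dist, tuple(sorted((canon_i, canon_j)))),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    partition = {members for members, _ in clusters}
    trees = {canon for members, canon in clusters if len(members) > 1}
    return partition, trees


# ---------------------------------------------------------------------------
# Pattern matching


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_pattern(rng, max_elements: int = 20, max_gap: int = 4) -> Pattern:
    """Random syntactically valid pattern (first/last element conserved)."""
    n_conserved = rng.randint(2, max(2, max_elements // 2))
    elements = []
    for i in range(n_conserved):
        if rng.random() < 0.6:
            elements.append(Literal(rng.choice(AMINO_ACIDS)))
        else:
            elements.append(
                ResidueClass(frozenset(rng.sample(AMINO_ACIDS, rng.randint(2, 4))))
            )
        if i < n_conserved - 1 and rng.random() < 0.5:
            lo = rng.randint(0, max_gap)
            hi = rng.randint(lo, max_gap)
            elements.append(Gap(lo, hi))
    from enzpat.patterns import PatternSource

    return Pattern(
        elements=tuple(elements),
        ec_set=frozenset(),
        source=PatternSource(kind="node", tree_id="t", node_id="n"),
        span=len(elements),
    )


def planted_pattern(rng, sequence: str, max_gap: int = 4) -> Pattern:
    """Pattern constructed to occur in ``sequence`` by covering a window."""
    from enzpat.patterns import PatternSource

    start = rng.randrange(0, max(1, len(sequence) - 30))
    pos = start
    elements = []
    n_conserved = rng.randint(3, 8)
    emitted = 0
    while emitted < n_conserved and pos < len(sequence):
        residue = sequence[pos]
        if rng.random() < 0.7:
            elements.append(Literal(residue))
        else:
            extra = rng.sample(AMINO_ACIDS.replace(residue, ""), rng.randint(1, 3))
            elements.append(ResidueClass(frozenset([residue, *extra])))
        emitted += 1
        pos += 1
        if emitted < n_conserved and pos < len(sequence) - 1 and rng.random() < 0.5:
            width = rng.randint(0, min(max_gap, len(sequence) - pos - 1))
            lo = rng.randint(0, width)
            hi = rng.randint(width, max_gap)
            elements.append(Gap(lo, hi))
            pos += width
    if isinstance(elements[-1], Gap):
        elements.pop()
    return Pattern(
        elements=tuple(elements),
        ec_set=frozenset(),
        source=PatternSource(kind="node", tree_id="t", node_id="n"),
        span=len(elements),
    )


def oracle_match(pattern: Pattern, sequence: str) -> bool:
    """Exhaustive substring enumeration of the element list."""
    elements = pattern.elements

    def consume(ei: int, pos: int) -> bool:
        if ei == len(elements):
            return True
        el = elements[ei]
        if isinstance(el, Literal):
            return (
                pos < len(sequence)
                and sequence[pos] == el.residue
                and consume(ei + 1, pos + 1)
            )
        if isinstance(el, ResidueClass):
            return (
                pos < len(sequence)
                and sequence[pos] in el.residues
                and consume(ei + 1, pos + 1)
            )
        assert isinstance(el, Gap)
        for width in range(el.min, el.max + 1):
            if pos + width <= len(sequence) and consume(ei + 1, pos + width):
                return True
        return False

    return any(consume(0, start) for start in range(len(sequence) + 1))
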
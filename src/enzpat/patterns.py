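"""Deterministic sequence patterns from conserved alignment columns.

For each merge tree, patterns are computed for *qualified* nodes -- the
root, and any node whose EC set is strictly smaller than its parent's --
processed top-down, skipping nodes with 1000 or more member sequences.
The node members are multiply aligned; fully conserved columns (one
residue, no gaps: the "star" columns of ClustalW markup) become pattern
literals, columns whose residues all fall into one ClustalW strong group
("colon" columns) become residue classes, and the stretches in between
become bounded wildcards x(min,max).  Patterns with fewer than eight
conserved positions are discarded as insignificant, and every kept
pattern must re-match all of its own input sequences.

If the patterns of the qualified nodes cover less than a threshold
fraction of a tree's enzymes (%pce, pattern-covered enzymes, default
0.9), additional candidate nodes are tried in order of descending merge
E-value until the threshold is reached or candidates run out.  Enzymes
that never clustered are represented by their exact sequence, so a
query identical to a known enzyme is always recognized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .clustering import ClusterNode
from .ec import ECNumber, format_ec_set

MIN_CONSERVED = 8
MAX_NODE_MEMBERS = 1000
DEFAULT_PCE_THRESHOLD = 0.9

#: ClustalW "strong" residue groups; a gap-free column whose residue set is
#: contained in one of these is marked with a colon in ClustalW output.
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)


# ---------------------------------------------------------------------------
# Pattern elements


@dataclass(frozen=True)
class Literal:
    residue: str


@dataclass(frozen=True)
class ResidueClass:
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a residue class needs at least two residues")


@dataclass(frozen=True)
class Gap:
    min: int
    max: int

    def __post_init__(self) -> None:
        if not 0 <= self.min <= self.max:
            raise ValueError(f"invalid gap bounds ({self.min},{self.max})")


Element = Literal | ResidueClass | Gap


@dataclass(frozen=True)
class PatternSource:
    """Where a pattern came from: a tree node, or an exact sequence."""

    kind: str  # "node" | "exact"
    tree_id: str = ""
    node_id: str = ""
    record_id: str = ""


@dataclass(frozen=True)
class Pattern:
    elements: tuple[Element, ...]
    ec_set: frozenset[ECNumber]
    source: PatternSource
    span: int  # columns from first to last conserved column in the MSA

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty pattern")
        if isinstance(self.elements[0], Gap) or isinstance(self.elements[-1], Gap):
            raise ValueError("pattern may not start or end with a wildcard")

    @property
    def n_conserved(self) -> int:
        return sum(1 for e in self.elements if not isinstance(e, Gap))


# ---------------------------------------------------------------------------
# PROSITE-syntax text form


def format_pattern(pattern: Pattern) -> str:
    parts: list[str] = []
    for el in pattern.elements:
        if isinstance(el, Literal):
            parts.append(el.residue)
        elif isinstance(el, ResidueClass):
            parts.append("[" + "".join(sorted(el.residues)) + "]")
        else:
            if el.min == el.max:
                parts.append("x" if el.min == 1 else f"x({el.min})")
            else:
                parts.append(f"x({el.min},{el.max})")
    return "-".join(parts) + "."


_GAP_RE = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$")


def parse_pattern_elements(text: str) -> tuple[Element, ...]:
    text = text.strip()
    if not text.endswith("."):
        raise ValueError(f"pattern text must end with '.': {text!r}")
    elements: list[Element] = []
    for token in text[:-1].split("-"):
        token = token.strip()
        gap_match = _GAP_RE.match(token)
        if gap_match:
            lo = gap_match.group(1)
            hi = gap_match.group(2)
            if lo is None:
                elements.append(Gap(1, 1))
            elif hi is None:
                elements.append(Gap(int(lo), int(lo)))
            else:
                elements.append(Gap(int(lo), int(hi)))
        elif token.startswith("[") and token.endswith("]"):
            elements.append(ResidueClass(frozenset(token[1:-1])))
        elif len(token) == 1 and token.isalpha():
            elements.append(Literal(token.upper()))
        else:
            raise ValueError(f"cannot parse pattern element {token!r}")
    return tuple(elements)


# ---------------------------------------------------------------------------
# Conservation classes


@dataclass(frozen=True)
class ConservationColumn:
    index: int
    klass: str  # "STAR" | "COLON" | "NONE"
    residues: frozenset[str]


def conservation_classes(msa: Sequence[str]) -> list[ConservationColumn]:
    """Classify every alignment column as STAR, COLON or NONE.

    STAR: all rows share one residue, no gaps.  COLON: no gaps and the
    residue set lies within one strong group.  Everything else: NONE.
    Weak ("period") groups are deliberately not used.
    """
    if len(msa) < 2:
        raise ValueError("conservation needs at least two rows")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment rows")
    columns: list[ConservationColumn] = []
    for i in range(width):
        residues = {row[i] for row in msa}
        if "-" in residues:
            klass = "NONE"
        elif len(residues) == 1:
            klass = "STAR"
        elif any(residues <= g for g in STRONG_GROUPS):
            klass = "COLON"
        else:
            klass = "NONE"
        columns.append(
            ConservationColumn(i, klass, frozenset(residues - {"-"}))
        )
    return columns


# ---------------------------------------------------------------------------
# Pattern construction


def build_pattern(
    msa: Sequence[str],
    ec_set: frozenset[ECNumber],
    source: PatternSource,
    min_conserved: int = MIN_CONSERVED,
) -> Pattern | None:
    """Convert conserved columns of an alignment into a pattern.

    Returns None (rejected) when fewer than ``min_conserved`` conserved
    columns exist.  Runs of unconserved columns between conserved ones
    become x(min,max) wildcards, whose bounds are the fewest/most residues
    any single row places in that run; the pattern is trimmed to the
    region between the first and last conserved column.
    """
    columns = conservation_classes(msa)
    conserved = [c for c in columns if c.klass != "NONE"]
    if len(conserved) < min_conserved:
        return None
    first, last = conserved[0].index, conserved[-1].index
    elements: list[Element] = []
    run_start: int | None = None
    for col in columns[first : last + 1]:
        if col.klass == "NONE":
            if run_start is None:
                run_start = col.index
            continue
        if run_start is not None:
            gap = _gap_bounds(msa, run_start, col.index)
            if gap is not None:
                elements.append(gap)
            run_start = None
        if col.klass == "STAR":
            elements.append(Literal(next(iter(col.residues))))
        else:
            elements.append(ResidueClass(col.residues))
    return Pattern(
        elements=tuple(elements),
        ec_set=ec_set,
        source=source,
        span=last - first + 1,
    )


def _gap_bounds(msa: Sequence[str], start: int, stop: int) -> Gap | None:
    """Wildcard bounds for the unconserved run of columns [start, stop)."""
    counts = [sum(1 for c in row[start:stop] if c != "-") for row in msa]
    lo, hi = min(counts), max(counts)
    if hi == 0:
        return None  # all-gap run contributes nothing
    return Gap(lo, hi)


def exact_sequence_pattern(record_id: str, sequence: str, ec_set) -> Pattern:
    """All-literal pattern for an unclustered enzyme (exact-match search)."""
    return Pattern(
        elements=tuple(Literal(c) for c in sequence),
        ec_set=frozenset(ec_set),
        source=PatternSource(kind="exact", record_id=record_id),
        span=len(sequence),
    )


def self_recognition(pattern: Pattern, member_sequences: Iterable[str]) -> bool:
    """Does the pattern match every sequence it was built from?

    A failed self-recognition means the alignment placed non-homologous
    residues in a conserved column; such patterns are rejected.
    """
    from .verification import match  # late import: verification uses Pattern

    return all(match(pattern, seq) for seq in member_sequences)


# ---------------------------------------------------------------------------
# Node selection and coverage


def qualified_nodes(
    tree: ClusterNode, max_members: int = MAX_NODE_MEMBERS
) -> list[ClusterNode]:
    """Breadth-first list of nodes that get a pattern attempt up front:
    the root, plus any node with strictly fewer EC numbers than its
    parent; nodes at or above ``max_members`` member sequences are skipped
    (they mix many EC numbers and would only yield short, unspecific
    patterns)."""
    out: list[ClusterNode] = []
    queue: list[tuple[ClusterNode, ClusterNode | None]] = [(tree, None)]
    while queue:
        node, parent = queue.pop(0)
        qualifies = parent is None or len(node.ec_set) < len(parent.ec_set)
        if qualifies and len(node.members) < max_members:
            out.append(node)
        queue.extend((child, node) for child in node.children)
    return out


@dataclass
class TreePatterns:
    """Patterns and failure log for one tree."""

    tree_id: str
    patterns: dict[str, Pattern] = field(default_factory=dict)  # node_id -> Pattern
    failures: dict[str, str] = field(default_factory=dict)  # node_id -> reason
    tried: set[str] = field(default_factory=set)


def pce(tree: ClusterNode, pattern_node_ids: Iterable[str]) -> float:
    """Fraction of the tree's enzymes inside >=1 pattern-bearing node."""
    with_pattern = set(pattern_node_ids)
    covered: set[str] = set()
    for node in tree.walk():
        if node.node_id in with_pattern:
            covered |= node.members
    return len(covered) / len(tree.members)


def _attempt(
    node: ClusterNode,
    tree_id: str,
    seq_by_id: Mapping[str, str],
    msa_provider: Callable[[Sequence[str]], list[str]],
    result: TreePatterns,
    min_conserved: int,
) -> bool:
    member_ids = sorted(node.members)
    seqs = [seq_by_id[m] for m in member_ids]
    source = PatternSource(kind="node", tree_id=tree_id, node_id=node.node_id)
    if len(seqs) == 1:
        # a one-sequence node conserves every position
        if len(seqs[0]) < min_conserved:
            result.failures[node.node_id] = "sequence shorter than minimum pattern"
            return False
        pattern = Pattern(
            elements=tuple(Literal(c) for c in seqs[0]),
            ec_set=node.ec_set,
            source=source,
            span=len(seqs[0]),
        )
    else:
        msa = msa_provider(seqs)
        pattern = build_pattern(msa, node.ec_set, source, min_conserved)
        if pattern is None:
            result.failures[node.node_id] = (
                f"fewer than {min_conserved} conserved positions"
            )
            return False
    if not self_recognition(pattern, seqs):
        result.failures[node.node_id] = "pattern does not match all input sequences"
        return False
    result.patterns[node.node_id] = pattern
    return True


def ensure_coverage(
    tree: ClusterNode,
    tree_id: str,
    result: TreePatterns,
    seq_by_id: Mapping[str, str],
    msa_provider: Callable[[Sequence[str]], list[str]],
    threshold: float = DEFAULT_PCE_THRESHOLD,
    min_conserved: int = MIN_CONSERVED,
    max_members: int = MAX_NODE_MEMBERS,
) -> TreePatterns:
    """Iteratively add patterns until %pce reaches ``threshold``.

    Candidates are pattern-less internal nodes not yet tried (leaves are
    never candidates in multi-leaf trees); each round attempts *all*
    candidates sharing the current worst (highest) merge E-value.
    """
    while pce(tree, result.patterns) < threshold:
        candidates = [
            n
            for n in tree.internal_nodes()
            if n.node_id not in result.patterns
            and n.node_id not in result.tried
            and len(n.members) < max_members
        ]
        if not candidates:
            break
        worst = max(n.merge_evalue for n in candidates)  # type: ignore[type-var]
        batch = [n for n in candidates if n.merge_evalue == worst]
        for node in batch:
            result.tried.add(node.node_id)
            _attempt(node, tree_id, seq_by_id, msa_provider, result, min_conserved)
    return result


def compute_tree_patterns(
    tree: ClusterNode,
    tree_id: str,
    seq_by_id: Mapping[str, str],
    msa_provider: Callable[[Sequence[str]], list[str]],
    pce_threshold: float = DEFAULT_PCE_THRESHOLD,
    min_conserved: int = MIN_CONSERVED,
    max_members: int = MAX_NODE_MEMBERS,
) -> TreePatterns:
    """Full per-tree pattern pass: qualified nodes, then the coverage loop."""
    result = TreePatterns(tree_id=tree_id)
    for node in qualified_nodes(tree, max_members):
        if node.is_leaf and not tree.is_leaf:
            continue  # single sequences in multi-leaf trees are not patterned
        result.tried.add(node.node_id)
        _attempt(node, tree_id, seq_by_id, msa_provider, result, min_conserved)
    ensure_coverage(
        tree,
        tree_id,
        result,
        seq_by_id,
        msa_provider,
        pce_threshold,
        min_conserved,
        max_members,
    )
    return result


# ---------------------------------------------------------------------------
# Persistence


def write_patterns(patterns: Mapping[str, Pattern], path) -> None:
    """TSV: pattern_id, tree_id, node_id, ec_list, n_conserved, pattern_text."""
    with open(path, "w") as fh:
        fh.write("pattern_id\ttree_id\tnode_id\tec_list\tn_conserved\tpattern_text\n")
        for pid in sorted(patterns):
            p = patterns[pid]
            if p.source.kind == "exact":
                tree_id, node_id = "singleton", p.source.record_id
            else:
                tree_id, node_id = p.source.tree_id, p.source.node_id
            fh.write(
                f"{pid}\t{tree_id}\t{node_id}\t{format_ec_set(p.ec_set)}\t"
                f"{p.n_conserved}\t{format_pattern(p)}\n"
            )


def read_patterns(path) -> dict[str, Pattern]:
    from .ec import parse_ec_set

    patterns: dict[str, Pattern] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            pid, tree_id, node_id, ec_list, _n, text = line.rstrip("\n").split("\t")
            if tree_id == "singleton":
                source = PatternSource(kind="exact", record_id=node_id)
            else:
                source = PatternSource(kind="node", tree_id=tree_id, node_id=node_id)
            elements = parse_pattern_elements(text)
            span = sum(
                e.max if isinstance(e, Gap) else 1 for e in elements
            )
            patterns[pid] = Pattern(
                elements=elements,
                ec_set=parse_ec_set(ec_list),
                source=source,
                span=span,
            )
    return patterns


# ---------------------------------------------------------------------------
# ClustalW ALN import


def read_clustal_aln(stream) -> list[str]:
    """Parse a ClustalW ALN file into equal-length rows.

    The printed conservation line is ignored: conservation is recomputed
    from the residues so the star/colon rules are applied uniformly.
    """
    first = stream.readline()
    if not first.upper().startswith("CLUSTAL"):
        raise ValueError("not a CLUSTAL alignment file")
    rows: dict[str, list[str]] = {}
    order: list[str] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line[0].isspace():
            continue  # conservation markup line
        parts = line.split()
        if len(parts) < 2:
            continue
        name, chunk = parts[0], parts[1]
        if name not in rows:
            rows[name] = []
            order.append(name)
        rows[name].append(chunk)
    out = ["".join(rows[name]) for name in order]
    if len({len(r) for r in out}) > 1:
        raise ValueError("ragged rows in ALN file")
    return out
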
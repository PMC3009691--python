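"""Pattern verification: matching, the EC calculus, specificity, A/B sets.

Every pattern is searched against the whole non-redundant database,
including the putative proteins and the proteins without enzymatic
activity.  A match on a non-enzyme scores a false positive (FP); a match
on a putative protein is neutral (NA); a match on an enzyme is judged by
an asymmetric EC-relationship calculus: the pattern's EC number promises
to find all enzymes at the same level of functional resolution, so

* TP  -- the target agrees at every level the pattern specifies and is at
         least as resolved as the pattern (e.g. pattern 1.2.3.-, target
         1.2.3.4);
* FP  -- some level specified on both sides differs;
* NA  -- the target is less resolved than the pattern with no conflict
         (e.g. pattern 1.2.3.4, target 1.2.3.-): no decision possible.

With multiple EC numbers on either side, all cross pairs are evaluated
and TP takes precedence over FP, FP over NA.  Specificity is
TP / (TP + FP), taken as 1.0 when there is no TP/FP evidence at all.

Two pattern sets are selected: set A (strict) contains the patterns with
specificity 1.0 whose EC numbers all share one sub-subclass, excluding
patterns carrying exactly one unresolved EC number; set B (loose)
additionally admits multi-sub-subclass and unresolved-EC patterns down
to specificity 0.75.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ec import ECNumber
from .patterns import Gap, Literal, Pattern, ResidueClass
from .sequence_db import Group, SequenceRecord


class Verdict(Enum):
    TP = "TP"
    FP = "FP"
    NA = "NA"


_PRECEDENCE = {Verdict.TP: 2, Verdict.FP: 1, Verdict.NA: 0}


# ---------------------------------------------------------------------------
# Matching


def pattern_to_regex(pattern: Pattern) -> "re.Pattern[str]":
    parts: list[str] = []
    for el in pattern.elements:
        if isinstance(el, Literal):
            parts.append(re.escape(el.residue))
        elif isinstance(el, ResidueClass):
            parts.append("[" + "".join(sorted(el.residues)) + "]")
        elif isinstance(el, Gap):
            if el.max == 0:
                continue
            parts.append("[A-Z]{%d,%d}" % (el.min, el.max))
    return re.compile("".join(parts))


def find(pattern: Pattern, sequence: str) -> tuple[int, int] | None:
    """First occurrence of the pattern as (start, end), 1-based inclusive;
    None if the pattern does not occur.  Matching is unanchored."""
    m = pattern_to_regex(pattern).search(sequence)
    if m is None:
        return None
    return m.start() + 1, m.end()


def match(pattern: Pattern, sequence: str) -> bool:
    return find(pattern, sequence) is not None


# ---------------------------------------------------------------------------
# EC calculus


def ec_pair_relation(p: ECNumber, t: ECNumber) -> Verdict:
    """Judge one (pattern EC, target EC) pair.  Asymmetric in (p, t)."""
    for a, b in zip(p.levels, t.levels):
        if a is not None and b is not None and a != b:
            return Verdict.FP
    for a, b in zip(p.levels, t.levels):
        if a is not None and b is None:
            return Verdict.NA
    return Verdict.TP


def aggregate_relation(
    p_set: Iterable[ECNumber], t_set: Iterable[ECNumber]
) -> Verdict:
    """Best verdict over the cross product (TP > FP > NA), short-circuiting
    on the first TP."""
    p_list, t_list = list(p_set), list(t_set)
    if not p_list or not t_list:
        raise ValueError("aggregate_relation requires nonempty EC sets")
    best = Verdict.NA
    for p in p_list:
        for t in t_list:
            verdict = ec_pair_relation(p, t)
            if verdict is Verdict.TP:
                return Verdict.TP
            if _PRECEDENCE[verdict] > _PRECEDENCE[best]:
                best = verdict
    return best


def score_hit(pattern: Pattern, record: SequenceRecord) -> Verdict:
    """Verdict for a record the pattern matched."""
    if record.group is Group.NON_ENZYME:
        return Verdict.FP
    if record.group is Group.PUTATIVE:
        return Verdict.NA
    return aggregate_relation(pattern.ec_set, record.ec_set)


# ---------------------------------------------------------------------------
# Database-wide verification


@dataclass(frozen=True)
class VerificationStats:
    pattern_id: str
    tp: int
    fp: int
    na: int

    @property
    def specificity(self) -> float:
        """TP/(TP+FP); 1.0 when the pattern produced no TP/FP evidence."""
        if self.tp + self.fp == 0:
            return 1.0
        return self.tp / (self.tp + self.fp)


def verify_all(
    patterns: Mapping[str, Pattern],
    records: Sequence[SequenceRecord],
) -> dict[str, VerificationStats]:
    """Search every record with every pattern and tally TP/FP/NA.

    ``records`` must already be deduplicated; each (pattern, record) pair
    contributes at most one verdict.
    """
    stats: dict[str, VerificationStats] = {}
    for pid in sorted(patterns):
        pattern = patterns[pid]
        regex = pattern_to_regex(pattern)
        counts = {Verdict.TP: 0, Verdict.FP: 0, Verdict.NA: 0}
        for record in records:
            if regex.search(record.sequence) is None:
                continue
            counts[score_hit(pattern, record)] += 1
        stats[pid] = VerificationStats(
            pattern_id=pid,
            tp=counts[Verdict.TP],
            fp=counts[Verdict.FP],
            na=counts[Verdict.NA],
        )
    return stats


# ---------------------------------------------------------------------------
# Set selection


def _same_sub_subclass(ecs: frozenset[ECNumber]) -> bool:
    return len({ec.sub_subclass for ec in ecs}) == 1


def _single_unresolved(ecs: frozenset[ECNumber]) -> bool:
    if len(ecs) != 1:
        return False
    return not next(iter(ecs)).is_fully_specified


def in_set_a(pattern: Pattern, stats: VerificationStats) -> bool:
    return (
        stats.fp == 0
        and _same_sub_subclass(pattern.ec_set)
        and not _single_unresolved(pattern.ec_set)
    )


def select_sets(
    patterns: Mapping[str, Pattern],
    stats: Mapping[str, VerificationStats],
    b_min_specificity: float = 0.75,
) -> tuple[list[str], list[str]]:
    """Pattern ids of set A (strict) and set B (loose); A is a subset of B."""
    set_a = [
        pid for pid in sorted(patterns) if in_set_a(patterns[pid], stats[pid])
    ]
    set_b = sorted(
        set(set_a)
        | {
            pid
            for pid in patterns
            if stats[pid].specificity >= b_min_specificity
        }
    )
    return set_a, set_b


# ---------------------------------------------------------------------------
# Persistence


def write_verification(
    stats: Mapping[str, VerificationStats],
    set_a: Sequence[str],
    set_b: Sequence[str],
    path: str | Path,
) -> None:
    a, b = set(set_a), set(set_b)
    with open(path, "w") as fh:
        fh.write("pattern_id\ttp\tfp\tna\tspecificity\tin_A\tin_B\n")
        for pid in sorted(stats):
            s = stats[pid]
            fh.write(
                f"{pid}\t{s.tp}\t{s.fp}\t{s.na}\t{s.specificity:.4f}\t"
                f"{int(pid in a)}\t{int(pid in b)}\n"
            )
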
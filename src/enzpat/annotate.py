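"""Annotation of query proteomes and comparison against a standard of truth.

A query genome's protein sequences are searched with a selected pattern
set; every pattern match predicts the pattern's EC numbers for that
protein.  Predictions are scored against a standard of truth (SOT) -- an
independent list of EC numbers accepted as present in the organism.  A
predicted EC that matches a SOT EC (same asymmetric calculus as in
verification, prediction playing the pattern role) is a true positive;
each SOT EC counts only once, however often it is re-predicted.  A
prediction that agrees with a SOT EC only on the first three levels
contributes a once-only "sub-subclass hit", which also absorbs unresolved
predicted ECs such as 1.1.1.-.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .ec import ECNumber, format_ec_set
from .patterns import Pattern
from .verification import Verdict, ec_pair_relation, pattern_to_regex


@dataclass(frozen=True)
class Prediction:
    query_id: str
    pattern_id: str
    ec_set: frozenset[ECNumber]


def search_sequences(
    queries: Iterable[tuple[str, str]],
    patterns: Mapping[str, Pattern],
) -> list[Prediction]:
    """One prediction per (query, matching pattern) pair.

    Deterministic patterns need no score threshold: a pattern either
    occurs in the sequence or it does not.
    """
    compiled = [
        (pid, patterns[pid], pattern_to_regex(patterns[pid]))
        for pid in sorted(patterns)
    ]
    predictions: list[Prediction] = []
    for query_id, sequence in queries:
        for pid, pattern, regex in compiled:
            if regex.search(sequence) is not None:
                predictions.append(Prediction(query_id, pid, pattern.ec_set))
    return predictions


def read_query_fasta(path: str | Path) -> list[tuple[str, str]]:
    import logging

    from Bio import SeqIO

    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logging.getLogger(__name__).warning("skipping empty record %s", rec.id)
            continue
        out.append((rec.id, seq))
    return out


# ---------------------------------------------------------------------------
# Standard-of-truth comparison


def read_sot(stream: TextIO) -> frozenset[ECNumber]:
    """One EC number per line; '#' starts a comment."""
    ecs: set[ECNumber] = set()
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if line:
            ecs.add(ECNumber.parse(line))
    return frozenset(ecs)


@dataclass
class SOTComparison:
    sot: frozenset[ECNumber]
    tp_ecs: frozenset[ECNumber]
    sub_subclass_hits: frozenset[tuple]
    predictions_used: int = 0

    @property
    def sensitivity(self) -> float:
        return len(self.tp_ecs) / len(self.sot)

    @property
    def sensitivity_with_subsub(self) -> float:
        return (len(self.tp_ecs) + len(self.sub_subclass_hits)) / len(self.sot)


def compare_to_sot(
    predictions: Sequence[Prediction], sot: frozenset[ECNumber]
) -> SOTComparison:
    """Score predictions against the SOT.

    Pass 1 collects every SOT EC that some predicted EC TP-matches.  Pass
    2 collects sub-subclass hits: SOT sub-subclasses (level 1-3 prefixes)
    matched by a predicted EC but not already represented among the TP
    ECs.  Duplicate predictions of the same EC are counted once by the
    set semantics.
    """
    if not sot:
        raise ValueError("empty standard of truth: nothing to evaluate")
    predicted: set[ECNumber] = set()
    for pred in predictions:
        predicted |= pred.ec_set

    tp_ecs: set[ECNumber] = set()
    for p in predicted:
        for t in sot:
            if ec_pair_relation(p, t) is Verdict.TP:
                tp_ecs.add(t)

    tp_subsubs = {t.sub_subclass for t in tp_ecs}
    subsub_hits: set[tuple] = set()
    for p in predicted:
        if any(ec_pair_relation(p, t) is Verdict.TP for t in sot):
            continue
        for t in sot:
            prefix = t.sub_subclass
            if (
                all(lv is not None for lv in p.sub_subclass)
                and p.sub_subclass == prefix
                and prefix not in tp_subsubs
            ):
                subsub_hits.add(prefix)
    return SOTComparison(
        sot=sot,
        tp_ecs=frozenset(tp_ecs),
        sub_subclass_hits=frozenset(subsub_hits),
        predictions_used=len(predictions),
    )


# ---------------------------------------------------------------------------
# Unique/common contribution of two methods


def contribution_split(
    tp_ecs_1: frozenset[ECNumber],
    tp_ecs_2: frozenset[ECNumber],
) -> tuple[float, float, float]:
    """Percentages (only method 1, only method 2, both) over the union of
    SOT ECs either method hit.  Sums to 100 up to rounding; all zeros on
    an empty union."""
    union = tp_ecs_1 | tp_ecs_2
    if not union:
        return (0.0, 0.0, 0.0)
    only_1 = len(tp_ecs_1 - tp_ecs_2) / len(union) * 100.0
    only_2 = len(tp_ecs_2 - tp_ecs_1) / len(union) * 100.0
    both = len(tp_ecs_1 & tp_ecs_2) / len(union) * 100.0
    return (only_1, only_2, both)


# ---------------------------------------------------------------------------
# Persistence


def write_predictions(predictions: Sequence[Prediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tpattern_id\tec_list\n")
        for p in predictions:
            fh.write(f"{p.query_id}\t{p.pattern_id}\t{format_ec_set(p.ec_set)}\n")


def read_predictions(path: str | Path) -> list[Prediction]:
    from .ec import parse_ec_set

    out: list[Prediction] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            query_id, pattern_id, ec_list = line.rstrip("\n").split("\t")
            out.append(Prediction(query_id, pattern_id, parse_ec_set(ec_list)))
    return out
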
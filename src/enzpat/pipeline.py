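"""End-to-end orchestration: flat file in, verified pattern sets out.

The stages mirror the protocol: classify and deduplicate the database,
mask and compare the enzymes all-vs-all, filter and symmetrify the hits,
cluster by complete linkage at the E-value cutoff, compute patterns for
qualified nodes (with the %pce coverage loop and exact-sequence patterns
for unclustered enzymes), verify every pattern against the full database
and select the strict/loose pattern sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import clustering, patterns, similarity, verification
from .align import BuiltinAligner
from .clustering import Forest
from .patterns import Pattern, TreePatterns
from .sequence_db import (
    DEFAULT_KEYWORDS,
    Group,
    RawEntry,
    SequenceRecord,
    classify_entries,
    deduplicate,
)
from .similarity import AlignerContract, DistanceEntry, PairwiseHit
from .verification import VerificationStats


@dataclass
class PipelineConfig:
    """All numeric thresholds of the protocol, with their defaults."""

    min_length: int = 100
    max_length: int = 7000
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    seg_window: int | None = 12
    seg_threshold: float = 2.2
    min_aligned_cols: int = 50
    max_evalue: float = 1e-3
    cluster_cutoff: float = 1e-3
    pce_threshold: float = 0.9
    min_conserved: int = 8
    max_node_members: int = 1000
    b_min_specificity: float = 0.75

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        config = cls()
        for key, value in mapping.items():
            if not hasattr(config, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(config, key)
            if isinstance(current, bool):
                value = bool(int(value))
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            elif isinstance(current, tuple):
                value = tuple(str(value).split(","))
            setattr(config, key, value)
        return config


@dataclass
class PipelineResult:
    records: list[SequenceRecord]
    enzymes: list[SequenceRecord]
    hits: list[PairwiseHit]
    distances: list[DistanceEntry]
    forest: Forest
    tree_ids: dict[int, str]  # index into forest.all_trees -> tree id
    tree_patterns: list[TreePatterns]
    patterns: dict[str, Pattern]
    stats: dict[str, VerificationStats]
    set_a: list[str]
    set_b: list[str]
    pce_by_tree: dict[str, float] = field(default_factory=dict)

    def patterns_in(self, pattern_ids: Sequence[str]) -> dict[str, Pattern]:
        return {pid: self.patterns[pid] for pid in pattern_ids}


def run_pipeline(
    raw_entries: Sequence[RawEntry],
    config: PipelineConfig | None = None,
    aligner: AlignerContract | None = None,
    distances: Sequence[DistanceEntry] | None = None,
) -> PipelineResult:
    """Run the whole protocol on parsed raw entries.

    ``distances`` can be supplied (e.g. from imported BLAST tabular hits)
    to skip the built-in all-vs-all step; ``aligner`` is still used for
    the multiple alignments.
    """
    config = config or PipelineConfig()
    aligner = aligner or BuiltinAligner()

    records = classify_entries(
        raw_entries,
        keywords=config.keywords,
        min_length=config.min_length,
        max_length=config.max_length,
    )
    records = deduplicate(records)
    enzymes = [r for r in records if r.group is Group.ENZYME]
    seq_by_id = {r.id: r.sequence for r in enzymes}
    ec_by_id = {r.id: r.ec_set for r in enzymes}

    if distances is None:
        hits = similarity.all_vs_all(
            enzymes,
            aligner,
            mask=config.seg_window is not None,
            window=config.seg_window,
            threshold=config.seg_threshold,
        )
        hits = similarity.filter_hits(
            hits, config.min_aligned_cols, config.max_evalue
        )
        distance_entries = similarity.symmetrify(hits)
    else:
        hits = []
        distance_entries = list(distances)

    forest = clustering.complete_linkage(
        distance_entries, seq_by_id.keys(), config.cluster_cutoff
    )
    clustering.singleton_trees(seq_by_id.keys(), forest)
    clustering.annotate_ec_sets(forest, ec_by_id)

    tree_ids = {
        idx: f"T{idx:04d}" for idx in range(len(forest.all_trees))
    }
    all_patterns: dict[str, Pattern] = {}
    tree_pattern_results: list[TreePatterns] = []
    pce_by_tree: dict[str, float] = {}
    counter = 0
    for idx, tree in enumerate(forest.all_trees):
        tree_id = tree_ids[idx]
        if tree.is_leaf:
            record_id = next(iter(tree.members))
            pattern = patterns.exact_sequence_pattern(
                record_id, seq_by_id[record_id], ec_by_id[record_id]
            )
            result = TreePatterns(tree_id=tree_id)
            result.patterns[tree.node_id] = pattern
            pce_by_tree[tree_id] = 1.0
        else:
            result = patterns.compute_tree_patterns(
                tree,
                tree_id,
                seq_by_id,
                aligner.msa,
                pce_threshold=config.pce_threshold,
                min_conserved=config.min_conserved,
                max_members=config.max_node_members,
            )
            pce_by_tree[tree_id] = patterns.pce(tree, result.patterns)
        tree_pattern_results.append(result)
        for node_id in sorted(result.patterns):
            counter += 1
            all_patterns[f"P{counter:05d}"] = result.patterns[node_id]

    stats = verification.verify_all(all_patterns, records)
    set_a, set_b = verification.select_sets(
        all_patterns, stats, config.b_min_specificity
    )
    return PipelineResult(
        records=records,
        enzymes=enzymes,
        hits=list(hits),
        distances=list(distance_entries),
        forest=forest,
        tree_ids=tree_ids,
        tree_patterns=tree_pattern_results,
        patterns=all_patterns,
        stats=stats,
        set_a=set_a,
        set_b=set_b,
        pce_by_tree=pce_by_tree,
    )
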
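import io

import pytest

from enzpat.clustering import ClusterNode
from enzpat.ec import ECNumber
from enzpat.patterns import (
    Gap,
    Literal,
    Pattern,
    PatternSource,
    ResidueClass,
    TreePatterns,
    build_pattern,
    conservation_classes,
    compute_tree_patterns,
    ensure_coverage,
    exact_sequence_pattern,
    format_pattern,
    parse_pattern_elements,
    pce,
    qualified_nodes,
    read_clustal_aln,
    self_recognition,
)

EC1 = frozenset({ECNumber.parse("1.1.1.1")})
SRC = PatternSource(kind="node", tree_id="T0000", node_id="N1")


class TestConservation:
    def test_identity_column_is_star(self):
        cols = conservation_classes(["G", "G", "G"])
        assert cols[0].klass == "STAR"

    def test_strong_group_column_is_colon(self):
        cols = conservation_classes(["M", "I", "L"])
        assert cols[0].klass == "COLON"
        assert cols[0].residues == frozenset("MIL")

    def test_gap_breaks_conservation(self):
        cols = conservation_classes(["G", "-", "G"])
        assert cols[0].klass == "NONE"

    def test_mixed_groups_are_none(self):
        # W+S is in no strong group
        cols = conservation_classes(["W", "S"])
        assert cols[0].klass == "NONE"

    def test_ragged_rows_error(self):
        with pytest.raises(ValueError):
            conservation_classes(["AB", "A"])

    def test_single_row_error(self):
        with pytest.raises(ValueError):
            conservation_classes(["ABC"])


class TestBuildPattern:
    def test_identical_rows_conserve_every_column(self):
        pattern = build_pattern(["GKSTACDEFW"] * 3, EC1, SRC)
        assert pattern is not None
        assert pattern.n_conserved == 10
        assert format_pattern(pattern) == "G-K-S-T-A-C-D-E-F-W."

    def test_strong_group_column_becomes_class(self):
        rows = ["ACDEFGHKLW", "ACDEYGHKLW"]  # column 5: {F,Y} in group FYW
        pattern = build_pattern(rows, EC1, SRC)
        assert pattern is not None
        assert ResidueClass(frozenset("FY")) in pattern.elements

    def test_seven_conserved_columns_rejected(self):
        rows = ["AAAAAAA" + "GW", "AAAAAAA" + "WG"]  # 7 conserved + 2 NONE
        assert build_pattern(rows, EC1, SRC) is None

    def test_eight_conserved_columns_kept(self):
        rows = ["AAAAAAAA" + "GW", "AAAAAAAA" + "WG"]
        pattern = build_pattern(rows, EC1, SRC)
        assert pattern is not None and pattern.n_conserved == 8

    def test_wildcard_bounds_from_residue_counts(self):
        # middle run of 3 columns carries 1-3 residues depending on the row
        rows = [
            "CCCCDDDD" + "W--" + "CCCCDDDD",
            "CCCCDDDD" + "AG-" + "CCCCDDDD",
            "CCCCDDDD" + "AGW" + "CCCCDDDD",
        ]
        pattern = build_pattern(rows, EC1, SRC)
        assert pattern is not None
        assert Gap(1, 3) in pattern.elements
        assert format_pattern(pattern).count("x(1,3)") == 1

    def test_trimmed_to_conserved_region(self):
        rows = ["W" + "A" * 8 + "G", "C" + "A" * 8 + "W"]
        pattern = build_pattern(rows, EC1, SRC)
        assert pattern is not None
        assert pattern.n_conserved == 8
        assert not isinstance(pattern.elements[0], Gap)
        assert not isinstance(pattern.elements[-1], Gap)

    def test_no_conserved_columns_rejected(self):
        assert build_pattern(["AC", "CA"], EC1, SRC) is None


class TestPatternText:
    def test_round_trip_through_prosite_syntax(self):
        elements = (
            Literal("G"),
            Literal("K"),
            ResidueClass(frozenset("ST")),
            Gap(2, 4),
            Literal("A"),
            Gap(1, 1),
            Literal("W"),
            Gap(3, 3),
            Literal("C"),
        )
        pattern = Pattern(elements=elements, ec_set=EC1, source=SRC, span=12)
        text = format_pattern(pattern)
        assert text == "G-K-[ST]-x(2,4)-A-x-W-x(3)-C."
        assert parse_pattern_elements(text) == elements

    def test_generated_patterns_round_trip(self, benchmark_result):
        for pattern in benchmark_result.patterns.values():
            text = format_pattern(pattern)
            assert parse_pattern_elements(text) == pattern.elements


class TestSelfRecognition:
    def test_pattern_from_identical_sequences_matches_them(self):
        seqs = ["GKSTACDEFW" * 2] * 3
        pattern = build_pattern(seqs, EC1, SRC)
        assert self_recognition(pattern, seqs)

    def test_artificially_narrowed_gap_fails(self):
        rows = [
            "CCCCDDDD" + "AG-" + "CCCCDDDD",
            "CCCCDDDD" + "AGW" + "CCCCDDDD",
        ]
        pattern = build_pattern(rows, EC1, SRC)
        assert self_recognition(pattern, [r.replace("-", "") for r in rows])
        narrowed = Pattern(
            elements=tuple(
                Gap(el.min, el.min) if isinstance(el, Gap) and el.min < el.max else el
                for el in pattern.elements
            ),
            ec_set=pattern.ec_set,
            source=pattern.source,
            span=pattern.span,
        )
        assert not self_recognition(narrowed, [r.replace("-", "") for r in rows])

    def test_exact_pattern_matches_its_record(self):
        seq = "MKVLITGASGFIGSHLVDRL" * 8
        pattern = exact_sequence_pattern("Q1", seq, EC1)
        assert len(pattern.elements) == len(seq)
        assert self_recognition(pattern, [seq])


def leaf(name, ec=EC1):
    return ClusterNode(node_id=name, members=frozenset({name}), ec_set=frozenset(ec))


def internal(name, children, evalue, ec):
    members = frozenset().union(*(c.members for c in children))
    return ClusterNode(
        node_id=name,
        members=members,
        children=tuple(children),
        merge_evalue=evalue,
        ec_set=frozenset(ec),
    )


class TestQualifiedNodes:
    def make_tree(self):
        ec_a = frozenset({ECNumber.parse("1.1.1.1")})
        ec_b = frozenset({ECNumber.parse("2.3.1.5")})
        left = internal("NL", [leaf("A", ec_a), leaf("B", ec_a)], 1e-20, ec_a)
        right = internal("NR", [leaf("C", ec_b), leaf("D", ec_b)], 1e-18, ec_b)
        return internal("ROOT", [left, right], 1e-5, ec_a | ec_b)

    def test_root_and_ec_drop_nodes_qualify(self):
        tree = self.make_tree()
        names = [n.node_id for n in qualified_nodes(tree)]
        assert names[0] == "ROOT"
        assert "NL" in names and "NR" in names

    def test_equal_ec_count_child_not_qualified(self):
        ec = frozenset({ECNumber.parse("1.1.1.1")})
        inner = internal("NI", [leaf("A", ec), leaf("B", ec)], 1e-20, ec)
        root = internal("ROOT", [inner, leaf("C", ec)], 1e-10, ec)
        names = [n.node_id for n in qualified_nodes(root)]
        assert names == ["ROOT"]

    def test_large_nodes_are_skipped(self):
        big = frozenset(f"S{i}" for i in range(1000))
        node = ClusterNode(node_id="BIG", members=big, ec_set=EC1)
        assert qualified_nodes(node) == []
        nearly = ClusterNode(
            node_id="OK", members=frozenset(f"S{i}" for i in range(999)), ec_set=EC1
        )
        assert [n.node_id for n in qualified_nodes(nearly)] == ["OK"]


class TestCoverage:
    def test_pce_counts_covered_members(self):
        tree = TestQualifiedNodes().make_tree()
        assert pce(tree, ["ROOT"]) == 1.0
        assert pce(tree, []) == 0.0
        assert pce(tree, ["NL"]) == 0.5

    def test_coverage_loop_attempts_equal_evalue_nodes_together(self):
        ec = frozenset({ECNumber.parse("1.1.1.1")})
        seqs = {k: "GKSTACDEFW" * 3 for k in "ABCD"}
        left = internal("NL", [leaf("A", ec), leaf("B", ec)], 1e-10, ec)
        right = internal("NR", [leaf("C", ec), leaf("D", ec)], 1e-10, ec)
        root = internal("ROOT", [left, right], 1e-5, ec)
        result = TreePatterns(tree_id="T0000")
        result.tried.add("ROOT")  # pretend the root already failed
        attempted = []

        def msa_provider(sequences):
            attempted.append(len(sequences))
            return list(sequences)

        ensure_coverage(root, "T0000", result, seqs, msa_provider, threshold=0.9)
        # both 1e-10 nodes attempted in the same round, root never retried
        assert attempted == [2, 2]
        assert set(result.patterns) == {"NL", "NR"}
        assert pce(root, result.patterns) == 1.0

    def test_no_node_is_attempted_twice(self):
        ec = frozenset({ECNumber.parse("1.1.1.1")})
        # conservation-free sequences: every attempt fails
        seqs = {"A": "AC" * 60, "B": "CA" * 60}
        node = internal("N1", [leaf("A", ec), leaf("B", ec)], 1e-10, ec)
        calls = []

        def msa_provider(sequences):
            calls.append(tuple(sequences))
            return ["AC" * 60, "CA" * 60]

        result = TreePatterns(tree_id="T0000")
        ensure_coverage(node, "T0000", result, seqs, msa_provider, threshold=1.0)
        assert len(calls) == 1
        assert result.patterns == {}

    def test_compute_tree_patterns_records_failures(self):
        ec = frozenset({ECNumber.parse("1.1.1.1")})
        seqs = {"A": "AC" * 60, "B": "CA" * 60}
        node = internal("N1", [leaf("A", ec), leaf("B", ec)], 1e-10, ec)

        def msa_provider(sequences):
            return ["AC" * 60, "CA" * 60]

        result = compute_tree_patterns(node, "T0000", seqs, msa_provider)
        assert result.patterns == {}
        assert "N1" in result.failures


def test_clustal_aln_import():
    text = """CLUSTAL W (1.82) multiple sequence alignment

seq1   GKSTAC--DEFW
seq2   GKSTACGGDEFW
       ******  ****

seq1   GHKL
seq2   GHKL
       ****
"""
    rows = read_clustal_aln(io.StringIO(text))
    assert rows == ["GKSTAC--DEFWGHKL", "GKSTACGGDEFWGHKL"]
    cols = conservation_classes(rows)
    assert [c.klass for c in cols[:8]] == ["STAR"] * 6 + ["NONE"] * 2
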
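# enzpat

Deterministic, enzyme-function-specific sequence patterns for EC-number
annotation.

## The problem

Reconstructing a metabolic network requires knowing which enzymes — which
EC numbers — an organism's genome encodes. Plain similarity search often
cannot decide between closely related activities, and multidomain proteins
routinely transfer annotations across unrelated functions. `enzpat`
implements a fully automatic protocol that turns an annotated protein
database into a library of *deterministic* PROSITE-syntax patterns, each
tied to one or a few EC numbers, whose specificity is measured before the
patterns are ever used for annotation. A pattern either occurs in a query
sequence or it does not — there is no score threshold to tune at
annotation time.

## The protocol

1. **Database preprocessing.** Entries are sorted into three groups:
   *enzymes* (EC-annotated, 100–7000 residues), *putative* proteins
   (descriptions containing keywords like "putative", "hypothetical",
   "fragment") and *non-enzymes* (the rest). Within each group redundant
   entries are removed; an enzyme *r* is redundant to *q* iff their
   sequences are identical and ec(*r*) ⊆ ec(*q*). IUBMB EC transfers and
   deletions can be applied from an update table.
2. **Similarity.** Enzymes are low-complexity masked and compared
   all-vs-all with a local aligner (built-in Smith–Waterman/BLOSUM62 with a
   Karlin–Altschul E-value surrogate, or imported BLAST tabular output).
   Alignments under 50 columns or with E > 10⁻³ are discarded; the two
   directed E-values of a pair are symmetrified by keeping the **higher**
   one.
3. **Clustering.** Complete-linkage clustering of the E-value matrix, cut
   at 10⁻³, yields a forest of binary merge trees; enzymes that never merge
   become one-node trees. The max-linkage rule keeps multidomain proteins
   from bridging unrelated families.
4. **Patterns.** For each tree, *qualified* nodes (the root, and nodes with
   fewer EC numbers than their parent; nodes under 1000 members only) are
   multiply aligned. Fully conserved columns become literals, columns
   conserved within one ClustalW strong group become residue classes
   `[..]`, unconserved stretches become bounded wildcards `x(n,m)`.
   Patterns with fewer than eight conserved positions are rejected, and
   every pattern must re-match all of its input sequences. If a tree's
   patterns cover less than 90 % of its enzymes (%pce), more nodes are
   tried in order of descending merge E-value. Unclustered enzymes are
   represented by their exact sequence.
5. **Verification.** Every pattern is searched against the full database.
   Matches on non-enzymes count FP, on putatives NA, and on enzymes the
   asymmetric EC calculus applies: pattern EC 1.2.3.- finding target
   1.2.3.4 is TP, but pattern 1.2.3.4 finding target 1.2.3.- is NA; any
   co-specified level that differs is FP; TP > FP > NA across multi-EC
   sets. Specificity = TP/(TP+FP). Set **A** keeps fully specific patterns
   whose ECs share one sub-subclass; set **B** loosens this to specificity
   ≥ 0.75 and mixed sub-subclasses.
6. **Annotation.** A query proteome is searched with a pattern set;
   predicted ECs are scored against a standard-of-truth list, counting
   each SOT EC once and crediting level-3 agreement as a "sub-subclass
   hit".

## Worked example

The built-in generator creates a database of synthetic enzyme families, so
the whole pipeline runs without any external data:

```bash
enzpat --seed 3 simulate -o db.dat --truth-out truth.tsv
enzpat build db.dat -o groups/
enzpat distances groups/ -o dist.tsv
enzpat cluster dist.tsv groups/ -o forest.json
enzpat make-patterns forest.json groups/ -o patterns.tsv
enzpat verify patterns.tsv groups/ -o verification.tsv
enzpat select patterns.tsv verification.tsv --a-out setA.tsv --b-out setB.tsv
enzpat search groups/enzyme.fasta setB.tsv -o pred.tsv
enzpat evaluate pred.tsv sot.txt
```

With the default simulation (5 families × 8 members, 20 putative decoys,
50 non-enzymes, 2 multidomain concatenations) this prints, stage by stage:

```
112 entries written
{"enzyme": 42, "putative": 20, "non_enzyme": 50}
177 distances
5 trees, 0 singletons
8 patterns
A: 6  B: 8
52 predictions
{
 "sot_size": 5,
 "tp_ecs": 5,
 "sub_subclass_hits": 0,
 "sensitivity": 1.0,
 "sensitivity_with_subsub": 1.0
}
```

Reading: the 42 non-redundant enzymes cluster into exactly one tree per
family (the two bifunctional multidomain entries attach to one of their
parent families but never fuse two families into one tree); 8 patterns are
derived, all with specificity 1.0; patterns carrying two sub-subclasses
(from the multidomain nodes) are admitted only to set B; and searching the
enzymes with set B recovers all five known EC numbers.

The same pipeline is available as a library:

```python
import io
from enzpat import run_pipeline, parse_flatfile
from enzpat.synthetic import benchmark_database

db = benchmark_database(seed=1)
result = run_pipeline(parse_flatfile(io.StringIO(db.flatfile_text)))
print(len(result.patterns), result.set_a, result.pce_by_tree)
```

Real databases enter through the Swiss-Prot-dialect flat-file reader (or
FASTA plus a TSV annotation table), and external BLAST tabular hits or
ClustalW `.aln` alignments can replace the built-in aligner at the
corresponding stage.

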
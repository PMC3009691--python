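"""Built-in desk-scale aligner.

Pairwise similarity uses optimal local alignment (Smith-Waterman via
biotite's C kernels) with BLOSUM62 scores and affine gaps (open 11,
extend 1), converted to an E-value surrogate by Karlin-Altschul statistics

    E = K * m * n * exp(-lambda * S)

with the published gapped BLOSUM62(11,1) parameters lambda = 0.267,
K = 0.041 as defaults.  A moment-matching calibration routine against the
score distribution of shuffled sequence pairs is provided for users who
change the scoring scheme.  The sequences handled here are closely related
family members, so a plain local aligner with a calibrated E-value scale
is sufficient; imported BLAST tabular hits can stand in for fidelity runs.

Multiple alignment uses a deterministic center-star progressive strategy:
the sequence with the highest summed pairwise score is the center, every
other sequence is aligned to it semi-globally (free terminal gaps), and
the pairwise alignments are merged by the usual "once a gap, always a
gap" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .similarity import EVALUE_FLOOR, PairwiseHit

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11/extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_VALID = set("ACDEFGHIKLMNPQRSTVWYBZX")


def _protein(sequence: str) -> bseq.ProteinSequence:
    cleaned = "".join(c if c in _VALID else "X" for c in sequence.upper())
    return bseq.ProteinSequence(cleaned)


@dataclass
class BuiltinAligner:
    """Local pairwise search + center-star MSA over BLOSUM62.

    ``gap_open``/``gap_extend`` follow the BLAST convention (a gap of
    length L costs open + L*extend).  ``report_threshold`` mimics a search
    tool's internal reporting cutoff: weaker hits are not emitted at all.
    """

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    k: float = DEFAULT_K
    report_threshold: float = 10.0
    #: above this many sequences the MSA center is picked by length medoid
    #: instead of the quadratic all-pairs score scan
    center_scan_limit: int = 60

    def __post_init__(self) -> None:
        self._matrix = balign.SubstitutionMatrix.std_protein_matrix()
        # biotite applies the open penalty to the first gap position only
        self._gap_penalty = (-(self.gap_open + self.gap_extend), -self.gap_extend)

    # -- E-value surrogate ------------------------------------------------

    def evalue(self, score: float, m: int, n: int) -> float:
        log_e = math.log(self.k * m * n) - self.lam * score
        if log_e < math.log(EVALUE_FLOOR):
            return EVALUE_FLOOR
        return math.exp(log_e)

    # -- pairwise search --------------------------------------------------

    def _align_local(self, s1: bseq.ProteinSequence, s2: bseq.ProteinSequence):
        return balign.align_optimal(
            s1, s2, self._matrix, gap_penalty=self._gap_penalty,
            local=True, max_number=1,
        )[0]

    def pairwise_hits(
        self, records: Sequence[tuple[str, str]]
    ) -> list[PairwiseHit]:
        """Directed hits for all ordered pairs (i, j), i != j.

        The optimal-alignment score is symmetric, so each unordered pair
        is aligned once and reported in both directions (with coordinates
        swapped); directional asymmetry only arises with imported hits
        from heuristic external tools.
        """
        seqs = [(rid, _protein(s)) for rid, s in records]
        hits: list[PairwiseHit] = []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                id_i, s_i = seqs[i]
                id_j, s_j = seqs[j]
                aln = self._align_local(s_i, s_j)
                if len(aln.trace) == 0:
                    continue
                ev = self.evalue(aln.score, len(s_i), len(s_j))
                if ev > self.report_threshold:
                    continue
                qi = aln.trace[:, 0]
                tj = aln.trace[:, 1]
                q_start = int(qi[qi >= 0].min()) + 1
                q_end = int(qi[qi >= 0].max()) + 1
                t_start = int(tj[tj >= 0].min()) + 1
                t_end = int(tj[tj >= 0].max()) + 1
                cols = len(aln.trace)
                hits.append(
                    PairwiseHit(id_i, id_j, q_start, q_end, t_start, t_end, cols, ev)
                )
                hits.append(
                    PairwiseHit(id_j, id_i, t_start, t_end, q_start, q_end, cols, ev)
                )
        return hits

    # -- calibration ------------------------------------------------------

    def calibrate(
        self, sequences: Sequence[str], rng: np.random.Generator, n_pairs: int = 200
    ) -> tuple[float, float]:
        """Fit (lambda, K) from shuffled-pair alignment scores.

        Scores of optimal local alignments of unrelated sequences follow a
        Gumbel law with location ln(K*m*n)/lambda and scale 1/lambda; the
        moments give lambda = pi / (sigma * sqrt(6)) and
        K = exp(lambda*mu - gamma) / (m*n).  Updates the aligner in place
        and returns the fitted pair.
        """
        if len(sequences) < 2:
            raise ValueError("need at least two sequences to calibrate")
        scores = []
        sizes = []
        pool = [list(s) for s in sequences]
        for _ in range(n_pairs):
            i, j = rng.choice(len(pool), size=2, replace=False)
            a = pool[i][:]
            b = pool[j][:]
            rng.shuffle(a)
            rng.shuffle(b)
            aln = self._align_local(_protein("".join(a)), _protein("".join(b)))
            scores.append(aln.score)
            sizes.append(len(a) * len(b))
        scores_arr = np.asarray(scores, dtype=float)
        mu = scores_arr.mean()
        sigma = scores_arr.std(ddof=1)
        lam = math.pi / (sigma * math.sqrt(6.0))
        euler_gamma = 0.5772156649015329
        k = math.exp(lam * mu - euler_gamma) / float(np.mean(sizes))
        self.lam, self.k = lam, k
        return lam, k

    # -- multiple alignment -----------------------------------------------

    def _align_semiglobal(self, s1: bseq.ProteinSequence, s2: bseq.ProteinSequence):
        return balign.align_optimal(
            s1, s2, self._matrix, gap_penalty=self._gap_penalty,
            local=False, terminal_penalty=False, max_number=1,
        )[0]

    def _pick_center(self, seqs: list[bseq.ProteinSequence]) -> int:
        if len(seqs) > self.center_scan_limit:
            # cheap deterministic medoid: length closest to the median,
            # ties to the smaller index
            lengths = np.array([len(s) for s in seqs])
            median = float(np.median(lengths))
            return int(np.argmin(np.abs(lengths - median)))
        totals = [0.0] * len(seqs)
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                score = self._align_semiglobal(seqs[i], seqs[j]).score
                totals[i] += score
                totals[j] += score
        return int(np.argmax(totals))

    def msa(self, sequences: Sequence[str]) -> list[str]:
        """Center-star multiple alignment; rows in input order."""
        if not sequences:
            return []
        if len(sequences) == 1:
            return [str(sequences[0])]
        seqs = [_protein(s) for s in sequences]
        center = self._pick_center(seqs)

        master_center: list[str] = list(str(seqs[center]))
        rows: dict[int, list[str]] = {center: list(str(seqs[center]))}
        order = [i for i in range(len(seqs)) if i != center]
        for idx in order:
            aln = self._align_semiglobal(seqs[center], seqs[idx])
            c_gapped, s_gapped = aln.get_gapped_sequences()
            new_center: list[str] = []
            new_row: list[str] = []
            gap_cols: list[int] = []  # columns newly inserted into master
            i = 0  # master position
            j = 0  # pairwise position
            while i < len(master_center) or j < len(c_gapped):
                m_char = master_center[i] if i < len(master_center) else None
                p_char = c_gapped[j] if j < len(c_gapped) else None
                if m_char == "-" and (p_char is None or p_char != "-"):
                    # existing master insertion absent from this pairwise aln
                    new_center.append("-")
                    new_row.append("-")
                    i += 1
                elif p_char == "-":
                    # new insertion relative to the center
                    if m_char == "-":
                        new_center.append("-")
                        i += 1
                    else:
                        new_center.append("-")
                        gap_cols.append(len(new_center) - 1)
                    new_row.append(s_gapped[j])
                    j += 1
                else:
                    new_center.append(m_char)  # type: ignore[arg-type]
                    new_row.append(s_gapped[j])
                    i += 1
                    j += 1
            for prev_idx, prev_row in rows.items():
                for col in gap_cols:
                    prev_row.insert(col, "-")
            master_center = new_center
            rows[idx] = new_row
        # the center row was padded in the per-row loop; refresh to be safe
        rows[center] = master_center
        width = len(master_center)
        out = []
        for i in range(len(seqs)):
            row = rows[i]
            assert len(row) == width, "center-star merge produced ragged rows"
            out.append("".join(row))
        return out
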
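"""Shared pairwise-alignment helpers (BLOSUM62, affine gaps).

Thin wrappers around :class:`Bio.Align.PairwiseAligner` used by the network
and curation modules.  Local alignments score similarity-network edges;
global alignments anchor queries to the annotated reference and measure
percent identity for redundancy reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix and affine gap penalties.

    Defaults follow protein-BLAST practice: BLOSUM62 with gap open 11 and
    extension 1.  ``lam`` and ``k`` are the Karlin–Altschul parameters used
    to convert raw local scores into bit scores (standard gapped BLOSUM62
    values).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float,
             mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    # global mode penalizes end gaps with the same affine scores, so
    # truncations cost what they should against the reference coordinates
    aligner.mode = mode
    return aligner


def local_score(x: str, y: str, params: ScoringParams = ScoringParams()) -> float:
    """Optimal local (Smith–Waterman) alignment score."""
    return float(_aligner(params.matrix, params.gap_open,
                          params.gap_extend, "local").score(x, y))


def local_alignment(x: str, y: str, params: ScoringParams = ScoringParams()):
    """Best local alignment (first of the co-optimal set)."""
    return _aligner(params.matrix, params.gap_open,
                    params.gap_extend, "local").align(x, y)[0]


def global_alignment(x: str, y: str, params: ScoringParams = ScoringParams()):
    """Best global alignment; Biopython's enumeration order makes the
    choice among co-optimal alignments deterministic."""
    return _aligner(params.matrix, params.gap_open,
                    params.gap_extend, "global").align(x, y)[0]


def alignment_identity(alignment) -> float:
    """Matches over aligned columns, excluding columns gapped in both rows."""
    a, b = str(alignment[0]), str(alignment[1])
    matches = columns = 0
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            continue
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    return matches / columns if columns else 0.0


def global_identity(x: str, y: str,
                    params: ScoringParams = ScoringParams()) -> float:
    """Percent identity (fraction) of the best global alignment."""
    return alignment_identity(global_alignment(x, y, params))


def column_map(alignment) -> dict[int, int]:
    """Map 1-based reference positions to 1-based query positions.

    The alignment's first row is the reference, the second the query.
    Reference positions aligned to a gap are absent from the map.
    """
    ref_aln, qry_aln = str(alignment[0]), str(alignment[1])
    mapping: dict[int, int] = {}
    ri = qi = 0
    for cr, cq in zip(ref_aln, qry_aln):
        if cr != "-":
            ri += 1
        if cq != "-":
            qi += 1
        if cr != "-" and cq != "-":
            mapping[ri] = qi
    return mapping
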
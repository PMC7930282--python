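"""Local-alignment validation against a reference venom-protein set.

Candidate secreted proteins are confirmed as venom components by alignment
against a curated reference set of venom proteins from a related species.
Heuristic seeded search (BLASTp-style) is unnecessary at this scale, so the
module runs exact Smith-Waterman local alignment with affine gaps (BLOSUM62,
gap open 11 / extend 1; a gap of length L scores -(11 + (L-1))). ``X`` scores
0 against every residue. No E-values are computed; matches are filtered on
raw score, percent identity over aligned columns, and query coverage.

The module also checks serine-protease candidates for the His/Asp/Ser
catalytic triad by aligning them to an annotated canonical trypsin and reading
the residues mapped to the annotated triad columns (defaults: H at 70, D at
125 or 130, S at 240 or 245, 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: annotated triad columns on the canonical trypsin (1-based alignment positions)
DEFAULT_TRIAD_COLUMNS: dict[str, tuple[int, ...]] = {
    "H": (70,),
    "D": (125, 130),
    "S": (240, 245),
}


def blosum62_x_neutral() -> substitution_matrices.Array:
    """BLOSUM62 with the X row/column zeroed (X scores 0 vs everything)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for aa in m.alphabet:
        m["X", aa] = 0.0
        m[aa, "X"] = 0.0
    return m


_MATRIX = blosum62_x_neutral()


def _aligner(
    mode: str,
    matrix: substitution_matrices.Array | None,
    gap_open: float,
    gap_extend: float,
) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _MATRIX if matrix is None else matrix
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    if mode == "global":
        # free end gaps: the canonical reference may be longer than the query
        al.end_gap_score = 0.0
    return al


@dataclass(frozen=True)
class Alignment:
    """One optimal pairwise alignment, 0-based half-open spans."""

    a_span: tuple[int, int]
    b_span: tuple[int, int]
    a_aligned: str  # gapped strings of equal length
    b_aligned: str

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.a_aligned, self.b_aligned) if x == y and x != "-"
        )

    @property
    def n_aligned_columns(self) -> int:
        """Columns where both sequences carry a residue (gap columns excluded)."""
        return sum(
            1 for x, y in zip(self.a_aligned, self.b_aligned) if x != "-" and y != "-"
        )


@dataclass(frozen=True)
class HomologyMatch:
    query_id: str
    reference_id: str
    score: float
    percent_identity: float  # over aligned columns, [0, 100]
    query_coverage: float  # aligned query span / query length, [0, 1]
    query_span: tuple[int, int]
    reference_span: tuple[int, int]


def smith_waterman(
    a: str,
    b: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, Alignment | None]:
    """Optimal local alignment score and one optimal alignment.

    Empty input or no positive-scoring local alignment gives ``(0.0, None)``.
    """
    if not a or not b:
        return 0.0, None
    al = _aligner("local", matrix, gap_open, gap_extend)
    score = float(al.score(a, b))
    if score <= 0:
        return max(score, 0.0), None
    best = al.align(a, b)[0]
    return score, _to_alignment(best)


def _to_alignment(aln: Align.Alignment) -> Alignment:
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    a_gapped, b_gapped = str(aln[0]), str(aln[1])
    # local mode pads with unaligned flanks in Biopython's string form only
    # when mode == 'global'; for local alignments aln[i] is already trimmed.
    return Alignment(a_span, b_span, a_gapped, b_gapped)


def search_reference(
    queries: Mapping[str, str],
    refs: Mapping[str, str],
    min_identity: float = 35.0,
    min_coverage: float = 0.5,
    min_score: float = 50.0,
) -> tuple[dict[str, HomologyMatch], list[HomologyMatch], list[str]]:
    """Align every query against the reference set and filter matches.

    Returns ``(best, all_matches, unmatched)``: the best-scoring passing
    reference per query, the long-form table of all passing matches, and the
    query ids with no passing match. An empty reference set leaves every
    query unmatched (with a warning).
    """
    if not refs:
        import warnings

        warnings.warn("empty reference set: all queries unmatched", stacklevel=2)
    best: dict[str, HomologyMatch] = {}
    all_matches: list[HomologyMatch] = []
    unmatched: list[str] = []
    for qid, qseq in queries.items():
        q_best: HomologyMatch | None = None
        for rid, rseq in refs.items():
            score, aln = smith_waterman(qseq, rseq)
            if aln is None or score < min_score:
                continue
            ncol = aln.n_aligned_columns
            identity = 100.0 * aln.n_identical / ncol if ncol else 0.0
            coverage = (aln.a_span[1] - aln.a_span[0]) / len(qseq)
            if identity < min_identity or coverage < min_coverage:
                continue
            match = HomologyMatch(
                query_id=qid,
                reference_id=rid,
                score=score,
                percent_identity=identity,
                query_coverage=coverage,
                query_span=aln.a_span,
                reference_span=aln.b_span,
            )
            all_matches.append(match)
            if q_best is None or (match.score, match.reference_id) > (
                q_best.score,
                q_best.reference_id,
            ):
                q_best = match
        if q_best is None:
            unmatched.append(qid)
        else:
            best[qid] = q_best
    return best, all_matches, unmatched


@dataclass(frozen=True)
class TriadReport:
    query_id: str
    his_state: str  # 'canonical' | 'substituted:<residue>' | 'undetermined'
    asp_state: str
    ser_state: str


def detect_catalytic_triad(
    query: str,
    canonical: str,
    query_id: str = "query",
    triad_columns: Mapping[str, Sequence[int]] | None = None,
    local: bool = False,
) -> TriadReport:
    """Read the query residues aligned to the canonical triad columns.

    ``canonical`` is an annotated reference trypsin; ``triad_columns`` maps
    each triad residue (H, D, S) to its allowed 1-based positions on that
    reference. A member is canonical when the query carries the expected
    residue at any allowed column, ``substituted:<residue>`` when an aligned
    column shows another residue, and undetermined when gaps cover every
    allowed column.
    """
    cols = dict(triad_columns) if triad_columns is not None else DEFAULT_TRIAD_COLUMNS
    for aa in "HDS":
        if aa not in cols or not cols[aa]:
            raise ValueError(f"canonical reference lacks {aa} triad annotation")
    if max(max(v) for v in cols.values()) > len(canonical):
        raise ValueError("triad column exceeds canonical sequence length")

    al = _aligner("local" if local else "global", None, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    aln = al.align(query, canonical)[0]
    q_blocks, c_blocks = aln.aligned
    # canonical position (0-based) -> query residue
    mapped: dict[int, str] = {}
    for (qs, qe), (cs, ce) in zip(q_blocks, c_blocks):
        for k in range(qe - qs):
            mapped[cs + k] = query[qs + k]

    states = {}
    for aa in "HDS":
        observed = [mapped[c - 1] for c in cols[aa] if (c - 1) in mapped]
        if not observed:
            states[aa] = "undetermined"
        elif aa in observed:
            states[aa] = "canonical"
        else:
            states[aa] = f"substituted:{observed[0]}"
    return TriadReport(
        query_id=query_id,
        his_state=states["H"],
        asp_state=states["D"],
        ser_state=states["S"],
    )
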
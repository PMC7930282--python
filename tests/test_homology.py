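"""Local alignment, reference search and catalytic-triad detection."""

import numpy as np
import pytest

from venomscan import (
    GeneratorConfig,
    detect_catalytic_triad,
    generate_reference_venom_db,
    generate_transcriptome,
    search_reference,
    smith_waterman,
)
from venomscan.homology import blosum62_x_neutral

MATRIX = blosum62_x_neutral()
GAP_OPEN, GAP_EXT = 11, 1


def brute_force_local(a: str, b: str) -> float:
    """Independent oracle: enumerate all chains of aligned residue pairs.

    A local alignment is a monotone chain of aligned pairs; between two
    consecutive pairs the skipped residues of each sequence form one gap run
    costing open + (len-1)*extend. Exponential, fine for len <= 8.
    """

    def gap(n):
        return 0 if n == 0 else GAP_OPEN + (n - 1) * GAP_EXT

    best = 0.0
    la, lb = len(a), len(b)

    def extend(i, j, score):
        nonlocal best
        best = max(best, score)
        for i2 in range(i + 1, la):
            for j2 in range(j + 1, lb):
                extend(
                    i2,
                    j2,
                    score
                    + MATRIX[a[i2], b[j2]]
                    - gap(i2 - i - 1)
                    - gap(j2 - j - 1),
                )

    for i in range(la):
        for j in range(lb):
            extend(i, j, float(MATRIX[a[i], b[j]]))
    return best


def test_self_alignment_scores_diagonal_sum():
    score, aln = smith_waterman("PAWHEAE", "PAWHEAE")
    assert score == 44.0
    assert aln.n_identical == 7 and aln.a_span == (0, 7)


def test_no_positive_alignment_scores_zero():
    assert smith_waterman("AAAA", "GGGG")[0] == 0.0
    assert smith_waterman("AAAA", "")[0] == 0.0
    assert smith_waterman("", "")[0] == 0.0


def test_matches_brute_force_oracle_on_short_pairs():
    rng = np.random.default_rng(11)
    alphabet = list("ACDE")
    for _ in range(150):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 9)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 9)))
        score, _ = smith_waterman(a, b)
        assert score == pytest.approx(brute_force_local(a, b)), (a, b)


def test_score_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(2, 15)))
        b = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(2, 15)))
        assert smith_waterman(a, b)[0] == smith_waterman(b, a)[0]


def test_x_scores_zero_against_everything():
    for aa in "ACDEFGHIKLMNPQRSTVWYX":
        assert MATRIX["X", aa] == 0.0 == MATRIX[aa, "X"]


def test_search_reference_identical_and_unrelated():
    q = "MKWVTFISLLLLFSSAYSRGVFRRQQQHHHEEE" * 3
    best, all_m, unmatched = search_reference(
        {"q1": q, "q2": "GGGGSGGGGSGGGGS"}, {"r1": q}
    )
    assert best["q1"].percent_identity == 100.0
    assert best["q1"].query_coverage == 1.0
    assert unmatched == ["q2"]
    with pytest.warns(UserWarning):
        _, _, un = search_reference({"q1": q}, {})
    assert un == ["q1"]


def test_threshold_tightening_never_adds_matches():
    rng = np.random.default_rng(5)
    queries = {
        f"q{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        for i in range(6)
    }
    refs = {"r1": queries["q0"][:50], "r2": queries["q1"][5:55]}
    loose = search_reference(queries, refs, min_identity=0, min_coverage=0, min_score=1)
    for kwargs in (
        {"min_identity": 50.0},
        {"min_coverage": 0.8},
        {"min_score": 100.0},
    ):
        tight = search_reference(queries, refs, **kwargs)
        assert set(tight[0]) <= set(loose[0])
        assert {(m.query_id, m.reference_id) for m in tight[1]} <= {
            (m.query_id, m.reference_id) for m in loose[1]
        }


def test_planted_homolog_recovered_at_60_percent_identity():
    config = GeneratorConfig(
        n_contigs=60, homolog_identity_range=(0.6, 0.6), seed=4
    )
    _, _, truth = generate_transcriptome(config)
    refs = dict(generate_reference_venom_db(truth, config))
    venom = truth[truth["is_venom"]]
    queries = {row["contig_id"]: row["protein_seq"] for _, row in venom.iterrows()}
    best, _, unmatched = search_reference(queries, refs)
    assert unmatched == []
    for cid, match in best.items():
        assert match.reference_id == f"ref_{cid}"
        # point substitutions only: alignment identity tracks the planted level
        assert match.percent_identity == pytest.approx(60.0, abs=5.0)


def test_reference_identity_one_is_exact_copy():
    config = GeneratorConfig(
        n_contigs=40, homolog_identity_range=(1.0, 1.0), seed=2, n_decoy_refs=0
    )
    _, _, truth = generate_transcriptome(config)
    refs = dict(generate_reference_venom_db(truth, config))
    planted = {f"ref_{r['contig_id']}": r["protein_seq"]
               for _, r in truth[truth["is_venom"]].iterrows()}
    assert refs == planted


# --- catalytic triad ----------------------------------------------------------


def _canonical():
    rng = np.random.default_rng(9)
    seq = list("".join(rng.choice(list("ACDEFGIKLMNPQTVWY"), size=260)))
    seq[69] = "H"
    seq[124] = "D"
    seq[129] = "D"
    seq[239] = "S"
    seq[244] = "S"
    return "".join(seq)


def test_triad_canonical_against_itself():
    canon = _canonical()
    rep = detect_catalytic_triad(canon, canon)
    assert (rep.his_state, rep.asp_state, rep.ser_state) == (
        "canonical", "canonical", "canonical",
    )


def test_triad_serine_to_arginine_substitution():
    canon = _canonical()
    query = list(canon)
    query[239] = "R"
    query[244] = "R"
    rep = detect_catalytic_triad("".join(query), canon)
    assert rep.ser_state == "substituted:R"
    assert rep.his_state == "canonical"


def test_triad_gapped_column_is_undetermined():
    canon = _canonical()
    query = canon[:60] + canon[80:]  # deletion spanning column 70
    rep = detect_catalytic_triad(query, canon)
    assert rep.his_state == "undetermined"
    assert rep.ser_state == "canonical"


def test_triad_requires_annotation():
    canon = _canonical()
    with pytest.raises(ValueError):
        detect_catalytic_triad(canon, canon, triad_columns={"H": [70], "D": [125]})
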
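"""End-to-end orchestration: simulate -> translate -> map -> secretome ->
homology -> keywords -> quantify -> enrich -> ledger.

The pipeline mirrors the integrated proteo-transcriptomic strategy for venom
characterization: six-frame translation of the venom-gland transcriptome into
a protein database, exact mapping of the observed MS peptides into it,
signal-peptide filtering of the identified proteins, cross-referencing against
a reference venom-protein set, keyword mining of the annotations for
transcript-only candidates, RPKM/qPCR quantification, GO enrichment, and a
count ledger whose additivity identities are verified on every run.

Contig-level classification of the secretory set:

* reference-matched  -- local alignment to the reference venom set passes the
  identity/coverage/score thresholds;
* other-venom-similar -- unmatched, but annotated with a venom/toxin keyword
  (similarity to venom components of other taxa is carried by annotation at
  this scale);
* unannotated         -- unmatched with an empty annotation;
* trace elements      -- unmatched, annotated, venom-unrelated.

Proteomic venom = reference-matched + other-venom-similar; the keyword-only
set is the keyword hits minus the proteomic venom contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import enrichment as enr
from . import keyword_mining as kw
from . import ledger as ledger_mod
from . import quantification as quant
from . import secretome as sec
from .homology import HomologyMatch, search_reference
from .peptide_mapping import ProteinCandidate, infer_identified_contigs, map_peptides
from .synthetic import (
    REFERENCE_GENES,
    GeneratorConfig,
    generate_reference_venom_db,
    generate_transcriptome,
    sample_peptides,
    simulate_counts,
    simulate_qpcr,
    synthetic_ontology,
)
from .translation import Contig, orf_sequence, translate_all


@dataclass
class PipelineResult:
    truth: pd.DataFrame
    annotations: pd.DataFrame
    candidates: list[ProteinCandidate]
    contig_candidates: dict[str, ProteinCandidate]
    sp_calls: dict[str, sec.SignalPeptideCall]
    secretory_contigs: set[str]
    ref_matched: set[str]
    other_venom_similar: set[str]
    unannotated: set[str]
    trace_elements: set[str]
    venom_proteomic: set[str]
    keyword_contigs: set[str]
    keyword_only: set[str]
    homology_best: dict[str, HomologyMatch]
    expression: pd.DataFrame
    enrichment: pd.DataFrame
    qpcr: pd.DataFrame
    ledger: ledger_mod.VenomLedger
    metrics: dict[str, float]


def _contig_level(candidates: list[ProteinCandidate]) -> dict[str, ProteinCandidate]:
    """Resolve multi-frame identifications: keep, per contig, the frame with
    the most distinct peptides, ties to the longest linked ORF then frame name."""
    best: dict[str, ProteinCandidate] = {}
    for cand in candidates:
        cur = best.get(cand.contig_id)
        key = (
            cand.n_unique_peptides,
            cand.orf.length if cand.orf else 0,
            cand.frame,
        )
        cur_key = (
            (cur.n_unique_peptides, cur.orf.length if cur.orf else 0, cur.frame)
            if cur
            else None
        )
        if cur is None or key > cur_key:
            best[cand.contig_id] = cand
    return best


def run_pipeline(
    config: GeneratorConfig,
    min_peptides: int = 1,
    il_equivalence: bool = True,
    min_identity: float = 35.0,
    min_coverage: float = 0.5,
    min_score: float = 50.0,
    keywords: tuple[str, ...] = kw.DEFAULT_KEYWORDS,
    alpha: float = enr.DEFAULT_ALPHA,
) -> PipelineResult:
    """Run the whole pipeline on a generated dataset and score it vs truth."""
    contigs, annotations, truth = generate_transcriptome(config)
    refs = dict(generate_reference_venom_db(truth, config))
    peptide_df = sample_peptides(truth, config, contigs=contigs)
    counts_df, library_total = simulate_counts(truth, config)
    qpcr_table, _ = simulate_qpcr(truth, config)

    return analyze(
        contigs=contigs,
        annotations=annotations,
        peptides=list(peptide_df["peptide"]),
        refs=refs,
        counts=dict(zip(counts_df["contig_id"], counts_df["count"])),
        qpcr_table=qpcr_table,
        ontology=synthetic_ontology(),
        direct_annotations={
            row["contig_id"]: set(filter(None, str(row["go_terms"] or "").split("|")))
            for _, row in annotations.iterrows()
        },
        truth=truth,
        min_peptides=min_peptides,
        il_equivalence=il_equivalence,
        min_identity=min_identity,
        min_coverage=min_coverage,
        min_score=min_score,
        keywords=keywords,
        alpha=alpha,
    )


def analyze(
    contigs: list[Contig],
    annotations: pd.DataFrame,
    peptides: list[str],
    refs: Mapping[str, str],
    counts: Mapping[str, int],
    qpcr_table: pd.DataFrame | None = None,
    ontology=None,
    direct_annotations: Mapping[str, set[str]] | None = None,
    truth: pd.DataFrame | None = None,
    min_peptides: int = 1,
    il_equivalence: bool = True,
    min_identity: float = 35.0,
    min_coverage: float = 0.5,
    min_score: float = 50.0,
    keywords: tuple[str, ...] = kw.DEFAULT_KEYWORDS,
    alpha: float = enr.DEFAULT_ALPHA,
) -> PipelineResult:
    """Analyze an assembled dataset (generated or user-supplied)."""
    db = translate_all(contigs)
    desc = dict(zip(annotations["contig_id"], annotations["description"].fillna("")))

    # proteomic identification
    matches = map_peptides(peptides, db, il_equivalence=il_equivalence)
    candidates = infer_identified_contigs(
        matches, min_peptides=min_peptides, db=db
    )
    contig_candidates = _contig_level(candidates)

    # secretome filter on the contig-level candidates
    sp_calls = sec.call_candidates(contig_candidates.values(), db)
    retained, _no_call = sec.filter_secretome(list(contig_candidates.values()), sp_calls)
    secretory_contigs = {c.contig_id for c in retained}

    # homology confirmation of the secretory set (mature ORF sequences)
    queries = {
        c.contig_id: orf_sequence(c.orf, db[c.protein_id]) for c in retained
    }
    best, _all_matches, _unmatched = search_reference(
        queries, refs, min_identity=min_identity,
        min_coverage=min_coverage, min_score=min_score,
    )
    ref_matched = set(best)
    unmatched_set = secretory_contigs - ref_matched
    kw_hits, _per_kw = kw.select_by_keyword(
        [
            kw.AnnotationRecord(cid, desc.get(cid, ""))
            for cid in sorted(desc)
        ],
        keywords,
    )
    other_venom_similar = {c for c in unmatched_set if c in kw_hits}
    unannotated = {c for c in unmatched_set - other_venom_similar if not desc.get(c)}
    trace_elements = unmatched_set - other_venom_similar - unannotated
    venom_proteomic = ref_matched | other_venom_similar

    # keyword-only transcripts, with SP / completeness breakdown
    keyword_only = kw_hits - venom_proteomic
    kw_sp, kw_completeness = _keyword_evidence(keyword_only, db, sp_calls, contig_candidates)
    breakdown = kw.build_keyword_breakdown(keyword_only, kw_sp, kw_completeness)

    # quantification
    lengths = {c.id: len(c.seq) for c in contigs}
    expression = quant.expression_table(counts, lengths)
    expression = quant.rank_by_expression(expression, desc)

    # enrichment of the venom set against the whole transcriptome
    if ontology is not None and direct_annotations is not None:
        test_set = sorted(venom_proteomic | keyword_only)
        enrich_df = enr.enrich(
            test_set, sorted(lengths), direct_annotations, ontology, alpha=alpha
        )
    else:
        enrich_df = pd.DataFrame()

    qpcr_df = pd.DataFrame()
    if qpcr_table is not None and not qpcr_table.empty:
        qpcr_df = quant.analyze_qpcr(
            qpcr_table,
            reference_genes=REFERENCE_GENES,
            calibrator_group="body",
            test_group="venom_gland",
        )

    ledger = ledger_mod.build_ledger(
        n_contigs=len(contigs),
        n_peptides_observed=len(set(peptides)),
        n_identified_contigs=len(contig_candidates),
        n_secretory=len(secretory_contigs),
        n_ref_matched=len(ref_matched),
        n_other_venom_similar=len(other_venom_similar),
        n_unannotated=len(unannotated),
        n_trace_elements=len(trace_elements),
        n_keyword_total=breakdown.n_keyword,
        n_keyword_sp=breakdown.n_with_sp,
        n_keyword_incomplete_5prime=breakdown.n_incomplete_5prime,
        n_keyword_complete=breakdown.n_complete,
        n_keyword_too_small=breakdown.n_too_small,
        n_keyword_only=len(keyword_only),
    )

    metrics: dict[str, float] = {}
    if truth is not None:
        planted = set(truth.loc[truth["is_venom"], "contig_id"])
        called = venom_proteomic
        tp = len(called & planted)
        metrics["sensitivity"] = tp / len(planted) if planted else float("nan")
        metrics["false_discovery_proportion"] = (
            (len(called) - tp) / len(called) if called else 0.0
        )
        planted_sec = set(truth.loc[truth["is_secreted"], "contig_id"])
        sec_called = secretory_contigs
        identified = set(contig_candidates)
        det_pos = identified & planted_sec
        det_neg = identified - planted_sec
        metrics["sp_sensitivity"] = (
            len(sec_called & det_pos) / len(det_pos) if det_pos else float("nan")
        )
        metrics["sp_specificity"] = (
            len(det_neg - sec_called) / len(det_neg) if det_neg else float("nan")
        )

    return PipelineResult(
        truth=truth if truth is not None else pd.DataFrame(),
        annotations=annotations,
        candidates=candidates,
        contig_candidates=contig_candidates,
        sp_calls=sp_calls,
        secretory_contigs=secretory_contigs,
        ref_matched=ref_matched,
        other_venom_similar=other_venom_similar,
        unannotated=unannotated,
        trace_elements=trace_elements,
        venom_proteomic=venom_proteomic,
        keyword_contigs=kw_hits,
        keyword_only=keyword_only,
        homology_best=best,
        expression=expression,
        enrichment=enrich_df,
        qpcr=qpcr_df,
        ledger=ledger,
        metrics=metrics,
    )


def _keyword_evidence(
    keyword_only: set[str],
    db: Mapping[str, object],
    sp_calls: Mapping[str, sec.SignalPeptideCall],
    contig_candidates: Mapping[str, ProteinCandidate],
) -> tuple[set[str], dict[str, str]]:
    """Signal-peptide flags and completeness labels for keyword-only contigs.

    Proteomically identified contigs reuse their candidate's call; the rest
    are evaluated on the longest ORF across their six frame translations.
    """
    from .translation import classify_orf_completeness, find_orfs

    sp_positive: set[str] = set()
    completeness: dict[str, str] = {}
    for cid in sorted(keyword_only):
        cand = contig_candidates.get(cid)
        if cand is not None and cand.orf is not None:
            call = sp_calls.get(cand.protein_id)
            ft = db[cand.protein_id]
            if call is not None and call.is_secreted:
                sp_positive.add(cid)
            else:
                label = classify_orf_completeness(cand.orf, ft)
                if call is not None and call.no_call_reason == "too_short":
                    label = "too_small"
                completeness[cid] = label
            continue
        # transcript-only contig: take the longest ORF over all six frames
        frames = [db[f"{cid}|frame={f}"] for f in ("+1", "+2", "+3", "-1", "-2", "-3")]
        best_orf, best_ft = None, None
        for ft in frames:
            for o in find_orfs(ft, min_aa=1):
                if best_orf is None or o.length > best_orf.length:
                    best_orf, best_ft = o, ft
        if best_orf is None:
            completeness[cid] = "too_small"
            continue
        label = classify_orf_completeness(best_orf, best_ft)
        if label == "complete":
            call = sec.score_signal_peptide(
                best_ft.aa_seq[best_orf.aa_start : best_orf.aa_end]
            )
            if call.is_secreted:
                sp_positive.add(cid)
                continue
            if call.no_call_reason == "too_short":
                label = "too_small"
        completeness[cid] = label
    return sp_positive, completeness
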
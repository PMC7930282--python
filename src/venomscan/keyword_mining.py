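"""Keyword-based selection of putative venom transcripts.

Besides direct proteomic evidence, venom-gland transcripts can be flagged from
their functional annotation alone: any contig whose description contains
"venom" or "toxin" (case-insensitive substring, so compounds like
"plancitoxin" count) is a putative venom transcript. The keyword-only set --
keyword hits minus the proteomically identified venom proteins -- is then
broken down by signal-peptide status and, for those missing the signal
peptide, by 5'-completeness of the underlying ORF.

Substring (rather than word-boundary) matching can in principle select
descriptions like "antivenom"; the per-keyword report makes such hits
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

DEFAULT_KEYWORDS = ("venom", "toxin")


class KeywordError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    contig_id: str
    description: str
    go_terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class KeywordBreakdown:
    n_keyword: int
    n_with_sp: int
    n_missing_sp: int
    n_incomplete_5prime: int
    n_complete: int
    n_too_small: int

    def __post_init__(self) -> None:
        if self.n_keyword != self.n_with_sp + self.n_missing_sp:
            raise KeywordError(
                "identity violated: n_keyword != n_with_sp + n_missing_sp "
                f"({self.n_keyword} != {self.n_with_sp} + {self.n_missing_sp})"
            )
        split = self.n_incomplete_5prime + self.n_complete + self.n_too_small
        if self.n_missing_sp != split:
            raise KeywordError(
                "identity violated: n_missing_sp != "
                "n_incomplete_5prime + n_complete + n_too_small "
                f"({self.n_missing_sp} != {split})"
            )


def select_by_keyword(
    annotations: Iterable[AnnotationRecord],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> tuple[set[str], dict[str, set[str]]]:
    """Contigs whose description contains any keyword (case-insensitive).

    Returns the selected contig-id set plus per-keyword hit sets (a contig
    matching several keywords appears in each; the selection is their union).
    """
    if not keywords:
        raise KeywordError("keyword list must be non-empty")
    kws = [k.lower() for k in keywords]
    per_keyword: dict[str, set[str]] = {k: set() for k in keywords}
    selected: set[str] = set()
    for rec in annotations:
        desc = (rec.description or "").lower()
        for kw, kw_lower in zip(keywords, kws):
            if kw_lower in desc:
                per_keyword[kw].add(rec.contig_id)
                selected.add(rec.contig_id)
    return selected, per_keyword


def build_keyword_breakdown(
    keyword_set: Iterable[str],
    sp_positive: Iterable[str] | Mapping[str, bool],
    orf_completeness: Mapping[str, str],
) -> KeywordBreakdown:
    """Signal-peptide / 5'-completeness ledger for the keyword set.

    ``sp_positive`` is the set of keyword contigs with a positive
    signal-peptide call (or a mapping contig -> flag); every other keyword
    contig needs a 5'-completeness label (``complete``, ``incomplete_5prime``
    or ``too_small``). A contig with a positive call is counted under
    ``n_with_sp`` regardless of completeness.
    """
    keyword_ids = sorted(set(keyword_set))
    if isinstance(sp_positive, Mapping):
        positive = {cid for cid, flag in sp_positive.items() if flag}
    else:
        positive = set(sp_positive)

    n_with_sp = 0
    tally = {"incomplete_5prime": 0, "complete": 0, "too_small": 0}
    for cid in keyword_ids:
        if cid in positive:
            n_with_sp += 1
            continue
        label = orf_completeness.get(cid)
        if label is None:
            raise KeywordError(
                f"contig {cid!r} has neither a signal-peptide call nor a "
                "completeness label"
            )
        if label not in tally:
            raise KeywordError(f"contig {cid!r}: unknown completeness label {label!r}")
        tally[label] += 1

    return KeywordBreakdown(
        n_keyword=len(keyword_ids),
        n_with_sp=n_with_sp,
        n_missing_sp=len(keyword_ids) - n_with_sp,
        n_incomplete_5prime=tally["incomplete_5prime"],
        n_complete=tally["complete"],
        n_too_small=tally["too_small"],
    )
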
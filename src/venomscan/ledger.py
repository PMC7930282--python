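"""Stage-count bookkeeping and functional categorization of venom proteins.

The pipeline's headline numbers obey hard arithmetic identities:

* database entries      = 6 x contigs
* secretory             = reference-matched + reference-unmatched
* reference-unmatched   = other-venom-similar + unannotated + trace elements
* proteomic venom       = reference-matched + other-venom-similar
* total venom           = proteomic venom + keyword-only transcripts
* keyword total         = keyword-with-SP + keyword-missing-SP
                          (the missing split into 5'-incomplete / complete /
                          too-small ORFs)

"Trace elements" are secreted, proteomically detected proteins with no
similarity to any known venom component (annotated, but venom-unrelated);
"unannotated" are those without any annotation at all. :func:`build_ledger`
verifies every identity and raises naming the first one violated, so an
inconsistent upstream count can never be reported silently.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class LedgerError(ValueError):
    pass


@dataclass(frozen=True)
class VenomLedger:
    n_contigs: int
    n_db_entries: int
    n_peptides_observed: int
    n_identified_contigs: int
    n_secretory: int
    n_ref_matched: int
    n_ref_unmatched: int
    n_other_venom_similar: int
    n_unannotated: int
    n_trace_elements: int
    n_venom_proteomic: int
    n_keyword_total: int
    n_keyword_only: int
    n_keyword_sp: int
    n_keyword_missing_sp: int
    n_keyword_incomplete_5prime: int
    n_keyword_complete: int
    n_keyword_too_small: int
    n_venom_total: int


_IDENTITIES = (
    ("n_db_entries", lambda d: d["n_db_entries"] == 6 * d["n_contigs"]),
    (
        "n_secretory",
        lambda d: d["n_secretory"] == d["n_ref_matched"] + d["n_ref_unmatched"],
    ),
    (
        "n_ref_unmatched",
        lambda d: d["n_ref_unmatched"]
        == d["n_other_venom_similar"] + d["n_unannotated"] + d["n_trace_elements"],
    ),
    (
        "n_venom_proteomic",
        lambda d: d["n_venom_proteomic"]
        == d["n_ref_matched"] + d["n_other_venom_similar"],
    ),
    (
        "n_venom_total",
        lambda d: d["n_venom_total"] == d["n_venom_proteomic"] + d["n_keyword_only"],
    ),
    (
        "n_keyword_total",
        lambda d: d["n_keyword_total"] == d["n_keyword_sp"] + d["n_keyword_missing_sp"],
    ),
    (
        "n_keyword_missing_sp",
        lambda d: d["n_keyword_missing_sp"]
        == d["n_keyword_incomplete_5prime"]
        + d["n_keyword_complete"]
        + d["n_keyword_too_small"],
    ),
)


def build_ledger(
    n_contigs: int,
    n_peptides_observed: int,
    n_identified_contigs: int,
    n_secretory: int,
    n_ref_matched: int,
    n_other_venom_similar: int,
    n_unannotated: int,
    n_trace_elements: int,
    n_keyword_total: int,
    n_keyword_sp: int,
    n_keyword_incomplete_5prime: int,
    n_keyword_complete: int,
    n_keyword_too_small: int,
    n_keyword_only: int | None = None,
) -> VenomLedger:
    """Assemble the count ledger and verify every identity.

    Derived fields (database size, reference-unmatched, proteomic venom,
    keyword-missing-SP, total venom) are computed from the stage counts;
    ``n_keyword_only`` defaults to the full keyword set (no overlap with the
    proteomic venom set). Any violated identity raises :class:`LedgerError`
    naming the identity.
    """
    d = {
        "n_contigs": n_contigs,
        "n_db_entries": 6 * n_contigs,
        "n_peptides_observed": n_peptides_observed,
        "n_identified_contigs": n_identified_contigs,
        "n_secretory": n_secretory,
        "n_ref_matched": n_ref_matched,
        "n_ref_unmatched": n_secretory - n_ref_matched,
        "n_other_venom_similar": n_other_venom_similar,
        "n_unannotated": n_unannotated,
        "n_trace_elements": n_trace_elements,
        "n_venom_proteomic": n_ref_matched + n_other_venom_similar,
        "n_keyword_total": n_keyword_total,
        "n_keyword_only": n_keyword_total if n_keyword_only is None else n_keyword_only,
        "n_keyword_sp": n_keyword_sp,
        "n_keyword_missing_sp": n_keyword_total - n_keyword_sp,
        "n_keyword_incomplete_5prime": n_keyword_incomplete_5prime,
        "n_keyword_complete": n_keyword_complete,
        "n_keyword_too_small": n_keyword_too_small,
    }
    d["n_venom_total"] = d["n_venom_proteomic"] + d["n_keyword_only"]
    for value in d.values():
        if value < 0:
            raise LedgerError("ledger counts must be non-negative")
    ledger = VenomLedger(**d)
    validate_ledger(ledger)
    return ledger


def validate_ledger(ledger: VenomLedger) -> None:
    d = asdict(ledger)
    for name, check in _IDENTITIES:
        if not check(d):
            raise LedgerError(f"ledger identity violated: {name}")


# --- functional categorization -------------------------------------------------

#: first-matching-rule category assignment, seeded from the standard venom
#: protein families; editable/replaceable by the caller.
DEFAULT_CATEGORY_RULES: tuple[tuple[str, str, str], ...] = (
    # (description regex, category, subfamily)
    (r"trypsin|chymotrypsin|serine protease(?! inhibitor)", "Hydrolases", "Serine proteases"),
    (r"metalloprote", "Hydrolases", "Metalloproteases"),
    (r"dipeptidase|dipeptidyl", "Hydrolases", "Dipeptidases"),
    (r"aminopeptidase", "Hydrolases", "Aminopeptidases"),
    (r"cathepsin|lysosomal .*protease", "Hydrolases", "Lysosomal proteases"),
    (r"carboxypeptidase", "Hydrolases", "Carboxypeptidases"),
    (r"acid phosphatase", "Hydrolases", "Venom acid phosphatases"),
    (r"carboxylesterase|esterase", "Hydrolases", "Carboxylesterases"),
    (r"lipase", "Hydrolases", "Lipases"),
    (r"glucosidase", "Hydrolases", "Glucosidases"),
    (r"galactosidase", "Hydrolases", "Galactosidases"),
    (r"amylase", "Hydrolases", "Amylases"),
    (r"trehalase", "Hydrolases", "Trehalases"),
    (r"chitinase|chitotriosidase", "Hydrolases", "Chitinases"),
    (r"nuclease|ribonuclease|plancitoxin|endoribonuclease", "Hydrolases", "Nucleases"),
    (r"serpin|protease inhibitor", "Protease inhibitors", "Serine protease inhibitors"),
    (r"kazal|ovomucoid", "Protease inhibitors", "Kazal-type inhibitors"),
    (r"cysteine.?rich", "Protease inhibitors", "Cysteine-rich proteins"),
    (r"calreticulin", "Immune related proteins", "Calreticulin"),
    (r"calnexin", "Immune related proteins", "Calnexin"),
    (r"nucleobindin", "Immune related proteins", "Nucleobindin"),
    (r"c1q", "Immune related proteins", "C1q-like venom protein"),
    (r"odorant.?binding", "Recognition/binding proteins", "Odorant binding proteins"),
    (r"chemosensory", "Recognition/binding proteins", "Chemosensory proteins"),
    (
        r"low.?density lipoprotein",
        "Recognition/binding proteins",
        "Low-density lipoprotein receptors",
    ),
    (r"apolipopho|apolipoprotein", "Recognition/binding proteins", "Apolipophorins"),
    (
        r"insulin-like growth factor",
        "Recognition/binding proteins",
        "IGF-binding proteins",
    ),
    (r"glutamyl cyclotransferase|glutathione", "Glutathione metabolism", ""),
    (r"laccase|oxidase", "Oxidase", ""),
    (r"dehydrogenase", "Dehydrogenases", ""),
    (r"isomerase|fk506", "Isomerases", ""),
    (r"endoplasmin|heat shock", "Heat shock proteins", ""),
    (r"allergen|royal jelly|ferritin|lachesin|neurotrophic|vitellogenin|agatoxin"
     r"|adipocyte", "Other proteins", ""),
)

DEFAULT_CATEGORY = ("Unknown and hypothetical proteins", "")


@dataclass(frozen=True)
class CategoryAssignment:
    protein_id: str
    category: str
    subfamily: str
    evidence: str  # the matched pattern, or '' for the default rule


def compile_rules(
    rules: Sequence[tuple[str, str, str]] = DEFAULT_CATEGORY_RULES,
) -> list[tuple[re.Pattern, str, str]]:
    compiled = []
    for i, rule in enumerate(rules):
        try:
            pattern, category, subfamily = rule
            compiled.append((re.compile(pattern, re.IGNORECASE), category, subfamily))
        except (re.error, ValueError) as exc:
            raise LedgerError(f"malformed category rule at index {i}: {exc}") from exc
    return compiled


def categorize_proteins(
    descriptions: Mapping[str, str],
    rules: Sequence[tuple[str, str, str]] = DEFAULT_CATEGORY_RULES,
) -> list[CategoryAssignment]:
    """First-matching-rule functional category for each venom protein."""
    compiled = compile_rules(rules)
    out = []
    for pid in sorted(descriptions):
        desc = descriptions[pid] or ""
        for pattern, category, subfamily in compiled:
            if pattern.search(desc):
                out.append(CategoryAssignment(pid, category, subfamily, pattern.pattern))
                break
        else:
            out.append(CategoryAssignment(pid, *DEFAULT_CATEGORY, ""))
    return out


def export_report(
    ledger: VenomLedger,
    categories: Iterable[CategoryAssignment],
    rankings: pd.DataFrame | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the machine-readable (JSON/TSV) and human-readable summaries.

    Deterministic: identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ledger_json = outdir / "ledger.json"
    ledger_json.write_text(json.dumps(asdict(ledger), indent=2, sort_keys=True) + "\n")
    paths["ledger_json"] = ledger_json

    cat_df = pd.DataFrame(
        [asdict(c) for c in sorted(categories, key=lambda c: c.protein_id)],
        columns=["protein_id", "category", "subfamily", "evidence"],
    )
    cat_tsv = outdir / "categories.tsv"
    cat_df.to_csv(cat_tsv, sep="\t", index=False)
    paths["categories_tsv"] = cat_tsv

    if rankings is not None:
        rank_tsv = outdir / "expression_ranking.tsv"
        rankings.to_csv(rank_tsv, sep="\t", index=False, float_format="%.6g")
        paths["ranking_tsv"] = rank_tsv

    lines = ["venom protein ledger", "====================", ""]
    for key, value in sorted(asdict(ledger).items()):
        lines.append(f"{key:28s} {value}")
    lines += [
        "",
        f"categories assigned: {len(cat_df)}",
    ]
    txt = outdir / "report.txt"
    txt.write_text("\n".join(lines) + "\n")
    paths["report_txt"] = txt
    return paths
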
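"""Signal-peptide calling and secretome filtering.

Secreted proteins begin with an N-terminal signal peptide: a short positively
charged n-region, a hydrophobic h-region, and a c-region ending in small
residues at the -3 and -1 positions relative to the cleavage site (the
classical von Heijne architecture). The caller here is a transparent
rule-based stand-in for trained predictors such as SignalP: it is the filter
the pipeline applies by default, and genuine external predictor output can be
imported through :func:`import_external_sp_calls` to override it.

A positive call requires a candidate cleavage site p in residues 15..35 with

* small residues (A, G, S, C, T or V) at positions p-2 and p (-3/-1 rule),
* an 8-residue window inside positions 1..p whose mean Kyte-Doolittle
  hydropathy is >= 2.0 (the h-region), and
* non-negative net charge (K/R +1, D/E -1) over the residues before that
  window (the n-region).

Among valid (site, window) combinations the window with the highest mean
hydropathy wins; ties go to the smallest cleavage site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .peptide_mapping import ProteinCandidate
from .translation import (
    DEFAULT_TOO_SMALL_AA,
    FrameTranslation,
    classify_orf_completeness,
    orf_sequence,
)

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SMALL_RESIDUES = frozenset("AGSCTV")
H_WINDOW = 8
MIN_HYDROPATHY = 2.0
CLEAVAGE_RANGE = (15, 35)  # 1-based, inclusive
MIN_SEQ_LEN = 18


class SecretomeError(ValueError):
    pass


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str | None
    is_secreted: bool
    cleavage_site: int | None = None  # 1-based residue after which cleavage occurs
    score: float | None = None  # mean hydropathy of the best h-window
    no_call_reason: str | None = None  # 'too_short' | 'incomplete_5prime'
    provenance: str = "heuristic"

    @property
    def is_no_call(self) -> bool:
        return self.no_call_reason is not None


def _net_charge(seq: str) -> int:
    return sum(+1 if c in "KR" else -1 if c in "DE" else 0 for c in seq)


def _window_hydropathy(seq: str, start: int) -> float:
    w = seq[start : start + H_WINDOW]
    return sum(KYTE_DOOLITTLE.get(c, 0.0) for c in w) / H_WINDOW


def score_signal_peptide(aa_seq: str, protein_id: str | None = None) -> SignalPeptideCall:
    """Apply the signal-peptide rule to a sequence starting at its N-terminus."""
    seq = aa_seq.upper()
    if len(seq) < MIN_SEQ_LEN:
        return SignalPeptideCall(protein_id, False, no_call_reason="too_short")

    lo, hi = CLEAVAGE_RANGE
    best: tuple[float, int] | None = None  # (window hydropathy, cleavage site)
    for p in range(lo, min(hi, len(seq) - 1) + 1):
        if seq[p - 1] not in SMALL_RESIDUES or seq[p - 3] not in SMALL_RESIDUES:
            continue
        for w0 in range(0, p - H_WINDOW + 1):  # window within positions 1..p
            hyd = _window_hydropathy(seq, w0)
            if hyd < MIN_HYDROPATHY:
                continue
            if _net_charge(seq[:w0]) < 0:
                continue
            if best is None or (hyd, -p) > (best[0], -best[1]):
                best = (hyd, p)

    # reported score: best h-window hydropathy over the N-terminal region
    n_scan = min(len(seq), CLEAVAGE_RANGE[1]) - H_WINDOW + 1
    scan = max(
        (_window_hydropathy(seq, i) for i in range(max(n_scan, 1))), default=0.0
    )
    if best is None:
        return SignalPeptideCall(protein_id, False, score=scan)
    return SignalPeptideCall(
        protein_id, True, cleavage_site=best[1], score=best[0]
    )


def call_candidates(
    candidates: Iterable[ProteinCandidate],
    db: Mapping[str, FrameTranslation],
    too_small_aa: int = DEFAULT_TOO_SMALL_AA,
) -> dict[str, SignalPeptideCall]:
    """Signal-peptide calls for protein candidates, keyed by protein id.

    Candidates whose supporting ORF is 5'-incomplete get
    ``no_call(incomplete_5prime)`` rather than a negative call: with the true
    N-terminus missing, secretion is undecidable, and the ledger books them
    separately. Candidates without a linked ORF are treated the same way.
    """
    calls: dict[str, SignalPeptideCall] = {}
    for cand in candidates:
        pid = cand.protein_id
        if cand.orf is None:
            calls[pid] = SignalPeptideCall(
                pid, False, no_call_reason="incomplete_5prime"
            )
            continue
        ft = db[pid]
        label = classify_orf_completeness(cand.orf, ft, too_small_aa=too_small_aa)
        if label == "too_small":
            calls[pid] = SignalPeptideCall(pid, False, no_call_reason="too_short")
        elif label == "incomplete_5prime":
            calls[pid] = SignalPeptideCall(
                pid, False, no_call_reason="incomplete_5prime"
            )
        else:
            calls[pid] = score_signal_peptide(orf_sequence(cand.orf, ft), pid)
    return calls


def filter_secretome(
    candidates: list[ProteinCandidate],
    calls: Mapping[str, SignalPeptideCall],
) -> tuple[list[ProteinCandidate], list[ProteinCandidate]]:
    """Keep candidates with a positive call.

    Returns ``(retained, no_call)``; negative calls are dropped, no-calls are
    returned separately so they can be counted. A candidate without any call
    is an error.
    """
    retained, no_call = [], []
    for cand in candidates:
        call = calls.get(cand.protein_id)
        if call is None:
            raise SecretomeError(f"candidate {cand.protein_id} has no signal-peptide call")
        if call.is_secreted:
            retained.append(cand)
        elif call.is_no_call:
            no_call.append(cand)
    return retained, no_call


def import_external_sp_calls(
    path: str | Path, known_ids: Iterable[str]
) -> dict[str, SignalPeptideCall]:
    """Load predictor output (TSV: protein_id, flag, optional cleavage site).

    The flag accepts YES/NO, TRUE/FALSE or 1/0 (case-insensitive). Calls are
    flagged with external provenance and override the built-in rule. Unknown
    protein ids and malformed rows raise with the offending line number.
    """
    known = set(known_ids)
    calls: dict[str, SignalPeptideCall] = {}
    truthy = {"yes", "true", "1", "y"}
    falsy = {"no", "false", "0", "n"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace(",", "\t").split("\t")]
            if lineno == 1 and parts[0].lower() in {"protein_id", "id"}:
                continue
            if len(parts) < 2:
                raise SecretomeError(f"line {lineno}: expected at least 2 fields")
            pid, flag = parts[0], parts[1].lower()
            if pid not in known:
                raise SecretomeError(f"line {lineno}: unknown protein id {pid!r}")
            if flag in truthy:
                site = None
                if len(parts) > 2 and parts[2]:
                    try:
                        site = int(parts[2])
                    except ValueError as exc:
                        raise SecretomeError(
                            f"line {lineno}: bad cleavage site {parts[2]!r}"
                        ) from exc
                calls[pid] = SignalPeptideCall(
                    pid, True, cleavage_site=site, provenance="external"
                )
            elif flag in falsy:
                calls[pid] = SignalPeptideCall(pid, False, provenance="external")
            else:
                raise SecretomeError(f"line {lineno}: bad flag {parts[1]!r}")
    return calls
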
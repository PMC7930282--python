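"""In-silico tryptic digestion and exact peptide-to-database mapping.

The proteomic input boundary of the pipeline is a flat list of observed
peptide sequences. Each peptide is located as an exact contiguous substring of
the six-frame translations (optionally identifying the isobaric residues I and
L, which standard MS/MS cannot distinguish); per-(contig, frame) aggregation of
the matches yields the proteomically identified protein candidates.

Digestion follows the trypsin rule -- cleave after K or R, but not when the
next residue is P -- with up to ``max_missed`` missed cleavages and a peptide
length window, matching common search-engine settings (2 missed cleavages,
7-35 residues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .translation import FrameTranslation, Orf, find_orfs

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestionParams:
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 35

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    contig_id: str
    frame: str
    offset: int  # 0-based position in the frame translation
    il_collapsed: bool
    tryptic_nterm: bool
    tryptic_cterm: bool


@dataclass(frozen=True)
class ProteinCandidate:
    """A (contig, frame) with at least one supporting peptide."""

    contig_id: str
    frame: str
    supporting_peptides: frozenset[str]
    orf: Orf | None = None

    @property
    def n_unique_peptides(self) -> int:
        return len(self.supporting_peptides)

    @property
    def protein_id(self) -> str:
        return f"{self.contig_id}|frame={self.frame}"


def cleavage_sites(seq: str) -> list[int]:
    """Positions after which trypsin cleaves (0-based, site i cuts i|i+1)."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def digest_protein(seq: str, params: DigestionParams = DigestionParams()) -> list[str]:
    """All tryptic peptides of ``seq`` with 0..max_missed missed cleavages.

    Peptides are emitted in N-to-C order, fully-cleaved products first for each
    start site, then their missed-cleavage joins, filtered to the length
    window.
    """
    if not seq:
        raise ValueError("empty sequence")
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for m in range(params.max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            pep = seq[bounds[i] : bounds[j]]
            if params.min_len <= len(pep) <= params.max_len:
                peptides.append(pep)
    return peptides


def collapse_il(seq: str) -> str:
    """Map I and L onto a single letter (J) for isobaric-equivalent matching."""
    return seq.replace("I", "J").replace("L", "J")


class _FrameIndex:
    """Concatenated frame translations with '#' separators for fast substring
    search via str.find (C-level Two-Way algorithm)."""

    def __init__(self, frames: list[FrameTranslation], il_equivalence: bool):
        self.frames = frames
        self.il = il_equivalence
        parts = []
        self.starts = []  # start offset of each frame in the corpus
        pos = 0
        for ft in frames:
            aa = ft.aa_seq
            if il_equivalence:
                aa = collapse_il(aa)
            # frame 'X' must match nothing: lowercase it so uppercase peptides miss
            aa = aa.replace("X", "x")
            parts.append(aa)
            self.starts.append(pos)
            pos += len(aa) + 1
        self.corpus = "#".join(parts)

    def locate(self, pos: int) -> tuple[int, int]:
        """Map a corpus position to (frame index, offset within frame)."""
        import bisect

        i = bisect.bisect_right(self.starts, pos) - 1
        return i, pos - self.starts[i]

    def find_all(self, peptide: str) -> list[tuple[int, int]]:
        key = collapse_il(peptide) if self.il else peptide
        # peptide-side X/* must never match anything in the corpus
        key = key.replace("X", "!").replace("*", "!")
        hits = []
        start = self.corpus.find(key)
        while start != -1:
            hits.append(self.locate(start))
            start = self.corpus.find(key, start + 1)
        return hits


def map_peptides(
    peptides: list[str],
    db: list[FrameTranslation] | dict[str, FrameTranslation],
    il_equivalence: bool = True,
) -> list[PeptideMatch]:
    """Every occurrence of every peptide as a substring of a frame translation.

    ``X`` (ambiguous codon) and ``*`` (stop) in the database match nothing.
    Empty peptides are skipped with a warning. Duplicate peptides in the input
    list are mapped once.
    """
    frames = list(db.values()) if isinstance(db, dict) else list(db)
    index = _FrameIndex(frames, il_equivalence)
    matches: list[PeptideMatch] = []
    seen: set[str] = set()
    for pep in peptides:
        pep = pep.strip().upper()
        if not pep:
            warnings.warn("empty peptide skipped", stacklevel=2)
            continue
        if pep in seen:
            continue
        seen.add(pep)
        for fi, off in index.find_all(pep):
            ft = frames[fi]
            aa = ft.aa_seq
            end = off + len(pep)
            prev = aa[off - 1] if off > 0 else None
            last = aa[end - 1]
            nxt = aa[end] if end < len(aa) else None
            nterm = prev is None or prev == "*" or (prev in "KR" and pep[0] != "P")
            cterm = nxt is None or nxt == "*" or (last in "KR" and nxt != "P")
            matches.append(
                PeptideMatch(
                    peptide=pep,
                    contig_id=ft.contig_id,
                    frame=ft.frame,
                    offset=off,
                    il_collapsed=il_equivalence,
                    tryptic_nterm=nterm,
                    tryptic_cterm=cterm,
                )
            )
    return matches


def infer_identified_contigs(
    matches: list[PeptideMatch],
    min_peptides: int = 1,
    require_tryptic: bool = False,
    db: dict[str, FrameTranslation] | None = None,
    min_orf_aa: int = 10,
) -> list[ProteinCandidate]:
    """Aggregate matches into per-(contig, frame) protein candidates.

    A candidate needs at least ``min_peptides`` distinct supporting peptides
    (optionally counting only fully tryptic matches). When the frame database
    is supplied, each candidate is linked to the longest ORF of its frame that
    contains at least one supporting peptide.
    """
    by_cf: dict[tuple[str, str], dict[str, list[PeptideMatch]]] = {}
    for m in matches:
        if require_tryptic and not (m.tryptic_nterm and m.tryptic_cterm):
            continue
        by_cf.setdefault((m.contig_id, m.frame), {}).setdefault(m.peptide, []).append(m)

    candidates = []
    for (contig_id, frame), peps in sorted(by_cf.items()):
        if len(peps) < min_peptides:
            continue
        orf = None
        if db is not None:
            ft = db[f"{contig_id}|frame={frame}"]
            containing = []
            for o in find_orfs(ft, min_aa=min_orf_aa):
                for plist in peps.values():
                    if any(
                        o.aa_start <= m.offset and m.offset + len(m.peptide) <= o.aa_end
                        for m in plist
                    ):
                        containing.append(o)
                        break
            if containing:
                orf = max(containing, key=lambda o: (o.length, -o.aa_start))
        candidates.append(
            ProteinCandidate(
                contig_id=contig_id,
                frame=frame,
                supporting_peptides=frozenset(peps),
                orf=orf,
            )
        )
    return candidates
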
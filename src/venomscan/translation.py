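"""Six-frame translation of assembled contigs and ORF handling.

The protein database searched by the proteomic stage is the set of *whole*
frame translations (stop characters included), six per contig: three forward
offsets and three offsets on the reverse complement. ORFs -- maximal stop-free
segments of a frame translation -- are a separate view used for 5'-completeness
classification and as input to the secretome filter.

Coordinates are 0-based, half-open throughout. Frames are named ``+1..+3`` and
``-1..-3``; frame ``-k`` is defined on the reverse complement at offset
``k - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

#: codon -> amino acid for the standard code; any other codon (ambiguity
#: characters included) is an 'X' -- ambiguity is never resolved
_CODON_AA = dict(standard_dna_table.forward_table)
_CODON_AA.update({c: "*" for c in standard_dna_table.stop_codons})

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")

#: nucleotide alphabet accepted on input (IUPAC ambiguity codes translate to X)
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")

#: a protein shorter than the signal-peptide window cannot be evaluated
DEFAULT_TOO_SMALL_AA = 30


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class Contig:
    """An assembled transcript: the unit of transcriptomic identity."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise TranslationError(f"contig {self.id!r}: empty sequence")
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise TranslationError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class FrameTranslation:
    contig_id: str
    frame: str  # one of FRAMES
    aa_seq: str  # '*' marks stops, 'X' ambiguous codons

    @property
    def protein_id(self) -> str:
        return f"{self.contig_id}|frame={self.frame}"


@dataclass(frozen=True)
class Orf:
    """A maximal stop-free segment of one frame translation."""

    contig_id: str
    frame: str
    aa_start: int  # 0-based, in frame-translation coordinates
    aa_end: int  # half-open
    has_start_codon: bool  # first residue is M
    preceded_by_stop: bool
    followed_by_stop: bool

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start


def database_size(n_contigs: int) -> int:
    """Number of entries in the translated protein database: exactly 6n."""
    return 6 * n_contigs


def six_frame_translate(contig: Contig) -> list[FrameTranslation]:
    """Translate a contig in all six reading frames.

    Codons containing an ambiguity character (N etc.) translate to ``X``;
    trailing 1-2 nucleotides of each frame are dropped.
    """
    fwd = contig.seq.replace("U", "T")
    rev = fwd.translate(_COMPLEMENT)[::-1]
    out = []
    for strand, nt in (("+", fwd), ("-", rev)):
        for offset in range(3):
            frame = f"{strand}{offset + 1}"
            aa = "".join(
                _CODON_AA.get(nt[i : i + 3], "X")
                for i in range(offset, len(nt) - 2, 3)
            )
            out.append(FrameTranslation(contig.id, frame, aa))
    return out


def translate_all(contigs: list[Contig]) -> dict[str, FrameTranslation]:
    """Build the protein database; keys are ``<contig_id>|frame=<f>``."""
    db: dict[str, FrameTranslation] = {}
    for c in contigs:
        for ft in six_frame_translate(c):
            db[ft.protein_id] = ft
    return db


def find_orfs(ft: FrameTranslation, min_aa: int = 1) -> list[Orf]:
    """Maximal stop-free segments of ``ft.aa_seq`` with length >= ``min_aa``."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    orfs: list[Orf] = []
    aa = ft.aa_seq
    start = 0
    n = len(aa)
    for i in range(n + 1):
        if i == n or aa[i] == "*":
            if i - start >= min_aa:
                orfs.append(
                    Orf(
                        contig_id=ft.contig_id,
                        frame=ft.frame,
                        aa_start=start,
                        aa_end=i,
                        has_start_codon=aa[start] == "M",
                        preceded_by_stop=start > 0 and aa[start - 1] == "*",
                        followed_by_stop=i < n,
                    )
                )
            start = i + 1
    return orfs


def orf_sequence(orf: Orf, ft: FrameTranslation) -> str:
    _check_pairing(orf, ft)
    return ft.aa_seq[orf.aa_start : orf.aa_end]


def _check_pairing(orf: Orf, ft: FrameTranslation) -> None:
    if orf.contig_id != ft.contig_id or orf.frame != ft.frame:
        raise TranslationError(
            f"ORF {orf.contig_id}|{orf.frame} does not belong to "
            f"translation {ft.contig_id}|{ft.frame}"
        )
    if orf.aa_end > len(ft.aa_seq):
        raise TranslationError("ORF coordinates exceed frame translation")


def classify_orf_completeness(
    orf: Orf, ft: FrameTranslation, too_small_aa: int = DEFAULT_TOO_SMALL_AA
) -> str:
    """5'-completeness label: ``complete``, ``incomplete_5prime`` or ``too_small``.

    A segment abutting the frame start without a start codon is 5'-incomplete
    (the true N-terminus lies upstream of the contig edge). A segment whose
    first residue is M and which either starts the frame or is preceded by a
    stop is complete. A stop-preceded segment without a leading M also yields
    ``incomplete_5prime``: no N-terminus can be fixed for it, so it carries no
    signal-peptide information. 3'-incompleteness (no bounding stop at the
    frame end) is reported by :func:`is_3prime_incomplete` and never overrides
    the 5' label in the ledger.
    """
    _check_pairing(orf, ft)
    if orf.length < too_small_aa:
        return "too_small"
    if orf.has_start_codon:
        return "complete"
    return "incomplete_5prime"


def is_3prime_incomplete(orf: Orf) -> bool:
    return not orf.followed_by_stop
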
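"""Ground-truthed miniature venom-gland dataset generator.

Every downstream stage of the pipeline is testable without external downloads
against data from this module: a small transcriptome with planted ORFs, a
planted secreted fraction bearing constructed signal peptides, homologs of a
reference venom set at controlled identity, annotation descriptions with and
without the venom/toxin keywords, tryptic-peptide observations sampled from
expressed proteins (plus contaminants), overdispersed read counts, and
dilution-series Ct values with known efficiencies and fold changes.

Signal peptides are planted *by construction* to satisfy the secretome
module's rule (positive n-region, >= 8-residue strongly hydrophobic h-region,
small residues at -3/-1); conversely, non-secreted proteins have their
N-terminal region re-drawn until the rule scores them negative. The rule and
the generator are intentionally coupled and evolve together -- truth labels
are definitions, not predictions.

Each generator stage seeds its own ``numpy`` Generator from ``(seed, stage)``,
so outputs are reproducible and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .peptide_mapping import DigestionParams, collapse_il, digest_protein
from .secretome import score_signal_peptide
from .translation import Contig, six_frame_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: standard-code codons per amino acid (for back-translation)
_CODONS: dict[str, list[str]] = {}


def _build_codons() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        _CODONS.setdefault(aa, []).append(codon)
    for aa in _CODONS:
        _CODONS[aa].sort()
    _CODONS["*"] = sorted(standard_dna_table.stop_codons)


_build_codons()

# background amino-acid composition is uniform (simplicity over realism);
# the hydrophilic-leaning alphabet is used when drawing non-secreted N-termini
_HYDROPHILIC = "DENQKRSTHGAP"

STRONG_HYDROPHOBIC = "LIVF"  # min Kyte-Doolittle 2.8: any 8-window passes 2.0
SMALL = "AGS"

VENOM_DESCRIPTIONS = (
    "venom protein U precursor",
    "venom allergen 5-like",
    "venom acid phosphatase",
    "kazal-type serine protease inhibition-like venom protein",
    "venom serine protease precursor",
    "plancitoxin-like deoxyribonuclease",
    "venom metalloprotease",
    "c1q-like venom protein",
    "venom carboxylesterase clade B",
    "agatoxin-like venom peptide",
)

NEUTRAL_DESCRIPTIONS = (
    "serine protease 33 isoform X2",
    "trypsin-like protease",
    "alpha-amylase-like",
    "cathepsin L",
    "pancreatic triacylglycerol lipase",
    "heat shock protein 70",
    "calreticulin precursor",
    "peptidyl-prolyl cis-trans isomerase 5",
    "ribosomal protein L3",
    "elongation factor 1-alpha",
    "actin-related protein 2/3 complex subunit",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "ferritin precursor",
    "vitellogenin",
    "serpin 5 precursor",
)

#: fraction of non-secreted, non-venom contigs given a keyword description
#: (emulates transcript-only venom annotations) and fraction left unannotated
KEYWORD_DECOY_FRACTION = 0.05
UNANNOTATED_FRACTION = 0.10

_STAGE = {
    "transcriptome": 1,
    "reference": 2,
    "peptides": 3,
    "counts": 4,
    "qpcr": 5,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_contigs: int = 300
    secreted_fraction: float = 0.2
    venom_fraction_of_secreted: float = 0.5
    homolog_identity_range: tuple[float, float] = (0.6, 0.9)
    peptide_sampling_depth: float = 10.0
    contaminant_peptide_rate: float = 0.05
    count_dispersion: float = 0.3
    qpcr_efficiency_range: tuple[float, float] = (0.85, 1.0)
    qpcr_noise_sd: float = 0.15
    n_decoy_refs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        for name in ("secreted_fraction", "venom_fraction_of_secreted",
                     "contaminant_peptide_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.homolog_identity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("homolog_identity_range must be ordered within [0, 1]")
        elo, ehi = self.qpcr_efficiency_range
        if not (0.0 < elo <= ehi <= 1.1):
            raise ConfigError("qpcr_efficiency_range must be ordered within (0, 1.1]")
        if self.peptide_sampling_depth < 0 or self.count_dispersion < 0:
            raise ConfigError("depth and dispersion must be non-negative")
        if self.qpcr_noise_sd < 0:
            raise ConfigError("qpcr_noise_sd must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])


# --- protein construction ------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _signal_peptide(rng: np.random.Generator) -> str:
    """n/h/c-region template randomized within the secretome rule's bounds."""
    n_len = rng.integers(3, 7)  # positive n-region
    n_region = list(rng.choice(list("NQST"), size=n_len))
    n_region[rng.integers(0, n_len)] = rng.choice(list("KR"))
    h_region = rng.choice(list(STRONG_HYDROPHOBIC), size=rng.integers(9, 13))
    c_region = [rng.choice(list(SMALL)), rng.choice(list("NQP")), rng.choice(list(SMALL))]
    sp = "M" + "".join(n_region) + "".join(h_region) + "".join(c_region)
    assert 15 <= len(sp) <= 35
    return sp


def _secreted_protein(rng: np.random.Generator, mature_len: int) -> str:
    return _signal_peptide(rng) + _random_protein(rng, mature_len)


def _nonsecreted_protein(rng: np.random.Generator, length: int) -> str:
    """M-initial protein whose N-terminus scores negative under the SP rule."""
    tail = _random_protein(rng, max(length - 40, 10))
    for _ in range(100):
        head = "M" + "".join(rng.choice(list(_HYDROPHILIC), size=39))
        protein = head + tail
        if not score_signal_peptide(protein).is_secreted:
            return protein
    raise RuntimeError("could not construct a negative N-terminus")  # pragma: no cover


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# --- synthetic ontology --------------------------------------------------------

_ONTOLOGY_SPEC = [
    # (id, name, parents)
    ("GO:0000001", "molecular_function", []),
    ("GO:0000002", "binding", ["GO:0000001"]),
    ("GO:0000003", "catalytic activity", ["GO:0000001"]),
    ("GO:0000004", "hydrolase activity", ["GO:0000003"]),
    ("GO:0000005", "transferase activity", ["GO:0000003"]),
    ("GO:0000006", "peptidase activity", ["GO:0000004"]),
    ("GO:0000007", "serine-type endopeptidase activity", ["GO:0000006"]),
    ("GO:0000008", "ion binding", ["GO:0000002"]),
    ("GO:0000009", "protein binding", ["GO:0000002"]),
    ("GO:0000010", "lipase activity", ["GO:0000004"]),
    ("GO:0000011", "oxidoreductase activity", ["GO:0000003"]),
    ("GO:0000012", "isomerase activity", ["GO:0000003"]),
]

#: leaf terms assigned to background contigs
_BACKGROUND_TERMS = (
    "GO:0000005", "GO:0000008", "GO:0000009", "GO:0000010",
    "GO:0000011", "GO:0000012", "GO:0000006",
)
#: term planted at elevated frequency in venom contigs
VENOM_TERM = "GO:0000007"


def synthetic_ontology() -> nx.DiGraph:
    """A 12-term is_a DAG (child -> parent edges) mirroring GO structure."""
    g = nx.DiGraph()
    for tid, name, parents in _ONTOLOGY_SPEC:
        g.add_node(tid, name=name, namespace="molecular_function")
        for p in parents:
            g.add_edge(tid, p)
    return g


def ontology_to_obo(g: nx.DiGraph) -> str:
    """Serialize the is_a DAG as a minimal OBO document."""
    lines = ["format-version: 1.2", ""]
    for tid in sorted(g.nodes):
        lines += [
            "[Term]",
            f"id: {tid}",
            f"name: {g.nodes[tid].get('name', tid)}",
        ]
        ns = g.nodes[tid].get("namespace")
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(g.successors(tid)):
            lines.append(f"is_a: {parent} ! {g.nodes[parent].get('name', parent)}")
        lines.append("")
    return "\n".join(lines)


# --- generators ----------------------------------------------------------------


def generate_transcriptome(
    config: GeneratorConfig,
) -> tuple[list[Contig], pd.DataFrame, pd.DataFrame]:
    """Contigs with planted ORFs, an annotation table, and the truth table.

    Exactly ``round(secreted_fraction * n_contigs)`` contigs carry a
    constructed signal peptide, and ``round(venom_fraction_of_secreted *
    n_secreted)`` of those are venom proteins (each later receives a homolog
    in the reference set). Planted ORFs are flanked by in-frame stops, so the
    translated segment recovers the planted protein exactly.
    """
    rng = config.rng("transcriptome")
    n = config.n_contigs
    n_sec = round(config.secreted_fraction * n)
    order = rng.permutation(n)
    secreted_idx = set(order[:n_sec].tolist())
    sec_order = [i for i in order if i in secreted_idx]
    n_venom = round(config.venom_fraction_of_secreted * n_sec)
    venom_idx = set(sec_order[:n_venom])
    nonsec = [i for i in range(n) if i not in secreted_idx]
    n_kw_decoy = round(KEYWORD_DECOY_FRACTION * len(nonsec))
    kw_decoy_idx = set(rng.permutation(nonsec)[:n_kw_decoy].tolist()) if nonsec else set()

    contigs: list[Contig] = []
    truth_rows = []
    annot_rows = []
    width = len(str(n))
    for i in range(n):
        cid = f"c{i + 1:0{width}d}"
        is_sec = i in secreted_idx
        is_venom = i in venom_idx
        mature_len = int(rng.integers(80, 200))
        if is_sec:
            protein = _secreted_protein(rng, mature_len)
        else:
            protein = _nonsecreted_protein(rng, mature_len)

        utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
        orf_nt = _back_translate(rng, protein)
        stop = str(rng.choice(_CODONS["*"]))
        stop2 = str(rng.choice(_CODONS["*"]))
        fwd = utr5 + stop + orf_nt + stop2 + utr3
        orf_start = len(utr5) + 3
        orf_end = orf_start + len(orf_nt)

        strand = "+" if rng.random() < 0.5 else "-"
        # frame offset is defined on the reading strand: for '-' contigs the
        # reading strand (reverse complement of the stored sequence) is `fwd`
        frame = f"{strand}{orf_start % 3 + 1}"
        if strand == "+":
            seq = fwd
            start, end = orf_start, orf_end
        else:
            seq = _revcomp(fwd)
            start, end = len(fwd) - orf_end, len(fwd) - orf_start
        contigs.append(Contig(cid, seq))

        keyword = is_venom or (i in kw_decoy_idx)
        if keyword:
            desc = str(rng.choice(VENOM_DESCRIPTIONS))
        elif rng.random() < UNANNOTATED_FRACTION:
            desc = ""
        else:
            desc = str(rng.choice(NEUTRAL_DESCRIPTIONS))

        if desc == "":
            terms: list[str] = []
        else:
            terms = [str(t) for t in rng.choice(_BACKGROUND_TERMS, size=2, replace=False)]
            if is_venom and rng.random() < 0.8:
                terms[0] = VENOM_TERM

        identity = (
            float(rng.uniform(*config.homolog_identity_range)) if is_venom else np.nan
        )
        truth_rows.append(
            {
                "contig_id": cid,
                "orf_start": start,
                "orf_end": end,
                "strand": strand,
                "frame": frame,
                "is_secreted": is_sec,
                "is_venom": is_venom,
                "homolog_identity": identity,
                "expression_level": float(rng.lognormal(np.log(200.0), 1.0)),
                "keyword_planted": keyword,
                "qpcr_fold_change": float(2 ** rng.uniform(1, 5)) if is_venom else 1.0,
                "protein_seq": protein,
            }
        )
        annot_rows.append(
            {"contig_id": cid, "description": desc, "go_terms": "|".join(sorted(terms))}
        )

    truth = pd.DataFrame(truth_rows)
    annotations = pd.DataFrame(annot_rows)
    return contigs, annotations, truth


def generate_reference_venom_db(
    truth: pd.DataFrame, config: GeneratorConfig
) -> list[tuple[str, str]]:
    """One reference entry per planted venom protein, mutated to the sampled
    identity by point substitution, plus unrelated decoy entries."""
    rng = config.rng("reference")
    refs: list[tuple[str, str]] = []
    for _, row in truth[truth["is_venom"]].iterrows():
        protein = row["protein_seq"]
        identity = float(row["homolog_identity"])
        k = round((1.0 - identity) * len(protein))
        positions = rng.choice(len(protein), size=k, replace=False)
        mutated = list(protein)
        for p in positions:
            choices = [aa for aa in AA20 if aa != mutated[p]]
            mutated[p] = str(rng.choice(choices))
        refs.append((f"ref_{row['contig_id']}", "".join(mutated)))
    for d in range(config.n_decoy_refs):
        refs.append((f"decoy_{d + 1}", _random_protein(rng, int(rng.integers(100, 200)))))
    return refs


def sample_peptides(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    contigs: Sequence[Contig] | None = None,
    params: DigestionParams = DigestionParams(),
) -> pd.DataFrame:
    """Observed peptide list sampled from tryptic digests of expressed proteins.

    Each protein contributes ``Poisson(depth * e)`` draws (with replacement)
    from its digest, where ``e`` is its expression level divided by the median
    level, so detection probability rises with expression. Contaminant
    peptides are random sequences verified (I/L-collapsed) not to occur in any
    six-frame translation of the contigs. Columns: ``peptide, source``
    (contig id, or ``contaminant``); the pipeline consumes only ``peptide``.
    """
    rng = config.rng("peptides")
    levels = truth["expression_level"].to_numpy(dtype=float)
    median = float(np.median(levels[levels > 0])) if (levels > 0).any() else 1.0

    rows = []
    for _, row in truth.iterrows():
        expr = float(row["expression_level"])
        if expr <= 0:
            continue
        peptides = digest_protein(row["protein_seq"], params)
        if not peptides:
            continue
        k = int(rng.poisson(config.peptide_sampling_depth * expr / median))
        for pick in rng.integers(0, len(peptides), size=k):
            rows.append({"peptide": peptides[int(pick)], "source": row["contig_id"]})

    rate = config.contaminant_peptide_rate
    if rate > 0 and rows:
        if contigs is not None:
            corpus = "#".join(
                collapse_il(ft.aa_seq)
                for c in contigs
                for ft in six_frame_translate(c)
            )
        else:
            corpus = "#".join(collapse_il(p) for p in truth["protein_seq"])
        n_cont = round(rate * len(rows) / (1.0 - rate))
        made = 0
        while made < n_cont:
            pep = _random_protein(rng, int(rng.integers(8, 21)))
            if collapse_il(pep) in corpus:
                continue
            rows.append({"peptide": pep, "source": "contaminant"})
            made += 1

    return pd.DataFrame(rows, columns=["peptide", "source"])


def simulate_counts(
    truth: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, int]:
    """Per-contig uniquely-mapped read counts and the library total.

    Counts follow a negative-binomial noise model with mean equal to the
    planted expression level and variance ``mu + d * mu**2`` (dispersion
    ``d = count_dispersion``); ``d = 0`` degenerates to the rounded mean.
    """
    rng = config.rng("counts")
    d = config.count_dispersion
    counts = []
    for mu in truth["expression_level"].to_numpy(dtype=float):
        if mu <= 0:
            counts.append(0)
        elif d == 0:
            counts.append(int(round(mu)))
        else:
            size = 1.0 / d
            counts.append(int(rng.negative_binomial(size, size / (size + mu))))
    df = pd.DataFrame({"contig_id": truth["contig_id"], "count": counts})
    return df, int(df["count"].sum())


REFERENCE_GENES = ("GAPDH", "beta_tubulin")
QPCR_DILUTIONS = (1.0, 0.1, 0.01)
N_BIO_REPS = 3
N_TECH_REPS = 3


def simulate_qpcr(
    truth: pd.DataFrame, config: GeneratorConfig, n_targets: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table for target genes plus two reference genes, two tissue groups.

    Ct = intercept + S log10(dilution) + noise with ``S = -1/log10(1 + E)``;
    in the venom-gland group a target with fold change F is shifted by
    ``-log(F)/log(1 + E)`` cycles. Reference genes have fold change 1.
    Returns the long-form Ct table and a gene-truth table (E, fold change).
    """
    rng = config.rng("qpcr")
    venom = truth[truth["is_venom"]].sort_values(
        "expression_level", ascending=False, kind="mergesort"
    )
    targets = list(venom["contig_id"].head(n_targets))
    folds = dict(zip(venom["contig_id"], venom["qpcr_fold_change"]))

    genes = targets + list(REFERENCE_GENES)
    gene_rows = []
    ct_rows = []
    for gene in genes:
        E = float(rng.uniform(*config.qpcr_efficiency_range))
        fold = float(folds.get(gene, 1.0))
        S = -1.0 / np.log10(1.0 + E)
        intercept = float(rng.uniform(18.0, 24.0))
        gene_rows.append({"gene": gene, "efficiency": E, "fold_change": fold})
        for group in ("body", "venom_gland"):
            shift = -np.log(fold) / np.log(1.0 + E) if group == "venom_gland" else 0.0
            for bio in range(1, N_BIO_REPS + 1):
                for dil in QPCR_DILUTIONS:
                    base = intercept + S * np.log10(dil) + shift
                    for tech in range(1, N_TECH_REPS + 1):
                        ct_rows.append(
                            {
                                "gene": gene,
                                "group": group,
                                "dilution": dil,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "ct": float(
                                    base + rng.normal(0.0, config.qpcr_noise_sd)
                                ),
                            }
                        )
    return (
        pd.DataFrame(ct_rows, columns=["gene", "group", "dilution", "bio_rep", "tech_rep", "ct"]),
        pd.DataFrame(gene_rows, columns=["gene", "efficiency", "fold_change"]),
    )


def write_outputs(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all generators and write the plain-text dataset to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, annotations, truth = generate_transcriptome(config)
    refs = generate_reference_venom_db(truth, config)
    peptides = sample_peptides(truth, config, contigs=contigs)
    counts, _ = simulate_counts(truth, config)
    qpcr, qpcr_truth = simulate_qpcr(truth, config)

    paths = {
        "contigs": outdir / "contigs.fasta",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "reference": outdir / "reference_venom.fasta",
        "peptides": outdir / "peptides.tsv",
        "counts": outdir / "counts.tsv",
        "qpcr": outdir / "qpcr.csv",
        "qpcr_truth": outdir / "qpcr_truth.csv",
        "ontology": outdir / "ontology.obo",
    }
    io.write_fasta([(c.id, c.seq) for c in contigs], paths["contigs"])
    io.write_table(annotations, paths["annotations"])
    io.write_table(truth, paths["truth"])
    io.write_fasta(refs, paths["reference"])
    io.write_table(peptides, paths["peptides"])
    io.write_table(counts, paths["counts"])
    io.write_table(qpcr, paths["qpcr"], sep=",")
    io.write_table(qpcr_truth, paths["qpcr_truth"], sep=",")
    paths["ontology"].write_text(ontology_to_obo(synthetic_ontology()))
    return paths
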
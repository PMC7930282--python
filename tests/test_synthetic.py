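"""Ground-truth contracts of the synthetic dataset generator."""

import numpy as np
import pandas as pd
import pytest

from venomscan import (
    Contig,
    GeneratorConfig,
    generate_reference_venom_db,
    generate_transcriptome,
    sample_peptides,
    simulate_counts,
    simulate_qpcr,
    six_frame_translate,
)
from venomscan.io import fasta_bytes
from venomscan.peptide_mapping import DigestionParams, collapse_il, digest_protein
from venomscan.synthetic import ConfigError


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(n_contigs=0)
    with pytest.raises(ConfigError):
        GeneratorConfig(secreted_fraction=1.5)
    with pytest.raises(ConfigError):
        GeneratorConfig(homolog_identity_range=(0.9, 0.6))
    with pytest.raises(ConfigError):
        GeneratorConfig(qpcr_efficiency_range=(0.0, 1.0))


def test_counts_contract():
    config = GeneratorConfig(n_contigs=300, seed=7)
    contigs, annotations, truth = generate_transcriptome(config)
    assert len(contigs) == 300 and len(truth) == 300 and len(annotations) == 300
    assert int(truth["is_secreted"].sum()) == round(0.2 * 300) == 60


def test_determinism_byte_identical():
    config = GeneratorConfig(n_contigs=50, seed=7)
    a = generate_transcriptome(config)
    b = generate_transcriptome(config)
    assert fasta_bytes([(c.id, c.seq) for c in a[0]]) == fasta_bytes(
        [(c.id, c.seq) for c in b[0]]
    )
    pd.testing.assert_frame_equal(a[2], b[2])
    assert generate_reference_venom_db(a[2], config) == generate_reference_venom_db(
        b[2], config
    )
    pd.testing.assert_frame_equal(
        sample_peptides(a[2], config), sample_peptides(b[2], config)
    )
    ca, na = simulate_counts(a[2], config)
    cb, nb = simulate_counts(b[2], config)
    pd.testing.assert_frame_equal(ca, cb)
    assert na == nb
    qa, ga = simulate_qpcr(a[2], config)
    qb, gb = simulate_qpcr(b[2], config)
    pd.testing.assert_frame_equal(qa, qb)
    pd.testing.assert_frame_equal(ga, gb)


def test_truth_table_invariants(dataset):
    contigs, annotations, truth = dataset
    lengths = {c.id: len(c.seq) for c in contigs}
    # every venom contig is secreted; identity defined iff venom
    assert (truth.loc[truth["is_venom"], "is_secreted"]).all()
    assert truth["homolog_identity"].notna().equals(truth["is_venom"])
    for _, row in truth.iterrows():
        span = row["orf_end"] - row["orf_start"]
        assert span % 3 == 0 and span > 0
        assert 0 <= row["orf_start"] < row["orf_end"] <= lengths[row["contig_id"]]
    # keyword-planted contigs carry the keyword in their description
    desc = dict(zip(annotations["contig_id"], annotations["description"]))
    for _, row in truth.iterrows():
        d = (desc[row["contig_id"]] or "").lower()
        if row["keyword_planted"]:
            assert "venom" in d or "toxin" in d


def test_planted_orf_translates_to_planted_protein(dataset):
    contigs, _, truth = dataset
    by_id = {c.id: c for c in contigs}
    for _, row in truth.head(40).iterrows():
        contig = by_id[row["contig_id"]]
        frames = {f.frame: f for f in six_frame_translate(contig)}
        ft = frames[row["frame"]]
        protein = row["protein_seq"]
        assert protein in ft.aa_seq
        # flanked by stops on both sides (complete ORF by construction)
        idx = ft.aa_seq.index(protein)
        assert ft.aa_seq[idx - 1] == "*" if idx > 0 else True
        assert ft.aa_seq[idx + len(protein)] == "*"


def test_reference_identity_controlled(dataset, default_config):
    """Alignment-measured identity of planted homolog pairs stays in range."""
    from venomscan import smith_waterman

    _, _, truth = dataset
    refs = dict(generate_reference_venom_db(truth, default_config))
    lo, hi = default_config.homolog_identity_range
    for _, row in truth[truth["is_venom"]].head(15).iterrows():
        ref = refs[f"ref_{row['contig_id']}"]
        _, aln = smith_waterman(row["protein_seq"], ref)
        identity = aln.n_identical / len(row["protein_seq"])
        assert identity == pytest.approx(row["homolog_identity"], abs=0.05)


def test_venom_fraction_zero_gives_only_decoys():
    config = GeneratorConfig(
        n_contigs=30, venom_fraction_of_secreted=0.0, n_decoy_refs=3, seed=1
    )
    _, _, truth = generate_transcriptome(config)
    refs = generate_reference_venom_db(truth, config)
    assert [r[0] for r in refs] == ["decoy_1", "decoy_2", "decoy_3"]


def test_peptide_sampling_contracts():
    config = GeneratorConfig(n_contigs=40, peptide_sampling_depth=0.0, seed=3)
    _, _, truth = generate_transcriptome(config)
    assert sample_peptides(truth, config).empty

    config = GeneratorConfig(n_contigs=40, contaminant_peptide_rate=0.0, seed=3)
    _, _, truth = generate_transcriptome(config)
    peptides = sample_peptides(truth, config)
    assert (peptides["source"] != "contaminant").all()
    digests = {
        row["contig_id"]: set(digest_protein(row["protein_seq"], DigestionParams()))
        for _, row in truth.iterrows()
    }
    for _, row in peptides.iterrows():
        assert row["peptide"] in digests[row["source"]]


def test_contaminants_match_no_contig():
    config = GeneratorConfig(n_contigs=40, contaminant_peptide_rate=0.2, seed=5)
    contigs, _, truth = generate_transcriptome(config)
    peptides = sample_peptides(truth, config, contigs=contigs)
    contaminants = peptides[peptides["source"] == "contaminant"]
    assert len(contaminants) > 0
    corpus = "#".join(
        collapse_il(ft.aa_seq) for c in contigs for ft in six_frame_translate(c)
    )
    for pep in contaminants["peptide"]:
        assert collapse_il(pep) not in corpus


def test_deep_sampling_covers_secreted_proteins():
    config = GeneratorConfig(n_contigs=100, peptide_sampling_depth=20.0, seed=1)
    _, _, truth = generate_transcriptome(config)
    peptides = sample_peptides(truth, config)
    sources = set(peptides["source"])
    secreted = truth.loc[truth["is_secreted"], "contig_id"]
    covered = sum(1 for cid in secreted if cid in sources)
    assert covered / len(secreted) >= 0.95


def test_count_simulation_contracts():
    config = GeneratorConfig(n_contigs=40, count_dispersion=0.0, seed=2)
    _, _, truth = generate_transcriptome(config)
    counts, total = simulate_counts(truth, config)
    assert np.array_equal(
        counts["count"].to_numpy(),
        np.round(truth["expression_level"]).astype(int),
    )
    assert total == int(counts["count"].sum())

    zero = truth.copy()
    zero["expression_level"] = 0.0
    counts0, total0 = simulate_counts(zero, config)
    assert total0 == 0 and (counts0["count"] == 0).all()


def test_qpcr_series_has_exact_spacing_at_e1_no_noise():
    config = GeneratorConfig(
        n_contigs=40, qpcr_noise_sd=0.0, qpcr_efficiency_range=(1.0, 1.0), seed=4
    )
    _, _, truth = generate_transcriptome(config)
    table, gene_truth = simulate_qpcr(truth, config)
    assert (gene_truth["efficiency"] == 1.0).all()
    one = table[
        (table["gene"] == gene_truth["gene"].iloc[0])
        & (table["group"] == "body")
        & (table["bio_rep"] == 1)
        & (table["tech_rep"] == 1)
    ].set_index("dilution")["ct"]
    spacing = one[0.1] - one[1.0]
    assert spacing == pytest.approx(1 / np.log10(2), abs=1e-9)  # 3.3219
    # reference genes present with fold change 1
    ref_rows = gene_truth[gene_truth["gene"].isin(["GAPDH", "beta_tubulin"])]
    assert (ref_rows["fold_change"] == 1.0).all()
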
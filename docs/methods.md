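# Methods

## Scope and model

`venomscan` operationalizes the integrated proteo-transcriptomic strategy for
characterizing the venom of parasitoid wasps. The unit of transcriptomic
identity is the contig; the unit of proteomic evidence is an observed peptide
sequence. The pipeline's input boundary is deliberately downstream of raw
data: assembly (contigs), annotation (descriptions + GO ids) and spectral
search (the peptide list) are inputs, not steps. Everything from six-frame
translation onward is computed by the package.

### Six-frame database

Whole frame translations — stops included — form the protein database, six
per contig (three forward offsets, three on the reverse complement), because
peptide evidence is matched against translated frames, not curated gene
models. ORFs (maximal stop-free segments) are a separate view used for
5′-completeness classification and as secretome input. Codons containing
ambiguity characters translate to `X`, which never matches a peptide residue
and scores 0 in alignments. Coordinates are 0-based half-open; frame `-k` is
defined on the reverse complement at offset `k−1`. An ORF shorter than
30 residues (`too_small_aa`) is classed `too_small`: it is shorter than the
window a signal-peptide call needs. A maximal segment without a leading
methionine has no fixable N-terminus and is classed `incomplete_5prime`;
3′-incompleteness is reported alongside and never overrides the 5′ label.

### Peptide mapping

Peptides are matched as exact substrings (optionally identifying I and L,
default on — the residues are isobaric and indistinguishable to standard
MS/MS). Mass tolerances belong to the out-of-scope spectral search; a
peptide list is already mass-resolved. Matching uses one concatenated,
separator-delimited corpus per database and C-level substring search, which
keeps full-database scans linear in practice. Candidates need ≥ 1 distinct
peptide per (contig, frame) by default (`min_peptides`); no fully-tryptic
requirement is imposed by default. Multi-frame identifications of one contig
are resolved to the frame with the most distinct peptides (ties: longer
linked ORF, then frame name).

### Secretome rule

The signal-peptide caller is a transparent rule, not a trained model: a
cleavage site p ∈ [15, 35] with small residues (A/G/S/C/T/V) at −3/−1, an
8-residue window within positions 1..p of mean Kyte–Doolittle hydropathy
≥ 2.0, and non-negative net charge (K/R +1, D/E −1) before that window.
Among valid combinations the highest-hydropathy window wins; ties go to the
smallest p. Sequences shorter than 18 residues and candidates whose ORF is
5′-incomplete get a *no-call* (reason `too_short` / `incomplete_5prime`)
rather than a negative: with the N-terminus missing, secretion is
undecidable, and the ledger books such contigs separately. Output of a real
predictor can be imported from a TSV and overrides the rule, flagged with
external provenance.

### Homology

At desk scale, exact Smith–Waterman replaces seeded heuristics: BLOSUM62
with the X row/column zeroed, affine gaps costing 11 + (L−1). The alignment
engine is Biopython's `PairwiseAligner` (exact affine-gap DP); tests check
it against an independent brute-force enumeration of aligned-pair chains.
No E-values are computed (they are database-size dependent); matches are
filtered on raw score ≥ 50, percent identity ≥ 35 over aligned columns, and
query coverage ≥ 0.5 — conventional values for confirming homology of
~100-residue proteins. Catalytic-triad detection aligns a query globally
(free end gaps) to an annotated canonical trypsin and reads the residues
mapped to the annotated columns (defaults H70, D125/130, S240/245); a member
is `canonical` if the expected residue appears at any allowed column,
`substituted:<residue>` otherwise, `undetermined` if gaps cover all allowed
columns.

### Keyword mining

Case-insensitive substring matching ("venom", "toxin" by default) is
deliberate: genuine annotations include compounds like "plancitoxin". The
accepted risk of substring false positives (e.g. "antivenom") is surfaced by
per-keyword hit reports. The keyword-only set is the keyword hits minus the
proteomically identified venom contigs.

### Quantification

RPKM(A) = 10⁶ · C · 10³ / (N · L) with C the uniquely aligned reads of A,
L its length in bases, N the library total. Two identities are enforced by
tests: scale invariance in C, and Σ RPKM·L = 10⁹ whenever N = ΣC.
Efficiency comes from the least-squares slope S of Ct on log₁₀(dilution):
E = 10^(−1/S) − 1 (perfect doubling gives S = −3.3219). Relative expression
uses the efficiency-corrected Pfaffl form, which reduces to 2^(−ΔΔCt) at
E = 1; with two reference genes (GAPDH, beta-tubulin) the normalization
factors are combined by geometric mean — the standard multi-reference rule.
Group comparison is the classical equal-variance unpaired t-test
(SEM = sd/√n); Welch is available behind a flag.

### Enrichment

Annotations are closed under the true-path rule on the is_a DAG before
counting. Over-representation is a one-sided Fisher's exact test on the
(test-with, test-without, rest-with, rest-without) table — the test set must
be a subset of the reference set — adjusted by Benjamini–Hochberg, with
α = 0.05. Enriched terms that are proper ancestors of other enriched terms
are dropped ("most specific" reduction; the output is an antichain).
Enrichment counts contigs, not proteins. Only `is_a` edges are interpreted;
`part_of`/`regulates` semantics and GO-slim mapping are out of scope.

### Ledger

The stage counts satisfy six additivity identities (see README). They are
*checked, not assumed*: `build_ledger` recomputes derived counts and raises
naming the first violated identity. "Venom trace elements" are defined
operationally as secretory, proteomically identified proteins with
annotation but no venom similarity; "unannotated" as secretory unmatched
proteins without any annotation. Functional categories are assigned by a
first-matching-rule pattern table seeded from the standard venom protein
families (hydrolase subfamilies, protease inhibitors, immune-related,
recognition/binding, etc.), defaulting to "Unknown and hypothetical
proteins" — categorization mimics expert annotation and is meant to be
edited, not learned.

## Synthetic data: what it emulates, and what it does not

The generator produces a miniature venom-gland study: each contig carries one
planted ORF (protein 80–200 residues plus any signal peptide) flanked by
in-frame stops, with 5′/3′ UTRs of 6–60 nt, on a random strand. Default
conditions: 300 contigs, 20 % secreted, half of the secreted planted as venom
proteins with reference homologs at 60–90 % identity (point substitutions
only), peptide sampling depth 10, 5 % contaminant peptides, count dispersion
0.3, qPCR efficiencies 0.85–1.0 with Ct noise sd 0.15. Expression levels are
log-normal (median 200 reads, σ = 1) — a realistic dynamic range for a
gland library at this scale. Counts are negative-binomial with mean equal to
the planted level and variance μ + d·μ² (d = 0 degenerates to the rounded
mean). Peptide observations are draws from the protein's tryptic digest with
Poisson counts proportional to relative expression; contaminants are random
peptides verified (I/L-collapsed) absent from all six-frame translations.
qPCR tables follow Ct = intercept + S·log₁₀(dilution) + noise over three
tenfold dilutions, three technical × three biological replicates, with the
venom-gland group shifted by −log(F)/log(1+E) for planted fold change F;
reference genes have F = 1.

Two couplings are deliberate and documented:

* **Signal peptides are planted to satisfy the secretome rule** (n-region
  from polar residues with ≥ 1 K/R; h-region of 9–12 residues from
  {L,I,V,F}, whose every 8-window has mean hydropathy ≥ 2.8; c-region with
  small residues at −3/−1). Conversely, non-secreted N-termini are re-drawn
  from a hydrophilic-biased alphabet until the rule scores them negative.
  Truth labels are therefore definitions: tests of the secretome stage
  measure the pipeline's bookkeeping, not the rule's biological accuracy on
  real sequences, which would require a trained predictor as reference.
* **Keyword decoys** (5 % of non-secreted contigs get venom-flavored
  descriptions) live only in the non-secreted pool, so the synthetic
  keyword-only set emulates transcript-only evidence without inflating the
  proteomic false-discovery proportion.

Not emulated: raw reads or spectra, codon-usage bias, sequence-level
homology structure beyond point substitution (no indels in homologs),
chimeric/fragmented assembly, and protein-level abundance bias in MS
detection beyond the expression coupling.

Every generator stage seeds `numpy.random.default_rng([seed, stage_id])`, so
outputs are byte-identical across calls and independent of call order.

## Numerical and design choices

* Digit convention: a gap of length L scores −(11 + (L−1)); identity is
  computed over aligned (both-residue) columns; query coverage over the
  query span of the local alignment.
* The alignment traceback returns one optimal alignment chosen
  deterministically by the DP engine; downstream logic depends only on its
  score, identity, coverage and column mapping, not on which co-optimal
  path is reported.
* `estimate_efficiency` warns (not errors) on S ≥ 0: the series is
  uninterpretable but the caller may want to inspect it.
* Ties in expression ranking break lexicographically by contig id, making
  reports byte-stable.
* Degenerate inputs: N = 0 or L = 0 is an error for RPKM; an all-zero count
  vector is flagged by the generator rather than silently producing NaNs;
  empty peptide strings are skipped with a warning; an empty reference set
  warns and leaves all queries unmatched.
* Problem sizes in the test-suite and acceptance runs (300 contigs,
  10 seeds; brute-force alignment oracle at length ≤ 8 over a 4-letter
  alphabet; Fisher enumeration at margins ≤ 12) are the package's chosen
  desk-scale study conditions: large enough for stable recovery statistics,
  small enough that the exhaustive oracles stay exact.

## Known limitations

* The secretome rule is a transparent approximation of trained predictors;
  on real proteomes its error rate is unknown and the external-import path
  is the recommended route for publication-grade secretome calls.
* Exact substring peptide matching cannot place peptides across frame
  boundaries of mis-assembled contigs, and modified residues are matched by
  their plain letters.
* The homology stage has no E-value calibration; thresholds are fixed, not
  database-size aware.
* The generator's homologs differ by substitutions only, so coverage is
  always ≈ 1 for planted pairs; indel robustness of the search thresholds is
  untested by construction.
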
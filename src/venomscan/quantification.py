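"""Expression quantification: RPKM from read counts, efficiency-corrected
relative expression from qPCR dilution series.

RPKM for a contig with C uniquely aligned reads, length L bases, in a library
of N uniquely aligned reads is ``10^9 * C / (N * L)`` (reads per kilobase of
transcript per million mapped reads); rankings report the log2-transformed
value. qPCR amplification efficiency comes from the dilution-series slope S
(Ct regressed on log10 dilution) via ``E = 10^(-1/S) - 1``, and relative
expression uses the efficiency-corrected (Pfaffl-form) ratio

    ratio = (1+E_t)^(dCt_t) / geomean_r (1+E_r)^(dCt_r),   dCt = Ct_cal - Ct_test,

which reduces to the classical 2^(-ddCt) when all efficiencies are 1. With
two reference genes the per-gene normalization factors are combined by
geometric mean. Groups are compared with the classical unpaired
equal-variance t-test (Welch available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionRecord:
    contig_id: str
    C: int  # uniquely aligned reads
    L: int  # contig length, bases
    N: int  # library total of uniquely aligned reads
    rpkm: float
    log2_rpkm: float | None  # None when C == 0


def compute_rpkm(C: int, N: int, L: int) -> float:
    """``1,000,000 * C * 1000 / (N * L)``."""
    if N <= 0:
        raise QuantificationError("library total N must be > 0")
    if L <= 0:
        raise QuantificationError("contig length L must be > 0")
    if C < 0:
        raise QuantificationError("read count C must be >= 0")
    return 1e9 * C / (N * L)


def expression_table(
    counts: Mapping[str, int], lengths: Mapping[str, int], N: int | None = None
) -> pd.DataFrame:
    """Per-contig RPKM table (contig_id, C, L, rpkm, log2_rpkm).

    ``N`` defaults to the sum of the counts (every uniquely aligned read in
    the library maps to some contig).
    """
    ids = sorted(counts)
    if N is None:
        N = int(sum(counts.values()))
    rows = []
    for cid in ids:
        C = int(counts[cid])
        rpkm = compute_rpkm(C, N, int(lengths[cid]))
        rows.append(
            {
                "contig_id": cid,
                "C": C,
                "L": int(lengths[cid]),
                "rpkm": rpkm,
                "log2_rpkm": np.log2(rpkm) if rpkm > 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=["contig_id", "C", "L", "rpkm", "log2_rpkm"])
    df.attrs["N"] = N
    return df


def rank_by_expression(
    records: pd.DataFrame, annotations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Descending RPKM order, ties broken by contig id; optional descriptions."""
    df = records.sort_values(
        ["rpkm", "contig_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if annotations is not None:
        df = df.copy()
        df.insert(1, "description", [annotations.get(c, "") for c in df["contig_id"]])
    return df


def estimate_efficiency(
    ct_by_log10_dilution: Mapping[float, Sequence[float] | float],
) -> tuple[float, float]:
    """Least-squares slope S of Ct on log10(dilution) and E = 10^(-1/S) - 1."""
    xs, ys = [], []
    for x, cts in ct_by_log10_dilution.items():
        vals = np.atleast_1d(np.asarray(cts, dtype=float))
        xs.extend([float(x)] * len(vals))
        ys.extend(vals.tolist())
    if len(set(xs)) < 2:
        raise QuantificationError("need Ct values at >= 2 distinct dilutions")
    S = float(stats.linregress(xs, ys).slope)
    if S >= 0:
        warnings.warn(
            f"non-negative dilution slope S={S:.3g}: efficiency uninterpretable",
            stacklevel=2,
        )
    E = 10 ** (-1.0 / S) - 1.0
    return S, E


def relative_expression(
    ct_target_test: float,
    ct_target_cal: float,
    ct_ref_test: Sequence[float],
    ct_ref_cal: Sequence[float],
    E_target: float,
    E_refs: Sequence[float],
) -> float:
    """Efficiency-corrected expression ratio of the test sample vs calibrator."""
    effs = [E_target, *E_refs]
    if any(e <= 0 or e > 1.1 for e in effs):
        raise QuantificationError("efficiencies must lie in (0, 1.1]")
    if len(ct_ref_test) != len(ct_ref_cal) or len(ct_ref_test) != len(E_refs):
        raise QuantificationError("reference Ct/E lists must have equal length")
    num = (1.0 + E_target) ** (ct_target_cal - ct_target_test)
    ref_factors = [
        (1.0 + e) ** (cal - test)
        for e, test, cal in zip(E_refs, ct_ref_test, ct_ref_cal)
    ]
    denom = float(np.exp(np.mean(np.log(ref_factors))))
    return num / denom


def compare_groups(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> dict[str, float]:
    """Unpaired t-test between two replicate groups, with mean +/- SEM."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise QuantificationError("need >= 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(a.mean()),
        "sem_a": float(stats.sem(a)),
        "mean_b": float(b.mean()),
        "sem_b": float(stats.sem(b)),
    }


def analyze_qpcr(
    table: pd.DataFrame,
    reference_genes: Sequence[str],
    calibrator_group: str,
    test_group: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Full qPCR workflow on a long-form Ct table.

    Expected columns: ``gene, group, dilution, bio_rep, ct`` (technical
    replicates are extra rows and are averaged). Per gene, the amplification
    efficiency is fitted on the calibrator-group dilution series; relative
    expression is computed at dilution 1 per biological replicate with the
    reference-gene geometric-mean normalization, calibrated to the mean of the
    calibrator group; groups are compared by unpaired t-test on the ratios.
    """
    required = {"gene", "group", "dilution", "bio_rep", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise QuantificationError(f"qPCR table lacks columns {sorted(missing)}")

    genes = sorted(table["gene"].unique())
    refs = [g for g in reference_genes if g in genes]
    if not refs:
        raise QuantificationError("no reference gene present in the table")
    targets = [g for g in genes if g not in refs]

    eff: dict[str, float] = {}
    for gene, sub in table[table["group"] == calibrator_group].groupby("gene"):
        series = {
            float(np.log10(d)): grp["ct"].to_numpy()
            for d, grp in sub.groupby("dilution")
        }
        eff[gene] = estimate_efficiency(series)[1]

    # mean Ct over technical replicates at the working dilution
    work = table[table["dilution"] == 1.0]
    mean_ct = (
        work.groupby(["gene", "group", "bio_rep"])["ct"].mean().unstack("bio_rep")
    )

    def quantity(gene: str, group: str, rep) -> float:
        ct_t = mean_ct.loc[(gene, group), rep]
        ref_factors = [
            (1.0 + eff[r]) ** (-mean_ct.loc[(r, group), rep]) for r in refs
        ]
        return (1.0 + eff[gene]) ** (-ct_t) / float(
            np.exp(np.mean(np.log(ref_factors)))
        )

    reps = list(mean_ct.columns)
    rows = []
    for gene in targets:
        q_cal = [quantity(gene, calibrator_group, r) for r in reps]
        q_test = [quantity(gene, test_group, r) for r in reps]
        calibrator = float(np.mean(q_cal))
        ratios_test = [q / calibrator for q in q_test]
        ratios_cal = [q / calibrator for q in q_cal]
        cmp = compare_groups(ratios_test, ratios_cal, welch=welch)
        rows.append(
            {
                "gene": gene,
                "efficiency": eff[gene],
                "ratio_mean": cmp["mean_a"],
                "ratio_sem": cmp["sem_a"],
                "calibrator_mean": cmp["mean_b"],
                "calibrator_sem": cmp["sem_b"],
                "t": cmp["t"],
                "p": cmp["p"],
            }
        )
    return pd.DataFrame(rows)
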
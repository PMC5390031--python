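"""qPCR and RA-PCR expression analytics.

Implements the standard relative-quantification chain: multi-reference
normalization by the geometric mean of reference relative quantities,
2^-ddCt fold changes against a calibrator, regional-amplification
(RA-PCR) cleavage inference from 5'/middle/3' amplicon abundances, and
miRNA-target anticorrelation across developmental stages.

RA-PCR background: reverse transcription of a miRNA-cleaved mRNA cannot
proceed past the cleavage site, so amplicons spanning or upstream of the
site are depleted relative to the 3' amplicon. The reduction statistic
is (1 - q_mid/q_3')*100 and a transcript is called cleaved when every
stage shows a reduction above the threshold. The 5' amplicon is reported
descriptively but never enters the call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats


@dataclass(frozen=True)
class RaPcrProfile:
    transcript_id: str
    genotype: str
    stage: str
    q5: float
    qmid: float
    q3: float
    reduction_pct: float


@dataclass(frozen=True)
class FoldChange:
    genotype: str
    stage: str
    gene_id: str
    fold: float
    log2_fold: float
    se_log2: float          # SD of replicate dCt values


def _mean_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to mean Ct per (genotype, stage, gene_id)."""
    return (
        df.groupby(["genotype", "stage", "gene_id"], as_index=False)["ct"]
        .mean()
    )


def normalization_factor(ref_ct: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalization factor from reference-gene Ct values.

    ``ref_ct`` columns: genotype, stage, gene_id, ct (replicates allowed;
    they are averaged first). For each reference gene the relative
    quantity 2^-(Ct - mean Ct of that gene across samples) is formed; the
    factor of a sample is the geometric mean over reference genes.
    Returns columns genotype, stage, factor.
    """
    req = {"genotype", "stage", "gene_id", "ct"}
    if not req <= set(ref_ct.columns):
        raise ValueError(f"reference table needs columns {sorted(req)}")
    mean = _mean_ct(ref_ct)
    samples = mean[["genotype", "stage"]].drop_duplicates()
    genes = mean["gene_id"].unique()
    pivot = mean.pivot_table(
        index=["genotype", "stage"], columns="gene_id", values="ct"
    )
    if pivot.isna().any().any():
        missing = [
            f"{idx}:{col}"
            for col in pivot.columns
            for idx in pivot.index[pivot[col].isna()]
        ]
        raise ValueError(f"missing reference Ct for sample(s) {missing}")
    dct = pivot - pivot.mean(axis=0)
    rq = np.power(2.0, -dct)
    factor = np.exp(np.log(rq).mean(axis=1))
    out = factor.reset_index().rename(columns={0: "factor"})
    out.columns = ["genotype", "stage", "factor"]
    del samples, genes
    return out


def fold_change_ddct(
    target_ct: pd.DataFrame,
    ref_ct: pd.DataFrame,
    calibrator: tuple,
) -> list[FoldChange]:
    """2^-ddCt fold changes per (genotype, stage, gene).

    ``calibrator`` is (genotype, stage): dCt of each sample is referenced
    to that sample's dCt for the same gene. dCt = mean target Ct minus the
    composite reference Ct (arithmetic mean of the per-gene mean
    reference Ct, i.e. the log of the geometric-mean quantity). The
    replicate spread of the target Ct is carried as the SD of per
    replicate dCt values.
    """
    ref_mean = _mean_ct(ref_ct)
    ref_composite = (
        ref_mean.groupby(["genotype", "stage"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "ref_ct"})
    )
    merged = target_ct.merge(ref_composite, on=["genotype", "stage"], how="left")
    if merged["ref_ct"].isna().any():
        bad = merged[merged["ref_ct"].isna()][["genotype", "stage"]]
        raise ValueError(f"no reference Ct for samples:\n{bad.drop_duplicates()}")
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    per_sample = merged.groupby(
        ["genotype", "stage", "gene_id"], as_index=False
    ).agg(dct=("dct", "mean"), sd=("dct", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0))
    cal_geno, cal_stage = calibrator
    cal = per_sample[
        (per_sample["genotype"] == cal_geno) & (per_sample["stage"] == cal_stage)
    ].set_index("gene_id")["dct"]
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator} not present")
    out = []
    for _, row in per_sample.iterrows():
        if row["gene_id"] not in cal.index:
            raise ValueError(
                f"calibrator lacks gene {row['gene_id']!r}"
            )
        ddct = row["dct"] - cal[row["gene_id"]]
        out.append(
            FoldChange(
                genotype=row["genotype"],
                stage=row["stage"],
                gene_id=row["gene_id"],
                fold=2.0 ** (-ddct),
                log2_fold=-ddct,
                se_log2=float(row["sd"]),
            )
        )
    return out


def fold_change_vs_control_gene(
    target_ct: pd.DataFrame, ref_ct: pd.DataFrame, control_gene: str
) -> list[FoldChange]:
    """2^-ddCt using a control *gene* as calibrator within each sample
    (the figure-legend convention where one transcript/miRNA serves as
    the ddCt baseline across all stages)."""
    ref_mean = _mean_ct(ref_ct)
    ref_composite = (
        ref_mean.groupby(["genotype", "stage"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "ref_ct"})
    )
    merged = target_ct.merge(ref_composite, on=["genotype", "stage"], how="left")
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    per_sample = merged.groupby(
        ["genotype", "stage", "gene_id"], as_index=False
    ).agg(dct=("dct", "mean"), sd=("dct", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0))
    ctl = per_sample[per_sample["gene_id"] == control_gene].set_index(
        ["genotype", "stage"]
    )["dct"]
    if ctl.empty:
        raise ValueError(f"control gene {control_gene!r} not present")
    out = []
    for _, row in per_sample.iterrows():
        if row["gene_id"] == control_gene:
            continue
        ddct = row["dct"] - ctl[(row["genotype"], row["stage"])]
        out.append(
            FoldChange(
                genotype=row["genotype"],
                stage=row["stage"],
                gene_id=row["gene_id"],
                fold=2.0 ** (-ddct),
                log2_fold=-ddct,
                se_log2=float(row["sd"]),
            )
        )
    return out


def rapcr_reduction(
    transcript_id: str,
    genotype: str,
    stage: str,
    q5: float,
    qmid: float,
    q3: float,
) -> RaPcrProfile:
    """Reduction of the middle (target-site) amplicon vs the 3' amplicon."""
    if min(q5, qmid, q3) <= 0:
        raise ValueError("RA-PCR quantities must be positive")
    return RaPcrProfile(
        transcript_id=transcript_id,
        genotype=genotype,
        stage=stage,
        q5=q5,
        qmid=qmid,
        q3=q3,
        reduction_pct=(1.0 - qmid / q3) * 100.0,
    )


def rapcr_profiles_from_ct(ra_ct: pd.DataFrame) -> list[RaPcrProfile]:
    """Build RA-PCR profiles from a Ct table.

    Columns: transcript_id, genotype, stage, region (5p|mid|3p), ct
    (replicates averaged). Relative quantities are 2^-Ct up to a common
    factor, which cancels in the reduction statistic.
    """
    req = {"transcript_id", "genotype", "stage", "region", "ct"}
    if not req <= set(ra_ct.columns):
        raise ValueError(f"RA-PCR table needs columns {sorted(req)}")
    mean = ra_ct.groupby(
        ["transcript_id", "genotype", "stage", "region"], as_index=False
    )["ct"].mean()
    out = []
    for (tid, geno, stage), grp in mean.groupby(
        ["transcript_id", "genotype", "stage"]
    ):
        ct = grp.set_index("region")["ct"]
        missing = {"5p", "mid", "3p"} - set(ct.index)
        if missing:
            raise ValueError(
                f"{tid} {geno} {stage}: missing region(s) {sorted(missing)}"
            )
        base = ct.min()
        q = {r: 2.0 ** (base - ct[r]) for r in ("5p", "mid", "3p")}
        out.append(
            rapcr_reduction(tid, geno, stage, q["5p"], q["mid"], q["3p"])
        )
    return out


def call_cleavage(profiles: list[RaPcrProfile], min_reduction: float = 0.0):
    """Stage-wise and overall cleavage calls for one transcript.

    A stage is called cleaved when its reduction exceeds
    ``min_reduction`` percent; the overall call requires every stage
    cleaved (matching the all-stages depletion argument).
    """
    if not profiles:
        raise ValueError("need at least one stage profile")
    tids = {p.transcript_id for p in profiles}
    if len(tids) != 1:
        raise ValueError("profiles must belong to one transcript")
    stage_calls = {
        (p.genotype, p.stage): p.reduction_pct > min_reduction for p in profiles
    }
    overall = all(stage_calls.values())
    return stage_calls, ("cleaved" if overall else "not_cleaved")


def mirna_target_correlation(
    mirna_folds, target_folds, method: str = "pearson", sign_threshold: float = 0.5
):
    """Correlation of a miRNA's per-stage folds with its target's.

    Returns ``(coefficient, call)`` with call ``"negative"`` when the
    coefficient < -sign_threshold, ``"positive"`` when > +threshold, else
    ``"none"``; constant series give ``(nan, "NA")``.
    """
    x = np.asarray(list(mirna_folds), dtype=float)
    y = np.asarray(list(target_folds), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired stages")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return math.nan, "NA"
    if method == "pearson":
        r = float(_sstats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(_sstats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    if r < -sign_threshold:
        return r, "negative"
    if r > sign_threshold:
        return r, "positive"
    return r, "none"
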
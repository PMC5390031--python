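"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was designed
for: an EST corpus with miRNA homologs planted inside hairpin-forming
contexts, a reference set of mature miRNAs, two genotypes x four seed
developmental stages x three replicates of qPCR cycle thresholds with
planted fold changes, three-region RA-PCR quantities with a planted
cleavage fraction, five-point linear HPLC standard responses, and
gene->term annotation maps with planted enriched terms. Every generator
is fully deterministic for a fixed seed (one ``numpy`` generator per
call, no global state) and returns the ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology_scan import revcomp
from .io_formats import SequenceRecord
from .precursor_fold import PrecursorCandidate

_DNA = "ACGT"
_RNA = "ACGU"

GENOTYPES = ("NRC7", "NRC37")
STAGES = ("35DAF", "45DAF", "55DAF", "65DAF")
N_REPLICATES = 3
STANDARD_PPM = (5.0, 10.0, 20.0, 40.0, 50.0)

# The five mature miRNAs recovered in the isoflavone-pathway study;
# used as default references so planted corpora exercise real sequences.
PATHWAY_MATURES = {
    "Gma_miRNA12": "AGACAGUUAUUUUGGGACGGA",
    "Gma_miRNA24": "UCUUGAAGUCUCGCUUGCAG",
    "Gma_miRNA26": "UAAUUGUCGCAGUUUUGAACU",
    "Gma_miRNA28": "UCUGUACCAUAAUAUAAGAC",
    "Gma_miRNA29": "UAGAUACAUCCAUAUGUAGA",
}

# Reported measurements for the five pathway hairpins:
# (precursor length nt, GC %, MFE kcal/mol). The derived statistics
# (AMFE, MFEI, AU%) follow from these by the hairpin_stats arithmetic.
PATHWAY_HAIRPIN_MEASUREMENTS = {
    "Gma_miRNA12": (121, 41.32231, -44.0),
    "Gma_miRNA24": (120, 49.16667, -36.3),
    "Gma_miRNA26": (121, 31.40496, -36.1),
    "Gma_miRNA28": (120, 40.0, -35.1),
    "Gma_miRNA29": (120, 35.0, -34.4),
}


@dataclass
class GroundTruth:
    planted_homologs: list = field(default_factory=list)
    planted_precursors: list = field(default_factory=list)
    planted_target_sites: list = field(default_factory=list)
    planted_fold_changes: dict = field(default_factory=dict)
    planted_cleaved: dict = field(default_factory=dict)
    planted_reductions: dict = field(default_factory=dict)
    planted_enriched_terms: list = field(default_factory=list)
    planted_concentrations: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def keyed(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}

        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            payload[f.name] = keyed(v) if isinstance(v, dict) else v
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        gt = cls()
        for f in dataclasses.fields(cls):
            v = raw.get(f.name)
            if v is None:
                continue
            if isinstance(v, dict):
                v = {
                    tuple(k.split("|")) if "|" in k else k: val
                    for k, val in v.items()
                }
                setattr(gt, f.name, v)
            else:
                setattr(gt, f.name, [tuple(x) if isinstance(x, list) else x for x in v])
        return gt


def _random_seq(rng, length: int, gc: float = 0.5, alphabet: str = _DNA) -> str:
    s = gc / 2.0
    w = (1 - gc) / 2.0
    probs = [w, s, s, w]  # A C G T/U order
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


def _mutate(rng, seq: str, n: int, alphabet: str, positions=None) -> str:
    if n == 0:
        return seq
    if positions is None:
        positions = rng.choice(len(seq), size=n, replace=False)
    s = list(seq)
    for p in positions:
        choices = [c for c in alphabet if c != s[p]]
        s[p] = choices[rng.integers(0, len(choices))]
    return "".join(s)


def gen_hairpin_precursor(
    mature: SequenceRecord,
    loop_len: int = 11,
    mutations_in_star: int = 0,
    seed: int = 0,
    gc_pad: float = 0.5,
) -> PrecursorCandidate:
    """A precursor candidate with the mature in the 5' arm.

    Layout: 5' pad + mature + loop + (mutated) reverse complement of the
    mature + 3' pad, total length mature + 100, matching the flank-50
    extraction geometry. ``mutations_in_star`` substitutions are placed
    in the star arm, so the curated star-mismatch count is known by
    construction.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = np.random.default_rng(seed)
    m = mature.as_rna().sequence
    star = revcomp(m.replace("U", "T")).replace("T", "U")
    star = _mutate(rng, star, mutations_in_star, _RNA)
    pad_total = 100 - loop_len - len(m)
    if pad_total < 0:
        raise ValueError("loop too long for the mature+100 layout")
    pad5 = pad_total // 2
    pad3 = pad_total - pad5
    seq = (
        _random_seq(rng, pad5, gc_pad, _RNA)
        + m
        + _random_seq(rng, loop_len, gc_pad, _RNA)
        + star
        + _random_seq(rng, pad3, gc_pad, _RNA)
    )
    return PrecursorCandidate(
        id=f"synthetic-hairpin-{mature.id}",
        sequence=seq,
        mature_start=pad5 + 1,
        mature_end=pad5 + len(m),
    )


def gen_est_corpus(
    n_background: int = 190,
    n_planted: int = 10,
    mismatch_spectrum=None,
    seed: int = 0,
    references: dict | None = None,
    polya_fraction: float = 0.3,
    gc: float = 0.45,
    loop_len: int = 11,
):
    """An EST corpus with miRNA homologs planted in hairpin contexts.

    Background ESTs are random 300-800-nt sequences. Each planted EST
    embeds one reference mature (mutated per ``mismatch_spectrum``, a
    list of per-plant substitution counts; mutations avoid the first 7
    bases so one exact seed word always survives) inside a
    hairpin-forming context built as in :func:`gen_hairpin_precursor`.
    A ``polya_fraction`` of records gets a 3' poly(A) tail. Returns
    ``(records, reference_records, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    references = references or PATHWAY_MATURES
    ref_records = [
        SequenceRecord(mid, seq, "rna") for mid, seq in references.items()
    ]
    if mismatch_spectrum is None:
        mismatch_spectrum = [0] * n_planted
    if len(mismatch_spectrum) != n_planted:
        raise ValueError("mismatch_spectrum length must equal n_planted")
    truth = GroundTruth()
    records = []
    ref_ids = list(references)
    for i in range(n_background + n_planted):
        est_id = f"est{i + 1:04d}"
        length = int(rng.integers(300, 801))
        seq = _random_seq(rng, length, gc)
        if i < n_planted:
            mid = ref_ids[i % len(ref_ids)]
            n_mm = int(mismatch_spectrum[i])
            mature_rna = references[mid]
            positions = (
                rng.choice(np.arange(7, len(mature_rna)), size=n_mm, replace=False)
                if n_mm
                else []
            )
            mutated = _mutate(rng, mature_rna, n_mm, _RNA, positions=positions)
            hp = gen_hairpin_precursor(
                SequenceRecord(mid, mutated, "rna"),
                loop_len=loop_len,
                seed=int(rng.integers(0, 2**31)),
                gc_pad=gc,
            )
            hp_dna = hp.sequence.replace("U", "T")
            insert_at = int(rng.integers(10, length - len(hp_dna) - 10))
            seq = seq[:insert_at] + hp_dna + seq[insert_at + len(hp_dna):]
            mature_offset = insert_at + hp.mature_start  # 1-based in EST
            truth.planted_homologs.append((mid, est_id, mature_offset, n_mm))
            truth.planted_precursors.append(est_id)
        if rng.random() < polya_fraction:
            seq = seq + "A" * int(rng.integers(12, 25))
        records.append(SequenceRecord(est_id, seq, "dna"))
    perm = rng.permutation(len(records))
    records = [records[int(k)] for k in perm]
    return records, ref_records, truth


def gen_target_transcripts(
    mirnas: list[SequenceRecord],
    n_decoy: int = 5,
    length: int = 300,
    seed: int = 0,
    gc: float = 0.45,
):
    """Transcripts with one planted perfect target site per miRNA plus
    decoy transcripts with no planted site. Returns
    ``(transcripts, GroundTruth)`` (positions 1-based)."""
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    out = []
    for i, m in enumerate(mirnas):
        mat = m.as_rna().sequence
        site = revcomp(mat.replace("U", "T"))  # DNA reverse complement
        tid = f"tx{i + 1:03d}"
        seq = _random_seq(rng, length, gc)
        pos = int(rng.integers(20, length - len(site) - 20))
        seq = seq[:pos] + site + seq[pos + len(site):]
        out.append(SequenceRecord(tid, seq, "dna"))
        truth.planted_target_sites.append((m.id, tid, pos + 1, 0.0))
    for j in range(n_decoy):
        out.append(
            SequenceRecord(f"decoy{j + 1:03d}", _random_seq(rng, length, gc), "dna")
        )
    return out, truth


def gen_expression_tables(
    genes=None,
    genotypes=GENOTYPES,
    stages=STAGES,
    fold_spec: dict | None = None,
    noise_sd_ct: float = 0.1,
    seed: int = 0,
    calibrator=None,
    n_replicates: int = N_REPLICATES,
    base_ct: float = 25.0,
    ref_genes=("ref5S", "refEF1a", "refActin"),
):
    """Ct tables with planted 2^-ddCt fold changes.

    Reference genes are constant across samples up to noise. For target
    genes, Ct = calibrator Ct - log2(planted fold) + noise, so the ddCt
    chain inverts exactly at zero noise. ``fold_spec`` maps
    (genotype, stage, gene) -> fold; missing entries default to 1 and the
    calibrator sample (default: first genotype, first stage) is forced to
    fold 1. Returns ``(target_ct, ref_ct, GroundTruth)`` DataFrames with
    columns genotype, stage, gene_id, replicate, ct.
    """
    rng = np.random.default_rng(seed)
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be >= 0")
    genes = list(genes) if genes is not None else [f"gene{i:03d}" for i in range(1, 6)]
    calibrator = calibrator or (genotypes[0], stages[0])
    fold_spec = dict(fold_spec or {})
    truth = GroundTruth()
    ref_rows, tgt_rows = [], []
    for geno in genotypes:
        for stage in stages:
            for ref in ref_genes:
                for rep in range(1, n_replicates + 1):
                    ref_rows.append(
                        dict(
                            genotype=geno, stage=stage, gene_id=ref,
                            replicate=rep,
                            ct=base_ct - 5 + rng.normal(0, noise_sd_ct),
                        )
                    )
            for gene in genes:
                key = (geno, stage, gene)
                fold = 1.0 if (geno, stage) == calibrator else float(
                    fold_spec.get(key, 1.0)
                )
                truth.planted_fold_changes[key] = fold
                for rep in range(1, n_replicates + 1):
                    tgt_rows.append(
                        dict(
                            genotype=geno, stage=stage, gene_id=gene,
                            replicate=rep,
                            ct=base_ct - np.log2(fold) + rng.normal(0, noise_sd_ct),
                        )
                    )
    return pd.DataFrame(tgt_rows), pd.DataFrame(ref_rows), truth


def gen_rapcr_tables(
    transcripts=None,
    genotypes=GENOTYPES,
    stages=STAGES,
    cleaved_fraction: float = 0.7,
    reduction_range=(50.0, 99.0),
    noise_sd_ct: float = 0.1,
    seed: int = 0,
    n_replicates: int = N_REPLICATES,
    base_ct: float = 24.0,
):
    """Three-region RA-PCR Ct tables with a planted cleavage fraction.

    Cleaved transcripts get a per-transcript reduction drawn uniformly in
    ``reduction_range`` percent, applied at every stage: the middle
    region's Ct is raised by -log2(1 - reduction/100). Non-cleaved
    transcripts have equal expected mid and 3' abundance. Returns
    ``(ra_ct, GroundTruth)`` with columns transcript_id, genotype, stage,
    region, replicate, ct.
    """
    rng = np.random.default_rng(seed)
    transcripts = (
        list(transcripts)
        if transcripts is not None
        else [f"tx{i:03d}" for i in range(1, 21)]
    )
    truth = GroundTruth()
    rows = []
    for tid in transcripts:
        cleaved = bool(rng.random() < cleaved_fraction)
        reduction = float(rng.uniform(*reduction_range)) if cleaved else 0.0
        truth.planted_cleaved[tid] = cleaved
        truth.planted_reductions[tid] = reduction
        mid_shift = -np.log2(1.0 - reduction / 100.0) if cleaved else 0.0
        for geno in genotypes:
            for stage in stages:
                ct_3p = base_ct + rng.normal(0, 0.5)   # per-sample level
                ct_5p = ct_3p + rng.normal(0, 0.3)     # descriptive only
                for region, ct0 in (
                    ("5p", ct_5p), ("mid", ct_3p + mid_shift), ("3p", ct_3p)
                ):
                    for rep in range(1, n_replicates + 1):
                        rows.append(
                            dict(
                                transcript_id=tid, genotype=geno, stage=stage,
                                region=region, replicate=rep,
                                ct=ct0 + rng.normal(0, noise_sd_ct),
                            )
                        )
    return pd.DataFrame(rows), truth


def gen_annotation(
    population: int = 1000,
    terms: int = 30,
    study_size: int = 20,
    enrichment_odds: float = 10.0,
    terms_per_gene: int = 2,
    seed: int = 0,
):
    """Annotation map with one planted enriched term.

    Background: every gene draws ``terms_per_gene`` terms uniformly.
    Study genes additionally receive the planted term with probability
    ``min(1, enrichment_odds * terms_per_gene / terms)``; odds 1 reduces
    to the null. Returns ``(annotation dict, study list, GroundTruth)``.
    """
    if enrichment_odds < 1:
        raise ValueError("enrichment odds must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(population)]
    term_ids = [f"TERM:{i:04d}" for i in range(terms)]
    planted = term_ids[0]
    annotation = {
        g: sorted({term_ids[int(t)] for t in rng.integers(0, terms, terms_per_gene)})
        for g in genes
    }
    study = [genes[int(i)] for i in rng.choice(population, study_size, replace=False)]
    base_rate = terms_per_gene / terms
    p_extra = min(1.0, enrichment_odds * base_rate)
    if enrichment_odds > 1:
        for g in study:
            if rng.random() < p_extra and planted not in annotation[g]:
                annotation[g] = sorted(annotation[g] + [planted])
    truth = GroundTruth(planted_enriched_terms=[planted] if enrichment_odds > 1 else [])
    return annotation, study, truth


def gen_hplc(
    curve_truth: dict | None = None,
    concentrations_truth: dict | None = None,
    noise_sd_area: float = 0.0,
    seed: int = 0,
    sample_mass_g: float = 0.125,
    extract_volume_ml: float = 6.0,
    dilution: float = 1.0,
    n_replicates: int = N_REPLICATES,
):
    """Five-point HPLC standards plus sample areas from planted ug/g.

    ``curve_truth`` maps analyte -> (slope, intercept); sample areas are
    the exact inversion of the quantification arithmetic plus optional
    noise, so zero noise round-trips planted concentrations exactly.
    ``concentrations_truth`` maps (genotype, stage, analyte) -> ug/g.
    Returns ``(standards, samples, GroundTruth)`` DataFrames.
    """
    rng = np.random.default_rng(seed)
    curve_truth = curve_truth or {
        "daidzein": (10.0, 0.0),
        "glycitein": (12.0, 5.0),
        "genistein": (8.0, 2.0),
    }
    if concentrations_truth is None:
        concentrations_truth = {}
        rng_c = np.random.default_rng(seed + 1)
        for geno in GENOTYPES:
            for stage in STAGES:
                for analyte in curve_truth:
                    concentrations_truth[(geno, stage, analyte)] = float(
                        rng_c.uniform(20, 600)
                    )
    std_rows = []
    for analyte, (slope, intercept) in curve_truth.items():
        for ppm in STANDARD_PPM:
            std_rows.append(
                dict(
                    analyte=analyte, ppm=ppm,
                    area=slope * ppm + intercept + rng.normal(0, noise_sd_area),
                )
            )
    sample_rows = []
    truth = GroundTruth(
        planted_concentrations={k: v for k, v in concentrations_truth.items()}
    )
    for (geno, stage, analyte), ugg in concentrations_truth.items():
        slope, intercept = curve_truth[analyte]
        ppm = ugg * sample_mass_g / (extract_volume_ml * dilution)
        for rep in range(1, n_replicates + 1):
            sample_rows.append(
                dict(
                    genotype=geno, stage=stage, analyte=analyte, replicate=rep,
                    area=slope * ppm + intercept + rng.normal(0, noise_sd_area),
                )
            )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows), truth
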
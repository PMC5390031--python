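"""End-to-end discovery chain: ESTs in, curated pre-miRNA candidates out.

Order of operations: poly(A/T) trimming -> low-complexity soft-masking ->
(optional) greedy assembly -> seeded homology scan against the reference
matures -> precursor extraction with 50-nt flanks -> folding -> triplet
classifier -> coding/contaminant exclusion -> curation rules. The result
object keeps every intermediate so tests can interrogate each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import est_preprocess as prep
from . import hairpin_filter as hf
from . import homology_scan as hs
from . import precursor_fold as pf
from . import synthetic_data as synth
from .io_formats import SequenceRecord


@dataclass
class DiscoveryResult:
    cleaned: list = field(default_factory=list)
    units: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    folds: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)        # cand id -> (label, margin)
    exclusions: dict = field(default_factory=dict)    # cand id -> reason
    verdicts: dict = field(default_factory=dict)      # cand id -> CurationVerdict
    accepted: list = field(default_factory=list)      # surviving candidates

    def accepted_unit_ids(self) -> set:
        return {c.source_hit.unit_id for c in self.accepted}


def default_classifier(
    seed: int = 7, engine=None, n_per_class: int = 60
) -> hf.TripletClassifier:
    """Train the hairpin classifier on generator output.

    Positives: synthetic perfect hairpins around random 20-22-nt matures;
    negatives: the same sequences mononucleotide-shuffled (structure
    destroyed, composition preserved), both folded with ``engine``.
    Deterministic for fixed seed.
    """
    engine = engine or pf.get_engine("auto")
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for i in range(n_per_class):
        mlen = int(rng.integers(20, 23))
        mature = SequenceRecord(
            f"train{i}", synth._random_seq(rng, mlen, 0.45, "ACGU"), "rna"
        )
        hp = synth.gen_hairpin_precursor(
            mature, seed=int(rng.integers(0, 2**31)), gc_pad=0.45
        )
        fold = engine.fold(hp.sequence)
        if fold.structure.n_pairs:
            pos.append(hf.triplet_features(hp, fold))
        shuffled = "".join(rng.permutation(list(hp.sequence)))
        sp = pf.PrecursorCandidate(
            id=f"shuf{i}", sequence=shuffled,
            mature_start=hp.mature_start, mature_end=hp.mature_end,
        )
        sfold = engine.fold(shuffled)
        if sfold.structure.n_pairs:
            neg.append(hf.triplet_features(sp, sfold))
    return hf.train_classifier(pos, neg, seed=seed)


def discover(
    ests: list[SequenceRecord],
    references: list[SequenceRecord],
    classifier: hf.TripletClassifier | None = None,
    engine=None,
    contaminants=None,
    assemble: bool = False,
    word: int = 7,
    max_mismatch: int = 3,
    min_len: int = 18,
    flank: int = 50,
    min_flank: int = 20,
    curation: hf.CurationConfig = hf.CurationConfig(),
    classifier_seed: int = 7,
) -> DiscoveryResult:
    """Run the full discovery chain on an EST set."""
    engine = engine or pf.get_engine("auto")
    if classifier is None:
        classifier = default_classifier(seed=classifier_seed, engine=engine)
    res = DiscoveryResult()
    for r in ests:
        try:
            c = prep.trim_polyAT(r)
        except prep.DropRecord:
            continue
        res.cleaned.append(prep.mask_low_complexity(c))
    if assemble:
        res.units = prep.assemble_greedy(res.cleaned)
    else:
        res.units = res.cleaned
    index = hs.build_word_index(res.units, word=word)
    res.hits = hs.scan_homologs(
        references, index, max_mismatch=max_mismatch, min_len=min_len
    )
    units_by_id = {u.id: u for u in res.units}
    for hit in res.hits:
        try:
            cand = pf.extract_precursor(
                hit, units_by_id, flank=flank, min_flank=min_flank
            )
        except pf.RejectedCandidate:
            continue
        res.candidates.append(cand)
        fold = engine.fold(cand.sequence)
        res.folds[cand.id] = fold
        if fold.structure.n_pairs == 0:
            res.labels[cand.id] = ("pseudo", float("-inf"))
            continue
        res.stats[cand.id] = pf.hairpin_stats(cand, fold)
        feat = hf.triplet_features(cand, fold)
        label, margin = hf.classify_hairpin(feat, classifier)
        res.labels[cand.id] = (label, margin)
        if label != "real":
            continue
        keep, reason = hf.exclude_coding(cand, contaminants)
        if not keep:
            res.exclusions[cand.id] = reason
            continue
        verdict = hf.curate(cand, fold, res.stats[cand.id], curation)
        res.verdicts[cand.id] = verdict
        if verdict.passed:
            res.accepted.append(cand)
    return res


def recovery_counts(res: DiscoveryResult, truth: synth.GroundTruth):
    """(planted recovered, decoys admitted) against generator truth."""
    planted_units = set(truth.planted_precursors)
    accepted_units = res.accepted_unit_ids()
    recovered = len(planted_units & accepted_units)
    decoys = len(accepted_units - planted_units)
    return recovered, decoys
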
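"""Decide which folded candidates are genuine pre-miRNA hairpins.

Three successive screens, mirroring common practice for homology-mined
candidates:

1. a linear-kernel maximum-margin classifier over 32-dimensional triplet
   structure-sequence features (the classic local-pairing-context encoding:
   paired/unpaired status of each 3-base window x the middle base);
2. exclusion of likely protein-coding or structural-RNA sequence (long
   open reading frame in any frame, or an exact 16-mer shared with a
   user-supplied rRNA/tRNA/snRNA contaminant set);
3. programmatic curation rules for hairpin geometry: mature contained in
   one arm, limited mature/star mismatches, no multibranch junction in
   the mature, AU% in a stated band, and a minimum |MFEI|.

No published classifier weights are assumed: :func:`train_classifier`
fits the model on labelled feature vectors (the synthetic generator
provides positives and shuffled negatives with known truth), and models
serialize to JSON for reuse.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.svm import LinearSVC

from .io_formats import SequenceRecord
from .precursor_fold import FoldResult, HairpinStats, PrecursorCandidate

_BASES = "ACGU"
_STATUS = [(a, b, c) for a in "pu" for b in "pu" for c in "pu"]
FEATURE_NAMES = tuple(
    f"{base}-{''.join(st)}" for base in _BASES for st in _STATUS
)


@dataclass(frozen=True)
class TripletFeatures:
    """32 frequencies: middle base x paired/unpaired status of a 3-window."""

    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) != 32:
            raise ValueError("triplet feature vector must have 32 entries")
        if any(v < 0 for v in self.values):
            raise ValueError("negative feature frequency")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CurationVerdict:
    in_one_arm: bool
    star_mismatches: int
    no_branch_in_mature: bool
    au_in_range: bool
    mfei_ok: bool
    max_star_mismatch: int
    passed: bool


@dataclass(frozen=True)
class CurationConfig:
    max_star_mismatch: int = 6
    au_lo: float = 30.0
    au_hi: float = 70.0
    min_abs_mfei: float = 0.5


def triplet_features(p: PrecursorCandidate, f: FoldResult) -> TripletFeatures:
    """Triplet structure-sequence features of a folded precursor.

    For every interior position i, the paired ('(' or ')') / unpaired
    status of positions (i-1, i, i+1) and the base at i select one of
    32 counters; counts are normalized to frequencies.
    """
    seq = p.sequence.upper().replace("T", "U")
    struct = f.structure.structure
    n = len(seq)
    if n < 3 or len(struct) != n:
        raise ValueError("need structure of length >= 3 matching the sequence")
    status = ["p" if c in "()" else "u" for c in struct]
    counts = np.zeros(32)
    for i in range(1, n - 1):
        base = seq[i]
        if base not in _BASES:
            continue
        b_idx = _BASES.index(base)
        s_idx = _STATUS.index((status[i - 1], status[i], status[i + 1]))
        counts[b_idx * 8 + s_idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable interior positions")
    return TripletFeatures(tuple(counts / total))


class TripletClassifier:
    """Linear maximum-margin hairpin classifier over triplet features."""

    def __init__(self, weights: np.ndarray, bias: float, seed: int, digest: str):
        self.weights = np.asarray(weights, dtype=float)
        self.bias = float(bias)
        self.seed = seed
        self.digest = digest

    def margin(self, feat: TripletFeatures) -> float:
        return float(self.weights @ feat.as_array() + self.bias)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": list(self.weights),
                "bias": self.bias,
                "seed": self.seed,
                "digest": self.digest,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TripletClassifier":
        d = json.loads(text)
        return cls(np.array(d["weights"]), d["bias"], d["seed"], d["digest"])


def train_classifier(
    pos: list[TripletFeatures], neg: list[TripletFeatures], seed: int = 0
) -> TripletClassifier:
    """Fit the linear classifier on labelled triplet features.

    Requires >= 20 examples per class; warns on >10:1 imbalance. Training
    is deterministic for a fixed seed and input order; the returned model
    carries a digest of its training data.
    """
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    if len(pos) < 20 or len(neg) < 20:
        raise ValueError("need >= 20 examples per class")
    ratio = max(len(pos), len(neg)) / min(len(pos), len(neg))
    if ratio > 10:
        warnings.warn(f"class imbalance {ratio:.1f}:1", stacklevel=2)
    X = np.vstack([f.as_array() for f in pos] + [f.as_array() for f in neg])
    y = np.array([1] * len(pos) + [0] * len(neg))
    clf = LinearSVC(C=1.0, random_state=seed, max_iter=20000, dual="auto")
    clf.fit(X, y)
    digest = hashlib.sha256(
        X.tobytes() + y.tobytes() + str(seed).encode()
    ).hexdigest()[:16]
    return TripletClassifier(clf.coef_[0], clf.intercept_[0], seed, digest)


def classify_hairpin(feat: TripletFeatures, model: TripletClassifier):
    """Label a candidate ``real`` or ``pseudo`` with its signed margin."""
    if model is None:
        raise ValueError("classifier not trained")
    m = model.margin(feat)
    return ("real" if m > 0 else "pseudo"), m


_STOPS = {"UAA", "UAG", "UGA"}


def longest_orf(seq: str) -> int:
    """Longest open reading frame in codons (AUG..stop, 3 forward frames
    on the given strand and its reverse complement)."""
    rc = seq.upper().replace("T", "U")
    comp = str.maketrans("ACGU", "UGCA")
    best = 0
    for s in (rc, rc.translate(comp)[::-1]):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            i = 0
            while i < len(codons):
                if codons[i] == "AUG":
                    j = i
                    while j < len(codons) and codons[j] not in _STOPS:
                        j += 1
                    best = max(best, j - i)
                    i = j
                i += 1
    return best


def exclude_coding(
    p: PrecursorCandidate,
    contaminants: Optional[list[SequenceRecord]] = None,
    min_orf: int = 60,
    kmer: int = 16,
):
    """Drop precursors that look protein-coding or match structural RNA.

    Returns ``(keep: bool, reason: str)``; reason is ``"orf"`` when any
    reading frame holds an ORF of >= ``min_orf`` codons, ``"contaminant"``
    on an exact shared ``kmer`` with the supplied rRNA/tRNA/snRNA set,
    else ``""``.
    """
    if longest_orf(p.sequence) >= min_orf:
        return False, "orf"
    if contaminants:
        s = p.sequence.upper().replace("T", "U")
        bad = set()
        for c in contaminants:
            cs = c.as_rna().sequence
            for i in range(len(cs) - kmer + 1):
                bad.add(cs[i:i + kmer])
        for i in range(len(s) - kmer + 1):
            if s[i:i + kmer] in bad:
                return False, "contaminant"
    return True, ""


def _mature_pair_info(p: PrecursorCandidate, f: FoldResult):
    table = f.structure.pair_table()
    lo, hi = p.mature_start - 1, p.mature_end - 1  # 0-based inclusive
    partners = [table.get(i) for i in range(lo, hi + 1)]
    return lo, hi, partners


def curate(
    p: PrecursorCandidate,
    f: FoldResult,
    s: HairpinStats,
    cfg: CurationConfig = CurationConfig(),
) -> CurationVerdict:
    """Apply the programmatic hairpin-curation rules.

    * mature wholly within one arm: every paired mature base points to a
      partner on the same side, outside the mature span, and the mature
      has at least one paired base;
    * star mismatches: mature bases left unpaired in the fold, capped at
      ``cfg.max_star_mismatch``;
    * no multibranch junction overlapping the mature: the mature carries
      brackets of a single orientation;
    * AU% within [au_lo, au_hi]; |MFEI| >= min_abs_mfei.
    """
    lo, hi, partners = _mature_pair_info(p, f)
    paired = [q for q in partners if q is not None]
    bracket_kinds = {
        f.structure.structure[i]
        for i in range(lo, hi + 1)
        if f.structure.structure[i] in "()"
    }
    in_one_arm = bool(paired) and (
        all(q > hi for q in paired) or all(q < lo for q in paired)
    )
    no_branch = len(bracket_kinds) <= 1
    star_mm = sum(q is None for q in partners)
    au_ok = cfg.au_lo <= s.au_percent <= cfg.au_hi
    mfei_ok = abs(s.mfei) >= cfg.min_abs_mfei
    passed = (
        in_one_arm
        and no_branch
        and star_mm <= cfg.max_star_mismatch
        and au_ok
        and mfei_ok
    )
    return CurationVerdict(
        in_one_arm=in_one_arm,
        star_mismatches=star_mm,
        no_branch_in_mature=no_branch,
        au_in_range=au_ok,
        mfei_ok=mfei_ok,
        max_star_mismatch=cfg.max_star_mismatch,
        passed=passed,
    )
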
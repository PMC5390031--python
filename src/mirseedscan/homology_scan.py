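"""Seeded homology scan of assembled EST units against known mature miRNAs.

A word index (default word size 7) anchors candidate loci; each anchor is
extended ungapped over the full mature length and kept when the alignment
shows no gaps, at most ``max_mismatch`` substitutions (default 3) and an
aligned span of at least ``min_len`` bases (default 18). This deterministic
filter replaces a permissive-E-value BLASTN pass: any hit passing the
mismatch cap necessarily clears an E-value threshold of 10 at word size 7,
so the mismatch cap is the binding filter.

Coordinates are 1-based inclusive on the unit's forward strand; minus-strand
hits carry ``strand="-"`` and downstream flank extraction works on the hit
strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io_formats import SequenceRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class HomologHit:
    mirna_id: str
    unit_id: str
    unit_start: int      # 1-based inclusive, forward strand of the unit
    unit_end: int
    strand: str          # "+" or "-"
    aligned_length: int
    mismatches: int
    gaps: int = 0

    def __post_init__(self) -> None:
        if self.gaps != 0:
            raise ValueError("homology hits are ungapped")
        if self.unit_end - self.unit_start + 1 != self.aligned_length:
            raise ValueError("coordinates inconsistent with aligned_length")


class WordIndex:
    """Exact-word index over the unmasked portions of assembled units.

    Words are stored T-normalized and uppercase. Masked (lowercase) bases
    never seed a word, mirroring soft-masking semantics; they may still
    fall inside an alignment extension.
    """

    def __init__(self, units, word: int = 7):
        if word < 4:
            raise ValueError("word size must be >= 4")
        self.word = word
        self.units = {u.id: u for u in units}
        self.index: dict[str, list] = defaultdict(list)
        for u in units:
            seq = u.sequence
            n = len(seq)
            for i in range(n - word + 1):
                w = seq[i:i + word]
                if not w.isupper():     # touches a masked base
                    continue
                self.index[w].append((u.id, i))

    def lookup(self, word: str) -> list:
        return self.index.get(word.upper().replace("U", "T"), [])


def build_word_index(units, word: int = 7) -> WordIndex:
    return WordIndex(units, word)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_homologs(
    mirnas: list[SequenceRecord],
    index: WordIndex,
    max_mismatch: int = 3,
    min_len: int = 18,
) -> list[HomologHit]:
    """Scan every mature miRNA against the indexed units.

    Each exact seed-word match anchors an ungapped placement of the full
    mature sequence; placements clipped by a unit boundary are kept when
    the surviving span still reaches ``min_len``. Mismatches are counted
    over the aligned span (case-insensitive, so masked bases align
    normally). Duplicate placements reached from different seeds collapse
    to one hit.
    """
    hits: dict[tuple, HomologHit] = {}
    word = index.word
    skipped = []
    for m in mirnas:
        query = m.as_dna().sequence
        if len(query) < min_len:
            skipped.append(m.id)
            continue
        for strand, q in (("+", query), ("-", revcomp(query))):
            for s in range(len(q) - word + 1):
                for unit_id, pos in index.lookup(q[s:s + word]):
                    unit_seq = index.units[unit_id].sequence.upper()
                    start = pos - s          # 0-based placement of q
                    lo = max(start, 0)
                    hi = min(start + len(q), len(unit_seq))
                    if hi - lo < min_len:
                        continue
                    sub_q = q[lo - start:hi - start]
                    mm = _hamming(sub_q, unit_seq[lo:hi])
                    if mm > max_mismatch:
                        continue
                    key = (m.id, unit_id, lo, strand)
                    if key not in hits:
                        hits[key] = HomologHit(
                            mirna_id=m.id,
                            unit_id=unit_id,
                            unit_start=lo + 1,
                            unit_end=hi,
                            strand=strand,
                            aligned_length=hi - lo,
                            mismatches=mm,
                        )
    return sorted(
        hits.values(),
        key=lambda h: (h.mirna_id, h.unit_id, h.unit_start, h.strand),
    )


def brute_force_scan(
    mirnas: list[SequenceRecord],
    units,
    max_mismatch: int = 3,
    min_len: int = 18,
    require_seed: int = 7,
) -> list[HomologHit]:
    """Reference scan: slide each mature over both strands of every unit
    and count Hamming mismatches directly. With ``require_seed`` set, a
    placement must contain one exact, fully unmasked seed word to be
    reported (matching the seeded scanner's reachability); pass 0 to
    drop that requirement."""
    out = []
    for m in mirnas:
        query = m.as_dna().sequence
        if len(query) < min_len:
            continue
        for u in units:
            seq = u.sequence
            n = len(seq)
            for strand, q in (("+", query), ("-", revcomp(query))):
                for start in range(-(len(q) - min_len), n - min_len + 1):
                    lo = max(start, 0)
                    hi = min(start + len(q), n)
                    if hi - lo < min_len:
                        continue
                    sub_q = q[lo - start:hi - start]
                    mm = _hamming(sub_q, seq[lo:hi].upper())
                    if mm > max_mismatch:
                        continue
                    if require_seed:
                        w = require_seed
                        ok = any(
                            sub_q[k:k + w] == seq[lo + k:lo + k + w]
                            for k in range(hi - lo - w + 1)
                        )
                        if not ok:
                            continue
                    out.append(
                        HomologHit(m.id, u.id, lo + 1, hi, strand, hi - lo, mm)
                    )
    uniq = {(h.mirna_id, h.unit_id, h.unit_start, h.strand): h for h in out}
    return sorted(
        uniq.values(),
        key=lambda h: (h.mirna_id, h.unit_id, h.unit_start, h.strand),
    )
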
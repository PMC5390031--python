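"""EST cleanup before homology scanning.

Single-pass cDNA reads carry poly(A) tails (or poly(T) heads on
reverse-strand reads), low-complexity stretches, and heavy redundancy.
This module trims tails, soft-masks low-complexity windows with a
DUST-style score, collapses exact duplicates, and assembles overlapping
reads into contigs with a greedy suffix–prefix merger. The assembler is
deliberately simple: at desk scale the downstream homology scan only
needs redundancy collapsed, not a faithful re-implementation of a
production EST assembler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .io_formats import SequenceRecord


class DropRecord(Exception):
    """Raised when trimming reduces a record to length zero."""


@dataclass(frozen=True)
class CleanedEst:
    id: str
    sequence: str          # uppercase DNA; masked bases lowercase
    trimmed_5p: int = 0
    trimmed_3p: int = 0
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.trimmed_5p < 0 or self.trimmed_3p < 0:
            raise ValueError("negative trim count")
        if not 0.0 <= self.masked_fraction <= 1.0:
            raise ValueError("masked_fraction outside [0,1]")
        if not self.sequence:
            raise DropRecord(self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssembledUnit:
    id: str
    sequence: str
    kind: str                      # "contig" or "singlet"
    member_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.kind == "contig" and len(self.member_ids) < 2:
            raise ValueError("contig must have >=2 members")
        if self.kind == "singlet" and len(self.member_ids) != 1:
            raise ValueError("singlet must have exactly 1 member")


def _tail_run_length(seq: str, base: str, min_run: int) -> int:
    """Longest suffix that is a run of `base` allowing <=1 interruption
    per 10 bases of run; the run must end (terminally) on `base`."""
    if not seq or seq[-1] != base:
        return 0
    best = 0
    interruptions = 0
    for k in range(1, len(seq) + 1):
        c = seq[-k]
        if c != base:
            interruptions += 1
        if interruptions > k // 10:
            break
        if c == base and seq[-1] == base:
            best = k
    return best if best >= min_run else 0


def trim_polyAT(r: SequenceRecord, min_run: int = 10) -> CleanedEst:
    """Trim a 3' poly(A) tail and/or a 5' poly(T) head.

    A tail is a terminal run of at least ``min_run`` identical bases,
    tolerating one interruption per 10 bases of run. Raises
    :class:`DropRecord` if nothing remains.
    """
    seq = r.as_dna().sequence
    t3 = _tail_run_length(seq, "A", min_run)
    if t3:
        seq = seq[:-t3]
    t5 = _tail_run_length(seq[::-1], "T", min_run)
    if t5:
        seq = seq[t5:]
    if not seq:
        raise DropRecord(r.id)
    return CleanedEst(r.id, seq, trimmed_5p=t5, trimmed_3p=t3)


def dust_score(window: str) -> float:
    """DUST low-complexity score: sum of c*(c-1)/2 over triplet counts,
    normalized by the number of triplets (len-2)."""
    n = len(window)
    if n < 3:
        return 0.0
    counts = Counter(window[i:i + 3].upper() for i in range(n - 2))
    raw = sum(c * (c - 1) / 2 for c in counts.values())
    return raw / (n - 2)


def mask_low_complexity(
    r: CleanedEst, window: int = 12, threshold: float = 2.0
) -> CleanedEst:
    """Soft-mask (lowercase) every window whose DUST score reaches
    ``threshold``. Masked bases are excluded from seed matching
    downstream but remain in the sequence."""
    if window < 4:
        raise ValueError("window must be >= 4")
    seq = r.sequence.upper()
    n = len(seq)
    mask = [False] * n
    for start in range(0, max(n - window + 1, 1)):
        w = seq[start:start + window]
        if len(w) < 3:
            break
        if dust_score(w) >= threshold:
            for i in range(start, min(start + window, n)):
                mask[i] = True
    masked = "".join(c.lower() if m else c for c, m in zip(seq, mask))
    return replace(r, sequence=masked, masked_fraction=sum(mask) / n)


def deduplicate(rs: list) -> list:
    """Collapse exact-sequence duplicates, keeping the first id; order
    preserved. Case-insensitive on the sequence."""
    seen: set[str] = set()
    out = []
    for r in rs:
        key = r.sequence.upper()
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float):
    """Longest suffix(a)/prefix(b) overlap meeting the identity bar."""
    a_u, b_u = a.upper(), b.upper()
    for olen in range(min(len(a_u), len(b_u)), min_overlap - 1, -1):
        sa, sb = a_u[-olen:], b_u[:olen]
        matches = sum(x == y for x, y in zip(sa, sb))
        if matches / olen >= min_identity:
            return olen
    return 0


def assemble_greedy(
    rs: list, min_overlap: int = 30, min_identity: float = 0.95
) -> list[AssembledUnit]:
    """Greedy overlap-layout assembly of cleaned ESTs.

    Repeatedly merges the ordered pair with the longest suffix–prefix
    overlap (>= ``min_overlap`` bases at >= ``min_identity``) until no
    pair qualifies; the left read's bases win inside the overlap.
    Unmerged inputs become singlets. Forward strand only.
    """
    if min_overlap < 16:
        raise ValueError("min_overlap must be >= 16")
    if min_identity < 0.9:
        raise ValueError("min_identity must be >= 0.9")
    frags = [(r.id, r.sequence, [r.id]) for r in rs]
    while True:
        best = (0, None, None)  # (olen, i, j)
        for i in range(len(frags)):
            for j in range(len(frags)):
                if i == j:
                    continue
                olen = _best_overlap(
                    frags[i][1], frags[j][1], min_overlap, min_identity
                )
                if olen > best[0]:
                    best = (olen, i, j)
        olen, i, j = best
        if olen == 0:
            break
        left, right = frags[i], frags[j]
        merged = (left[0], left[1] + right[1][olen:], left[2] + right[2])
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    out = []
    n_contig = 0
    for fid, seq, members in frags:
        if len(members) >= 2:
            n_contig += 1
            out.append(
                AssembledUnit(f"contig{n_contig}", seq, "contig", tuple(members))
            )
        else:
            out.append(AssembledUnit(fid, seq, "singlet", tuple(members)))
    return out


def screen_contaminants(
    rs: list, contaminants: list[SequenceRecord], k: int = 16
) -> list:
    """Drop records sharing any exact k-mer with a contaminant set
    (vector-screen stand-in)."""
    bad_kmers: set[str] = set()
    for c in contaminants:
        s = c.as_dna().sequence
        for i in range(len(s) - k + 1):
            bad_kmers.add(s[i:i + k])
    kept = []
    for r in rs:
        s = r.sequence.upper()
        if any(s[i:i + k] in bad_kmers for i in range(len(s) - k + 1)):
            continue
        kept.append(r)
    return kept
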
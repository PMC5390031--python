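"""miRNA target prediction by complementarity expectation scoring.

A candidate site is a transcript window aligned antiparallel to the
miRNA. The expectation score is a penalty: 0 for a perfect reverse
complement, +1 per mismatch, +0.5 per G:U wobble, +2 per gap, with every
penalty doubled when the alignment column falls at miRNA positions 2
through ``seed_end`` (default 13) counted from the miRNA 5' end — the
convention of the plant target-prediction servers this scoring follows.
At most ``max_gaps`` (default 1) gaps are allowed and sites scoring above
``max_expectation`` (default 3.0) are not reported.

The minimal-penalty alignment is found by dynamic programming over
(miRNA position, window position, gaps used); for the small windows
involved this is exact.

Inhibition mode follows the central-complementarity convention: a
mismatch, wobble or gap touching miRNA positions 10-11 (the cleavage
site) calls translational repression, otherwise cleavage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import SequenceRecord


@dataclass(frozen=True)
class ScoringConfig:
    max_expectation: float = 3.0
    seed_start: int = 2        # first double-penalty miRNA position (1-based)
    seed_end: int = 13         # last double-penalty miRNA position
    max_gaps: int = 1
    gap_penalty: float = 2.0
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    t_start: int               # 1-based inclusive on the transcript
    t_end: int
    expectation: float
    alignment: tuple           # (miRNA 3'->5', match line, target 5'->3')
    mode: str = ""             # "cleavage" or "translation"
    mismatch_positions: tuple = field(default=())   # miRNA positions (1-based)

    def __post_init__(self) -> None:
        if self.expectation < 0:
            raise ValueError("expectation must be >= 0")
        a, b, c = self.alignment
        if not (len(a) == len(b) == len(c)):
            raise ValueError("alignment rows must have equal length")


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _col_penalty(m_base: str, t_base: str, cfg: ScoringConfig) -> float:
    """Penalty of pairing miRNA base with target base (both 5'->3' RNA)."""
    if (m_base, t_base) in _WC:
        return 0.0
    if (m_base, t_base) in _WOBBLE:
        return cfg.wobble_penalty
    return cfg.mismatch_penalty


def _pos_weight(mirna_pos: int, cfg: ScoringConfig) -> float:
    return 2.0 if cfg.seed_start <= mirna_pos <= cfg.seed_end else 1.0


def score_site(
    mirna: SequenceRecord,
    window: str,
    cfg: ScoringConfig = ScoringConfig(),
):
    """Minimal-penalty antiparallel alignment of a miRNA to one window.

    ``window`` is the transcript subsequence 5'->3' (DNA or RNA); its
    length must be within 4 of the mature length. Returns
    ``(expectation, alignment, mismatch_positions)`` where the alignment
    is the 3-row text block (miRNA written 3'->5' over the target
    5'->3') and mismatch positions are the 1-based miRNA positions of
    every penalized column (gap columns included).
    """
    m = mirna.as_rna().sequence          # 5'->3'
    w = window.upper().replace("T", "U")  # 5'->3'
    if abs(len(w) - len(m)) > 4:
        raise ValueError("window length outside +/-4 of the mature length")
    # Antiparallel: miRNA position k (1-based from 5') faces target base
    # counted from the window's 3' end. Work against the reversed window.
    t = w[::-1]                          # now index i faces miRNA index i
    nm, nt = len(m), len(t)
    INF = math.inf
    G = cfg.max_gaps
    # dp[g][i][j]: min penalty aligning m[:i] with t[:j] using g gaps
    dp = [[[INF] * (nt + 1) for _ in range(nm + 1)] for _ in range(G + 1)]
    dp[0][0][0] = 0.0
    for g in range(G + 1):
        for i in range(nm + 1):
            for j in range(nt + 1):
                cur = dp[g][i][j]
                if cur == INF:
                    continue
                if i < nm and j < nt:
                    pen = _col_penalty(m[i], t[j], cfg) * _pos_weight(i + 1, cfg)
                    if cur + pen < dp[g][i + 1][j + 1]:
                        dp[g][i + 1][j + 1] = cur + pen
                if g < G:
                    # gap in target: miRNA base i+1 unpaired
                    if i < nm:
                        pen = cfg.gap_penalty * _pos_weight(i + 1, cfg)
                        if cur + pen < dp[g + 1][i + 1][j]:
                            dp[g + 1][i + 1][j] = cur + pen
                    # gap in miRNA: target base unpaired, attributed to
                    # the next miRNA position from the 5' end
                    if j < nt:
                        pen = cfg.gap_penalty * _pos_weight(min(i + 1, nm), cfg)
                        if cur + pen < dp[g + 1][i][j + 1]:
                            dp[g + 1][i][j + 1] = cur + pen
    best = min(dp[g][nm][nt] for g in range(G + 1))
    if best == INF:
        raise ValueError("window not alignable within the gap limit")
    expectation, aln, mm_pos = _traceback(m, t, dp, best, cfg)
    return expectation, aln, mm_pos


def _traceback(m, t, dp, best, cfg):
    nm, nt = len(m), len(t)
    G = cfg.max_gaps
    g = next(gg for gg in range(G + 1) if dp[gg][nm][nt] == best)
    i, j = nm, nt
    cols = []  # (m_char, t_char, penalty, mirna_pos)
    while i > 0 or j > 0:
        cur = dp[g][i][j]
        if i > 0 and j > 0:
            pen = _col_penalty(m[i - 1], t[j - 1], cfg) * _pos_weight(i, cfg)
            if math.isclose(dp[g][i - 1][j - 1] + pen, cur):
                cols.append((m[i - 1], t[j - 1], pen, i))
                i, j = i - 1, j - 1
                continue
        if g > 0 and i > 0:
            pen = cfg.gap_penalty * _pos_weight(i, cfg)
            if math.isclose(dp[g - 1][i - 1][j] + pen, cur):
                cols.append((m[i - 1], "-", pen, i))
                g, i = g - 1, i - 1
                continue
        if g > 0 and j > 0:
            pen = cfg.gap_penalty * _pos_weight(min(i + 1, nm), cfg)
            if math.isclose(dp[g - 1][i][j - 1] + pen, cur):
                cols.append(("-", t[j - 1], pen, min(i + 1, nm)))
                g, j = g - 1, j - 1
                continue
        raise AssertionError("traceback failed")  # pragma: no cover
    cols.reverse()
    # cols run miRNA 5'->3'; display convention is miRNA 3'->5' on top of
    # the target 5'->3', so reverse for the text block.
    disp = cols[::-1]
    m_row = "".join(c[0] for c in disp)
    t_row = "".join(c[1] for c in disp)
    match = []
    for mc, tc, pen, _pos in disp:
        if mc == "-" or tc == "-":
            match.append(" ")
        elif (mc, tc) in _WC:
            match.append("|")
        elif (mc, tc) in _WOBBLE:
            match.append("o")
        else:
            match.append(" ")
    mm_pos = tuple(sorted(pos for _mc, _tc, pen, pos in cols if pen > 0))
    return best, (m_row, "".join(match), t_row), mm_pos


def call_mode(mismatch_positions, cleavage_sites=(10, 11)) -> str:
    """Cleavage unless a penalized column touches the central positions."""
    return (
        "translation"
        if any(p in cleavage_sites for p in mismatch_positions)
        else "cleavage"
    )


def scan_targets(
    mirnas: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    cfg: ScoringConfig = ScoringConfig(),
) -> list[TargetSite]:
    """Score every transcript window against every miRNA.

    Window lengths ``mature-1 .. mature+1`` are scanned (one gap shifts
    the footprint by at most one base). Sites with expectation <=
    ``cfg.max_expectation`` are kept; overlapping sites of the same
    (miRNA, transcript) pair collapse to the lowest-expectation one
    (ties: leftmost).
    """
    sites: list[TargetSite] = []
    for mir in mirnas:
        mlen = len(mir.sequence)
        lengths = {mlen}
        if cfg.max_gaps > 0:
            lengths |= {mlen - 1, mlen + 1}
        for tx in transcripts:
            seq = tx.as_rna().sequence
            found = []
            for wlen in sorted(lengths):
                if wlen < 1:
                    continue
                for start in range(0, len(seq) - wlen + 1):
                    window = seq[start:start + wlen]
                    exp, aln, mm = score_site(mir, window, cfg)
                    if exp <= cfg.max_expectation:
                        found.append(
                            TargetSite(
                                mirna_id=mir.id,
                                transcript_id=tx.id,
                                t_start=start + 1,
                                t_end=start + wlen,
                                expectation=exp,
                                alignment=aln,
                                mode=call_mode(mm),
                                mismatch_positions=mm,
                            )
                        )
            sites.extend(_collapse_overlaps(found))
    return sorted(
        sites, key=lambda s: (s.mirna_id, s.transcript_id, s.t_start)
    )


def _collapse_overlaps(found: list[TargetSite]) -> list[TargetSite]:
    found = sorted(found, key=lambda s: (s.expectation, s.t_start, s.t_end))
    kept: list[TargetSite] = []
    for s in found:
        if any(
            s.t_start <= k.t_end and k.t_start <= s.t_end for k in kept
        ):
            continue
        kept.append(s)
    return kept
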
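"""Precursor extraction, secondary-structure folding, hairpin statistics.

Candidate loci from the homology scan are widened by 50-nt flanks on the
hit strand to form precursor candidates (so a 21-nt mature yields a 121-nt
precursor, a 20-nt mature a 120-nt one, when no unit boundary truncates a
flank). Each candidate is folded by a pluggable engine and summarized by
the standard pre-miRNA hairpin statistics:

* ``gc_percent``  — 100*(G+C)/length
* ``au_percent``  — 100 - gc_percent
* ``mfe``         — minimum free energy, kcal/mol (negative when structured)
* ``amfe``        — adjusted MFE, mfe/length*100 (per 100 nt)
* ``mfei``        — minimal folding free energy index, amfe/gc_percent

MFEI is the classic discriminator: genuine pre-miRNA hairpins fold more
stably per GC unit than bulk transcripts.

Two fold engines are provided. ``BuiltinFoldEngine`` is a self-contained
energy-minimization over nested structures scoring only base-pair stacks
(Watson-Crick and G:U, minimum hairpin loop 3, no dangling ends); it has
no external dependencies and is deterministic. ``ViennaFoldEngine`` wraps
the ViennaRNA bindings (37 degC Turner parameters) when they are
installed. All downstream arithmetic consumes whatever MFE the chosen
engine reports, so the statistics above are engine-agnostic by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .homology_scan import HomologHit, revcomp
from .io_formats import DotBracket, validate_dotbracket

MIN_LOOP = 3

# Pair stabilities for the simplified stacking model (kcal/mol-ish units):
# a stack of two adjacent pairs contributes -(strength(p1)+strength(p2))/2.
_PAIR_STRENGTH = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


class RejectedCandidate(Exception):
    """Precursor extraction could not satisfy the flank requirement."""


@dataclass(frozen=True)
class PrecursorCandidate:
    id: str
    sequence: str                    # RNA alphabet
    mature_start: int                # 1-based inclusive within precursor
    mature_end: int
    source_hit: Optional[HomologHit] = None

    def __post_init__(self) -> None:
        if not (1 <= self.mature_start <= self.mature_end <= len(self.sequence)):
            raise ValueError("mature coordinates outside precursor")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start - 1:self.mature_end]


@dataclass(frozen=True)
class FoldResult:
    structure: DotBracket
    mfe: float

    def __post_init__(self) -> None:
        if self.structure.n_pairs == 0 and self.mfe != 0.0:
            raise ValueError("unstructured fold must have mfe 0")


@dataclass(frozen=True)
class HairpinStats:
    precursor_length: int
    gc_percent: float
    au_percent: float
    mfe: float
    amfe: float
    mfei: float


def extract_precursor(
    hit: HomologHit, units, flank: int = 50, min_flank: int = 20
) -> PrecursorCandidate:
    """Extract mature +/- ``flank`` nt on the hit strand.

    Flanks are truncated at unit boundaries; if either surviving flank is
    shorter than ``min_flank``, the candidate is rejected (the hairpin
    arm opposite the mature could not be contained).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    unit = units[hit.unit_id] if not hasattr(units, "units") else units.units[hit.unit_id]
    seq = unit.sequence.upper()
    lo = hit.unit_start - 1
    hi = hit.unit_end
    ext_lo = max(lo - flank, 0)
    ext_hi = min(hi + flank, len(seq))
    left = lo - ext_lo
    right = ext_hi - hi
    if left < min_flank or right < min_flank:
        raise RejectedCandidate(
            f"{hit.mirna_id}@{hit.unit_id}: flank truncated to "
            f"({left}, {right}) < {min_flank}"
        )
    region = seq[ext_lo:ext_hi]
    if hit.strand == "-":
        region = revcomp(region)
        m_start = right + 1
    else:
        m_start = left + 1
    m_end = m_start + hit.aligned_length - 1
    return PrecursorCandidate(
        id=f"{hit.mirna_id}|{hit.unit_id}|{hit.unit_start}{hit.strand}",
        sequence=region.replace("T", "U"),
        mature_start=m_start,
        mature_end=m_end,
        source_hit=hit,
    )


def _stack_energy(s: str, i: int, j: int) -> float:
    return -(_PAIR_STRENGTH[(s[i], s[j])] + _PAIR_STRENGTH[(s[i + 1], s[j - 1])]) / 2.0


class BuiltinFoldEngine:
    """Minimum-energy nested folding scoring base-pair stacks only.

    Energy model: each pair of directly stacked base pairs (i,j)/(i+1,j-1)
    contributes the mean stability of the two pairs, negated (G:C 3.0,
    A:U 2.0, G:U 1.0). Isolated pairs contribute nothing and are omitted
    from the traceback. Hairpin loops must span at least three unpaired
    bases. O(n^3) dynamic program; adequate for precursor-scale inputs.
    """

    name = "builtin"

    def fold(self, sequence: str) -> FoldResult:
        s = sequence.upper().replace("T", "U")
        n = len(s)
        if n == 0:
            raise ValueError("empty sequence")
        pairable = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + MIN_LOOP + 1, n):
                if (s[i], s[j]) in _PAIR_STRENGTH:
                    pairable[i, j] = True
        INF = math.inf
        # W[a, b]: min energy over interval [a, b]; 0 when a > b.
        W = np.zeros((n + 1, n + 1))
        V = np.full((n, n), INF)
        for L in range(MIN_LOOP + 2, n + 1):
            for i in range(0, n - L + 1):
                j = i + L - 1
                if pairable[i, j]:
                    v = W[i + 1, j - 1]
                    if j - i >= MIN_LOOP + 3 and pairable[i + 1, j - 1] \
                            and V[i + 1, j - 1] < INF:
                        v = min(v, V[i + 1, j - 1] + _stack_energy(s, i, j))
                    V[i, j] = v
                w = W[i + 1, j]
                ks = np.flatnonzero(pairable[i, i:j + 1]) + i
                if ks.size:
                    cand = V[i, ks] + W[ks + 1, j]
                    w = min(w, cand.min())
                W[i, j] = w
        pairs = self._traceback(s, W, V, pairable, n)
        struct = ["."] * n
        kept = []
        pairset = set(pairs)
        for (i, j) in pairs:
            # drop isolated (zero-energy) pairs
            if (i + 1, j - 1) in pairset or (i - 1, j + 1) in pairset:
                kept.append((i, j))
        for (i, j) in kept:
            struct[i], struct[j] = "(", ")"
        mfe = float(W[0, n - 1])
        if not kept:
            return FoldResult(DotBracket("." * n), 0.0)
        return FoldResult(validate_dotbracket("".join(struct)), round(mfe, 2))

    def _traceback(self, s, W, V, pairable, n):
        pairs = []
        stack = [("W", 0, n - 1)]
        while stack:
            kind, i, j = stack.pop()
            if i >= j:
                continue
            if kind == "W":
                # prefer the pair-free branch on ties: avoids isolated pairs
                if W[i, j] == W[i + 1, j]:
                    stack.append(("W", i + 1, j))
                    continue
                done = False
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if pairable[i, k] and math.isclose(
                        W[i, j], V[i, k] + W[k + 1, j]
                    ):
                        stack.append(("V", i, k))
                        stack.append(("W", k + 1, j))
                        done = True
                        break
                if not done:
                    stack.append(("W", i + 1, j))
            else:  # V: (i, j) is paired
                pairs.append((i, j))
                if (
                    j - i >= MIN_LOOP + 3
                    and pairable[i + 1, j - 1]
                    and V[i + 1, j - 1] < math.inf
                    and math.isclose(
                        V[i, j], V[i + 1, j - 1] + _stack_energy(s, i, j)
                    )
                ):
                    stack.append(("V", i + 1, j - 1))
                else:
                    stack.append(("W", i + 1, j - 1))
        return pairs


class ViennaFoldEngine:
    """Thermodynamic folding through the ViennaRNA bindings (37 degC)."""

    name = "vienna"

    def __init__(self):
        import RNA  # deferred: optional dependency
        self._RNA = RNA

    def fold(self, sequence: str) -> FoldResult:
        s = sequence.upper().replace("T", "U")
        struct, mfe = self._RNA.fold(s)
        if "(" not in struct:
            return FoldResult(DotBracket("." * len(s)), 0.0)
        return FoldResult(validate_dotbracket(struct), round(float(mfe), 2))


def get_engine(name: str = "auto"):
    """Resolve a fold engine: ``builtin``, ``vienna``, or ``auto``
    (vienna when importable, else builtin)."""
    if name == "builtin":
        return BuiltinFoldEngine()
    if name == "vienna":
        return ViennaFoldEngine()
    if name == "auto":
        try:
            return ViennaFoldEngine()
        except ImportError:
            return BuiltinFoldEngine()
    raise ValueError(f"unknown fold engine {name!r}")


def fold_hairpin(p: PrecursorCandidate, engine=None) -> FoldResult:
    """Fold a precursor candidate with the given engine (default auto)."""
    engine = engine or get_engine("auto")
    return engine.fold(p.sequence)


def hairpin_stats(p, f: FoldResult) -> HairpinStats:
    """Compute the hairpin statistics from a precursor and its fold.

    ``p`` may be a PrecursorCandidate or any object with a ``sequence``
    attribute. Values are returned at full precision; use
    :func:`round_half_away` for 2-decimal display.
    """
    seq = p.sequence.upper() if hasattr(p, "sequence") else str(p).upper()
    n = len(seq)
    gc = 100.0 * (seq.count("G") + seq.count("C")) / n
    if gc == 0.0 and f.mfe != 0.0:
        raise ZeroDivisionError("MFEI undefined for zero GC content")
    amfe = f.mfe / n * 100.0
    mfei = amfe / gc if gc > 0 else 0.0
    return HairpinStats(
        precursor_length=n,
        gc_percent=gc,
        au_percent=100.0 - gc,
        mfe=f.mfe,
        amfe=amfe,
        mfei=mfei,
    )


def stats_from_values(length: int, gc_percent: float, mfe: float) -> HairpinStats:
    """Hairpin statistics from already-measured (length, GC%, MFE)."""
    if gc_percent <= 0:
        raise ZeroDivisionError("MFEI undefined for zero GC content")
    amfe = mfe / length * 100.0
    return HairpinStats(
        precursor_length=length,
        gc_percent=gc_percent,
        au_percent=100.0 - gc_percent,
        mfe=mfe,
        amfe=amfe,
        mfei=amfe / gc_percent,
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for the statistics).

    Works on the decimal representation, so 0.615 -> 0.62 even though the
    nearest binary double sits just below the tie.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )
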
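"""Breakage-fusion-bridge simulation and count-vector inference.

A BFB cycle acting on a signed segment string truncates the string at a
segment boundary and appends the inversion of the retained prefix,
emitting one fold-back junction per cycle.  Count vectors (per-segment
copy counts, centromere to telomere) are tested for BFB achievability by
a pruned search over reachable strings; observed real-valued vectors are
matched to the most likely achievable integer vector under an independent
per-segment Poisson model.

The search is bounded (configurable cycle/count caps); when the cycle
bound is hit before a decision the result is reported as undecided, never
silently negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence, Union

import numpy as np

from .rearrangements import Breakend, FoldBack, Junction

__all__ = [
    "BFBString",
    "CountVector",
    "BFBCall",
    "simulate_bfb",
    "check_bfb_string",
    "is_bfb_count_vector",
    "enumerate_bfb_strings",
    "nearest_bfb_poisson",
    "bfb_confidence",
    "reconstruct_amplicon",
    "UNDECIDED",
    "DEFAULT_MAX_CYCLES",
    "DEFAULT_HOMOLOG_BASELINE",
]

DEFAULT_MAX_CYCLES = 12
DEFAULT_HOMOLOG_BASELINE = 1.0
HIGH_CONFIDENCE_MIN_SEGMENTS = 8
_ZERO_RATE_FLOOR_LOGP = -30.0

UNDECIDED = "undecided"
Decision = Union[bool, Literal["undecided"]]


def _invert(symbols: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-x for x in reversed(symbols))


@dataclass(frozen=True)
class BFBString:
    """Signed segment string plus the cycle history that produced it."""

    symbols: tuple[int, ...]
    cycles: int = 0
    break_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.break_positions) != self.cycles:
            raise ValueError("one break position per cycle required")
        if not self.symbols:
            raise ValueError("empty BFB string")

    @property
    def n_segments(self) -> int:
        return max(abs(x) for x in self.symbols)

    def count_vector(self, n_segments: Optional[int] = None) -> "CountVector":
        k = n_segments or self.n_segments
        counts = [0] * k
        for x in self.symbols:
            counts[abs(x) - 1] += 1
        return CountVector(tuple(counts))


@dataclass(frozen=True)
class CountVector:
    """Per-segment copy counts, ordered centromere -> telomere."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("count vector needs at least one segment")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def n_segments(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts)


def _reference(k: int) -> tuple[int, ...]:
    return tuple(range(1, k + 1))


def _apply_cycle(symbols: tuple[int, ...], p: int) -> tuple[int, ...]:
    """Truncate after the first ``p`` symbols and append the inverted
    retained prefix."""
    if not (1 <= p <= len(symbols)):
        raise ValueError(
            f"break index {p} invalid for string of length {len(symbols)}"
        )
    u = symbols[:p]
    return u + _invert(u)


@dataclass
class SimulatedBFB:
    string: BFBString
    count_vector: CountVector
    foldbacks: list[FoldBack]
    telomeric_loss: bool


def simulate_bfb(
    n_segments: int,
    n_cycles: int,
    breaks: Union[Sequence[int], Callable[[np.random.Generator, int], int], None] = None,
    seed: Optional[int] = None,
    boundaries: Optional[Sequence[int]] = None,
    chrom: str = "chr8",
    support: int = 20,
) -> SimulatedBFB:
    """Run ``n_cycles`` BFB cycles from the reference string 1..k.

    ``breaks`` may be explicit 1-based boundary indices (one per cycle), a
    sampler ``f(rng, current_length) -> index``, or None for uniform
    sampling.  ``boundaries`` maps segment i to the genomic interval
    [boundaries[i-1], boundaries[i]); fold-back junctions are emitted at
    the boundary coordinate implied by each cycle's break.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if boundaries is None:
        boundaries = [i * 1_000_000 for i in range(n_segments + 1)]
    if len(boundaries) != n_segments + 1:
        raise ValueError("need n_segments + 1 boundary coordinates")
    rng = np.random.default_rng(seed)
    symbols = _reference(n_segments)
    break_positions: list[int] = []
    foldbacks: list[FoldBack] = []
    telomeric_loss = False
    for cycle in range(n_cycles):
        if isinstance(breaks, Sequence):
            p = breaks[cycle]
        elif callable(breaks):
            p = breaks(rng, len(symbols))
        else:
            p = int(rng.integers(1, len(symbols) + 1))
        if not (1 <= p <= len(symbols)):
            raise ValueError(
                f"cycle {cycle}: break index {p} invalid for length {len(symbols)}"
            )
        if p < len(symbols):
            telomeric_loss = True
        last = symbols[p - 1]
        if last > 0:
            # forward copy meets its inversion at the segment's genomic end:
            # both flanks at lower coordinates are retained (tail-to-tail)
            coord = boundaries[last]
            side = "left"
        else:
            coord = boundaries[-last - 1]
            side = "right"
        j = Junction(
            Breakend(chrom, coord, side),
            Breakend(chrom, coord, side),
            support=support,
            name=f"bfb_cycle_{cycle + 1}",
        )
        foldbacks.append(FoldBack(j))
        symbols = _apply_cycle(symbols, p)
        break_positions.append(p)
    s = BFBString(symbols, cycles=n_cycles, break_positions=tuple(break_positions))
    return SimulatedBFB(
        string=s,
        count_vector=s.count_vector(n_segments),
        foldbacks=foldbacks,
        telomeric_loss=telomeric_loss,
    )


def check_bfb_string(s: Union[BFBString, Sequence[int]]) -> bool:
    """True iff the string is reachable from a reference 1..k by BFB cycles.

    Verified structurally: a non-reference BFB string decomposes as
    u + inv(u) where u is a prefix of a reachable string.
    """
    symbols = tuple(s.symbols if isinstance(s, BFBString) else s)

    def ascending(u: tuple[int, ...]) -> bool:
        return u == _reference(len(u))

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def prefix_reachable(u: tuple[int, ...]) -> bool:
        if ascending(u):
            return True
        n = len(u)
        for m in range((n + 1) // 2, n):
            w = u[:m]
            if u[m:] == _invert(w)[: n - m] and prefix_reachable(w):
                return True
        return False

    if ascending(symbols):
        return True
    n = len(symbols)
    if n % 2:
        return False
    half = symbols[: n // 2]
    return symbols[n // 2 :] == _invert(half) and prefix_reachable(half)


def enumerate_bfb_strings(
    caps: Sequence[int],
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> dict[tuple[int, ...], BFBString]:
    """All reachable strings whose per-segment counts never exceed ``caps``.

    Returns a map from string symbols to a BFBString carrying the
    (shortest) cycle history found.  The reference string is always
    included even where caps are zero, since segments can only disappear
    through a first truncating cycle.
    """
    k = len(caps)
    ref = _reference(k)
    seen: dict[tuple[int, ...], BFBString] = {
        ref: BFBString(ref, 0, ())
    }
    frontier = [seen[ref]]
    for _ in range(max_cycles):
        new: list[BFBString] = []
        for s in frontier:
            for p in range(1, len(s.symbols) + 1):
                t = _apply_cycle(s.symbols, p)
                counts = [0] * k
                ok = True
                for x in t:
                    i = abs(x) - 1
                    counts[i] += 1
                    if counts[i] > caps[i]:
                        ok = False
                        break
                if not ok or t in seen:
                    continue
                child = BFBString(
                    t, s.cycles + 1, s.break_positions + (p,)
                )
                seen[t] = child
                new.append(child)
        frontier = new
        if not frontier:
            break
    return seen


def is_bfb_count_vector(
    n: Union[CountVector, Sequence[int]],
    max_cycles: int = DEFAULT_MAX_CYCLES,
    count_slack: int = 2,
) -> Decision:
    """Decide whether an integer count vector is exactly achievable by BFB.

    Pruned search over reachable strings with per-segment count caps of
    ``target + count_slack``.  Returns True/False when the bounded search
    is conclusive; returns ``UNDECIDED`` when the cycle bound was reached
    with live branches and no witness was found.
    """
    counts = tuple(n.counts if isinstance(n, CountVector) else n)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    k = len(counts)
    ref = _reference(k)
    target_caps = [c + count_slack if c > 0 else count_slack for c in counts]
    if counts == tuple(1 for _ in counts):
        return True

    seen = {ref}
    frontier = [ref]
    cycles = 0
    while frontier and cycles < max_cycles:
        cycles += 1
        new = []
        for s in frontier:
            for p in range(1, len(s) + 1):
                t = _apply_cycle(s, p)
                c = [0] * k
                ok = True
                for x in t:
                    i = abs(x) - 1
                    c[i] += 1
                    if c[i] > target_caps[i]:
                        ok = False
                        break
                if not ok or t in seen:
                    continue
                if tuple(c) == counts:
                    return True
                seen.add(t)
                new.append(t)
        frontier = new
    if frontier:
        # cycle bound hit with live branches: inconclusive
        return UNDECIDED
    return False


# -- Poisson matching -------------------------------------------------------


@dataclass
class BFBCall:
    """Result of matching an observed count vector to a BFB model."""

    observed: tuple[float, ...]
    approximation: Optional[CountVector]
    log_poisson_likelihood: float
    n_segments_in_approximation: int
    foldback_support: bool
    telomeric_loss: bool
    confidence: str = "ambiguous"
    string: Optional[BFBString] = None

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "approximation": (
                None if self.approximation is None else list(self.approximation.counts)
            ),
            "log_poisson_likelihood": self.log_poisson_likelihood,
            "n_segments_in_approximation": self.n_segments_in_approximation,
            "foldback_support": self.foldback_support,
            "telomeric_loss": self.telomeric_loss,
            "confidence": self.confidence,
            "string": None if self.string is None else list(self.string.symbols),
        }


def _log_poisson(x: float, lam: int) -> float:
    if lam == 0:
        return 0.0 if round(x) == 0 else _ZERO_RATE_FLOOR_LOGP
    return x * math.log(lam) - lam - math.lgamma(x + 1.0)


def nearest_bfb_poisson(
    observed: Sequence[float],
    baseline: float = DEFAULT_HOMOLOG_BASELINE,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    count_cap: Optional[int] = None,
    substring: bool = False,
    foldback_support: bool = False,
    telomeric_loss: bool = False,
) -> BFBCall:
    """Most likely BFB-achievable integer vector for an observed vector.

    The configurable homolog ``baseline`` (default one copy) is subtracted
    and clamped at zero before matching.  The achievable vector maximizing
    the summed per-segment log Poisson likelihood within the search bounds
    wins; ties break by fewer cycles, then lexicographically smaller
    string.  With ``substring`` the observation may match any contiguous
    sub-vector of an achievable vector.
    """
    obs = tuple(float(x) for x in observed)
    adj = tuple(max(0.0, x - baseline) for x in obs)
    k = len(adj)
    if all(round(x) == 0 for x in adj):
        # degenerate full-loss observation: the all-zero vector is the
        # unique zero-distance answer, reported without a cycle history
        call = BFBCall(
            observed=obs,
            approximation=CountVector(tuple(0 for _ in adj)),
            log_poisson_likelihood=0.0,
            n_segments_in_approximation=k,
            foldback_support=foldback_support,
            telomeric_loss=telomeric_loss,
        )
        call.confidence = bfb_confidence(call)
        return call
    if count_cap is None:
        count_cap = int(math.ceil(max(adj))) + 2 if max(adj) > 0 else 2
    caps = [count_cap] * k
    strings = enumerate_bfb_strings(caps, max_cycles=max_cycles)

    best = None  # (loglik, cycles, symbols, counts_tuple, string)
    for sym, bstr in strings.items():
        cv = bstr.count_vector(k)
        candidates = [cv.counts]
        if substring:
            base = cv.counts
            candidates = [base[i : i + k] for i in range(0, len(base) - k + 1)]
        for cand in candidates:
            if len(cand) != k:
                continue
            ll = sum(_log_poisson(x, lam) for x, lam in zip(adj, cand))
            key = (-ll, bstr.cycles, sym)
            if best is None or key < best[0]:
                best = (key, ll, cand, bstr)

    if best is None:
        return BFBCall(
            observed=obs,
            approximation=None,
            log_poisson_likelihood=float("-inf"),
            n_segments_in_approximation=0,
            foldback_support=foldback_support,
            telomeric_loss=telomeric_loss,
            confidence="excluded",
        )
    _, ll, cand, bstr = best
    call = BFBCall(
        observed=obs,
        approximation=CountVector(tuple(cand)),
        log_poisson_likelihood=ll,
        n_segments_in_approximation=len(cand),
        foldback_support=foldback_support,
        telomeric_loss=telomeric_loss,
        string=bstr,
    )
    call.confidence = bfb_confidence(call)
    return call


def bfb_confidence(call: BFBCall) -> str:
    """Classify a BFB call.

    high: approximation with at least 8 segments and fold-back support;
    ambiguous: fewer than 8 segments and/or no fold-back support;
    excluded: no BFB approximation exists within the search bounds.
    Telomeric loss is reported as metadata, not gated on.
    """
    if call.approximation is None:
        return "excluded"
    if (
        call.n_segments_in_approximation >= HIGH_CONFIDENCE_MIN_SEGMENTS
        and call.foldback_support
    ):
        return "high"
    return "ambiguous"


# -- amplicon reconstruction ------------------------------------------------


def reconstruct_amplicon(
    foldbacks: Iterable[FoldBack],
    observed_counts: Sequence[int],
    boundaries: Sequence[int],
    max_cycles: Optional[int] = None,
) -> list[BFBString]:
    """BFB strings consistent with the observed fold-backs and counts.

    ``boundaries`` maps segment i to [boundaries[i-1], boundaries[i]), as
    in :func:`simulate_bfb`.  Candidate strings must use exactly the
    observed fold-back positions (as a multiset of break coordinates) and
    reproduce the observed count vector; results are ranked by Poisson
    likelihood of the observation given the string (exact matches tie at
    the maximum and are ordered by cycle count, then lexicographically).
    """
    foldbacks = list(foldbacks)
    counts = tuple(int(c) for c in observed_counts)
    k = len(counts)
    if len(boundaries) != k + 1:
        raise ValueError("need k + 1 boundary coordinates")
    n_cycles = len(foldbacks)
    if max_cycles is not None and n_cycles > max_cycles:
        return []

    from collections import Counter

    remaining = Counter(fb.junction.a.pos for fb in foldbacks)
    found: dict[tuple[int, ...], BFBString] = {}

    # depth is fixed at the observed fold-back count and every cycle must
    # consume an observed fold-back coordinate, so the search tree stays
    # small without count-based pruning (intermediates may legitimately
    # overshoot the final counts before a later truncation)

    def dfs(sym: tuple[int, ...], depth: int, history: tuple[int, ...]) -> None:
        if depth == n_cycles:
            cv = [0] * k
            for x in sym:
                cv[abs(x) - 1] += 1
            if tuple(cv) == counts and sym not in found:
                found[sym] = BFBString(sym, n_cycles, history)
            return
        for p in range(1, len(sym) + 1):
            last = sym[p - 1]
            coord = boundaries[last] if last > 0 else boundaries[-last - 1]
            if remaining[coord] <= 0:
                continue
            t = _apply_cycle(sym, p)
            remaining[coord] -= 1
            dfs(t, depth + 1, history + (p,))
            remaining[coord] += 1

    dfs(_reference(k), 0, ())
    # exact matches tie at the maximal Poisson likelihood; order by cycle
    # count then lexicographically for a deterministic ranking
    matches = sorted(found.items(), key=lambda kv: (kv[1].cycles, kv[0]))
    return [bstr for _, bstr in matches]
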
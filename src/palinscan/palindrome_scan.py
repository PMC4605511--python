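"""Detection of peptide palindromes (PALINs) in protein chain sequences.

A PALIN is a contiguous window of at least ``min_len`` residues that reads
identically in both directions at the character level (no complementation).
Windows are enumerated by sliding one residue at a time over every allowed
length; each self-palindromic window is reported exactly once (the
probe/target duplicate of the sliding-search formulation is collapsed).

Filters mirror the survey protocol: continuous single-amino-acid repeats
(CARPs, e.g. ``AAAAA``) are excluded, as are windows touching residues with
missing heavy atoms or nonstandard residues ('X'); exact positional
duplicates are dropped.  Matched non-palindrome control windows ("non-PALINs")
of identical length are sampled from the same chain set for the comparison
series.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .structure_io import ChainSequence

__all__ = [
    "ScanConfig",
    "PalindromeHit",
    "ControlWindow",
    "is_palindrome",
    "enumerate_palindromes",
    "filter_hits",
    "unique_sequences",
    "sample_control_windows",
    "scan_chain",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScanConfig:
    """Scan parameters.

    min_len/max_len bound the window lengths considered (survey range 5–9);
    ``max_len=None`` means unlimited.  ``maximal_only`` drops windows whose
    interval is properly contained in another palindromic window (off by
    default: co-centered sub-palindromes are genuine hits).
    """

    min_len: int = 5
    max_len: Optional[int] = 9
    exclude_carp: bool = True
    require_complete: bool = True
    maximal_only: bool = False
    seed: int = 0
    max_control_retries: int = 10_000

    def __post_init__(self) -> None:
        if self.min_len < 3:
            raise ValueError("min_len must be >= 3")
        if self.max_len is not None and self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


@dataclass
class PalindromeHit:
    pdb_id: str
    chain_id: str
    start_index: int          # 0-based offset into the chain sequence
    sequence: str
    start_pos: tuple[int, str] = (0, "")   # author number + insertion code
    end_pos: tuple[int, str] = (0, "")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end_index(self) -> int:
        """Half-open end offset."""
        return self.start_index + len(self.sequence)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_index, self.end_index)

    @property
    def location(self) -> str:
        """Author-numbered 1-based inclusive interval, e.g. ``167-171``."""
        s = f"{self.start_pos[0]}{self.start_pos[1]}"
        e = f"{self.end_pos[0]}{self.end_pos[1]}"
        return f"{s}-{e}"


@dataclass
class ControlWindow:
    pdb_id: str
    chain_id: str
    start_index: int
    sequence: str
    start_pos: tuple[int, str] = (0, "")
    end_pos: tuple[int, str] = (0, "")
    is_palindrome: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end_index(self) -> int:
        return self.start_index + len(self.sequence)


def is_palindrome(seq: str) -> bool:
    """True iff ``seq`` equals its reversal, character-exact.

    'X' (nonstandard residue) never matches anything, itself included, so a
    window containing 'X' is never palindromic.
    """
    if not seq:
        raise ValueError("empty sequence")
    return "X" not in seq and seq == seq[::-1]


def _positions(chain: ChainSequence, start: int, length: int
               ) -> tuple[tuple[int, str], tuple[int, str]]:
    return chain.residue_index[start], chain.residue_index[start + length - 1]


def enumerate_palindromes(chain: ChainSequence, cfg: ScanConfig | None = None
                          ) -> list[PalindromeHit]:
    """Every palindromic window of an allowed length, before filters.

    Windows are produced by sliding one residue at a time for each length;
    output is sorted by (start_index, length) and each window appears once.
    """
    cfg = cfg or ScanConfig()
    seq = chain.sequence
    n = len(seq)
    max_len = min(cfg.max_len if cfg.max_len is not None else n, n)
    hits: list[PalindromeHit] = []
    for i in range(n):
        for L in range(cfg.min_len, max_len + 1):
            if i + L > n:
                break
            window = seq[i:i + L]
            if window != window[::-1] or "X" in window:
                continue
            sp, ep = _positions(chain, i, L)
            hits.append(PalindromeHit(pdb_id=chain.pdb_id,
                                      chain_id=chain.chain_id,
                                      start_index=i, sequence=window,
                                      start_pos=sp, end_pos=ep))
    if cfg.maximal_only:
        hits = [h for h in hits
                if not any(o is not h
                           and o.start_index <= h.start_index
                           and o.end_index >= h.end_index
                           for o in hits)]
    return hits


def filter_hits(hits: Iterable[PalindromeHit], chain: ChainSequence,
                cfg: ScanConfig | None = None,
                exclusion_log: list | None = None) -> list[PalindromeHit]:
    """Apply the survey's exclusion rules to hits from one chain.

    Removes CARPs (all residues identical), windows touching incomplete or
    nonstandard residues, and exact positional duplicates; order preserved.
    ``exclusion_log`` (optional) collects ``(hit, reason)`` pairs.
    """
    cfg = cfg or ScanConfig()
    seen: set[tuple[int, int]] = set()
    kept: list[PalindromeHit] = []
    for hit in hits:
        if hit.start_index < 0 or hit.end_index > len(chain):
            raise ValueError(
                f"hit {hit.sequence} at [{hit.start_index}, {hit.end_index}) "
                f"outside chain of length {len(chain)}")
        reason = None
        window_letters = chain.sequence[hit.start_index:hit.end_index]
        if cfg.exclude_carp and len(set(hit.sequence)) == 1:
            reason = "CARP"
        elif "X" in window_letters:
            reason = "nonstandard residue"
        elif cfg.require_complete and not all(
                chain.complete_mask[hit.start_index:hit.end_index]):
            reason = "missing atoms"
        elif hit.interval in seen:
            reason = "duplicate"
        if reason is None:
            seen.add(hit.interval)
            kept.append(hit)
        elif exclusion_log is not None:
            exclusion_log.append((hit, reason))
    return kept


def scan_chain(chain: ChainSequence, cfg: ScanConfig | None = None,
               exclusion_log: list | None = None) -> list[PalindromeHit]:
    """enumerate_palindromes followed by filter_hits."""
    cfg = cfg or ScanConfig()
    return filter_hits(enumerate_palindromes(chain, cfg), chain, cfg,
                       exclusion_log=exclusion_log)


def unique_sequences(hits: Iterable[PalindromeHit]
                     ) -> dict[int, Counter]:
    """Unique palindrome strings per length, with multiplicities.

    A sequence observed at k locations across the dataset counts once as a
    unique string; the Counter records k.
    """
    out: dict[int, Counter] = {}
    for hit in hits:
        out.setdefault(hit.length, Counter())[hit.sequence] += 1
    return out


def sample_control_windows(chains: list[ChainSequence],
                           hits: list[PalindromeHit],
                           cfg: ScanConfig | None = None
                           ) -> list[ControlWindow]:
    """One matched non-palindrome window per hit (the non-PALIN set).

    For each hit a window of identical length is drawn uniformly at random
    (seeded) over valid placements in the chain set: not palindromic, passing
    the same completeness filter, and not coinciding positionally with any
    hit.  Sampling is with replacement across chains.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(cfg.seed)
    hit_intervals = {(h.pdb_id, h.chain_id, h.start_index, h.length)
                     for h in hits}
    controls: list[ControlWindow] = []
    for hit in hits:
        L = hit.length
        eligible = [c for c in chains if len(c) >= L]
        if not eligible:
            raise RuntimeError(f"no chain long enough for a length-{L} control")
        placed = False
        for _ in range(cfg.max_control_retries):
            chain = eligible[int(rng.integers(len(eligible)))]
            start = int(rng.integers(len(chain) - L + 1))
            window = chain.sequence[start:start + L]
            if "X" in window:
                continue
            if window == window[::-1]:
                continue
            if cfg.require_complete and not all(
                    chain.complete_mask[start:start + L]):
                continue
            if (chain.pdb_id, chain.chain_id, start, L) in hit_intervals:
                continue
            sp, ep = _positions(chain, start, L)
            controls.append(ControlWindow(pdb_id=chain.pdb_id,
                                          chain_id=chain.chain_id,
                                          start_index=start, sequence=window,
                                          start_pos=sp, end_pos=ep))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a length-{L} non-palindrome control after "
                f"{cfg.max_control_retries} draws; chain set too small or "
                "too palindromic")
    return controls
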
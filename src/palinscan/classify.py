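"""Classification of palindrome hits.

Secondary-structure category: a hit is *helix* when a strict majority
(> 50%) of its residues carry helix codes, *strand* likewise for strand
codes, *coil* only when every residue is 'C', otherwise *irregular* (turns,
bends, mixtures).  Which codes count as helix (H alone, or H+G) and strand
(E alone, or E+B) and the majority fraction are parameters, since surveys
differ in how they collapse the eight-letter alphabet.

Occurrence modes on one chain: *nested* (interval containment), *overlapping*
(partial intersection), *consecutive* (exact adjacency), *repeated* (same
sequence at disjoint locations).  *Chameleon* groups collect identical
sequences observed with different categories across the dataset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SSCategoryRule",
    "ModeAnnotation",
    "ChameleonGroup",
    "ss_category",
    "detect_modes",
    "find_chameleons",
    "family_distribution",
    "CATEGORIES",
]

CATEGORIES = ("helix", "strand", "coil", "irregular")


@dataclass(frozen=True)
class SSCategoryRule:
    majority: float = 0.5          # strict: fraction must exceed this
    helix_codes: frozenset = frozenset("H")
    strand_codes: frozenset = frozenset("E")
    include_g_in_helix: bool = False
    include_b_in_strand: bool = False

    def effective_helix(self) -> frozenset:
        return self.helix_codes | (frozenset("G") if self.include_g_in_helix
                                   else frozenset())

    def effective_strand(self) -> frozenset:
        return self.strand_codes | (frozenset("B") if self.include_b_in_strand
                                    else frozenset())


def ss_category(ss: str, rule: SSCategoryRule | None = None) -> str:
    """Assign exactly one of helix/strand/coil/irregular to an SS string.

    Helix is checked before strand; under a strict majority both cannot hold.
    Coil requires every residue 'C'.  '-' codes violate the precondition
    (hits over residues without coordinates are excluded upstream).
    """
    if not ss:
        raise ValueError("empty secondary-structure string")
    if "-" in ss:
        raise ValueError("SS string contains '-' (missing coordinates); "
                         "such hits must be excluded before classification")
    rule = rule or SSCategoryRule()
    n = len(ss)
    helix_frac = sum(c in rule.effective_helix() for c in ss) / n
    strand_frac = sum(c in rule.effective_strand() for c in ss) / n
    if helix_frac > rule.majority:
        return "helix"
    if strand_frac > rule.majority:
        return "strand"
    if all(c == "C" for c in ss):
        return "coil"
    return "irregular"


@dataclass
class ModeAnnotation:
    nested_in: Optional[object] = None          # innermost enclosing hit
    overlaps: list = field(default_factory=list)
    consecutive_with: list = field(default_factory=list)
    repeat_group: Optional[str] = None

    @property
    def is_nested(self) -> bool:
        return self.nested_in is not None


def detect_modes(hits: Sequence) -> dict[int, ModeAnnotation]:
    """Pairwise occurrence modes for hits of one chain, keyed by position in
    the (start-sorted) input.

    Containment must be proper (equal intervals are duplicates, not nesting);
    adjacency means one window's half-open end equals the other's start;
    overlap is a nonempty intersection without containment either way.
    """
    order = sorted(range(len(hits)), key=lambda k: (hits[k].start_index,
                                                    hits[k].length))
    ann = {k: ModeAnnotation() for k in range(len(hits))}
    for a_i in range(len(hits)):
        a = hits[a_i]
        for b_i in range(len(hits)):
            if a_i == b_i:
                continue
            b = hits[b_i]
            a_s, a_e = a.interval
            b_s, b_e = b.interval
            contains = b_s <= a_s and a_e <= b_e and (a_s, a_e) != (b_s, b_e)
            if contains:
                cur = ann[a_i].nested_in
                if cur is None or (cur.end_index - cur.start_index) > b.length:
                    ann[a_i].nested_in = b
            elif a_e == b_s or b_e == a_s:
                ann[a_i].consecutive_with.append(b)
            elif max(a_s, b_s) < min(a_e, b_e) and not (
                    a_s <= b_s and b_e <= a_e):
                ann[a_i].overlaps.append(b)
    by_seq: dict[str, list[int]] = {}
    for k, h in enumerate(hits):
        by_seq.setdefault(h.sequence, []).append(k)
    for seq, members in by_seq.items():
        if len(members) >= 2:
            gid = f"{hits[members[0]].chain_id}:{seq}"
            for k in members:
                ann[k].repeat_group = gid
    del order
    return ann


@dataclass
class ChameleonGroup:
    sequence: str
    members: list  # (hit, category) pairs

    @property
    def is_chameleon(self) -> bool:
        return len({cat for _, cat in self.members}) >= 2


def find_chameleons(hits_with_categories: Iterable[tuple[object, str]]
                    ) -> list[ChameleonGroup]:
    """Group (hit, category) pairs by exact sequence, dataset-wide.

    Output order (and hence the chameleon report) is independent of input
    order: groups sorted by sequence, members by (pdb, chain, start).
    """
    groups: dict[str, list] = {}
    for hit, cat in hits_with_categories:
        groups.setdefault(hit.sequence, []).append((hit, cat))
    out = []
    for seq in sorted(groups):
        members = sorted(groups[seq],
                         key=lambda m: (m[0].pdb_id, m[0].chain_id,
                                        m[0].start_index))
        out.append(ChameleonGroup(sequence=seq, members=members))
    return out


def family_distribution(hits: Iterable, classifications: Mapping[str, str]
                        ) -> Counter:
    """Hit counts per PDB header classification (protein family).

    ``classifications`` maps pdb_id -> HEADER classification string; missing
    or empty entries are binned as ``UNCLASSIFIED``.
    """
    counts: Counter = Counter()
    for hit in hits:
        label = classifications.get(hit.pdb_id, "").strip().upper()
        counts[label or "UNCLASSIFIED"] += 1
    return counts
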
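"""Paralog assignment of contigs and PSV-state profiling.

A contig placed on the repeat unit is compared base-by-base against both
paralog references over its aligned span; the fraction of matching aligned
bases to each reference gives two identities, and the contig is assigned to
the paralog of the highest identity. Alignments spanning less than
``min_span`` reference bases are excluded from assignment. When several
placed alignments overlap on the reference, a maximal non-overlapping subset
(by total span) is kept.

The PSV profile of a contig is the ordered sequence of its states at the
catalog PSVs it covers: ``A`` if the contig base equals the A-paralog base,
``B`` if the B-paralog base, ``other`` for anything else (sequencing error
or diverged sequence). Profiles are the substrate for breakpoint and
gene-conversion detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .locus import Contig, ParalogPair

State = Literal["A", "B", "other"]


@dataclass(frozen=True)
class AlignmentConfig:
    min_span: int = 400
    tie_policy: Literal["ambiguous", "first"] = "ambiguous"

    def __post_init__(self) -> None:
        if self.min_span < 1:
            raise ValueError("min_span must be at least 1")


@dataclass(frozen=True)
class AssignmentResult:
    contig_id: str
    identity_a: float
    identity_b: float
    label: Literal["A", "B", "ambiguous", "unassigned"]
    aligned_span: int
    reason: str = ""


@dataclass(frozen=True)
class PSVProfile:
    """Ordered (position, state) pairs at the PSVs a contig covers."""

    states: tuple[tuple[int, State], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.states]
        if positions != sorted(set(positions)):
            raise ValueError("PSV positions must be strictly increasing")

    @property
    def positions(self) -> list[int]:
        return [p for p, _ in self.states]

    def informative(self) -> list[tuple[int, State]]:
        return [(p, s) for p, s in self.states if s in ("A", "B")]


def sequence_identity(
    contig: Contig, reference: str, offset: int | None = None
) -> tuple[float, int]:
    """Identity (fraction of matching aligned bases) and aligned span.

    The contig is placed at ``offset`` (1-based; defaults to the contig's
    truth placement) and compared position-wise against the reference over
    the overlapping span.
    """
    start = (offset if offset is not None else contig.start) - 1
    if start < 0 or start >= len(reference):
        raise ValueError("placement outside the reference")
    span = min(len(contig.sequence), len(reference) - start)
    if span <= 0:
        raise ValueError("contig does not overlap the reference")
    c = np.frombuffer(contig.sequence[:span].encode(), dtype="S1")
    r = np.frombuffer(reference[start : start + span].encode(), dtype="S1")
    return float(np.mean(c == r)), span


def assign_paralog(
    contig: Contig,
    pair: ParalogPair,
    config: AlignmentConfig = AlignmentConfig(),
    offset: int | None = None,
) -> AssignmentResult:
    """Assign a placed contig to the paralog of the highest identity."""
    identity_a, span = sequence_identity(contig, pair.seq_a, offset)
    identity_b, _ = sequence_identity(contig, pair.seq_b, offset)
    if span < config.min_span:
        return AssignmentResult(
            contig.contig_id, identity_a, identity_b, "unassigned", span,
            reason=f"aligned span {span} < min_span {config.min_span}",
        )
    if identity_a == identity_b:
        if config.tie_policy == "ambiguous":
            return AssignmentResult(
                contig.contig_id, identity_a, identity_b, "ambiguous", span,
                reason="equal identity to both paralogs",
            )
        label: Literal["A", "B"] = "A"
    else:
        label = "A" if identity_a > identity_b else "B"
    return AssignmentResult(contig.contig_id, identity_a, identity_b, label, span)


@dataclass(frozen=True)
class PlacedAlignment:
    """A candidate alignment on the reference with its span as score."""

    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start must not exceed end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def select_nonoverlapping(
    alignments: Sequence[PlacedAlignment],
) -> list[PlacedAlignment]:
    """Maximum-total-span set of pairwise non-overlapping alignments.

    Weighted interval scheduling by dynamic programming; the result is
    independent of input order (ties broken by coordinates, then name).
    """
    items = sorted(alignments, key=lambda a: (a.end, a.start, a.name))
    n = len(items)
    if n == 0:
        return []
    # p[i]: rightmost j < i with items[j].end < items[i].start
    ends = [a.end for a in items]
    p = [int(np.searchsorted(ends, a.start)) - 1 for a in items]
    best = [0] * (n + 1)
    take = [False] * n
    for i in range(n):
        with_i = items[i].span + best[p[i] + 1]
        if with_i > best[i]:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = best[i]
    chosen: list[PlacedAlignment] = []
    i = n - 1
    while i >= 0:
        if take[i]:
            chosen.append(items[i])
            i = p[i]
        else:
            i -= 1
    return sorted(chosen, key=lambda a: a.start)


def psv_profile(
    contig: Contig,
    pair: ParalogPair,
    offset: int | None = None,
) -> PSVProfile:
    """PSV states of a placed contig; uncovered catalog PSVs are omitted."""
    start = offset if offset is not None else contig.start
    end = start + len(contig.sequence) - 1
    states: list[tuple[int, State]] = []
    for pos, a_base, b_base in pair.psv_catalog:
        if not (start <= pos <= end):
            continue
        base = contig.sequence[pos - start]
        if base == a_base:
            state: State = "A"
        elif base == b_base:
            state = "B"
        else:
            state = "other"
        states.append((pos, state))
    return PSVProfile(states=tuple(states))


def place_by_psv_anchor(contig: Contig, pair: ParalogPair) -> int | None:
    """Label-free placement by exact substring search against both paralogs.

    Returns the 1-based offset of the first exact occurrence of the contig's
    leading 32-mer in either reference, or None when no anchor matches. This
    supports substitution-free prefixes only; the synthetic generator's truth
    placement is the default elsewhere.
    """
    k = min(32, len(contig.sequence))
    anchor = contig.sequence[:k]
    for ref in (pair.seq_a, pair.seq_b):
        hit = ref.find(anchor)
        if hit >= 0:
            return hit + 1
    return None


def pool_profiles(
    profiles: Sequence[PSVProfile],
) -> tuple[PSVProfile, list[int]]:
    """Merge per-contig profiles of one sample into a single profile.

    PSVs with conflicting informative states across contigs (e.g., a
    conversion on one homolog obscuring the breakpoint region) are masked:
    they are dropped from the pooled profile and returned separately.
    """
    by_pos: dict[int, set[State]] = {}
    for prof in profiles:
        for pos, state in prof.states:
            by_pos.setdefault(pos, set()).add(state)
    pooled: list[tuple[int, State]] = []
    conflicting: list[int] = []
    for pos in sorted(by_pos):
        informative = by_pos[pos] & {"A", "B"}
        if len(informative) == 1:
            pooled.append((pos, next(iter(informative))))
        elif len(informative) == 2:
            conflicting.append(pos)
        else:
            pooled.append((pos, "other"))
    return PSVProfile(states=tuple(pooled)), conflicting
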
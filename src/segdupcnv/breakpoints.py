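"""Breakpoint and gene-conversion mapping from PSV-state profiles.

A chimeric unit produced by NAHR shows a single switch from one paralog
state to the other along its PSV profile; the crossover lies strictly
between the last PSV of the first state and the first PSV of the second, so
a breakpoint is reported as that open interval. A gene conversion shows a
pair of opposite switches returning to the original state; the tract is
reported as the inner interval spanned by the donor-state PSVs.

Isolated discordant PSVs (runs shorter than ``min_run``) are treated as
noise or ambiguity and masked, the profile analogue of graying out
unreliable sites. When the number of switches is odd, one of them is a true
NAHR breakpoint; the parser chooses the parse that minimizes the total
length of called conversion tracts, since conversion tracts (kilobases) are
short relative to the chimera halves they interrupt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .assign import PSVProfile, State
from .intervals import GenomicInterval

HotspotCatalog = Mapping[str, GenomicInterval]


@dataclass(frozen=True)
class SwitchEvent:
    from_state: Literal["A", "B"]
    to_state: Literal["A", "B"]
    interval: GenomicInterval  # (last from-state PSV, first to-state PSV)
    n_support: tuple[int, int]  # consistent PSVs on the (left, right) side

    def __post_init__(self) -> None:
        if self.interval.start >= self.interval.end:
            raise ValueError("switch interval must have positive width")


@dataclass(frozen=True)
class ConversionCall:
    """A called gene-conversion tract.

    ``tract`` is the inner span of observed donor-state PSVs (always inside
    the true tract); ``outer`` extends to the flanking acceptor-state PSVs
    and is the uncertainty interval guaranteed to contain the true tract.
    """

    tract: GenomicInterval
    donor: Literal["A", "B"]
    acceptor: Literal["A", "B"]
    n_psvs: int
    outer: GenomicInterval | None = None


@dataclass(frozen=True)
class BreakpointInterval:
    interval: GenomicInterval
    hotspot_label: str = "unassigned"
    ambiguous_psvs: tuple[int, ...] = ()
    tie_labels: tuple[str, ...] = ()


def detect_switches(
    profile: PSVProfile, min_run: int = 2
) -> tuple[list[SwitchEvent], list[int]]:
    """Detect A/B state switches; return (switches, masked PSV positions).

    Only informative (A/B) states are scanned. Maximal runs shorter than
    ``min_run`` are masked and recorded; adjacent surviving runs of equal
    state are merged, and one event is emitted per boundary between
    surviving runs.
    """
    if min_run < 1:
        raise ValueError("min_run must be at least 1")
    informative = profile.informative()
    if not informative:
        warnings.warn("profile has no informative PSV", stacklevel=2)
        return [], []

    runs: list[tuple[State, list[int]]] = []
    for pos, state in informative:
        if runs and runs[-1][0] == state:
            runs[-1][1].append(pos)
        else:
            runs.append((state, [pos]))

    masked: list[int] = []
    kept: list[tuple[State, list[int]]] = []
    for state, positions in runs:
        if len(positions) < min_run:
            masked.extend(positions)
        elif kept and kept[-1][0] == state:
            kept[-1][1].extend(positions)
        else:
            kept.append((state, list(positions)))

    switches: list[SwitchEvent] = []
    for (s1, p1), (s2, p2) in zip(kept, kept[1:]):
        switches.append(
            SwitchEvent(
                from_state=s1,  # type: ignore[arg-type]
                to_state=s2,  # type: ignore[arg-type]
                interval=GenomicInterval(p1[-1], p2[0]),
                n_support=(len(p1), len(p2)),
            )
        )
    return switches, masked


def _parse_chain(
    switches: Sequence[SwitchEvent], unpaired: int | None
) -> tuple[list[tuple[SwitchEvent, SwitchEvent]], int]:
    """Pair adjacent switches, skipping index ``unpaired``; return pairs and
    the total tract length of the parse."""
    pairs: list[tuple[SwitchEvent, SwitchEvent]] = []
    idx = [i for i in range(len(switches)) if i != unpaired]
    total = 0
    for i, j in zip(idx[::2], idx[1::2]):
        tract = GenomicInterval(switches[i].interval.end, switches[j].interval.start)
        pairs.append((switches[i], switches[j]))
        total += len(tract)
    return pairs, total


def classify_events(
    switches: Sequence[SwitchEvent],
    profile: PSVProfile,
    min_tract_psvs: int = 2,
    known_conversions: Sequence[GenomicInterval] = (),
) -> tuple[list[BreakpointInterval], list[ConversionCall]]:
    """Partition switches into conversion pairs and NAHR breakpoints.

    An even number of switches parses entirely into conversions; an odd
    number leaves exactly one breakpoint, chosen as the parse of minimal
    total conversion-tract length (ties resolved toward the terminal
    switch). Breakpoint intervals overlapping ``known_conversions`` have the
    affected PSVs recorded as ambiguous.
    """
    if not switches:
        return [], []
    n = len(switches)
    if n % 2 == 0:
        pairs, _ = _parse_chain(switches, unpaired=None)
        unpaired_events: list[SwitchEvent] = []
    else:
        # candidate breakpoints are the even-index switches (those moving
        # away from the profile's starting state)
        best: tuple[int, int] | None = None  # (total tract length, -index)
        for j in range(0, n, 2):
            _, total = _parse_chain(switches, unpaired=j)
            key = (total, -j)
            if best is None or key < best:
                best = key
        j = -best[1]
        pairs, _ = _parse_chain(switches, unpaired=j)
        unpaired_events = [switches[j]]

    conversions: list[ConversionCall] = []
    breakpoints: list[BreakpointInterval] = []
    state_at = dict(profile.states)
    for first, second in pairs:
        tract = GenomicInterval(first.interval.end, second.interval.start)
        donor = first.to_state
        n_psvs = sum(
            1
            for pos, s in profile.states
            if tract.contains(pos) and s == donor
        )
        if n_psvs >= min_tract_psvs:
            conversions.append(
                ConversionCall(
                    tract=tract,
                    donor=donor,
                    acceptor=first.from_state,
                    n_psvs=n_psvs,
                    outer=GenomicInterval(first.interval.start, second.interval.end),
                )
            )
        else:
            breakpoints.append(BreakpointInterval(interval=first.interval))
            breakpoints.append(BreakpointInterval(interval=second.interval))
    for event in unpaired_events:
        ambiguous = tuple(
            pos
            for pos in state_at
            if event.interval.start <= pos <= event.interval.end
            and any(t.contains(pos) for t in known_conversions)
        )
        breakpoints.append(
            BreakpointInterval(interval=event.interval, ambiguous_psvs=ambiguous)
        )
    return breakpoints, conversions


def assign_hotspot(
    bp: BreakpointInterval, catalog: HotspotCatalog
) -> BreakpointInterval:
    """Label a breakpoint with the catalog region of maximal overlap."""
    if not catalog:
        raise ValueError("hotspot catalog is empty")
    overlaps = {
        name: bp.interval.overlap_bp(region) for name, region in catalog.items()
    }
    best = max(overlaps.values())
    if best == 0:
        return BreakpointInterval(bp.interval, "unassigned", bp.ambiguous_psvs)
    winners = sorted(name for name, o in overlaps.items() if o == best)
    return BreakpointInterval(
        bp.interval,
        winners[0],
        bp.ambiguous_psvs,
        tie_labels=tuple(winners[1:]),
    )


def compare_alleles(
    interval_a: GenomicInterval,
    flank_a: Mapping[int, State],
    interval_b: GenomicInterval,
    flank_b: Mapping[int, State],
) -> Literal["consistent_IBD", "distinct"]:
    """Identity-by-descent support for two breakpoint alleles.

    Consistent with a single shared origin iff the breakpoint intervals are
    identical and every informative PSV state observed on both alleles
    agrees; any difference indicates identity-by-state (recurrent NAHR).
    """
    if (interval_a.start, interval_a.end) != (interval_b.start, interval_b.end):
        return "distinct"
    shared = set(flank_a) & set(flank_b)
    for pos in shared:
        sa, sb = flank_a[pos], flank_b[pos]
        if sa in ("A", "B") and sb in ("A", "B") and sa != sb:
            return "distinct"
    return "consistent_IBD"


@dataclass(frozen=True)
class SeparationResult:
    differences: np.ndarray  # pairwise Hamming-difference counts
    statistic: float  # mean between-label / mean within-label distance
    separable: bool


def divergence_separation(
    sequences: Sequence[str], labels: Sequence[str]
) -> SeparationResult:
    """Quantify two-group separability of realized unit sequences.

    The statistic is the ratio of the mean between-label to the mean
    within-label pairwise Hamming distance; values above 1 indicate that
    same-label sequences resemble each other more than cross-label ones. A
    zero within-label mean (e.g., identical sequences) leaves the ratio
    undefined and the groups are reported as not separable.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    arr = np.array([np.frombuffer(s.encode(), dtype="S1") for s in sequences])
    diff = np.zeros((len(sequences), len(sequences)), dtype=int)
    for i in range(len(sequences)):
        diff[i] = np.sum(arr != arr[i], axis=1)
    labels_arr = np.asarray(labels)
    same = labels_arr[:, None] == labels_arr[None, :]
    upper = np.triu(np.ones_like(diff, dtype=bool), k=1)
    within = diff[same & upper]
    between = diff[~same & upper]
    if within.size == 0 or between.size == 0 or within.mean() == 0:
        return SeparationResult(diff, float("nan"), False)
    statistic = float(between.mean() / within.mean())
    return SeparationResult(diff, statistic, statistic > 1.0)
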
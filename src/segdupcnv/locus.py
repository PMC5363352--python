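"""Synthetic two-unit segmental duplication locus with known truth.

This module generates the raw material the rest of the package analyses:

* a pair of paralogous repeat-unit references at a configurable divergence,
  with an explicit catalog of paralog sequence variants (PSVs) — the fixed
  differences that distinguish unit A from unit B;
* structural alleles produced by nonallelic homologous recombination (NAHR)
  — a deletion allele carrying a single A/B chimeric unit, the reciprocal
  duplication allele carrying three units — and by gene conversion, which
  copies a tract from one paralog onto the other;
* fosmid-like contigs tiling the realized unit sequences, optionally with
  i.i.d. substitution errors;
* an array-CGH log2-ratio matrix whose probe response depends on both total
  copy number and the paralog identity of each retained unit, through a
  cross-hybridization weight gamma.

Every generator is deterministic given its seed, and every simulated object
carries truth annotations so downstream calls can be scored against the
generating events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

Source = Literal["A", "B"]
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Paralog reference pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogPair:
    """Two repeat-unit reference sequences plus the PSV catalog.

    ``psv_catalog`` is an ordered tuple of ``(position, a_base, b_base)``
    with 1-based positions; at every PSV the two references differ, and at
    every other position they agree.
    """

    seq_a: str
    seq_b: str
    psv_catalog: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("paralog references must have equal length")
        positions = [p for p, _, _ in self.psv_catalog]
        if positions != sorted(set(positions)):
            raise ValueError("PSV positions must be strictly increasing")
        for pos, a, b in self.psv_catalog:
            if a == b:
                raise ValueError(f"PSV at {pos} has identical bases")

    @property
    def unit_length(self) -> int:
        return len(self.seq_a)

    @property
    def divergence(self) -> float:
        return len(self.psv_catalog) / self.unit_length

    @property
    def psv_positions(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.psv_catalog], dtype=int)

    def identity(self) -> float:
        """Fraction of positions at which the two references agree."""
        return 1.0 - self.divergence


def simulate_paralog_pair(
    unit_length: int,
    divergence: float,
    seed: int,
    psv_desert: GenomicInterval | None = None,
    desert_density: float = 0.1,
) -> ParalogPair:
    """Simulate a paralog pair with ``round(divergence * unit_length)`` PSVs.

    PSV positions are drawn uniformly without replacement. An optional
    ``psv_desert`` interval receives ``desert_density`` times the baseline
    sampling weight, emulating a PSV-poor region; off by default.
    """
    if unit_length < 100:
        raise ValueError("unit_length must be at least 100")
    if not (0.0 <= divergence < 0.2):
        raise ValueError("divergence must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    seq_a = rng.choice(_BASES, size=unit_length)
    n_psv = round(divergence * unit_length)

    weights = np.ones(unit_length)
    if psv_desert is not None:
        weights[psv_desert.start - 1 : psv_desert.end] = desert_density
    weights /= weights.sum()
    positions = np.sort(
        rng.choice(unit_length, size=n_psv, replace=False, p=weights)
    )

    seq_b = seq_a.copy()
    catalog: list[tuple[int, str, str]] = []
    for idx in positions:
        a = seq_a[idx]
        alternatives = _BASES[_BASES != a]
        b = rng.choice(alternatives)
        seq_b[idx] = b
        catalog.append((int(idx) + 1, a.decode(), b.decode()))
    return ParalogPair(
        seq_a=seq_a.tobytes().decode(),
        seq_b=seq_b.tobytes().decode(),
        psv_catalog=tuple(catalog),
    )


# ---------------------------------------------------------------------------
# Structural alleles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A run of positions on one unit drawn from one source paralog."""

    start: int  # 1-based inclusive
    end: int
    source: Source

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit as a mosaic of A/B-sourced segments tiling [1, L]."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("unit must have at least one segment")
        if self.segments[0].start != 1:
            raise ValueError("segments must start at position 1")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start != prev.end + 1:
                raise ValueError("segments must be contiguous and sorted")

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def source_at(self, position: int) -> Source:
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.source
        raise ValueError(f"position {position} outside unit [1, {self.length}]")

    def a_mask(self) -> np.ndarray:
        """Boolean array over [0, L): True where the source is paralog A."""
        mask = np.zeros(self.length, dtype=bool)
        for seg in self.segments:
            if seg.source == "A":
                mask[seg.start - 1 : seg.end] = True
        return mask


def _pure_unit(source: Source, length: int) -> RepeatUnit:
    return RepeatUnit((Segment(1, length, source),))


def _chimera(first: Source, second: Source, breakpoint: int, length: int) -> RepeatUnit:
    return RepeatUnit(
        (Segment(1, breakpoint, first), Segment(breakpoint + 1, length, second))
    )


@dataclass(frozen=True)
class NahrDeletion:
    breakpoint: int


@dataclass(frozen=True)
class NahrDuplication:
    breakpoint: int


@dataclass(frozen=True)
class GeneConversion:
    unit: int  # index into the allele's unit list
    donor: Source
    start: int
    end: int  # end == start - 1 encodes an empty tract (no-op)


Event = NahrDeletion | NahrDuplication | GeneConversion


@dataclass(frozen=True)
class StructuralAllele:
    """A haplotype: an ordered list of repeat units plus truth annotations."""

    units: tuple[RepeatUnit, ...]
    events: tuple[Event, ...] = ()

    @property
    def n_units(self) -> int:
        return len(self.units)


def _apply_tract(
    segments: Sequence[Segment], start: int, end: int, source: Source
) -> tuple[Segment, ...]:
    """Overwrite the source label on [start, end] and renormalize."""
    pieces: list[Segment] = []
    for seg in segments:
        if seg.end < start or seg.start > end:
            pieces.append(seg)
            continue
        if seg.start < start:
            pieces.append(Segment(seg.start, start - 1, seg.source))
        if seg.end > end:
            pieces.append(Segment(end + 1, seg.end, seg.source))
    pieces.append(Segment(start, end, source))
    pieces.sort(key=lambda s: s.start)
    merged: list[Segment] = [pieces[0]]
    for seg in pieces[1:]:
        last = merged[-1]
        if seg.source == last.source and seg.start == last.end + 1:
            merged[-1] = Segment(last.start, seg.end, last.source)
        else:
            merged.append(seg)
    return tuple(merged)


def build_allele(
    pair: ParalogPair,
    events: Iterable[Event] = (),
    duplication_middle: tuple[Source, Source] = ("B", "A"),
) -> StructuralAllele:
    """Build a structural allele from at most one NAHR event plus conversions.

    The normal allele is ``[A, B]``. An NAHR deletion at breakpoint ``b``
    collapses it to a single chimera, A-source on ``[1, b]`` and B-source on
    ``(b, L]``. The reciprocal duplication yields three units whose middle
    unit is the opposite chimera (``duplication_middle`` sources, default
    B then A). Gene conversions overwrite a tract's source with the donor
    paralog. Overlapping conversion tracts on one unit are rejected.
    """
    events = tuple(events)
    length = pair.unit_length
    structural = [e for e in events if isinstance(e, (NahrDeletion, NahrDuplication))]
    if len(structural) > 1:
        raise ValueError("at most one NAHR event per allele")

    if not structural:
        units = [_pure_unit("A", length), _pure_unit("B", length)]
    else:
        event = structural[0]
        b = event.breakpoint
        if not (1 < b < length):
            raise ValueError(f"breakpoint {b} outside (1, {length})")
        if isinstance(event, NahrDeletion):
            units = [_chimera("A", "B", b, length)]
        else:
            mid_first, mid_second = duplication_middle
            units = [
                _pure_unit("A", length),
                _chimera(mid_first, mid_second, b, length),
                _pure_unit("B", length),
            ]

    tracts_by_unit: dict[int, list[tuple[int, int]]] = {}
    for conv in (e for e in events if isinstance(e, GeneConversion)):
        if conv.end == conv.start - 1:  # empty tract: explicit no-op
            continue
        if not (1 <= conv.start <= conv.end <= length):
            raise ValueError(f"conversion tract [{conv.start}, {conv.end}] outside unit")
        if not (0 <= conv.unit < len(units)):
            raise ValueError(f"conversion unit index {conv.unit} out of range")
        for s, e in tracts_by_unit.get(conv.unit, []):
            if conv.start <= e and s <= conv.end:
                raise ValueError("overlapping conversion tracts on one unit")
        tracts_by_unit.setdefault(conv.unit, []).append((conv.start, conv.end))
        units[conv.unit] = RepeatUnit(
            _apply_tract(units[conv.unit].segments, conv.start, conv.end, conv.donor)
        )

    return StructuralAllele(units=tuple(units), events=events)


def realize_sequence(allele: StructuralAllele, pair: ParalogPair) -> list[str]:
    """Realized DNA string of every unit: per-position source lookup."""
    a = np.frombuffer(pair.seq_a.encode(), dtype="S1")
    b = np.frombuffer(pair.seq_b.encode(), dtype="S1")
    out = []
    for unit in allele.units:
        if unit.length != pair.unit_length:
            raise ValueError("unit length does not match the paralog pair")
        seq = np.where(unit.a_mask(), a, b)
        out.append(seq.tobytes().decode())
    return out


# ---------------------------------------------------------------------------
# Contigs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A fosmid-like contig with truth placement on its generating unit."""

    contig_id: str
    sequence: str
    unit_index: int
    start: int  # 1-based position on the unit
    strand: str = "+"


def simulate_contigs(
    allele: StructuralAllele,
    pair: ParalogPair,
    contig_length: int,
    step: int,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "ctg",
) -> list[Contig]:
    """Tile each realized unit with contigs at the given step.

    Start positions are ``1, 1+step, ...`` up to ``L - contig_length + 1``;
    a terminal contig ending exactly at ``L`` is appended when the grid does
    not already reach it. Substitution errors are i.i.d. at ``error_rate``.
    """
    if contig_length < 1:
        raise ValueError("contig_length must be positive")
    if contig_length > pair.unit_length:
        raise ValueError("contig_length exceeds unit length")
    if step < 1:
        raise ValueError("step must be at least 1")
    rng = np.random.default_rng(seed)
    sequences = realize_sequence(allele, pair)
    contigs: list[Contig] = []
    last_start = pair.unit_length - contig_length + 1
    starts = list(range(1, last_start + 1, step))
    if starts[-1] != last_start:
        starts.append(last_start)
    for u, unit_seq in enumerate(sequences):
        for s in starts:
            raw = np.frombuffer(
                unit_seq[s - 1 : s - 1 + contig_length].encode(), dtype="S1"
            ).copy()
            if error_rate > 0:
                hits = np.flatnonzero(rng.random(contig_length) < error_rate)
                for h in hits:
                    raw[h] = rng.choice(_BASES[_BASES != raw[h]])
            contigs.append(
                Contig(
                    contig_id=f"{id_prefix}_u{u}_s{s}",
                    sequence=raw.tobytes().decode(),
                    unit_index=u,
                    start=s,
                )
            )
    return contigs


# ---------------------------------------------------------------------------
# aCGH simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    unit_position: int  # 1-based bp on the repeat unit
    design_paralog: Source


@dataclass(frozen=True)
class ACGHParams:
    """Parameters of the probe-response model.

    ``gamma`` is the cross-hybridization weight: the relative signal a probe
    collects from a unit of the non-target paralog. ``floor`` guards the log
    for genotypes with zero effective copies.
    """

    gamma: float = 0.3
    noise_sd: float = 0.15
    cohort_offsets: dict[str, float] = field(default_factory=dict)
    floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass(frozen=True)
class DiploidGenotype:
    sample_id: str
    allele1: StructuralAllele
    allele2: StructuralAllele
    cohort: str
    status: Literal["case", "control"]


@dataclass
class IntensityMatrix:
    """Samples x probes log2-ratio matrix with sample and probe metadata."""

    values: pd.DataFrame  # index: sample_id, columns: probe_id
    samples: pd.DataFrame  # index: sample_id, columns: cohort, status
    probes: tuple[ProbeAnnotation, ...]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and probe labels must be unique")
        if list(self.values.index) != list(self.samples.index):
            raise ValueError("sample metadata does not match the matrix rows")
        if [p.probe_id for p in self.probes] != list(self.values.columns):
            raise ValueError("probe metadata does not match the matrix columns")

    @property
    def probe_positions(self) -> np.ndarray:
        return np.array([p.unit_position for p in self.probes])


def expected_log2_ratio(
    genotype: DiploidGenotype,
    probe: ProbeAnnotation,
    gamma: float,
    floor: float = 0.05,
) -> float:
    """Noise-free probe response for one genotype.

    With ``m`` units (across both alleles) matching the probe's design
    paralog at the probe position and ``u`` units of the other paralog, the
    response is ``log2(max(m + gamma*u, floor) / (2 + 2*gamma))`` — zero for
    the reference diploid (two A units, two B units) at any gamma.
    """
    m = u = 0
    for allele in (genotype.allele1, genotype.allele2):
        for unit in allele.units:
            if unit.source_at(probe.unit_position) == probe.design_paralog:
                m += 1
            else:
                u += 1
    return math.log2(max(m + gamma * u, floor) / (2.0 + 2.0 * gamma))


def simulate_acgh(
    genotypes: Sequence[DiploidGenotype],
    probes: Sequence[ProbeAnnotation],
    params: ACGHParams,
) -> IntensityMatrix:
    """Simulate the log2-ratio matrix for a cohort of diploid genotypes."""
    if not genotypes:
        raise ValueError("empty genotype list")
    positions = np.array([p.unit_position for p in probes]) - 1
    design_is_a = np.array([p.design_paralog == "A" for p in probes])
    rng = np.random.default_rng(params.seed)
    denom = 2.0 + 2.0 * params.gamma

    rows = np.empty((len(genotypes), len(probes)))
    for i, g in enumerate(genotypes):
        masks = [
            unit.a_mask()[positions]
            for allele in (g.allele1, g.allele2)
            for unit in allele.units
        ]
        a_count = np.sum(masks, axis=0)
        total = len(masks)
        m = np.where(design_is_a, a_count, total - a_count)
        u = total - m
        effective = np.maximum(m + params.gamma * u, params.floor)
        offset = params.cohort_offsets.get(g.cohort, 0.0)
        rows[i] = np.log2(effective / denom) + offset
    if params.noise_sd > 0:
        rows += rng.normal(0.0, params.noise_sd, size=rows.shape)

    sample_ids = [g.sample_id for g in genotypes]
    values = pd.DataFrame(
        rows, index=sample_ids, columns=[p.probe_id for p in probes]
    )
    samples = pd.DataFrame(
        {"cohort": [g.cohort for g in genotypes], "status": [g.status for g in genotypes]},
        index=sample_ids,
    )
    return IntensityMatrix(values=values, samples=samples, probes=tuple(probes))
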
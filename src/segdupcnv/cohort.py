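"""Default locus design and case/control cohort simulation.

The default design mirrors a two-hotspot NAHR locus: breakpoints of one
deletion class cluster in a proximal hotspot, the other class in a distal
hotspot, and the region between the hotspots is the deletion-determining
region — the stretch whose paralog identity on the retained chimeric unit
differs between the two deletion classes. The probe design places 20 of the
33 array probes inside that region.

Deletion-class naming follows the retained unit: a breakpoint in the distal
hotspot leaves a chimera that is A-source across the deletion-determining
region ("B_deletion", the B-identity copy of the region is lost); a proximal
breakpoint leaves a B-source chimera there ("A_deletion").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .locus import (
    ACGHParams,
    DiploidGenotype,
    GeneConversion,
    IntensityMatrix,
    NahrDeletion,
    NahrDuplication,
    ParalogPair,
    ProbeAnnotation,
    StructuralAllele,
    build_allele,
    simulate_acgh,
    simulate_paralog_pair,
)

DEFAULT_UNIT_LENGTH = 16_000
DEFAULT_DIVERGENCE = 0.015


def default_hotspots(unit_length: int = DEFAULT_UNIT_LENGTH) -> dict[str, GenomicInterval]:
    """Two NAHR hotspot intervals at fixed fractions of the unit."""
    L = unit_length
    return {
        "proximal": GenomicInterval(round(0.175 * L), round(0.25 * L), "proximal"),
        "distal": GenomicInterval(round(0.7625 * L), round(0.8375 * L), "distal"),
    }


def default_probe_design(
    unit_length: int = DEFAULT_UNIT_LENGTH,
    n_total: int = 33,
    n_discriminating: int = 20,
    hotspots: dict[str, GenomicInterval] | None = None,
) -> list[ProbeAnnotation]:
    """Probe panel: ``n_discriminating`` probes strictly between the hotspots,
    the rest flanking them, design paralog alternating A/B."""
    hotspots = hotspots or default_hotspots(unit_length)
    prox, dist = hotspots["proximal"], hotspots["distal"]
    inner = np.linspace(prox.end + 200, dist.start - 200, n_discriminating)
    n_left = (n_total - n_discriminating) // 2
    n_right = n_total - n_discriminating - n_left
    left = np.linspace(200, prox.start - 200, n_left)
    right = np.linspace(dist.end + 200, unit_length - 200, n_right)
    positions = np.concatenate([left, inner, right]).round().astype(int)
    return [
        ProbeAnnotation(
            probe_id=f"probe_{i:02d}",
            unit_position=int(pos),
            design_paralog="A" if i % 2 == 0 else "B",
        )
        for i, pos in enumerate(sorted(positions))
    ]


def deletion_allele(
    pair: ParalogPair,
    hotspot: GenomicInterval,
    rng: np.random.Generator,
) -> StructuralAllele:
    """Deletion allele with its breakpoint drawn uniformly in ``hotspot``."""
    b = int(rng.integers(hotspot.start, hotspot.end + 1))
    return build_allele(pair, [NahrDeletion(breakpoint=b)])


def duplication_allele(
    pair: ParalogPair, hotspot: GenomicInterval, rng: np.random.Generator
) -> StructuralAllele:
    b = int(rng.integers(hotspot.start, hotspot.end + 1))
    return build_allele(pair, [NahrDuplication(breakpoint=b)])


@dataclass
class CohortDesign:
    """Study conditions for a simulated case/control aCGH cohort.

    ``carrier_freq_control`` is the heterozygous B-deletion carrier frequency
    among controls; the case carrier odds are the control odds times
    ``carrier_or``. The remaining genotype classes occur at status-independent
    rates. ``planted_known`` forces a fixed number of (B-type, A-type)
    heterozygous deletion carriers of known truth into the cohort — the
    synthetic counterpart of validation samples typed by an orthogonal
    paralog-ratio assay.
    """

    n_samples: int = 400
    case_fraction: float = 0.5
    carrier_freq_control: float = 0.025
    carrier_or: float = 1.6
    freq_het_a: float = 0.012
    freq_hom_b: float = 0.002
    freq_dup: float = 0.08
    cohorts: tuple[str, ...] = ("58C", "NBS", "RA")
    case_cohort: str = "RA"
    cohort_offset_sd: float = 0.04
    planted_known: tuple[int, int] = (10, 5)
    planted_hom_b: int = 2
    conversion_fraction: float = 0.0  # fraction of normal alleles carrying a tract


@dataclass
class SimulatedCohort:
    pair: ParalogPair
    genotypes: list[DiploidGenotype]
    intensities: IntensityMatrix
    truth: pd.DataFrame  # sample_id index; category, del_type, known
    probes: list[ProbeAnnotation]
    hotspots: dict[str, GenomicInterval]
    cohort_offsets: dict[str, float] = field(default_factory=dict)


def simulate_cohort(
    design: CohortDesign | None = None,
    acgh: ACGHParams | None = None,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    divergence: float = DEFAULT_DIVERGENCE,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a full cohort: genotypes, truth table and intensity matrix.

    The caller's ``acgh.cohort_offsets`` is honored if non-empty; otherwise a
    per-run offset is drawn for every cohort except the first (the reference,
    fixed at 0) and recorded in the returned object.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    pair = simulate_paralog_pair(
        unit_length, divergence, seed=int(rng.integers(2**31))
    )
    hotspots = default_hotspots(unit_length)
    probes = default_probe_design(unit_length)

    normal = build_allele(pair)
    p0 = design.carrier_freq_control
    odds_case = design.carrier_or * p0 / (1 - p0)
    p_case = odds_case / (1 + odds_case)

    categories: list[str] = []
    n_b, n_a = design.planted_known
    n_hom = design.planted_hom_b
    for i in range(design.n_samples):
        if i < n_b:
            categories.append("het_b")
        elif i < n_b + n_a:
            categories.append("het_a")
        elif i < n_b + n_a + n_hom:
            categories.append("hom_b")
        else:
            categories.append("")  # drawn below, status-dependent

    statuses = np.where(
        rng.random(design.n_samples) < design.case_fraction, "case", "control"
    )
    control_cohorts = tuple(c for c in design.cohorts if c != design.case_cohort)
    cohort_labels = [
        design.case_cohort if s == "case" else control_cohorts[int(rng.integers(len(control_cohorts)))]
        for s in statuses
    ]

    genotypes: list[DiploidGenotype] = []
    truth_rows = []
    for i in range(design.n_samples):
        status = statuses[i]
        category = categories[i]
        known = i < n_b + n_a  # planted known-type heterozygous carriers
        if category == "":
            p_b = p_case if status == "case" else p0
            r = rng.random()
            if r < p_b:
                category = "het_b"
            elif r < p_b + design.freq_het_a:
                category = "het_a"
            elif r < p_b + design.freq_het_a + design.freq_hom_b:
                category = "hom_b"
            elif r < p_b + design.freq_het_a + design.freq_hom_b + design.freq_dup:
                category = "dup"
            else:
                category = "normal"

        other = normal
        if design.conversion_fraction and rng.random() < design.conversion_fraction:
            start = int(rng.integers(hotspots["proximal"].end, hotspots["distal"].start - 2400))
            other = build_allele(
                pair, [GeneConversion(unit=0, donor="B", start=start, end=start + 2399)]
            )
        if category == "het_b":
            a1, a2 = deletion_allele(pair, hotspots["distal"], rng), other
            del_type = "B"
        elif category == "het_a":
            a1, a2 = deletion_allele(pair, hotspots["proximal"], rng), other
            del_type = "A"
        elif category == "hom_b":
            a1 = deletion_allele(pair, hotspots["distal"], rng)
            a2 = deletion_allele(pair, hotspots["distal"], rng)
            del_type = "B"
        elif category == "dup":
            a1, a2 = duplication_allele(pair, hotspots["distal"], rng), other
            del_type = ""
        else:
            a1, a2 = other, normal
            del_type = ""
        sample_id = f"S{i:04d}"
        genotypes.append(
            DiploidGenotype(
                sample_id=sample_id,
                allele1=a1,
                allele2=a2,
                cohort=cohort_labels[i],
                status=status,  # type: ignore[arg-type]
            )
        )
        truth_rows.append(
            {"sample_id": sample_id, "category": category, "del_type": del_type, "known": known}
        )

    acgh = acgh or ACGHParams()
    offsets = dict(acgh.cohort_offsets)
    if not offsets:
        offsets = {design.cohorts[0]: 0.0}
        for c in design.cohorts[1:]:
            offsets[c] = float(rng.normal(0.0, design.cohort_offset_sd))
    acgh = ACGHParams(
        gamma=acgh.gamma,
        noise_sd=acgh.noise_sd,
        cohort_offsets=offsets,
        floor=acgh.floor,
        seed=int(rng.integers(2**31)),
    )
    intensities = simulate_acgh(genotypes, probes, acgh)
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return SimulatedCohort(
        pair=pair,
        genotypes=genotypes,
        intensities=intensities,
        truth=truth,
        probes=probes,
        hotspots=hotspots,
        cohort_offsets=offsets,
    )
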
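"""End-to-end pipeline: simulate -> assign -> map -> call -> classify -> associate.

Each stage consumes only what an analyst of real data would have (sequences,
placements, intensities, cohort and status labels); truth annotations from
the simulator are used exclusively to score the calls in the report. Every
filtering step reports counts before and after, and the whole run is
deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import AlignmentConfig, assign_paralog, pool_profiles, psv_profile
from .assoc import ContingencyTable, associate
from .breakpoints import assign_hotspot, classify_events, detect_switches
from .classify import (
    DeletionTypeClassifier,
    auto_homozygote_threshold,
    filter_homozygotes,
    select_discriminating_probes,
)
from .cohort import CohortDesign, SimulatedCohort, simulate_cohort
from .io import write_bed, write_fasta, write_json, write_tsv
from .locus import ACGHParams, GeneConversion, build_allele, realize_sequence
from .mixture import CohortGaussianMixture, OrientedPC1, call_copy_number


@dataclass
class PipelineConfig:
    unit_length: int = 16_000
    divergence: float = 0.015
    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    gamma: float = 0.3
    noise_sd: float = 0.15
    floor: float = 0.05
    contig_length: int = 4_000
    contig_step: int = 3_000
    contig_error_rate: float = 0.001
    min_run: int = 2
    min_tract_psvs: int = 2
    homozygote_threshold: float | str = "auto"
    min_posterior: float = 0.5
    mixture_restarts: int = 10

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "design" in payload and isinstance(payload["design"], dict):
            design = dict(payload["design"])
            for key in ("cohorts", "planted_known"):
                if key in design:
                    design[key] = tuple(design[key])
            payload["design"] = CohortDesign(**design)
        return cls(**payload)


def _acgh_params(config: PipelineConfig) -> ACGHParams:
    return ACGHParams(gamma=config.gamma, noise_sd=config.noise_sd, floor=config.floor)


def _simulate_stage(config: PipelineConfig) -> SimulatedCohort:
    return simulate_cohort(
        design=config.design,
        acgh=_acgh_params(config),
        unit_length=config.unit_length,
        divergence=config.divergence,
        seed=config.seed,
    )


def _exemplar_alleles(cohort: SimulatedCohort, config: PipelineConfig):
    """One allele of each structural class for the sequence-level stages."""
    truth = cohort.truth
    exemplars = {}
    for category in ("het_b", "het_a", "dup"):
        hits = truth.index[truth["category"] == category]
        if len(hits):
            sample = next(g for g in cohort.genotypes if g.sample_id == hits[0])
            exemplars[category] = sample.allele1
    exemplars["normal"] = build_allele(cohort.pair)
    # a conversion allele exercising tract detection: a 2.4-kb donor-B tract
    # inside the deletion-determining region of an otherwise pure A unit
    mid = (cohort.hotspots["proximal"].end + cohort.hotspots["distal"].start) // 2
    exemplars["conversion"] = build_allele(
        cohort.pair,
        [GeneConversion(unit=0, donor="B", start=mid - 1200, end=mid + 1199)],
    )
    return exemplars


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run all stages and return the machine-readable report."""
    from .locus import simulate_contigs  # local to keep module import light

    config = config or PipelineConfig()
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        },
        "stages": {},
        "warnings": [],
    }

    # --- stage 1: simulate -------------------------------------------------
    cohort = _simulate_stage(config)
    n = len(cohort.genotypes)
    report["stages"]["simulate"] = {
        "n_samples": n,
        "n_probes": len(cohort.probes),
        "n_psvs": len(cohort.pair.psv_catalog),
        "cohort_offsets": cohort.cohort_offsets,
        "truth_categories": cohort.truth["category"].value_counts().to_dict(),
    }

    # --- stage 2: paralog assignment on exemplar alleles -------------------
    rng = np.random.default_rng(config.seed + 1)
    exemplars = _exemplar_alleles(cohort, config)
    align_cfg = AlignmentConfig()
    assign_counts = {"A": 0, "B": 0, "ambiguous": 0, "unassigned": 0}
    contigs_by_category = {}
    for category, allele in exemplars.items():
        contigs = simulate_contigs(
            allele,
            cohort.pair,
            contig_length=config.contig_length,
            step=config.contig_step,
            error_rate=config.contig_error_rate,
            seed=int(rng.integers(2**31)),
            id_prefix=category,
        )
        contigs_by_category[category] = contigs
        for contig in contigs:
            result = assign_paralog(contig, cohort.pair, align_cfg)
            assign_counts[result.label] += 1
    report["stages"]["assign"] = {
        "n_contigs": sum(len(c) for c in contigs_by_category.values()),
        "labels": assign_counts,
    }

    # --- stage 3: breakpoint and conversion mapping ------------------------
    mapping: dict = {}
    for category in ("het_b", "het_a", "conversion"):
        if category not in contigs_by_category:
            continue
        contigs = [
            c for c in contigs_by_category[category] if c.unit_index == 0
        ]
        profiles = [psv_profile(c, cohort.pair) for c in contigs]
        pooled, conflicting = pool_profiles(profiles)
        switches, masked = detect_switches(pooled, min_run=config.min_run)
        bps, convs = classify_events(
            switches, pooled, min_tract_psvs=config.min_tract_psvs
        )
        labelled = [assign_hotspot(bp, cohort.hotspots) for bp in bps]
        mapping[category] = {
            "n_informative_psvs": len(pooled.informative()),
            "n_conflicting_psvs": len(conflicting),
            "n_masked_psvs": len(masked),
            "breakpoints": [
                {
                    "start": bp.interval.start,
                    "end": bp.interval.end,
                    "hotspot": bp.hotspot_label,
                }
                for bp in labelled
            ],
            "conversions": [
                {
                    "start": cv.tract.start,
                    "end": cv.tract.end,
                    "donor": cv.donor,
                    "n_psvs": cv.n_psvs,
                }
                for cv in convs
            ],
        }
    report["stages"]["map_breakpoints"] = mapping

    # --- stage 4: copy-number calling --------------------------------------
    matrix = cohort.intensities
    pc = OrientedPC1().fit(matrix.values.to_numpy())
    scores = pc.transform(matrix.values.to_numpy())
    cohorts = matrix.samples["cohort"].tolist()
    cn_fit = CohortGaussianMixture(
        n_components=3, n_init=config.mixture_restarts, random_state=config.seed + 2
    ).fit(scores, cohorts)
    calls = call_copy_number(
        cn_fit, list(matrix.values.index), min_posterior=config.min_posterior
    )
    call_frame = pd.DataFrame(
        {
            "copy_class": [c.copy_class for c in calls],
            "posterior": [c.posterior for c in calls],
        },
        index=matrix.values.index,
    )
    truth_loss = cohort.truth["category"].isin(["het_b", "het_a", "hom_b"])
    truth_gain = cohort.truth["category"] == "dup"
    truth_class = np.where(truth_loss, "loss", np.where(truth_gain, "gain", "normal"))
    confusion = (
        pd.crosstab(pd.Series(truth_class, index=cohort.truth.index), call_frame["copy_class"])
        .to_dict()
    )
    report["stages"]["call_cn"] = {
        "n_in": n,
        "n_called": len(calls),
        "class_counts": call_frame["copy_class"].value_counts().to_dict(),
        "n_uncertain": int(sum(c.uncertain for c in calls)),
        "mixture_means": cn_fit.means_.tolist(),
        "mixture_converged": bool(cn_fit.converged_),
        "confusion_truth_vs_call": {
            str(k): {str(kk): int(vv) for kk, vv in v.items()} for k, v in confusion.items()
        },
    }

    # a loss component that is not separated from normal means the mixture
    # split a single cluster (e.g. a cohort without deletions): its calls
    # are not deletions and must not feed the classifier
    pooled_sd = float(np.sqrt(np.mean(cn_fit.sds_[1:] ** 2)))
    loss_separation = float((cn_fit.means_[2] - cn_fit.means_[1]) / pooled_sd)
    report["stages"]["call_cn"]["loss_normal_separation_sd"] = loss_separation

    # --- stage 5: A/B deletion-type classification -------------------------
    loss_ids = call_frame.index[call_frame["copy_class"] == "loss"]
    classify_report: dict = {"n_deletion_flagged": int(len(loss_ids))}
    if loss_separation < 2.0:
        loss_ids = loss_ids[:0]
        classify_report["n_deletion_flagged"] = 0
        report["warnings"].append(
            "call_cn: loss and normal components not separated; "
            "deletion calls suppressed"
        )
    ab_calls = None
    if len(loss_ids) < 4:
        classify_report["error"] = "too few deletion carriers to classify"
        report["warnings"].append("classify_ab: " + classify_report["error"])
    else:
        loss_scores = pd.Series(scores, index=matrix.values.index)[loss_ids]
        if config.homozygote_threshold == "auto":
            threshold = auto_homozygote_threshold(cn_fit)
        else:
            threshold = float(config.homozygote_threshold)
        kept_idx, removed_idx = filter_homozygotes(loss_scores.to_numpy(), threshold)
        kept_ids = [loss_ids[i] for i in kept_idx]
        removed_ids = [loss_ids[i] for i in removed_idx]
        classify_report.update(
            {
                "homozygote_threshold": threshold,
                "n_removed_homozygotes": len(removed_ids),
                "n_kept_heterozygotes": len(kept_ids),
            }
        )
        disc = select_discriminating_probes(
            cohort.probes, cohort.hotspots["proximal"], cohort.hotspots["distal"]
        )
        sub = matrix.values.loc[kept_ids, [p.probe_id for p in disc]]
        clf = DeletionTypeClassifier(
            random_state=config.seed + 3, min_posterior=config.min_posterior
        ).fit(sub.to_numpy(), matrix.samples.loc[kept_ids, "status"].tolist())
        ab_calls = clf.calls(kept_ids)
        classify_report.update(
            {
                "n_discriminating_probes": len(disc),
                "separable": bool(clf.separable_),
                "label_counts": pd.Series([c.label for c in ab_calls])
                .value_counts()
                .to_dict(),
            }
        )
        if not clf.separable_:
            report["warnings"].append("classify_ab: components not separable")
        known = cohort.truth.loc[kept_ids]
        known_mask = known["known"].to_numpy()
        if known_mask.any():
            truth_labels = known.loc[known_mask, "del_type"].map(
                {"B": "B_deletion", "A": "A_deletion"}
            )
            called = pd.Series(
                {c.sample_id: c.label for c in ab_calls}
            )[known.index[known_mask]]
            concordance = float((called == truth_labels).mean()) * 100.0
            classify_report["known_carrier_concordance_pct"] = concordance
            classify_report["n_known_carriers"] = int(known_mask.sum())
    report["stages"]["classify_ab"] = classify_report

    # --- stage 6: association ----------------------------------------------
    assoc_report: dict = {}
    status = matrix.samples["status"]
    n_case = int((status == "case").sum())
    n_control = int((status == "control").sum())
    if ab_calls is None:
        assoc_report["error"] = "no deletion-type calls; association skipped"
        report["warnings"].append("associate: " + assoc_report["error"])
    else:
        b_ids = [c.sample_id for c in ab_calls if c.label == "B_deletion"]
        case_carriers = int((status[b_ids] == "case").sum())
        control_carriers = len(b_ids) - case_carriers
        assoc_report["table"] = {
            "case_carriers": case_carriers,
            "control_carriers": control_carriers,
            "case_noncarriers": n_case - case_carriers,
            "control_noncarriers": n_control - control_carriers,
        }
        if case_carriers == 0 or control_carriers == 0:
            assoc_report["error"] = "empty carrier cell; odds ratio not estimable"
            report["warnings"].append("associate: " + assoc_report["error"])
        else:
            result = associate(
                ContingencyTable(
                    case_carriers,
                    control_carriers,
                    n_case - case_carriers,
                    n_control - control_carriers,
                )
            )
            assoc_report.update(
                {
                    "or_sample": result.or_sample,
                    "or_cmle": result.or_cmle,
                    "p_two_sided": result.p_two_sided,
                    "ci_low": result.ci[0],
                    "ci_high": result.ci[1],
                    "level": result.level,
                }
            )
    report["stages"]["associate"] = assoc_report

    if outdir is not None:
        _write_outputs(Path(outdir), config, cohort, call_frame, report)
    return report


def _write_outputs(outdir, config, cohort, call_frame, report) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        outdir / "references.fasta",
        {"paralog_A": cohort.pair.seq_a, "paralog_B": cohort.pair.seq_b},
    )
    from .intervals import GenomicInterval

    write_bed(
        outdir / "psvs.bed",
        [
            ("unit", GenomicInterval(pos, pos, f"psv_{a}>{b}"))
            for pos, a, b in cohort.pair.psv_catalog
        ],
    )
    write_bed(
        outdir / "hotspots.bed",
        [("unit", iv) for iv in cohort.hotspots.values()],
    )
    write_tsv(outdir / "intensities.tsv", cohort.intensities.values, "sample_id")
    write_tsv(outdir / "samples.tsv", cohort.intensities.samples, "sample_id")
    write_tsv(outdir / "truth.tsv", cohort.truth, "sample_id")
    write_tsv(outdir / "cn_calls.tsv", call_frame, "sample_id")
    write_json(outdir / "report.json", report)
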
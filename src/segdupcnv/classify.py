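"""Classification of heterozygous deletions into A-type and B-type.

Both deletion classes remove one repeat unit, so total copy number cannot
distinguish them. What differs is the paralog identity of the retained
chimeric unit across the deletion-determining region (the stretch between
the two NAHR hotspots): an A-type deletion chromosome is B-source there, a
B-type chromosome A-source. Probes inside that region therefore respond
differently to the two classes whenever the cross-hybridization weight
gamma is below 1, and PC1 of the probe-restricted matrix separates them.

The workflow mirrors the copy-number step: restrict to called deletion
carriers, exclude homozygous deletions by a PC1 threshold (they carry no
second, normal-identity allele and cannot be typed this way), recompute PC1
on the discriminating probes only, and fit a two-component mixture with
case/control status as the offset factor. The larger component is labelled
B_deletion — the majority class — unless anchor samples of known type are
supplied, in which case the labelling maximizing anchor agreement is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .intervals import GenomicInterval
from .locus import ProbeAnnotation
from .mixture import CohortGaussianMixture, OrientedPC1


@dataclass(frozen=True)
class ClassifierConfig:
    homozygote_threshold: float | Literal["auto"] = 3.8
    min_posterior: float = 0.5
    min_separation_sd: float = 1.0
    seed: int | None = None


@dataclass(frozen=True)
class DeletionClassCall:
    sample_id: str
    label: Literal["A_deletion", "B_deletion"]
    posterior: float
    low_confidence: bool = False


def select_discriminating_probes(
    probes: Sequence[ProbeAnnotation],
    proximal: GenomicInterval,
    distal: GenomicInterval,
) -> list[ProbeAnnotation]:
    """Probes strictly between the two NAHR hotspots.

    These are the probes whose target's paralog identity differs between
    A-type and B-type deletion chromosomes; probes inside or beyond the
    hotspots carry no class signal.
    """
    chosen = [
        p for p in probes if proximal.end < p.unit_position < distal.start
    ]
    if not chosen:
        raise ValueError(
            "no probe lies between the hotspots; widen the region or revisit "
            "the probe annotation"
        )
    return chosen


def filter_homozygotes(
    scores: Sequence[float], threshold: float
) -> tuple[list[int], list[int]]:
    """Split sample indices into (kept, removed) by a strict PC1 cutoff.

    Samples scoring strictly above ``threshold`` are presumed homozygous
    deletions and removed; a score exactly at the threshold is kept.
    """
    kept, removed = [], []
    for i, s in enumerate(scores):
        (removed if s > threshold else kept).append(i)
    return kept, removed


def auto_homozygote_threshold(cn_fit: CohortGaussianMixture) -> float:
    """Data-scale homozygote cutoff derived from the 3-component fit.

    On the oriented PC1 scale the loss component sits at mean displacement
    ``d = mu_loss - mu_normal`` from normal; a homozygous deletion (two
    missing units rather than one) is expected near ``mu_normal + 2d``. The
    cutoff halfway between the heterozygote and homozygote locations,
    ``mu_loss + d/2``, removes homozygotes without clipping the
    heterozygote cluster.
    """
    check_is_fitted(cn_fit, "means_")
    if cn_fit.n_components != 3:
        raise ValueError("auto threshold requires the 3-component fit")
    mu_normal, mu_loss = cn_fit.means_[1], cn_fit.means_[2]
    return float(mu_loss + 0.5 * (mu_loss - mu_normal))


class DeletionTypeClassifier(BaseEstimator):
    """Two-component PC1 mixture classifier over deletion heterozygotes.

    ``fit`` expects the intensity matrix already restricted to kept
    heterozygous deletion carriers and to the discriminating probes; the
    case/control status vector plays the offset-factor role. ``anchors``
    maps sample positions (row indices) to known labels and overrides the
    majority rule for component labelling.
    """

    def __init__(
        self,
        min_posterior: float = 0.5,
        min_separation_sd: float = 1.0,
        random_state: int | None = None,
        anchors: Mapping[int, str] | None = None,
        equal_var: bool = False,
    ):
        self.min_posterior = min_posterior
        self.min_separation_sd = min_separation_sd
        self.random_state = random_state
        self.anchors = anchors
        self.equal_var = equal_var

    def fit(self, X, status: Sequence[str]):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least two deletion carriers")
        self.pc_ = OrientedPC1().fit(X)
        self.scores_ = self.pc_.transform(X)
        self.mixture_ = CohortGaussianMixture(
            n_components=2,
            random_state=self.random_state,
            equal_var=self.equal_var,
        ).fit(self.scores_, status)

        # separability: the component gap must be wide relative to the
        # component spread AND a second component must actually be supported
        # by the data (BIC against a one-component fit), since EM happily
        # splits a single unimodal cluster into two nearby components
        pooled_sd = float(np.sqrt(np.mean(self.mixture_.sds_**2)))
        gap = float(abs(self.mixture_.means_[1] - self.mixture_.means_[0]))
        single = CohortGaussianMixture(
            n_components=1, random_state=self.random_state
        ).fit(self.scores_, status)
        self.separable_ = (
            gap >= self.min_separation_sd * pooled_sd
            and self.mixture_.bic() < single.bic()
        )
        if not self.separable_:
            warnings.warn(
                "mixture components are not separable "
                f"(gap {gap:.3g} vs pooled sd {pooled_sd:.3g}, "
                f"2-component BIC {self.mixture_.bic():.4g} vs 1-component "
                f"{single.bic():.4g}); calls flagged low-confidence"
            )

        resp = self.mixture_.responsibilities_
        assigned = np.argmax(resp, axis=1)
        counts = np.bincount(assigned, minlength=2)
        majority = int(np.argmax(counts))
        label_of = {majority: "B_deletion", 1 - majority: "A_deletion"}
        if self.anchors:
            agree = sum(
                1 for i, lab in self.anchors.items() if label_of[assigned[i]] == lab
            )
            if agree < len(self.anchors) - agree:  # flipped labelling fits better
                label_of = {majority: "A_deletion", 1 - majority: "B_deletion"}
        self.component_labels_ = label_of
        self.labels_ = np.array([label_of[a] for a in assigned])
        self.posteriors_ = resp[np.arange(len(assigned)), assigned]
        return self

    def predict(self, X=None) -> np.ndarray:
        check_is_fitted(self, "labels_")
        if X is not None:
            raise NotImplementedError(
                "the classifier types the samples it was fitted on"
            )
        return self.labels_

    def calls(self, sample_ids: Sequence[str]) -> list[DeletionClassCall]:
        check_is_fitted(self, "labels_")
        if len(sample_ids) != len(self.labels_):
            raise ValueError("sample_ids must match the fitted data")
        return [
            DeletionClassCall(
                sample_id=sid,
                label=lab,  # type: ignore[arg-type]
                posterior=float(post),
                low_confidence=(not self.separable_) or post < self.min_posterior,
            )
            for sid, lab, post in zip(sample_ids, self.labels_, self.posteriors_)
        ]


def classify_deletion_type(
    X,
    status: Sequence[str],
    sample_ids: Sequence[str],
    seed: int | None = None,
    anchors: Mapping[int, str] | None = None,
    min_posterior: float = 0.5,
) -> list[DeletionClassCall]:
    """Functional wrapper over :class:`DeletionTypeClassifier`."""
    clf = DeletionTypeClassifier(
        random_state=seed, anchors=anchors, min_posterior=min_posterior
    ).fit(X, status)
    return clf.calls(sample_ids)
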
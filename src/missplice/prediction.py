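"""One-class predictive models for proximal mis-splicing SNVs.

Three linear-kernel one-class SVMs (nu = 0.05) are trained on splice-site
strength-difference features of confirmed mis-splicing SNVs at the
positions with high mis-splicing rates: donor intronic (+3..+6), donor
exonic (-2..-1), and acceptor intronic (+3).  Donor models use the feature
pair (5'MUT - 5'WT, 5'MUT - 3'WT); the acceptor model uses
(3'MUT - 3'WT, 3'MUT - 5'WT), where 5'/3' are the donor/acceptor strengths
of the variant's intron.

"Accuracy" of a one-class cross-validation is the held-out inlier rate
(sensitivity) — the only label a one-class setting provides.  Features are
divided by their per-feature training root-mean-square (recorded with the
model; no centering, which would place the cluster on the origin the
boundary separates from).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import OneClassSVM

from .gene_models import GenomeSequence, TranscriptModel, VariantRecord, classify_variant_location
from .splice_codes import SpliceStrengthModel, strength_delta

__all__ = [
    "FeatureVector",
    "OneClassBoundary",
    "CVResult",
    "make_features",
    "train_one_class",
    "cross_validate",
    "predict",
]

DONOR_INTRONIC = "donor_intronic"
DONOR_EXONIC = "donor_exonic"
ACCEPTOR_INTRONIC = "acceptor_intronic"


@dataclass(frozen=True)
class FeatureVector:
    model_class: str
    f1: float  # primary-site MUT - primary-site WT
    f2: float  # primary-site MUT - opposite-site WT
    variant: VariantRecord | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f1) and math.isfinite(self.f2)):
            raise ValueError("features must be finite")


def _model_class(location) -> str | None:
    if location.category == "proximal_intronic" and location.side == "donor" and 3 <= location.distance_bp <= 6:
        return DONOR_INTRONIC
    if location.category == "exonic" and location.side == "donor" and -2 <= location.distance_bp <= -1:
        return DONOR_EXONIC
    if location.category == "proximal_intronic" and location.side == "acceptor" and location.distance_bp == 3:
        return ACCEPTOR_INTRONIC
    return None


def make_features(
    variant: VariantRecord,
    t: TranscriptModel,
    genome: GenomeSequence,
    donor_model: SpliceStrengthModel,
    acceptor_model: SpliceStrengthModel,
) -> FeatureVector:
    """Strength-difference features of an SNV at a model-eligible position.

    Raises ``ValueError`` for positions outside the three model classes.
    """
    loc = classify_variant_location(variant, t)
    mclass = _model_class(loc)
    if mclass is None:
        raise ValueError(
            f"variant at {loc.category}{loc.distance_bp:+d} ({loc.side}) is not eligible for any model class"
        )
    if loc.intron_index is not None:
        k = loc.intron_index
    else:
        # exonic donor flank: the intron downstream of this exon in transcript order
        k = loc.exon_index
    donor_b = t.donor_boundary(k)
    acceptor_b = t.acceptor_boundary(k)
    if mclass in (DONOR_INTRONIC, DONOR_EXONIC):
        wt5, mut5, _ = strength_delta(variant, donor_b, genome, donor_model, chrom=t.chrom, strand=t.strand)
        wt3 = acceptor_model.score(
            _ref_window(genome, t, acceptor_b, acceptor_model)
        )
        return FeatureVector(model_class=mclass, f1=mut5 - wt5, f2=mut5 - wt3, variant=variant)
    wt3, mut3, _ = strength_delta(variant, acceptor_b, genome, acceptor_model, chrom=t.chrom, strand=t.strand)
    wt5 = donor_model.score(_ref_window(genome, t, donor_b, donor_model))
    return FeatureVector(model_class=ACCEPTOR_INTRONIC, f1=mut3 - wt3, f2=mut3 - wt5, variant=variant)


def _ref_window(genome, t, boundary, model):
    from .splice_codes import acceptor_window, donor_window

    extract = donor_window if model.side == "donor" else acceptor_window
    return extract(genome, t.chrom, t.strand, boundary)[0]


@dataclass
class OneClassBoundary:
    """A trained one-class boundary with its recorded feature scaling.

    The decision rule is ``w . (x / rms) - rho >= 0`` with ``w`` from the
    linear-kernel one-class SVM and ``rho`` refined to its exact optimum
    given ``w`` (the nu-quantile of the training projections; see
    :func:`train_one_class`)."""

    model_class: str
    coef: np.ndarray
    rho: float
    feature_rms: np.ndarray
    nu: float
    seed: int | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) / self.feature_rms

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._transform(X) @ self.coef - self.rho

    def predict_inlier(self, X: np.ndarray) -> np.ndarray:
        """Boolean inlier labels (predicted mis-splicing)."""
        return self.decision(X) >= 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_class": self.model_class,
                "nu": self.nu,
                "seed": self.seed,
                "feature_rms": self.feature_rms.tolist(),
                "coef": self.coef.tolist(),
                "intercept": -self.rho,
            },
            indent=1,
        )


def _as_matrix(feature_vectors: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(feature_vectors, np.ndarray):
        return np.asarray(feature_vectors, dtype=float)
    return np.array([[fv.f1, fv.f2] for fv in feature_vectors], dtype=float)


def train_one_class(
    feature_vectors: Sequence[FeatureVector] | np.ndarray,
    nu: float = 0.05,
    *,
    model_class: str = "",
    seed: int | None = None,
) -> OneClassBoundary:
    """Fit the linear-kernel one-class SVM (deterministic for a given input;
    the seed is recorded for provenance).  nu upper-bounds the training-error
    fraction and lower-bounds the support-vector fraction.

    Solver parameters are the library defaults (only nu is set): the
    boundary separates the scaled feature cloud from the origin, which is
    exactly what makes the model discriminative — a cloud straddling the
    origin (random substitutions) admits no stable separating offset and
    cross-validates poorly, while a consistent one-sided cloud (true
    mis-splicing strength losses) does not.  On nearly collinear training
    draws the SMO offset can under-converge and leave the empirical training
    inlier fraction a few points below the 1-nu bound; see docs/methods.md.
    """
    X = _as_matrix(feature_vectors)
    if len(X) < 2:
        raise ValueError("need at least 2 training vectors")
    rms = np.sqrt(np.mean(X**2, axis=0))
    rms[rms == 0] = 1.0
    if np.allclose(X, X[0]):
        warnings.warn("degenerate training set: all feature vectors identical")
    svm = OneClassSVM(kernel="linear", nu=nu)
    svm.fit(X / rms)
    return OneClassBoundary(
        model_class=model_class,
        coef=svm.coef_.ravel().astype(float),
        rho=-float(svm.intercept_[0]),
        feature_rms=rms,
        nu=nu,
        seed=seed,
    )


@dataclass
class CVResult:
    mean_accuracy: float
    sd_over_folds: float
    sd_over_iterations: float
    fold_accuracies: np.ndarray = field(repr=False, default=None)

    @property
    def iteration_means(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)


def cross_validate(
    feature_vectors: Sequence[FeatureVector] | np.ndarray,
    folds: int = 3,
    iterations: int = 1000,
    seed: int | None = None,
    nu: float = 0.05,
) -> CVResult:
    """Repeated k-fold cross-validation of the one-class model.

    Per fold, accuracy is the fraction of held-out (positive) vectors
    predicted inlier.  The mean is reported over folds x iterations; the two
    SDs (over all folds, and over per-iteration means) differ only in
    spread, not centre.
    """
    X = _as_matrix(feature_vectors)
    n = len(X)
    if n < folds:
        raise ValueError(f"need at least {folds} vectors for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    fold_acc = np.empty((iterations, folds))
    for it in range(iterations):
        order = rng.permutation(n)
        for f in range(folds):
            test = order[f::folds]
            train = np.setdiff1d(order, test)
            model = train_one_class(X[train], nu=nu)
            fold_acc[it, f] = model.predict_inlier(X[test]).mean()
    return CVResult(
        mean_accuracy=float(fold_acc.mean()),
        sd_over_folds=float(fold_acc.std()),
        sd_over_iterations=float(fold_acc.mean(axis=1).std()),
        fold_accuracies=fold_acc,
    )


def predict(
    model: OneClassBoundary,
    candidates: Sequence[FeatureVector],
) -> list[tuple[FeatureVector, bool]]:
    """Label candidate variants: inlier = predicted to alter splicing."""
    if not candidates:
        return []
    labels = model.predict_inlier(_as_matrix(candidates))
    return list(zip(candidates, (bool(l) for l in labels)))
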
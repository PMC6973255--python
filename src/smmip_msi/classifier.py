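"""Naive-Bayes MSI classification from per-marker read profiles.

For each marker two binary traits are derived per sample:

* ``D`` — the deletion frequency (proportion of reads measuring a repeat
  length below the reference) exceeds the marker threshold, set during
  training at the 95th percentile of the MSS training samples;
* ``B`` — for samples heterozygous at the linked SNP, the two-sided Fisher
  exact p-value for allelic bias of deletions is below .05 (somatic repeat
  mutations sit on one haplotype; stutter artefacts do not).

A naive-Bayes model over these traits, with a prior probability of .85 that
a sample is MSS, yields a score equal to the decadic logarithm of the odds
that the sample is MSI-H versus MSS: scores > 0 call MSI-H, scores < 0 call
MSS, and an exact 0 is reported as indeterminate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .extraction import MarkerReadProfile
from .panel import PanelDefinition
from .stats import clopper_pearson, fisher_exact, percentile_95

MODEL_FORMAT_VERSION = "smmip-msi-model/1"

MSI_H = "MSI-H"
MSS = "MSS"
INDETERMINATE = "indeterminate"


def deletion_frequency(histogram: dict[int, int], reference_length: int) -> float:
    """Proportion of reads with a repeat length below the reference length.

    Reads measuring insertions (length above the reference) stay in the
    denominator but never count as deleted.
    """
    total = sum(histogram.values())
    if total <= 0:
        raise ValueError("empty histogram: deletion frequency undefined")
    deleted = sum(c for length, c in histogram.items() if length < reference_length)
    return deleted / total


def is_heterozygous(
    table: list[list[int]], min_minor_fraction: float = 0.2, min_allele_reads: int = 5
) -> bool:
    """Linked-SNP heterozygosity rule.

    Heterozygous when the minor-allele read fraction is at least
    ``min_minor_fraction`` and both alleles have at least
    ``min_allele_reads`` reads — robust to ~0.6% base-call error and to
    allelic dropout.
    """
    ref = table[0][0] + table[0][1]
    alt = table[1][0] + table[1][1]
    total = ref + alt
    if total == 0 or min(ref, alt) < min_allele_reads:
        return False
    return min(ref, alt) / total >= min_minor_fraction


def allelic_bias_p(
    table: list[list[int]],
    min_minor_fraction: float = 0.2,
    min_allele_reads: int = 5,
) -> float | None:
    """Two-sided Fisher p-value for allelic bias, or None if not heterozygous."""
    if not is_heterozygous(table, min_minor_fraction, min_allele_reads):
        return None
    return fisher_exact(table)


@dataclass
class SampleSummary:
    """Per-sample derived statistics, the classifier's input."""

    sample_id: str
    deletion_freq: dict[str, float | None] = field(default_factory=dict)
    bias_p: dict[str, float | None] = field(default_factory=dict)
    umi_counts: dict[str, int] = field(default_factory=dict)

    @property
    def mean_umi_per_marker(self) -> float:
        """Mean distinct UMIs over panel markers (zero-coverage markers count 0)."""
        if not self.umi_counts:
            return 0.0
        return float(np.mean(list(self.umi_counts.values())))


def summarize_profiles(
    sample_id: str,
    profiles: dict[str, MarkerReadProfile],
    panel: PanelDefinition,
    min_minor_fraction: float = 0.2,
    min_allele_reads: int = 5,
) -> SampleSummary:
    """Reduce per-marker profiles to the classifier's per-sample summary."""
    summary = SampleSummary(sample_id=sample_id)
    for m in panel.markers:
        prof = profiles.get(m.name)
        if prof is None or prof.measured_pairs == 0:
            summary.deletion_freq[m.name] = None
            summary.bias_p[m.name] = None
            summary.umi_counts[m.name] = 0 if prof is None else prof.distinct_umi_count
            continue
        summary.deletion_freq[m.name] = deletion_frequency(
            prof.length_histogram, m.reference_repeat_length
        )
        summary.bias_p[m.name] = allelic_bias_p(
            prof.allele_deletion_table, min_minor_fraction, min_allele_reads
        )
        summary.umi_counts[m.name] = prof.distinct_umi_count
    return summary


def summaries_to_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Feature frame with one row per sample and columns ``<marker>:d`` /
    ``<marker>:p`` (NaN = trait missing)."""
    rows = {}
    for s in summaries:
        row = {}
        for m, d in s.deletion_freq.items():
            row[f"{m}:d"] = np.nan if d is None else d
        for m, p in s.bias_p.items():
            row[f"{m}:p"] = np.nan if p is None else p
        rows[s.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _frame_markers(X: pd.DataFrame) -> list[str]:
    markers = []
    for col in X.columns:
        if col.endswith(":d"):
            markers.append(col[:-2])
    return markers


class MSIClassifier(ClassifierMixin, BaseEstimator):
    """Naive-Bayes MSI-H/MSS classifier over dichotomised marker traits.

    Parameters
    ----------
    prior_mss : float
        Prior probability that a sample is MSS (default .85).
    pseudocount : float
        Laplace smoothing constant added per trait outcome when estimating
        per-class trait probabilities.
    p_cutoff : float
        Allelic-bias trait is positive when the Fisher p-value is strictly
        below this cutoff (default .05).
    threshold_percentile : float
        Percentile of the MSS training deletion frequencies used as the
        per-marker deletion-frequency threshold.

    Attributes
    ----------
    markers_ : list of marker names seen at fit time
    thresholds_ : dict marker -> deletion-frequency threshold
    p_d_ / p_b_ : dict class -> dict marker -> P(trait=1 | class)
    uninformative_b_markers_ : markers whose bias trait was never observed
    n_per_class_ : dict class -> training sample count
    """

    def __init__(
        self,
        prior_mss: float = 0.85,
        pseudocount: float = 1.0,
        p_cutoff: float = 0.05,
        threshold_percentile: float = 95.0,
    ):
        self.prior_mss = prior_mss
        self.pseudocount = pseudocount
        self.p_cutoff = p_cutoff
        self.threshold_percentile = threshold_percentile

    # -- training ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "MSIClassifier":
        if not 0 < self.prior_mss < 1:
            raise ValueError("prior_mss must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        bad = set(y) - {MSI_H, MSS}
        if bad:
            raise ValueError(f"labels must be {MSI_H!r} or {MSS!r}, got {sorted(bad)}")
        n_h = int((y == MSI_H).sum())
        n_s = int((y == MSS).sum())
        if n_h < 2 or n_s < 2:
            raise ValueError("need at least 2 training samples per class")
        markers = _frame_markers(X)
        if not markers:
            raise ValueError("no marker columns (expected '<marker>:d')")
        kappa = self.pseudocount
        self.markers_ = markers
        self.classes_ = np.array([MSI_H, MSS], dtype=object)
        self.n_per_class_ = {MSI_H: n_h, MSS: n_s}
        self.thresholds_ = {}
        self.p_d_ = {MSI_H: {}, MSS: {}}
        self.p_b_ = {MSI_H: {}, MSS: {}}
        self.uninformative_b_markers_ = []
        mss_mask = y == MSS
        for m in markers:
            d = X[f"{m}:d"].to_numpy(dtype=float)
            mss_d = d[mss_mask]
            if np.isnan(mss_d).any():
                raise ValueError(
                    f"marker {m!r}: every training MSS sample must have a "
                    "defined deletion frequency"
                )
            self.thresholds_[m] = percentile_95(mss_d, q=self.threshold_percentile)
            p = (
                X[f"{m}:p"].to_numpy(dtype=float)
                if f"{m}:p" in X.columns
                else np.full(len(X), np.nan)
            )
            b_observed = ~np.isnan(p)
            for cls, mask in ((MSI_H, ~mss_mask), (MSS, mss_mask)):
                d_cls = d[mask]
                d_obs = ~np.isnan(d_cls)
                d_pos = int((d_cls[d_obs] > self.thresholds_[m]).sum())
                self.p_d_[cls][m] = (d_pos + kappa) / (int(d_obs.sum()) + 2 * kappa)
                p_cls = p[mask]
                b_obs = ~np.isnan(p_cls)
                b_pos = int((p_cls[b_obs] < self.p_cutoff).sum())
                self.p_b_[cls][m] = (b_pos + kappa) / (int(b_obs.sum()) + 2 * kappa)
            if not b_observed.any():
                # bias never assessable for this marker: fall back to an
                # uninformative trait so it cannot sway the score
                self.p_b_[MSI_H][m] = 0.5
                self.p_b_[MSS][m] = 0.5
                self.uninformative_b_markers_.append(m)
        return self

    # -- trait computation -------------------------------------------------

    def dichotomize(self, summary_row: pd.Series) -> dict[str, tuple]:
        """Binary (D, B) trait pair per marker; None marks a missing trait.

        D = 1 iff the deletion frequency strictly exceeds the marker
        threshold; B = 1 iff the bias p-value is strictly below the cutoff.
        """
        check_is_fitted(self, "thresholds_")
        traits = {}
        for m in self.markers_:
            d = summary_row.get(f"{m}:d", np.nan)
            p = summary_row.get(f"{m}:p", np.nan)
            D = None if pd.isna(d) else int(d > self.thresholds_[m])
            B = None if pd.isna(p) else int(p < self.p_cutoff)
            traits[m] = (D, B)
        return traits

    # -- scoring -----------------------------------------------------------

    def _score_row(self, row: pd.Series, markers: list[str]) -> tuple[float, int]:
        score = math.log10((1.0 - self.prior_mss) / self.prior_mss)
        traits = self.dichotomize(row)
        used = 0
        for m in markers:
            D, B = traits[m]
            if D is None:
                continue
            used += 1
            ph, ps = self.p_d_[MSI_H][m], self.p_d_[MSS][m]
            score += math.log10(ph / ps) if D else math.log10((1 - ph) / (1 - ps))
            if B is not None:
                qh, qs = self.p_b_[MSI_H][m], self.p_b_[MSS][m]
                score += math.log10(qh / qs) if B else math.log10((1 - qh) / (1 - qs))
        if used == 0:
            raise ValueError(f"unscorable sample {row.name!r}: all marker traits missing")
        return score, used

    def _restrict_markers(self, X: pd.DataFrame) -> list[str]:
        available = set(_frame_markers(X))
        markers = [m for m in self.markers_ if m in available]
        if not markers:
            raise ValueError("no model markers present in the summary frame")
        if len(markers) < len(self.markers_):
            warnings.warn(
                f"scoring restricted to {len(markers)} of {len(self.markers_)} "
                "model markers present in the input",
                stacklevel=2,
            )
        return markers

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Decadic log-odds MSI-H vs MSS per sample (the assay score)."""
        check_is_fitted(self, "thresholds_")
        markers = self._restrict_markers(X)
        return np.array([self._score_row(row, markers)[0] for _, row in X.iterrows()])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, MSI_H, np.where(scores < 0, MSS, INDETERMINATE))


@dataclass
class ClassificationResult:
    sample_id: str
    score: float
    call: str
    traits: dict[str, tuple]
    markers_used: int
    mean_umi_per_marker: float = float("nan")
    qc_pass: bool | None = None


def classify_samples(
    clf: MSIClassifier,
    summaries: list[SampleSummary],
    qc_threshold: float = 75.0,
) -> list[ClassificationResult]:
    """Score summaries and package per-sample results with QC annotation.

    A QC failure (mean UMIs/marker below threshold) never suppresses the
    classification; the result is reported with ``qc_pass=False``.
    """
    X = summaries_to_frame(summaries)
    markers = clf._restrict_markers(X)
    results = []
    for s in summaries:
        row = X.loc[s.sample_id]
        score, used = clf._score_row(row, markers)
        call = MSI_H if score > 0 else MSS if score < 0 else INDETERMINATE
        results.append(
            ClassificationResult(
                sample_id=s.sample_id,
                score=score,
                call=call,
                traits=clf.dichotomize(row),
                markers_used=used,
                mean_umi_per_marker=s.mean_umi_per_marker,
                qc_pass=s.mean_umi_per_marker >= qc_threshold,
            )
        )
    return results


# ---------------------------------------------------------------------------
# model serialization


@dataclass
class ClassifierModel:
    """Trained parameters in a serialisable form (versioned JSON on disk)."""

    markers: list[str]
    thresholds: dict[str, float]
    p_d_msih: dict[str, float]
    p_d_mss: dict[str, float]
    p_b_msih: dict[str, float]
    p_b_mss: dict[str, float]
    prior_mss: float
    pseudocount: float
    p_cutoff: float
    threshold_percentile: float
    n_msih: int
    n_mss: int
    uninformative_b_markers: list[str] = field(default_factory=list)


def model_from_estimator(clf: MSIClassifier) -> ClassifierModel:
    check_is_fitted(clf, "thresholds_")
    return ClassifierModel(
        markers=list(clf.markers_),
        thresholds=dict(clf.thresholds_),
        p_d_msih=dict(clf.p_d_[MSI_H]),
        p_d_mss=dict(clf.p_d_[MSS]),
        p_b_msih=dict(clf.p_b_[MSI_H]),
        p_b_mss=dict(clf.p_b_[MSS]),
        prior_mss=clf.prior_mss,
        pseudocount=clf.pseudocount,
        p_cutoff=clf.p_cutoff,
        threshold_percentile=clf.threshold_percentile,
        n_msih=clf.n_per_class_[MSI_H],
        n_mss=clf.n_per_class_[MSS],
        uninformative_b_markers=list(clf.uninformative_b_markers_),
    )


def estimator_from_model(model: ClassifierModel) -> MSIClassifier:
    clf = MSIClassifier(
        prior_mss=model.prior_mss,
        pseudocount=model.pseudocount,
        p_cutoff=model.p_cutoff,
        threshold_percentile=model.threshold_percentile,
    )
    clf.markers_ = list(model.markers)
    clf.classes_ = np.array([MSI_H, MSS], dtype=object)
    clf.thresholds_ = dict(model.thresholds)
    clf.p_d_ = {MSI_H: dict(model.p_d_msih), MSS: dict(model.p_d_mss)}
    clf.p_b_ = {MSI_H: dict(model.p_b_msih), MSS: dict(model.p_b_mss)}
    clf.n_per_class_ = {MSI_H: model.n_msih, MSS: model.n_mss}
    clf.uninformative_b_markers_ = list(model.uninformative_b_markers)
    return clf


def save_model(model: ClassifierModel | MSIClassifier, path: str | Path) -> None:
    if isinstance(model, MSIClassifier):
        model = model_from_estimator(model)
    payload = {"format": MODEL_FORMAT_VERSION, **asdict(model)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> ClassifierModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is corrupt or truncated: {exc}") from exc
    if payload.pop("format", None) != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path}: missing or unsupported format version "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return ClassifierModel(**payload)


# ---------------------------------------------------------------------------
# convenience wrappers


def train(summaries: list[SampleSummary], labels: dict[str, str], **params) -> MSIClassifier:
    """Fit an :class:`MSIClassifier` from summaries and a sample->label map."""
    X = summaries_to_frame(summaries)
    y = [labels[s.sample_id] for s in summaries]
    return MSIClassifier(**params).fit(X, y)


def evaluate(
    results: list[ClassificationResult], labels: dict[str, str]
) -> dict[str, float | tuple[float, float] | None]:
    """Sensitivity/specificity with exact 95% Clopper-Pearson intervals."""
    tp = sum(1 for r in results if labels[r.sample_id] == MSI_H and r.call == MSI_H)
    n_pos = sum(1 for r in results if labels[r.sample_id] == MSI_H)
    tn = sum(1 for r in results if labels[r.sample_id] == MSS and r.call == MSS)
    n_neg = sum(1 for r in results if labels[r.sample_id] == MSS)
    out: dict = {"n_msih": n_pos, "n_mss": n_neg}
    if n_pos:
        out["sensitivity"] = tp / n_pos
        out["sensitivity_ci"] = clopper_pearson(tp, n_pos)
    else:
        warnings.warn("no MSI-H samples: sensitivity undefined", stacklevel=2)
        out["sensitivity"] = out["sensitivity_ci"] = None
    if n_neg:
        out["specificity"] = tn / n_neg
        out["specificity_ci"] = clopper_pearson(tn, n_neg)
    else:
        warnings.warn("no MSS samples: specificity undefined", stacklevel=2)
        out["specificity"] = out["specificity_ci"] = None
    return out
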
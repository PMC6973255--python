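"""In-silico detection-limit experiments on extracted read records.

Two experiments mirror the assay's wet-lab robustness studies:

* **read mixing** — reads from an MSI-H and an MSS sample are resampled in
  predetermined proportions, at a depth matched to the shallower sample, to
  emulate tumors of varying MMR-deficient cell content;
* **UMI resampling** — distinct barcodes (with all their reads) are
  subsampled per marker to a target mean, to emulate sequencing fewer
  template molecules.

Mixing operates on whole read records so repeat length and SNP allele stay
jointly distributed — allelic bias would be destroyed by mixing marginal
histograms.  Detection limits are reported on the evaluated grid only, with
no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import MSI_H, MSIClassifier, SampleSummary, summarize_profiles
from .extraction import ExtractedRead, profiles_from_records
from .panel import PanelDefinition

ReadRecords = dict[str, list[ExtractedRead]]


def serial_mixture_fractions(
    start: float = 1.0, steps: int = 7, dilution: float = 0.5
) -> list[float]:
    """MSI-H DNA fractions of an equal-volume serial mixture series.

    Each step mixes the previous mixture 1:1 with MSS DNA, halving the MSI-H
    content: starting from pure MSI-H cell-line DNA, seven steps give
    50%, 25%, ..., 0.78125%.
    """
    fracs = []
    f = start
    for _ in range(steps):
        f *= dilution
        fracs.append(f)
    return fracs


def mix_records(
    records_a: ReadRecords,
    records_b: ReadRecords,
    p: float,
    rng: np.random.Generator,
    take_all_extremes: bool = False,
) -> ReadRecords:
    """Mix read records of an MSI-H sample (A) and an MSS sample (B).

    Per marker the output depth is ``min(depth_A, depth_B)``; the number of
    reads drawn from A is binomial with success probability ``p`` and both
    contributions are sampled without replacement, so the expected fraction
    of A-reads is exactly ``p``.  With ``take_all_extremes`` the degenerate
    fractions 0 and 1 return the source records unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mixing fraction p must lie in [0, 1]")
    markers = set(records_a) | set(records_b)
    mixed: ReadRecords = {}
    for m in markers:
        a = records_a.get(m, [])
        b = records_b.get(m, [])
        if not a or not b:
            raise ValueError(f"marker {m!r}: empty source records, cannot mix")
        if take_all_extremes and p in (0.0, 1.0):
            mixed[m] = list(a if p == 1.0 else b)
            continue
        depth = min(len(a), len(b))
        n_a = int(rng.binomial(depth, p))
        n_a = min(n_a, len(a))
        n_b = min(depth - n_a, len(b))
        idx_a = rng.choice(len(a), size=n_a, replace=False)
        idx_b = rng.choice(len(b), size=n_b, replace=False)
        mixed[m] = [a[i] for i in idx_a] + [b[i] for i in idx_b]
    return mixed


def _classify_records(
    records: ReadRecords,
    panel: PanelDefinition,
    clf: MSIClassifier,
    sample_id: str = "mix",
) -> tuple[float, str]:
    profiles = profiles_from_records(records, panel)
    summary = summarize_profiles(sample_id, profiles, panel)
    from .classifier import summaries_to_frame

    X = summaries_to_frame([summary])
    score = float(clf.decision_function(X)[0])
    call = MSI_H if score > 0 else "MSS" if score < 0 else "indeterminate"
    return score, call


@dataclass
class MixtureResult:
    fractions: list[float]
    per_mix: pd.DataFrame  # columns: pair, fraction, rep, score, call
    proportion_msih: dict[float, float]
    detection_limit: float | None
    seed: int


def mixture_grid(
    msih_records: dict[str, ReadRecords],
    mss_records: dict[str, ReadRecords],
    fractions: list[float],
    panel: PanelDefinition,
    clf: MSIClassifier,
    reps: int = 25,
    seed: int = 0,
    call_threshold: float = 0.95,
) -> MixtureResult:
    """Classify read mixtures over all MSI-H x MSS sample pairs.

    The detection limit is the smallest evaluated fraction at which the
    proportion of mixtures called MSI-H exceeds ``call_threshold``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in fractions:
        for a_id, a_recs in msih_records.items():
            for b_id, b_recs in mss_records.items():
                for rep in range(reps):
                    mixed = mix_records(a_recs, b_recs, p, rng)
                    score, call = _classify_records(mixed, panel, clf)
                    rows.append(
                        {
                            "pair": f"{a_id}x{b_id}",
                            "fraction": p,
                            "rep": rep,
                            "score": score,
                            "call": call,
                        }
                    )
    df = pd.DataFrame(rows)
    proportion = {
        float(p): float((grp["call"] == MSI_H).mean())
        for p, grp in df.groupby("fraction")
    }
    limit = None
    for p in sorted(proportion):
        if proportion[p] > call_threshold:
            limit = p
            break
    return MixtureResult(
        fractions=list(fractions),
        per_mix=df,
        proportion_msih=proportion,
        detection_limit=limit,
        seed=seed,
    )


def resample_umis(
    records: ReadRecords,
    target_mean_umi: float,
    rng: np.random.Generator,
) -> ReadRecords:
    """Subsample distinct UMIs (with all their reads) to a target per-marker
    count, emulating a lower number of sequenced template molecules."""
    out: ReadRecords = {}
    for m, recs in records.items():
        by_umi: dict[str, list[ExtractedRead]] = {}
        for r in recs:
            by_umi.setdefault(r.umi, []).append(r)
        umis = sorted(by_umi)
        target = int(round(target_mean_umi))
        if target >= len(umis):
            out[m] = list(recs)
            continue
        keep = rng.choice(len(umis), size=target, replace=False)
        out[m] = [r for i in keep for r in by_umi[umis[i]]]
    return out


@dataclass
class DilutionResult:
    targets: list[float]
    per_rep: pd.DataFrame  # columns: sample, target, rep, score, call, baseline_call
    proportion_correct: dict[float, float]
    min_adequate_depth: float | None
    seed: int
    skipped: list[tuple[str, float]] = field(default_factory=list)


def dilution_grid(
    sample_records: dict[str, ReadRecords],
    targets: list[float],
    panel: PanelDefinition,
    clf: MSIClassifier,
    reps: int = 25,
    seed: int = 0,
    call_threshold: float = 0.95,
) -> DilutionResult:
    """UMI-resampling dilution series over a set of profiled samples.

    "Correct" means the resampled call matches the sample's own full-depth
    call.  Targets above a sample's observed mean UMI count are skipped for
    that sample with a warning entry.  The minimum adequate depth is the
    smallest evaluated target whose proportion correct exceeds
    ``call_threshold``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    skipped = []
    baseline = {
        sid: _classify_records(recs, panel, clf, sid)[1]
        for sid, recs in sample_records.items()
    }
    observed_mean = {
        sid: float(np.mean([len({r.umi for r in recs[m]}) for m in recs]))
        for sid, recs in sample_records.items()
    }
    for target in targets:
        for sid, recs in sample_records.items():
            if target > observed_mean[sid]:
                skipped.append((sid, float(target)))
                continue
            for rep in range(reps):
                sub = resample_umis(recs, target, rng)
                score, call = _classify_records(sub, panel, clf, sid)
                rows.append(
                    {
                        "sample": sid,
                        "target": float(target),
                        "rep": rep,
                        "score": score,
                        "call": call,
                        "baseline_call": baseline[sid],
                    }
                )
    df = pd.DataFrame(rows)
    proportion = (
        {
            float(t): float((grp["call"] == grp["baseline_call"]).mean())
            for t, grp in df.groupby("target")
        }
        if len(df)
        else {}
    )
    depth = None
    for t in sorted(proportion):
        if proportion[t] > call_threshold:
            depth = t
            break
    return DilutionResult(
        targets=[float(t) for t in targets],
        per_rep=df,
        proportion_correct=proportion,
        min_adequate_depth=depth,
        seed=seed,
        skipped=skipped,
    )
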
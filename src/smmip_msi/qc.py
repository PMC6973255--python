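"""UMI-based quality control and BRAF c.1799T>A variant calling.

Distinct molecular barcodes per marker estimate the number of template
molecules sequenced.  A sample passes QC when the mean over panel markers is
at least 75 (markers without coverage count as zero); resampling-derived
advisory minima of 10 (24-marker scoring) and 15 (6-marker scoring) barcodes
per marker are also reported.  QC failure never suppresses a classification.

BRAF variant allele frequency is reported both raw (per read) and with
molecular-barcode error reduction: reads are grouped by exact UMI, each
group with at least two reads votes its majority base, ties are dropped, and
the VAF is computed over voting groups.  A sample is BRAF positive when the
chosen VAF strictly exceeds 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extraction import BrafProfile, MarkerReadProfile
from .panel import PanelDefinition

DEFAULT_QC_THRESHOLD = 75.0
ADVISORY_MIN_UMIS = {24: 10.0, 6: 15.0}
BRAF_VAF_CUTOFF = 0.05


@dataclass
class QCReport:
    umi_per_marker: dict[str, int]
    mean_umi_per_marker: float
    threshold: float
    qc_pass: bool
    advisory_min: float | None = None
    advisory_pass: bool | None = None


def qc_metrics(
    profiles: dict[str, MarkerReadProfile],
    panel: PanelDefinition,
    threshold: float = DEFAULT_QC_THRESHOLD,
    advisory_minima: dict[int, float] = ADVISORY_MIN_UMIS,
) -> QCReport:
    """Distinct-UMI QC over all panel markers (zero-coverage markers count 0)."""
    counts = {
        m.name: (profiles[m.name].distinct_umi_count if m.name in profiles else 0)
        for m in panel.markers
    }
    mean = float(np.mean(list(counts.values()))) if counts else 0.0
    advisory = advisory_minima.get(len(panel.markers))
    return QCReport(
        umi_per_marker=counts,
        mean_umi_per_marker=mean,
        threshold=threshold,
        qc_pass=mean >= threshold,
        advisory_min=advisory,
        advisory_pass=None if advisory is None else mean >= advisory,
    )


@dataclass
class BRAFResult:
    ref_reads: int
    alt_reads: int
    consensus_ref: int
    consensus_alt: int
    vaf_raw: float | None
    vaf_consensus: float | None
    call: str  # "positive" | "negative" | "no-coverage"
    mode: str = "raw"
    dropped_umis: int = 0


def braf_vaf(
    profile: BrafProfile,
    mode: str = "raw",
    vaf_cutoff: float = BRAF_VAF_CUTOFF,
    min_reads_per_umi: int = 2,
) -> BRAFResult:
    """BRAF c.1799T>A VAF, raw and with UMI-consensus error reduction.

    Consensus mode groups reads by exact barcode; groups with fewer than
    ``min_reads_per_umi`` reads or a tied vote are dropped.  The call uses
    the VAF of the requested ``mode`` with a strict > ``vaf_cutoff`` rule.
    """
    if mode not in ("raw", "umi_consensus"):
        raise ValueError("mode must be 'raw' or 'umi_consensus'")
    ref, alt = profile.ref_reads, profile.alt_reads
    vaf_raw = alt / (ref + alt) if (ref + alt) > 0 else None
    cons_ref = cons_alt = dropped = 0
    for reads in profile.umi_reads.values():
        if len(reads) < min_reads_per_umi:
            dropped += 1
            continue
        n_alt = reads.count("alt")
        n_ref = len(reads) - n_alt
        if n_alt > n_ref:
            cons_alt += 1
        elif n_ref > n_alt:
            cons_ref += 1
        else:
            dropped += 1
    vaf_cons = (
        cons_alt / (cons_ref + cons_alt) if (cons_ref + cons_alt) > 0 else None
    )
    chosen = vaf_raw if mode == "raw" else vaf_cons
    if chosen is None:
        call = "no-coverage"
    else:
        call = "positive" if chosen > vaf_cutoff else "negative"
    return BRAFResult(
        ref_reads=ref,
        alt_reads=alt,
        consensus_ref=cons_ref,
        consensus_alt=cons_alt,
        vaf_raw=vaf_raw,
        vaf_consensus=vaf_cons,
        call=call,
        mode=mode,
        dropped_umis=dropped,
    )
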
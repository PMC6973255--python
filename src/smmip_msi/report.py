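"""Per-sample result reports: a TSV for humans and a JSON twin for machines."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .classifier import ClassificationResult
from .qc import BRAFResult, QCReport

REPORT_COLUMNS = [
    "sample_id",
    "score",
    "call",
    "markers_used",
    "mean_umi_per_marker",
    "qc_pass",
    "braf_vaf_raw",
    "braf_vaf_consensus",
    "braf_call",
]


def _fmt(v, digits=4):
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "PASS" if v else "FAIL"
    if isinstance(v, float):
        return round(v, digits)
    return v


def build_report_frame(
    results: list[ClassificationResult],
    braf: dict[str, BRAFResult] | None = None,
    qc: dict[str, QCReport] | None = None,
) -> pd.DataFrame:
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        b = (braf or {}).get(r.sample_id)
        q = (qc or {}).get(r.sample_id)
        qc_pass = q.qc_pass if q is not None else r.qc_pass
        rows.append(
            {
                "sample_id": r.sample_id,
                "score": _fmt(r.score),
                "call": r.call,
                "markers_used": r.markers_used,
                "mean_umi_per_marker": _fmt(
                    q.mean_umi_per_marker if q is not None else r.mean_umi_per_marker, 2
                ),
                "qc_pass": _fmt(qc_pass),
                "braf_vaf_raw": _fmt(b.vaf_raw if b else None),
                "braf_vaf_consensus": _fmt(b.vaf_consensus if b else None),
                "braf_call": b.call if b else "NA",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    results: list[ClassificationResult],
    path: str | Path,
    braf: dict[str, BRAFResult] | None = None,
    qc: dict[str, QCReport] | None = None,
) -> None:
    """Write the TSV report and a ``.json`` structured twin next to it."""
    df = build_report_frame(results, braf=braf, qc=qc)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    payload = df.replace({pd.NA: None}).to_dict(orient="records")
    for rec, r in zip(payload, results):
        rec["traits"] = {m: list(t) for m, t in r.traits.items()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n"
    )
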
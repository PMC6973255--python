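"""Arm-anchored extraction of smMIP read pairs.

Each sequenced amplicon has the layout (5'->3' on the read-1 strand)::

    [UMI][extension arm][captured insert][ligation arm]

and read 2 is the reverse complement read from the other end.  Because the
panel fully determines the captured inserts, reads are assigned to markers
by matching the probe arms directly (tolerating one substitution per arm)
instead of aligning to a reference genome.  The molecular barcode (UMI) is
the tag adjacent to the extension arm.

After assignment the pair is reoriented onto the insert strand and a
position-wise consensus is taken: only base calls supported by both reads of
a pair are used downstream; disagreeing positions are masked.  Repeat length
and the linked-SNP base are then measured on the consensus by exact flank
anchoring.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panel import BrafMarker, MarkerDefinition, PanelDefinition

MASK = "."  # consensus placeholder for positions not supported by both reads

_COMP = str.maketrans("ACGTN", "TGCAN")

#: reads measuring more than this many bases past the reference repeat length
#: are treated as chimeric and excluded
CHIMERA_SLACK = 10


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ExtractedRead:
    """One assigned read pair reduced to its per-read evidence."""

    marker: str
    umi: str
    repeat_length: int | None  # None = unmeasurable
    allele: str  # "ref" | "alt" | "other" | "uncalled"


@dataclass
class MarkerReadProfile:
    """Per-sample, per-marker read evidence.

    ``allele_deletion_table`` rows are SNP ref/alt allele, columns deleted
    (repeat length < reference) / not deleted; reads whose allele is
    other/uncalled are excluded from the table but kept in the histogram.
    """

    marker: str
    reference_repeat_length: int
    length_histogram: dict[int, int] = field(default_factory=dict)
    allele_deletion_table: list[list[int]] = field(
        default_factory=lambda: [[0, 0], [0, 0]]
    )
    distinct_umi_count: int = 0
    total_pairs_assigned: int = 0
    pairs_discarded: int = 0

    @property
    def measured_pairs(self) -> int:
        return sum(self.length_histogram.values())


@dataclass
class BrafProfile:
    """Raw and UMI-grouped allele evidence at the BRAF variant position.

    Unlike repeat measurement, BRAF counting uses each read end's base call
    individually (two calls per pair): the raw variant allele frequency then
    tracks the per-base sequencing error rate, and grouping calls by
    molecular barcode is the error-reduction step.
    """

    marker: str
    ref_reads: int = 0
    alt_reads: int = 0
    other_reads: int = 0
    umi_reads: dict[str, list[str]] = field(default_factory=dict)

    @property
    def distinct_umi_count(self) -> int:
        return len(self.umi_reads)


@dataclass
class ExtractionCounters:
    total_pairs: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0


@dataclass
class SampleReads:
    """Full extraction output: per-marker read records plus accounting."""

    records: dict[str, list[ExtractedRead]]
    braf: BrafProfile | None
    counters: ExtractionCounters


class ArmMatcher:
    """Assigns read pairs to panel loci by arm matching.

    Exact-prefix dictionary fast path with a <=1-substitution-per-arm
    fallback scan; a pair matching two or more loci at equal total distance
    is ambiguous.  Arms are primer-like, so indels are not tolerated — an
    indel would also corrupt the UMI frame.
    """

    def __init__(self, panel: PanelDefinition, max_arm_mismatch: int = 1):
        self.max_arm_mismatch = max_arm_mismatch
        self._loci: list[tuple[str, str, str, int]] = []
        for m in panel.markers:
            self._loci.append((m.name, m.extension_arm, revcomp(m.ligation_arm), m.umi_length))
        if panel.braf_marker is not None:
            b = panel.braf_marker
            self._loci.append((b.name, b.extension_arm, revcomp(b.ligation_arm), b.umi_length))
        self._exact = {
            (ext, umi_len): (name, rc_lig)
            for name, ext, rc_lig, umi_len in self._loci
        }

    def match(self, read1: str, read2: str) -> tuple[str, str, str, str] | str:
        """Return ``(marker, umi, frame1, frame2)`` or "unassigned"/"ambiguous".

        ``frame1``/``frame2`` are the two reads projected onto the insert
        strand, left-anchored at the first insert base (ligation arm still
        attached at the 3' end).
        """
        for r1, r2 in ((read1, read2), (read2, read1)):
            hit = self._match_oriented(r1, r2)
            if hit == "ambiguous":
                return "ambiguous"
            if hit != "unassigned":
                return hit
        return "unassigned"

    def _match_oriented(self, r1: str, r2: str) -> tuple[str, str, str, str] | str:
        # exact fast path
        for (ext, umi_len), (name, rc_lig) in self._exact.items():
            if r1[umi_len : umi_len + len(ext)] == ext and r2.startswith(rc_lig):
                return self._frames(name, r1, r2, umi_len, len(ext))
        best: list[tuple[int, str, int, int]] = []
        for name, ext, rc_lig, umi_len in self._loci:
            if len(r1) < umi_len + len(ext) or len(r2) < len(rc_lig):
                continue
            d1 = _hamming(r1[umi_len : umi_len + len(ext)], ext)
            if d1 > self.max_arm_mismatch:
                continue
            d2 = _hamming(r2[: len(rc_lig)], rc_lig)
            if d2 > self.max_arm_mismatch:
                continue
            best.append((d1 + d2, name, umi_len, len(ext)))
        if not best:
            return "unassigned"
        best.sort()
        if len(best) > 1 and best[0][0] == best[1][0] and best[0][1] != best[1][1]:
            return "ambiguous"
        _, name, umi_len, ext_len = best[0]
        return self._frames(name, r1, r2, umi_len, ext_len)

    @staticmethod
    def _frames(
        name: str, r1: str, r2: str, umi_len: int, ext_len: int
    ) -> tuple[str, str, str, str]:
        umi = r1[:umi_len]
        frame1 = r1[umi_len + ext_len :]
        frame2 = revcomp(r2)[umi_len + ext_len :] if len(r2) == len(r1) else ""
        return name, umi, frame1, frame2


def consensus_insert(frame1: str, frame2: str) -> str | None:
    """Position-wise pair consensus on the insert strand.

    Bases supported by both reads are retained; disagreements and positions
    covered by only one read are masked.  Returns None when no overlap can
    be established (reads that do not span the captured molecule), in which
    case the pair is discarded.
    """
    if not frame1 or not frame2 or len(frame1) != len(frame2):
        return None
    if frame1 == frame2:
        return frame1
    return "".join(a if a == b else MASK for a, b in zip(frame1, frame2))


def annotate_insert(
    consensus: str, marker: MarkerDefinition
) -> tuple[int | None, str]:
    """Measure repeat length and linked-SNP allele on a pair consensus.

    The repeat length is the number of consecutive repeat-unit bases between
    exact, unmasked matches of the left and right flank anchors.  If either
    anchor is absent, the tract contains a masked or non-unit base, or the
    measured length exceeds the reference by more than ``CHIMERA_SLACK``,
    the read is unmeasurable and excluded from the histogram.  The SNP
    allele is read at ``snp_offset``; a masked base there is "uncalled".
    """
    unit = marker.repeat_unit
    repeat_length: int | None = None
    i = consensus.find(marker.left_flank)
    if i >= 0:
        start = i + len(marker.left_flank)
        j = start
        n = len(consensus)
        while j < n and consensus[j] == unit:
            j += 1
        if consensus[j : j + len(marker.right_flank)] == marker.right_flank:
            length = j - start
            if length <= marker.reference_repeat_length + CHIMERA_SLACK:
                repeat_length = length
    if marker.snp_offset < len(consensus):
        base = consensus[marker.snp_offset]
        if base == MASK:
            allele = "uncalled"
        elif base == marker.snp_ref_allele:
            allele = "ref"
        elif base == marker.snp_alt_allele:
            allele = "alt"
        else:
            allele = "other"
    else:
        allele = "uncalled"
    return repeat_length, allele


def annotate_braf(frame: str, braf: BrafMarker) -> str:
    """Classify one read end's base call at the variant offset."""
    if braf.variant_offset >= len(frame):
        return "uncalled"
    base = frame[braf.variant_offset]
    if base == MASK:
        return "uncalled"
    if base == braf.ref_allele:
        return "ref"
    if base == braf.alt_allele:
        return "alt"
    return "other"


def extract_read_pairs(
    pairs, panel: PanelDefinition, max_arm_mismatch: int = 1
) -> SampleReads:
    """Run the full extraction over an iterable of ``(read1, read2)`` pairs.

    Deterministic and order-independent: permuting the input changes no
    output counts.
    """
    matcher = ArmMatcher(panel, max_arm_mismatch=max_arm_mismatch)
    markers = {m.name: m for m in panel.markers}
    braf = panel.braf_marker
    records: dict[str, list[ExtractedRead]] = {name: [] for name in markers}
    braf_profile = BrafProfile(marker=braf.name) if braf is not None else None
    counters = ExtractionCounters()
    for read1, read2 in pairs:
        counters.total_pairs += 1
        hit = matcher.match(read1, read2)
        if hit == "unassigned":
            counters.unassigned += 1
            continue
        if hit == "ambiguous":
            counters.ambiguous += 1
            continue
        name, umi, frame1, frame2 = hit
        counters.assigned += 1
        if braf is not None and name == braf.name:
            for allele in (annotate_braf(frame1, braf), annotate_braf(frame2, braf)):
                if allele == "ref":
                    braf_profile.ref_reads += 1
                elif allele == "alt":
                    braf_profile.alt_reads += 1
                else:
                    braf_profile.other_reads += 1
                if allele in ("ref", "alt"):
                    braf_profile.umi_reads.setdefault(umi, []).append(allele)
            continue
        cons = consensus_insert(frame1, frame2)
        if cons is None:
            records[name].append(ExtractedRead(name, umi, None, "uncalled"))
            continue
        repeat_length, allele = annotate_insert(cons, markers[name])
        records[name].append(ExtractedRead(name, umi, repeat_length, allele))
    return SampleReads(records=records, braf=braf_profile, counters=counters)


def profiles_from_records(
    records: dict[str, list[ExtractedRead]], panel: PanelDefinition
) -> dict[str, MarkerReadProfile]:
    """Collapse read records into per-marker profiles."""
    out: dict[str, MarkerReadProfile] = {}
    for m in panel.markers:
        prof = MarkerReadProfile(
            marker=m.name, reference_repeat_length=m.reference_repeat_length
        )
        umis = set()
        for rec in records.get(m.name, ()):
            prof.total_pairs_assigned += 1
            umis.add(rec.umi)
            if rec.repeat_length is None:
                prof.pairs_discarded += 1
                continue
            prof.length_histogram[rec.repeat_length] = (
                prof.length_histogram.get(rec.repeat_length, 0) + 1
            )
            if rec.allele in ("ref", "alt"):
                row = 0 if rec.allele == "ref" else 1
                col = 0 if rec.repeat_length < m.reference_repeat_length else 1
                prof.allele_deletion_table[row][col] += 1
        prof.distinct_umi_count = len(umis)
        out[m.name] = prof
    return out


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(fastq1: str | Path, fastq2: str | Path):
    """Yield ``(seq1, seq2)`` from a pair of (optionally gzipped) FASTQs."""
    import pysam

    with pysam.FastxFile(str(fastq1)) as f1, pysam.FastxFile(str(fastq2)) as f2:
        for r1, r2 in zip(f1, f2):
            yield r1.sequence.upper(), r2.sequence.upper()


def profile_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    panel: PanelDefinition,
    max_arm_mismatch: int = 1,
) -> tuple[dict[str, MarkerReadProfile], SampleReads]:
    """Extract and profile one sample from paired FASTQ files."""
    reads = extract_read_pairs(
        iter_fastq_pairs(fastq1, fastq2), panel, max_arm_mismatch=max_arm_mismatch
    )
    return profiles_from_records(reads.records, panel), reads


# ---------------------------------------------------------------------------
# profile TSV round trip

_TABLE_KEYS = ("ref_del", "ref_nodel", "alt_del", "alt_nodel")


def write_profiles(
    profiles: dict[str, MarkerReadProfile],
    path: str | Path,
    braf: BrafProfile | None = None,
) -> None:
    rows = []
    for name in sorted(profiles):
        p = profiles[name]
        rows.append((name, "reference_repeat_length", "", p.reference_repeat_length))
        for length in sorted(p.length_histogram):
            rows.append((name, "length", str(length), p.length_histogram[length]))
        t = p.allele_deletion_table
        for key, val in zip(_TABLE_KEYS, (t[0][0], t[0][1], t[1][0], t[1][1])):
            rows.append((name, "table", key, val))
        rows.append((name, "umi_count", "", p.distinct_umi_count))
        rows.append((name, "assigned", "", p.total_pairs_assigned))
        rows.append((name, "discarded", "", p.pairs_discarded))
    if braf is not None:
        rows.append((braf.marker, "braf_ref", "", braf.ref_reads))
        rows.append((braf.marker, "braf_alt", "", braf.alt_reads))
        rows.append((braf.marker, "braf_other", "", braf.other_reads))
        for umi in sorted(braf.umi_reads):
            alleles = braf.umi_reads[umi]
            rows.append((braf.marker, "braf_umi_ref", umi, alleles.count("ref")))
            rows.append((braf.marker, "braf_umi_alt", umi, alleles.count("alt")))
    pd.DataFrame(rows, columns=["marker", "field", "key", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(
    path: str | Path,
) -> tuple[dict[str, MarkerReadProfile], BrafProfile | None]:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "field": str, "key": str})
    profiles: dict[str, MarkerReadProfile] = {}
    braf: BrafProfile | None = None
    for marker, grp in df.groupby("marker", sort=False):
        fields = set(grp["field"])
        if "braf_ref" in fields:
            braf = BrafProfile(marker=str(marker))
            get = lambda f: int(grp.loc[grp["field"] == f, "value"].iloc[0])
            braf.ref_reads = get("braf_ref")
            braf.alt_reads = get("braf_alt")
            braf.other_reads = get("braf_other")
            for _, r in grp[grp["field"].isin(["braf_umi_ref", "braf_umi_alt"])].iterrows():
                allele = "ref" if r["field"] == "braf_umi_ref" else "alt"
                braf.umi_reads.setdefault(str(r["key"]), []).extend(
                    [allele] * int(r["value"])
                )
            continue
        ref_len = int(grp.loc[grp["field"] == "reference_repeat_length", "value"].iloc[0])
        prof = MarkerReadProfile(marker=str(marker), reference_repeat_length=ref_len)
        for _, r in grp[grp["field"] == "length"].iterrows():
            prof.length_histogram[int(r["key"])] = int(r["value"])
        tvals = {
            r["key"]: int(r["value"])
            for _, r in grp[grp["field"] == "table"].iterrows()
        }
        prof.allele_deletion_table = [
            [tvals["ref_del"], tvals["ref_nodel"]],
            [tvals["alt_del"], tvals["alt_nodel"]],
        ]
        scal = lambda f: int(grp.loc[grp["field"] == f, "value"].iloc[0])
        prof.distinct_umi_count = scal("umi_count")
        prof.total_pairs_assigned = scal("assigned")
        prof.pairs_discarded = scal("discarded")
        profiles[str(marker)] = prof
    return profiles, braf
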
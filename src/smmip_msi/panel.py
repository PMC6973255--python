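"""Marker-panel definitions, validation, and panel/sample-sheet file formats.

A panel describes a set of short mononucleotide-repeat (MNR) loci captured by
single-molecule molecular inversion probes (smMIPs).  Each marker carries the
probe arms, the flanking anchor sequences that delimit the repeat tract inside
the captured insert, the repeat unit and its reference length, and a linked
SNP used to assess allelic bias of deletions.  Coordinates are 0-based,
half-open, on the captured-insert strand written 5'->3' from the extension
arm.

Panels are stored as versioned JSON (see :func:`load_panel` /
:func:`save_panel`); sample sheets are TSV with columns
``sample_id, fastq1, fastq2, label``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

PANEL_FORMAT_VERSION = "smmip-msi-panel/1"
VALID_LABELS = {"MSI-H", "MSS", "unknown"}
_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised when a panel, marker, or sample sheet violates its contract."""


def _check_dna(seq: str, what: str, marker: str) -> None:
    if not seq or not set(seq) <= _DNA:
        raise PanelError(
            f"marker {marker!r}: {what} must be non-empty uppercase ACGT, got {seq!r}"
        )


@dataclass(frozen=True)
class MarkerDefinition:
    """One MNR locus of the panel.

    ``reference_insert`` is the full captured insert on the reference allele
    (what remains after the UMI and probe arms are stripped).  It contains,
    in order: optional leading sequence holding the linked SNP,
    ``left_flank``, the repeat tract (``reference_repeat_length`` copies of
    ``repeat_unit``), ``right_flank`` and optional trailing sequence.
    ``snp_offset`` indexes into the insert and must lie outside the repeat
    tract; placing the SNP 5' of the repeat keeps its offset invariant under
    repeat-length mutations.
    """

    name: str
    extension_arm: str
    ligation_arm: str
    reference_insert: str
    left_flank: str
    repeat_unit: str
    reference_repeat_length: int
    right_flank: str
    snp_offset: int
    snp_ref_allele: str
    snp_alt_allele: str
    umi_length: int = 6

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("marker name must be non-empty")
        for what, seq in (
            ("extension_arm", self.extension_arm),
            ("ligation_arm", self.ligation_arm),
            ("reference_insert", self.reference_insert),
            ("left_flank", self.left_flank),
            ("right_flank", self.right_flank),
            ("repeat_unit", self.repeat_unit),
            ("snp_ref_allele", self.snp_ref_allele),
            ("snp_alt_allele", self.snp_alt_allele),
        ):
            _check_dna(seq, what, self.name)
        if len(self.repeat_unit) != 1:
            raise PanelError(f"marker {self.name!r}: repeat_unit must be a single base")
        if len(self.snp_ref_allele) != 1 or len(self.snp_alt_allele) != 1:
            raise PanelError(f"marker {self.name!r}: SNP alleles must be single bases")
        if self.snp_ref_allele == self.snp_alt_allele:
            raise PanelError(f"marker {self.name!r}: SNP ref and alt alleles are equal")
        if len(self.left_flank) < 4 or len(self.right_flank) < 4:
            raise PanelError(f"marker {self.name!r}: flanks must be >= 4 nt")
        if not 5 <= self.reference_repeat_length <= 20:
            raise PanelError(
                f"marker {self.name!r}: reference_repeat_length "
                f"{self.reference_repeat_length} outside [5, 20]"
            )
        if not 7 <= self.reference_repeat_length <= 12:
            warnings.warn(
                f"marker {self.name!r}: repeat length {self.reference_repeat_length} "
                "outside the assay's usual 7-12 bp range",
                stacklevel=2,
            )
        # Repeat length is only well defined if the flanks do not extend the tract.
        if self.left_flank.endswith(self.repeat_unit):
            raise PanelError(
                f"marker {self.name!r}: left_flank ends with repeat unit "
                f"{self.repeat_unit!r}; repeat length would be ill-defined"
            )
        if self.right_flank.startswith(self.repeat_unit):
            raise PanelError(
                f"marker {self.name!r}: right_flank starts with repeat unit "
                f"{self.repeat_unit!r}; repeat length would be ill-defined"
            )
        core = self.reference_insert_core
        if self.reference_insert.count(core) != 1:
            raise PanelError(
                f"marker {self.name!r}: reference_insert must contain "
                "left_flank + repeat + right_flank exactly once"
            )
        if not 0 <= self.snp_offset < len(self.reference_insert):
            raise PanelError(
                f"marker {self.name!r}: snp_offset {self.snp_offset} outside "
                f"the captured insert (length {len(self.reference_insert)})"
            )
        rs, re_ = self.repeat_span
        if rs <= self.snp_offset < re_:
            raise PanelError(
                f"marker {self.name!r}: snp_offset {self.snp_offset} falls inside "
                f"the repeat tract [{rs}, {re_})"
            )
        if self.reference_insert[self.snp_offset] != self.snp_ref_allele:
            raise PanelError(
                f"marker {self.name!r}: reference_insert base at snp_offset "
                f"{self.snp_offset} is {self.reference_insert[self.snp_offset]!r}, "
                f"not the declared ref allele {self.snp_ref_allele!r}"
            )
        if self.umi_length < 1:
            raise PanelError(f"marker {self.name!r}: umi_length must be >= 1")

    @property
    def repeat_span(self) -> tuple[int, int]:
        """Half-open insert coordinates of the reference repeat tract."""
        start = self.reference_insert.index(self.reference_insert_core) + len(
            self.left_flank
        )
        return start, start + self.reference_repeat_length

    @property
    def reference_insert_core(self) -> str:
        """left_flank + reference repeat + right_flank."""
        return (
            self.left_flank
            + self.repeat_unit * self.reference_repeat_length
            + self.right_flank
        )


@dataclass(frozen=True)
class BrafMarker:
    """A single-nucleotide variant locus (BRAF c.1799T>A) captured alongside
    the MNR panel: no repeat, just a variant offset with ref/alt bases."""

    name: str
    extension_arm: str
    ligation_arm: str
    reference_insert: str
    variant_offset: int
    ref_allele: str = "T"
    alt_allele: str = "A"
    umi_length: int = 6

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("braf marker name must be non-empty")
        _check_dna(self.extension_arm, "extension_arm", self.name)
        _check_dna(self.ligation_arm, "ligation_arm", self.name)
        _check_dna(self.reference_insert, "reference_insert", self.name)
        _check_dna(self.ref_allele, "ref_allele", self.name)
        _check_dna(self.alt_allele, "alt_allele", self.name)
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise PanelError(f"marker {self.name!r}: alleles must be single bases")
        if not 0 <= self.variant_offset < len(self.reference_insert):
            raise PanelError(
                f"marker {self.name!r}: variant_offset outside the captured insert"
            )
        if self.reference_insert[self.variant_offset] != self.ref_allele:
            raise PanelError(
                f"marker {self.name!r}: reference_insert base at variant_offset "
                f"is not the declared ref allele {self.ref_allele!r}"
            )


@dataclass(frozen=True)
class PanelDefinition:
    markers: tuple[MarkerDefinition, ...]
    braf_marker: BrafMarker | None = None

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise PanelError("panel must contain at least one MNR marker")
        names = [m.name for m in self.markers]
        if self.braf_marker is not None:
            names.append(self.braf_marker.name)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate marker names: {dupes}")
        object.__setattr__(self, "markers", tuple(self.markers))

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


def save_panel(panel: PanelDefinition, path: str | Path) -> None:
    payload = {
        "format": PANEL_FORMAT_VERSION,
        "markers": [asdict(m) for m in panel.markers],
        "braf_marker": asdict(panel.braf_marker) if panel.braf_marker else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_panel(path: str | Path) -> PanelDefinition:
    """Load and validate a panel JSON file.

    Raises :class:`PanelError` naming the offending field and marker on any
    schema or invariant violation.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PanelError(f"panel file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != PANEL_FORMAT_VERSION:
        raise PanelError(
            f"panel file {path}: missing or unsupported format tag "
            f"(expected {PANEL_FORMAT_VERSION!r}, got {payload.get('format')!r})"
        )
    try:
        markers = tuple(MarkerDefinition(**m) for m in payload["markers"])
    except TypeError as exc:
        raise PanelError(f"panel file {path}: bad marker record: {exc}") from exc
    braf = payload.get("braf_marker")
    braf_marker = BrafMarker(**braf) if braf else None
    return PanelDefinition(markers=markers, braf_marker=braf_marker)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    fastq1: str
    fastq2: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise PanelError(
                f"sample {self.sample_id!r}: label {self.label!r} not in {sorted(VALID_LABELS)}"
            )


@dataclass(frozen=True)
class SampleSheet:
    samples: tuple[SampleEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate sample ids: {dupes}")
        object.__setattr__(self, "samples", tuple(self.samples))

    def training_samples(self) -> list[SampleEntry]:
        return [s for s in self.samples if s.label in ("MSI-H", "MSS")]


def load_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"sample_id", "fastq1", "fastq2"}
    if not required <= set(df.columns):
        raise PanelError(
            f"sample sheet {path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "label" not in df.columns:
        df["label"] = "unknown"
    entries = tuple(
        SampleEntry(r.sample_id, r.fastq1, r.fastq2, r.label)
        for r in df.itertuples(index=False)
    )
    return SampleSheet(samples=entries)


def save_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame([asdict(s) for s in sheet.samples]).to_csv(path, sep="\t", index=False)
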
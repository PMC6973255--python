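"""Synthetic smMIP cohorts with the statistical structure the assay assumes.

The generator emulates what the wet assay produces: paired reads over a
panel of short (7-12 bp) mononucleotide repeats, each read pair carrying a
6-base molecular barcode (UMI) adjacent to the extension arm.  MSI-H samples
draw mutant template molecules (1-3 bp repeat deletions, geometric sizes) at
a rate ``mutant_fraction * tumor_content``, with deletions preferentially on
one haplotype of the linked SNP — the mechanism behind the allelic-bias
signal.  MSS samples accumulate only stutter: a per-amplicon-copy 1 bp
slippage deletion whose probability grows with repeat length.  Stutter is
shared by both reads of a pair (it happens during amplification, before
sequencing), whereas substitution errors (0.62% per base, the observed
MiSeq base-calling error rate) are independent per read end — which is
exactly what the both-reads-agree consensus can remove and the repeat-level
traits cannot.

Every byte of output is a deterministic function of the configuration and
its seed.  UMIs are assigned collision-free within a sample-marker so that
distinct-barcode counts are an exact census of sequenced templates.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import revcomp
from .panel import BrafMarker, MarkerDefinition, PanelDefinition

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return b"".join(rng.choice(_BASES, size=length)).decode()


def _edit_distance(a: str, b: str) -> int:
    try:
        import edlib

        return edlib.align(a, b)["editDistance"]
    except ImportError:  # pragma: no cover - edlib is a declared dependency
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


def make_fixture_panel(
    k: int = 6,
    seed: int = 0,
    umi_length: int = 6,
    arm_length: int = 20,
    with_braf: bool = True,
    min_arm_distance: int = 5,
) -> PanelDefinition:
    """Deterministic synthetic stand-in panel of ``k`` MNR markers.

    Repeat lengths cycle 7-12 bp; each marker carries one SNP 5' of the
    repeat so its insert offset is invariant under repeat mutations.  All
    arms are mutually distant (pairwise edit distance >= ``min_arm_distance``)
    so one substitution can never flip an assignment.  This panel is
    synthetic: the assay's real marker loci and probe sequences are not
    reproduced here.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    arms: list[str] = []

    def new_arm() -> str:
        while True:
            cand = _random_dna(rng, arm_length)
            if max(len(list(g)) for _, g in itertools.groupby(cand)) > 4:
                continue  # avoid repeat-like arms
            if all(_edit_distance(cand, a) >= min_arm_distance for a in arms):
                arms.append(cand)
                return cand

    markers = []
    repeat_lengths = itertools.cycle(range(7, 13))
    for i in range(k):
        ref_len = next(repeat_lengths)
        unit = "ACGT"[i % 4]
        while True:
            left_pad = _random_dna(rng, 6)
            left_flank = _random_dna(rng, 5)
            right_flank = _random_dna(rng, 5)
            right_pad = _random_dna(rng, 4)
            if left_flank.endswith(unit) or right_flank.startswith(unit):
                continue
            if left_pad.endswith(unit):  # pad must not extend the tract either
                continue
            insert = left_pad + left_flank + unit * ref_len + right_flank + right_pad
            core = left_flank + unit * ref_len + right_flank
            if insert.count(core) != 1 or insert.count(left_flank) != 1:
                continue
            snp_offset = 2
            ref_allele = insert[snp_offset]
            alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
            break
        markers.append(
            MarkerDefinition(
                name=f"MNR{i + 1:02d}",
                extension_arm=new_arm(),
                ligation_arm=new_arm(),
                reference_insert=insert,
                left_flank=left_flank,
                repeat_unit=unit,
                reference_repeat_length=ref_len,
                right_flank=right_flank,
                snp_offset=snp_offset,
                snp_ref_allele=ref_allele,
                snp_alt_allele=str(alt_allele),
                umi_length=umi_length,
            )
        )
    braf = None
    if with_braf:
        insert = _random_dna(rng, 12) + "T" + _random_dna(rng, 12)
        braf = BrafMarker(
            name="BRAF_c1799",
            extension_arm=new_arm(),
            ligation_arm=new_arm(),
            reference_insert=insert,
            variant_offset=12,
            ref_allele="T",
            alt_allele="A",
            umi_length=umi_length,
        )
    return PanelDefinition(markers=tuple(markers), braf_marker=braf)


def _stutter_rate(ref_len: int, lo: float, hi: float) -> float:
    """Per-amplicon-copy slippage probability, linear in repeat length 7->12."""
    t = (min(max(ref_len, 7), 12) - 7) / 5.0
    return lo + t * (hi - lo)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults reflect the assay's working point: 6-base UMIs, ~150 template
    molecules per marker, ~3 reads per template, 0.62% per-base substitution
    error, stutter rising from 0.5% at 7 bp repeats to 3% at 12 bp, MSI-H
    mutant-template fractions of 0.3-0.7 diluted by tumor content.
    """

    seed: int
    n_msih: int = 0
    n_mss: int = 0
    panel: PanelDefinition | None = None
    n_markers: int = 6
    mutant_fraction_range: tuple[float, float] = (0.3, 0.7)
    stutter_range: tuple[float, float] = (0.005, 0.03)
    tumor_content_range: tuple[float, float] = (0.3, 1.0)
    snp_het_prob: float = 0.3
    base_error: float = 0.0062
    templates_per_marker: int = 150
    reads_per_template: float = 3.0
    poisson_reads: bool = True
    umi_length: int = 6
    bias_linkage: float = 0.9
    braf_alt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name in (
            "snp_het_prob",
            "base_error",
            "bias_linkage",
            "braf_alt_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("mutant_fraction_range", "stutter_range", "tumor_content_range"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{name} must be an ordered pair within [0, 1]")
        if self.templates_per_marker < 1:
            raise ValueError("templates_per_marker must be >= 1")
        if self.reads_per_template <= 0:
            raise ValueError("reads_per_template must be positive")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    labels: dict[str, str]
    tumor_content: dict[str, float]
    marker_truth: pd.DataFrame
    braf_truth: pd.DataFrame
    mutant_fractions: dict[str, float]
    stutter_rates: dict[str, float]


def _umi_pool(rng: np.random.Generator, n: int, umi_length: int) -> list[str]:
    space = 4**umi_length
    if n > space:
        raise ValueError("more templates than distinct UMIs")
    codes = rng.choice(space, size=n, replace=False)
    out = []
    for c in codes:
        s = []
        for _ in range(umi_length):
            s.append("ACGT"[c % 4])
            c //= 4
        out.append("".join(s))
    return out


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Independent per-base substitutions at the given rate."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(3)]
    return "".join(chars)


def _marker_insert(m: MarkerDefinition, allele: str, deletion: int) -> str:
    """Insert sequence for a haplotype allele and repeat deletion size."""
    insert = m.reference_insert
    if allele == "alt":
        insert = (
            insert[: m.snp_offset] + m.snp_alt_allele + insert[m.snp_offset + 1 :]
        )
    if deletion > 0:
        rs, re_ = m.repeat_span
        deletion = min(deletion, m.reference_repeat_length)
        insert = insert[:rs] + insert[rs + deletion :]
    return insert


def simulate_sample_reads(
    rng: np.random.Generator,
    panel: PanelDefinition,
    label: str,
    cfg: SyntheticCohortConfig,
    mutant_fractions: dict[str, float],
    stutter_rates: dict[str, float],
    tumor_content: float,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Emit read pairs and per-marker truth rows for one sample."""
    pairs: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for m in panel.markers:
        het = bool(rng.random() < cfg.snp_het_prob)
        linked = "ref" if rng.random() < 0.5 else "alt"
        stutter = stutter_rates[m.name]
        mut_rate = (
            mutant_fractions[m.name] * tumor_content if label == "MSI-H" else 0.0
        )
        n_templates = cfg.templates_per_marker
        umis = _umi_pool(rng, n_templates, m.umi_length)
        n_mutant = 0
        n_sequenced = 0
        for umi in umis:
            mutant = bool(rng.random() < mut_rate)
            if mutant:
                n_mutant += 1
                deletion = int(min(rng.geometric(0.7), 3))
                if het:
                    allele = (
                        linked
                        if rng.random() < cfg.bias_linkage
                        else ("alt" if linked == "ref" else "ref")
                    )
                else:
                    allele = "ref"
            else:
                deletion = 0
                allele = ("ref" if rng.random() < 0.5 else "alt") if het else "ref"
            n_reads = (
                int(rng.poisson(cfg.reads_per_template))
                if cfg.poisson_reads
                else int(round(cfg.reads_per_template))
            )
            if n_reads > 0:
                n_sequenced += 1
            for _ in range(n_reads):
                slip = 1 if rng.random() < stutter else 0
                insert = _marker_insert(m, allele, deletion + slip)
                amplicon = umi + m.extension_arm + insert + m.ligation_arm
                r1 = _mutate(amplicon, rng, cfg.base_error)
                r2 = _mutate(revcomp(amplicon), rng, cfg.base_error)
                pairs.append((r1, r2))
        truth_rows.append(
            {
                "marker": m.name,
                "n_templates": n_templates,
                "n_templates_sequenced": n_sequenced,
                "n_mutant_templates": n_mutant,
                "mutant_rate": mut_rate,
                "stutter_rate": stutter,
                "heterozygous": het,
                "linked_allele": linked if het else "",
            }
        )
    braf = panel.braf_marker
    if braf is not None:
        n_templates = cfg.templates_per_marker
        umis = _umi_pool(rng, n_templates, braf.umi_length)
        n_alt = 0
        n_braf_sequenced = 0
        for umi in umis:
            is_alt = bool(rng.random() < cfg.braf_alt_fraction)
            n_alt += is_alt
            seq = braf.reference_insert
            if is_alt:
                seq = (
                    seq[: braf.variant_offset]
                    + braf.alt_allele
                    + seq[braf.variant_offset + 1 :]
                )
            n_reads = (
                int(rng.poisson(cfg.reads_per_template))
                if cfg.poisson_reads
                else int(round(cfg.reads_per_template))
            )
            if n_reads > 0:
                n_braf_sequenced += 1
            for _ in range(n_reads):
                amplicon = umi + braf.extension_arm + seq + braf.ligation_arm
                r1 = _mutate(amplicon, rng, cfg.base_error)
                r2 = _mutate(revcomp(amplicon), rng, cfg.base_error)
                pairs.append((r1, r2))
        truth_rows.append(
            {
                "marker": braf.name,
                "n_templates": n_templates,
                "n_templates_sequenced": n_braf_sequenced,
                "n_mutant_templates": n_alt,
                "mutant_rate": cfg.braf_alt_fraction,
                "stutter_rate": 0.0,
                "heterozygous": False,
                "linked_allele": "",
            }
        )
    return pairs, truth_rows


def generate_cohort(
    cfg: SyntheticCohortConfig, outdir: str | Path | None = None
) -> tuple[PanelDefinition, dict[str, list[tuple[str, str]]] | dict[str, tuple[Path, Path]], CohortTruth]:
    """Generate a labeled cohort.

    Returns ``(panel, reads, truth)`` where ``reads`` maps sample id to
    in-memory ``(read1, read2)`` pairs, or to written FASTQ paths when
    ``outdir`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel or make_fixture_panel(cfg.n_markers, seed=cfg.seed, umi_length=cfg.umi_length)
    lo, hi = cfg.mutant_fraction_range
    mutant_fractions = {
        m.name: float(lo + rng.random() * (hi - lo)) for m in panel.markers
    }
    stutter_rates = {
        m.name: _stutter_rate(m.reference_repeat_length, *cfg.stutter_range)
        for m in panel.markers
    }
    sample_ids = [f"MSIH_{i + 1:03d}" for i in range(cfg.n_msih)] + [
        f"MSS_{i + 1:03d}" for i in range(cfg.n_mss)
    ]
    labels = {
        sid: ("MSI-H" if sid.startswith("MSIH") else "MSS") for sid in sample_ids
    }
    tc_lo, tc_hi = cfg.tumor_content_range
    reads_out: dict = {}
    marker_rows = []
    braf_rows = []
    tumor_content = {}
    for sid in sample_ids:
        label = labels[sid]
        tc = float(tc_lo + rng.random() * (tc_hi - tc_lo)) if label == "MSI-H" else 0.0
        tumor_content[sid] = tc
        pairs, rows = simulate_sample_reads(
            rng, panel, label, cfg, mutant_fractions, stutter_rates, tc
        )
        for r in rows:
            r["sample_id"] = sid
            r["label"] = label
            r["tumor_content"] = tc
            if r["marker"].startswith("BRAF"):
                braf_rows.append(r)
            else:
                marker_rows.append(r)
        if outdir is None:
            reads_out[sid] = pairs
        else:
            reads_out[sid] = write_fastq_pair(pairs, Path(outdir), sid)
    truth = CohortTruth(
        labels=labels,
        tumor_content=tumor_content,
        marker_truth=pd.DataFrame(marker_rows),
        braf_truth=pd.DataFrame(braf_rows),
        mutant_fractions=mutant_fractions,
        stutter_rates=stutter_rates,
    )
    return panel, reads_out, truth


def write_fastq_pair(
    pairs: list[tuple[str, str]], outdir: Path, sample_id: str, gz: bool = False
) -> tuple[Path, Path]:
    """Write read pairs as a standard FASTQ pair (flat qualities)."""
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gz else ".fastq"
    p1 = outdir / f"{sample_id}_R1{ext}"
    p2 = outdir / f"{sample_id}_R2{ext}"
    op = (lambda p: gzip.open(p, "wt")) if gz else (lambda p: open(p, "w"))
    with op(p1) as f1, op(p2) as f2:
        for i, (r1, r2) in enumerate(pairs):
            f1.write(f"@{sample_id}:{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{sample_id}:{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    return p1, p2


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    df = truth.marker_truth.copy()
    if len(truth.braf_truth):
        df = pd.concat([df, truth.braf_truth], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
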
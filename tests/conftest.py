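"""Shared fixtures: a deterministic fixture panel and small synthetic cohorts.

Everything is generated programmatically at test time; session scope keeps
the expensive cohort builds to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import smmip_msi as sm


@pytest.fixture(scope="session")
def fixture_panel():
    return sm.make_fixture_panel(6, seed=1)


@pytest.fixture(scope="session")
def marker(fixture_panel):
    """A representative marker (7 bp A-repeat)."""
    return fixture_panel.markers[0]


def build_pair(marker, umi="ACGTTG", allele="ref", deletion=0, braf=False):
    """Hand-construct an error-free read pair for a marker."""
    from smmip_msi.extraction import revcomp
    from smmip_msi.simulate import _marker_insert

    if braf:
        insert = marker.reference_insert
    else:
        insert = _marker_insert(marker, allele, deletion)
    amplicon = umi + marker.extension_arm + insert + marker.ligation_arm
    return amplicon, revcomp(amplicon)


@pytest.fixture(scope="session")
def small_cohort(fixture_panel):
    """12 MSI-H + 12 MSS samples at default study conditions, pre-extracted."""
    cfg = sm.SyntheticCohortConfig(seed=11, n_msih=12, n_mss=12, panel=fixture_panel)
    panel, reads, truth = sm.generate_cohort(cfg)
    records = {}
    summaries = []
    for sid, pairs in reads.items():
        sr = sm.extract_read_pairs(pairs, panel)
        records[sid] = sr.records
        profiles = sm.profiles_from_records(sr.records, panel)
        summaries.append(sm.summarize_profiles(sid, profiles, panel))
    return {
        "panel": panel,
        "truth": truth,
        "records": records,
        "summaries": summaries,
    }


@pytest.fixture(scope="session")
def trained_cohort(small_cohort):
    clf = sm.train(small_cohort["summaries"], small_cohort["truth"].labels)
    return {**small_cohort, "clf": clf}


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by brute-force hypergeometric enumeration."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
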
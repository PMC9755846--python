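import numpy as np
import pytest

from cdrlight import DeletionCohort, DeletionRecord, GenomicInterval


def make_cohort(spans, chrom="chr1", locus=(1, 1000)):
    records = tuple(
        DeletionRecord(f"S{i + 1}", GenomicInterval(chrom, s, e))
        for i, (s, e) in enumerate(spans)
    )
    return DeletionCohort(records, GenomicInterval(chrom, *locus))


@pytest.fixture
def toy_cohort():
    """Four fragments whose depth peaks at 3 exactly on [250, 300]."""
    return make_cohort([(100, 500), (200, 600), (250, 300), (700, 900)])


def brute_force_depth(cohort, lo, hi):
    """Per-base stabbing depth by direct counting — the coverage oracle."""
    depth = np.zeros(hi - lo + 1, dtype=int)
    for rec in cohort.records:
        s = max(rec.interval.start, lo)
        e = min(rec.interval.end, hi)
        if s <= e:
            depth[s - lo : e - lo + 1] += 1
    return depth


def profile_as_array(profile, lo, hi):
    """Materialize a coverage step function over [lo, hi]."""
    return np.array([profile.depth_at(p) for p in range(lo, hi + 1)])
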
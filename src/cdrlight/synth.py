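"""Synthetic data with the statistical structure the analysis assumes.

Three generators, all pure functions of their config (same seed, same
output):

* deletion cohorts with a *planted* common deletion region contained in a
  set fraction of fragments, breakpoints scattered in the flanks;
* qPCR plates with Ct values derived from true copy numbers under a
  cycle-scale Gaussian noise model;
* clinical call tables with covariates linked to the deletion call through
  a logistic model with planted log-odds.

The qPCR noise model reflects a duplex reaction: target and reference are
read from the *same well*, so well-level variation (pipetting, template
load) is shared between the two channels and cancels in dCt, while
channel-specific noise does not.  ``ct_noise_sd`` is the total per-Ct
standard deviation; ``shared_noise_fraction`` is the portion of that
variance carried by the shared well effect (default 0.8, giving a
replicate dCt SD of about 0.06 cycles at the default sd of 0.1 — the
precision regime in which a 20% zero-copy spike-in is reliably detected
from triplicates).

``table2_preset`` is different in kind: a deterministic 139-row call
table whose per-covariate margins reproduce a published gastric-carcinoma
cross-tabulation exactly, for end-to-end checks of the association stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .intervals import (
    DeletionCohort,
    DeletionRecord,
    GenomicInterval,
    Source,
    Zygosity,
)
from .qpcr import Assay, CtMeasurement, MixtureSeries, TitrationSeries

__all__ = [
    "SynthCohortConfig",
    "PlateSample",
    "SynthPlateConfig",
    "SynthClinicalConfig",
    "gen_deletion_cohort",
    "gen_qpcr_plate",
    "gen_mixture_series",
    "gen_titration_series",
    "gen_clinical_table",
    "table2_preset",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20220917


@dataclass(frozen=True)
class SynthCohortConfig:
    """Geometry and sampling plan for a planted-CDR deletion cohort."""

    seed: int = DEFAULT_SEED
    n_fragments: int = 100
    locus: GenomicInterval = GenomicInterval("chr9", 21_800_000, 22_200_000)
    planted_cdr: GenomicInterval = GenomicInterval("chr9", 21_970_277, 21_975_386)
    containment_fraction: float = 0.9
    breakpoint_spread: int = 50_000

    def __post_init__(self) -> None:
        if not self.locus.contains(self.planted_cdr):
            raise InputError("planted CDR must lie within the locus")
        if not (0.0 <= self.containment_fraction <= 1.0):
            raise InputError("containment_fraction must be in [0, 1]")
        if self.breakpoint_spread < 1:
            raise InputError("breakpoint_spread must be >= 1 bp")


def gen_deletion_cohort(config: SynthCohortConfig) -> DeletionCohort:
    """Simulate a deletion cohort with a planted CDR.

    Each fragment contains the planted CDR with probability
    ``containment_fraction``; containing fragments extend the CDR by
    uniform breakpoints into the flanks.  The first containers are pinned
    to *attain* the planted boundaries — one fragment equal to the CDR
    itself (the minimal observed deletion that delimits a real CDR), one
    starting exactly at the CDR start and one ending exactly at the CDR
    end — so the depth plateau over the planted region stands at least
    two above any flank position and the region is recovered base-exactly
    whenever at least three fragments contain it.  Non-containing
    fragments are placed wholly within one flank (lengths on the
    ``breakpoint_spread`` scale) and never erode the plateau.
    """
    if config.n_fragments < 1:
        raise AnalysisError("n_fragments must be >= 1")
    rng = np.random.default_rng(config.seed)
    locus, cdr = config.locus, config.planted_cdr
    left = (locus.start, cdr.start - 1) if cdr.start > locus.start else None
    right = (cdr.end + 1, locus.end) if cdr.end < locus.end else None

    contains = rng.random(config.n_fragments) < config.containment_fraction
    records = []
    n_containers_seen = 0
    for i in range(config.n_fragments):
        sid = f"S{i + 1:03d}"
        if contains[i]:
            n_containers_seen += 1
            start = int(rng.integers(locus.start, cdr.start + 1))
            end = int(rng.integers(cdr.end, locus.end + 1))
            if n_containers_seen == 1:
                start, end = cdr.start, cdr.end
            elif n_containers_seen == 2:
                start = cdr.start
            elif n_containers_seen == 3:
                end = cdr.end
            iv = GenomicInterval(locus.chrom, start, end)
        else:
            flanks = [f for f in (left, right) if f is not None]
            if not flanks:
                raise AnalysisError(
                    "planted CDR at locus edge leaves no flank for "
                    "non-containing fragments"
                )
            weights = np.array([f[1] - f[0] + 1 for f in flanks], dtype=float)
            flank = flanks[rng.choice(len(flanks), p=weights / weights.sum())]
            flen = flank[1] - flank[0] + 1
            # exponential length truncated below the flank size, so a
            # fragment never degenerates to the whole flank
            u = rng.random()
            scale = config.breakpoint_spread
            trunc = 1.0 - math.exp(-(flen - 1) / scale)
            length = int(max(1, min(flen - 1, 1 + math.floor(-scale * math.log1p(-u * trunc)))))
            if flen == 1:
                length = 1
            start = int(rng.integers(flank[0], flank[1] - length + 2))
            iv = GenomicInterval(locus.chrom, start, start + length - 1)
        records.append(
            DeletionRecord(sid, iv, Source.SEQUENCING_BASE_RESOLUTION, Zygosity.HOMOZYGOUS)
        )
    return DeletionCohort(tuple(records), locus)


@dataclass(frozen=True)
class PlateSample:
    """True state of one simulated sample on a plate.

    ``true_copies`` is the target copy number per diploid genome in the
    non-null DNA; ``null_fraction`` is the mass fraction of zero-copy DNA
    mixed in (spike-in design).  The reference gene always has 2 copies.
    """

    sample_id: str
    true_copies: float = 2.0
    null_fraction: float = 0.0


@dataclass(frozen=True)
class SynthPlateConfig:
    seed: int = DEFAULT_SEED
    samples: tuple[PlateSample, ...] = ()
    replicates: int = 3
    baseline_ct: float = 28.0
    ct_noise_sd: float = 0.1
    shared_noise_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise InputError("need >= 2 replicates")
        if self.ct_noise_sd < 0:
            raise InputError("ct_noise_sd must be >= 0")
        if not (0.0 <= self.shared_noise_fraction <= 1.0):
            raise InputError("shared_noise_fraction must be in [0, 1]")


def gen_qpcr_plate(config: SynthPlateConfig) -> list[CtMeasurement]:
    """Simulate replicate Ct values for each sample on a plate.

    Ct = baseline - log2(effective copies / 2) + well + channel noise,
    with effective target copies ``(1 - null_fraction) * true_copies``
    and reference copies fixed at 2.  Zero effective copies yield the
    no-amplification sentinel for the target wells.
    """
    rng = np.random.default_rng(config.seed)
    sd_w = config.ct_noise_sd * math.sqrt(config.shared_noise_fraction)
    sd_c = config.ct_noise_sd * math.sqrt(1.0 - config.shared_noise_fraction)
    out: list[CtMeasurement] = []
    for s in config.samples:
        effective = (1.0 - s.null_fraction) * s.true_copies
        for rep in range(1, config.replicates + 1):
            w = rng.normal(0.0, sd_w) if sd_w else 0.0
            e_t = rng.normal(0.0, sd_c) if sd_c else 0.0
            e_r = rng.normal(0.0, sd_c) if sd_c else 0.0
            if effective > 0:
                ct_t = config.baseline_ct - math.log2(effective / 2.0) + w + e_t
            else:
                ct_t = None
            ct_r = config.baseline_ct + w + e_r
            out.append(CtMeasurement(s.sample_id, Assay.TARGET, rep, ct_t))
            out.append(CtMeasurement(s.sample_id, Assay.REFERENCE, rep, ct_r))
    return out


def gen_mixture_series(
    seed: int = DEFAULT_SEED,
    null_fractions: Sequence[float] = (0.0, 0.10, 0.20, 0.25, 0.30),
    replicates: int = 3,
    ct_noise_sd: float = 0.1,
    shared_noise_fraction: float = 0.8,
    baseline_ct: float = 28.0,
) -> MixtureSeries:
    """Simulate the spike-in dilution series (zero-copy DNA into two-copy DNA)."""
    if any(f >= 1.0 for f in null_fractions):
        raise InputError("null fractions must be < 1 (target must amplify)")
    samples = tuple(
        PlateSample(f"mix_{f:g}", true_copies=2.0, null_fraction=f)
        for f in null_fractions
    )
    plate = gen_qpcr_plate(
        SynthPlateConfig(
            seed=seed,
            samples=samples,
            replicates=replicates,
            baseline_ct=baseline_ct,
            ct_noise_sd=ct_noise_sd,
            shared_noise_fraction=shared_noise_fraction,
        )
    )
    target: dict[float, tuple[float, ...]] = {}
    reference: dict[float, tuple[float, ...]] = {}
    for f in null_fractions:
        sid = f"mix_{f:g}"
        target[f] = tuple(m.ct for m in plate if m.sample_id == sid and m.assay is Assay.TARGET)
        reference[f] = tuple(
            m.ct for m in plate if m.sample_id == sid and m.assay is Assay.REFERENCE
        )
    return MixtureSeries(tuple(null_fractions), target, reference)


def gen_titration_series(
    seed: int = DEFAULT_SEED,
    input_ng: Sequence[float] = (10.0, 5.0, 2.5, 1.25, 0.63),
    replicates: int = 3,
    ct_noise_sd: float = 0.1,
    shared_noise_fraction: float = 0.8,
    baseline_ct: float = 28.0,
) -> TitrationSeries:
    """Simulate a template titration at perfect efficiency.

    Each halving of input raises both channels' Ct by one cycle
    (Ct = baseline + log2(max_ng / ng) + noise).
    """
    rng = np.random.default_rng(seed)
    sd_w = ct_noise_sd * math.sqrt(shared_noise_fraction)
    sd_c = ct_noise_sd * math.sqrt(1.0 - shared_noise_fraction)
    ref_ng = max(input_ng)
    target: dict[float, tuple[float, ...]] = {}
    reference: dict[float, tuple[float, ...]] = {}
    for a in input_ng:
        base = baseline_ct + math.log2(ref_ng / a)
        t_cts, r_cts = [], []
        for _ in range(replicates):
            w = rng.normal(0.0, sd_w) if sd_w else 0.0
            t_cts.append(base + w + (rng.normal(0.0, sd_c) if sd_c else 0.0))
            r_cts.append(base + w + (rng.normal(0.0, sd_c) if sd_c else 0.0))
        target[a] = tuple(t_cts)
        reference[a] = tuple(r_cts)
    return TitrationSeries(tuple(input_ng), target, reference)


@dataclass(frozen=True)
class SynthClinicalConfig:
    """Logistic-model clinical cohort: binary covariates at set prevalences,
    deletion call with planted per-covariate log-odds."""

    seed: int = DEFAULT_SEED
    n_samples: int = 500
    covariate_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"distant_metastasis": 0.25}
    )
    base_rate: float = 0.3
    log_odds: Mapping[str, float] = field(
        default_factory=lambda: {"distant_metastasis": math.log(4.0)}
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")
        for name, p in self.covariate_prevalence.items():
            if not (0.0 < p < 1.0):
                raise InputError(f"prevalence of {name} must be in (0, 1)")
        if not (0.0 < self.base_rate < 1.0):
            raise InputError("base_rate must be in (0, 1)")


def gen_clinical_table(config: SynthClinicalConfig) -> pd.DataFrame:
    """Simulate a per-sample call table from the logistic model.

    Covariates are independent Bernoulli columns (True = positive level);
    the deletion call is drawn with
    logit P(call) = logit(base_rate) + sum_j beta_j x_j.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    df = pd.DataFrame({"sample_id": [f"SYN{i + 1:05d}" for i in range(n)]})
    eta = np.full(n, math.log(config.base_rate / (1.0 - config.base_rate)))
    for name, prev in config.covariate_prevalence.items():
        x = rng.random(n) < prev
        df[name] = x
        eta = eta + config.log_odds.get(name, 0.0) * x
    p = 1.0 / (1.0 + np.exp(-eta))
    df["call_p16light"] = rng.random(n) < p
    return df


# Per covariate level: counts of the four call patterns
# (both assays positive, first-only, second-only, neither) among the
# 139-sample cross-sectional cohort.  Within every level the OR-merged
# positives equal first + second - both.  `None` marks a missing level.
_TABLE2_PATTERNS: dict[str, list[tuple[str | None, tuple[int, int, int, int]]]] = {
    "age_group": [("<60", (8, 15, 10, 35)), (">=60", (11, 17, 15, 28))],
    "sex": [("male", (15, 25, 18, 43)), ("female", (4, 7, 7, 20))],
    "location": [("cardiac", (2, 7, 1, 8)), ("noncardiac", (17, 25, 24, 55))],
    "differentiation": [
        ("poor", (12, 21, 18, 48)),
        ("well_moderate", (7, 9, 7, 14)),
        (None, (0, 2, 0, 1)),
    ],
    "stage": [
        ("I-II", (4, 7, 12, 23)),
        ("III", (5, 9, 3, 20)),
        ("IV", (10, 16, 10, 20)),
    ],
    "invasion": [
        ("T1-2", (5, 6, 8, 8)),
        ("T3", (9, 19, 10, 41)),
        ("T4", (5, 7, 7, 14)),
    ],
    "lymph_metastasis": [
        ("negative", (7, 9, 11, 24)),
        ("positive", (12, 23, 14, 39)),
    ],
    "distant_metastasis": [
        ("negative", (11, 20, 22, 54)),
        ("positive", (8, 12, 3, 9)),
    ],
}

_TABLE2_PATTERN_TOTALS = (19, 32, 25, 63)  # both, first-only, second-only, neither


def table2_preset() -> pd.DataFrame:
    """Deterministic 139-row call table reproducing the published margins.

    Samples are grouped by call pattern (19 positive by both assays, 32 by
    the CDR assay only, 25 by the exon-1beta assay only, 63 by neither);
    within each pattern block every covariate's levels are laid out in
    fixed-order runs matching its per-level pattern counts, so every
    covariate-by-call cross-tabulation equals the published table while
    covariate-covariate structure stays arbitrary.
    """
    n = sum(_TABLE2_PATTERN_TOTALS)
    df = pd.DataFrame({"sample_id": [f"GC{i + 1:03d}" for i in range(n)]})
    pattern_calls = [(True, True), (True, False), (False, True), (False, False)]
    p16, p14 = [], []
    for (c16, c14), count in zip(pattern_calls, _TABLE2_PATTERN_TOTALS):
        p16 += [c16] * count
        p14 += [c14] * count
    df["call_p16light"] = p16
    df["call_p14"] = p14
    for cov, level_counts in _TABLE2_PATTERNS.items():
        col: list[str | None] = []
        for k in range(4):
            for level, counts in level_counts:
                col += [level] * counts[k]
        df[cov] = col
    return df
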
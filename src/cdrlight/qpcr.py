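"""Relative copy-number quantification from multiplex qPCR Ct data.

The assay measures a target amplicon (inside the gene's common deletion
region) and a reference-gene amplicon (GAPDH) in the same reaction, in
replicate.  Quantification follows classic comparative-Ct:

    dCt      = Ct_target - Ct_reference
    RCN      = E^-(dCt_sample - dCt_calibrator)        (E = 2 by default)
    deletion_proportion = 1 - RCN

where the calibrator is a two-copy reference (a paired normal-tissue sample
or the 100% wild-type control), so RCN = 1 means two copies per diploid
genome.  A sample is *informative* only when its reference-gene mean Ct is
at most ``INFORMATIVE_CT_CUTOFF`` cycles (enough amplifiable input DNA).

Copy-number calls compare the replicate RCN values of a sample against
those of its paired normal by a two-sided Student's t-test: significantly
lower means somatic deletion, significantly higher means amplification.
The detection limit of a spike-in dilution series is the smallest
zero-copy fraction that tests significantly different from the pure
two-copy control, with all larger fractions also significant.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, InputError, InsufficientReplicatesError

__all__ = [
    "NO_AMPLIFICATION",
    "INFORMATIVE_CT_CUTOFF",
    "Assay",
    "Call",
    "CtMeasurement",
    "SampleQuant",
    "TitrationSeries",
    "MixtureSeries",
    "LodResult",
    "aggregate_replicates",
    "is_informative",
    "relative_copy_number",
    "call_scnv",
    "quantify_pair",
    "titration_efficiency",
    "mixture_linearity",
    "detection_limit",
    "replicate_rcns",
]

#: Sentinel for a well with no amplification within the run's cycle limit.
NO_AMPLIFICATION = None

#: Reference-gene (GAPDH) mean-Ct cutoff for an informative sample, cycles.
INFORMATIVE_CT_CUTOFF = 34.0


class Assay(str, enum.Enum):
    TARGET = "target"
    REFERENCE = "reference"


class Call(str, enum.Enum):
    DELETION = "deletion"
    AMPLIFICATION = "amplification"
    NEUTRAL = "neutral"
    NON_INFORMATIVE = "non_informative"


@dataclass(frozen=True)
class CtMeasurement:
    """One well: a Ct value (or ``NO_AMPLIFICATION``) for one assay replicate."""

    sample_id: str
    assay: Assay
    replicate: int
    ct: float | None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise InputError("replicate index must be >= 1")
        if self.ct is not None and not self.ct > 0:
            raise InputError(f"Ct must be positive, got {self.ct}")


@dataclass(frozen=True)
class SampleQuant:
    """Per-sample quantification result relative to its paired normal."""

    sample_id: str
    call: Call
    mean_ct_target: float | None = None
    mean_ct_reference: float | None = None
    delta_ct: float | None = None
    rel_copy_number: float | None = None
    deletion_proportion: float | None = None
    p_value: float | None = None
    complete_dropout: bool = False

    @property
    def informative(self) -> bool:
        return self.call is not Call.NON_INFORMATIVE


def aggregate_replicates(
    measurements: Sequence[CtMeasurement],
) -> tuple[float, float, int]:
    """Mean and sample SD of the amplified replicate Ct values.

    Wells with ``NO_AMPLIFICATION`` are excluded from the mean but still
    counted in the input; fewer than two amplified replicates is an error.
    Returns ``(mean, sd, n_used)``.
    """
    cts = [m.ct for m in measurements if m.ct is not None]
    if len(cts) < 2:
        raise InsufficientReplicatesError(
            f"insufficient replicates: {len(cts)} usable of {len(measurements)}"
        )
    arr = np.asarray(cts, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), len(cts)


def is_informative(
    mean_ct_reference: float | None, cutoff: float = INFORMATIVE_CT_CUTOFF
) -> bool:
    """True iff the reference-gene mean Ct is at or below the cutoff."""
    if mean_ct_reference is None:
        return False
    return mean_ct_reference <= cutoff


def relative_copy_number(
    delta_ct_sample: float,
    delta_ct_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """Comparative-Ct relative copy number: E^-(dCt_sample - dCt_calibrator)."""
    if not (1.0 < efficiency <= 2.2):
        raise InputError(f"efficiency must be in (1, 2.2], got {efficiency}")
    return efficiency ** -(delta_ct_sample - delta_ct_calibrator)


def _ttest_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Student's t-test p-value with a defined zero-variance limit.

    When both replicate sets have zero variance the statistic is undefined;
    we take the limit: p = 0 if the means differ, p = 1 if they are equal
    (and warn, since this only arises in noise-free simulation).
    """
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn(
            "zero-variance replicate sets; reporting degenerate p-value",
            stacklevel=3,
        )
        return 0.0 if a.mean() != b.mean() else 1.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def call_scnv(
    sample_rcns: Sequence[float],
    reference_rcns: Sequence[float],
    alpha: float = 0.05,
) -> tuple[Call, float]:
    """Deletion/amplification call from replicate relative copy numbers.

    Two-sided two-sample Student's t-test of the sample's replicate RCNs
    against the paired reference's; deletion if significantly lower,
    amplification if significantly higher, else neutral.
    """
    if len(sample_rcns) < 2 or len(reference_rcns) < 2:
        raise InsufficientReplicatesError("need >= 2 replicate values per side")
    a = np.asarray(sample_rcns, dtype=float)
    b = np.asarray(reference_rcns, dtype=float)
    p = _ttest_two_sided(a, b)
    if p < alpha:
        call = Call.DELETION if a.mean() < b.mean() else Call.AMPLIFICATION
    else:
        call = Call.NEUTRAL
    return call, p


def _paired_dcts(
    measurements: Sequence[CtMeasurement],
) -> tuple[list[float | None], list[float | None], list[float]]:
    """Per-replicate target and reference Cts and the dCts of complete pairs."""
    target = {m.replicate: m.ct for m in measurements if m.assay is Assay.TARGET}
    ref = {m.replicate: m.ct for m in measurements if m.assay is Assay.REFERENCE}
    dcts = [
        target[r] - ref[r]
        for r in sorted(set(target) & set(ref))
        if target[r] is not None and ref[r] is not None
    ]
    return list(target.values()), list(ref.values()), dcts


def replicate_rcns(
    dcts: Sequence[float], delta_ct_calibrator: float, efficiency: float = 2.0
) -> list[float]:
    """Per-replicate RCN values against a fixed calibrator mean dCt."""
    return [relative_copy_number(d, delta_ct_calibrator, efficiency) for d in dcts]


def quantify_pair(
    sample_measurements: Sequence[CtMeasurement],
    normal_measurements: Sequence[CtMeasurement],
    alpha: float = 0.05,
    efficiency: float = 2.0,
    informative_cutoff: float = INFORMATIVE_CT_CUTOFF,
) -> SampleQuant:
    """Quantify one tumor sample against its paired normal reference.

    The paired normal's mean dCt is the calibrator, so the reported RCN is
    on the two-copy scale of the normal tissue.  Either member failing the
    reference-gene informativeness gate yields ``non_informative`` with no
    test run.  A sample whose target fails every replicate while the
    reference amplifies is a complete dropout: called ``deletion`` with
    RCN 0 and p recorded as 0.
    """
    sid = sample_measurements[0].sample_id if sample_measurements else "?"

    s_tgt, s_ref, s_dcts = _paired_dcts(sample_measurements)
    n_tgt, n_ref, n_dcts = _paired_dcts(normal_measurements)

    def _mean(values: Sequence[float | None]) -> float | None:
        present = [v for v in values if v is not None]
        return float(np.mean(present)) if len(present) >= 2 else None

    mean_s_ref = _mean(s_ref)
    mean_n_ref = _mean(n_ref)
    if not (
        is_informative(mean_s_ref, informative_cutoff)
        and is_informative(mean_n_ref, informative_cutoff)
    ):
        return SampleQuant(sample_id=sid, call=Call.NON_INFORMATIVE)

    mean_s_tgt = _mean(s_tgt)
    if mean_s_tgt is None and all(ct is None for ct in s_tgt):
        # complete target dropout against an informative reference
        return SampleQuant(
            sample_id=sid,
            call=Call.DELETION,
            mean_ct_target=None,
            mean_ct_reference=mean_s_ref,
            delta_ct=None,
            rel_copy_number=0.0,
            deletion_proportion=1.0,
            p_value=0.0,
            complete_dropout=True,
        )

    if len(s_dcts) < 2 or len(n_dcts) < 2:
        raise InsufficientReplicatesError(
            f"sample {sid}: need >= 2 complete target/reference replicate pairs"
        )

    cal = float(np.mean(n_dcts))
    s_rcns = replicate_rcns(s_dcts, cal, efficiency)
    n_rcns = replicate_rcns(n_dcts, cal, efficiency)
    call, p = call_scnv(s_rcns, n_rcns, alpha)
    delta_ct = float(np.mean(s_dcts))
    rcn = relative_copy_number(delta_ct, cal, efficiency)
    return SampleQuant(
        sample_id=sid,
        call=call,
        mean_ct_target=mean_s_tgt,
        mean_ct_reference=mean_s_ref,
        delta_ct=delta_ct,
        rel_copy_number=rcn,
        deletion_proportion=1.0 - rcn,
        p_value=p,
    )


@dataclass(frozen=True)
class TitrationSeries:
    """Template-titration data: Ct values at a ladder of input DNA amounts.

    ``input_ng`` are the per-reaction template amounts; ``target_ct`` and
    ``reference_ct`` map each amount to its replicate Ct values.
    """

    input_ng: tuple[float, ...]
    target_ct: Mapping[float, tuple[float, ...]]
    reference_ct: Mapping[float, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(set(self.input_ng)) < 3:
            raise InputError("titration needs >= 3 distinct input amounts")


def titration_efficiency(
    series: TitrationSeries,
) -> tuple[float, float, dict[float, float]]:
    """Amplification efficiency from a template titration.

    Fits mean target Ct against log2(input ng) by least squares; a
    perfectly efficient PCR loses exactly one cycle per template doubling
    (slope -1).  Returns ``(slope, efficiency, dct_by_amount)`` where
    ``efficiency = 2^(-1/slope)`` and ``dct_by_amount`` records the
    target-minus-reference mean dCt at each amount (its constancy is the
    duplex-balance check).
    """
    amounts = sorted(set(series.input_ng))
    x = np.log2(amounts)
    if x.max() - x.min() < 2.0 - 1e-9:
        raise InputError("titration must span at least two doublings")
    y = np.array([np.mean(series.target_ct[a]) for a in amounts])
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= -1e-9:
        raise AnalysisError("no amplification response")
    efficiency = 2.0 ** (-1.0 / slope)
    dct_by_amount = {
        a: float(np.mean(series.target_ct[a]) - np.mean(series.reference_ct[a]))
        for a in amounts
    }
    return slope, efficiency, dct_by_amount


@dataclass(frozen=True)
class MixtureSeries:
    """Spike-in dilution series: zero-copy DNA mixed into two-copy DNA.

    ``null_fractions`` are the mass fractions of zero-copy DNA (must be
    strictly increasing and include 0, the pure two-copy control);
    ``target_ct``/``reference_ct`` map each fraction to replicate Cts.
    """

    null_fractions: tuple[float, ...]
    target_ct: Mapping[float, tuple[float, ...]]
    reference_ct: Mapping[float, tuple[float, ...]]

    def __post_init__(self) -> None:
        f = self.null_fractions
        if len(f) < 2 or any(b <= a for a, b in zip(f, f[1:])):
            raise InputError("null fractions must be strictly increasing")
        if f[0] != 0:
            raise InputError("mixture series must include the 0% control")
        if any(x < 0 or x > 1 for x in f):
            raise InputError("null fractions must lie in [0, 1]")

    def dcts(self, fraction: float) -> np.ndarray:
        t = np.asarray(self.target_ct[fraction], dtype=float)
        r = np.asarray(self.reference_ct[fraction], dtype=float)
        if t.shape != r.shape:
            raise InputError("target/reference replicate counts differ")
        return t - r


@dataclass(frozen=True)
class LodResult:
    """Detection-limit estimate for a spike-in series.

    ``detection_limit`` is the smallest null fraction significantly
    different from the 0% control with every larger fraction also
    significant, or ``None`` when nothing qualifies (not detected).
    """

    detection_limit: float | None
    per_fraction_p: dict[float, float]
    alpha: float

    @property
    def detected(self) -> bool:
        return self.detection_limit is not None


def _monotone_lowest(per_fraction_p: Mapping[float, float], alpha: float) -> float | None:
    """Smallest fraction significant with all larger fractions significant."""
    fractions = sorted(per_fraction_p)
    limit: float | None = None
    for f in reversed(fractions):
        if per_fraction_p[f] < alpha:
            limit = f
        else:
            break
    return limit


def mixture_linearity(
    series: MixtureSeries, efficiency: float = 2.0
) -> tuple[float, float, float]:
    """Linearity of measured deletion proportion against the spiked fraction.

    The 0% mixture is the calibrator; returns the least-squares
    ``(slope, intercept, r)`` of mean deletion proportion vs null fraction.
    An unbiased assay gives slope 1, intercept 0.
    """
    if len(series.null_fractions) < 3:
        raise InputError("mixture linearity needs >= 3 fractions")
    cal = float(series.dcts(0.0).mean())
    x = np.asarray(series.null_fractions, dtype=float)
    y = np.array(
        [
            1.0 - float(np.mean(replicate_rcns(series.dcts(f), cal, efficiency)))
            for f in series.null_fractions
        ]
    )
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def detection_limit(
    series: MixtureSeries, alpha: float = 0.05, efficiency: float = 2.0
) -> LodResult:
    """Detection limit of the assay from a spike-in dilution series.

    Each nonzero fraction's replicate RCNs are tested two-sided against the
    0% control's; the limit is the smallest consistently significant
    fraction (all larger fractions must also be significant, guarding the
    'lowest significant dilution' rule against isolated false positives).
    """
    cal = float(series.dcts(0.0).mean())
    ctrl = np.asarray(replicate_rcns(series.dcts(0.0), cal, efficiency))
    per_p: dict[float, float] = {}
    for f in series.null_fractions:
        if f == 0:
            continue
        rcns = np.asarray(replicate_rcns(series.dcts(f), cal, efficiency))
        per_p[f] = _ttest_two_sided(rcns, ctrl)
    return LodResult(_monotone_lowest(per_p, alpha), per_p, alpha)
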
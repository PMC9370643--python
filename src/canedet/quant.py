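"""Wet-lab validation quantifications: qPCR ΔCt expression and MPN counts.

Two independent measurements back the transcriptome results.  Relative
expression from quantitative PCR uses the ΔCt method against the mean of
two reference genes (28S rRNA and GAPDH; the same scheme normalizes
bacterial 23S rRNA for colonization ratios).  Bacterial load in plant
tissue is quantified by the most-probable-number (MPN) method: positive or
negative growth outcomes across a ten-fold serial-dilution ladder are fit
by maximum likelihood under the single-hit Poisson model, then converted to
organisms per gram of tissue via the homogenate dilution factor (1 g of
plant macerated in 9 mL of saline, i.e. 10 mL of homogenate per gram).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, EmptyInputError, FormatError

#: bisection bracket for the MPN concentration (organisms/mL) and the
#: relative tolerance at which the search stops
MPN_BRACKET = (1e-6, 1e15)
MPN_RTOL = 1e-9


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target Ct plus two reference-gene Cts."""

    sample_id: str
    target_ct: float
    reference_cts: tuple[float, float]
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        values = (self.target_ct, *self.reference_cts)
        if len(self.reference_cts) != 2:
            raise FormatError("two reference Cts are required (e.g. 28S rRNA and GAPDH)")
        if any(not math.isfinite(v) or v <= 0 for v in values):
            raise FormatError(f"Ct values must be finite and > 0, got {values}")


def relative_expression(record: CtRecord, efficiency: float = 2.0) -> float:
    """ΔCt relative quantity: efficiency**-(target_ct - mean(reference_cts)).

    Averaging the two reference Cts is equivalent to normalizing by the
    geometric mean of the two reference quantities.  ``efficiency`` is the
    per-cycle amplification factor (2 = perfect doubling).
    """
    if efficiency <= 1:
        raise DomainError("amplification efficiency must exceed 1")
    delta_ct = record.target_ct - (record.reference_cts[0] + record.reference_cts[1]) / 2
    return float(efficiency ** (-delta_ct))


@dataclass(frozen=True)
class ExpressionRatio:
    ratio: float
    sd: float
    log2_ratio: float


def expression_ratio(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> ExpressionRatio:
    """mean(a)/mean(b) of relative quantities, with first-order propagated sd."""
    a = np.asarray(list(sample_a), dtype=np.float64)
    b = np.asarray(list(sample_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("both samples need at least one replicate")
    ma, mb = float(a.mean()), float(b.mean())
    if mb == 0:
        raise DomainError("denominator sample has zero mean expression")
    ratio = ma / mb
    sa = float(a.std(ddof=1)) if a.size > 1 else 0.0
    sb = float(b.std(ddof=1)) if b.size > 1 else 0.0
    rel_var = (sa / ma) ** 2 if ma else 0.0
    rel_var += (sb / mb) ** 2
    return ExpressionRatio(ratio=ratio, sd=abs(ratio) * math.sqrt(rel_var), log2_ratio=math.log2(ratio))


@dataclass(frozen=True)
class ConcordanceSummary:
    fraction_agreeing: float
    n_shared: int
    pairs: tuple[tuple[str, float, float], ...]  # (transcript, qpcr_log2, rnaseq_log2)


def concordance(
    qpcr_log2: Mapping[str, float], rnaseq_log2: Mapping[str, float]
) -> ConcordanceSummary:
    """Sign agreement between qPCR log2 ratios and RNA-seq log2 fold changes.

    A zero on either side matches nothing.
    """
    shared = sorted(set(qpcr_log2) & set(rnaseq_log2))
    if not shared:
        raise EmptyInputError("no transcripts shared between qPCR and RNA-seq results")
    pairs = tuple((t, float(qpcr_log2[t]), float(rnaseq_log2[t])) for t in shared)
    agree = sum(1 for _, q, r in pairs if q * r > 0)
    return ConcordanceSummary(
        fraction_agreeing=agree / len(pairs), n_shared=len(pairs), pairs=pairs
    )


# ---------------------------------------------------------------------------
# MPN


class MpnStatus(str, enum.Enum):
    OK = "OK"
    ALL_NEGATIVE = "ALL_NEGATIVE"
    ALL_POSITIVE = "ALL_POSITIVE"


@dataclass(frozen=True)
class DilutionSeries:
    """Tube outcomes across a ten-fold serial-dilution ladder.

    ``dilution_exponents`` are the log10 dilution factors (e.g. -1 .. -9);
    each tube at exponent e receives ``inoculum_volume * 10**e`` mL of
    undiluted homogenate.  ``homogenate_factor`` converts organisms/mL of
    homogenate to organisms/g of tissue (default 10: 1 g in 9 mL saline).
    """

    dilution_exponents: tuple[int, ...]
    tubes_per_dilution: int
    positives: tuple[int, ...]
    inoculum_volume: float = 0.1
    homogenate_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.tubes_per_dilution < 1:
            raise FormatError("tubes_per_dilution must be >= 1")
        if len(self.positives) != len(self.dilution_exponents):
            raise FormatError("one positives count per dilution is required")
        for e, p in zip(self.dilution_exponents, self.positives):
            if not 0 <= p <= self.tubes_per_dilution:
                raise FormatError(
                    f"positives={p} at dilution 10^{e} outside [0, {self.tubes_per_dilution}]"
                )
        if self.inoculum_volume <= 0 or self.homogenate_factor <= 0:
            raise FormatError("inoculum_volume and homogenate_factor must be > 0")

    @property
    def volumes(self) -> np.ndarray:
        """mL of undiluted homogenate delivered to each tube, per dilution."""
        return self.inoculum_volume * np.power(
            10.0, np.asarray(self.dilution_exponents, dtype=np.float64)
        )


@dataclass(frozen=True)
class MpnEstimate:
    mpn_per_ml: float
    mpn_per_g: float
    status: MpnStatus
    log10_ci: tuple[float, float] | None = None


def _score(c: float, volumes: np.ndarray, positives: np.ndarray, tubes: int) -> float:
    """d/dc of the single-hit log likelihood at concentration c."""
    cv = c * volumes
    # p * v / (e^{cv} - 1) - (n - p) * v
    with np.errstate(over="ignore"):
        expm1 = np.expm1(cv)
    pos_term = np.where(positives > 0, positives * volumes / expm1, 0.0)
    neg_term = (tubes - positives) * volumes
    return float(np.sum(pos_term - neg_term))


def mpn_log_likelihood(c, series: DilutionSeries) -> np.ndarray:
    """Single-hit Poisson log likelihood of the tube outcomes at conc. c."""
    c = np.asarray(c, dtype=np.float64)[..., None]
    v = series.volumes
    p = np.asarray(series.positives, dtype=np.float64)
    n = series.tubes_per_dilution
    with np.errstate(divide="ignore"):
        log_ppos = np.log(-np.expm1(-c * v))
    terms = np.where(p > 0, p * log_ppos, 0.0) - (n - p) * c * v
    return terms.sum(axis=-1)


def mpn_estimate(series: DilutionSeries, with_ci: bool = False) -> MpnEstimate:
    """Maximum-likelihood MPN from serial-dilution tube outcomes.

    Under the single-hit model each tube at delivered volume v is positive
    with probability 1 - exp(-c v); the likelihood is a product of binomials
    and its score function is strictly decreasing in c, so the MLE is found
    by bisection on the bracket [1e-6, 1e15] organisms/mL to 1e-9 relative
    tolerance.  All-negative outcomes give 0 (ALL_NEGATIVE); all-positive
    outcomes are reported as a lower bound at the bracket limit
    (ALL_POSITIVE).  ``with_ci`` adds the standard log10 interval
    estimate +/- 1.96 sigma with sigma from the observed information.
    """
    volumes = series.volumes
    positives = np.asarray(series.positives, dtype=np.int64)
    tubes = series.tubes_per_dilution
    if (positives == 0).all():
        return MpnEstimate(0.0, 0.0, MpnStatus.ALL_NEGATIVE)
    if (positives == tubes).all():
        c = MPN_BRACKET[1]
        return MpnEstimate(c, c * series.homogenate_factor, MpnStatus.ALL_POSITIVE)

    lo, hi = MPN_BRACKET
    if _score(lo, volumes, positives, tubes) <= 0:
        c = lo
    else:
        while (hi - lo) > MPN_RTOL * hi:
            mid = math.sqrt(lo * hi)  # geometric midpoint: the scale is multiplicative
            if _score(mid, volumes, positives, tubes) > 0:
                lo = mid
            else:
                hi = mid
        c = math.sqrt(lo * hi)

    ci = None
    if with_ci:
        # observed information for theta = ln c
        cv = c * volumes
        info = float(np.sum(tubes * cv**2 * np.exp(-cv) / -np.expm1(-cv)))
        if info > 0:
            sigma_log10 = 1.0 / (math.log(10) * math.sqrt(info))
            center = math.log10(c)
            ci = (center - 1.96 * sigma_log10, center + 1.96 * sigma_log10)
    return MpnEstimate(c, c * series.homogenate_factor, MpnStatus.OK, log10_ci=ci)


def cfu_per_gram(estimate: MpnEstimate, series: DilutionSeries) -> float:
    """Organisms per gram of tissue.

    The estimate's status travels with it: an ALL_POSITIVE ladder yields a
    lower bound, not a point estimate.
    """
    return estimate.mpn_per_ml * series.homogenate_factor


def read_ct_table(path) -> list[CtRecord]:
    """TSV with columns sample_id, replicate, target_ct, ref1_ct, ref2_ct."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "replicate", "target_ct", "ref1_ct", "ref2_ct"}
    if not required <= set(df.columns):
        raise FormatError(f"Ct table needs columns {sorted(required)}")
    return [
        CtRecord(
            sample_id=str(r.sample_id),
            target_ct=float(r.target_ct),
            reference_cts=(float(r.ref1_ct), float(r.ref2_ct)),
            replicate_id=str(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def read_dilution_series(
    path, inoculum_volume: float = 0.1, homogenate_factor: float = 10.0
) -> DilutionSeries:
    """TSV with columns exponent, tubes, positives (tubes must be constant)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"exponent", "tubes", "positives"}
    if not required <= set(df.columns):
        raise FormatError(f"dilution table needs columns {sorted(required)}")
    tubes = df["tubes"].unique()
    if len(tubes) != 1:
        raise FormatError("tubes per dilution must be constant across the ladder")
    return DilutionSeries(
        dilution_exponents=tuple(int(e) for e in df["exponent"]),
        tubes_per_dilution=int(tubes[0]),
        positives=tuple(int(p) for p in df["positives"]),
        inoculum_volume=inoculum_volume,
        homogenate_factor=homogenate_factor,
    )
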
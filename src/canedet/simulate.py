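"""Synthetic data with known ground truth for every pipeline input.

The generator emulates the study design: 16 libraries covering 2 genotypes
x 2 tissues x 2 growth conditions x 2 replicates, with negative-binomial
read counts, planted genotype fold changes, planted genotype-exclusive
transcripts, annotation maps with a planted enriched term, qPCR Ct tables
and serial-dilution tube outcomes.  Everything is a pure function of its
configuration and seed; substreams are derived from one master seed so
components stay independent and reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SpecificationError
from .io import (
    AnnotationMap,
    CountMatrix,
    Genotype,
    LibraryDescriptor,
    Namespace,
    canonical_design,
)
from .quant import CtRecord, DilutionSeries


class TruthStatus(str, enum.Enum):
    NULL = "NULL"
    DE_UP_HIGH = "DE_UP_HIGH"  # more expressed in the high-BNF genotype
    DE_UP_LOW = "DE_UP_LOW"
    EXCLUSIVE_HIGH = "EXCLUSIVE_HIGH"
    EXCLUSIVE_LOW = "EXCLUSIVE_LOW"


@dataclass
class TruthTable:
    """Planted ground truth: per-transcript status and true log2 fold change
    (high-BNF over low-BNF), plus any planted term memberships."""

    frame: pd.DataFrame  # columns: status, true_log2fc
    planted_term: str | None = None
    planted_term_members: frozenset[str] = frozenset()

    def with_status(self, *statuses: TruthStatus) -> set[str]:
        wanted = {s.value for s in statuses}
        return set(self.frame.index[self.frame["status"].isin(wanted)])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the count-matrix generator.

    Defaults mirror the experimental design: the canonical 16-library
    factorial, one million reads per library, log2 baseline expression
    drawn N(5, 1.5) (median 32 reads per library), negative-binomial
    dispersion 0.1 (variance mu + 0.1 mu^2), 10% of transcripts
    differentially expressed at |log2FC| = 2 between genotypes and 2%
    exclusive to one genotype.
    """

    n_transcripts: int = 500
    design: tuple[LibraryDescriptor, ...] = tuple(canonical_design())
    library_total: int = 1_000_000
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    exclusive_fraction: float = 0.02
    min_positive_libraries: int = 5
    transcript_length_range: tuple[int, int] = (200, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise SpecificationError("n_transcripts must be >= 1")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.exclusive_fraction <= 1:
            raise SpecificationError("fractions must lie in [0, 1]")
        if self.de_fraction + self.exclusive_fraction > 1:
            raise SpecificationError("de_fraction + exclusive_fraction must be <= 1")
        if self.library_total < 1:
            raise SpecificationError("library_total must be >= 1")
        if self.nb_dispersion < 0:
            raise SpecificationError("nb_dispersion must be >= 0")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[LibraryDescriptor], TruthTable]:
    """Simulate a count matrix under the factorial design with planted truth.

    DE transcripts get genotype-specific means split symmetrically around
    the baseline (each genotype shifted by half the planted log2FC, so the
    planted contrast is exactly ``de_log2fc``).  Exclusive transcripts are
    zero in one genotype and guaranteed >= 1 read in at least
    ``min_positive_libraries`` libraries of the other.
    """
    rng_len, rng_base, rng_counts, rng_assign, rng_excl = _substreams(config.seed, 5)
    design = list(config.design)
    n, n_libs = config.n_transcripts, len(design)
    if n_libs < 2:
        raise SpecificationError("the design needs at least two libraries")

    ids = [f"T{i:05d}" for i in range(n)]
    lo, hi = config.transcript_length_range
    lengths = rng_len.integers(lo, hi + 1, size=n)
    baseline = 2.0 ** rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    n_de = int(round(config.de_fraction * n))
    n_excl = int(round(config.exclusive_fraction * n))
    perm = rng_assign.permutation(n)
    de_idx = perm[:n_de]
    excl_idx = perm[n_de : n_de + n_excl]
    status = np.full(n, TruthStatus.NULL.value, dtype=object)
    true_lfc = np.zeros(n)
    # half of each planted class favors each genotype
    status[de_idx[: n_de // 2]] = TruthStatus.DE_UP_HIGH.value
    status[de_idx[n_de // 2 :]] = TruthStatus.DE_UP_LOW.value
    true_lfc[de_idx[: n_de // 2]] = config.de_log2fc
    true_lfc[de_idx[n_de // 2 :]] = -config.de_log2fc
    status[excl_idx[: n_excl // 2]] = TruthStatus.EXCLUSIVE_HIGH.value
    status[excl_idx[n_excl // 2 :]] = TruthStatus.EXCLUSIVE_LOW.value

    is_high = np.array([d.genotype is Genotype.HIGH_BNF for d in design])
    shift = 2.0 ** (true_lfc / 2.0)
    counts = np.zeros((n, n_libs), dtype=np.int64)
    for j, high in enumerate(is_high):
        mean_j = baseline * (shift if high else 1.0 / shift)
        counts[:, j] = _nb_draw(rng_counts, mean_j, config.nb_dispersion)

    # enforce exclusivity by construction
    for i in np.concatenate([excl_idx[: n_excl // 2], excl_idx[n_excl // 2 :]]):
        keep_high = status[i] == TruthStatus.EXCLUSIVE_HIGH.value
        allowed = np.flatnonzero(is_high == keep_high)
        forbidden = np.flatnonzero(is_high != keep_high)
        counts[i, forbidden] = 0
        positive = allowed[counts[i, allowed] > 0]
        need = config.min_positive_libraries - len(positive)
        if need > 0:
            zeros = allowed[counts[i, allowed] == 0]
            boost = rng_excl.choice(zeros, size=need, replace=False)
            counts[i, boost] = 1

    lib_ids = [d.library_id for d in design]
    frame = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=lib_ids)
    colsums = frame.sum(axis=0)
    totals = pd.Series(
        np.maximum(config.library_total, colsums.to_numpy()), index=lib_ids, dtype=np.int64
    )
    matrix = CountMatrix(
        counts=frame,
        lengths=pd.Series(lengths, index=frame.index, name="length_bp"),
        library_totals=totals,
    )
    truth = TruthTable(
        frame=pd.DataFrame(
            {"status": status, "true_log2fc": true_lfc, "baseline_mean": baseline},
            index=frame.index,
        )
    )
    return matrix, design, truth


def simulate_annotation(
    n_background: int,
    n_terms: int,
    planted_term_effect: float,
    truth: TruthTable,
    seed: int,
    base_term_prob: float = 0.1,
    namespace: Namespace = Namespace.GO_BP,
) -> AnnotationMap:
    """Annotation map with one term over-represented among DE transcripts.

    Each (transcript, term) pair is assigned independently with probability
    ``base_term_prob``, except the planted term (TERM0000), whose odds among
    DE transcripts are multiplied by ``planted_term_effect``.
    """
    if n_terms < 1:
        raise SpecificationError("n_terms must be >= 1")
    if planted_term_effect <= 0:
        raise DomainError("planted_term_effect must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ids = np.asarray(truth.frame.index[:n_background], dtype=object)
    de = truth.with_status(TruthStatus.DE_UP_HIGH, TruthStatus.DE_UP_LOW)
    de_mask = np.array([t in de for t in ids])

    q0 = base_term_prob
    odds = planted_term_effect * q0 / (1 - q0)
    q_de = odds / (1 + odds)

    amap = AnnotationMap()
    planted = "TERM0000"
    planted_mask = rng.random(len(ids)) < np.where(de_mask, q_de, q0)
    for t in ids[planted_mask]:
        amap.add(t, planted, namespace)
    members = set(ids[planted_mask])
    for j in range(1, n_terms):
        mask = rng.random(len(ids)) < q0
        term = f"TERM{j:04d}"
        for t in ids[mask]:
            amap.add(t, term, namespace)
    truth.planted_term = planted
    truth.planted_term_members = frozenset(members)
    return amap


def simulate_dilution_series(
    true_conc: float, series_spec: DilutionSeries, seed: int
) -> DilutionSeries:
    """Tube outcomes under the single-hit model at a known concentration."""
    if true_conc < 0:
        raise DomainError("true concentration must be >= 0")
    rng = np.random.default_rng(seed)
    p_pos = -np.expm1(-true_conc * series_spec.volumes)
    positives = rng.binomial(series_spec.tubes_per_dilution, p_pos)
    return replace(series_spec, positives=tuple(int(p) for p in positives))


def simulate_ct_table(
    true_ratios: Mapping[str, float],
    base_ct: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[dict[str, list[CtRecord]], dict[str, list[CtRecord]]]:
    """Ct records for two samples A and B with known expression ratios A/B.

    Reference Cts sit at ``base_ct``; the sample-A target Ct is offset by
    -log2(ratio) so that the recovered ΔCt ratio equals ``true_ratios``
    exactly when ``noise_sd`` is zero.
    """
    if any(r <= 0 for r in true_ratios.values()):
        raise DomainError("expression ratios must be > 0")
    rng = np.random.default_rng(seed)
    sample_a: dict[str, list[CtRecord]] = {}
    sample_b: dict[str, list[CtRecord]] = {}
    for transcript, ratio in true_ratios.items():
        offset = float(np.log2(ratio))
        sample_a[transcript] = [
            CtRecord(
                sample_id="A",
                target_ct=base_ct - offset + rng.normal(0.0, noise_sd),
                reference_cts=(base_ct, base_ct),
                replicate_id=str(r + 1),
            )
            for r in range(n_replicates)
        ]
        sample_b[transcript] = [
            CtRecord(
                sample_id="B",
                target_ct=base_ct + rng.normal(0.0, noise_sd),
                reference_cts=(base_ct, base_ct),
                replicate_id=str(r + 1),
            )
            for r in range(n_replicates)
        ]
    return sample_a, sample_b
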
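"""Differential expressed transcript (DET) calling between genotype groups.

The statistic is deliberately simple and count-exact: read counts are
normalized as RPKM, each transcript is tested with a two-sided Fisher exact
test on the 2x2 table of (reads on transcript, remaining reads) in the two
groups, p-values are Bonferroni-adjusted over the transcripts actually
tested, and the direction of a call follows the larger RPKM.  Transcripts
expressed in only one genotype are handled by a separate exclusivity rule
(>= 1 read in at least 5 libraries of one genotype, zero reads in every
library of the other) rather than by a fold change against zero.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DomainError, SpecificationError
from .io import CountMatrix, Genotype, LibraryDescriptor

#: relative slack on the "probability <= observed" comparison that defines
#: the two-sided Fisher p-value; guards against float noise in ties
TIE_RTOL = 1e-7


class ReplicateMode(str, enum.Enum):
    POOLED = "POOLED"
    PER_PAIR_CONSENSUS = "PER_PAIR_CONSENSUS"


class Call(str, enum.Enum):
    UP_A = "UP_A"
    UP_B = "UP_B"
    NS = "NS"


class Exclusivity(str, enum.Enum):
    NONE = "NONE"
    EXCLUSIVE_A = "EXCLUSIVE_A"
    EXCLUSIVE_B = "EXCLUSIVE_B"


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint library groups to contrast (A = condition of interest)."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    replicate_mode: ReplicateMode = ReplicateMode.POOLED

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise SpecificationError(f"{self.label}: both groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise SpecificationError(f"{self.label}: groups overlap")

    def validate_against(self, matrix: CountMatrix) -> None:
        known = set(matrix.library_ids)
        unknown = (set(self.group_a) | set(self.group_b)) - known
        if unknown:
            raise SpecificationError(f"{self.label}: unknown libraries {sorted(unknown)}")


@dataclass
class DetTable:
    """Per-transcript DET statistics for one comparison."""

    comparison: ComparisonSpec
    frame: pd.DataFrame  # indexed by transcript_id
    alpha: float
    m_tests: int

    @property
    def called(self) -> pd.DataFrame:
        return self.frame[self.frame["call"] != Call.NS.value]

    def counts_by_direction(self) -> dict[str, int]:
        vc = self.frame["call"].value_counts()
        return {c.value: int(vc.get(c.value, 0)) for c in (Call.UP_A, Call.UP_B)}

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "comparison", self.comparison.label)
        for col in ("p_raw", "p_adj"):
            out[col] = out[col].map(lambda p: f"{p:.6e}")
        for col in ("rpkm_a", "rpkm_b", "log2fc"):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# elementary statistics


def compute_rpkm(count, length, library_total):
    """RPKM = count * 1e9 / (library_total * length).

    Reads per kilobase of transcript per million sequenced reads; accepts
    scalars or aligned arrays.
    """
    length = np.asarray(length, dtype=np.float64)
    total = np.asarray(library_total, dtype=np.float64)
    if np.any(length < 1) or np.any(total < 1):
        raise DomainError("length and library_total must be >= 1")
    out = np.asarray(count, dtype=np.float64) * 1e9 / (total * length)
    return float(out) if out.ndim == 0 else out


def log2_fold_change(rpkm_interest, rpkm_control, pseudo: float = 0.0):
    """log2 of the (optionally pseudocounted) RPKM ratio interest/control."""
    if pseudo < 0:
        raise DomainError("pseudocount must be >= 0")
    a = np.asarray(rpkm_interest, dtype=np.float64) + pseudo
    b = np.asarray(rpkm_control, dtype=np.float64) + pseudo
    if np.any(b == 0) or np.any(a == 0):
        raise DomainError(
            "zero RPKM with zero pseudocount; route all-zero transcripts to the exclusivity rule"
        )
    out = np.log2(a / b)
    return float(out) if out.ndim == 0 else out


def _fisher_two_sided_batch(
    count_a: np.ndarray, count_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables sharing their totals.

    Table t is [[count_a[t], total_a - count_a[t]], [count_b[t],
    total_b - count_b[t]]].  Conditioning on margins, the first cell is
    hypergeometric; the two-sided p sums the probabilities of all tables at
    most as probable as the one observed (with relative slack TIE_RTOL on
    the comparison).  The support has at most count_a + count_b + 1 points,
    so the enumeration stays cheap even for library-scale totals.
    """
    ca = np.asarray(count_a, dtype=np.int64)
    cb = np.asarray(count_b, dtype=np.int64)
    if (ca < 0).any() or (cb < 0).any() or (ca > total_a).any() or (cb > total_b).any():
        raise DomainError("counts must satisfy 0 <= count <= group total")
    if total_a < 1 or total_b < 1:
        raise DomainError("group totals must be >= 1")
    k = ca + cb
    lo = np.maximum(0, k - total_b)
    hi = np.minimum(k, total_a)
    widths = hi - lo + 1
    p = np.empty(len(ca), dtype=np.float64)
    # process in width-sorted chunks with bounded width spread, so padding
    # stays near each chunk's own support size instead of the global maximum
    order = np.argsort(widths, kind="stable")
    sorted_w = widths[order]
    start = 0
    n = len(order)
    while start < n:
        limit = max(int(sorted_w[start] * 1.3), int(sorted_w[start]) + 8)
        end = int(np.searchsorted(sorted_w, limit, side="right"))
        end = max(end, start + 1)
        idx = order[start:end]
        p[idx] = _fisher_chunk(ca[idx], k[idx], lo[idx], hi[idx], total_a, total_b)
        start = end
    return p


def _fisher_chunk(
    ca: np.ndarray, k: np.ndarray, lo: np.ndarray, hi: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    width = int((hi - lo).max()) + 1
    offsets = np.arange(width, dtype=np.int64)
    x = lo[:, None] + offsets[None, :]
    valid = x <= hi[:, None]
    xc = np.where(valid, x, 0)
    kx = np.where(valid, k[:, None] - xc, 0)
    # log C(total_a, x) + log C(total_b, k - x); the constant log C(N, k)
    # cancels in the <= comparison and in the normalized sum
    logw = (
        -gammaln(xc + 1)
        - gammaln(total_a - xc + 1)
        - gammaln(kx + 1)
        - gammaln(total_b - kx + 1)
    )
    logw = np.where(valid, logw, -np.inf)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    obs = w[np.arange(len(ca)), (ca - lo).astype(np.int64)]
    take = w <= obs[:, None] * (1.0 + TIE_RTOL)
    p = (w * take).sum(axis=1) / w.sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_exact_two_sided(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher exact test on [[count_a, rest_a], [count_b, rest_b]]."""
    return float(
        _fisher_two_sided_batch(
            np.array([count_a]), np.array([count_b]), int(total_a), int(total_b)
        )[0]
    )


def adjust_bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m), order preserved."""
    p = np.asarray(list(p_values), dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise DomainError("Bonferroni m must be >= 1")
    if m < len(p):
        raise DomainError(f"m={m} smaller than the number of tests ({len(p)})")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# DET calling


def _pooled_stats(matrix: CountMatrix, libraries: Sequence[str]) -> tuple[np.ndarray, int]:
    counts = matrix.counts[list(libraries)].to_numpy(dtype=np.int64).sum(axis=1)
    total = int(matrix.library_totals[list(libraries)].sum())
    return counts, total


def _assemble_frame(
    matrix: CountMatrix,
    ca: np.ndarray,
    cb: np.ndarray,
    total_a: int,
    total_b: int,
    p_raw: np.ndarray,
    p_adj: np.ndarray,
    tested: np.ndarray,
    alpha: float,
    min_abs_log2fc: float,
    pseudo: float,
) -> pd.DataFrame:
    lengths = matrix.lengths.to_numpy(dtype=np.float64)
    rpkm_a = compute_rpkm(ca, lengths, total_a)
    rpkm_b = compute_rpkm(cb, lengths, total_b)
    log2fc = log2_fold_change(rpkm_a, rpkm_b, pseudo=pseudo)
    significant = tested & (p_adj < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
    # direction follows the larger RPKM; an exact RPKM tie cannot be called
    call = np.where(
        significant & (rpkm_a > rpkm_b),
        Call.UP_A.value,
        np.where(significant & (rpkm_b > rpkm_a), Call.UP_B.value, Call.NS.value),
    )
    exclusive = np.where(
        (ca > 0) & (cb == 0),
        Exclusivity.EXCLUSIVE_A.value,
        np.where((cb > 0) & (ca == 0), Exclusivity.EXCLUSIVE_B.value, Exclusivity.NONE.value),
    )
    return pd.DataFrame(
        {
            "count_a": ca,
            "count_b": cb,
            "total_a": total_a,
            "total_b": total_b,
            "rpkm_a": rpkm_a,
            "rpkm_b": rpkm_b,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": call,
            "exclusive": exclusive,
        },
        index=matrix.counts.index,
    )


def call_dets(
    matrix: CountMatrix,
    spec: ComparisonSpec,
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.0,
    pseudo: float = 0.25,
    m_global: int | None = None,
) -> DetTable:
    """Call DETs between the two library groups of ``spec``.

    POOLED mode sums counts and totals within each group and tests every
    transcript with a nonzero pooled count; the Bonferroni denominator is
    the number of transcripts tested (``m_global`` overrides it for
    across-comparison control).  PER_PAIR_CONSENSUS tests every
    (library-in-A, library-in-B) pair separately and calls a transcript only
    when all pairs agree on a significant direction; reported statistics are
    the pooled ones, with p_raw/p_adj the worst (largest) across pairs.
    """
    spec.validate_against(matrix)
    ca, total_a = _pooled_stats(matrix, spec.group_a)
    cb, total_b = _pooled_stats(matrix, spec.group_b)
    tested = (ca + cb) > 0
    m = int(tested.sum())
    denom = m_global if m_global is not None else max(m, 1)

    def _test(counts_a, counts_b, ta, tb):
        p = np.ones(len(counts_a), dtype=np.float64)
        if tested.any():
            p[tested] = _fisher_two_sided_batch(counts_a[tested], counts_b[tested], ta, tb)
        return p

    def _adjust(p_raw):
        # untested transcripts carry p = 1 and do not enter the family
        p_adj = np.ones_like(p_raw)
        if tested.any():
            p_adj[tested] = adjust_bonferroni(p_raw[tested], m=denom)
        return p_adj

    if spec.replicate_mode is ReplicateMode.POOLED:
        p_raw = _test(ca, cb, total_a, total_b)
        p_adj = _adjust(p_raw)
        frame = _assemble_frame(
            matrix, ca, cb, total_a, total_b, p_raw, p_adj, tested, alpha, min_abs_log2fc, pseudo
        )
    else:
        pair_p = []
        pair_dir = []
        lengths = matrix.lengths.to_numpy(dtype=np.float64)
        for lib_a, lib_b in itertools.product(spec.group_a, spec.group_b):
            a1, t1 = _pooled_stats(matrix, [lib_a])
            b1, t2 = _pooled_stats(matrix, [lib_b])
            pair_p.append(_test(a1, b1, t1, t2))
            ra = compute_rpkm(a1, lengths, t1)
            rb = compute_rpkm(b1, lengths, t2)
            pair_dir.append(np.sign(ra - rb))
        p_raw = np.max(pair_p, axis=0)  # consensus: worst pair must pass
        p_adj = _adjust(p_raw)
        frame = _assemble_frame(
            matrix, ca, cb, total_a, total_b, p_raw, p_adj, tested, alpha, min_abs_log2fc, pseudo
        )
        dirs = np.stack(pair_dir)
        consistent = (dirs == dirs[0]).all(axis=0) & (dirs[0] != 0)
        frame.loc[~consistent, "call"] = Call.NS.value
    return DetTable(comparison=spec, frame=frame, alpha=alpha, m_tests=m)


def call_exclusive(
    matrix: CountMatrix,
    sheet: Sequence[LibraryDescriptor],
    min_positive_libraries: int = 5,
) -> dict[str, Exclusivity]:
    """Genotype-exclusive transcripts.

    A transcript is exclusive to a genotype iff it has >= 1 read in at least
    ``min_positive_libraries`` libraries of that genotype and zero reads in
    every library of the other genotype ("and vice versa").  Returns only
    the exclusive transcripts, keyed by id, with EXCLUSIVE_A = HIGH_BNF and
    EXCLUSIVE_B = LOW_BNF.
    """
    by_geno: dict[Genotype, list[str]] = {g: [] for g in Genotype}
    for d in sheet:
        if d.library_id in matrix.library_ids:
            by_geno[d.genotype].append(d.library_id)
    for g, libs in by_geno.items():
        if not libs:
            raise SpecificationError(f"no libraries for genotype {g.value}")
        if min_positive_libraries > len(libs):
            raise SpecificationError(
                f"min_positive_libraries={min_positive_libraries} exceeds the "
                f"{len(libs)} libraries of {g.value}"
            )
    high = matrix.counts[by_geno[Genotype.HIGH_BNF]].to_numpy(dtype=np.int64)
    low = matrix.counts[by_geno[Genotype.LOW_BNF]].to_numpy(dtype=np.int64)
    high_pos = (high > 0).sum(axis=1)
    low_pos = (low > 0).sum(axis=1)
    excl_high = (high_pos >= min_positive_libraries) & (low_pos == 0)
    excl_low = (low_pos >= min_positive_libraries) & (high_pos == 0)
    out: dict[str, Exclusivity] = {}
    ids = matrix.counts.index
    for i in np.flatnonzero(excl_high):
        out[ids[i]] = Exclusivity.EXCLUSIVE_A
    for i in np.flatnonzero(excl_low):
        out[ids[i]] = Exclusivity.EXCLUSIVE_B
    return out
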
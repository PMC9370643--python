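"""Hypergeometric term enrichment of DET sets with Rich Factor.

For each annotation term, the number of foreground (DET) transcripts
carrying it is compared with what a uniform draw of the foreground from the
annotated background would give: with N background transcripts, K of them
carrying the term and a foreground of size n containing k, the enrichment
p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n).  The Rich
Factor k/K summarizes effect size.  Raw p < alpha is the default
significance rule; Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, SpecificationError
from .io import AnnotationMap, Namespace


class Adjustment(str, enum.Enum):
    NONE = "NONE"
    BH = "BH"


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    namespace: Namespace
    k: int  # foreground transcripts with the term
    K: int  # background transcripts with the term
    n: int  # foreground size
    N: int  # background size
    rich_factor: float
    p_raw: float
    p_adj: float | None
    significant: bool


def rich_factor(k: int, K: int) -> float:
    """Foreground transcripts in a category over background transcripts in it."""
    if K < 1:
        raise DomainError("background category count K must be >= 1")
    if not 0 <= k <= K:
        raise DomainError(f"k={k} outside [0, K={K}]")
    return k / K


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    foreground: Iterable[str],
    annotations: AnnotationMap,
    background: Iterable[str],
    alpha: float = 0.05,
    adjust: Adjustment | str = Adjustment.NONE,
) -> list[EnrichmentRecord]:
    """Test every annotated term for over-representation in the foreground.

    ``foreground`` must be a subset of ``background``; terms observed in the
    background with K >= 1 are tested.  Records come back sorted by p_raw
    ascending (ties by term id for stable output).
    """
    adjust = Adjustment(adjust if isinstance(adjust, Adjustment) else str(adjust).upper())
    fg = set(foreground)
    bg = set(background)
    if not bg:
        raise SpecificationError("background is empty")
    stray = fg - bg
    if stray:
        raise SpecificationError(f"foreground ids outside background: {sorted(stray)[:10]}")
    N = len(bg)
    n = len(fg)

    term_bg: dict[tuple[str, Namespace], set[str]] = {}
    for t in bg:
        for term in annotations.terms_for(t):
            term_bg.setdefault(term, set()).add(t)

    raw: list[tuple[str, Namespace, int, int, float]] = []
    for (term_id, namespace), members in term_bg.items():
        K = len(members)
        k = len(members & fg)
        raw.append((term_id, namespace, k, K, hypergeom_upper_tail(k, N, K, n)))
    raw.sort(key=lambda r: (r[4], r[0]))

    if adjust is Adjustment.BH and raw:
        rejected, p_adj, _, _ = multipletests(
            [r[4] for r in raw], alpha=alpha, method="fdr_bh"
        )
    else:
        p_adj = [None] * len(raw)
        rejected = [r[4] < alpha for r in raw]

    return [
        EnrichmentRecord(
            term_id=term_id,
            namespace=namespace,
            k=k,
            K=K,
            n=n,
            N=N,
            rich_factor=rich_factor(k, K),
            p_raw=p,
            p_adj=None if padj is None else float(padj),
            significant=bool(sig),
        )
        for (term_id, namespace, k, K, p), padj, sig in zip(raw, p_adj, rejected)
    ]


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    import pandas as pd

    rows = [
        {
            "term_id": r.term_id,
            "namespace": r.namespace.value,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "rich_factor": f"{r.rich_factor:.6g}",
            "p_raw": f"{r.p_raw:.6e}",
            "p_adj": "" if r.p_adj is None else f"{r.p_adj:.6e}",
            "significant": str(r.significant).lower(),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "namespace",
            "k",
            "K",
            "n",
            "N",
            "rich_factor",
            "p_raw",
            "p_adj",
            "significant",
        ],
    ).to_csv(path, sep="\t", index=False)
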
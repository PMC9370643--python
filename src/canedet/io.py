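"""Readers, writers and summary statistics for the pipeline's external artifacts.

The pipeline consumes transcript-by-library read-count tables, sample sheets
describing the two-genotype / two-tissue / two-growth-condition design,
transcript lengths (TSV or FASTA), transcript-to-term annotation maps and
12-column tabular BLAST hit files; it emits DET tables, enrichment tables and
summary reports.  Everything here is plain UTF-8 text so results stay
diff-able and reproducible.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    DuplicateDesignError,
    DuplicateKeyError,
    EmptyInputError,
    FormatError,
    MissingLengthError,
    VocabularyError,
)

MIN_RELIABLE_LENGTH = 100  # bp; assembled transcripts at or below this are suspect


class Genotype(str, enum.Enum):
    """The two BNF-contrasting genotypes (SP70-1143 vs. Chunee)."""

    HIGH_BNF = "HIGH_BNF"
    LOW_BNF = "LOW_BNF"


class Tissue(str, enum.Enum):
    ROOT = "ROOT"
    SHOOT = "SHOOT"


class GrowthCondition(str, enum.Enum):
    """Germinated stalks (naturally colonized) vs. bacteria-free hydroponics."""

    STALK = "STALK"
    HYDROPONIC = "HYDROPONIC"


class Namespace(str, enum.Enum):
    GO_BP = "GO_BP"
    GO_MF = "GO_MF"
    GO_CC = "GO_CC"
    KEGG = "KEGG"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class LibraryDescriptor:
    """One sequencing library and its position in the factorial design."""

    library_id: str
    genotype: Genotype
    tissue: Tissue
    growth_condition: GrowthCondition
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def material_group(self) -> tuple[Genotype, Tissue, GrowthCondition]:
        """The plant material this library was sequenced from."""
        return (self.genotype, self.tissue, self.growth_condition)


def canonical_design(library_totals: int | None = None) -> list[LibraryDescriptor]:
    """The canonical 16-library design: 8 material groups x 2 replicates."""
    design = []
    for genotype in Genotype:
        for condition in GrowthCondition:
            for tissue in Tissue:
                for replicate in (1, 2):
                    geno = "SP" if genotype is Genotype.HIGH_BNF else "CH"
                    cond = "ST" if condition is GrowthCondition.STALK else "HY"
                    tiss = "R" if tissue is Tissue.ROOT else "S"
                    design.append(
                        LibraryDescriptor(
                            library_id=f"{geno}_{cond}_{tiss}{replicate}",
                            genotype=genotype,
                            tissue=tissue,
                            growth_condition=condition,
                            replicate=replicate,
                        )
                    )
    return design


@dataclass
class CountMatrix:
    """Reads per transcript per library, with lengths and library sizes.

    ``counts`` is an integer DataFrame indexed by transcript id with one
    column per library.  ``lengths`` (bp) is indexed identically.
    ``library_totals`` holds the per-library RPKM denominator; by default the
    column sums of ``counts``, optionally overridden by a sequencing-depth
    side table (totals can exceed column sums when not every read maps).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_totals: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DuplicateKeyError(f"duplicate transcript ids: {dupes}")
        if self.counts.columns.has_duplicates:
            raise DuplicateKeyError("duplicate library ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts in matrix")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise MissingLengthError(f"transcripts missing a length: {missing.tolist()}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any():
            raise FormatError("transcript lengths must be >= 1 bp")
        n_short = int((self.lengths < MIN_RELIABLE_LENGTH).sum())
        if n_short:
            warnings.warn(
                f"{n_short} transcript(s) shorter than {MIN_RELIABLE_LENGTH} bp",
                stacklevel=2,
            )
        self.library_totals = self.library_totals.reindex(self.counts.columns)
        if self.library_totals.isna().any():
            raise FormatError("every library needs a total read count")
        colsums = self.counts.sum(axis=0)
        if (self.library_totals < colsums).any():
            bad = self.library_totals.index[self.library_totals < colsums].tolist()
            raise FormatError(f"library totals below column sums for: {bad}")

    @property
    def transcript_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def library_ids(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass(frozen=True)
class AssemblyStats:
    """Descriptive statistics of an assembled transcript set."""

    n_sequences: int
    total_length: int
    mean_length: float
    n50: int


@dataclass
class AnnotationMap:
    """Transcript -> {(term, namespace)} assignments.

    Unannotated transcripts are simply absent from the mapping.
    """

    assignments: dict[str, set[tuple[str, Namespace]]] = field(default_factory=dict)

    def add(self, transcript_id: str, term_id: str, namespace: Namespace) -> None:
        self.assignments.setdefault(transcript_id, set()).add((term_id, namespace))

    def terms_for(self, transcript_id: str) -> set[tuple[str, Namespace]]:
        return self.assignments.get(transcript_id, set())

    def transcripts_with(self, term_id: str, namespace: Namespace | None = None) -> set[str]:
        return {
            t
            for t, terms in self.assignments.items()
            if any(term == term_id and (namespace is None or ns == namespace) for term, ns in terms)
        }

    def all_terms(self) -> set[tuple[str, Namespace]]:
        out: set[tuple[str, Namespace]] = set()
        for terms in self.assignments.values():
            out |= terms
        return out

    @property
    def annotated_transcripts(self) -> set[str]:
        return set(self.assignments)


# ---------------------------------------------------------------------------
# readers


def _coerce_enum(cls, value: str, column: str):
    try:
        return cls(str(value).strip().upper())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise VocabularyError(
            f"unknown {column} value {value!r}; allowed: {allowed}"
        ) from None


def read_sample_sheet(path: str | Path) -> list[LibraryDescriptor]:
    """Parse a TSV/CSV sample sheet into validated library descriptors."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"library_id", "genotype", "tissue", "growth_condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    descriptors = []
    for _, row in df.iterrows():
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise FormatError(f"non-integer replicate {row['replicate']!r}") from None
        descriptors.append(
            LibraryDescriptor(
                library_id=str(row["library_id"]).strip(),
                genotype=_coerce_enum(Genotype, row["genotype"], "genotype"),
                tissue=_coerce_enum(Tissue, row["tissue"], "tissue"),
                growth_condition=_coerce_enum(
                    GrowthCondition, row["growth_condition"], "growth_condition"
                ),
                replicate=replicate,
            )
        )
    designs = [(d.genotype, d.tissue, d.growth_condition, d.replicate) for d in descriptors]
    if len(set(designs)) != len(designs):
        seen, dupes = set(), []
        for key in designs:
            if key in seen:
                dupes.append(key)
            seen.add(key)
        raise DuplicateDesignError(f"duplicate design cells: {dupes}")
    ids = [d.library_id for d in descriptors]
    if len(set(ids)) != len(ids):
        raise DuplicateKeyError("duplicate library_id in sample sheet")
    return descriptors


def n_material_groups(descriptors: Iterable[LibraryDescriptor]) -> int:
    return len({d.material_group for d in descriptors})


def lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Transcript lengths (bp) from a FASTA file.

    Ids are the header token before the first whitespace.  Sequences shorter
    than 100 bp are kept but counted in a warning, mirroring the assembly
    convention that only transcripts above 100 bp are trusted.
    """
    lengths: dict[str, int] = {}
    n_short = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise DuplicateKeyError(f"duplicate FASTA id: {record.id}")
        length = len(record.seq)
        lengths[record.id] = length
        if length < MIN_RELIABLE_LENGTH:
            n_short += 1
    if not lengths:
        raise EmptyInputError(f"no FASTA records in {path}")
    if n_short:
        warnings.warn(
            f"{n_short} sequence(s) shorter than {MIN_RELIABLE_LENGTH} bp", stacklevel=2
        )
    return lengths


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    """Two-column (transcript_id, length_bp) TSV -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("lengths TSV needs two columns: transcript_id, length_bp")
    first = df.iloc[0]
    if not str(first[1]).strip().lstrip("-").isdigit():  # header row
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DuplicateKeyError(f"duplicate ids in lengths file: {ids[ids.duplicated()].tolist()}")
    try:
        vals = df.iloc[:, 1].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer length in {path}: {exc}") from None
    return dict(zip(ids, vals))


def read_count_matrix(
    counts_path: str | Path,
    lengths_source: str | Path | Mapping[str, int],
    totals_path: str | Path | None = None,
) -> CountMatrix:
    """Read a transcript x library count TSV plus transcript lengths.

    ``lengths_source`` may be a 2-column TSV, a FASTA file, or an in-memory
    mapping.  ``totals_path`` optionally supplies per-library sequencing
    depths (2-column TSV: library_id, total_reads); otherwise library totals
    default to column sums.
    """
    raw = pd.read_csv(counts_path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError("count matrix needs a transcript_id column plus counts")
    ids = raw.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DuplicateKeyError(
            f"duplicate transcript ids: {ids[ids.duplicated()].unique().tolist()}"
        )
    body = raw.iloc[:, 1:]
    counts = pd.DataFrame(index=pd.Index(ids, name="transcript_id"))
    for col in body.columns:
        parsed = pd.to_numeric(body[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round()) | (parsed < 0)
        if bad.any():
            row = ids.iloc[int(np.argmax(bad.to_numpy()))]
            raise FormatError(
                f"non-integer or negative count at transcript {row!r}, library {col!r}"
            )
        counts[col] = parsed.astype(np.int64).to_numpy()

    if isinstance(lengths_source, (str, Path)):
        text = str(lengths_source)
        if text.endswith((".fa", ".fasta", ".fna")):
            length_map = lengths_from_fasta(lengths_source)
        else:
            length_map = read_lengths_tsv(lengths_source)
    else:
        length_map = dict(lengths_source)
    lengths = pd.Series(length_map, dtype=np.int64, name="length_bp")

    if totals_path is not None:
        tdf = pd.read_csv(totals_path, sep="\t", header=None, dtype=str, comment="#")
        if not str(tdf.iloc[0, 1]).strip().isdigit():
            tdf = tdf.iloc[1:]
        totals = pd.Series(
            tdf.iloc[:, 1].astype(np.int64).to_numpy(),
            index=tdf.iloc[:, 0].astype(str),
            name="library_total",
        )
    else:
        totals = counts.sum(axis=0)
    return CountMatrix(counts=counts, lengths=lengths, library_totals=totals)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path, lengths_path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "transcript_id"
    out.to_csv(counts_path, sep="\t")
    lengths = matrix.lengths.rename("length_bp")
    lengths.index.name = "transcript_id"
    lengths.to_csv(lengths_path, sep="\t")


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """3-column TSV (transcript_id, term_id, namespace) -> AnnotationMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "term_id", "namespace"}
    if not required <= set(df.columns):
        raise FormatError(f"annotation map needs columns {sorted(required)}")
    amap = AnnotationMap()
    for row in df.itertuples(index=False):
        amap.add(row.transcript_id, row.term_id, _coerce_enum(Namespace, row.namespace, "namespace"))
    return amap


def read_annotation_gmt(path: str | Path, namespace: Namespace = Namespace.CUSTOM) -> AnnotationMap:
    """GMT-like file: term <tab> description <tab> transcript ids."""
    amap = AnnotationMap()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line needs term, description and >= 1 id: {line!r}")
        term = parts[0]
        for transcript in parts[2:]:
            if transcript:
                amap.add(transcript, term, namespace)
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"transcript_id": t, "term_id": term, "namespace": ns.value}
        for t, terms in sorted(amap.assignments.items())
        for term, ns in sorted(terms)
    ]
    pd.DataFrame(rows, columns=["transcript_id", "term_id", "namespace"]).to_csv(
        path, sep="\t", index=False
    )


BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


def read_blast_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tabular (outfmt 6 dialect) BLAST hit file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise FormatError(f"BLAST table has {df.shape[1]} columns; 12 required")
    if df.shape[1] > 12:
        warnings.warn(
            f"BLAST table has {df.shape[1]} columns; ignoring extras beyond 12",
            stacklevel=2,
        )
        df = df.iloc[:, :12]
    df.columns = BLAST_COLUMNS
    if (df["e_value"] < 0).any():
        raise FormatError("negative e-value in BLAST table")
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise FormatError("percent identity outside [0, 100]")
    return df


def filter_blast_hits(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_identity: float = 70.0,
    best_hit_only: bool = True,
) -> pd.DataFrame:
    """Apply the annotation filter: e-value cutoff, identity floor, best hit.

    Keeps rows with ``e_value <= max_evalue`` and
    ``percent_identity > min_identity``.  With ``best_hit_only`` the single
    best row per query survives: smallest e-value, ties broken by larger bit
    score, residual ties by input order.  Output order is stable by query
    then rank.
    """
    kept = hits[(hits["e_value"] <= max_evalue) & (hits["percent_identity"] > min_identity)]
    if not best_hit_only:
        return kept.reset_index(drop=True)
    kept = kept.reset_index(drop=True)
    if kept.empty:
        return kept
    order = kept.assign(_pos=np.arange(len(kept))).sort_values(
        ["e_value", "bit_score", "_pos"], ascending=[True, False, True], kind="stable"
    )
    best = order.drop_duplicates("query_id", keep="first")
    best = best.sort_values(["query_id", "_pos"], kind="stable").drop(columns="_pos")
    return best.reset_index(drop=True)


def compute_assembly_stats(lengths: Sequence[int] | np.ndarray) -> AssemblyStats:
    """N50 and basic length statistics of an assembly.

    N50 is the length at which the descending cumulative sum of sequence
    lengths first reaches at least half the total assembly length.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise EmptyInputError("cannot summarize an empty assembly")
    if (arr < 1).any():
        raise FormatError("sequence lengths must be >= 1 bp")
    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    cumulative = np.cumsum(desc)
    n50 = int(desc[np.argmax(cumulative >= total / 2)])
    return AssemblyStats(
        n_sequences=int(arr.size),
        total_length=total,
        mean_length=total / arr.size,
        n50=n50,
    )
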
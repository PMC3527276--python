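"""Domain types shared by every stage of the dropout-screen pipeline.

A pooled shRNA screen compares shRNA abundance in an isogenic cell-line pair
(p53+ / p53-) at two timepoints (T0, shortly after transduction; T10, after
ten days of growth).  Each shRNA is identified in sequencing reads by its
21-nt core sequence, bounded by fixed 6-nt vector flanks.  This module holds
the library, sample and count-matrix containers plus the analysis
configuration; it performs no statistics itself.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import pandas as pd

CORE_LENGTH = 21
FLANK_LENGTH = 6
_BASE_RE = re.compile(r"^[ACGT]+$")


class Genotype(enum.Enum):
    """The engineered difference of the isogenic pair."""

    P53_PLUS = "p53plus"
    P53_MINUS = "p53minus"


class Timepoint(enum.Enum):
    """Screen sampling times: T0 is 40 h post-transduction, T10 is day 10."""

    T0 = "T0"
    T10 = "T10"


@dataclass(frozen=True)
class SampleId:
    """One of the screen's four genotype x timepoint samples."""

    genotype: Genotype
    timepoint: Timepoint

    @property
    def column(self) -> str:
        return f"{self.genotype.value}_{self.timepoint.value}"


#: Canonical sample order used in count tables and FASTQ file naming.
SAMPLES: tuple[SampleId, ...] = (
    SampleId(Genotype.P53_PLUS, Timepoint.T0),
    SampleId(Genotype.P53_PLUS, Timepoint.T10),
    SampleId(Genotype.P53_MINUS, Timepoint.T0),
    SampleId(Genotype.P53_MINUS, Timepoint.T10),
)

SAMPLE_COLUMNS: tuple[str, ...] = tuple(s.column for s in SAMPLES)


@dataclass(frozen=True)
class ShRNARecord:
    """A single hairpin: identifier, targeted gene, and 21-nt core sequence."""

    shrna_id: str
    gene_id: str
    core_seq: str

    def __post_init__(self) -> None:
        if not self.shrna_id:
            raise ValueError("shrna_id must be non-empty")
        if not self.gene_id:
            raise ValueError(f"{self.shrna_id}: gene_id must be non-empty")
        if len(self.core_seq) != CORE_LENGTH:
            raise ValueError(
                f"{self.shrna_id}: core_seq length {len(self.core_seq)} != {CORE_LENGTH}"
            )
        if not _BASE_RE.match(self.core_seq):
            raise ValueError(
                f"{self.shrna_id}: core_seq contains characters outside ACGT"
            )


@dataclass
class ShRNALibrary:
    """Ordered reference set of hairpins plus the vector flank anchors.

    Invariants: shrna_ids unique, core sequences unique, flanks exactly 6 nt.
    Record order is preserved through serialization and defines row order in
    every downstream count matrix and result table.
    """

    records: list[ShRNARecord]
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        for name, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(flank) != FLANK_LENGTH or not _BASE_RE.match(flank):
                raise ValueError(f"{name} must be {FLANK_LENGTH} nt over ACGT, got {flank!r}")
        seen_ids: dict[str, int] = {}
        seen_cores: dict[str, int] = {}
        for row, rec in enumerate(self.records, start=1):
            if rec.shrna_id in seen_ids:
                raise ValueError(
                    f"duplicate shrna_id {rec.shrna_id!r} at rows "
                    f"{seen_ids[rec.shrna_id]} and {row}"
                )
            if rec.core_seq in seen_cores:
                raise ValueError(
                    f"duplicate core_seq for {rec.shrna_id!r} at rows "
                    f"{seen_cores[rec.core_seq]} and {row}"
                )
            seen_ids[rec.shrna_id] = row
            seen_cores[rec.core_seq] = row

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ShRNARecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShRNALibrary):
            return NotImplemented
        return (
            self.records == other.records
            and self.flank5 == other.flank5
            and self.flank3 == other.flank3
        )

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def cores(self) -> list[str]:
        return [r.core_seq for r in self.records]

    def gene_of(self) -> dict[str, str]:
        """Map shrna_id -> gene_id."""
        return {r.shrna_id: r.gene_id for r in self.records}


_LIBRARY_COLUMNS = ("shrna_id", "gene_id", "core_seq")


def read_library(
    path: str | Path,
    flank5: str | None = None,
    flank3: str | None = None,
) -> ShRNALibrary:
    """Read a library TSV (columns shrna_id, gene_id, core_seq; header row).

    Flank anchors are taken from ``#flank5``/``#flank3`` comment lines written
    by :func:`write_library`; explicit arguments override them (needed for
    externally produced tables that carry no comment lines).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    records: list[ShRNARecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if tuple(header) != _LIBRARY_COLUMNS:
                    raise ValueError(
                        f"{path}: expected header {list(_LIBRARY_COLUMNS)}, got {header}"
                    )
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                records.append(ShRNARecord(*parts))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if header is None:
        raise ValueError(f"{path}: missing header row")
    f5 = flank5 if flank5 is not None else meta.get("flank5")
    f3 = flank3 if flank3 is not None else meta.get("flank3")
    if f5 is None or f3 is None:
        raise ValueError(
            f"{path}: flank sequences not found in file metadata; "
            "pass flank5= and flank3= explicitly"
        )
    try:
        return ShRNALibrary(records, f5, f3)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_library(library: ShRNALibrary, path: str | Path) -> None:
    """Write a library TSV; flanks go into leading ``#`` metadata lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#flank5\t{library.flank5}\n")
        fh.write(f"#flank3\t{library.flank3}\n")
        fh.write("\t".join(_LIBRARY_COLUMNS) + "\n")
        for rec in library:
            fh.write(f"{rec.shrna_id}\t{rec.gene_id}\t{rec.core_seq}\n")


@dataclass
class CountMatrix:
    """Per-shRNA read counts across the four genotype x timepoint samples.

    ``counts`` is indexed by shrna_id in library order with the four columns
    of :data:`SAMPLE_COLUMNS`; ``gene_ids`` is aligned to the same index.
    """

    counts: pd.DataFrame
    gene_ids: pd.Series

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != SAMPLE_COLUMNS:
            raise ValueError(
                f"count columns must be {list(SAMPLE_COLUMNS)}, got {list(self.counts.columns)}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.gene_ids.index):
            raise ValueError("gene_ids index must match counts index")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate shrna_id in count matrix")
        self.counts = self.counts.astype("int64")

    @property
    def shrna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def totals(self) -> pd.Series:
        """Per-sample assigned-read totals (column sums)."""
        return self.counts.sum(axis=0)

    def sample(self, sample_id: SampleId) -> pd.Series:
        return self.counts[sample_id.column]


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "gene_id", matrix.gene_ids)
    out.index.name = "shrna_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="shrna_id")
    missing = [c for c in ("gene_id", *SAMPLE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return CountMatrix(df[list(SAMPLE_COLUMNS)], df["gene_id"])


@dataclass
class PipelineConfig:
    """Analysis thresholds and matching parameters.

    Defaults are the screen's published decision rule: adjusted p < 0.01 with
    at least four-fold depletion in p53- cells and at most two-fold depletion
    (or non-significance) in p53+ cells; read assignment tolerates up to two
    core mismatches; odds-ratio confidence level 95%.
    """

    min_fold_p53minus: float = 4.0
    max_fold_p53plus: float = 2.0
    alpha_adj: float = 0.01
    ci_level: float = 0.95
    max_mismatch: int = 2
    pseudocount: float = 0.5
    flank_max_mismatch: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.flank_max_mismatch < 0:
            raise ValueError("flank_max_mismatch must be >= 0")
        if self.min_fold_p53minus <= 0 or self.max_fold_p53plus <= 0:
            raise ValueError("fold thresholds must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown analysis config keys: {unknown}")
        cfg = cls(**d)
        cfg.validate()
        return cfg
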
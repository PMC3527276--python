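"""Deconvolution of screen FASTQ reads into per-shRNA counts.

Reads are anchored by the two fixed 6-nt vector flanks: positions 1-6 must
match the 5' flank and positions 28-33 the 3' flank (1-based, inclusive).
The 21-nt core at positions 7-27 is then assigned to the library shRNA with
the unique minimal Hamming distance, up to a configurable mismatch budget
(default 2).  Reads failing the flank check, reads with no library core
within the budget, and reads with a tied best hit are counted separately and
excluded.  There is no genome alignment step: the informative sequence is a
library core, so matching is done directly against the known library.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    CORE_LENGTH,
    FLANK_LENGTH,
    PipelineConfig,
    ShRNALibrary,
)

_READ_LENGTH = 2 * FLANK_LENGTH + CORE_LENGTH  # 33


@dataclass
class ExtractionStats:
    """Read-fate tally for one sample; the four fates partition all reads."""

    n_reads: int = 0
    n_flank_fail: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0
    n_assigned: int = 0

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        parts = self.n_flank_fail + self.n_unassigned + self.n_ambiguous + self.n_assigned
        if self.n_reads != parts:
            raise ValueError(
                f"read fates do not partition: {self.n_reads} != {parts}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_reads": self.n_reads,
            "n_flank_fail": self.n_flank_fail,
            "n_unassigned": self.n_unassigned,
            "n_ambiguous": self.n_ambiguous,
            "n_assigned": self.n_assigned,
        }


class AssignStatus(enum.Enum):
    ASSIGNED = "ASSIGNED"
    UNASSIGNED = "UNASSIGNED"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class Assignment:
    status: AssignStatus
    shrna_id: str | None = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def check_flanks(
    read_seq: str,
    flank5: str,
    flank3: str,
    max_mismatch: int = 0,
) -> bool:
    """True iff both 6-nt flank anchors match at their fixed positions.

    Reads shorter than 33 nt always fail (never raise).  ``max_mismatch``
    relaxes the per-flank match; the default is exact, the strictest reading
    of "reads that did not contain the six bases".
    """
    if len(read_seq) < _READ_LENGTH:
        return False
    got5 = read_seq[:FLANK_LENGTH]
    got3 = read_seq[FLANK_LENGTH + CORE_LENGTH:_READ_LENGTH]
    if max_mismatch == 0:
        return got5 == flank5 and got3 == flank3
    return _hamming(got5, flank5) <= max_mismatch and _hamming(got3, flank3) <= max_mismatch


def extract_core(read_seq: str) -> str:
    """Return the 21-nt core at positions 7-27 (1-based, inclusive).

    Caller must have validated the read with :func:`check_flanks`.
    """
    if len(read_seq) < _READ_LENGTH:
        raise ValueError(
            f"extract_core called on a {len(read_seq)}-nt read; "
            f"reads must be >= {_READ_LENGTH} nt (check_flanks first)"
        )
    return read_seq[FLANK_LENGTH:FLANK_LENGTH + CORE_LENGTH]


class CoreIndex:
    """Assignment index over a library: exact hash plus a dense Hamming scan.

    Exact hits resolve through a dict; everything else is compared to every
    library core (cheap at screen scale, and exactly the specified
    minimum-distance rule rather than a heuristic).
    """

    def __init__(self, library: ShRNALibrary):
        self.ids = np.array(library.shrna_ids)
        self.exact = {rec.core_seq: rec.shrna_id for rec in library}
        self.encoded = np.frombuffer(
            "".join(library.cores).encode("ascii"), dtype=np.uint8
        ).reshape(len(library), CORE_LENGTH)

    def assign(self, core: str, max_mismatch: int) -> Assignment:
        if len(core) != CORE_LENGTH:
            raise ValueError(f"core must be {CORE_LENGTH} nt, got {len(core)}")
        hit = self.exact.get(core)
        if hit is not None:
            return Assignment(AssignStatus.ASSIGNED, hit)
        q = np.frombuffer(core.encode("ascii"), dtype=np.uint8)
        dists = (self.encoded != q).sum(axis=1)
        dmin = int(dists.min())
        if dmin > max_mismatch:
            return Assignment(AssignStatus.UNASSIGNED)
        ties = np.flatnonzero(dists == dmin)
        if len(ties) > 1:
            return Assignment(AssignStatus.AMBIGUOUS)
        return Assignment(AssignStatus.ASSIGNED, str(self.ids[ties[0]]))

    def assign_many(self, cores: list[str], max_mismatch: int) -> list[Assignment]:
        """Batch assignment; non-exact cores are scanned in one vector pass."""
        out: list[Assignment | None] = [None] * len(cores)
        pending: list[int] = []
        for i, core in enumerate(cores):
            hit = self.exact.get(core)
            if hit is not None:
                out[i] = Assignment(AssignStatus.ASSIGNED, hit)
            else:
                pending.append(i)
        if pending:
            q = np.frombuffer(
                "".join(cores[i] for i in pending).encode("ascii"), dtype=np.uint8
            ).reshape(len(pending), CORE_LENGTH)
            for start in range(0, len(pending), 2048):
                chunk = q[start:start + 2048]
                d = (chunk[:, None, :] != self.encoded[None, :, :]).sum(axis=2)
                dmin = d.min(axis=1)
                n_at_min = (d == dmin[:, None]).sum(axis=1)
                argmin = d.argmin(axis=1)
                for j in range(chunk.shape[0]):
                    i = pending[start + j]
                    if dmin[j] > max_mismatch:
                        out[i] = Assignment(AssignStatus.UNASSIGNED)
                    elif n_at_min[j] > 1:
                        out[i] = Assignment(AssignStatus.AMBIGUOUS)
                    else:
                        out[i] = Assignment(
                            AssignStatus.ASSIGNED, str(self.ids[argmin[j]])
                        )
        return out  # type: ignore[return-value]


def _index_for(library: ShRNALibrary) -> CoreIndex:
    idx = getattr(library, "_core_index", None)
    if idx is None:
        idx = CoreIndex(library)
        library._core_index = idx  # cache on the library instance
    return idx


def assign_shrna(core: str, library: ShRNALibrary, max_mismatch: int) -> Assignment:
    """Assign one 21-nt core to the library by unique minimal Hamming distance."""
    return _index_for(library).assign(core, max_mismatch)


def count_fastq(
    path: str | Path,
    library: ShRNALibrary,
    config: PipelineConfig,
) -> tuple[pd.Series, ExtractionStats]:
    """Count assigned reads per shRNA for one sample FASTQ.

    Identical cores are deduplicated before distance computation, so the
    result is independent of read order by construction.  Raises with the
    offending record number on malformed FASTQ.
    """
    config.validate()
    index = _index_for(library)
    core_tally: Counter[str] = Counter()
    n_reads = 0
    n_flank_fail = 0
    path = Path(path)
    with path.open(encoding="ascii") as fh:
        iterator = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {n_reads + 1}: {exc}") from exc
            n_reads += 1
            seq = seq.upper()
            if not check_flanks(seq, library.flank5, library.flank3, config.flank_max_mismatch):
                n_flank_fail += 1
                continue
            core_tally[extract_core(seq)] += 1

    unique_cores = list(core_tally)
    assignments = index.assign_many(unique_cores, config.max_mismatch)
    counts = pd.Series(0, index=pd.Index(library.shrna_ids, name="shrna_id"), dtype="int64")
    n_unassigned = 0
    n_ambiguous = 0
    n_assigned = 0
    for core, assignment in zip(unique_cores, assignments):
        k = core_tally[core]
        if assignment.status is AssignStatus.ASSIGNED:
            counts[assignment.shrna_id] += k
            n_assigned += k
        elif assignment.status is AssignStatus.AMBIGUOUS:
            n_ambiguous += k
        else:
            n_unassigned += k
    stats = ExtractionStats(
        n_reads=n_reads,
        n_flank_fail=n_flank_fail,
        n_unassigned=n_unassigned,
        n_ambiguous=n_ambiguous,
        n_assigned=n_assigned,
    )
    return counts, stats


def write_stats(stats: ExtractionStats, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("metric\tvalue\n")
        for key, value in stats.as_dict().items():
            fh.write(f"{key}\t{value}\n")
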
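"""Generative model of a pooled shRNA dropout screen in an isogenic pair.

The simulator reproduces the screen's mechanics at desk scale: a library of
21-nt cores with ~log-normal initial representation is transduced into p53+
and p53- populations, cells grow exponentially with genotype-specific fitness
penalties for a minority of shRNAs, cultures are bottlenecked by 4-fold
dilution passages, and each of the four samples (genotype x T0/T10) is
sequenced as a multinomial draw of fixed depth.  Reads are emitted with the
fixed layout flank5(6) + core(21) + flank3(6) and optional per-base
substitution noise, so the extraction and statistics stages can be tested
against known ground truth.

Expectation mode skips every sampling step and returns rounded expected
counts, which makes closed-form checks (e.g. a fold depletion of exactly
2**(r*s*dt)) possible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CORE_LENGTH,
    FLANK_LENGTH,
    SAMPLES,
    CountMatrix,
    Genotype,
    SampleId,
    ShRNALibrary,
    ShRNARecord,
    Timepoint,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Minimum pairwise Hamming distance between simulated cores.  With up-to-2
#: mismatch assignment, distance >= 5 guarantees a unique best hit for any
#: read with <= 2 core errors.
MIN_CORE_DISTANCE = 5


class ShRNAClass(enum.Enum):
    NEUTRAL = "NEUTRAL"
    SYNTHETIC_P53MINUS = "SYNTHETIC_P53MINUS"
    ESSENTIAL_BOTH = "ESSENTIAL_BOTH"


@dataclass
class SimConfig:
    """Study conditions of the simulated screen.

    Defaults mirror the screen protocol: MOI 1 with 75% transduction of 1e6
    plated cells, T0 harvested 40 h post-transduction, T10 at day 10, and
    4-fold dilution passaging (modelled on days 3, 6 and 9, keeping 25% of
    cells).  ``effect_size_s`` is the fractional growth-rate reduction of an
    affected shRNA; ``abundance_sigma`` the log-normal spread of initial
    library representation.  ``overdispersion`` > 0 switches sequencing from
    multinomial to Dirichlet-multinomial (PCR jackpotting); default off.
    """

    n_genes: int = 200
    shrnas_per_gene: int = 2
    n_cells0: int = 1_000_000
    moi: float = 1.0
    transduced_fraction: float = 0.75
    doublings_per_day: float = 1.0
    t0_hours: float = 40.0
    t_final_days: float = 10.0
    passage_days: tuple[float, ...] = (3.0, 6.0, 9.0)
    passage_keep_fraction: float = 0.25
    depth_per_sample: int = 200_000
    abundance_sigma: float = 0.5
    error_rate: float = 0.0
    fraction_synthetic: float = 0.05
    fraction_essential_both: float = 0.05
    effect_size_s: float = 0.8
    overdispersion: float = 0.0
    expectation_mode: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.shrnas_per_gene < 1:
            raise ValueError("n_genes and shrnas_per_gene must be >= 1")
        if self.fraction_synthetic + self.fraction_essential_both > 1:
            raise ValueError(
                "fraction_synthetic + fraction_essential_both must be <= 1"
            )
        if not 0 <= self.effect_size_s <= 1:
            raise ValueError("effect_size_s must be in [0, 1]")
        if self.t0_hours / 24.0 >= self.t_final_days:
            raise ValueError("T0 must fall before t_final_days")
        if not 0 < self.passage_keep_fraction <= 1:
            raise ValueError("passage_keep_fraction must be in (0, 1]")
        if self.depth_per_sample < 1:
            raise ValueError("depth_per_sample must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.abundance_sigma < 0 or self.overdispersion < 0:
            raise ValueError("abundance_sigma and overdispersion must be >= 0")
        if self.doublings_per_day <= 0:
            raise ValueError("doublings_per_day must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown simulate config keys: {unknown}")
        d = dict(d)
        if "passage_days" in d:
            d["passage_days"] = tuple(float(x) for x in d["passage_days"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SimTruth:
    """Ground-truth fitness effects: one row per shRNA.

    Columns: shrna_id, gene_id, class, s_plus, s_minus.  All shRNAs of a gene
    share a class; NEUTRAL means s=0 in both genotypes, SYNTHETIC_P53MINUS a
    penalty only in p53-, ESSENTIAL_BOTH the same penalty in both.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["shrna_id", "gene_id", "class", "s_plus", "s_minus"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"truth table missing columns {missing}")
        self.table = self.table.set_index("shrna_id") if self.table.index.name != "shrna_id" else self.table

    def s_for(self, genotype: Genotype) -> np.ndarray:
        col = "s_plus" if genotype is Genotype.P53_PLUS else "s_minus"
        return self.table[col].to_numpy(dtype=float)

    def classes(self) -> pd.Series:
        return self.table["class"]

    def gene_classes(self) -> pd.Series:
        """Per-gene class (all shRNAs of a gene share one)."""
        return self.table.groupby("gene_id")["class"].first()


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", lineterminator="\n")


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    return SimTruth(df)


def _random_cores(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unique 21-nt cores with pairwise Hamming distance >= 5.

    Random 21-mers are almost never this close, so rejection sampling is
    cheap; the attempt budget guards against pathological sizes.
    """
    budget = 200 * n + 1000
    chosen = np.empty((n, CORE_LENGTH), dtype=np.uint8)
    k = 0
    attempts = 0
    while k < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not place {n} cores at pairwise Hamming >= "
                f"{MIN_CORE_DISTANCE} within {budget} attempts; "
                "use fewer shRNAs"
            )
        cand = _BASES[rng.integers(0, 4, size=CORE_LENGTH)]
        if k and int((chosen[:k] != cand).sum(axis=1).min()) < MIN_CORE_DISTANCE:
            continue
        chosen[k] = cand
        k += 1
    return chosen


def make_library(config: SimConfig, rng: np.random.Generator) -> tuple[ShRNALibrary, SimTruth]:
    """Build a random screen library and its ground-truth labels.

    Gene classes are independent draws (synthetic / essential-both /
    neutral with the configured fractions), so planted-gene counts are
    binomial around ``fraction * n_genes``.  Flank anchors are drawn once.
    """
    config.validate()
    n = config.n_genes * config.shrnas_per_gene
    cores = _random_cores(n, rng)
    flank5 = bytes(_BASES[rng.integers(0, 4, size=FLANK_LENGTH)]).decode()
    flank3 = bytes(_BASES[rng.integers(0, 4, size=FLANK_LENGTH)]).decode()

    u = rng.random(config.n_genes)
    gene_class = np.where(
        u < config.fraction_synthetic,
        ShRNAClass.SYNTHETIC_P53MINUS.value,
        np.where(
            u < config.fraction_synthetic + config.fraction_essential_both,
            ShRNAClass.ESSENTIAL_BOTH.value,
            ShRNAClass.NEUTRAL.value,
        ),
    )

    records: list[ShRNARecord] = []
    rows: list[dict] = []
    width = max(4, len(str(config.n_genes)))
    k = 0
    for g in range(config.n_genes):
        gene_id = f"GENE{g:0{width}d}"
        cls = gene_class[g]
        s = config.effect_size_s
        s_plus = s if cls == ShRNAClass.ESSENTIAL_BOTH.value else 0.0
        s_minus = s if cls != ShRNAClass.NEUTRAL.value else 0.0
        for j in range(config.shrnas_per_gene):
            shrna_id = f"sh{g:0{width}d}.{j + 1}"
            records.append(ShRNARecord(shrna_id, gene_id, bytes(cores[k]).decode()))
            rows.append(
                {
                    "shrna_id": shrna_id,
                    "gene_id": gene_id,
                    "class": cls,
                    "s_plus": s_plus,
                    "s_minus": s_minus,
                }
            )
            k += 1
    library = ShRNALibrary(records, flank5, flank3)
    truth = SimTruth(pd.DataFrame(rows))
    return library, truth


def _n_passages_before(t_days: float, passage_days: tuple[float, ...]) -> int:
    return sum(1 for d in passage_days if d < t_days)


def expected_frequencies(
    truth: SimTruth, config: SimConfig, genotype: Genotype, t_days: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Exact expected shRNA frequencies at time ``t_days`` for one genotype.

    Each shRNA grows as w_i * 2**(r * (1 - s_i) * t); passage dilutions scale
    every shRNA equally and cancel on normalization.  ``weights`` defaults to
    equal initial representation (the log-normal draw is a sampling step and
    belongs to the callers that want it).
    """
    s = truth.s_for(genotype)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    log2_ab = np.log2(w) + config.doublings_per_day * (1.0 - s) * t_days
    log2_ab -= log2_ab.max()  # stabilise before exponentiating
    ab = np.exp2(log2_ab)
    total = ab.sum()
    if total <= 0:
        raise ValueError(f"zero total abundance in {genotype.value} at t={t_days}")
    return ab / total


def _sequence_sample(
    freqs: np.ndarray, depth: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.overdispersion > 0:
        alpha = freqs / config.overdispersion
        freqs = rng.dirichlet(np.where(alpha > 0, alpha, 1e-12))
    return rng.multinomial(depth, freqs)


def simulate_counts(
    library: ShRNALibrary,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Simulate the 4-sample count matrix.

    Stochastic mode draws initial cells per shRNA from a multinomial over
    log-normal weights, grows them deterministically in expectation between
    events, applies binomial thinning at each passage, and sequences each
    timepoint as a multinomial of ``depth_per_sample``.  Expectation mode
    replaces every draw by its expectation and rounds only at the end, so
    column sums match the depth within library-size rounding.
    """
    config.validate()
    n = len(library)
    if truth.table.shape[0] != n:
        raise ValueError("truth table does not cover the library")
    t0 = config.t0_hours / 24.0
    t10 = config.t_final_days

    if config.expectation_mode:
        data = {}
        for sid in SAMPLES:
            t = t0 if sid.timepoint is Timepoint.T0 else t10
            freqs = expected_frequencies(truth, config, sid.genotype, t)
            data[sid.column] = np.rint(config.depth_per_sample * freqs).astype("int64")
        counts = pd.DataFrame(data, index=pd.Index(library.shrna_ids, name="shrna_id"))
        return CountMatrix(counts, pd.Series(library.gene_ids, index=counts.index, name="gene_id"))

    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    n_transduced = int(round(config.n_cells0 * config.transduced_fraction))
    data = {}
    for genotype in (Genotype.P53_PLUS, Genotype.P53_MINUS):
        s = truth.s_for(genotype)
        growth = config.doublings_per_day * (1.0 - s)  # doublings/day per shRNA
        cells = rng.multinomial(n_transduced, weights / weights.sum()).astype(float)
        events = sorted(
            [(t0, "T0"), (t10, "T10")] + [(d, "passage") for d in config.passage_days if d < t10]
        )
        t_prev = 0.0
        for t_ev, kind in events:
            cells = cells * np.exp2(growth * (t_ev - t_prev))
            t_prev = t_ev
            if kind == "passage":
                cells = rng.binomial(
                    np.rint(cells).astype(np.int64), config.passage_keep_fraction
                ).astype(float)
            else:
                total = cells.sum()
                if total <= 0:
                    raise ValueError(f"zero total abundance in {genotype.value} at t={t_ev}")
                tp = Timepoint.T0 if kind == "T0" else Timepoint.T10
                col = SampleId(genotype, tp).column
                data[col] = _sequence_sample(
                    cells / total, config.depth_per_sample, config, rng
                )
    counts = pd.DataFrame(
        {sid.column: data[sid.column] for sid in SAMPLES},
        index=pd.Index(library.shrna_ids, name="shrna_id"),
    )
    return CountMatrix(counts, pd.Series(library.gene_ids, index=counts.index, name="gene_id"))


def emit_fastq(
    sample_counts: pd.Series,
    library: ShRNALibrary,
    config: SimConfig,
    rng: np.random.Generator,
    path: str | Path,
    sample_name: str = "sample",
) -> None:
    """Write one FASTQ record per counted molecule.

    Read layout (1-based): positions 1-6 flank5, 7-27 core, 28-33 flank3.
    Each base is substituted independently with probability ``error_rate``
    (substitutions are uniform over the three other bases).  Quality is a
    constant 'I' line; the pipeline never reads it.
    """
    counts = sample_counts.reindex(library.shrna_ids).fillna(0).astype(int).to_numpy()
    read_len = 2 * FLANK_LENGTH + CORE_LENGTH
    templates = np.empty((len(library), read_len), dtype=np.uint8)
    f5 = np.frombuffer(library.flank5.encode(), dtype=np.uint8)
    f3 = np.frombuffer(library.flank3.encode(), dtype=np.uint8)
    for i, rec in enumerate(library):
        templates[i, :FLANK_LENGTH] = f5
        templates[i, FLANK_LENGTH:FLANK_LENGTH + CORE_LENGTH] = np.frombuffer(
            rec.core_seq.encode(), dtype=np.uint8
        )
        templates[i, FLANK_LENGTH + CORE_LENGTH:] = f3

    reads = np.repeat(templates, counts, axis=0)
    n_reads = reads.shape[0]
    if config.error_rate > 0 and n_reads:
        mask = rng.random(reads.shape) < config.error_rate
        idx = np.searchsorted(_BASES, reads[mask])
        shift = rng.integers(1, 4, size=idx.shape)
        reads[mask] = _BASES[(idx + shift) % 4]

    qual = "I" * read_len
    path = Path(path)
    with path.open("w", encoding="ascii", newline="\n") as fh:
        for i in range(n_reads):
            fh.write(f"@{sample_name}.{i + 1}\n")
            fh.write(bytes(reads[i]).decode("ascii"))
            fh.write(f"\n+\n{qual}\n")
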
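"""Synthetic inputs with the statistical structure the analyses assume.

Everything the pipeline consumes can be fabricated here with ground
truth attached: a diploid genome with SNV-only heterozygosity (shared
coordinates between haplotypes make k-mer and variant truth exact),
uniform paired-end reads carrying the five QC violation classes at
configured rates, a pair of diverged circular mitochondrial genomes
sequenced at an unequal copy ratio, a core-gene match table, and a
pair of GO count tables with planted enrichment.

Every simulator is deterministic for a fixed seed.  The read simulator
enforces *label soundness* both ways: a read labelled with a violation
class verifiably trips exactly that QC rule, and an unlabelled read
trips none (spurious violations are rejection-sampled away), so the
planted label set is exactly the set a correct filter must drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import readqc
from .enrichment import GoCountTable
from .readqc import QCConfig, ReadPair, revcomp

__all__ = [
    "DiploidGenome",
    "ReadSimConfig",
    "PlantedLabels",
    "simulate_diploid_genome",
    "simulate_reads",
    "sample_uniform_reads",
    "reads_for_kmer_coverage",
    "simulate_mito_pair",
    "simulate_ceg_table",
    "simulate_go_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
VIOLATION_CLASSES = ("N", "polyA", "lowQ", "adapter", "overlap")


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class DiploidGenome:
    hap_a: str
    hap_b: str
    variant_positions: np.ndarray
    het_rate: float
    seed: int

    @property
    def length(self) -> int:
        return len(self.hap_a)


def simulate_diploid_genome(length: int, het_rate: float, seed: int) -> DiploidGenome:
    """Two haplotypes of equal length differing only by SNVs.

    Bases are uniform; heterozygous sites are Bernoulli(het_rate) per
    position and the alternate allele is uniform over the three
    non-reference bases.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= het_rate < 0.5:
        raise ValueError("het_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=length, dtype=np.uint8)
    if het_rate > 0:
        positions = np.flatnonzero(rng.random(length) < het_rate)
    else:
        positions = np.empty(0, dtype=np.int64)
    b = a.copy()
    if positions.size:
        b[positions] = (a[positions] + rng.integers(1, 4, size=positions.size)) % 4
    return DiploidGenome(
        hap_a=_decode(a),
        hap_b=_decode(b),
        variant_positions=positions,
        het_rate=het_rate,
        seed=seed,
    )


@dataclass
class ReadSimConfig:
    depth: float = 30.0  # fold base coverage over one haplotype length
    read_length: int = 100
    insert_sizes: tuple[int, ...] = (180, 500, 800)
    error_rate: float = 0.0
    adapter_sequence: str = readqc.DEFAULT_ADAPTER
    violation_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        for cls, r in self.violation_rates.items():
            if cls not in VIOLATION_CLASSES:
                raise ValueError(f"unknown violation class {cls!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {cls!r} must be in [0, 1]")
        if sum(self.violation_rates.values()) > 1.0:
            raise ValueError("violation rates sum to more than 1")


@dataclass
class PlantedLabels:
    violations: dict[str, frozenset[str]] = field(default_factory=dict)
    mito_sources: dict[str, str] = field(default_factory=dict)
    read_origins: dict[str, tuple[int, bool]] = field(default_factory=dict)
    snv_alleles: dict[int, tuple[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# uniform single-end reads (k-mer work)


def sample_uniform_reads(
    genome: DiploidGenome,
    n_reads: int,
    *,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[str]:
    """Single-end reads drawn uniformly from both haplotypes and strands."""
    L = genome.length
    if read_length > L:
        raise ValueError("read_length exceeds haplotype length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    haps = rng.integers(0, 2, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    sources = (genome.hap_a, genome.hap_b)
    reads = []
    for s, h, st in zip(starts, haps, strands):
        seq = sources[h][s : s + read_length]
        if st:
            seq = revcomp(seq)
        reads.append(seq)
    if error_rate > 0:
        n_err = rng.binomial(read_length, error_rate, size=n_reads)
        for i in np.flatnonzero(n_err):
            chars = list(reads[i])
            for p in rng.choice(read_length, size=n_err[i], replace=False):
                chars[p] = "ACGT"[(("ACGT".index(chars[p])) + rng.integers(1, 4)) % 4]
            reads[i] = "".join(chars)
    return reads


def reads_for_kmer_coverage(
    genome: DiploidGenome,
    kmer_coverage: float,
    k: int,
    *,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[str]:
    """Enough uniform reads for a target total k-mer coverage.

    The number of reads is chosen so that the total k-mer count (both
    haplotypes pooled) equals ``kmer_coverage`` times the haplotype
    length; homozygous k-mers then peak at ``kmer_coverage`` and
    heterozygous ones at half that.
    """
    windows_per_read = read_length - k + 1
    if windows_per_read <= 0:
        raise ValueError("read_length must exceed k")
    n_reads = math.ceil(kmer_coverage * genome.length / windows_per_read)
    return sample_uniform_reads(
        genome, n_reads, read_length=read_length, seed=seed, error_rate=error_rate
    )


# ---------------------------------------------------------------------------
# paired-end reads with planted QC violations


def _plant_n(seq: str, qual: np.ndarray, config: QCConfig, rng) -> tuple[str, np.ndarray]:
    rl = len(seq)
    n_n = int(config.max_n_fraction * rl) + 1 + int(rng.integers(0, 5))
    pos = rng.choice(rl, size=min(n_n, rl), replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = "N"
    return "".join(chars), qual


def _plant_polya(seq: str, qual: np.ndarray, config: QCConfig, rng) -> tuple[str, np.ndarray]:
    # tail long enough that the whole-read A fraction reaches the QC cutoff
    rl = len(seq)
    tail = min(rl, int(math.ceil(config.polya_min_fraction * rl)) + 2)
    return seq[: rl - tail] + "A" * tail, qual


def _plant_lowq(seq: str, qual: np.ndarray, config: QCConfig, rng) -> tuple[str, np.ndarray]:
    rl = len(seq)
    n_low = config.lowq_max_count + int(rng.integers(0, 6))
    pos = rng.choice(rl, size=min(n_low, rl), replace=False)
    qual = qual.copy()
    qual[pos] = rng.integers(0, config.lowq_phred_threshold + 1, size=pos.size)
    return seq, qual


def _plant_adapter(seq: str, qual: np.ndarray, config: QCConfig, rng) -> tuple[str, np.ndarray]:
    rl = len(seq)
    m = min(len(config.adapter_sequence), max(config.adapter_min_match + 9, 20), rl)
    return seq[: rl - m] + config.adapter_sequence[:m], qual


_PLANTERS = {"N": _plant_n, "polyA": _plant_polya, "lowQ": _plant_lowq, "adapter": _plant_adapter}


def _jittered_quals(rl: int, rng) -> np.ndarray:
    return rng.integers(33, 38, size=rl)  # Q35 +- small jitter


def _inject_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    chars = list(seq)
    for p in rng.choice(len(seq), size=n, replace=False):
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def simulate_reads(
    genome: DiploidGenome, config: ReadSimConfig
) -> tuple[list[ReadPair], PlantedLabels]:
    """Paired-end reads from both haplotypes with planted QC violations.

    Each pair carries at most one planted violation class, drawn with
    the configured rates, so labels are disjoint by construction.
    Clean pairs are drawn only from insert sizes long enough that the
    mates cannot overlap; overlap violations use a short fragment
    (1.5 read lengths) so the mates genuinely read into each other.
    Candidate pairs that would trip any rule other than their planted
    one are redrawn, so the label set is exactly the QC-droppable set.
    """
    rng = np.random.default_rng(config.seed)
    qc = QCConfig(adapter_sequence=config.adapter_sequence)
    L, rl = genome.length, config.read_length
    n_pairs = max(1, round(config.depth * L / (2 * rl)))

    clean_inserts = [i for i in config.insert_sizes if i >= 2 * rl + qc.overlap_min]
    if not clean_inserts:
        clean_inserts = [2 * rl + qc.overlap_min + 20]
    overlap_insert = max(rl, int(1.5 * rl))
    if max(clean_inserts) > L or overlap_insert > L:
        raise ValueError("insert size exceeds haplotype length")

    classes = list(VIOLATION_CLASSES)
    probs = np.array([config.violation_rates.get(c, 0.0) for c in classes])
    probs = np.append(probs, 1.0 - probs.sum())
    draws = rng.choice(len(classes) + 1, size=n_pairs, p=probs)

    sources = (genome.hap_a, genome.hap_b)
    pairs: list[ReadPair] = []
    labels = PlantedLabels()
    for i in range(n_pairs):
        planted = classes[draws[i]] if draws[i] < len(classes) else None
        pid = f"pair{i:07d}"
        for _attempt in range(100):
            insert = (
                overlap_insert
                if planted == "overlap"
                else int(clean_inserts[rng.integers(0, len(clean_inserts))])
            )
            hap = sources[rng.integers(0, 2)]
            start = int(rng.integers(0, L - insert + 1))
            frag = hap[start : start + insert]
            seq1 = _inject_errors(frag[:rl], config.error_rate, rng)
            seq2 = _inject_errors(revcomp(frag[-rl:]), config.error_rate, rng)
            qual1, qual2 = _jittered_quals(rl, rng), _jittered_quals(rl, rng)
            if planted in _PLANTERS:
                if rng.integers(0, 2):
                    seq2, qual2 = _PLANTERS[planted](seq2, qual2, qc, rng)
                else:
                    seq1, qual1 = _PLANTERS[planted](seq1, qual1, qc, rng)
            pair = ReadPair(id=pid, seq1=seq1, seq2=seq2, qual1=qual1, qual2=qual2)
            if readqc.first_failing_rule(pair, qc) == planted:
                break
        else:  # pragma: no cover - would need an adversarial adapter/genome
            raise RuntimeError(f"could not realise planted class {planted!r} for {pid}")
        pairs.append(pair)
        if planted is not None:
            labels.violations[pid] = frozenset({planted})
    return pairs, labels


# ---------------------------------------------------------------------------
# mitochondrial pair


def simulate_mito_pair(
    length: int,
    divergence: float,
    copy_ratio: float,
    depth_f: float,
    seed: int,
    *,
    read_length: int = 100,
    error_rate: float = 0.0,
) -> tuple[str, str, list[tuple[str, str]], PlantedLabels]:
    """Two diverged circular genomes sequenced at an unequal copy ratio.

    The second (M-like) sequence derives from the first (F-like) by
    SNVs at exactly ``round(divergence * length)`` sites.  Reads of
    ``read_length`` start uniformly anywhere on each circle (wrapping
    the origin); the M genome is sampled at ``depth_f / copy_ratio``.
    Returns ``(seq_f, seq_m, reads, labels)`` where reads are
    ``(read_id, sequence)`` and labels record per-read source genome,
    origin, and the planted SNV alleles.
    """
    if length <= read_length:
        raise ValueError("length must exceed read_length")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    if copy_ratio <= 0:
        raise ValueError("copy_ratio must be positive")
    if depth_f < 0:
        raise ValueError("depth_f must be >= 0")
    rng = np.random.default_rng(seed)
    f_codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    n_div = round(divergence * length)
    div_pos = np.sort(rng.choice(length, size=n_div, replace=False))
    m_codes = f_codes.copy()
    m_codes[div_pos] = (f_codes[div_pos] + rng.integers(1, 4, size=n_div)) % 4
    seq_f, seq_m = _decode(f_codes), _decode(m_codes)

    labels = PlantedLabels(
        snv_alleles={int(p): (seq_f[p], seq_m[p]) for p in div_pos}
    )
    reads: list[tuple[str, str]] = []

    def draw(seq: str, depth: float, tag: str) -> None:
        n = round(depth * length / read_length)
        if n <= 0:
            return
        doubled = seq + seq
        starts = rng.integers(0, length, size=n)
        strands = rng.integers(0, 2, size=n)
        for j, (s, st) in enumerate(zip(starts, strands)):
            rseq = doubled[s : s + read_length]
            if st:
                rseq = revcomp(rseq)
            rseq = _inject_errors(rseq, error_rate, rng)
            rid = f"mt{tag}_{j:06d}"
            reads.append((rid, rseq))
            labels.mito_sources[rid] = tag
            labels.read_origins[rid] = (int(s), bool(st))

    draw(seq_f, depth_f, "F")
    draw(seq_m, depth_f / copy_ratio, "M")
    return seq_f, seq_m, reads, labels


# ---------------------------------------------------------------------------
# tabular fixtures


def simulate_ceg_table(
    n_total: int, n_complete: int, n_partial_only: int, seed: int
):
    """Core-gene match table: aligned fraction per recovered protein.

    Complete entries draw their aligned fraction in (0.90, 1.0],
    partial-only entries in (0, 0.90]; the remaining proteins are
    absent from the table.  Returns a pandas DataFrame with columns
    ``protein_id, aligned_fraction, significant``.
    """
    import pandas as pd

    if min(n_total, n_complete, n_partial_only) < 0:
        raise ValueError("counts must be non-negative")
    if n_complete + n_partial_only > n_total:
        raise ValueError("complete + partial exceeds total")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_complete):
        rows.append(("KOG%04d" % i, 1.0 - 0.1 * rng.random(), True))  # (0.9, 1.0]
    for i in range(n_partial_only):
        rows.append(("KOG%04d" % (n_complete + i), 0.9 - 0.9 * rng.random(), True))  # (0, 0.9]
    return pd.DataFrame(rows, columns=["protein_id", "aligned_fraction", "significant"])


def simulate_go_tables(
    n_terms: int,
    background_total_a: int,
    background_total_b: int,
    enriched_terms: dict[str, float] | dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[GoCountTable, GoCountTable, set[str]]:
    """Two per-term GO count tables, optionally with planted enrichment.

    Each term's base annotation proportion is drawn uniformly in
    [0.002, 0.02]; counts are Binomial(total, p) in both tables, with
    the proportion multiplied by the configured fold in table A for
    enriched terms.  Returns ``(table_a, table_b, truth)`` where truth
    is the set of term ids planted as enriched.
    """
    if n_terms <= 0:
        raise ValueError("need at least one GO term")
    enriched_terms = enriched_terms or {}
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    folds = {}
    for key, fold in enriched_terms.items():
        if fold <= 0:
            raise ValueError("fold must be positive")
        term = terms[key] if isinstance(key, int) else key
        folds[term] = fold
    base = rng.uniform(0.002, 0.02, size=n_terms)
    counts_a, counts_b = {}, {}
    for t, p in zip(terms, base):
        pa = min(1.0, p * folds.get(t, 1.0))
        counts_a[t] = int(rng.binomial(background_total_a, pa))
        counts_b[t] = int(rng.binomial(background_total_b, p))
    return (
        GoCountTable(label="A", total=background_total_a, counts=counts_a),
        GoCountTable(label="B", total=background_total_b, counts=counts_b),
        set(folds),
    )
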
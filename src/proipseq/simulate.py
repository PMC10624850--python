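"""Ground-truthed synthetic PRO-IP-seq experiments.

The generator emulates the statistical structure the downstream analysis
assumes: each gene initiates at a single transcription start nucleotide
(TSN) that sits a variable distance downstream of its annotated TSS;
engaged polymerase accumulates at a promoter-proximal pause drawn from a
two-component positional mixture (early pause +1..+30, late pause
+31..+60 nt from the TSN, 1-based); the remaining signal distributes
over the gene body and a termination window past the CPS, in
CTD-state-dependent proportions; a configurable fraction of reads is
uniform background noise and another fraction originates from a foreign
spike-in genome. Optionally, reads are emitted as FASTQ with the inline
3'-barcode / 5'-UMI adapter architecture and PCR duplicates.

Every molecule carries one 5'-end (at the gene's TSN, with small jitter)
and one 3'-end (the active site). Aligned records are emitted one per
molecule; PCR duplication applies only to the FASTQ path, where
duplicates share UMI and sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genes import GeneModel
from .readproc import ADAPTER_READ1, ReadRecord, revcomp
from .tracks import BED6_COLUMNS

ANTIBODIES = ("unPh", "Ser2Ph", "Ser5Ph", "Ser7Ph")

#: default (pause, body, termination) weight of each CTD state: the
#: unphosphorylated CTD is pause-dominant, Ser2P marks productive
#: elongation and termination, Ser5P/Ser7P are intermediate.
DEFAULT_CTD_WEIGHTS = {
    "unPh": (0.70, 0.25, 0.05),
    "Ser2Ph": (0.30, 0.50, 0.20),
    "Ser5Ph": (0.50, 0.45, 0.05),
    "Ser7Ph": (0.45, 0.45, 0.10),
}

PRIMARY_CHROM = "chrSim1"
SPIKE_CHROM = "chrSpk1"


@dataclass
class PauseMixture:
    """Two-component positional mixture for the dominant pause offset.

    Offsets are 1-based nt from the TSN (+1 = TSN). Components are
    discretized truncated normals over the early (+1..+30) and late
    (+31..+60) windows; the early component peaks at +25, where
    unphosphorylated polymerase is maximally enriched.
    """

    weight_early: float = 0.6
    weight_late: float = 0.4
    early_mean: float = 25.0
    early_sd: float = 3.0
    late_mean: float = 45.0
    late_sd: float = 6.0

    def __post_init__(self) -> None:
        if not np.isclose(self.weight_early + self.weight_late, 1.0):
            raise ValueError("pause mixture weights must sum to 1")
        if min(self.weight_early, self.weight_late) < 0:
            raise ValueError("pause mixture weights must be non-negative")

    def component_pmf(self, component: str) -> tuple[np.ndarray, np.ndarray]:
        if component == "early":
            offsets = np.arange(1, 31)
            mean, sd = self.early_mean, self.early_sd
        elif component == "late":
            offsets = np.arange(31, 61)
            mean, sd = self.late_mean, self.late_sd
        else:
            raise ValueError(f"unknown pause component {component!r}")
        w = np.exp(-0.5 * ((offsets - mean) / sd) ** 2)
        return offsets, w / w.sum()

    def mixture_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        off_e, p_e = self.component_pmf("early")
        off_l, p_l = self.component_pmf("late")
        return (
            np.concatenate([off_e, off_l]),
            np.concatenate([self.weight_early * p_e, self.weight_late * p_l]),
        )


@dataclass
class SimConfig:
    """Study conditions of a simulated experiment.

    Defaults mirror the assay design: ~0.5% spike-in chromatin, a
    TSN placed a median 55 nt downstream of the annotated TSS, and a
    handful of >150 kb genes whose far ends anchor the between-condition
    normalization factor.
    """

    n_genes: int = 200
    genome_length: int = 6_000_000
    spike_genome_length: int = 200_000
    gene_length_range: tuple[int, int] = (3_000, 20_000)
    n_long_genes: int = 3
    long_gene_length: int = 200_000
    tsn_offset_median: float = 55.0
    tsn_offset_fixed: int | None = None
    pause_mix: PauseMixture = field(default_factory=PauseMixture)
    ctd_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CTD_WEIGHTS)
    )
    reads_per_sample: int = 100_000
    noise_rate: float = 0.02
    spike_in_fraction: float = 0.005
    pcr_dup_rate: float = 0.5
    pause_focus: float = 0.6
    tsn_focus: float = 0.9
    term_window: int = 2_000
    conditions: tuple[str, str] = ("NHS", "HS30")
    hs_activated_frac: float = 0.1
    hs_repressed_frac: float = 0.1
    hs_up_fold: float = 4.0
    hs_down_fold: float = 0.25
    barcode_table: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_rate", "spike_in_fraction", "pause_focus", "tsn_focus"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.pcr_dup_rate < 0:
            raise ValueError("pcr_dup_rate must be non-negative")
        for ab, w in self.ctd_weights.items():
            if len(w) != 3 or min(w) < 0 or sum(w) <= 0:
                raise ValueError(f"ctd_weights[{ab}] must be 3 non-negative weights")
        if self.barcode_table is not None:
            codes = list(self.barcode_table.values())
            if len(set(codes)) != len(codes):
                raise ValueError("barcodes must be unique")
            for code in codes:
                if len(code) != 6 or set(code) - set("ACGTN"):
                    raise ValueError(f"barcode {code!r} must be 6 nt of ACGTN")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pause_mix" in raw and isinstance(raw["pause_mix"], dict):
            raw["pause_mix"] = PauseMixture(**raw["pause_mix"])
        for key in ("gene_length_range", "conditions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "ctd_weights" in raw:
            raw["ctd_weights"] = {k: tuple(v) for k, v in raw["ctd_weights"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class TruthTable:
    """Per-gene and per-sample ground truth of one simulated experiment."""

    genes: pd.DataFrame  # gene_id, chrom, strand, tss, tsn, tsn_offset, pause ...
    samples: pd.DataFrame  # filled in as samples are simulated

    def expected_weights(self, config: SimConfig, condition: str) -> np.ndarray:
        w = self.genes["expr_weight"].to_numpy(dtype=float).copy()
        if condition != config.conditions[0]:
            w = w * self.genes["hs_multiplier"].to_numpy(dtype=float)
        return w


def _stream_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic, stream-separated generator for a named purpose."""
    crc = zlib.crc32("/".join(str(t) for t in tags).encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, crc])


def simulate_gene_set(config: SimConfig) -> tuple[list[GeneModel], TruthTable]:
    """Lay out non-overlapping genes on both strands and draw their truths.

    Each gene receives a true TSN offset (fixed, or drawn from a
    discretized exponential with the configured median, capped at
    +400 nt so the TSN stays inside the calling window), a dominant
    pause offset from the configured mixture, a log-normal expression
    weight, and a heat-shock multiplier.
    """
    rng = _stream_rng(config.seed, "gene_set")
    n = config.n_genes
    if n == 0:
        empty = pd.DataFrame(
            columns=[
                "gene_id", "chrom", "strand", "start", "end", "tss", "tsn",
                "tsn_offset", "pause_component", "pause_offset", "pause_coord",
                "expr_weight", "hs_class", "hs_multiplier",
            ]
        )
        return [], TruthTable(genes=empty, samples=pd.DataFrame())

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    n_long = min(config.n_long_genes, n)
    lengths[:n_long] = config.long_gene_length
    gaps = rng.integers(500, 5_001, size=n)
    starts = np.cumsum(gaps + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths
    if ends[-1] + 500 > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} too small to place "
            f"{n} genes totalling {int(lengths.sum())} bp"
        )
    strands = rng.choice(np.array(["+", "-"]), size=n)

    if config.tsn_offset_fixed is not None:
        offsets = np.full(n, int(config.tsn_offset_fixed))
    else:
        scale = config.tsn_offset_median / np.log(2.0)
        offsets = np.minimum(np.floor(rng.exponential(scale, size=n)).astype(int), 400)

    comp = np.where(
        rng.random(n) < config.pause_mix.weight_early, "early", "late"
    )
    pause_offsets = np.empty(n, dtype=int)
    for name in ("early", "late"):
        idx = np.flatnonzero(comp == name)
        if len(idx):
            off, pmf = config.pause_mix.component_pmf(name)
            pause_offsets[idx] = rng.choice(off, size=len(idx), p=pmf)

    expr = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    u = rng.random(n)
    hs_class = np.where(
        u < config.hs_activated_frac,
        "activated",
        np.where(u < config.hs_activated_frac + config.hs_repressed_frac, "repressed", "unchanged"),
    )
    # long genes anchor the between-condition factor: a 30-min
    # transcription wave cannot reach their ends, so they stay unchanged
    hs_class[:n_long] = "unchanged"
    hs_mult = np.where(
        hs_class == "activated",
        config.hs_up_fold,
        np.where(hs_class == "repressed", config.hs_down_fold, 1.0),
    )

    genes: list[GeneModel] = []
    rows = []
    for i in range(n):
        gid = f"gene{i:04d}"
        strand = str(strands[i])
        start, end = int(starts[i]), int(ends[i])
        gene = GeneModel(gid, PRIMARY_CHROM, strand, start, end)
        tss = gene.tss
        tsn = gene.offset_to_pos(tss, int(offsets[i]))
        pause_coord = gene.offset_to_pos(tsn, int(pause_offsets[i]) - 1)
        genes.append(gene)
        rows.append(
            dict(
                gene_id=gid, chrom=PRIMARY_CHROM, strand=strand, start=start,
                end=end, tss=tss, tsn=tsn, tsn_offset=int(offsets[i]),
                pause_component=str(comp[i]), pause_offset=int(pause_offsets[i]),
                pause_coord=pause_coord, expr_weight=float(expr[i]),
                hs_class=str(hs_class[i]), hs_multiplier=float(hs_mult[i]),
            )
        )
    truth = TruthTable(genes=pd.DataFrame(rows), samples=pd.DataFrame())
    return genes, truth


@dataclass
class SampleSim:
    """One simulated sample: aligned molecules plus optional raw reads."""

    sample: str
    condition: str
    antibody: str
    replicate: int
    alignments: pd.DataFrame  # primary-genome BED6, one record per molecule
    spike_alignments: pd.DataFrame  # spike-in-genome BED6
    n_molecules: int
    reads: list[ReadRecord] | None = None  # FASTQ path, with PCR duplicates


def simulate_sample_reads(
    genes: list[GeneModel],
    truth: TruthTable,
    config: SimConfig,
    antibody: str,
    condition: str,
    replicate: int = 1,
    emit_fastq: bool = False,
    genome_seq: str | None = None,
    barcode: str | None = None,
) -> SampleSim:
    """Simulate one sample's molecules as aligned end coordinates.

    Reads are apportioned: a binomial draw at ``spike_in_fraction`` goes
    to the spike-in genome, a binomial draw at ``noise_rate`` of the
    remainder is uniform background, and the rest distribute over genes
    proportionally to expression weight. Within a gene, the 3'-end falls
    in the pause region, gene body, or termination window according to
    ``ctd_weights[antibody]``; the 5'-end sits at the true TSN with
    probability ``tsn_focus`` (small downstream jitter otherwise).
    """
    if antibody not in config.ctd_weights:
        raise ValueError(f"unknown antibody label {antibody!r}")
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _stream_rng(config.seed, "sample", condition, antibody, replicate)
    n_total = config.reads_per_sample
    n_spike = int(rng.binomial(n_total, config.spike_in_fraction))
    n_rest = n_total - n_spike
    n_noise = int(rng.binomial(n_rest, config.noise_rate)) if genes else n_rest
    n_signal = n_rest - n_noise

    frames = []
    gene_df = truth.genes
    if n_signal > 0 and genes:
        weights = truth.expected_weights(config, condition)
        p = weights / weights.sum()
        gene_idx = rng.choice(len(genes), size=n_signal, p=p)
        frames.append(_signal_records(gene_idx, gene_df, config, antibody, rng))
    if n_noise > 0:
        frames.append(
            _uniform_records(rng, n_noise, PRIMARY_CHROM, config.genome_length, "noise")
        )
    primary = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=BED6_COLUMNS)
    )
    primary = primary.sort_values(["chrom", "start", "end", "strand"], kind="stable").reset_index(drop=True)
    primary["name"] = [f"mol{i:07d}" for i in range(len(primary))]

    spike = _uniform_records(rng, n_spike, SPIKE_CHROM, config.spike_genome_length, "spk")

    sample = f"{condition}_{antibody}_r{replicate}"
    reads = None
    if emit_fastq:
        if genome_seq is None:
            raise ValueError("emit_fastq requires the primary genome sequence")
        if barcode is None:
            table = config.barcode_table or default_barcode_table([sample])
            barcode = table.get(sample, next(iter(table.values())))
        reads = _emit_fastq_reads(primary, genome_seq, barcode, config, rng)

    return SampleSim(
        sample=sample, condition=condition, antibody=antibody, replicate=replicate,
        alignments=primary, spike_alignments=spike, n_molecules=len(primary),
        reads=reads,
    )


def _signal_records(gene_idx, gene_df, config: SimConfig, antibody: str, rng) -> pd.DataFrame:
    n = len(gene_idx)
    pw, bw, tw = config.ctd_weights[antibody]
    total = pw + bw + tw
    compartment = rng.choice(3, size=n, p=[pw / total, bw / total, tw / total])

    tsn = gene_df["tsn"].to_numpy()[gene_idx]
    strand = gene_df["strand"].to_numpy()[gene_idx]
    start = gene_df["start"].to_numpy()[gene_idx]
    end = gene_df["end"].to_numpy()[gene_idx]
    gene_pause = gene_df["pause_offset"].to_numpy()[gene_idx]  # 1-based from TSN
    plus = strand == "+"
    # distance TSN -> CPS along the direction of transcription
    cps_off = np.where(plus, (end - 1) - tsn, tsn - start)

    # 3'-end offset from TSN (0-based: 0 == TSN)
    off3 = np.zeros(n, dtype=np.int64)
    is_pause = compartment == 0
    n_pause = int(is_pause.sum())
    if n_pause:
        mix_off, mix_p = config.pause_mix.mixture_pmf()
        drawn = rng.choice(mix_off, size=n_pause, p=mix_p)
        focused = rng.random(n_pause) < config.pause_focus
        off3[is_pause] = np.where(focused, gene_pause[is_pause], drawn) - 1
    is_body = compartment == 1
    n_body = int(is_body.sum())
    if n_body:
        span = np.maximum(cps_off[is_body] - 60, 1)
        off3[is_body] = 60 + rng.integers(0, 1 << 31, size=n_body) % span + 1
    is_term = compartment == 2
    n_term = int(is_term.sum())
    if n_term:
        off3[is_term] = cps_off[is_term] + 1 + (
            rng.integers(0, 1 << 31, size=n_term) % config.term_window
        )

    # 5'-end offset from TSN: 0 with prob tsn_focus, else small downstream jitter
    jitter = np.minimum(rng.geometric(0.4, size=n), 5)
    off5 = np.where(rng.random(n) < config.tsn_focus, 0, jitter)
    off5 = np.minimum(off5, off3)  # a molecule's 5'-end cannot pass its 3'-end

    pos5 = np.where(plus, tsn + off5, tsn - off5)
    pos3 = np.where(plus, tsn + off3, tsn - off3)
    rec_start = np.minimum(pos5, pos3)
    rec_end = np.maximum(pos5, pos3) + 1
    rec_start = np.clip(rec_start, 0, None)
    return pd.DataFrame(
        {
            "chrom": PRIMARY_CHROM, "start": rec_start, "end": rec_end,
            "name": "", "score": 1, "strand": strand,
        }
    )


def _uniform_records(rng, n, chrom, genome_length, prefix) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(columns=BED6_COLUMNS)
    length = rng.integers(20, 61, size=n)
    start = rng.integers(0, max(genome_length - 61, 1), size=n)
    strand = rng.choice(np.array(["+", "-"]), size=n)
    return pd.DataFrame(
        {
            "chrom": chrom, "start": start, "end": start + length,
            "name": [f"{prefix}{i:07d}" for i in range(n)],
            "score": 1, "strand": strand,
        }
    )


def _emit_fastq_reads(
    primary: pd.DataFrame, genome_seq: str, barcode: str, config: SimConfig, rng
) -> list[ReadRecord]:
    """Emit Read-1 records with the inline-barcode/UMI adapter layout.

    The nascent-RNA insert is the (up to 40 nt) 3'-portion of the
    molecule. Read 1 runs antisense to the RNA:
    ``barcode + C + revcomp(insert) + G + umi_field + 3'-adapter``; the
    barcode and UMI fields are stored in read orientation. Each molecule
    is written ``1 + Poisson(pcr_dup_rate)`` times; duplicates share
    UMI and sequence.
    """
    reads: list[ReadRecord] = []
    alphabet = "ACGT"
    n = len(primary)
    dup_counts = 1 + rng.poisson(config.pcr_dup_rate, size=n)
    used: set[tuple[str, str]] = set()
    for i, row in enumerate(primary.itertuples(index=False)):
        start, end, strand = int(row.start), int(row.end), row.strand
        seq = genome_seq[start:end]
        rna = seq if strand == "+" else revcomp(seq)
        insert = rna[-40:]  # sequencing reads into the 3' portion
        # identical molecules get distinct UMIs (idealized UMI space) so
        # the molecule count is exactly recoverable after collapse
        for _ in range(100):
            umi = "".join(alphabet[j] for j in rng.integers(0, 4, size=6))
            if (insert, umi) not in used:
                break
        else:
            raise RuntimeError("UMI space exhausted for identical molecules")
        used.add((insert, umi))
        read1 = f"{barcode}C{revcomp(insert)}G{umi}{ADAPTER_READ1}"
        qual = "I" * len(read1)
        for d in range(int(dup_counts[i])):
            reads.append(
                ReadRecord(name=f"{row.name}/{d}", seq=read1, qual=qual)
            )
    order = rng.permutation(len(reads))
    return [reads[j] for j in order]


def simulate_genome_sequences(config: SimConfig) -> dict[str, str]:
    """Random primary and spike-in genome sequences (no shared homology)."""
    alphabet = np.array(list("ACGT"))
    out = {}
    for chrom, length, tag in (
        (PRIMARY_CHROM, config.genome_length, "genome_primary"),
        (SPIKE_CHROM, config.spike_genome_length, "genome_spike"),
    ):
        rng = _stream_rng(config.seed, tag)
        out[chrom] = "".join(alphabet[rng.integers(0, 4, size=length)])
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def default_barcode_table(samples: list[str]) -> dict[str, str]:
    """Deterministic 6-nt barcodes with pairwise Hamming distance >= 3."""
    pool = [
        "ATCACG", "CGATGT", "TTAGGC", "TGACCA", "ACAGTG", "GCCAAT",
        "CAGATC", "ACTTGA", "GATCAG", "TAGCTT", "GGCTAC", "CTTGTA",
        "AGTCAA", "AGTTCC", "ATGTCA", "CCGTCC", "GTCCGC", "GTGAAA",
        "GTGGCC", "GTTTCG", "CGTACG", "GAGTGG", "ACTGAT", "ATTCCT",
    ]
    if len(samples) > len(pool):
        raise ValueError(f"barcode pool supports at most {len(pool)} samples")
    return {s: pool[i] for i, s in enumerate(samples)}
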
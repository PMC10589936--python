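"""Synthetic multiplexed nanopore-run generator with ground truth.

The generator emulates the statistical structure of a multiplexed MinION run
so the whole analysis pipeline is exercisable without any sequencing data:

* library-strategy-specific read-length and quality models (ligation-like,
  tagmentation-like and PCR-like presets);
* 512-channel occupancy with overdispersion (Dirichlet-multinomial);
* a configurable fraction of demultiplexing loss (unclassified reads),
  barcode leakage, and unmappable noise reads;
* artifactual exact tandem repeats planted near read ends, mirroring the
  edge-located tandem artifacts seen in real runs.

Outputs are the same files a real run analysis consumes — FASTQ, an ONT-style
sequencing summary, a PAF of ground-truth-derived alignments, a TRF-style
``.dat`` tandem report — plus a truth table for parameter-recovery tests.
The simulated PAF is derived from the generator's own knowledge of each
read's origin and identity; no aligner is run.

All randomness flows through one seeded generator with per-read draws in a
fixed field order, so a given seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import BarcodeGenomeMap
from .errors import ConfigError
from .io_formats import (
    DEFAULT_N_CHANNELS,
    UNCLASSIFIED,
    AlignmentRecord,
    ReadRecord,
    write_fasta,
    write_fastq,
    write_paf,
    write_sequencing_summary,
)
from .planted import plant_table_fixture  # noqa: F401  (re-export: fixture planting)

__all__ = [
    "LibraryModel",
    "LIBRARY_MODELS",
    "RunConfig",
    "TruthRow",
    "SimulatedRun",
    "simulate_run",
    "default_config",
    "plant_table_fixture",
]

#: Sentinel origin label for unmappable noise reads.
NOISE = "NOISE"

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LibraryModel:
    """Distributional preset for one library-preparation strategy.

    Read lengths follow a log-normal body (``length_median`` bp, shape
    ``length_sigma``) truncated at ``length_cap``; the PCR-like preset caps at
    30 kbp, the processivity ceiling of a long-range polymerase.  Noise reads
    draw from their own, typically shorter, log-normal.  ``channel_dispersion``
    is the symmetric Dirichlet concentration for channel occupancy: smaller
    values give more overdispersed (less homogeneous) channel output.
    ``noise_qscore_mean`` lets noise reads run at lower quality than mappable
    ones (ligation/tagmentation-like) or at equal quality (PCR-like, where
    artifacts sequence cleanly through pores).
    """

    name: str
    length_median: float
    length_sigma: float
    length_cap: int
    noise_length_median: float
    noise_length_sigma: float
    noise_rate: float
    identity_mean: float
    identity_sd: float
    qscore_mean: float
    qscore_sd: float
    noise_qscore_mean: float
    channel_dispersion: float
    tandem_artifact_rate: float


LIBRARY_MODELS: dict[str, LibraryModel] = {
    # ligation: defined length peak, low noise, homogeneous channels
    "LIG": LibraryModel(
        name="LIG",
        length_median=2500.0,
        length_sigma=1.1,
        length_cap=200_000,
        noise_length_median=1500.0,
        noise_length_sigma=1.0,
        noise_rate=0.07,
        identity_mean=0.903,
        identity_sd=0.05,
        qscore_mean=11.0,
        qscore_sd=1.5,
        noise_qscore_mean=9.0,
        channel_dispersion=30.0,
        tandem_artifact_rate=0.19,
    ),
    # tagmentation: broad length distribution, moderate noise
    "TAG": LibraryModel(
        name="TAG",
        length_median=2800.0,
        length_sigma=1.25,
        length_cap=150_000,
        noise_length_median=1200.0,
        noise_length_sigma=1.0,
        noise_rate=0.13,
        identity_mean=0.913,
        identity_sd=0.05,
        qscore_mean=11.0,
        qscore_sd=1.5,
        noise_qscore_mean=9.0,
        channel_dispersion=10.0,
        tandem_artifact_rate=0.28,
    ),
    # PCR: short amplicons, hard length cap, dominant short noise,
    # noise quality equal to mappable quality
    "PCR": LibraryModel(
        name="PCR",
        length_median=900.0,
        length_sigma=0.9,
        length_cap=30_000,
        noise_length_median=450.0,
        noise_length_sigma=0.7,
        noise_rate=0.75,
        identity_mean=0.843,
        identity_sd=0.07,
        qscore_mean=11.0,
        qscore_sd=1.5,
        noise_qscore_mean=11.0,
        channel_dispersion=3.0,
        tandem_artifact_rate=0.63,
    ),
}

_MIN_READ_LENGTH = 100


@dataclass(frozen=True)
class RunConfig:
    """Full specification of one simulated run; the seed fixes every draw."""

    seed: int
    n_reads: int
    model: LibraryModel
    genomes: tuple[tuple[str, int], ...]
    barcode_map: BarcodeGenomeMap
    n_channels: int = DEFAULT_N_CHANNELS
    unclassified_rate: float = 0.20
    leakage_rate: float = 0.015
    tandem_edge_window: int = 2500
    noise_rate: float | None = None  # overrides the model preset when set
    tandem_artifact_rate: float | None = None
    channel_dispersion: float | None = None

    def __post_init__(self) -> None:
        rates = {
            "unclassified_rate": self.unclassified_rate,
            "leakage_rate": self.leakage_rate,
            "noise_rate": self.effective_noise_rate,
            "tandem_artifact_rate": self.effective_tandem_rate,
        }
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not self.genomes and self.effective_noise_rate < 1.0:
            raise ConfigError("no genomes configured but noise_rate < 1")
        if self.n_reads < 0:
            raise ConfigError(f"n_reads must be >= 0, got {self.n_reads}")

    @property
    def effective_noise_rate(self) -> float:
        return self.model.noise_rate if self.noise_rate is None else self.noise_rate

    @property
    def effective_tandem_rate(self) -> float:
        return (
            self.model.tandem_artifact_rate
            if self.tandem_artifact_rate is None
            else self.tandem_artifact_rate
        )

    @property
    def effective_dispersion(self) -> float:
        return (
            self.model.channel_dispersion
            if self.channel_dispersion is None
            else self.channel_dispersion
        )


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated read."""

    read_id: str
    true_genome: str  # genome label or NOISE
    emitted_barcode: str  # barcode label or the unclassified sentinel
    is_leaked: bool  # leaked AND still classified (detectable leakage)
    planted_tandem_intervals: tuple[tuple[int, int], ...]
    channel: int


@dataclass
class SimulatedRun:
    """In-memory artifacts of one simulated run, writable to a directory."""

    config: RunConfig
    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    summary: list[ReadRecord]
    alignments: list[AlignmentRecord]
    dat_text: str
    truth: list[TruthRow]
    genomes: list[tuple[str, str]]  # (label, sequence)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all artifacts; returns a name -> path manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads.fastq": out / "reads.fastq",
            "sequencing_summary.txt": out / "sequencing_summary.txt",
            "alignments.paf": out / "alignments.paf",
            "tandems.dat": out / "tandems.dat",
            "truth.tsv": out / "truth.tsv",
            "barcode_map.tsv": out / "barcode_map.tsv",
            "genomes.fasta": out / "genomes.fasta",
        }
        write_fastq(self.reads, paths["reads.fastq"])
        write_sequencing_summary(self.summary, paths["sequencing_summary.txt"])
        write_paf(self.alignments, paths["alignments.paf"])
        paths["tandems.dat"].write_text(self.dat_text)
        with paths["truth.tsv"].open("w") as handle:
            handle.write(
                "read_id\ttrue_genome\temitted_barcode\tis_leaked"
                "\tplanted_tandem_intervals\tchannel\n"
            )
            for row in self.truth:
                ivs = ";".join(f"{s}-{e}" for s, e in row.planted_tandem_intervals)
                handle.write(
                    f"{row.read_id}\t{row.true_genome}\t{row.emitted_barcode}"
                    f"\t{'TRUE' if row.is_leaked else 'FALSE'}\t{ivs}\t{row.channel}\n"
                )
        self.config.barcode_map.to_tsv(paths["barcode_map.tsv"])
        write_fasta(self.genomes, paths["genomes.fasta"])
        return paths


def default_config(
    model: str | LibraryModel = "LIG",
    n_reads: int = 20_000,
    seed: int = 0,
    n_genomes: int = 12,
    genome_length: int = 200_000,
    **overrides,
) -> RunConfig:
    """A run over ``n_genomes`` synthetic replicons with one barcode each.

    Twelve replicons mirror a typical multiplexed bacterial run; their length
    only bounds read lengths, so a compact 200 kb default keeps simulation
    cheap without changing any measured statistic.
    """
    if isinstance(model, str):
        try:
            model = LIBRARY_MODELS[model]
        except KeyError:
            raise ConfigError(
                f"unknown library model {model!r}; choose from {sorted(LIBRARY_MODELS)}"
            ) from None
    genomes = tuple((f"genome{i + 1:02d}", genome_length) for i in range(n_genomes))
    barcode_map = BarcodeGenomeMap(
        {f"barcode{i + 1:02d}": label for i, (label, _) in enumerate(genomes)}
    )
    return RunConfig(
        seed=seed,
        n_reads=n_reads,
        model=model,
        genomes=genomes,
        barcode_map=barcode_map,
        **overrides,
    )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ACGT[rng.integers(0, 4, size=length)]


def _draw_lengths(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    cap: int,
    size: int,
) -> np.ndarray:
    raw = np.exp(rng.normal(np.log(median), sigma, size=size))
    return np.clip(raw, _MIN_READ_LENGTH, cap).astype(np.int64)


def simulate_run(config: RunConfig) -> SimulatedRun:
    """Generate one multiplexed run according to ``config``.

    Per-read draw order: channel occupancy and read-level attribute vectors
    are drawn first (channel, noise flag, origin, lengths, leakage and
    unclassified masks, tandem flag, Qscore), then the per-read loop draws
    sequence start, alignment identity/coverage and tandem geometry.  Barcode
    leakage is applied before unclassified masking, so a leaked read can end
    up unclassified — undetectable leakage, as in real runs; recovery
    analyses therefore condition on classified reads.
    """
    model = config.model
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    n_genomes = len(config.genomes)
    noise_rate = config.effective_noise_rate
    tandem_rate = config.effective_tandem_rate

    genome_seqs = [
        (label, _random_sequence(rng, length)) for label, length in config.genomes
    ]

    # vectorised per-read attribute draws (fixed order)
    channel_probs = rng.dirichlet(
        np.full(config.n_channels, config.effective_dispersion)
    )
    channels = rng.choice(config.n_channels, size=n, p=channel_probs) + 1
    is_noise = rng.random(n) < noise_rate
    origin_idx = rng.integers(0, max(n_genomes, 1), size=n)
    lengths_mappable = _draw_lengths(
        rng, model.length_median, model.length_sigma, model.length_cap, n
    )
    lengths_noise = _draw_lengths(
        rng, model.noise_length_median, model.noise_length_sigma, model.length_cap, n
    )
    lengths = np.where(is_noise, lengths_noise, lengths_mappable)
    leak_flip = rng.random(n) < config.leakage_rate
    leak_shift = rng.integers(1, max(n_genomes, 2), size=n)
    unclassified = rng.random(n) < config.unclassified_rate
    has_tandem = rng.random(n) < tandem_rate
    qscore_means = np.where(is_noise, model.noise_qscore_mean, model.qscore_mean)
    qscores = np.clip(rng.normal(qscore_means, model.qscore_sd), 1.0, 30.0)

    barcodes_by_genome = [
        config.barcode_map.barcode_for(label) for label, _ in config.genomes
    ]

    reads: list[tuple[str, str, str]] = []
    summary: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    truth: list[TruthRow] = []
    dat_lines: list[str] = [
        "Tandem Repeats Finder (synthetic report)",
        "Parameters: 2 5 7 80 10 50 2000",
        "",
    ]

    for i in range(n):
        read_id = f"{model.name}_read_{i:06d}"
        length = int(lengths[i])
        noise = bool(is_noise[i])
        g_idx = int(origin_idx[i])

        if noise:
            seq = _random_sequence(rng, length)
            true_genome = NOISE
        else:
            label, genome = genome_seqs[g_idx]
            glen = len(genome)
            length = min(length, glen)
            start = int(rng.integers(0, glen))
            if start + length <= glen:
                seq = genome[start : start + length].copy()
            else:  # circular replicon: wrap around
                seq = np.concatenate((genome[start:], genome[: start + length - glen]))
            true_genome = label

        # barcode: origin barcode, possibly leaked, possibly lost
        bc_idx = g_idx
        leaked = False
        if n_genomes > 1 and bool(leak_flip[i]):
            bc_idx = (g_idx + int(leak_shift[i])) % n_genomes
            leaked = True
        barcode = barcodes_by_genome[bc_idx] if n_genomes else UNCLASSIFIED
        if bool(unclassified[i]):
            barcode = UNCLASSIFIED
        classified = barcode != UNCLASSIFIED

        # ground-truth alignment for mappable reads
        if not noise:
            identity = float(np.clip(rng.normal(model.identity_mean, model.identity_sd), 0.70, 1.0))
            coverage = float(np.clip(rng.normal(0.97, 0.02), 0.50, 1.0))
            span = max(1, int(round(coverage * length)))
            q_start = int(rng.integers(0, length - span + 1))
            matched = max(1, int(round(identity * span)))
            alignments.append(
                AlignmentRecord(
                    read_id=read_id,
                    read_length=length,
                    q_start=q_start,
                    q_end=q_start + span,
                    target_id=true_genome,
                    matched_bases=matched,
                    block_length=span,
                    mapq=60,
                    is_primary=True,
                )
            )

        # edge-located tandem artifact
        planted: tuple[tuple[int, int], ...] = ()
        tandem_row = ""
        if bool(has_tandem[i]):
            t_max = min(2000, length, config.tandem_edge_window)
            period = int(rng.integers(5, 201))
            period = max(1, min(period, t_max // 3))
            max_copies = t_max // period
            copies = int(rng.integers(3, max_copies + 1)) if max_copies > 3 else 3
            t_len = period * copies
            side_3p = bool(rng.integers(0, 2))
            max_off = min(config.tandem_edge_window, length) - t_len
            offset = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0
            t_start = (length - offset - t_len) if side_3p else offset
            unit = _random_sequence(rng, period)
            seq[t_start : t_start + t_len] = np.tile(unit, copies)[:t_len]
            planted = ((t_start, t_start + t_len),)
            tandem_row = f"{t_start + 1} {t_start + t_len} {period} {copies:.1f}"

        dat_lines.append(f"Sequence: {read_id}")
        if tandem_row:
            dat_lines.append(tandem_row)

        q = float(qscores[i])
        qual_char = chr(33 + max(2, min(40, int(round(q)))))
        reads.append((read_id, seq.tobytes().decode("ascii"), qual_char * length))
        summary.append(
            ReadRecord(
                read_id=read_id,
                length=length,
                mean_qscore=round(q, 2),
                channel=int(channels[i]),
                passes_filtering=q >= 7.0,
                barcode=barcode,
                library=model.name,
            )
        )
        truth.append(
            TruthRow(
                read_id=read_id,
                true_genome=true_genome,
                emitted_barcode=barcode,
                is_leaked=leaked and classified,
                planted_tandem_intervals=planted,
                channel=int(channels[i]),
            )
        )

    return SimulatedRun(
        config=config,
        reads=reads,
        summary=summary,
        alignments=alignments,
        dat_text="\n".join(dat_lines) + "\n",
        truth=truth,
        genomes=[(label, seq.tobytes().decode("ascii")) for label, seq in genome_seqs],
    )
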
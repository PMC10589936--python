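"""End-to-end orchestration: simulate -> classify -> tandem -> report.

The pipeline consumes either a simulation block or paths to existing inputs
(sequencing summary, PAF, barcode map, TRF dat), joins them into the per-read
synthesis table, runs tandem merging and edge profiling, and writes the
reporting tables plus a machine-readable manifest.  The sequencing summary is
the read universe: alignments referencing unknown reads are an error, while
summary reads with no alignment are legitimately unmapped.

Machine outputs carry percentages at 4 decimals; display rounding (M, Gbp,
1-decimal percentages) is applied only in the human-facing tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import summary as summ
from .classify import (
    BarcodeGenomeMap,
    ReadAttributes,
    build_synthesis,
    synthesis_frame,
)
from .errors import ConfigError
from .io_formats import read_paf, read_sequencing_summary, read_trf_dat
from .simulate import default_config, simulate_run
from .tandem import edge_profile, merge_by_read

logger = logging.getLogger("nanoplex_qc")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative pipeline run description (YAML/JSON loadable)."""

    out_dir: Path
    # either a simulate block ...
    simulate: dict[str, Any] | None = None
    # ... or explicit input paths
    summary_path: Path | None = None
    paf_path: Path | None = None
    barcode_map_path: Path | None = None
    trf_dat_path: Path | None = None
    library: str = ""
    # thresholds
    min_len: int = 5000
    min_identity: float = 95.0
    min_cover: float = 80.0
    bin_width: int = 500
    window: int = 15_000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {
            "out_dir", "simulate", "summary_path", "paf_path", "barcode_map_path",
            "trf_dat_path", "library", "min_len", "min_identity", "min_cover",
            "bin_width", "window", "seed", "log_level",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "out_dir" not in data:
            raise ConfigError("pipeline config requires out_dir")
        kwargs = dict(data)
        for key in ("out_dir", "summary_path", "paf_path", "barcode_map_path", "trf_dat_path"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("summary_path", "paf_path", "barcode_map_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"pipeline config needs {name} (or a simulate block)")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: no such file: {path}")
            if self.trf_dat_path is not None and not self.trf_dat_path.exists():
                raise ConfigError(f"trf_dat_path: no such file: {self.trf_dat_path}")


def _write_tables(
    rows: list[ReadAttributes],
    out: Path,
    bin_width: int,
    window: int,
) -> dict[str, Path]:
    """Write table3/4/5/6-style TSVs, barcode profile and edge profile."""
    paths: dict[str, Path] = {}

    lib = summ.library_summary(rows)
    with (out / "table3.tsv").open("w") as fh:
        fh.write(
            "library\tpartition\treads_M\tcum_length_Gbp\ttandem_reads_M\tcum_tandem_Gbp\n"
        )
        for part in ("mapped", "unmapped", "all"):
            g = getattr(lib, part)
            fh.write(
                f"{lib.library}\t{part}\t{summ.to_millions(g.read_count)}"
                f"\t{summ.to_gbp(g.cum_read_length)}"
                f"\t{summ.to_millions(g.tandem_read_count)}"
                f"\t{summ.to_gbp(g.cum_tandem_length)}\n"
            )
    paths["table3.tsv"] = out / "table3.tsv"

    chan = summ.channel_summary(rows)
    with (out / "table4.tsv").open("w") as fh:
        fh.write("library\tpartition\tmetric\tmean\tsd\ttotal\n")
        for part in ("mapped", "unmapped", "all"):
            for metric in ("read_count", "cum_read_length", "tandem_read_count",
                           "cum_tandem_length"):
                fh.write(
                    f"{lib.library}\t{part}\t{metric}\t{chan.mean(part, metric):.4f}"
                    f"\t{chan.sd(part, metric):.4f}\t{chan.total(part, metric)}\n"
                )
    paths["table4.tsv"] = out / "table4.tsv"

    if rows:
        stats = summ.length_quality_stats(rows)
        stats.round(4).to_csv(out / "table5.tsv", sep="\t", index_label="partition")
    else:
        (out / "table5.tsv").write_text("partition\n")
    paths["table5.tsv"] = out / "table5.tsv"

    cls = summ.classified_summary(rows)
    with (out / "table6.tsv").open("w") as fh:
        fh.write("library\tcategory\treads_M\tcum_length_Gbp\tpct_of_classified\n")
        for cat, n, bp in (
            ("correct", cls.correct_reads, cls.correct_bp),
            ("leaked", cls.leaked_reads, cls.leaked_bp),
            ("unmapped", cls.unmapped_reads, cls.unmapped_bp),
            ("all_classified", cls.all_reads, cls.all_bp),
        ):
            fh.write(
                f"{cls.library}\t{cat}\t{summ.to_millions(n)}\t{summ.to_gbp(bp)}"
                f"\t{summ.percent(n, cls.all_reads, 4)}\n"
            )
        fh.write(
            f"{cls.library}\tunclassified_fraction\t"
            f"{round(cls.unclassified_fraction * 100, 4)}\t\t\n"
        )
    paths["table6.tsv"] = out / "table6.tsv"

    # per-barcode profile: counts and cumulative bp per category,
    # leakage broken down by source genome
    profile: dict[tuple[str, str], list[int]] = {}
    for r in rows:
        if r.assignment.value.startswith("UNCLASSIFIED"):
            key = (r.barcode, "unclassified")
        elif r.assignment.value == "LEAKED":
            key = (r.barcode, f"leaked:{r.mapped_target}")
        elif r.assignment.value == "CORRECT":
            key = (r.barcode, "correct")
        else:
            key = (r.barcode, "unmapped")
        entry = profile.setdefault(key, [0, 0])
        entry[0] += 1
        entry[1] += r.length
    with (out / "barcode_profile.tsv").open("w") as fh:
        fh.write("barcode\tcategory\tread_count\tcum_bp\n")
        for (barcode, category), (count, bp) in sorted(profile.items()):
            fh.write(f"{barcode}\t{category}\t{count}\t{bp}\n")
    paths["barcode_profile.tsv"] = out / "barcode_profile.tsv"

    # edge profile over merged tandem intervals is written by the caller when
    # interval-level data exist; here we emit per-read tandem totals
    with (out / "per_read_tandem.tsv").open("w") as fh:
        fh.write("read_id\ttotal_tandem_length\n")
        for r in rows:
            fh.write(f"{r.read_id}\t{r.total_tandem_length}\n")
    paths["per_read_tandem.tsv"] = out / "per_read_tandem.tsv"
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages; returns a manifest mapping file names to line counts.

    Re-running on identical inputs (and seed) reproduces byte-identical
    outputs: every stage is deterministic and all randomness flows through
    the configured seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        run_config = default_config(**sim_kwargs)
        logger.info("simulating %d reads (%s-like model)", run_config.n_reads,
                    run_config.model.name)
        sim = simulate_run(run_config)
        written.update(sim.write(out))
        summary_path = written["sequencing_summary.txt"]
        paf_path = written["alignments.paf"]
        barcode_map_path = written["barcode_map.tsv"]
        trf_dat_path = written["tandems.dat"]
        library = run_config.model.name
    else:
        summary_path = config.summary_path
        paf_path = config.paf_path
        barcode_map_path = config.barcode_map_path
        trf_dat_path = config.trf_dat_path
        library = config.library

    reads = read_sequencing_summary(summary_path, library=library)
    alignments = read_paf(paf_path)
    barcode_map = BarcodeGenomeMap.from_tsv(barcode_map_path)
    logger.info("classifying %d reads against %d alignments", len(reads), len(alignments))

    profiles = {}
    if trf_dat_path is not None:
        intervals = read_trf_dat(trf_dat_path)
        profiles = merge_by_read(intervals)
    tandem_lengths = {rid: p.total_tandem_length for rid, p in profiles.items()}

    rows = build_synthesis(reads, alignments, barcode_map, tandem_lengths)
    frame = synthesis_frame(rows)
    for col in ("percent_identity", "query_coverage"):
        frame[col] = frame[col].round(4)
    frame.to_csv(out / "synthesis.tsv", sep="\t", index=False)
    written["synthesis.tsv"] = out / "synthesis.tsv"

    if profiles:
        lengths = {r.read_id: r.length for r in reads}
        prof = edge_profile(
            profiles.values(), lengths, bin_width=config.bin_width, window=config.window
        )
        with (out / "edge_profile.tsv").open("w") as fh:
            fh.write("side\tbin_start\ttandem_bases\n")
            for b, start in enumerate(prof.bin_starts()):
                fh.write(f"5p\t{start}\t{prof.counts_5p[b]}\n")
            for b, start in enumerate(prof.bin_starts()):
                fh.write(f"3p\t{start}\t{prof.counts_3p[b]}\n")
        written["edge_profile.tsv"] = out / "edge_profile.tsv"

    written.update(_write_tables(rows, out, config.bin_width, config.window))

    manifest = {
        "files": {
            name: sum(1 for _ in path.open())
            for name, path in sorted(written.items())
        }
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote %d files to %s", len(written), out)
    return manifest
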
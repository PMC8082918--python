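"""End-to-end orchestration of the finishing stages on a simulated dataset.

Stage order mirrors the assembly workflow: simulate -> fish -> select-contig
-> circularize (reliable ends, overlap trimming, anchor orientation) ->
polish -> qv / repeats / heteroplasmy. Every stage writes its inputs and
outputs in standard formats under the output directory, and the run summary
is machine-readable JSON. The upstream de novo assembler is outside this
toolkit's scope; a simulated concatemeric contig stands in for its output.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import circular, fish, io, mitocontig, polish, qc, simulate
from .matchfinder import LinearMapper
from .records import Interval, SequenceRecord

log = logging.getLogger("mitofinish")

DEFAULT_CONFIG = {
    "seed": 1,
    "base_len": 16000,
    "repeat_unit_len": 84,
    "repeat_copies": 11,
    "repeat_position": 500,
    "dup_len": 0,
    "anchor_len": 70,
    "long_coverage": 30.0,
    "len_mean": 6000.0,
    "len_sd": 3000.0,
    "sub_rate": 0.01,
    "ins_rate": 0.02,
    "del_rate": 0.01,
    "short_coverage": 100.0,
    "short_sub_rate": 0.001,
    "n_nuclear_reads": 50,
    "nuclear_len_mean": 6000.0,
    "rotation": 4321,
    "contig_copies": 2.3,
    "min_fraction": 0.70,   # confident-read threshold (the 70% rule)
    "p": 5.0,               # contig query-coverage cutoff, percent
    "f": None,              # maximum long-read length
    "z": 500,               # match-extension gap tolerance
    "min_depth": 3,
    "qv_k": 31,
    "qv_min_freq": 25,      # scaled to the simulated short-read depth
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def load_config(path) -> dict:
    """Flat key = value config file; '#' starts a comment."""
    cfg = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, val = (x.strip() for x in line.split("=", 1))
        if key not in cfg:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        default = cfg[key]
        if val.lower() in ("none", ""):
            cfg[key] = None
        elif isinstance(default, bool):
            cfg[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(default, int) and default is not None:
            cfg[key] = int(float(val))
        else:
            cfg[key] = float(val)
    return cfg


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, float) and x == float("inf"):
        return "inf"
    return x


class _Stage:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        log.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full simulated-finishing pipeline; returns the summary dict."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"parameters": _jsonable(cfg), "stages": {}}

    with _Stage("simulate"):
        repeat_specs = []
        if cfg["repeat_copies"] and cfg["repeat_unit_len"]:
            repeat_specs.append(
                simulate.RepeatSpec(
                    int(cfg["repeat_unit_len"]), int(cfg["repeat_copies"]),
                    position=int(cfg["repeat_position"]),
                )
            )
        dup_specs = []
        if cfg["dup_len"]:
            dup_specs.append(
                simulate.DuplicationSpec(
                    source=Interval("base", 5000, 5000 + int(cfg["dup_len"])),
                    insert_at=int(cfg["base_len"]) - 600,
                )
            )
        truth = simulate.simulate_mitogenome(
            base_len=int(cfg["base_len"]),
            repeat_specs=repeat_specs,
            dup_specs=dup_specs,
            anchor_len=int(cfg["anchor_len"]),
            seed=seed,
        )
        profile = simulate.ErrorProfile(cfg["sub_rate"], cfg["ins_rate"], cfg["del_rate"])
        mt_reads = simulate.simulate_long_reads(
            truth, coverage=cfg["long_coverage"], len_mean=cfg["len_mean"],
            len_sd=cfg["len_sd"], profile=profile, seed=seed + 1,
        )
        nuclear = simulate.simulate_nuclear_background(
            truth.genome, n_reads=int(cfg["n_nuclear_reads"]),
            len_mean=cfg["nuclear_len_mean"], seed=seed + 2,
        )
        long_reads = mt_reads + nuclear
        short_reads = simulate.simulate_short_reads(
            truth.genome, coverage=cfg["short_coverage"],
            sub_rate=cfg["short_sub_rate"], seed=seed + 3,
        )
        contig = simulate.make_concatemer_contig(
            truth, rotation=int(cfg["rotation"]), copies=cfg["contig_copies"]
        )
        decoy = SequenceRecord("tig_decoy", simulate._random_seq(
            np.random.default_rng(seed + 4), 5000, 0.41))
        io.write_sequences([truth.genome], out / "genome.fasta", "fasta")
        io.write_sequences(long_reads, out / "long.fastq", "fastq")
        io.write_sequences(short_reads, out / "short.fastq", "fastq")
        io.write_sequences([contig, decoy], out / "contig.fasta", "fasta")
        truth_iv = [r.region for r in truth.repeats] + truth.duplications + [truth.anchor]
        names = [f"repeat_u{r.unit_len}" for r in truth.repeats] + [
            "duplication"] * len(truth.duplications) + ["anchor"]
        io.write_bed(truth_iv, out / "truth.bed", names)
        (out / "truth.json").write_text(json.dumps(_jsonable({
            "genome_len": len(truth.genome),
            "repeats": [
                {"start": r.region.start, "end": r.region.end,
                 "unit_len": r.unit_len, "copies": r.copy_number}
                for r in truth.repeats
            ],
            "duplications": [{"start": d.start, "end": d.end} for d in truth.duplications],
        }), indent=2))
        summary["stages"]["simulate"] = {
            "genome_len": len(truth.genome),
            "n_long_reads": len(long_reads),
            "n_short_reads": len(short_reads),
            "n_mt_reads_truth": len(mt_reads),
        }

    with _Stage("fish"):
        max_len = cfg["f"]
        selected, report = fish.select_mt_reads(
            long_reads, truth.genome,
            min_fraction=cfg["min_fraction"],
            max_read_len=int(max_len) if max_len else None,
        )
        io.write_sequences(selected, out / "selected.fastq", "fastq")
        io.write_tsv(report, out / "fish_report.tsv")
        summary["stages"]["fish"] = {"n_selected": len(selected)}
        if not selected:
            raise PipelineError("fish", "no long mtDNA reads were available")

    with _Stage("select-contig"):
        best, creport = mitocontig.select_mitocontig(
            [contig, decoy], truth.genome, min_query_cov_pct=cfg["p"]
        )
        io.write_tsv(creport, out / "contig_report.tsv")
        summary["stages"]["select_contig"] = {
            "selected": best.id,
            "n_filtered": int((~creport["passed"]).sum()),
        }

    with _Stage("circularize"):
        lin = LinearMapper(best, max_edit_frac=0.25)
        # use every placement: on a concatemer, primary-only mapping piles
        # all ambiguous reads onto the first copy and starves the rest
        short_alns = [a for r in short_reads for a in lin.align(r, all_placements=True)]
        reliable = circular.reliable_ends(best, short_alns, min_depth=int(cfg["min_depth"]))
        trimmed = SequenceRecord(best.id, best.seq[reliable.start : reliable.end])
        call = circular.find_terminal_overlap(trimmed, match_gap=int(cfg["z"]))
        unit = circular.collapse_to_unit(trimmed, call)
        anchor = SequenceRecord("anchor", truth.anchor_seq)
        circ = circular.rotate_to_anchor(unit, anchor)
        io.write_sequences([circ], out / "circular.fasta", "fasta")
        overlap_info = {
            "period": call.period if call else None,
            "n_copies": round(call.n_copies, 3) if call else None,
            "head": [call.head.start, call.head.end] if call else None,
            "tail": [call.tail.start, call.tail.end] if call else None,
        }
        summary["stages"]["circularize"] = overlap_info

    with _Stage("polish"):
        result = polish.pileup_polish(circ, short_reads, min_depth=int(cfg["min_depth"]))
        polished = result.sequence
        io.write_sequences([polished], out / "polished.fasta", "fasta")
        import pandas as pd

        io.write_tsv(
            pd.DataFrame(
                [
                    {"pos": v.pos, "ref": v.ref_allele, "alt": v.alt_allele,
                     "depth": v.depth, "alt_support": v.alt_support}
                    for v in result.variants
                ],
                columns=["pos", "ref", "alt", "depth", "alt_support"],
            ),
            out / "variants.tsv",
        )
        summary["stages"]["polish"] = {
            "n_variants": len(result.variants),
            "n_low_coverage_intervals": len(result.low_coverage),
        }

    with _Stage("qc"):
        read_counts = qc.count_kmers(short_reads, int(cfg["qv_k"]))
        filtered = qc.filter_high_frequency(read_counts, int(cfg["qv_min_freq"]))
        qv = qc.kmer_qv(polished, filtered, int(cfg["qv_k"]))
        repeats = qc.annotate_repeats(polished)
        het = {}
        if repeats:
            rep = max(repeats, key=lambda r: len(r.region))
            obs = qc.spanning_observations(mt_reads, polished, rep.region)
            hist, majority = qc.copy_number_histogram(
                obs, rep.unit_len, int(round(rep.copy_number))
            )
            het = {
                "n_spanning": len(obs),
                "histogram": {str(k): v for k, v in hist.items()},
                "majority_fraction": round(majority, 4),
            }
        summary["stages"]["qc"] = {
            "qv": "inf" if qv.qv == float("inf") else round(qv.qv, 2),
            "false_kmers": qv.false_positions,
            "repeats": [
                {"start": r.region.start, "end": r.region.end,
                 "unit_len": r.unit_len, "copy_number": round(r.copy_number, 2)}
                for r in repeats
            ],
            "heteroplasmy": het,
        }

    summary["success"] = True
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return summary
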
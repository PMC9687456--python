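"""End-to-end pipeline: simulate -> dedup -> callpeaks -> diffm6a -> annotate
-> motifs -> integrate -> report, with a manifest for reproducibility.

Each stage writes plain-text outputs (FASTA/GTF/BED/TSV/JSON) into the run
directory; the manifest records parameters, package version, and the sha256
of every written file, so a rerun with the same config and seed is
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import region_distribution
from .differential import differential_peaks, summarize_differential
from .expression import quantify_expression, overlap_analysis
from .io import write_bed, write_fasta, write_fastq, write_tsv
from .motifs import extract_peak_sequences, kmer_enrichment, rrach_match_fraction
from .peaks import call_peaks
from .simulate import SimulationConfig, simulate_dataset
from .umi import deduplicate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dedup", "callpeaks", "diffm6a", "annotate", "motifs",
          "integrate", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(outdir: str | Path, sim_config: SimulationConfig | None = None,
                 window: int = 20, alpha: float = 0.05, min_cov: int = 10,
                 identity_threshold: float = 0.95, k: int = 5,
                 dedup_max_reads: int = 20_000) -> dict:
    """Run all stages on a synthetic dataset and return the manifest.

    The deduplication stage runs on the FASTQ expansion of the coarse IP
    library (capped at ``dedup_max_reads`` reads to keep desk-scale runs
    fast); peak calling and everything downstream consume the molecule-level
    placements directly, since read alignment is outside the pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimulationConfig(depth_per_library=10_000, n_genes=50)
    manifest: dict = {"version": __version__, "stages": {},
                      "parameters": {"window": window, "alpha": alpha,
                                     "min_cov": min_cov, "k": k,
                                     "identity_threshold": identity_threshold,
                                     "simulation": dataclasses.asdict(cfg)}}
    files: dict[str, str] = {}

    def done(stage: str, **info):
        manifest["stages"][stage] = {"status": "complete", **info}
        logger.info("stage %s complete", stage)

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # simulate
    try:
        genome, ann, sim = simulate_dataset(cfg)
        write_fasta(genome, outdir / "genome.fa")
        ann.to_gtf(outdir / "annotation.gtf")
        tp = sim.truth.true_peaks
        write_bed(tp.assign(name=tp["gene"], score=0), outdir / "true_peaks.bed")
        write_tsv(sim.reads, outdir / "reads.tsv")
        de = pd.DataFrame({"gene": list(sim.truth.true_de),
                           "fold": list(sim.truth.true_de.values())})
        write_tsv(de, outdir / "true_de.tsv")
        done("simulate", molecules=sim.truth.true_molecules and
             {f"{c}_{l}": n for (c, l), n in sim.truth.true_molecules.items()})
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)

    # dedup (FASTQ round trip on one library)
    try:
        fastq = sim.fastq_reads("coarse", "IP")[:dedup_max_reads]
        write_fastq(fastq, outdir / "coarse_IP.fastq")
        from .io import strip_umi_prefix

        stripped = [strip_umi_prefix(r, cfg.umi_length) for r in fastq]
        consensus_reads = deduplicate(stripped, identity_threshold)
        write_fastq(consensus_reads, outdir / "coarse_IP.dedup.fastq")
        write_tsv(pd.DataFrame({"reads_in": [len(fastq)],
                                "consensus_out": [len(consensus_reads)]}),
                  outdir / "dedup_report.tsv")
        done("dedup", reads_in=len(fastq), consensus_out=len(consensus_reads))
    except Exception as exc:  # noqa: BLE001
        fail("dedup", exc)

    # callpeaks per condition
    peaks_by_cond = {}
    try:
        for cond in ("coarse", "fine"):
            ip = sim.library(cond, "IP")
            inp = sim.library(cond, "Input")
            _w, pk = call_peaks(ip, inp, ann.chrom_sizes, w=window, alpha=alpha,
                                min_cov=min_cov)
            pk["name"] = [f"{cond}_peak_{i}" for i in range(len(pk))]
            pk["score"] = -np.log10(np.clip(pk["p_value"].to_numpy(dtype=float),
                                            1e-300, None)) if len(pk) else 0.0
            write_bed(pk, outdir / f"peaks_{cond}.bed",
                      extra_columns=["ip_count", "input_count", "enrichment"])
            peaks_by_cond[cond] = pk
        done("callpeaks", n_coarse=len(peaks_by_cond["coarse"]),
             n_fine=len(peaks_by_cond["fine"]))
    except Exception as exc:  # noqa: BLE001
        fail("callpeaks", exc)

    # diffm6a
    try:
        records = differential_peaks(peaks_by_cond["coarse"], peaks_by_cond["fine"],
                                     sim.reads, alpha=alpha)
        records["gene"] = ann.assign_genes(records)
        write_tsv(records, outdir / "differential_peaks.tsv")
        summary = summarize_differential(records)
        done("diffm6a", **summary)
    except Exception as exc:  # noqa: BLE001
        fail("diffm6a", exc)

    # annotate
    try:
        dist_frames = {}
        for cond, pk in peaks_by_cond.items():
            dist = region_distribution(pk, ann)
            dist_frames[cond] = dist
            write_tsv(dist.reset_index(names="region"),
                      outdir / f"region_distribution_{cond}.tsv")
        done("annotate")
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)

    # motifs
    try:
        seqs = extract_peak_sequences(peaks_by_cond["coarse"], genome)
        if seqs:
            enr = kmer_enrichment(seqs, k=k, seed=cfg.seed)
            write_tsv(enr, outdir / "motif_enrichment.tsv")
            top = enr.iloc[0]["kmer"]
            rrach = rrach_match_fraction(seqs)
        else:
            top, rrach = None, 0.0
        done("motifs", top_kmer=top, rrach_fraction=rrach)
    except Exception as exc:  # noqa: BLE001
        fail("motifs", exc)

    # integrate
    try:
        expr = quantify_expression(sim.reads, ann)
        write_tsv(expr, outdir / "expression.tsv")
        up_m6a = set(records.loc[records["peak_class"] == "up", "gene"].dropna())
        spec_m6a = set(records.loc[records["peak_class"] == "coarse_specific",
                                   "gene"].dropna())
        de_up = set(expr.loc[expr["de_class"] == "up", "gene"])
        de_down = set(expr.loc[expr["de_class"] == "down", "gene"])
        report = overlap_analysis({"up_m6a": up_m6a, "coarse_specific_m6a": spec_m6a,
                                   "up_expr": de_up})
        report_down = overlap_analysis({"up_m6a": up_m6a,
                                        "coarse_specific_m6a": spec_m6a,
                                        "down_expr": de_down})
        (outdir / "overlap_report.json").write_text(
            json.dumps({"vs_up": report, "vs_down": report_down}, indent=2))
        done("integrate", n_de=int((expr["de_class"] != "ns").sum()))
    except Exception as exc:  # noqa: BLE001
        fail("integrate", exc)

    # report
    try:
        for f in sorted(outdir.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                files[f.name] = _sha256(f)
        manifest["files"] = files
        done("report", n_files=len(files))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("report", exc)
    return manifest
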
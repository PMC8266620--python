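"""End-to-end pipeline: design -> layout -> masks -> simulate -> profile -> spatial.

Every stage logs its wall time to stderr; all outputs are plain text (FASTA,
FASTQ, TSV, PBM, YAML) under one report directory, and a manifest echoes the
fully resolved configuration so the run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from . import design as _design
from . import io as _io
from . import profiler as _prof
from . import spatial as _spatial
from .config import RunConfig
from .layout import build_layout, generate_masks, write_masks
from .simulate import simulate_synthesis, truth_table

logger = logging.getLogger("maskless")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s ...", name)
    try:
        yield
    except Exception:
        logger.error("stage %s FAILED", name)
        raise
    logger.info("stage %s done in %.2f s", name, time.perf_counter() - t0)


def table1_report(em: _prof.EventMatrix) -> pd.DataFrame:
    """One-row summary mirroring the headline per-bp error-rate table."""
    rates = _prof.per_bp_rates(em)
    subm = _prof.substitution_matrix(em)
    runs = _prof.deletion_run_lengths(em)
    return pd.DataFrame([{
        "total": rates.total,
        "deletion": rates.deletion,
        "insertion": rates.insertion,
        "substitution": rates.substitution,
        "substitution_G_to_T": subm.loc["G", "T"],
        "deletion_x1": runs.loc["1", "rate_bases"],
        "deletion_x2": runs.loc["2", "rate_bases"],
        "deletion_x3": runs.loc["3+", "rate_bases"],
        "mean_deletion_len": rates.mean_deletion_len,
        "mean_insertion_len": rates.mean_insertion_len,
        "n_ref_bases": rates.n_ref_bases,
        "n_reads": em.n_reads,
        "n_unreadable": em.n_unreadable,
    }])


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("design"):
        spec = config.design.spec(config.seed)
        lib = _design.design_library(spec)
        sequences = lib.sequences
        _io.write_fasta(sequences, out / "panel.fasta")
        _io.write_tsv(_design.design_report(lib), out / "design_report.tsv",
                      index=False)

    with _stage("layout"):
        layout = build_layout(config.layout.design,
                              config.layout.geometry(),
                              n_features=config.layout.n_features
                              or len(lib),
                              seed=config.seed, oligo_ids=lib.ids)
        _io.write_tsv(layout.to_frame(), out / "layout.tsv", index=False)

    with _stage("masks"):
        masks = generate_masks(layout, sequences)
        if config.write_masks:
            write_masks(masks, out / "masks")

    with _stage("simulate"):
        photo = config.photochem.params()
        chem = config.chem.params(config.seed)
        readset = simulate_synthesis(sequences, layout, masks, photo, chem)
        readset.to_fastq(out / "reads.fastq")
        truth = truth_table(readset, layout)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    with _stage("profile"):
        em = _prof.align_readset(readset, sequences,
                                 min_identity=config.analysis.min_identity)
        _io.write_tsv(table1_report(em), out / "report.tsv", index=False)
        _io.write_tsv(_prof.substitution_matrix(em),
                      out / "substitution_matrix.tsv")
        _io.write_tsv(_prof.match_matrix(em), out / "match_matrix.tsv")
        _io.write_tsv(_prof.deletion_run_lengths(em),
                      out / "deletion_runs.tsv")
        _io.write_tsv(_prof.per_cycle_rates(em, sequences),
                      out / "per_cycle.tsv")
        _io.write_tsv(_prof.per_position_rates(em), out / "per_position.tsv")
        _io.write_tsv(_prof.insertion_wait_histogram(em).to_frame(),
                      out / "wait_histogram.tsv")
        _io.write_tsv(_prof.dinucleotide_distribution(em),
                      out / "dinucleotide.tsv")
        _io.write_tsv(
            _prof.estimate_coupling_efficiencies(
                em, capped=config.chem.capping_enabled),
            out / "coupling_efficiency.tsv")

    with _stage("spatial"):
        smap = _spatial.feature_profiles(
            em, layout, min_reads=config.analysis.min_reads,
            n_areas=config.analysis.n_areas)
        _io.write_tsv(smap, out / "spatial_map.tsv", index=False)
        _io.write_tsv(_spatial.area_summary(smap), out / "area_summary.tsv")
        bad, blobs = _spatial.detect_unreadable(
            smap, min_reads=config.analysis.min_reads)
        _io.write_tsv(bad, out / "unreadable_features.tsv", index=False)
        _io.write_tsv(pd.DataFrame(blobs), out / "unreadable_blobs.tsv",
                      index=False)
        for metric in ("deletion", "insertion", "substitution"):
            _spatial.export_heatmap(smap, metric,
                                    out / f"heatmap_{metric}.tsv")
        _spatial.export_heatmap(smap, "reads", out / "heatmap_reads.tsv",
                                log_scale=True)

    with _stage("manifest"):
        config.to_yaml(out / "manifest.yaml")

    return out
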
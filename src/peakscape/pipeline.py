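"""End-to-end pipeline orchestration and the machine-readable report.

Stages run in a fixed order — annotate, coloc, quant, targets, motif — and
each emits one JSON-serializable block; stages whose inputs are absent from
the config are skipped, and a failure in one companion track does not abort
the others. The report carries provenance (config hash, seed, package
version) so a rerun with the identical config reproduces it bit-for-bit
apart from nothing: there are no timestamps in the report body.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_peaks, annotations_to_frame, summarize_regions
from .colocalization import colocalization_test
from .genome_io import (read_chrom_sizes, read_coverage, read_de_table,
                        read_gene_models, read_peaks)
from .signal import rpkm_at_peaks, stratified_enrichment
from .simulate import SyntheticConfig, simulate_all
from .stats import mann_whitney
from .targets import call_direct_targets

__all__ = ["run_pipeline", "compare_groups", "significance_stars",
           "load_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

log = logging.getLogger("peakscape")


def significance_stars(p: float) -> str:
    """Encode a p-value as asterisks.

    Cutpoints honour the usual figure-legend convention literally:
    ``****`` p <= 1e-4, ``***`` p <= 1e-3, ``**`` p <= 0.01, ``*`` p < 0.05,
    ``ns`` p >= 0.05.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0,1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(values_by_stratum: Mapping[str, Sequence[float]],
                   pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons between strata with star encoding.

    Pairs whose strata have fewer than 2 values are skipped with a warning.
    No multiple-testing correction is applied by default (per-comparison
    p-values are reported as-is); apply Bonferroni downstream if desired.
    """
    rows = []
    for g1, g2 in pairs:
        x = values_by_stratum.get(g1, [])
        y = values_by_stratum.get(g2, [])
        if len(x) < 2 or len(y) < 2:
            log.warning("skipping comparison %s vs %s: stratum too small", g1, g2)
            continue
        res = mann_whitney(x, y)
        rows.append({"group1": g1, "group2": g2, "n1": res.n1, "n2": res.n2,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "method": res.method,
                     "stars": significance_stars(res.p_value)})
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2",
                                       "statistic", "p_value", "method", "stars"])


def load_config(path: str | Path) -> dict:
    with open(path, "rt", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _validate_inputs(cfg: dict) -> None:
    inputs = cfg.get("inputs", {})
    for key in ("peaks", "genes", "de", "genome", "fasta"):
        entry = inputs.get(key)
        path = entry.get("path") if isinstance(entry, dict) else entry
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input {key!r}: no such file {path}")
    for group in ("peak_tracks", "coverage_tracks"):
        for entry in inputs.get(group, []):
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(
                    f"input {group}: no such file {entry['path']}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Run all applicable stages and return the pipeline report.

    ``config`` is a mapping (or YAML path) with either a ``simulate`` block
    (a SyntheticConfig field mapping) or an ``inputs`` block naming files;
    a ``params`` block tunes thresholds. Input files are validated up front
    so nothing runs against a half-missing configuration.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    params = config.get("params", {})
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.get("simulate", {}).get("seed"),
            "version": __version__,
        },
        "stages": {},
    }

    peak_tracks: dict[str, list] = {}
    coverage_tracks: list = []
    fasta = None
    if "simulate" in config:
        sim_cfg = SyntheticConfig(**config["simulate"])
        sim = simulate_all(sim_cfg)
        peaks, genes, de = sim["peaks"], sim["genes"], sim["de"]
        genome = sim_cfg.chrom_lengths
        annotations = sim["annotations"]
        peak_tracks["coloc"] = sim["coloc_peaks"]
        coverage_tracks = [sim["coverage"]]
    else:
        _validate_inputs(config)
        inputs = config["inputs"]
        peaks = read_peaks(inputs["peaks"]["path"],
                           inputs["peaks"].get("format", "bed6"))
        genes = read_gene_models(inputs["genes"]["path"],
                                 inputs["genes"].get("format", "tsv"))
        genome = read_chrom_sizes(inputs["genome"]) if "genome" in inputs else None
        de = read_de_table(inputs["de"]) if "de" in inputs else None
        for entry in inputs.get("peak_tracks", []):
            peak_tracks[entry.get("label", Path(entry["path"]).stem)] = read_peaks(
                entry["path"], entry.get("format", "bed6"))
        for entry in inputs.get("coverage_tracks", []):
            coverage_tracks.append(read_coverage(
                entry["path"], entry.get("format", "readbed"),
                entry.get("library_size"), entry.get("label")))
        fasta = inputs.get("fasta")
        annotations = None

    # --- annotate ---------------------------------------------------------
    if annotations is None:
        annotations = annotate_peaks(peaks, genes)
    summary = summarize_regions(annotations)
    report["stages"]["annotate"] = {
        "n_peaks": len(annotations),
        "regions": summary.to_dict(orient="records"),
    }
    log.info("annotate: %d peaks classified", len(annotations))

    # --- coloc ------------------------------------------------------------
    if peak_tracks and genome:
        block = {}
        for label, other in peak_tracks.items():
            try:
                res = colocalization_test(peaks, other,
                                          genome, params.get("bin_width"))
                block[label] = res.to_dict()
            except Exception as exc:  # one bad track must not sink the rest
                log.warning("coloc failed for track %s: %s", label, exc)
                block[label] = {"error": str(exc)}
        report["stages"]["coloc"] = block

    # --- quant ------------------------------------------------------------
    if coverage_tracks:
        region_of = {a.peak.name: a.region_class for a in annotations}
        block = {}
        for track in coverage_tracks:
            try:
                signals = rpkm_at_peaks(peaks, track,
                                        flank=params.get("flank", 1000),
                                        chrom_sizes=genome)
                enr = stratified_enrichment(signals, region_of)
                strata_vals: dict[str, list[float]] = {}
                for s in signals:
                    strata_vals.setdefault(region_of[s.peak], []).append(s.rpkm)
                labels = sorted(strata_vals)
                tests = compare_groups(strata_vals,
                                       [(a, b) for i, a in enumerate(labels)
                                        for b in labels[i + 1:]])
                block[track.label] = {
                    "enrichment": enr.to_dict(orient="records"),
                    "comparisons": tests.to_dict(orient="records"),
                }
            except Exception as exc:
                log.warning("quant failed for track %s: %s", track.label, exc)
                block[track.label] = {"error": str(exc)}
        report["stages"]["quant"] = block

    # --- targets ----------------------------------------------------------
    if de is not None:
        calls, tsummary = call_direct_targets(
            de, annotations, lfc_threshold=params.get("lfc", 0.5),
            fdr_threshold=params.get("fdr", 0.05),
            min_mean_count=params.get("min_count", 25),
            max_tss_distance=params.get("max_tss_distance"))
        report["stages"]["targets"] = tsummary.to_dict()
        report["stages"]["targets"]["n_genes"] = len(calls)

    # --- motif ------------------------------------------------------------
    if fasta is not None:
        from .motifs import HNF1B_CONSENSUS, peaks_with_motif

        counts, frac = peaks_with_motif(peaks, fasta,
                                        params.get("motif", HNF1B_CONSENSUS))
        report["stages"]["motif"] = {
            "fraction_with_hit": frac,
            "n_peaks_with_hit": sum(1 for c in counts.values() if c > 0),
        }
    return report
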
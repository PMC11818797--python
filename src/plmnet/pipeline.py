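"""Cohort-to-results orchestration with reproducibility metadata.

A single :class:`PipelineConfig` drives the full chain

    band decomposition -> instantaneous phase -> PLM connectivity
    -> eigenvector centrality -> lobe averaging -> permutation tests
    -> correlations with clinical scores

either from files on disk (signals + cohort CSV + partition CSV) or from
a synthetic :class:`~plmnet.simulate.CohortSpec`.  A manifest with config
snapshot, seeds, and input digests is written before results; identical
config + seed reproduces byte-identical result CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import LobePartition, default_lobe_partition
from .centrality import eigenvector_centrality, lobe_average
from .io import (file_digest, read_cohort_csv, read_subject_signals,
                 write_cohort_csv, write_matrix_csv, write_result_csv,
                 write_signals_csv)
from .plm import PlmConfig, plm_matrix
from .signal import CANONICAL_BANDS, BandDefinition, decompose_bands, \
    instantaneous_phase
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs",
           "subject_lobe_table"]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    output_dir: str | Path = "plmnet_results"
    # Real inputs: a directory of per-subject signal CSVs (or one .h5).
    signals_path: str | Path | None = None
    cohort_csv: str | Path | None = None
    partition_csv: str | Path | None = None
    # Or a synthetic cohort.
    synthetic: CohortSpec | None = None
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    plm: PlmConfig = field(default_factory=PlmConfig)
    n_perm: int = 50_000
    seed: int = 0
    fdr_q: float = 0.05
    subgroup: str | None = None
    correlate_all_pairs: bool = False
    edge_trim_s: float = 1.0

    def __post_init__(self) -> None:
        has_real = self.signals_path is not None or self.cohort_csv is not None
        if has_real and self.synthetic is not None:
            raise ValueError("give either real input paths or a synthetic "
                             "spec, not both")
        if not has_real and self.synthetic is None:
            raise ValueError("one of signals_path+cohort_csv or synthetic "
                             "must be provided")
        if has_real and (self.signals_path is None or self.cohort_csv is None):
            raise ValueError("real input needs both signals_path and cohort_csv")


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        cohort, signals = generate_cohort(config.synthetic)
        sig_map = dict(zip(cohort["subject_id"], signals))
        partition = default_lobe_partition() \
            if config.partition_csv is None \
            else LobePartition.from_csv(config.partition_csv)
        return cohort, sig_map, partition
    cohort = read_cohort_csv(config.cohort_csv)
    path = Path(config.signals_path)
    if path.is_dir():
        sig_map = {}
        for sid in cohort["subject_id"]:
            fp = next((path / f"{sid}{ext}" for ext in (".csv", ".tsv", ".txt")
                       if (path / f"{sid}{ext}").exists()), None)
            if fp is None:
                raise FileNotFoundError(f"no signal file for subject {sid} in {path}")
            sig_map[sid] = read_subject_signals(fp)
    else:
        sig_map = read_subject_signals(path)
    partition = (LobePartition.from_csv(config.partition_csv)
                 if config.partition_csv else default_lobe_partition())
    return cohort, sig_map, partition


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-check label agreement between signals, partition, and cohort.

    Never raises; returns a report dict with a (possibly empty) list of
    failures plus per-file shape information.
    """
    report = {"failures": [], "subjects": {}}
    try:
        cohort, sig_map, partition = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - report, don't raise
        report["failures"].append(f"loading inputs failed: {exc}")
        return report
    bad_groups = set(cohort["group"]) - {"PD", "HC"}
    if bad_groups:
        report["failures"].append(
            f"cohort group labels outside {{PD, HC}}: {sorted(bad_groups)}")
    missing_sig = [s for s in cohort["subject_id"] if s not in sig_map]
    if missing_sig:
        report["failures"].append(f"subjects without signals: {missing_sig}")
    for sid, ts in sig_map.items():
        report["subjects"][sid] = {"n_regions": ts.n_regions,
                                   "n_samples": ts.n_samples, "fs": ts.fs}
        uncovered = [lab for lab in ts.region_labels
                     if lab not in partition.mapping]
        if uncovered:
            report["failures"].append(
                f"subject {sid}: regions missing from partition: "
                f"{uncovered[:5]}")
    return report


def subject_lobe_table(sig_map, partition: LobePartition,
                       bands=CANONICAL_BANDS, plm_cfg: PlmConfig | None = None,
                       edge_trim_s: float = 1.0, out_dir: Path | None = None):
    """Run signal -> PLM -> EC -> lobe stages for every subject and band.

    Returns ``(ec_table, lobe_table)`` DataFrames; optionally writes
    per-subject connectivity matrices under ``out_dir/connectivity``.
    """
    plm_cfg = plm_cfg or PlmConfig()
    ec_rows, lobe_rows = [], []
    conn_dir = None
    if out_dir is not None:
        conn_dir = Path(out_dir) / "connectivity"
        conn_dir.mkdir(parents=True, exist_ok=True)
    for i, (sid, ts) in enumerate(sig_map.items()):
        banded = decompose_bands(ts, bands=tuple(bands))
        for band_name, bts in banded.items():
            phases = instantaneous_phase(bts, edge_s=edge_trim_s).trimmed()
            conn = plm_matrix(phases, band=band_name, cfg=plm_cfg)
            if conn_dir is not None:
                write_matrix_csv(conn.region_labels, conn.values,
                                 conn_dir / f"{sid}_{band_name}.csv")
            cv = eigenvector_centrality(conn)
            for lab, score in zip(cv.region_labels, cv.scores):
                ec_rows.append({"subject_id": sid, "band": band_name,
                                "region_label": lab, "ec": float(score)})
            lc = lobe_average(cv, partition)
            for lobe, val in lc.values.items():
                lobe_rows.append({"subject_id": sid, "band": band_name,
                                  "lobe": lobe, "ec_mean": val})
        logger.info("subject %d/%d (%s) done", i + 1, len(sig_map), sid)
    return pd.DataFrame(ec_rows), pd.DataFrame(lobe_rows)


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: enc(getattr(v, f.name))
                    for f in dataclasses.fields(v)}
        if isinstance(v, (frozenset, set, tuple, list)):
            return [enc(x) for x in v]
        if isinstance(v, Path):
            return str(v)
        return v
    return {f.name: enc(getattr(config, f.name))
            for f in dataclasses.fields(config)}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the results directory.

    Emits per-subject connectivity matrices, region- and lobe-level EC
    tables, permutation and correlation result CSVs, the cohort table, a
    run manifest (config snapshot, software version, input digests,
    per-stage timestamps), and is byte-reproducible for identical
    (config, seed).
    """
    from .model import LobeCentralityModel

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": _config_snapshot(config),
                "stages": {}, "input_digests": {}}

    def stamp(stage):
        manifest["stages"][stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    stamp("load")
    cohort, sig_map, partition = _load_inputs(config)
    for p in (config.cohort_csv, config.partition_csv):
        if p and Path(p).is_file():
            manifest["input_digests"][str(p)] = file_digest(p)
    if config.signals_path and Path(config.signals_path).is_file():
        manifest["input_digests"][str(config.signals_path)] = \
            file_digest(config.signals_path)
    # Manifest written before results, refreshed with timings at the end.
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if config.synthetic is not None:
        write_cohort_csv(cohort, out / "cohort.csv")
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for sid, ts in sig_map.items():
            write_signals_csv(ts, sig_dir / f"{sid}.csv")

    stamp("connectivity")
    ec_table, lobe_table = subject_lobe_table(
        sig_map, partition, bands=config.bands, plm_cfg=config.plm,
        edge_trim_s=config.edge_trim_s, out_dir=out)
    write_result_csv(ec_table, out / "ec_regions.csv")
    write_result_csv(lobe_table, out / "ec_lobes.csv")

    stamp("stats")
    model = LobeCentralityModel(lobe_table, cohort)
    results = model.fit(n_perm=config.n_perm, seed=config.seed,
                        q=config.fdr_q, subgroup=config.subgroup,
                        all_pairs=config.correlate_all_pairs)
    write_result_csv(results.tests, out / "permutation_tests.csv")
    write_result_csv(results.correlations, out / "correlations.csv")
    (out / "summary.txt").write_text(results.summary() + "\n")

    stamp("done")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON key-value document."""
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = dict(raw or {})
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        syn = dict(kwargs["synthetic"])
        if "hub_regions" in syn:
            syn["hub_regions"] = frozenset(syn["hub_regions"])
        if "carrier_band" in syn:
            syn["carrier_band"] = tuple(syn["carrier_band"])
        if "region_labels" in syn and syn["region_labels"] is not None:
            syn["region_labels"] = tuple(syn["region_labels"])
        kwargs["synthetic"] = CohortSpec(**syn)
    if "bands" in kwargs and kwargs["bands"] is not None:
        kwargs["bands"] = tuple(BandDefinition(**b) for b in kwargs["bands"])
    if "plm" in kwargs and kwargs["plm"] is not None:
        kwargs["plm"] = PlmConfig(**kwargs["plm"])
    return PipelineConfig(**kwargs)
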
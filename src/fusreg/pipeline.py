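"""End-to-end orchestration: simulate -> MBA -> diagnostics -> fit -> pool -> ORA.

A single config (YAML/JSON) wires the stages together. Every output table is
TSV with commented provenance header lines carrying the package version and a
hash of the resolved config, so a rerun with the same config and seed is
byte-identical. A JSON run manifest records per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .enrichment import concept_network, network_edge_list, ora, prune_redundant
from .gmt import read_gmt, write_gmt
from .nb_glm import run_models
from .normalization import collinearity, drop_allzero_genes, size_factors, vst_pca
from .pcd import SpectralConfig, WaveformRecord, compute_mba
from .pooling import build_pools, overlap_fraction, pools_to_frame, upset_intersections
from .synthetic import (
    SYNTHETIC_REFERENCE_CENTER,
    SimConfig,
    make_toy_gmt,
    read_counts_tsv,
    read_metadata_tsv,
    simulate_dataset,
    write_counts_tsv,
    write_metadata_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (see the CLI for the file format)."""

    out_dir: str
    seed: int = 0
    counts: Optional[str] = None
    metadata: Optional[str] = None
    waveform_manifest: Optional[str] = None
    waveform_fs: Optional[float] = None
    gmt: Optional[str] = None
    simulate: Optional[Dict[str, Any]] = None
    spectral: Dict[str, Any] = field(default_factory=dict)
    model_alpha: float = 0.05
    ora_alpha: float = 0.01
    min_mean: float = 0.0
    n_top_genes: int = 500
    n_components: int = 2
    ora_min_size: int = 10
    ora_max_size: int = 500
    jaccard_threshold: float = 0.7
    network_top_k: int = 5

    def __post_init__(self) -> None:
        for name in ("model_alpha", "ora_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.simulate is None and (self.counts is None or self.metadata is None):
            raise ValueError("either 'simulate' or both 'counts' and 'metadata' must be given")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False, index_label=None) -> None:
    with open(path, "w") as handle:
        handle.write(f"# fusreg v{__version__} config={cfg_hash}\n")
        df.to_csv(handle, sep="\t", index=index, index_label=index_label)


def compute_mba_from_manifest(
    manifest_path: str | Path, fs: float, spectral: SpectralConfig
) -> pd.DataFrame:
    """Per-sample MBA from a manifest TSV (columns sample_id, pulse_file).

    Pulse files are single-column delimited text (volts), listed in
    acquisition order; all pulses of a sample are appended into one session
    spectrum, giving one MBA value per sample.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", comment="#")
    base = Path(manifest_path).parent
    rows = []
    for sample_id, group in manifest.groupby("sample_id", sort=True):
        pulses = [pd.read_csv(base / f, header=None)[0].to_numpy(dtype=float) for f in group["pulse_file"]]
        rec = WaveformRecord(pulses=pulses, fs=fs)
        res = compute_mba(rec, spectral)
        rows.append(
            {"sample_id": sample_id, "mba": res.mba,
             "harmonic_top_mean": res.harmonic_top_mean,
             "reference_top_mean": res.reference_top_mean}
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> Dict[str, Any]:
    """Execute every stage; returns the run manifest (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    manifest: Dict[str, Any] = {"version": __version__, "config_hash": cfg_hash, "stages": {}}

    # ---- stage: inputs (simulate or load) -------------------------------
    try:
        if cfg.simulate is not None:
            sim = SimConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
            counts, samples, truth = simulate_dataset(sim)
            write_counts_tsv(counts, out / "counts.tsv")
            write_metadata_tsv(samples, out / "metadata.tsv")
            truth.genes.to_csv(out / "ground_truth_genes.tsv", sep="\t", index=False)
        else:
            for name, path in (("counts", cfg.counts), ("metadata", cfg.metadata)):
                if not Path(path).exists():
                    raise FileNotFoundError(f"missing input file: {name} = {path}")
            counts = read_counts_tsv(cfg.counts)
            samples = read_metadata_tsv(cfg.metadata)
    except Exception as err:
        raise PipelineError(f"stage 'inputs' failed: {err}") from err
    manifest["stages"]["inputs"] = {"n_genes": int(len(counts)), "n_samples": int(len(samples))}

    # ---- stage: MBA from waveforms (optional) ---------------------------
    if cfg.waveform_manifest is not None:
        try:
            if cfg.waveform_fs is None:
                raise ValueError("waveform_fs required with waveform_manifest")
            spectral = SpectralConfig(
                reference_center=cfg.spectral.get("reference_center", SYNTHETIC_REFERENCE_CENTER),
                **{k: v for k, v in cfg.spectral.items() if k != "reference_center"},
            )
            mba_tab = compute_mba_from_manifest(cfg.waveform_manifest, cfg.waveform_fs, spectral)
            _write_tsv(mba_tab, out / "mba.tsv", cfg_hash)
            samples = samples.copy()
            for _, row in mba_tab.iterrows():
                samples.loc[samples["sample_id"] == row["sample_id"], "mba"] = row["mba"]
        except Exception as err:
            raise PipelineError(f"stage 'mba' failed: {err}") from err
        manifest["stages"]["mba"] = {"n_sessions": int(len(mba_tab))}

    # ---- stage: diagnostics ---------------------------------------------
    try:
        expressed = drop_allzero_genes(counts)
        sf = size_factors(expressed)
        _write_tsv(sf.to_frame(), out / "size_factors.tsv", cfg_hash, index=True, index_label="sample_id")
        coords, evr = vst_pca(
            expressed, sf,
            n_top_genes=min(cfg.n_top_genes, len(expressed)),
            n_components=cfg.n_components,
        )
        _write_tsv(coords, out / "pca_coordinates.tsv", cfg_hash, index=True, index_label="sample_id")
        report = collinearity(samples)
        with open(out / "collinearity.json", "w") as handle:
            json.dump({**asdict(report), "config_hash": cfg_hash}, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as err:
        raise PipelineError(f"stage 'diagnostics' failed: {err}") from err
    manifest["stages"]["diagnostics"] = {
        "r_squared": report.r_squared, "vif": report.vif, "n_samples_used": report.n_samples_used,
    }

    # ---- stage: regression ----------------------------------------------
    try:
        tables = run_models(counts, samples, min_mean=cfg.min_mean, alpha=cfg.model_alpha)
        for label, table in sorted(tables.items()):
            _write_tsv(table.drop(columns=["gene"]), out / f"fit_{label}.tsv", cfg_hash, index=True)
    except Exception as err:
        raise PipelineError(f"stage 'fit' failed: {err}") from err
    manifest["stages"]["fit"] = {
        label: {"n_genes": int(len(t)), "n_significant": int(t["significant"].sum())}
        for label, t in sorted(tables.items())
    }

    # ---- stage: pooling --------------------------------------------------
    try:
        pools = build_pools(tables, alpha=cfg.model_alpha)
        _write_tsv(pools_to_frame(pools), out / "pools.tsv", cfg_hash)
        overlaps = {}
        for label in sorted(pools):
            metric, tp = label.split("_")
            lin = tables[f"{metric}_linear_{tp}"]
            exp = tables[f"{metric}_exponential_{tp}"]
            overlaps[label] = overlap_fraction(
                set(lin.index[lin["significant"]]), set(exp.index[exp["significant"]])
            )
        pool_list = [pools[k] for k in sorted(pools)]
        for direction, tag in (("+", "pos"), ("-", "neg")):
            _write_tsv(upset_intersections(pool_list, direction), out / f"upset_{tag}.tsv", cfg_hash)
    except Exception as err:
        raise PipelineError(f"stage 'pool' failed: {err}") from err
    manifest["stages"]["pool"] = {
        "n_pools": len(pools),
        "pool_sizes": {k: len(p.members) for k, p in sorted(pools.items())},
        "linear_exponential_overlap": overlaps,
    }

    # ---- stage: enrichment ----------------------------------------------
    try:
        if cfg.gmt is not None:
            collection = read_gmt(cfg.gmt)
        else:
            hi = min(200, len(counts))
            collection = make_toy_gmt(50, (min(10, hi), hi), seed=cfg.seed + 17, universe=list(counts.index))
            write_gmt(collection, out / "gene_sets.gmt")
        ora_counts = {}
        for label in sorted(pools):
            metric, tp = label.split("_")
            universe = set(tables[f"{metric}_linear_{tp}"].index) | set(tables[f"{metric}_exponential_{tp}"].index)
            for direction, tag in (("+", "pos"), ("-", "neg")):
                query = pools[label].direction(direction)
                table = ora(
                    query, universe, collection,
                    min_size=cfg.ora_min_size, max_size=cfg.ora_max_size, alpha=cfg.ora_alpha,
                )
                pruned = prune_redundant(table, collection, universe, cfg.jaccard_threshold)
                _write_tsv(pruned, out / f"ora_{label}_{tag}.tsv", cfg_hash)
                ora_counts[f"{label}_{tag}"] = {
                    "n_tested": int(len(table)),
                    "n_enriched": int(table["enriched"].sum()) if len(table) else 0,
                    "n_after_pruning": int(len(pruned)),
                }
                if len(pruned):
                    graph = concept_network(pruned, pools, top_k=cfg.network_top_k)
                    _write_tsv(network_edge_list(graph), out / f"network_{label}_{tag}.tsv", cfg_hash)
    except Exception as err:
        raise PipelineError(f"stage 'ora' failed: {err}") from err
    manifest["stages"]["ora"] = ora_counts

    with open(out / "run_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
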
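"""End-to-end pipeline driver with a provenance manifest.

Strings the stages together on file inputs: genome-size estimation from
histogram/coverage tables, growth/volume trait construction, phylogenetic
signal and PGLS, path analysis, and the abundance model. Each requested
stage writes TSV outputs plus a JSON manifest recording inputs, seeds,
checksums and package version, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    tree: Path | None = None
    traits: Path | None = None
    kmer_histograms: list[Path] = field(default_factory=list)
    coverage_table: Path | None = None
    read_length: float | None = None
    n_reads: float | None = None
    otu_table: Path | None = None
    station_metadata: Path | None = None
    signal_column: str = "genome_size_log10"
    pgls_formula: str | None = None
    models: Path | None = None
    abundance_variant: str = "temperature"
    chains: int = 2
    iterations: int = 10_000
    stages: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = {"tree", "traits", "coverage_table", "otu_table",
                 "station_metadata", "models", "out_dir"}
        kwargs = {}
        for k, v in raw.items():
            if k in paths and v is not None:
                kwargs[k] = Path(v)
            elif k == "kmer_histograms":
                kwargs[k] = [Path(p) for p in v]
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def validate(self) -> None:
        missing = []
        for p in [self.tree, self.traits, self.coverage_table,
                  self.otu_table, self.station_metadata, self.models,
                  *self.kmer_histograms]:
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _header(cfg: PipelineConfig) -> str:
    return (f"# nucleotype {__version__} | seed={cfg.seed} "
            f"| config_hash={hash_config(cfg)}\n")


def hash_config(cfg: PipelineConfig) -> str:
    text = json.dumps({k: str(v) for k, v in vars(cfg).items()}, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Raises on validation failure before any computation; a stage failure is
    recorded in the manifest (marked failed) and re-raised after writing it.
    """
    from . import abundance as ab
    from . import comparative, genomesize, pathanalysis
    from .phylo import read_newick_file

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.stages or _infer_stages(cfg)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hash_config(cfg),
        "inputs": {
            str(p): _sha256(p)
            for p in [cfg.tree, cfg.traits, cfg.coverage_table, cfg.otu_table,
                      cfg.station_metadata, cfg.models, *cfg.kmer_histograms]
            if p is not None
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    tree = read_newick_file(cfg.tree) if cfg.tree else None
    trait_df = (
        pd.read_csv(cfg.traits, sep="\t", comment="#", index_col="species")
        if cfg.traits else None
    )

    try:
        for stage in stages:
            logger.info("stage: %s", stage)
            if stage == "genomesize":
                rows = []
                for hist_path in cfg.kmer_histograms:
                    hist = genomesize.DepthHistogram.from_tsv(hist_path)
                    est = genomesize.analyze_kmer_histogram(hist)
                    rows.append({"input": str(hist_path), "method": "kmer",
                                 "gs_bp": est.gs_bp, "peak_depth": est.peak_depth})
                if cfg.coverage_table is not None:
                    table = genomesize.ContigCoverageTable.from_tsv(cfg.coverage_table)
                    mode = genomesize.coverage_mode(table)
                    gs = genomesize.lander_waterman_gs(
                        cfg.read_length, cfg.n_reads, mode)
                    rows.append({"input": str(cfg.coverage_table),
                                 "method": "coverage", "gs_bp": gs,
                                 "peak_depth": mode})
                _write(pd.DataFrame(rows), out / "genome_size.tsv", cfg)
            elif stage == "signal":
                res = comparative.pagel_lambda_signal(
                    tree, trait_df[cfg.signal_column])
                _write(pd.DataFrame([vars(res)]), out / "signal.tsv", cfg)
            elif stage == "pgls":
                resp, rhs = (s.strip() for s in cfg.pgls_formula.split("~"))
                preds = [s.strip() for s in rhs.split("+")]
                fit = comparative.pgls_fit(tree, trait_df, resp, preds)
                tab = fit.summary()
                tab["lambda_hat"] = fit.lambda_hat
                tab["r2"] = fit.r2
                _write(tab, out / "pgls.tsv", cfg)
            elif stage == "pathfit":
                models = pathanalysis.model_registry(cfg.models)
                path_df = pathanalysis.path_variables_frame(trait_df)
                ranked, avg = pathanalysis.run_path_analysis(
                    tree, path_df, models)
                _write(pathanalysis.results_table(ranked),
                       out / "path_models.tsv", cfg)
                _write(avg.to_frame(), out / "path_average.tsv", cfg)
            elif stage == "abundance":
                otu = pd.read_csv(cfg.otu_table, sep="\t", comment="#")
                meta = pd.read_csv(cfg.station_metadata, sep="\t", comment="#")
                agg = ab.aggregate_species(otu)
                agg = ab.filter_prevalence(agg)
                tab = agg.merge(meta, on="sample_id")
                tab = tab.merge(
                    trait_df[["genome_size_log10"]], left_on="species",
                    right_index=True)
                fit = ab.fit_gamma_abundance(
                    tab, tree, variant=cfg.abundance_variant,
                    chains=cfg.chains, iterations=cfg.iterations,
                    seed=cfg.seed)
                _write(fit.summary(), out / "abundance_fit.tsv", cfg)
                _write(ab.predict_interaction(fit),
                       out / "abundance_predictions.tsv", cfg)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["stages"][stage] = "ok"
    except Exception:
        manifest["stages"][stage] = "failed"
        manifest["failed"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _infer_stages(cfg: PipelineConfig) -> list[str]:
    stages = []
    if cfg.kmer_histograms or cfg.coverage_table is not None:
        stages.append("genomesize")
    if cfg.tree is not None and cfg.traits is not None:
        stages.append("signal")
        if cfg.pgls_formula:
            stages.append("pgls")
        stages.append("pathfit")
    if cfg.otu_table is not None and cfg.station_metadata is not None:
        stages.append("abundance")
    return stages
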
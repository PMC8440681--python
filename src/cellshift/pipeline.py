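"""End-to-end pipeline: (simulate|load) -> QC -> embed -> shift -> contrasts.

Every stage is a pure function of (inputs, config, seed); rerunning with an
identical config reproduces all numeric outputs byte for byte.  A manifest
records the config echo, per-stage timings, and cell/gene counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from . import contrast, embed, io, qc, shift, simulate
from .errors import CellshiftError, ValidationError


def _package_version() -> str:
    try:
        return metadata.version("cellshift")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class PipelineConfig:
    """Declarative run description; mirrors the CLI flags."""

    out_dir: str = "cellshift_out"
    seed: int = 0
    # either a triplet directory + annotation, or a simulation recipe
    counts_dir: str | None = None
    annotation_path: str | None = None
    simulate: dict | None = None
    gmt_path: str | None = None
    qc: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    scale_total: float = embed.DEFAULT_SCALE_TOTAL
    hvg_n: int = embed.DEFAULT_N_HVGS
    pcs: int = embed.DEFAULT_N_PCS
    clip: float = embed.DEFAULT_CLIP
    n_sub: int = 500
    n_reps: int = 100
    min_cluster_size: int = 500
    cov_mode: str = "full"
    lfc_threshold: float = contrast.DEFAULT_LFC_THRESHOLD
    p_threshold: float = contrast.DEFAULT_P_THRESHOLD
    use_adjusted: bool = False
    min_frac_expressing: float = contrast.DEFAULT_MIN_FRAC

    def validate(self) -> None:
        has_files = self.counts_dir is not None and self.annotation_path is not None
        if bool(self.simulate) == has_files:
            raise ValidationError(
                "config must specify exactly one of counts_dir + "
                "annotation_path or a 'simulate' section"
            )
        for p in (self.counts_dir, self.annotation_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    def scheme(self) -> shift.SubsampleScheme:
        return shift.SubsampleScheme(
            n_sub=self.n_sub,
            n_reps=self.n_reps,
            min_cluster_size=self.min_cluster_size,
            seed=self.seed,
            cov_mode=self.cov_mode,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        return d


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    qc_raw = raw.pop("qc", {})
    cfg = PipelineConfig(**raw)
    if qc_raw:
        cfg.qc = qc.QCThresholds(**qc_raw)
    return cfg


def build_synthetic_spec(params: dict, seed: int) -> simulate.SyntheticSpec:
    """Turn a plain-dict simulation section into a SyntheticSpec."""
    params = dict(params)
    if "clusters" in params:
        params["clusters"] = tuple(
            simulate.ClusterSpec(**c) if isinstance(c, dict) else c
            for c in params["clusters"]
        )
    if "shift" in params:
        params["shift"] = {
            k: (simulate.ShiftSpec(**v) if isinstance(v, dict) else v)
            for k, v in params["shift"].items()
        }
    if "organelle" in params and isinstance(params["organelle"], dict):
        params["organelle"] = simulate.OrganelleSpec(**params["organelle"])
    params.setdefault("seed", seed)
    return simulate.SyntheticSpec(**params)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write outputs under ``config.out_dir``, and
    return the manifest (also written as ``manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cellshift",
        "version": _package_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def finish(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }

        return finish

    try:
        done = _stage("input")
        if config.simulate:
            spec = build_synthetic_spec(config.simulate, config.seed)
            counts, annotation, truth = simulate.generate_dataset(spec)
            io.write_counts_mtx(counts, out / "simulated_counts")
            io.write_cell_annotation(annotation, out / "annotation.tsv")
            _write_tsv(truth.cells, out / "truth_cells.tsv")
            _write_tsv(truth.genes, out / "truth_genes.tsv")
        else:
            counts = io.read_counts_mtx(config.counts_dir)
            annotation = io.read_cell_annotation(config.annotation_path)
        done(n_genes=counts.n_genes, n_cells=counts.n_cells)

        done = _stage("qc")
        filtered, report = qc.apply_qc_filters(counts, config.qc)
        (out / "qc_report.json").write_text(report.to_json())
        io.write_counts_mtx(filtered, out / "filtered_counts")
        kept = set(filtered.barcodes)
        annotation = annotation[annotation["barcode"].isin(kept)].reset_index(drop=True)
        done(n_genes=filtered.n_genes, n_cells=filtered.n_cells)

        done = _stage("embed")
        nm = embed.log_normalize(filtered, config.scale_total)
        hvgs = embed.select_hvgs(nm, config.hvg_n)
        scaled, _ = embed.scale_center(nm, hvgs, config.clip)
        k_eff = min(config.pcs, min(scaled.shape))
        embedding = embed.pca_embed(scaled, nm.barcodes, K=k_eff, seed=config.seed)
        _write_tsv(embedding.to_frame(), out / "embedding.tsv")
        done(n_hvgs=len(hvgs), n_pcs=k_eff)

        done = _stage("shift")
        summary, reps, skipped = shift.shift_by_cell_type(
            embedding, annotation, config.scheme()
        )
        _write_tsv(summary, out / "shift_summary.tsv")
        _write_tsv(reps, out / "shift_replicates.tsv")
        done(n_cell_types=len(summary), skipped=skipped)

        done = _stage("degs")
        deg_counts = contrast.deg_counts_per_cluster(
            nm,
            annotation,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
            min_frac_expressing=config.min_frac_expressing,
        )
        _write_tsv(deg_counts, out / "deg_counts.tsv")
        done(n_clusters=len(deg_counts))

        if config.gmt_path:
            done = _stage("genesets")
            sets = io.read_gmt(config.gmt_path)
            activity = contrast.geneset_activity(nm, annotation, sets, group_by="cluster")
            _write_tsv(activity.activity, out / "geneset_activity.tsv")
            cond = contrast.geneset_activity(nm, annotation, sets, group_by="condition")
            lfc = cond.log_fold_change("case", "control")
            _write_tsv(lfc, out / "geneset_condition_lfc.tsv")
            done(n_sets=len(sets), skipped=activity.skipped_sets)

        done = _stage("proportions")
        props = contrast.proportion_shift(annotation)
        _write_tsv(props, out / "proportions.tsv")
        done(n_clusters=len(props))
    except CellshiftError as exc:
        stage = next(reversed(manifest["stages"]), "input")
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
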
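"""End-to-end orchestration: normalize -> de -> homology -> enrichment ->
discover, with a structured config, per-stage logging and a JSON manifest.

Every published cut-off is a named, defaulted config field (CPM > 1 filter,
RPKM >= 0.3 expressed call, FDR < 0.05, minimum 10 GO mapping entries,
k in [2, 10], centroid correlation r > 0.99), so a default run reproduces
the method as described.  Stage outputs are pure functions of (inputs,
config, seed); rerunning with the same config reproduces every output
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import diffexp as de
from . import enrichment as en
from . import homology as hm
from . import normalize as nm
from .data_io import read_annotation, read_counts

logger = logging.getLogger("floraltime")

ALL_STAGES = ("normalize", "de", "homology", "enrichment", "discover")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for one pipeline run."""

    counts_path: str = "counts.tsv"
    samples_path: str = "samples.tsv"
    lengths_path: str = "lengths.tsv"
    homologues_path: str | None = "homologues.tsv"
    flowering_path: str | None = "flowering.tsv"
    tf_path: str | None = "tf_families.tsv"
    go_path: str | None = "go_terms.tsv"
    outdir: str = "results"

    min_cpm: float = 1.0
    rpkm_threshold: float = 0.3
    trim_m: float = 0.3
    trim_a: float = 0.05
    fdr: float = 0.05
    min_go_entries: int = 10
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 50
    gap_refs: int = 50
    r_threshold: float = 0.99
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})

    def validate(self) -> None:
        if not (0 <= self.fdr <= 1 and -1 <= self.r_threshold <= 1):
            raise ValueError("fdr must be in [0,1] and r_threshold in [-1,1]")
        if self.rpkm_threshold < 0 or self.min_cpm < 0 or self.min_go_entries < 1:
            raise ValueError("thresholds out of range")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest (also
    written to ``<outdir>/manifest.json``).

    Stage dependencies are resolved in memory: e.g. `discover` recomputes
    normalization and DE internally if those stages' outputs are toggled
    off, so toggles control what is written, not what is computable.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in ALL_STAGES if config.stages.get(s, True)]
    need_norm = bool(set(enabled) & {"normalize", "de", "enrichment", "discover"})
    need_de = bool(set(enabled) & {"de", "enrichment", "discover"})

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_enabled": enabled,
        "stages_completed": [],
        "outputs": [],
        "counts": {},
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        _tsv(df, path, index=index)
        manifest["outputs"].append(name)

    # ---- shared inputs -------------------------------------------------
    try:
        cm = read_counts(config.counts_path, config.samples_path)
        annotation = read_annotation(
            config.lengths_path,
            homologue_path=config.homologues_path,
            flowering_path=config.flowering_path,
            tf_path=config.tf_path,
            go_path=config.go_path,
        )
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError("inputs", exc) from exc
    manifest["counts"]["genes_input"] = cm.n_genes
    manifest["counts"]["samples"] = cm.n_samples

    filtered = nf = profiles = None
    if need_norm:
        try:
            filtered = nm.filter_low_counts(cm, min_cpm=config.min_cpm)
            nf = nm.tmm_factors(filtered, trim_m=config.trim_m, trim_a=config.trim_a)
            profiles = nm.cpm_rpkm(filtered, nf, annotation,
                                   rpkm_threshold=config.rpkm_threshold)
            categories = nm.classify_expression(profiles)
            mds = nm.mds_qc(filtered, nf)
        except Exception as exc:
            raise StageError("normalize", exc) from exc
        manifest["counts"]["genes_filtered"] = filtered.n_genes
        manifest["counts"]["genes_expressed"] = int(profiles.expressed_any().sum())
        if "normalize" in enabled:
            emit("normalization.tsv", nf.to_frame())
            expr_out = pd.concat(
                [profiles.mean_rpkm.add_prefix("mean_rpkm_"), categories], axis=1)
            expr_out.index.name = "gene_id"
            emit("expression.tsv", expr_out, index=True)
            emit("mds.tsv", mds.rename_axis("sample_id"), index=True)
            manifest["stages_completed"].append("normalize")
            logger.info("normalize: %d/%d genes kept, %d expressed",
                        filtered.n_genes, cm.n_genes,
                        manifest["counts"]["genes_expressed"])

    de_results = deg_summary = None
    if need_de:
        try:
            disp = de.estimate_common_dispersion(filtered, nf)
            de_results = de.fit_and_test(filtered, nf, disp.phi,
                                         fdr_threshold=config.fdr)
            deg_summary = de.summarize_degs(de_results)
        except Exception as exc:
            raise StageError("de", exc) from exc
        manifest["counts"]["common_dispersion"] = disp.phi
        manifest["counts"]["degs"] = int(deg_summary.shape[0])
        if "de" in enabled:
            for name, sub in de_results.groupby("contrast"):
                emit(f"de_{name}.tsv", sub.drop(columns="contrast"))
            emit("deg_summary.tsv", deg_summary, index=True)
            manifest["stages_completed"].append("de")
            logger.info("de: phi=%.4g, %d DEGs", disp.phi, deg_summary.shape[0])

    if "homology" in enabled:
        try:
            flowering_at = {a.arabidopsis_homologue for a in annotation.values()
                            if a.is_flowering_homologue and a.arabidopsis_homologue}
            if config.flowering_path is not None:
                flowering_at |= set(
                    pd.read_csv(config.flowering_path, sep="\t", header=None,
                                comment="#")[0].astype(str))
            spectrum = hm.copy_number_spectrum(annotation, flowering_at)
            test = hm.duplication_test(spectrum)
        except Exception as exc:
            raise StageError("homology", exc) from exc
        emit("copy_number.tsv", spectrum.table.rename_axis("arabidopsis_id"), index=True)
        (out / "duplication_test.json").write_text(json.dumps({
            "chi2": test.chi2, "df": test.df, "p": test.p, "n": test.n,
            "observed": test.observed.tolist(),
            "missing_flowering_homologues": len(spectrum.missing_flowering),
            "total_flowering_homologues": spectrum.n_flowering_homologues,
        }, indent=2, sort_keys=True))
        manifest["outputs"].append("duplication_test.json")
        manifest["counts"]["flowering_homologues"] = spectrum.n_flowering_homologues
        manifest["stages_completed"].append("homology")

    expressed_genes = degs_by_contrast = None
    if need_de:
        expressed_mask = profiles.expressed_any()
        expressed_genes = set(expressed_mask.index[expressed_mask])
        degs_by_contrast = de.deg_gene_sets(de_results)

    if "enrichment" in enabled:
        try:
            go_map = {g: set(a.go_terms) for g, a in annotation.items()}
            universe = {g for g in expressed_genes if go_map.get(g)}
            n_go_runs = 0
            for contrast, sets in degs_by_contrast.items():
                for direction in ("up", "down"):
                    genes = {g for g in sets[direction] if g in universe}
                    res = en.go_enrichment(genes, universe, go_map,
                                           min_entries=config.min_go_entries,
                                           fdr_threshold=config.fdr)
                    emit(f"go_{contrast}_{direction}.tsv", res)
                    n_go_runs += 1
            tf_map = {g: a.tf_family for g, a in annotation.items()
                      if a.tf_family is not None}
            all_degs = set(deg_summary.index) & expressed_genes
            flowering = {g for g, a in annotation.items() if a.is_flowering_homologue}
            tf_res = en.tf_family_enrichment(all_degs, expressed_genes, tf_map,
                                             flowering_genes=flowering,
                                             fdr_threshold=config.fdr)
            emit("tf_enrichment.tsv", tf_res)
        except Exception as exc:
            raise StageError("enrichment", exc) from exc
        manifest["counts"]["go_runs"] = n_go_runs
        manifest["counts"]["tf_families_tested"] = int(tf_res.shape[0])
        manifest["stages_completed"].append("enrichment")

    if "discover" in enabled:
        try:
            all_degs = set(deg_summary.index)
            flowering_degs = [g for g in deg_summary.index
                              if annotation[g].is_flowering_homologue]
            uncharacterized_degs = [
                g for g in all_degs
                if annotation[g].homologue_status in ("unknown_function", "no_homologue")
                and g not in set(flowering_degs)]
            profiles_tp = cl.timepoint_mean_log_cpm(filtered, nf)
            z = cl.zscore(profiles_tp)
            z_flower = z.loc[z.index.intersection(flowering_degs)]
            model = cl.select_k_and_cluster(
                z_flower, k_range=(config.k_min, config.k_max), seed=config.seed,
                restarts=config.kmeans_restarts, gap_refs=config.gap_refs)
            z_pool = z.loc[z.index.intersection(uncharacterized_degs)]
            matches = cl.match_candidates(model, z_pool, threshold=config.r_threshold)
        except Exception as exc:
            raise StageError("discover", exc) from exc
        clusters_out = pd.concat(
            [model.assignments, z_flower.add_prefix("z")], axis=1).rename_axis("gene_id")
        emit("clusters.tsv", clusters_out, index=True)
        matches = matches.merge(
            pd.Series({g: annotation[g].homologue_status for g in matches["gene_id"]},
                      name="status").rename_axis("gene_id"),
            left_on="gene_id", right_index=True)
        emit("candidates.tsv", matches)
        manifest["counts"]["k_selected"] = model.k
        manifest["counts"]["index_votes"] = model.index_votes
        manifest["counts"]["flowering_degs_clustered"] = int(z_flower.shape[0])
        manifest["counts"]["candidate_pool"] = int(z_pool.shape[0])
        manifest["counts"]["candidates"] = int(matches["is_candidate"].sum())
        manifest["stages_completed"].append("discover")
        logger.info("discover: k=%d, %d candidates of %d uncharacterized DEGs",
                    model.k, manifest["counts"]["candidates"], z_pool.shape[0])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
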
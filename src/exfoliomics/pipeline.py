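"""End-to-end orchestration of the analysis stages with provenance.

Stage order mirrors the analysis workflow: filter -> normalize ->
dispersion/BCV -> ordination/ANOSIM -> differential expression ->
intersections/MA tables -> sparse CCA -> LDA ranking -> marker scores.
Every written table gets a JSON provenance sidecar recording input
checksums, parameters, the seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from exfoliomics import __version__, io
from exfoliomics.matrix import CountMatrix
from exfoliomics.simulate import SimulationParams, simulate_counts
from exfoliomics import concordance, diffexpr, lda, ordination, preprocess, sparse_cca

logger = logging.getLogger("exfoliomics")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    sources: tuple = ("SI", "colon", "exfoliome")
    filter_min_samples: int = 4
    filter_min_total: int = 50
    fdr_threshold: float = 0.05
    lda_error_threshold: float = 0.05
    anosim_permutations: int = 999
    cca_grid_density: int = 3
    cca_components: int = 2
    cca_max_genes: int = 400
    cca_partner: str = "exfoliome"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not 0 < self.lda_error_threshold < 1:
            raise ValueError("lda_error_threshold must be in (0, 1)")
        if self.anosim_permutations < 1:
            raise ValueError("anosim_permutations must be >= 1")
        if self.cca_components < 1 or self.cca_grid_density < 1:
            raise ValueError("cca settings must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sources" in raw:
            raw["sources"] = tuple(raw["sources"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_provenance(out_path: Path, inputs: list[Path], params: dict, seed) -> None:
    side = Path(str(out_path) + ".prov.json")
    record = {
        "output": out_path.name,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "params": params,
        "seed": seed,
        "version": __version__,
    }
    side.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def simulate_to_dir(params: SimulationParams, out_dir) -> Path:
    """Write a self-contained simulated dataset (counts, metadata, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, truth = simulate_counts(params)
    meta_frames = []
    for source, cm in matrices.items():
        io.write_counts_tsv(cm, out / f"counts_{source}.tsv")
        meta_frames.append(cm.samples)
    io.write_metadata_tsv(pd.concat(meta_frames), out / "metadata.tsv")
    io.write_json(truth.to_dict(), out / "ground_truth.json")
    io.write_gene_list(sorted(truth.hk_gene_ids), out / "housekeeping_genes.txt")
    io.write_marker_panel(truth.marker_panel, out / "marker_panel.tsv")
    write_provenance(
        out / "ground_truth.json", [], asdict(params) | {"stage": "simulate"},
        params.seed,
    )
    return out


def _load_source(input_dir: Path, source: str, meta: pd.DataFrame) -> CountMatrix:
    path = input_dir / f"counts_{source}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing counts table for source {source}: {path}")
    cm = io.read_counts_tsv(path)
    return CountMatrix(cm.counts, meta.loc[meta["source"] == source])


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on the datasets under ``config.input_dir``."""
    config.validate()
    t0 = time.time()
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = input_dir / "metadata.tsv"
    meta = io.read_metadata_tsv(meta_path)

    hk_path = input_dir / "housekeeping_genes.txt"
    hk_genes = io.read_gene_list(hk_path) if hk_path.exists() else None
    panel_path = input_dir / "marker_panel.tsv"
    panel = io.read_marker_panel(panel_path) if panel_path.exists() else None

    summary: dict = {"stages": {}, "seed": config.seed}
    logcpm_by_source: dict[str, pd.DataFrame] = {}
    de_by_source: dict[str, pd.DataFrame] = {}
    de_sets: dict[str, set] = {}

    for source in config.sources:
        stage_t = time.time()
        logger.info("stage filter/normalize: %s", source)
        cm = _load_source(input_dir, source, meta)
        inputs = [input_dir / f"counts_{source}.tsv", meta_path]

        filtered, report = preprocess.filter_low_abundance(
            cm, config.filter_min_samples, config.filter_min_total
        )
        io.write_counts_tsv(filtered, out / f"filtered_{source}.tsv")
        io.write_json(report.to_dict(), out / f"filter_report_{source}.json")
        write_provenance(
            out / f"filtered_{source}.tsv",
            inputs,
            {
                "stage": "filter",
                "min_samples": config.filter_min_samples,
                "min_total": config.filter_min_total,
            },
            config.seed,
        )

        norm = preprocess.upper_quartile_factors(filtered)
        norm.to_frame().to_csv(out / f"normalization_{source}.tsv", sep="\t")
        logcpm = preprocess.cpm(filtered, norm, log=True)
        logcpm.to_csv(out / f"logcpm_{source}.tsv", sep="\t")
        logcpm_by_source[source] = logcpm

        if hk_genes:
            frac = preprocess.housekeeping_fraction(cm, hk_genes)
            frac.rename("hk_fraction").to_csv(out / f"hk_fraction_{source}.tsv", sep="\t")

        groups = filtered.groups()
        disp = diffexpr.estimate_common_dispersion(filtered, groups, norm)
        io.write_json(
            {"common_dispersion": disp.common_dispersion, "bcv": disp.bcv},
            out / f"dispersion_{source}.json",
        )

        cpm_mat = preprocess.cpm(filtered, norm, log=False)
        dist = ordination.bray_curtis(cpm_mat)
        dist.to_csv(out / f"braycurtis_{source}.tsv", sep="\t")
        res = ordination.anosim(
            dist, groups, n_perm=config.anosim_permutations, seed=config.seed
        )
        io.write_json(res.to_dict(), out / f"anosim_{source}.json")
        coords, stress, _ = ordination.nmds(dist, seed=config.seed)
        coords.assign(stress=stress).to_csv(out / f"nmds_{source}.tsv", sep="\t")
        mds_coords, _ = ordination.mds_leading_logfc(logcpm)
        mds_coords.to_csv(out / f"mds_{source}.tsv", sep="\t")

        de = diffexpr.exact_test(filtered, disp, groups, norm)
        de.to_csv(out / f"de_{source}.tsv", sep="\t")
        write_provenance(
            out / f"de_{source}.tsv",
            inputs,
            {"stage": "de", "dispersion": disp.common_dispersion},
            config.seed,
        )
        de_by_source[source] = de
        de_sets[source] = set(de.index[de["fdr"] < config.fdr_threshold])

        ranking = lda.rank_features(
            logcpm.loc[sorted(de_sets[source])], groups,
            threshold=config.lda_error_threshold,
        )
        ranking.to_csv(out / f"lda_ranking_{source}.tsv", sep="\t")

        if panel:
            scores = concordance.marker_scores(cm, panel)
            scores.to_csv(out / f"marker_scores_{source}.tsv", sep="\t", index=False)

        summary["stages"][source] = {
            "genes_after_filter": report.genes_after,
            "common_dispersion": disp.common_dispersion,
            "bcv": disp.bcv,
            "anosim_R": res.r_statistic,
            "anosim_p": res.p_value,
            "n_de": len(de_sets[source]),
            "n_lda_selected": int(ranking["selected"].sum()),
        }
        logger.info("stage %s done in %.2fs", source, time.time() - stage_t)

    if len(de_sets) >= 2:
        io.write_json(
            diffexpr.intersect_gene_sets(de_sets), out / "venn_de.json"
        )
        partner = config.cca_partner
        for source in config.sources:
            if source == partner:
                continue
            ma = diffexpr.ma_table(
                de_by_source[source],
                de_here=de_sets[source],
                de_other=de_sets.get(partner, set()) & set(de_by_source[source].index),
            )
            ma.to_csv(out / f"ma_{source}.tsv", sep="\t")

    partner = config.cca_partner
    if partner in logcpm_by_source:
        for source in config.sources:
            if source == partner:
                continue
            pair_name = f"{partner}_vs_{source}"
            logger.info("stage cca: %s", pair_name)
            x, y, x_ids, y_ids = _paired_matrices(
                logcpm_by_source[partner], logcpm_by_source[source], meta,
                config.cca_max_genes,
            )
            (c1, c2), table = sparse_cca.loo_cv_tune(
                x, y, grid_density=config.cca_grid_density
            )
            fit = sparse_cca.fit_sparse_cca(
                x, y, c1, c2, n_components=config.cca_components
            )
            fit.u.to_csv(out / f"cca_{pair_name}_u.tsv", sep="\t")
            fit.v.to_csv(out / f"cca_{pair_name}_v.tsv", sep="\t")
            score_table = sparse_cca.cca_score_table(fit, meta, x_ids, y_ids)
            score_table.to_csv(out / f"cca_{pair_name}_scores.tsv", sep="\t")
            io.write_json(
                {
                    "c1": c1,
                    "c2": c2,
                    "objective": fit.d.tolist(),
                    "score_correlation": fit.score_correlation.tolist(),
                    "criterion_table": table.to_dict(orient="records"),
                },
                out / f"cca_{pair_name}_tuning.json",
            )
            summary["stages"][f"cca_{pair_name}"] = {
                "c1": c1,
                "c2": c2,
                "component1_correlation": float(fit.score_correlation[0]),
            }

    logger.info("pipeline done in %.2fs", time.time() - t0)
    io.write_json(summary, out / "run_summary.json")
    write_provenance(
        out / "run_summary.json", [meta_path], asdict(config), config.seed
    )
    return out


def _paired_matrices(
    logcpm_x: pd.DataFrame,
    logcpm_y: pd.DataFrame,
    meta: pd.DataFrame,
    max_genes: Optional[int],
):
    """Samples-by-genes matrices for two sources, rows paired by subject."""
    sub_x = meta.loc[logcpm_x.columns]
    sub_y = meta.loc[logcpm_y.columns]
    shared_subjects = [s for s in sub_x["subject"] if s in set(sub_y["subject"])]
    x_ids = [sub_x.index[sub_x["subject"] == s][0] for s in shared_subjects]
    y_ids = [sub_y.index[sub_y["subject"] == s][0] for s in shared_subjects]
    shared_genes = logcpm_x.index.intersection(logcpm_y.index)
    if max_genes is not None and len(shared_genes) > max_genes:
        spread = (
            logcpm_x[x_ids].loc[shared_genes].var(axis=1)
            + logcpm_y[y_ids].loc[shared_genes].var(axis=1)
        )
        shared_genes = spread.nlargest(max_genes).index
    x = logcpm_x.loc[shared_genes, x_ids].T
    y = logcpm_y.loc[shared_genes, y_ids].T
    return x, y, x_ids, y_ids
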
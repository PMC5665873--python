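"""Coupled three-source negative-binomial count simulator with ground truth.

Generates one count matrix per RNA source (small-intestinal mucosa, colonic
mucosa, exfoliated cells) over a shared gene universe.  The same per-gene
baseline abundances drive all sources, so cross-source expression profiles
are strongly rank-correlated; a treatment effect is injected into a
configurable subset of genes and expressed only in the sources listed in
``shared_effect_sources``.  Per-source library sizes and dispersions default
to values on the scale observed in paired tissue/stool sequencing: the
exfoliated-cell library is an order of magnitude smaller than the tissue
libraries (non-host RNA displaces host reads) and has the largest
biological variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from exfoliomics.matrix import CountMatrix

SOURCES = ("SI", "colon", "exfoliome")

#: Mean per-sample library sizes (reads), before ``lib_scale`` division.
DEFAULT_LIB_SIZE_MEAN = {"SI": 27e6, "colon": 39e6, "exfoliome": 3.8e6}

#: Per-source negative-binomial dispersions (BCV^2).
DEFAULT_DISPERSION = {"SI": 0.143, "colon": 0.126, "exfoliome": 0.592}

#: Default cell-type / anatomic-site marker panel, instantiated against the
#: simulated gene universe by :func:`make_marker_panel`.
DEFAULT_MARKER_CELL_TYPES = (
    "enterocyte",
    "goblet",
    "paneth",
    "colonocyte",
    "stem",
    "immune",
)


def _default_lib_means() -> dict[str, float]:
    return dict(DEFAULT_LIB_SIZE_MEAN)


def _default_dispersions() -> dict[str, float]:
    return dict(DEFAULT_DISPERSION)


@dataclass
class SimulationParams:
    """Parameters of the three-source count simulation.

    ``lib_size_mean`` holds full-experiment library sizes; ``lib_scale``
    divides them so desk-scale runs stay cheap while preserving the
    inter-source ratios.  ``contamination_fraction`` shrinks the exfoliome
    library further (modelling displacement of host reads by non-host RNA;
    no non-host reads are emitted).  ``dropout_quantile`` zeroes the
    lowest-abundance fraction of genes in the exfoliome, emulating the
    smaller detected-gene universe of stool RNA.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    sources: Sequence[str] = SOURCES
    lib_size_mean: Mapping[str, float] = field(default_factory=_default_lib_means)
    lib_scale: float = 50.0
    lib_cv: float = 0.2
    dispersion: Mapping[str, float] = field(default_factory=_default_dispersions)
    de_fraction: float = 0.1
    lfc_magnitude: float = 3.5
    shared_effect_sources: Sequence[str] = ("SI", "exfoliome")
    contamination_fraction: float = 0.0
    dropout_quantile: float = 0.25
    dropout_sources: Sequence[str] = ("exfoliome",)
    hk_gene_count: int = 532
    marker_genes_per_type: int = 3
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("de_fraction", "contamination_fraction", "dropout_quantile"):
            val = float(getattr(self, name))
            if not np.isfinite(val) or not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a finite fraction in [0, 1]")
        for src in self.sources:
            phi = float(self.dispersion.get(src, np.nan))
            if not np.isfinite(phi) or phi < 0:
                raise ValueError(f"dispersion for {src!r} must be finite and >= 0")
            lib = float(self.lib_size_mean.get(src, np.nan))
            if not np.isfinite(lib) or lib <= 0:
                raise ValueError(f"lib_size_mean for {src!r} must be finite and > 0")
        if not np.isfinite(self.lfc_magnitude):
            raise ValueError("lfc_magnitude must be finite")
        if self.lib_scale <= 0 or not np.isfinite(self.lib_scale):
            raise ValueError("lib_scale must be finite and > 0")
        if self.lib_cv < 0 or not np.isfinite(self.lib_cv):
            raise ValueError("lib_cv must be finite and >= 0")
        if self.hk_gene_count >= self.n_genes:
            raise ValueError("hk_gene_count must be smaller than n_genes")
        unknown = set(self.shared_effect_sources) - set(self.sources)
        if unknown:
            raise ValueError(f"shared_effect_sources not in sources: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Truth annotations emitted alongside simulated counts."""

    de_gene_ids: dict[str, set]
    baseline_mean: pd.Series
    true_lfc: pd.Series
    hk_gene_ids: set
    marker_panel: dict[str, list[str]]
    dropped_gene_ids: dict[str, set]

    def to_dict(self) -> dict:
        return {
            "de_gene_ids": {s: sorted(v) for s, v in self.de_gene_ids.items()},
            "baseline_mean": self.baseline_mean.to_dict(),
            "true_lfc": self.true_lfc.to_dict(),
            "hk_gene_ids": sorted(self.hk_gene_ids),
            "marker_panel": self.marker_panel,
            "dropped_gene_ids": {s: sorted(v) for s, v in self.dropped_gene_ids.items()},
        }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Draw NB counts with variance mean + phi*mean^2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    params: SimulationParams,
) -> tuple[dict[str, CountMatrix], GroundTruth]:
    """Simulate one count matrix per source plus ground-truth annotations.

    Counts for gene g in sample i of source s are negative binomial with
    mean ``baseline_g / sum(baseline) * lib_i * 2^(lfc_g)`` when the sample
    is treated and the source carries the effect, and dispersion
    ``params.dispersion[s]``.  The draw order is fixed, so a given seed
    yields bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes = pd.Index([f"g{i:05d}" for i in range(params.n_genes)], name="gene")
    baseline = pd.Series(
        rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, params.n_genes),
        index=genes,
    )
    rel_abundance = baseline / baseline.sum()

    # treatment effects are placed on genes outside the exfoliome dropout
    # band so the shared effect is observable in every affected source
    order = np.argsort(baseline.to_numpy(), kind="stable")
    n_drop = int(np.floor(params.dropout_quantile * params.n_genes))
    dropped_genes = set(genes[order[:n_drop]])
    eligible = genes[order[n_drop:]]

    n_de = int(round(params.de_fraction * params.n_genes))
    n_de = min(n_de, len(eligible))
    de_genes = pd.Index(
        rng.choice(eligible.to_numpy(), size=n_de, replace=False)
    ).sort_values()
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = pd.Series(0.0, index=genes)
    true_lfc.loc[de_genes] = signs * params.lfc_magnitude

    hk_pool = [g for g in eligible if g not in set(de_genes)]
    if params.hk_gene_count > len(hk_pool):
        raise ValueError(
            f"hk_gene_count={params.hk_gene_count} exceeds the "
            f"{len(hk_pool)} non-DE, non-dropout genes; increase n_genes"
        )
    hk_genes = set(
        rng.choice(np.asarray(hk_pool), size=params.hk_gene_count, replace=False)
    )

    marker_panel = make_marker_panel(params, genes, rng)

    n = params.n_per_group
    group_labels = ["control"] * n + ["NSAID"] * n
    subjects = [f"m{i + 1:02d}" for i in range(2 * n)]
    treated = np.array([g == "NSAID" for g in group_labels], dtype=float)

    matrices: dict[str, CountMatrix] = {}
    de_by_source: dict[str, set] = {}
    dropped_by_source: dict[str, set] = {}
    for source in params.sources:
        phi = float(params.dispersion[source])
        lib_mean = float(params.lib_size_mean[source]) / params.lib_scale
        if source == "exfoliome":
            lib_mean *= 1.0 - params.contamination_fraction
        if params.lib_cv > 0:
            sdlog = np.sqrt(np.log1p(params.lib_cv**2))
            mulog = np.log(lib_mean) - sdlog**2 / 2.0
            libs = rng.lognormal(mulog, sdlog, 2 * n)
        else:
            libs = np.full(2 * n, lib_mean)

        carries_effect = source in set(params.shared_effect_sources)
        lfc_here = true_lfc.to_numpy() if carries_effect else np.zeros(params.n_genes)
        # genes x samples mean matrix
        mu = np.outer(rel_abundance.to_numpy(), libs)
        mu *= np.power(2.0, np.outer(lfc_here, treated))
        counts = _nb_draw(rng, mu, phi).astype(np.int64)

        if source in set(params.dropout_sources) and dropped_genes:
            drop_mask = genes.isin(dropped_genes)
            counts[drop_mask, :] = 0
            dropped_by_source[source] = set(dropped_genes)
        else:
            dropped_by_source[source] = set()

        sample_ids = [f"{source}_{subj}" for subj in subjects]
        samples = pd.DataFrame(
            {
                "source": source,
                "group": group_labels,
                "subject": subjects,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        matrices[source] = CountMatrix(
            pd.DataFrame(counts, index=genes, columns=sample_ids), samples
        )
        de_by_source[source] = set(de_genes) if carries_effect else set()

    truth = GroundTruth(
        de_gene_ids=de_by_source,
        baseline_mean=rel_abundance,
        true_lfc=true_lfc,
        hk_gene_ids=hk_genes,
        marker_panel=marker_panel,
        dropped_gene_ids=dropped_by_source,
    )
    return matrices, truth


def make_marker_panel(
    params: SimulationParams,
    gene_universe: pd.Index,
    rng: Optional[np.random.Generator] = None,
    panel: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict[str, list[str]]:
    """Build or validate a cell-type marker panel against a gene universe.

    When ``panel`` is given it is validated (>=2 distinct genes per cell
    type, all present in the universe); otherwise a default panel is sampled
    from the universe with ``params.marker_genes_per_type`` genes per type.
    """
    universe = set(gene_universe)
    if panel is not None:
        validated: dict[str, list[str]] = {}
        for cell_type, ids in panel.items():
            ids = list(dict.fromkeys(ids))  # dedupe, keep order
            if len(ids) < 2:
                raise ValueError(
                    f"cell type {cell_type!r} has {len(ids)} marker gene(s); need >= 2"
                )
            absent = [g for g in ids if g not in universe]
            if absent:
                raise ValueError(
                    f"marker genes for {cell_type!r} absent from universe: {absent}"
                )
            validated[cell_type] = ids
        return validated

    if params.marker_genes_per_type < 2:
        raise ValueError("marker_genes_per_type must be >= 2")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_needed = params.marker_genes_per_type * len(DEFAULT_MARKER_CELL_TYPES)
    chosen = rng.choice(np.asarray(gene_universe), size=n_needed, replace=False)
    out: dict[str, list[str]] = {}
    for i, cell_type in enumerate(DEFAULT_MARKER_CELL_TYPES):
        lo = i * params.marker_genes_per_type
        out[cell_type] = sorted(chosen[lo : lo + params.marker_genes_per_type])
    return out
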
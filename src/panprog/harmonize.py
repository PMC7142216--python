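"""Preprocessing of raw omics matrices into one aligned, z-scored dataset.

The harmonization steps mirror how TCGA-style matrices are prepared for
survival modelling:

1. keep primary-tumor samples (sample type code ``"01"``),
2. drop genes missing in more than 5% of samples (row-mean impute the
   remainder),
3. for expression layers, drop genes/miRNAs with too few expressed
   samples (GE: value > 0 in > 50% of samples; ME: value > 1 in > 10%),
4. average duplicate probe rows per gene,
5. map miRNAs onto target genes via a curated interaction table
   (≥ 5 supporting experiments, anti-correlated in ≥ 1 cancer), taking
   the mean over the miRNAs bound to each gene,
6. intersect samples and genes across layers and the clinical table,
7. z-score each matrix and keep four decimal places.

All threshold comparisons are strict (``>``), exactly as stated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    LAYER_KINDS,
    ClinicalTable,
    InteractionTable,
    MultiOmicsDataset,
    OmicsLayer,
)

log = logging.getLogger("panprog")

__all__ = [
    "filter_sample_type",
    "filter_missing",
    "filter_expression",
    "aggregate_duplicates",
    "map_mirna_to_genes",
    "zscore_normalize",
    "align_dataset",
    "harmonize_dataset",
]


def filter_sample_type(clinical: ClinicalTable, code: str = "01") -> ClinicalTable:
    """Keep only samples with the given sample type code (default
    ``"01"``, primary solid tumor)."""
    if "sample_type_code" not in clinical.data.columns:
        raise ValueError("clinical table has no sample_type_code column")
    kept = clinical.data[clinical.data["sample_type_code"] == code].reset_index(drop=True)
    if kept.empty:
        log.warning("filter_sample_type: no samples with code %r", code)
    return ClinicalTable(kept)


def filter_missing(layer: OmicsLayer, max_missing_frac: float = 0.05) -> OmicsLayer:
    """Remove genes missing in more than ``max_missing_frac`` of samples.

    Surviving rows have their remaining missing entries imputed by the
    gene-row mean (minimal-assumption imputation; leaves downstream
    z-scores nearly unchanged).
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    vals = layer.values
    frac = vals.isna().sum(axis=1) / vals.shape[1]
    kept = vals.loc[frac <= max_missing_frac].copy()
    if kept.isna().any().any():
        row_means = kept.mean(axis=1)
        kept = kept.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return OmicsLayer(layer.layer_kind, kept)


def filter_expression(layer: OmicsLayer) -> OmicsLayer:
    """Expression-support filter for GE and ME; other layers pass through.

    GE genes must have value > 0 in more than half the samples; ME
    miRNAs must have value > 1 in more than 10% of samples.
    """
    vals = layer.values
    n = vals.shape[1]
    if layer.layer_kind == "GE":
        keep = (vals > 0).sum(axis=1) > 0.5 * n
    elif layer.layer_kind == "ME":
        keep = (vals > 1).sum(axis=1) > 0.1 * n
    else:
        return layer
    return OmicsLayer(layer.layer_kind, vals.loc[keep].copy())


def aggregate_duplicates(layer: OmicsLayer) -> OmicsLayer:
    """Collapse rows sharing a gene id to their per-sample mean signal."""
    vals = layer.values
    if not vals.index.duplicated().any():
        return layer
    merged = vals.groupby(level=0, sort=False).mean()
    return OmicsLayer(layer.layer_kind, merged)


def map_mirna_to_genes(
    me: OmicsLayer,
    interactions: InteractionTable,
    min_experiments: int = 5,
    min_anticorr: int = 1,
) -> OmicsLayer:
    """Convert a miRNA matrix to a gene matrix via curated interactions.

    Interactions need at least ``min_experiments`` supporting
    experiments and anti-correlation in at least ``min_anticorr``
    cancers. Each target gene's row is the per-sample mean over its
    bound miRNAs present in the matrix; genes with no surviving
    interaction are absent from the output.
    """
    if me.layer_kind != "ME":
        raise ValueError("map_mirna_to_genes expects an ME layer")
    tab = interactions.data
    kept = tab[
        (tab["n_experiments"] >= min_experiments)
        & (tab["n_anticorrelated_cancers"] >= min_anticorr)
    ]
    if kept.empty:
        raise ValueError(
            "no interactions survive thresholds "
            f"(min_experiments={min_experiments}, min_anticorr={min_anticorr})"
        )
    present = kept[kept["mirna_id"].isin(me.values.index)]
    if present.empty:
        raise ValueError("no surviving interaction names a miRNA present in the matrix")
    rows = me.values.loc[present["mirna_id"]]
    rows.index = pd.Index(present["gene_id"], name="gene_id")
    gene_vals = rows.groupby(level=0, sort=True).mean()
    return OmicsLayer("ME", gene_vals)


def zscore_normalize(layer: OmicsLayer, mode: str = "global", decimals: int = 4) -> OmicsLayer:
    """Standardize the matrix to mean 0 / SD 1 and keep four decimals.

    ``mode="global"`` (default) standardizes by the mean and SD of the
    entire matrix, which preserves between-gene location differences and
    keeps the GS component of the Score informative; ``"per-gene"``
    standardizes each row (offered as a sensitivity variant — it forces
    every gene mean to 0 and with it GS ≈ 0). Values are rounded
    half-to-even at the fourth decimal.
    """
    vals = layer.values
    if mode == "global":
        arr = vals.to_numpy(float)
        mu = np.nanmean(arr)
        sd = np.nanstd(arr)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("matrix standard deviation is zero; cannot z-score")
        out = (vals - mu) / sd
    elif mode == "per-gene":
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError("constant gene row(s); cannot z-score per gene")
        out = vals.sub(mu, axis=0).div(sd, axis=0)
    else:
        raise ValueError("mode must be 'global' or 'per-gene'")
    out = out.round(decimals)  # numpy round = half-to-even
    return OmicsLayer(layer.layer_kind, out)


def align_dataset(layers: dict[str, OmicsLayer], clinical: ClinicalTable) -> MultiOmicsDataset:
    """Intersect samples and genes across all layers and the clinic table.

    The sample set is the intersection of the four layers' columns with
    the clinical sample ids; the gene set is the intersection of the
    four layers' rows. Rows/columns are reordered identically (sorted)
    across layers, and clinical rows follow the same sample order.
    """
    if set(layers) != set(LAYER_KINDS):
        raise ValueError(f"need exactly the four layers {LAYER_KINDS}")
    sample_sets = [set(l.sample_ids) for l in layers.values()]
    samples = set(clinical.sample_ids).intersection(*sample_sets)
    if not samples:
        raise ValueError("empty sample intersection across layers and clinical table")
    gene_sets = [set(l.gene_ids) for l in layers.values()]
    genes = set.intersection(*gene_sets)
    if not genes:
        raise ValueError("empty gene intersection across layers")
    samples = sorted(samples)
    genes = sorted(genes)
    log.info("align_dataset: %d samples, %d genes in common", len(samples), len(genes))
    aligned = {
        kind: OmicsLayer(kind, layer.values.loc[genes, samples].copy())
        for kind, layer in layers.items()
    }
    return MultiOmicsDataset(layers=aligned, clinical=clinical.subset(samples))


def harmonize_dataset(
    layers: dict[str, OmicsLayer],
    clinical: ClinicalTable,
    interactions: InteractionTable | None = None,
    zscore_mode: str = "global",
    sample_type_code: str = "01",
    max_missing_frac: float = 0.05,
) -> MultiOmicsDataset:
    """Full preprocessing chain: filters → aggregation → miRNA mapping →
    alignment → z-score (the order the steps are described in above)."""
    if "sample_type_code" in clinical.data.columns:
        clinical = filter_sample_type(clinical, sample_type_code)
    processed = {}
    for kind, layer in layers.items():
        layer = filter_missing(layer, max_missing_frac)
        layer = filter_expression(layer)
        layer = aggregate_duplicates(layer)
        processed[kind] = layer
    if interactions is not None:
        processed["ME"] = map_mirna_to_genes(processed["ME"], interactions)
    dataset = align_dataset(processed, clinical)
    normalized = {
        kind: zscore_normalize(layer, mode=zscore_mode)
        for kind, layer in dataset.layers.items()
    }
    return MultiOmicsDataset(layers=normalized, clinical=dataset.clinical)
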
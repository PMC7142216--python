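"""The gene-ranking procedure at the heart of the package.

Stage 1 (voting): for every gene, each omics layer is screened with a
univariate Cox model; a layer votes "1" when its likelihood-ratio test
p-value is below alpha. Genes voted in at least ``min_votes`` of the
four layers become candidates.

Stage 2 (integration): each candidate gets a 4-covariate multivariate
Cox fit on its [GE, SCNA, DM, ME] values; it is retained only if all
three overall tests (likelihood ratio, Wald, score/log-rank) are
significant. From the coefficient vector B and the per-sample omics
vector V,

    RS_j = B · V_j            (per-sample risk score)
    GS   = mean_j RS_j        (gene score)
    Score = A + B + C + D + GS

and genes are ranked by decreasing Score; the top k form the biomarker
panel. (The letters A–D are the layer vote flags; the coefficient
vector is held as ``b_coef`` to keep it distinct from the SCNA flag B.)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    LAYER_KINDS,
    BiomarkerPanel,
    CoxFit,
    GeneScoreRecord,
    MultiOmicsDataset,
    VoteVector,
)
from .survival import fit_cox

log = logging.getLogger("panprog")

__all__ = [
    "univariate_screen",
    "select_candidates",
    "fit_multiomics",
    "compute_rs",
    "compute_gs",
    "compute_score",
    "rank_genes",
    "score_candidates",
    "score_variant_voted_layers_only",
    "merged_matrix_screen",
]


def univariate_screen(
    dataset: MultiOmicsDataset, alpha: float = 0.05
) -> tuple[dict[str, VoteVector], pd.DataFrame]:
    """Per-gene, per-layer univariate Cox screen with voting.

    Returns a gene → :class:`VoteVector` mapping and a long-format table
    (gene_id, layer, beta, p_lrt, vote). A layer votes 1 iff its fit
    converged and the likelihood-ratio p is below ``alpha``; the sign of
    beta is retained so risk factors (beta > 0) can be told from
    protective associations. Failed fits are logged and vote 0.
    """
    time = dataset.clinical.time
    event = dataset.clinical.event
    votes: dict[str, VoteVector] = {}
    rows = []
    flags_by_layer: dict[str, dict[str, int]] = {k: {} for k in LAYER_KINDS}
    for kind in LAYER_KINDS:
        mat = dataset.layers[kind].values.to_numpy(float)
        gene_ids = dataset.layers[kind].gene_ids
        for g, gene_id in enumerate(gene_ids):
            beta = np.nan
            p = np.nan
            flag = 0
            try:
                fit = fit_cox(mat[g], time, event)
                beta, p = float(fit.beta[0]), fit.p_lrt
                flag = int(fit.converged and p < alpha)
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.debug("univariate fit failed for %s/%s: %s", gene_id, kind, exc)
            flags_by_layer[kind][gene_id] = flag
            rows.append(
                {"gene_id": gene_id, "layer": kind, "beta": beta, "p_lrt": p, "vote": flag}
            )
    for gene_id in dataset.gene_ids:
        votes[gene_id] = VoteVector(*(flags_by_layer[k].get(gene_id, 0) for k in LAYER_KINDS))
    return votes, pd.DataFrame(rows)


def select_candidates(votes: dict[str, VoteVector], min_votes: int = 2) -> list[str]:
    """Genes voted survival-related in at least ``min_votes`` layers."""
    return [g for g, v in votes.items() if v.total >= min_votes]


def fit_multiomics(
    gene_id: str, dataset: MultiOmicsDataset, alpha: float = 0.05
) -> tuple[CoxFit | None, dict | None]:
    """4-covariate Cox fit for one candidate gene with the triple-test gate.

    Returns ``(fit, None)`` when the gene is retained (fit converged and
    all three overall-test p-values < ``alpha``), else ``(None, record)``
    where the rejection record names the failed test(s).
    """
    V = dataset.gene_matrix(gene_id)
    try:
        fit = fit_cox(V, dataset.clinical.time, dataset.clinical.event)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return None, {"gene_id": gene_id, "reason": f"fit_error: {exc}"}
    failed = []
    if not fit.converged:
        failed.append("convergence")
    for name, p in (("likelihood", fit.p_lrt), ("wald", fit.p_wald), ("logrank", fit.p_score)):
        if not p < alpha:
            failed.append(name)
    if failed:
        return None, {"gene_id": gene_id, "reason": ",".join(failed)}
    return fit, None


def compute_rs(fit: CoxFit, V: np.ndarray) -> np.ndarray:
    """Per-sample risk score RS = B · V for one gene.

    ``V`` is the n_samples × 4 matrix of the gene's omics values in
    layer order GE, SCNA, DM, ME.
    """
    V = np.asarray(V, float)
    if V.ndim != 2 or V.shape[1] != len(fit.beta):
        raise ValueError(f"V must be n_samples x {len(fit.beta)}, got {V.shape}")
    return V @ fit.beta


def compute_gs(rs: np.ndarray) -> float:
    """Gene score GS: the mean risk score over samples."""
    rs = np.asarray(rs, float)
    if rs.size == 0:
        raise ValueError("empty risk-score vector")
    return float(rs.mean())


def compute_score(votes: VoteVector, gs: float) -> float:
    """Score = A + B + C + D + GS."""
    return float(votes.total + gs)


def score_candidates(
    dataset: MultiOmicsDataset,
    votes: dict[str, VoteVector],
    candidates: list[str],
    alpha: float = 0.05,
) -> tuple[list[GeneScoreRecord], list[dict]]:
    """Multivariate stage for every candidate gene.

    Genes passing the triple-test gate become :class:`GeneScoreRecord`
    entries; failures are collected in a rejects table for transparency.
    """
    records: list[GeneScoreRecord] = []
    rejects: list[dict] = []
    for gene_id in candidates:
        fit, reject = fit_multiomics(gene_id, dataset, alpha=alpha)
        if fit is None:
            rejects.append(reject)
            continue
        V = dataset.gene_matrix(gene_id)
        rs = compute_rs(fit, V)
        gs = compute_gs(rs)
        records.append(
            GeneScoreRecord(
                gene_id=gene_id,
                votes=votes[gene_id],
                b_coef=fit.beta.copy(),
                rs=rs,
                gs=gs,
                score=compute_score(votes[gene_id], gs),
                p_lrt=fit.p_lrt,
            )
        )
    return records, rejects


def rank_genes(
    records: list[GeneScoreRecord], k: int = 10, cancer_label: str = "cohort"
) -> BiomarkerPanel:
    """Sort by decreasing Score and return the top-``k`` panel.

    Ties break deterministically by (vote sum descending, multivariate
    LRT p ascending, gene id). If fewer than ``k`` genes are retained,
    the full list is returned with a warning.
    """
    if not records:
        raise ValueError("no retained genes to rank")
    ordered = sorted(
        records, key=lambda r: (-r.score, -r.votes.total, r.p_lrt, r.gene_id)
    )
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
    if k > len(ordered):
        log.warning("requested top-%d but only %d genes retained", k, len(ordered))
    return BiomarkerPanel(cancer_label=cancer_label, records=ordered[:k])


def score_variant_voted_layers_only(
    gene_id: str,
    dataset: MultiOmicsDataset,
    votes: dict[str, VoteVector],
    alpha: float = 0.05,
) -> float | None:
    """Robustness variant: recompute the Score using only voted layers.

    The multivariate fit is restricted to the layers where the gene was
    voted survival-related; GS comes from the reduced B and V. Returns
    ``None`` when the reduced fit fails the triple-test gate. For a gene
    voted on all four layers this is identical to the full Score.
    """
    vote = votes[gene_id]
    layer_idx = [i for i, flag in enumerate(vote.as_tuple()) if flag]
    if not layer_idx:
        return None
    V = dataset.gene_matrix(gene_id)[:, layer_idx]
    try:
        fit = fit_cox(V, dataset.clinical.time, dataset.clinical.event)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not (fit.converged and fit.p_lrt < alpha and fit.p_wald < alpha and fit.p_score < alpha):
        return None
    gs = compute_gs(V @ fit.beta)
    return compute_score(vote, gs)


def merged_matrix_screen(
    dataset: MultiOmicsDataset, alpha: float = 0.05, min_hits: int = 2
) -> list[str]:
    """Feature-merged robustness check.

    The four layers are stacked into one feature matrix in which the
    same gene appears as up to four distinct (gene, layer) features.
    Each feature is screened with a univariate Cox model; genes with at
    least ``min_hits`` significant features are returned. By
    construction this recovers a subset of (here: exactly) the voting
    candidates on the same data.
    """
    time = dataset.clinical.time
    event = dataset.clinical.event
    hits: dict[str, int] = {}
    for kind in LAYER_KINDS:
        mat = dataset.layers[kind].values.to_numpy(float)
        for g, gene_id in enumerate(dataset.layers[kind].gene_ids):
            try:
                fit = fit_cox(mat[g], time, event)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if fit.converged and fit.p_lrt < alpha:
                hits[gene_id] = hits.get(gene_id, 0) + 1
    return [g for g in dataset.gene_ids if hits.get(g, 0) >= min_hits]
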
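"""Core in-memory containers shared across the pipeline.

The pipeline operates on four omics layers measured on a common set of
genes and tumor samples:

* ``GE``   — gene expression (RNA-seq),
* ``SCNA`` — somatic copy-number alteration (continuous gene-level scores),
* ``DM``   — DNA methylation (gene-level beta/M values),
* ``ME``   — miRNA expression mapped onto target genes.

Each layer is a gene × sample matrix wrapped in :class:`OmicsLayer`;
:class:`MultiOmicsDataset` holds four sample- and gene-aligned layers
plus the clinical survival table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYER_KINDS = ("GE", "SCNA", "DM", "ME")

#: vote-flag letter per layer, in the order A (GE), B (SCNA), C (DM), D (ME)
VOTE_LETTERS = dict(zip("ABCD", LAYER_KINDS))


@dataclass
class OmicsLayer:
    """One gene × sample numeric matrix tagged with its omics modality.

    Parameters
    ----------
    layer_kind : {"GE", "SCNA", "DM", "ME"}
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id. Missing entries
        are ``NaN``. Units are layer-specific before normalization and
        z-units (rounded to 4 decimals) after.
    """

    layer_kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValueError(
                f"layer_kind must be one of {LAYER_KINDS}, got {self.layer_kind!r}"
            )
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsLayer":
        return OmicsLayer(self.layer_kind, self.values.copy())


@dataclass
class ClinicalTable:
    """Per-sample survival outcomes (and optional demographics).

    ``data`` has one row per sample with columns ``sample_id``,
    ``time_days`` (observed follow-up, > 0), ``event`` (1 = death
    observed, 0 = censored) and optionally ``age``, ``sex``,
    ``sample_type_code``.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "time_days", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("clinical table has duplicate sample ids")
        ev = self.data["event"]
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, sample_ids) -> "ClinicalTable":
        """Rows for ``sample_ids``, in that order."""
        idx = self.data.set_index("sample_id").loc[list(sample_ids)]
        return ClinicalTable(idx.reset_index())

    @property
    def time(self) -> np.ndarray:
        return self.data["time_days"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.data.copy())


@dataclass
class MultiOmicsDataset:
    """Four sample- and gene-aligned omics layers plus clinical outcomes.

    Invariant: all four layers share identical ``gene_ids`` and
    ``sample_ids`` vectors, and ``clinical`` rows follow the same sample
    order.
    """

    layers: dict[str, OmicsLayer]
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if set(self.layers) != set(LAYER_KINDS):
            raise ValueError(f"need exactly the four layers {LAYER_KINDS}")
        ref = self.layers["GE"]
        for kind, layer in self.layers.items():
            if layer.gene_ids != ref.gene_ids or layer.sample_ids != ref.sample_ids:
                raise ValueError(f"layer {kind} not aligned with GE")
        if self.clinical.sample_ids != ref.sample_ids:
            raise ValueError("clinical sample order does not match layers")

    @property
    def gene_ids(self) -> list[str]:
        return self.layers["GE"].gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.layers["GE"].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_matrix(self, gene_id: str) -> np.ndarray:
        """n_samples × 4 matrix [GE, SCNA, DM, ME] for one gene."""
        cols = [self.layers[k].values.loc[gene_id].to_numpy(float) for k in LAYER_KINDS]
        return np.column_stack(cols)


@dataclass
class InteractionTable:
    """miRNA → target-gene interactions with evidence counts.

    Columns: ``mirna_id``, ``gene_id``, ``n_experiments`` (supporting
    CLIP/degradome experiments), ``n_anticorrelated_cancers`` (cancer
    types where the pair is anti-correlated).
    """

    data: pd.DataFrame

    REQUIRED = ("mirna_id", "gene_id", "n_experiments", "n_anticorrelated_cancers")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        if self.data.duplicated(["mirna_id", "gene_id"]).any():
            raise ValueError("duplicate (mirna, gene) pairs")
        for c in ("n_experiments", "n_anticorrelated_cancers"):
            if (self.data[c] < 0).any():
                raise ValueError(f"{c} must be >= 0")


@dataclass
class CoxFit:
    """A fitted proportional-hazards model with the three overall tests.

    ``beta`` are log hazard ratios per covariate unit; ``p_lrt``,
    ``p_wald``, ``p_score`` are the likelihood-ratio, Wald and score
    (log-rank) test p-values for the global null ``beta = 0``.
    """

    beta: np.ndarray
    se: np.ndarray
    loglik_null: float
    loglik_fit: float
    p_lrt: float
    p_wald: float
    p_score: float
    converged: bool
    n_events: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        if self.beta.shape != self.se.shape:
            raise ValueError("beta and se length mismatch")


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class VoteVector:
    """Per-layer survival-relatedness flags A (GE), B (SCNA), C (DM), D (ME)."""

    A: int = 0
    B: int = 0
    C: int = 0
    D: int = 0

    def __post_init__(self) -> None:
        for letter in "ABCD":
            if getattr(self, letter) not in (0, 1):
                raise ValueError("vote flags must be 0 or 1")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.A, self.B, self.C, self.D)

    def voted_layers(self) -> list[str]:
        return [k for f, k in zip(self.as_tuple(), LAYER_KINDS) if f]


@dataclass
class GeneScoreRecord:
    """Everything the ranking needs for one retained candidate gene."""

    gene_id: str
    votes: VoteVector
    b_coef: np.ndarray          # multivariate coefficients, one per layer
    rs: np.ndarray              # per-sample risk score B . V
    gs: float                   # mean RS over samples
    score: float                # vote total + GS
    p_lrt: float                # multivariate LRT p, used for tie-breaking
    rank: int | None = None


@dataclass
class BiomarkerPanel:
    """Top-k genes ranked by decreasing Score for one cohort."""

    cancer_label: str
    records: list[GeneScoreRecord] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "A": r.votes.A,
                    "B": r.votes.B,
                    "C": r.votes.C,
                    "D": r.votes.D,
                    "beta_GE": r.b_coef[0],
                    "beta_SCNA": r.b_coef[1],
                    "beta_DM": r.b_coef[2],
                    "beta_ME": r.b_coef[3],
                    "GS": r.gs,
                    "Score": r.score,
                    "rank": r.rank,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CIndexDistribution:
    """Resampled concordance indexes and their summary."""

    values: np.ndarray
    subsample_frac: float
    n_reps: int
    seed: int
    p_sign: float  # one-sided sign test for median > 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != self.n_reps:
            raise ValueError("values length != n_reps")

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class NetBenefitCurve:
    """Decision-curve net benefit at each threshold probability."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )
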
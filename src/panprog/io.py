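"""TSV readers/writers and the pipeline run configuration.

All on-disk formats are plain tab-separated text, matching how TCGA
matrices circulate: omics matrices have a header row of sample ids and
a ``gene_id`` first column; the clinical table, interaction table and
gene-set collections are likewise flat text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

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
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "read_interactions",
    "read_gmt",
    "RunConfig",
    "run_pipeline",
]


def read_matrix(path, layer_kind: str = "GE") -> OmicsLayer:
    """Read a gene × sample TSV matrix into an :class:`OmicsLayer`.

    The first column holds gene ids, the header row sample ids. Cells
    that are empty or ``NA``/``NaN`` become missing. Ragged rows,
    duplicate sample columns and non-numeric cells are rejected with the
    offending location.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != n_fields:
                raise ValueError(f"{path}: ragged row at line {lineno}")
    sample_ids = header[1:]
    dup = pd.Index(sample_ids).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate sample column(s) {pd.Index(sample_ids)[dup].tolist()}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = sample_ids
    values = df.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
    try:
        # column-wise float conversion via numpy round-trips exactly
        values = values.astype(float)
    except ValueError:
        for j, col in enumerate(values.columns):
            for i, cell in enumerate(values[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {values.index[i]!r},"
                        f" column {col!r}"
                    ) from None
        raise
    values.index.name = "gene_id"
    return OmicsLayer(layer_kind, values)


def write_matrix(layer: OmicsLayer, path) -> None:
    """Write an :class:`OmicsLayer` as a gene × sample TSV."""
    out = layer.values.copy()
    out.index.name = "gene_id"
    # %.17g guarantees bit-exact float64 round-trips through text
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "sample_type_code": str},
        float_precision="round_trip",
    )
    return ClinicalTable(df)


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t")
    return InteractionTable(df)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: term, description, genes…

    An optional namespace suffix on the term (``term|BP``) survives in
    the key; filtering to biological-process terms happens downstream.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collection[parts[0]] = {g for g in parts[2:] if g}
    return collection


@dataclass
class RunConfig:
    """All knobs for one end-to-end pipeline run, serializable to text."""

    ge: str = ""
    scna: str = ""
    dm: str = ""
    me: str = ""
    clinical: str = ""
    interactions: str = ""
    out_dir: str = "panprog_out"
    alpha: float = 0.05
    min_votes: int = 2
    top_k: int = 10
    frac: float = 0.9
    reps: int = 100
    seed: int = 0
    zscore_mode: str = "global"     # "global" | "per-gene"
    threshold_lo: float = 0.01
    threshold_hi: float = 0.80
    threshold_step: float = 0.01
    cancer_label: str = "synthetic"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.min_votes <= 4:
            raise ValueError("min_votes must be in 1..4")
        if self.top_k < 1 or self.reps < 1:
            raise ValueError("top_k and reps must be positive")
        if not 0 < self.frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        if self.zscore_mode not in ("global", "per-gene"):
            raise ValueError("zscore_mode must be 'global' or 'per-gene'")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key}={val}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = line.split("=", 1)
                key = key.strip()
                if not hasattr(defaults, key):
                    raise ValueError(f"unknown config key {key!r}")
                cur = getattr(defaults, key)
                kwargs[key] = type(cur)(val.strip()) if not isinstance(cur, str) else val.strip()
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow and write every intermediate table.

    Stages: harmonize → univariate screen → candidate selection →
    multivariate fits → Score ranking → resampled C-index → decision
    curve. A ``manifest.json`` records the config, per-stage gene/sample
    counts and the package version; any stage failure aborts with the
    stage name while earlier outputs remain on disk.
    """
    from . import __version__
    from .evaluation import cindex_resampling, decision_curve, panel_risk_scores, stratify
    from .harmonize import harmonize_dataset
    from .scoring import rank_genes, score_candidates, select_candidates, univariate_screen
    from .survival import km_estimate, logrank_test

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def _record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    stage = "harmonize"
    try:
        layers = {
            "GE": read_matrix(config.ge, "GE"),
            "SCNA": read_matrix(config.scna, "SCNA"),
            "DM": read_matrix(config.dm, "DM"),
            "ME": read_matrix(config.me, "ME"),
        }
        clinical = read_clinical(config.clinical)
        interactions = read_interactions(config.interactions) if config.interactions else None
        dataset = harmonize_dataset(
            layers, clinical, interactions=interactions, zscore_mode=config.zscore_mode
        )
        _record(stage, n_genes=len(dataset.gene_ids), n_samples=dataset.n_samples)

        stage = "univariate_screen"
        votes, beta_table = univariate_screen(dataset, alpha=config.alpha)
        beta_table.to_csv(out / "votes.tsv", sep="\t", index=False)
        _record(stage, n_genes=len(votes))

        stage = "select_candidates"
        candidates = select_candidates(votes, min_votes=config.min_votes)
        pd.Series(candidates, name="gene_id").to_csv(out / "candidates.tsv", sep="\t", index=False)
        _record(stage, n_candidates=len(candidates))
        if not candidates:
            manifest["status"] = "stopped: no candidate genes"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            log.warning("no candidate genes at min_votes=%d; stopping", config.min_votes)
            return out

        stage = "score"
        records, rejects = score_candidates(dataset, votes, candidates)
        _record(stage, n_retained=len(records), n_rejected=len(rejects))
        pd.DataFrame(rejects).to_csv(out / "rejects.tsv", sep="\t", index=False)
        if not records:
            manifest["status"] = "stopped: no genes passed the triple-test gate"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            return out

        stage = "rank"
        panel = rank_genes(records, k=config.top_k, cancer_label=config.cancer_label)
        scores = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id, "A": r.votes.A, "B": r.votes.B, "C": r.votes.C,
                    "D": r.votes.D, "beta_GE": r.b_coef[0], "beta_SCNA": r.b_coef[1],
                    "beta_DM": r.b_coef[2], "beta_ME": r.b_coef[3], "GS": r.gs,
                    "Score": r.score, "rank": r.rank,
                }
                for r in sorted(records, key=lambda r: (r.rank is None, r.rank))
            ]
        )
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        panel.to_frame().to_csv(out / "panel.tsv", sep="\t", index=False)
        _record(stage, panel_size=len(panel.records))

        stage = "validate"
        dist = cindex_resampling(
            panel, dataset, frac=config.frac, reps=config.reps, seed=config.seed
        )
        pd.DataFrame({"rep": np.arange(1, dist.n_reps + 1), "cindex": dist.values}).to_csv(
            out / "cindex.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [{"median_cindex": dist.median, "p_sign": dist.p_sign, "reps": dist.n_reps}]
        ).to_csv(out / "cindex_summary.tsv", sep="\t", index=False)
        risk = panel_risk_scores(panel, dataset)
        groups = stratify(risk)
        time, event = dataset.clinical.time, dataset.clinical.event
        for label in ("high", "low"):
            mask = groups == label
            km_estimate(time[mask], event[mask]).to_frame().to_csv(
                out / f"km_{label}.tsv", sep="\t", index=False
            )
        p_lr = logrank_test(groups, time, event)
        thresholds = np.arange(
            config.threshold_lo, config.threshold_hi + 1e-12, config.threshold_step
        )
        prob = _risk_to_probability(risk, event)
        curve = decision_curve(prob, event, thresholds)
        curve.to_frame().to_csv(out / "decision_curve.tsv", sep="\t", index=False)
        _record(stage, median_cindex=dist.median, logrank_p=p_lr)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _risk_to_probability(risk: np.ndarray, event: np.ndarray) -> np.ndarray:
    from .evaluation import risk_to_probability

    return risk_to_probability(risk, event)


def read_fixture_dir(directory) -> tuple[dict[str, OmicsLayer], ClinicalTable]:
    """Read the six-file fixture layout written by ``write_fixture``."""
    directory = Path(directory)
    layers = {k: read_matrix(directory / f"{k.lower()}.tsv", k) for k in LAYER_KINDS}
    clinical = read_clinical(directory / "clinical.tsv")
    return layers, clinical


def dataset_from_dir(directory) -> MultiOmicsDataset:
    """Load an already-aligned fixture directory as a dataset."""
    layers, clinical = read_fixture_dir(directory)
    return MultiOmicsDataset(layers=layers, clinical=clinical)
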
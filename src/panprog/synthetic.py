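"""Synthetic multi-omics survival data with planted prognostic drivers.

The generator emulates the data model the pipeline consumes: four
gene × sample omics layers (GE, SCNA, DM, ME) on shared genes and
samples, a clinical table with right-censored survival, and a known
ground truth of driver genes so every downstream stage can be checked
against a planted answer.

Cross-layer structure follows the biology the layers represent: per gene
and sample a latent activity factor is mixed into each layer with signed
loadings, so DNA methylation and miRNA expression come out
anti-correlated with gene expression, and copy number positively
correlated, at a configurable magnitude.

Survival times follow an exponential (constant-baseline) proportional-
hazards model: ``T_i ~ Exp(h0 · exp(lp_i))`` with linear predictor
``lp_i = Σ_drivers Σ_layers effect · value``. Censoring is an
independent exponential whose rate is set so the expected censored
fraction matches ``censor_rate`` under a null predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LAYER_KINDS, ClinicalTable, MultiOmicsDataset, OmicsLayer

__all__ = ["SimConfig", "GroundTruth", "generate_dataset", "generate_survival", "write_fixture"]

#: mixing sign of the latent per-gene factor into each layer
LAYER_SIGNS = {"GE": +1.0, "SCNA": +1.0, "DM": -1.0, "ME": -1.0}

#: location of each layer on its raw scale. Expression layers sit well
#: inside the support filters real data are subjected to (GE abundances
#: positive, miRNA values mostly above 1); SCNA and DM emulate centered
#: Gistic scores and methylation M-values. Shifts are removed again by
#: the global z-score during harmonization and never carry survival
#: information.
LAYER_OFFSETS = {"GE": 5.0, "SCNA": 0.0, "DM": 0.0, "ME": 3.0}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults are the reference conditions used throughout the test
    battery: a 500-gene, 300-sample cohort with 5 driver genes, each
    acting through two layers at one log hazard ratio per SD, 30%
    censoring, and moderate (|rho| = 0.5) cross-layer correlation.
    """

    n_genes: int = 500
    n_samples: int = 300
    n_drivers: int = 5
    #: per-driver subset of layers through which the hazard acts;
    #: cycled if shorter than n_drivers
    driver_layers: list[tuple[str, ...]] = field(
        default_factory=lambda: [("GE", "DM"), ("GE", "SCNA"), ("SCNA", "ME"), ("DM", "ME"), ("GE", "ME")]
    )
    effect_size: float = 1.0           # log hazard ratio per 1 SD of layer value
    cross_layer_rho: float = 0.5       # |corr| between each layer and GE
    baseline_hazard: float = 1.0 / 365.0   # events per day; ~1-year median survival
    censor_rate: float = 0.3           # expected censored fraction
    missing_frac: float = 0.0          # fraction of entries set missing per layer
    dup_probe_frac: float = 0.0        # fraction of genes given a duplicate probe row
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if not 0 <= self.n_drivers <= self.n_genes:
            raise ValueError("need 0 <= n_drivers <= n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= abs(self.cross_layer_rho) <= 1.0:
            raise ValueError("cross_layer_rho must lie in [-1, 1]")
        if not 0.0 <= self.missing_frac < 1.0 or not 0.0 <= self.dup_probe_frac <= 1.0:
            raise ValueError("missing_frac/dup_probe_frac out of range")
        if self.n_drivers > 0:
            if not self.driver_layers:
                raise ValueError("each driver needs at least one designated layer")
            for layers in self.driver_layers:
                if not layers:
                    raise ValueError("each driver needs at least one designated layer")
                bad = set(layers) - set(LAYER_KINDS)
                if bad:
                    raise ValueError(f"unknown layer(s) {bad}")


@dataclass
class GroundTruth:
    """Planted drivers and their true per-layer log hazard ratios.

    ``effects`` is a driver × 4 DataFrame (columns GE, SCNA, DM, ME);
    non-driver genes have all-zero effects and are omitted.
    """

    driver_ids: list[str]
    effects: pd.DataFrame

    def effect_matrix(self, gene_ids: list[str]) -> pd.DataFrame:
        """Dense gene × layer effect table over ``gene_ids`` (zeros for non-drivers)."""
        full = pd.DataFrame(0.0, index=gene_ids, columns=list(LAYER_KINDS))
        full.loc[self.effects.index] = self.effects
        return full


def generate_survival(linear_predictor, baseline_hazard: float, censor_rate: float, seed: int):
    """Draw right-censored exponential survival times.

    ``T_i ~ Exp(baseline_hazard · exp(lp_i))``; an independent
    exponential censoring time with rate
    ``baseline_hazard · censor_rate / (1 − censor_rate)`` (the rate at
    which a null subject is censored first with probability
    ``censor_rate``) truncates follow-up. Returns ``(time, event)`` with
    ``event = 1`` iff death was observed first.
    """
    lp = np.asarray(linear_predictor, float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(1.0, size=lp.shape) / (baseline_hazard * np.exp(lp))
    if censor_rate == 0.0:
        return t_event, np.ones(lp.shape, dtype=int)
    c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
    t_cens = rng.exponential(1.0 / c_rate, size=lp.shape)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _simulate_layers(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent-factor mixing: value = sign · sqrt(rho) · f + sqrt(1−rho) · noise."""
    rho = abs(cfg.cross_layer_rho)
    load = np.sqrt(rho)
    resid = np.sqrt(1.0 - rho)
    factor = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    layers = {}
    for kind in LAYER_KINDS:
        noise = rng.standard_normal((cfg.n_genes, cfg.n_samples))
        layers[kind] = (
            LAYER_OFFSETS[kind] + LAYER_SIGNS[kind] * load * factor + resid * noise
        )
    return layers


def generate_dataset(config: SimConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate one multi-omics cohort with planted drivers.

    Returns the aligned dataset (gene ids ``g0001`` …, sample ids
    ``s0001`` …) and the ground truth. Drivers are the first
    ``n_drivers`` genes; each acts on the hazard through its designated
    layers with log hazard ratio ``effect_size`` per layer unit.
    Missing entries and duplicate probe rows, when configured, are
    injected into the layer matrices so the harmonization filters have
    something to exercise; the survival times are always generated from
    the clean signal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    sample_ids = [f"s{i + 1:04d}" for i in range(config.n_samples)]

    raw = _simulate_layers(config, rng)

    # A driver's hazard follows its underlying activity, so the effect
    # through each layer carries that layer's sign: high expression or
    # copy number raise the hazard, while the silencing layers (DM, ME)
    # of the same driver act with the opposite sign.
    driver_ids = gene_ids[: config.n_drivers]
    effects = pd.DataFrame(0.0, index=driver_ids, columns=list(LAYER_KINDS))
    lp = np.zeros(config.n_samples)
    for d, gid in enumerate(driver_ids):
        layers = config.driver_layers[d % len(config.driver_layers)]
        for kind in layers:
            eff = LAYER_SIGNS[kind] * config.effect_size
            effects.loc[gid, kind] = eff
            # centered signal: the layer's location offset carries no risk
            lp += eff * (raw[kind][d] - LAYER_OFFSETS[kind])

    surv_seed = int(rng.integers(0, 2**31 - 1))
    time, event = generate_survival(lp, config.baseline_hazard, config.censor_rate, surv_seed)

    matrices = {k: v.copy() for k, v in raw.items()}
    if config.missing_frac > 0:
        for kind in LAYER_KINDS:
            mask = rng.random(matrices[kind].shape) < config.missing_frac
            matrices[kind][mask] = np.nan
    gene_index = pd.Index(gene_ids, name="gene_id")
    frames = {
        kind: pd.DataFrame(matrices[kind], index=gene_index, columns=sample_ids)
        for kind in LAYER_KINDS
    }
    if config.dup_probe_frac > 0:
        n_dup = int(round(config.dup_probe_frac * config.n_genes))
        dup_genes = rng.choice(config.n_genes, size=n_dup, replace=False)
        for kind in LAYER_KINDS:
            extra = frames[kind].iloc[dup_genes] + 0.1 * rng.standard_normal(
                (n_dup, config.n_samples)
            )
            frames[kind] = pd.concat([frames[kind], extra])

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time_days": time,
                "event": event,
                "age": rng.integers(40, 85, size=config.n_samples),
                "sex": rng.choice(["F", "M"], size=config.n_samples),
                "sample_type_code": "01",
            }
        )
    )
    layers = {k: OmicsLayer(k, frames[k]) for k in LAYER_KINDS}
    truth = GroundTruth(driver_ids=driver_ids, effects=effects)
    return MultiOmicsDataset(layers=layers, clinical=clinical), truth


def write_fixture(dataset: MultiOmicsDataset, truth: GroundTruth, directory) -> list[Path]:
    """Write one TSV per layer plus clinical and ground-truth tables.

    Produces six files (``ge.tsv``, ``scna.tsv``, ``dm.tsv``,
    ``me.tsv``, ``clinical.tsv``, ``truth.tsv``) such that reading them
    back through :mod:`panprog.io` reproduces the dataset exactly.
    """
    from .io import write_matrix  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind in LAYER_KINDS:
        path = directory / f"{kind.lower()}.tsv"
        write_matrix(dataset.layers[kind], path)
        paths.append(path)
    clin_path = directory / "clinical.tsv"
    dataset.clinical.data.to_csv(clin_path, sep="\t", index=False, float_format="%.17g")
    truth_path = directory / "truth.tsv"
    truth.effects.rename_axis("gene_id").reset_index().to_csv(
        truth_path, sep="\t", index=False, float_format="%.17g"
    )
    paths.append(clin_path)
    paths.append(truth_path)
    return paths
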
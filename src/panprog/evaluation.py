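"""Validation of a biomarker panel's prognostic power.

* ``panel_risk_scores`` — one multivariate Cox fit over all 4·k
  covariates of a k-gene panel; the fitted linear predictor is each
  sample's risk score.
* ``stratify`` — median split into high/low risk groups for KM display
  and the log-rank test.
* ``cindex_resampling`` — the 90%-subsample × 100-replicate concordance
  index distribution, with a sign test for median > 0.5.
* ``decision_curve`` — net benefit TP/n − FP/n · p_t/(1−p_t) across a
  threshold-probability grid, against the treat-all and treat-none
  policies.
* ``single_vs_multi_comparison`` — the same resampling with the panel
  model restricted to each single layer, paired by common seeds.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import (
    LAYER_KINDS,
    BiomarkerPanel,
    CIndexDistribution,
    MultiOmicsDataset,
    NetBenefitCurve,
)
from .survival import concordance_index, fit_cox

log = logging.getLogger("panprog")

__all__ = [
    "panel_risk_scores",
    "stratify",
    "cindex_resampling",
    "decision_curve",
    "single_vs_multi_comparison",
    "risk_to_probability",
]


def _panel_covariates(
    panel: BiomarkerPanel, dataset: MultiOmicsDataset, layers: tuple[str, ...] = LAYER_KINDS
) -> np.ndarray:
    """n_samples × (len(layers)·k) covariate matrix for the panel genes."""
    cols = []
    for kind in layers:
        vals = dataset.layers[kind].values
        for gene_id in panel.gene_ids:
            cols.append(vals.loc[gene_id].to_numpy(float))
    return np.column_stack(cols)


def panel_risk_scores(
    panel: BiomarkerPanel,
    dataset: MultiOmicsDataset,
    sample_subset: np.ndarray | None = None,
    layers: tuple[str, ...] = LAYER_KINDS,
) -> np.ndarray:
    """Per-sample risk from one Cox fit over the panel's covariates.

    ``sample_subset`` (integer positions) restricts both the fit and the
    returned risks. The 4·k covariates of a 10-gene panel are often
    collinear; a singular fit is retried with an escalating ridge
    penalty (1e-6 × identity, ×10 per retry) until it converges.
    """
    X = _panel_covariates(panel, dataset, layers)
    time = dataset.clinical.time
    event = dataset.clinical.event
    if sample_subset is not None:
        idx = np.asarray(sample_subset)
        X, time, event = X[idx], time[idx], event[idx]
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(
            f"subset of {X.shape[0]} samples too small for {X.shape[1]} covariates"
        )
    ridge = 0.0
    for _ in range(14):
        try:
            fit = fit_cox(X, time, event, ridge=ridge)
        except np.linalg.LinAlgError:
            fit = None
        if fit is not None and fit.converged:
            return (X - X.mean(axis=0)) @ fit.beta
        ridge = 1e-6 if ridge == 0.0 else ridge * 10.0
    raise RuntimeError("panel Cox fit failed to converge even with ridge stabilization")


def stratify(risk: np.ndarray) -> np.ndarray:
    """Median split into ``"high"`` / ``"low"`` risk labels.

    Samples at or below the median go to the low group; if that leaves
    the high group empty the tie block is flipped upward so both groups
    are non-empty. All-identical risks are an error.
    """
    risk = np.asarray(risk, float)
    if len(risk) < 2:
        raise ValueError("need at least two samples to stratify")
    if np.ptp(risk) == 0:
        raise ValueError("all risks identical; cannot stratify")
    med = np.median(risk)
    low = risk <= med
    if low.all():
        low = risk < med
    return np.where(low, "low", "high")


def cindex_resampling(
    panel: BiomarkerPanel,
    dataset: MultiOmicsDataset,
    frac: float = 0.9,
    reps: int = 100,
    seed: int = 0,
    layers: tuple[str, ...] = LAYER_KINDS,
) -> CIndexDistribution:
    """Concordance-index distribution over random subsamples.

    Each replicate draws ``floor(frac · n)`` samples without
    replacement, fits the panel risk model on them and evaluates
    Harrell's C on the same subsample. A failed replicate is redrawn at
    most three times before being recorded as 0.5 (uninformative). Also
    reports a one-sided sign-test p-value for median C > 0.5.
    """
    n = dataset.n_samples
    m = int(np.floor(frac * n))
    if m < 2:
        raise ValueError("subsample too small")
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    n_failed = 0
    for r in range(reps):
        ci = None
        for _attempt in range(4):
            idx = rng.choice(n, size=m, replace=False)
            try:
                risk = panel_risk_scores(panel, dataset, sample_subset=idx, layers=layers)
                ci = concordance_index(
                    risk, dataset.clinical.time[idx], dataset.clinical.event[idx]
                )
                break
            except (ValueError, RuntimeError):
                continue
        if ci is None:
            n_failed += 1
            ci = 0.5
        values[r] = ci
    if n_failed:
        log.warning("cindex_resampling: %d/%d replicates failed all redraws", n_failed, reps)
    n_above = int((values > 0.5).sum())
    n_informative = int((values != 0.5).sum())
    p_sign = float(stats.binomtest(n_above, max(n_informative, 1), 0.5, "greater").pvalue)
    return CIndexDistribution(
        values=values, subsample_frac=frac, n_reps=reps, seed=seed, p_sign=p_sign
    )


def decision_curve(probability, event, thresholds=None) -> NetBenefitCurve:
    """Decision-curve analysis of a predicted event probability.

    At each threshold p_t a sample is called positive iff its
    probability is ≥ p_t; net benefit is
    ``TP/n − FP/n · p_t/(1−p_t)``. ``nb_all`` treats everyone
    (prevalence − (1−prevalence)·p_t/(1−p_t)); ``nb_none`` is zero.
    Default grid: 0.01–0.80 in steps of 0.01.
    """
    probability = np.asarray(probability, float)
    event = np.asarray(event, int)
    if probability.size == 0:
        raise ValueError("empty input")
    if probability.min() < 0 or probability.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 0.801, 0.01)
    thresholds = np.asarray(thresholds, float)
    if (thresholds <= 0).any() or (thresholds >= 1).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(probability)
    prevalence = event.mean()
    pos = probability[None, :] >= thresholds[:, None]
    tp = (pos & (event == 1)[None, :]).sum(axis=1)
    fp = (pos & (event == 0)[None, :]).sum(axis=1)
    odds = thresholds / (1.0 - thresholds)
    nb_model = tp / n - fp / n * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(
        thresholds=thresholds,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(thresholds),
        n=n,
    )


def risk_to_probability(risk, event) -> np.ndarray:
    """Map a risk score to an event probability by logistic regression.

    The observed event indicator is regressed on the risk score (with
    intercept); the fitted probabilities feed the decision curve. This
    is the simplest monotone mapping of a Cox linear predictor into
    [0, 1].
    """
    import statsmodels.api as sm

    risk = np.asarray(risk, float)
    event = np.asarray(event, int)
    X = sm.add_constant(risk)
    model = sm.GLM(event, X, family=sm.families.Binomial())
    return np.asarray(model.fit().predict(X))


def single_vs_multi_comparison(
    panel: BiomarkerPanel,
    dataset: MultiOmicsDataset,
    frac: float = 0.9,
    reps: int = 100,
    seed: int = 0,
) -> dict[str, CIndexDistribution]:
    """Resampled C-index for the multi-omics panel vs each single layer.

    The same ``seed`` drives every source, so replicate subsamples are
    identical across sources and the comparison is paired.
    """
    out = {"multi": cindex_resampling(panel, dataset, frac=frac, reps=reps, seed=seed)}
    for kind in LAYER_KINDS:
        out[kind] = cindex_resampling(
            panel, dataset, frac=frac, reps=reps, seed=seed, layers=(kind,)
        )
    return out
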
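"""Cross-validated predictive ability and model comparison.

Compares the four model variants (linear/threshold x univariate/
multivariate) by k-fold cross-validation stratified by doe: posterior-mean
fixed effects and breeding values are estimated on the training folds and
used to predict held-out records; predictive ability is the Pearson
correlation r(y, y_hat) per fold, averaged across folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GibbsConfig, ModelSpec, PosteriorSamples, run_gibbs
from .pedigree import UNKNOWN, Pedigree

logger = logging.getLogger("caprigen")

__all__ = [
    "CVResult",
    "MODEL_VARIANTS",
    "kfold_split",
    "predict_held_out",
    "predictive_ability",
    "compare_models",
    "cv_chain_config",
]

MODEL_VARIANTS = (
    "linear-univariate",
    "threshold-univariate",
    "linear-multivariate",
    "threshold-multivariate",
)


def cv_chain_config(seed: int = 0) -> GibbsConfig:
    """Reduced chain protocol for cross-validation fits (20,000 / 2,000 / 20)."""
    return GibbsConfig(n_iter=20_000, burn_in=2_000, thin=20, seed=seed)


@dataclass
class CVResult:
    """Predictive ability of one model variant for one trait."""

    model_label: str
    trait: int
    per_fold_r: list
    n_folds: int
    seed: int
    failed: bool = False
    reason: str = ""

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_fold_r)) if self.per_fold_r else float("nan")

    @property
    def p_value(self) -> float:
        """Two-sided one-sample t-test of Fisher-z per-fold correlations vs 0."""
        z = np.arctanh(np.clip(np.asarray(self.per_fold_r, dtype=float), -0.999999, 0.999999))
        if z.size < 2 or z.std(ddof=1) == 0:
            return float("nan")
        return float(stats.ttest_1samp(z, 0.0).pvalue)


def kfold_split(records: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Doe-stratified fold assignment: all of a doe's parities share a fold.

    Returns a Series mapping doe_id -> fold in [0, k); fold sizes differ by
    at most one doe and the split is deterministic under ``seed``.
    """
    does = pd.unique(records["doe_id"].astype(str))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > does.size:
        raise ValueError(f"k = {k} exceeds the number of does ({does.size})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(does.size)
    folds = np.empty(does.size, dtype=np.int64)
    folds[perm] = np.arange(does.size) % k
    return pd.Series(folds, index=does, name="fold")


def predict_held_out(
    train_fit: PosteriorSamples, test_records: pd.DataFrame, ped: Pedigree
) -> np.ndarray:
    """Point predictions for held-out records from training posterior means.

    Linear traits predict x'b + a; threshold traits predict the success
    probability Phi(x'b + a) (threshold at 0).  Breeding values come from
    the training fit's posterior means — every pedigree animal has a slot,
    so unphenotyped test does are predicted through their relatives; a doe
    missing from the fit entirely falls back to the mean of its parents'
    posterior means.  Fixed-effect levels unseen in training contribute 0
    with a warning.
    """
    st = train_fit.structure
    t_of = {p: k for k, p in enumerate(st.traits)}
    index_map = ped.index_map
    a_mean = train_fit.a_mean
    b_mean = train_fit.b_mean
    preds = np.empty(len(test_records))
    unseen: set = set()
    for r, row in enumerate(test_records.itertuples(index=False)):
        parity = row.parity
        t = t_of[parity]
        xb = 0.0
        for fac in st.factors:
            key = (parity, fac, getattr(row, fac))
            j = st.effect_index.get(key)
            if j is not None:
                xb += b_mean[j]
            elif key not in st.reference_levels:  # baselines contribute 0
                unseen.add(key)
        i = index_map.get(str(row.doe_id))
        if i is not None and i < a_mean.shape[0]:
            ahat = a_mean[i, t]
        else:  # not in the fitted pedigree: parent-average rule
            ahat = 0.0
            if i is not None:
                par = [
                    a_mean[p, t]
                    for p in (ped.sire[i], ped.dam[i])
                    if p != UNKNOWN and p < a_mean.shape[0]
                ]
                if par:
                    ahat = float(np.mean(par))
        eta = xb + ahat
        preds[r] = stats.norm.cdf(eta) if st.scales_u8[t] else eta
    if unseen:
        warnings.warn(
            f"{len(unseen)} fixed-effect levels unseen in training predicted as 0: "
            f"{sorted(map(str, unseen))[:5]}"
        )
    return preds


def predictive_ability(observed, predicted) -> tuple[float, float]:
    """Pearson r(y, y_hat) with the two-sided t-test p-value on n-2 df."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observation/prediction pairs")
    if y.std() == 0 or yhat.std() == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    r, p = stats.pearsonr(y, yhat)
    return float(r), float(p)


def _variant_specs(label: str, traits, fixed_terms) -> list[ModelSpec]:
    scale = "linear" if label.startswith("linear") else "threshold"
    if label.endswith("univariate"):
        return [ModelSpec(traits=(t,), scale=scale, fixed_terms=fixed_terms) for t in traits]
    return [ModelSpec(traits=tuple(traits), scale=scale, fixed_terms=fixed_terms)]


def compare_models(
    records: pd.DataFrame,
    ped: Pedigree,
    model_variants=MODEL_VARIANTS,
    k: int = 5,
    chain_cfg: GibbsConfig | None = None,
    seed: int = 0,
    traits=(1, 2, 3),
    fixed_terms=("year", "season", "age_class"),
) -> tuple[list[CVResult], pd.Series]:
    """Cross-validate every model variant on byte-identical folds.

    Returns the per-variant-per-trait results ranked by mean_r (descending,
    within trait) plus the shared fold assignment.  A variant whose fit
    fails in any fold is flagged failed; the others are still reported.
    """
    base = chain_cfg or cv_chain_config()
    folds = kfold_split(records, k=k, seed=seed)
    rec_fold = records["doe_id"].astype(str).map(folds)
    results: list[CVResult] = []
    for vi, label in enumerate(model_variants):
        per_trait: dict[int, list[float]] = {t: [] for t in traits}
        failed, reason = False, ""
        for f in range(k):
            train = records[rec_fold != f]
            test = records[rec_fold == f]
            try:
                obs_all, pred_all = {}, {}
                for si, spec in enumerate(_variant_specs(label, traits, fixed_terms)):
                    sub_seed = int(
                        np.random.SeedSequence(seed, spawn_key=(vi, f, si)).generate_state(1)[0]
                        & 0x7FFFFFFF
                    )
                    cfg = GibbsConfig(
                        n_iter=base.n_iter, burn_in=base.burn_in, thin=base.thin, seed=sub_seed
                    )
                    sub_train = train[train["parity"].isin(spec.traits)]
                    fit = run_gibbs(sub_train, ped, spec, cfg)
                    sub_test = test[test["parity"].isin(spec.traits)]
                    preds = predict_held_out(fit, sub_test, ped)
                    for t in spec.traits:
                        m = (sub_test["parity"] == t).to_numpy()
                        obs_all[t] = sub_test.loc[m, "outcome"].to_numpy(dtype=float)
                        pred_all[t] = preds[m]
                for t in traits:
                    r, _ = predictive_ability(obs_all[t], pred_all[t])
                    per_trait[t].append(r)
            except Exception as exc:  # noqa: BLE001 - variant-level containment
                failed, reason = True, f"fold {f}: {exc}"
                logger.warning("variant %s failed in fold %d: %s", label, f, exc)
                break
        for t in traits:
            results.append(
                CVResult(
                    model_label=label,
                    trait=t,
                    per_fold_r=[] if failed else per_trait[t],
                    n_folds=k,
                    seed=seed,
                    failed=failed,
                    reason=reason,
                )
            )
    results.sort(key=lambda r: (r.trait, -(r.mean_r if r.per_fold_r else -np.inf)))
    return results, folds


def cv_table(results: list[CVResult]) -> pd.DataFrame:
    """Ranked predictive-ability table (trait, model, mean_r, p_value)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "model": r.model_label,
                "mean_r": r.mean_r,
                "p_value": r.p_value,
                "n_folds": r.n_folds,
                "failed": r.failed,
                "reason": r.reason,
            }
            for r in results
        ]
    )
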
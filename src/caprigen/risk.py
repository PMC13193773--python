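"""Logistic risk-factor analysis of abortion status.

One-trait-at-a-time logistic regressions of the binary abortion outcome on
the categorical herd factors (year, season, age class), reported as odds
ratios with 95% Wald confidence intervals and per-factor joint
significance tests.  The event modeled is an abortion (outcome = 1);
maximum-likelihood fitting is delegated to statsmodels.

Note on the link: odds ratios require the logit link
log(pi / (1 - pi)) = X beta, and that is what is fitted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "odds_ratios",
    "factor_test",
    "risk_table",
]


@dataclass
class LogisticFit:
    """Converged ML logistic fit with factor-level bookkeeping.

    ``term_index`` maps factor -> list of (level, column index); the
    intercept is column 0.  ``reference_levels`` records each factor's
    baseline.
    """

    coefficients: pd.Series
    cov_matrix: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool
    reference_levels: dict
    term_index: dict
    _y: np.ndarray = None  # retained for likelihood-ratio refits
    _x: pd.DataFrame = None


def _design(
    records: pd.DataFrame, outcome: str, factors, reference_levels: dict | None
) -> tuple[np.ndarray, pd.DataFrame, dict, dict]:
    refs, term_index = {}, {}
    cols = {"const": np.ones(len(records))}
    for fac in factors:
        values = records[fac]
        levels = sorted(pd.unique(values), key=str)
        if len(levels) < 2:
            warnings.warn(f"factor {fac!r} has a single observed level; dropped")
            continue
        ref = (reference_levels or {}).get(fac, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for factor {fac!r}")
        refs[fac] = ref
        term_index[fac] = []
        for lev in levels:
            if lev == ref:
                continue
            name = f"{fac}[{lev}]"
            cols[name] = (values == lev).to_numpy(dtype=float)
            term_index[fac].append((lev, len(cols) - 1))
    x = pd.DataFrame(cols, index=records.index)
    y = records[outcome].to_numpy(dtype=float)
    return y, x, refs, term_index


def fit_logistic(
    records: pd.DataFrame,
    factors=("year", "season", "age_class"),
    reference_levels: dict | None = None,
    outcome: str = "outcome",
) -> LogisticFit:
    """ML logistic regression of a binary outcome on categorical factors.

    Raises on constant outcomes and on complete separation (the Newton
    fit fails to converge).  Factors with a single observed level are
    dropped with a warning.
    """
    y_raw = records[outcome].to_numpy(dtype=float)
    if np.unique(y_raw).size < 2:
        raise ValueError("outcome is constant; logistic model is degenerate")
    y, x, refs, term_index = _design(records, outcome, factors, reference_levels)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(disp=0, maxiter=200, tol=1e-10)
    except Exception as exc:
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (possible complete separation)")
    return LogisticFit(
        coefficients=pd.Series(res.params, index=x.columns),
        cov_matrix=np.asarray(res.cov_params()),
        log_likelihood=float(res.llf),
        n_obs=len(y),
        converged=True,
        reference_levels=refs,
        term_index=term_index,
        _y=y,
        _x=x,
    )


def odds_ratios(fit: LogisticFit, level: float = 0.95) -> pd.DataFrame:
    """Per-level odds ratios exp(beta) with Wald confidence intervals."""
    if not fit.converged:
        raise ValueError("cannot report odds ratios from a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    se_all = np.sqrt(np.diag(fit.cov_matrix))
    for fac, pairs in fit.term_index.items():
        rows.append(
            {"factor": fac, "level": fit.reference_levels[fac], "odds_ratio": 1.0,
             "ci_low": np.nan, "ci_high": np.nan, "reference": True}
        )
        for lev, j in pairs:
            beta = fit.coefficients.iloc[j]
            se = se_all[j]
            rows.append(
                {"factor": fac, "level": lev, "odds_ratio": float(np.exp(beta)),
                 "ci_low": float(np.exp(beta - z * se)),
                 "ci_high": float(np.exp(beta + z * se)), "reference": False}
            )
    return pd.DataFrame(rows)


def factor_test(fit: LogisticFit, factor: str, kind: str = "wald") -> float:
    """Joint test that all of a factor's level coefficients are zero.

    ``kind='wald'`` uses the chi-square Wald statistic b' V^-1 b on as many
    df as non-reference levels; ``kind='lrt'`` refits without the factor.
    A singular Wald sub-covariance falls back to the LRT with a warning.
    """
    if factor not in fit.term_index:
        raise KeyError(f"factor {factor!r} not in the fitted model")
    idx = [j for _, j in fit.term_index[factor]]
    if kind == "wald":
        beta = fit.coefficients.iloc[idx].to_numpy()
        sub = fit.cov_matrix[np.ix_(idx, idx)]
        try:
            stat = float(beta @ np.linalg.solve(sub, beta))
        except np.linalg.LinAlgError:
            warnings.warn("singular Wald sub-covariance; falling back to LRT")
            return factor_test(fit, factor, kind="lrt")
        return float(stats.chi2.sf(stat, df=len(idx)))
    if kind == "lrt":
        keep = [c for c in fit._x.columns if not c.startswith(f"{factor}[")]
        res0 = sm.Logit(fit._y, fit._x[keep]).fit(disp=0, maxiter=200)
        stat = 2.0 * (fit.log_likelihood - float(res0.llf))
        return float(stats.chi2.sf(max(stat, 0.0), df=len(idx)))
    raise ValueError(f"unknown test kind {kind!r}")


def risk_table(fits: dict, level: float = 0.95, test_kind: str = "wald") -> pd.DataFrame:
    """Merged multi-trait report: one block per factor and level, one
    OR(CI)/p-value column pair per trait.

    ``fits`` maps a trait label to a :class:`LogisticFit` or to an
    exception/string describing why that trait's fit failed.
    """
    frames = []
    for trait, fit in fits.items():
        if not isinstance(fit, LogisticFit):
            frames.append(
                pd.DataFrame(
                    [{"factor": "-", "level": "-", f"or_ci[{trait}]": f"failed: {fit}",
                      f"p_value[{trait}]": np.nan}]
                )
            )
            continue
        ors = odds_ratios(fit, level)
        col = []
        for _, row in ors.iterrows():
            if row["reference"]:
                col.append("Reference")
            else:
                col.append(
                    f"{row['odds_ratio']:.2f}({row['ci_low']:.2f}-{row['ci_high']:.2f})"
                )
        block = ors[["factor", "level"]].astype(str)
        block[f"or_ci[{trait}]"] = col
        pvals = {fac: factor_test(fit, fac, test_kind) for fac in fit.term_index}
        block[f"p_value[{trait}]"] = block["factor"].map(pvals)
        frames.append(block)
    out = frames[0]
    for block in frames[1:]:
        out = out.merge(block, on=["factor", "level"], how="outer")
    return out
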
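"""Posterior summaries for MCMC draws.

Posterior mean, posterior standard deviation (PSD), 95% highest-posterior-
density intervals by the empirical shortest-interval rule, effective sample
size with Geyer's initial-positive-sequence truncation, and trace-plot
export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSummary",
    "summarize",
    "hpd_interval",
    "effective_sample_size",
    "export_traces",
    "summary_table",
]


@dataclass(frozen=True)
class ParameterSummary:
    """Posterior mean +/- PSD with 95% HPD bounds and ESS.

    ``significant`` flags parameters whose HPD interval excludes zero —
    the decision rule used for heritabilities and correlations.
    """

    name: str
    mean: float
    psd: float
    hpd_low: float
    hpd_high: float
    ess: float
    significant: bool

    def __format__(self, _spec: str) -> str:
        return f"{self.mean:.2f}±{self.psd:.2f}({self.hpd_low:.2f}:{self.hpd_high:.2f})"


def hpd_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over sorted draws holding ``level`` mass."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    m = int(np.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m])


def effective_sample_size(draws) -> float:
    """ESS = n / (1 + 2 sum rho_k), Geyer initial-positive-sequence truncation.

    Autocorrelations are accumulated in lag pairs (rho_{2k} + rho_{2k+1})
    until a pair goes non-positive; the result is capped at n.  A
    zero-variance chain is reported as n with a degeneracy warning.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws for an ESS estimate")
    var = x.var()
    if var == 0:
        warnings.warn("zero-variance chain; ESS reported as the number of draws")
        return float(n)
    xc = x - x.mean()
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def summarize(draws, level: float = 0.95, name: str = "") -> ParameterSummary:
    """Mean, PSD, HPD interval, ESS and HPD-excludes-zero flag for a chain."""
    x = np.asarray(draws, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 draws to summarize a posterior")
    lo, hi = hpd_interval(x, level)
    return ParameterSummary(
        name=name,
        mean=float(x.mean()),
        psd=float(x.std(ddof=1)),
        hpd_low=lo,
        hpd_high=hi,
        ess=effective_sample_size(x),
        significant=not (lo <= 0.0 <= hi),
    )


def summary_table(summaries) -> pd.DataFrame:
    """Machine-readable summary table (one row per parameter)."""
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "mean": s.mean,
                "psd": s.psd,
                "hpd_low": s.hpd_low,
                "hpd_high": s.hpd_high,
                "ess": s.ess,
                "significant": s.significant,
            }
            for s in summaries
        ]
    )


def export_traces(draws: np.ndarray, labels, path) -> list[Path]:
    """Write one trace-plot PNG per parameter plus a tidy draws CSV.

    ``draws`` is (n_draws, n_params).  Plot failures never corrupt the
    numeric draws file.  Returns the written file paths.
    """
    labels = list(labels)
    if not labels:
        warnings.warn("no parameter labels supplied; nothing exported")
        return []
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[1] != len(labels):
        draws = draws.T
    frame = pd.DataFrame(draws, columns=labels)
    written = [out / "draws.csv"]
    frame.to_csv(written[0], index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for lab in labels:
            fig, ax = plt.subplots(figsize=(6, 2.2))
            ax.plot(frame[lab].to_numpy(), lw=0.6)
            ax.set_xlabel("retained iteration")
            ax.set_ylabel(lab)
            fig.tight_layout()
            target = out / f"trace_{lab.replace(':', '_').replace('=', '_')}.png"
            fig.savefig(target, dpi=100)
            plt.close(fig)
            written.append(target)
    except Exception as exc:  # plotting must never break numeric output
        warnings.warn(f"trace plotting failed: {exc}")
    return written
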
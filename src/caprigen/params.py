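"""Genetic parameters derived from (co)variance draws.

Heritabilities, genetic correlations and phenotypic correlations are
computed draw-by-draw from the retained G0/R0 samples and then summarized
(posterior mean, PSD, HPD) — never as ratios of posterior means.
Heritability of threshold traits is on the liability scale (residual
variance pinned to 1), so h2 = g / (g + 1) per draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorSamples
from .posterior import ParameterSummary, summarize

logger = logging.getLogger("caprigen")

__all__ = ["ParameterDraws", "derive_parameters", "parameter_matrix", "render_matrix"]


@dataclass
class ParameterDraws:
    """Per-draw heritabilities and correlation coefficients.

    ``h2`` maps trait label -> draw vector; ``r_g`` and ``r_p`` map trait
    pairs (i, j), i < j, -> draw vectors.  ``n_dropped`` counts draws
    excluded because a variance was zero (undefined ratio).
    """

    h2: dict
    r_g: dict
    r_p: dict
    traits: tuple
    n_dropped: int = 0


def derive_parameters(samples: PosteriorSamples | tuple) -> ParameterDraws:
    """Transform aligned G0/R0 draws into parameter draws.

    Accepts a :class:`PosteriorSamples` or a raw ``(g0, r0, traits)`` tuple
    of aligned (n, T, T) arrays.
    """
    if isinstance(samples, PosteriorSamples):
        g0, r0, traits = samples.g0, samples.r0, samples.structure.traits
    else:
        g0, r0, traits = samples
        g0 = np.asarray(g0, dtype=float)
        r0 = np.asarray(r0, dtype=float)
    nt = g0.shape[1]
    gd = np.einsum("ntt->nt", g0)  # diagonal views per draw
    rd = np.einsum("ntt->nt", r0)
    ok = (gd > 0).all(axis=1) & (rd > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%d draws dropped (zero variance component)", n_dropped)
    g0, r0, gd, rd = g0[ok], r0[ok], gd[ok], rd[ok]
    h2 = {traits[i]: gd[:, i] / (gd[:, i] + rd[:, i]) for i in range(nt)}
    r_g, r_p = {}, {}
    for i in range(nt):
        for j in range(i + 1, nt):
            r_g[(traits[i], traits[j])] = g0[:, i, j] / np.sqrt(gd[:, i] * gd[:, j])
            r_p[(traits[i], traits[j])] = (g0[:, i, j] + r0[:, i, j]) / np.sqrt(
                (gd[:, i] + rd[:, i]) * (gd[:, j] + rd[:, j])
            )
    return ParameterDraws(h2=h2, r_g=r_g, r_p=r_p, traits=tuple(traits), n_dropped=n_dropped)


def parameter_matrix(draws: ParameterDraws, level: float = 0.95) -> pd.DataFrame:
    """Trait x trait summary grid.

    Heritability summaries on the diagonal, genetic correlations above it,
    phenotypic correlations below; each cell is a
    :class:`~caprigen.posterior.ParameterSummary`.
    """
    traits = draws.traits
    nt = len(traits)
    grid = pd.DataFrame(index=list(traits), columns=list(traits), dtype=object)
    for i, ti in enumerate(traits):
        grid.loc[ti, ti] = summarize(draws.h2[ti], level, name=f"h2[{ti}]")
        for j in range(i + 1, nt):
            tj = traits[j]
            grid.loc[ti, tj] = summarize(draws.r_g[(ti, tj)], level, name=f"r_g[{ti},{tj}]")
            grid.loc[tj, ti] = summarize(draws.r_p[(ti, tj)], level, name=f"r_p[{ti},{tj}]")
    return grid


def render_matrix(grid: pd.DataFrame, path=None, heatmap_path=None) -> str:
    """Render the grid as delimited text (cells "mean±psd(lo:hi)") and,
    optionally, a correlation heat map."""
    text = grid.map(lambda c: format(c) if isinstance(c, ParameterSummary) else "")
    out = text.to_csv(sep="\t")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    if heatmap_path is not None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            vals = grid.map(lambda c: c.mean if isinstance(c, ParameterSummary) else np.nan)
            fig, ax = plt.subplots(figsize=(4.5, 4))
            im = ax.imshow(vals.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
            ax.set_xticks(range(len(grid.columns)), [f"parity {c}" for c in grid.columns])
            ax.set_yticks(range(len(grid.index)), [f"parity {c}" for c in grid.index])
            for i in range(len(grid.index)):
                for j in range(len(grid.columns)):
                    cell = grid.iloc[i, j]
                    if isinstance(cell, ParameterSummary):
                        ax.text(j, i, f"{cell.mean:.2f}", ha="center", va="center")
            fig.colorbar(im, label="posterior mean")
            fig.tight_layout()
            fig.savefig(heatmap_path, dpi=120)
            plt.close(fig)
        except Exception as exc:
            logger.warning("heat-map rendering failed: %s", exc)
    return out
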
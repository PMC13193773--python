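"""Synthetic herd generator.

Simulates a multi-generation goat pedigree and parity-wise binary abortion
records under the liability threshold model: latent liability = fixed
effects (year, season, age class) + additive genetic value + residual,
outcome = 1 when the liability exceeds a calibrated threshold.

Default parameters emulate a mid-sized intensive dairy-goat herd: a 15:1
doe-to-buck mating ratio, three parities treated as three genetically
distinct traits with liability-scale heritabilities (0.25, 0.11, 0.19),
genetic correlations (0.23, 0.29, 0.48), incidences (0.15, 0.18, 0.15) and
declining record counts across parities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import UNKNOWN, Pedigree, pedigree_from_records

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "simulate_dataset",
    "calibrate_threshold",
    "default_g0",
    "default_r0",
]


def _cov_from_corr(variances, corr):
    sd = np.sqrt(np.asarray(variances, dtype=float))
    return np.outer(sd, sd) * np.asarray(corr, dtype=float)


def default_g0(h2=(0.25, 0.11, 0.19), r_g=(0.23, 0.29, 0.48)) -> np.ndarray:
    """Genetic covariance implied by liability h2 with unit residual variance.

    With the threshold-model constraint sigma2_e = 1, h2 = g/(g+1) inverts to
    g = h2/(1-h2) per trait; off-diagonals follow from the genetic
    correlations (order: 1-2, 1-3, 2-3).
    """
    h2 = np.asarray(h2, dtype=float)
    g = h2 / (1.0 - h2)
    corr = np.array([[1, r_g[0], r_g[1]], [r_g[0], 1, r_g[2]], [r_g[1], r_g[2], 1.0]])
    return _cov_from_corr(g, corr[: len(h2), : len(h2)])


def default_r0(r_e=(0.0635, -0.1709, 0.0832), n_traits: int = 3) -> np.ndarray:
    """Unit-diagonal residual covariance (threshold identifiability scale).

    The default residual correlations are the values that combine with
    :func:`default_g0` to give phenotypic correlations of about
    (0.09, -0.07, 0.14) between the three parities.
    """
    corr = np.array([[1, r_e[0], r_e[1]], [r_e[0], 1, r_e[2]], [r_e[1], r_e[2], 1.0]])
    return corr[:n_traits, :n_traits].copy()


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic herd."""

    n_founder_sires: int = 200
    n_founder_dams: int = 3000
    does_per_buck: float = 15.0
    n_generations: int = 3
    offspring_per_dam: int = 2
    # which females carry abortion records: 'terminal' phenotypes only the
    # youngest generation's does, leaving the bulk of the pedigree as
    # unphenotyped ancestors (a few pedigree animals per record, as herd
    # books typically look); 'all' phenotypes every female
    phenotype: str = "terminal"
    n_traits: int = 3
    g0: np.ndarray = field(default_factory=default_g0)
    r0: np.ndarray = field(default_factory=default_r0)
    incidence_targets: tuple = (0.15, 0.18, 0.15)
    # per-level liability effects; first level of each factor is the baseline
    year_effects: tuple = (0.0, 0.25, 0.20, 0.15, 0.10, 0.05, -0.05)
    season_effects: tuple = (0.0, -0.25)
    age_effects: tuple = (0.0, -0.30, -0.45, -0.50)
    # probability a doe's parity-p record is retained (declining with parity)
    missingness: tuple = (1.0, 0.817, 0.596)
    seed: int = 20170101

    def __post_init__(self):
        self.g0 = np.atleast_2d(np.asarray(self.g0, dtype=float))
        self.r0 = np.atleast_2d(np.asarray(self.r0, dtype=float))
        for name, m in (("g0", self.g0), ("r0", self.r0)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if any(not 0 < p < 1 for p in self.incidence_targets[: self.n_traits]):
            raise ValueError("incidence_targets must lie in (0, 1)")
        if self.does_per_buck < 1:
            raise ValueError("does_per_buck must be >= 1")


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    breeding_values: np.ndarray  # animal x trait, pedigree order
    liabilities: pd.DataFrame  # record-level latent values
    records: pd.DataFrame  # doe_id, parity, outcome, year, season, age_class
    truth: dict

    def write(self, pedigree_path, phenotype_path, truth_path=None) -> None:
        self.pedigree.write(pedigree_path)
        self.records.to_csv(phenotype_path, index=False)
        if truth_path is not None:
            import yaml

            truth = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.truth.items()
            }
            with open(truth_path, "w") as fh:
                yaml.safe_dump(truth, fh)


# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree under a does-per-buck mating design.

    Founders are unrelated; each later generation mates the previous
    generation's females to a sire pool drawn at roughly one buck per
    ``does_per_buck`` does, so half sibs (and, from generation two on,
    matings between relatives, hence inbreeding) arise naturally.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[str, str | None, str | None]] = []
    males = [f"S{i:05d}" for i in range(cfg.n_founder_sires)]
    females = [f"D{i:05d}" for i in range(cfg.n_founder_dams)]
    for a in males + females:
        records.append((a, None, None))
    counter = 0
    for gen in range(1, cfg.n_generations + 1):
        n_bucks = max(1, int(round(len(females) / cfg.does_per_buck)))
        bucks = list(rng.choice(males, size=min(n_bucks, len(males)), replace=False))
        dams = list(females)
        rng.shuffle(dams)
        new_males, new_females = [], []
        for k, dam in enumerate(dams):
            sire = bucks[(k // int(cfg.does_per_buck)) % len(bucks)]
            for _ in range(cfg.offspring_per_dam):
                male = rng.random() < 0.5
                aid = f"{'M' if male else 'F'}{gen}{counter:06d}"
                counter += 1
                records.append((aid, sire, dam))
                (new_males if male else new_females).append(aid)
        males, females = new_males, new_females
    return pedigree_from_records(records)


def simulate_breeding_values(
    ped: Pedigree, g0: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Breeding values with covariance A (x) G0, by gene dropping.

    Founders are N(0, G0); descendants are the parent average plus a
    Mendelian-sampling deviation N(0, d_i G0) with d_i shrunk by parental
    inbreeding; an unknown parent contributes 0 with compensating d_i.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    t = g0.shape[0]
    w, v = np.linalg.eigh(g0)
    if w.min() < -1e-8:
        raise ValueError("g0 must be positive semi-definite")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    n = ped.n
    a = np.zeros((n, t))
    f = ped.inbreeding
    z = rng.standard_normal((n, t))
    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        mean = np.zeros(t)
        if si != UNKNOWN and di != UNKNOWN:
            mean = 0.5 * (a[si] + a[di])
            d_i = 0.5 - 0.25 * (f[si] + f[di])
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            mean = 0.5 * a[p]
            d_i = 0.75 - 0.25 * f[p]
        else:
            d_i = 1.0
        a[i] = mean + np.sqrt(d_i) * (factor @ z[i])
    return a


def calibrate_threshold(
    target_incidence: float, fixed_part, total_variance: float, tol: float = 1e-6
) -> float:
    """Threshold t with E[Phi((mu_fixed - t)/sigma)] = target, by bisection."""
    if not 0 < target_incidence < 1:
        raise ValueError("target incidence must be in (0, 1)")
    mu = np.asarray(fixed_part, dtype=float)
    sd = float(np.sqrt(total_variance))

    def excess(t):
        return float(np.mean(stats.norm.sf((t - mu) / sd))) - target_incidence

    lo = mu.min() - 10 * sd
    hi = mu.max() + 10 * sd
    return float(optimize.bisect(excess, lo, hi, xtol=tol))


def simulate_records(
    ped: Pedigree, breeding_values: np.ndarray, cfg: SimulationConfig
) -> SimulatedDataset:
    """Parity-wise binary records for every female in the pedigree.

    Residuals are per-doe trait vectors drawn from R0, so residual
    covariance between a doe's parities is preserved; per-trait thresholds
    are calibrated so expected incidence matches ``incidence_targets``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    t = cfg.n_traits
    if cfg.phenotype == "terminal" and cfg.n_generations >= 1:
        tip = f"F{cfg.n_generations}"
        is_doe = np.array([aid.startswith(tip) for aid in ped.ids])
    else:
        is_doe = np.array([aid[0] in ("D", "F") for aid in ped.ids])
    doe_idx = np.flatnonzero(is_doe)
    n_doe = doe_idx.size
    # fixed-effect level draws: year uniform; season uniform; age tied to parity
    year = rng.integers(0, len(cfg.year_effects), size=(n_doe, t))
    season = rng.integers(0, len(cfg.season_effects), size=(n_doe, t))
    age = np.empty((n_doe, t), dtype=int)
    for p in range(t):
        # parity p+1 -> age classes p or p+1 (ages advance with parity)
        hi = min(p + 1, len(cfg.age_effects) - 1)
        age[:, p] = np.where(rng.random(n_doe) < 0.5, p, hi)
    year_e = np.asarray(cfg.year_effects)[year]
    season_e = np.asarray(cfg.season_effects)[season]
    age_e = np.asarray(cfg.age_effects)[age]
    fixed = year_e + season_e + age_e

    resid = rng.multivariate_normal(np.zeros(t), cfg.r0, size=n_doe, method="svd")
    liab = fixed + breeding_values[doe_idx, :t] + resid

    thresholds = np.empty(t)
    outcomes = np.empty((n_doe, t), dtype=int)
    for p in range(t):
        sigma2 = cfg.g0[p, p] + cfg.r0[p, p]
        thresholds[p] = calibrate_threshold(cfg.incidence_targets[p], fixed[:, p], sigma2)
        outcomes[:, p] = (liab[:, p] > thresholds[p]).astype(int)

    keep = rng.random((n_doe, t)) < np.asarray(cfg.missingness)[:t]
    rows = []
    liab_rows = []
    ids = np.asarray(ped.ids, dtype=object)
    for j, i in enumerate(doe_idx):
        for p in range(t):
            if keep[j, p]:
                rows.append(
                    (ids[i], p + 1, outcomes[j, p], 2017 + year[j, p],
                     season[j, p] + 1, age[j, p] + 1)
                )
                liab_rows.append((ids[i], p + 1, liab[j, p]))
    records = pd.DataFrame(
        rows, columns=["doe_id", "parity", "outcome", "year", "season", "age_class"]
    )
    liabilities = pd.DataFrame(liab_rows, columns=["doe_id", "parity", "liability"])
    truth = {
        "g0": cfg.g0.copy(),
        "r0": cfg.r0.copy(),
        "thresholds": thresholds,
        "h2": np.diag(cfg.g0) / (np.diag(cfg.g0) + np.diag(cfg.r0)),
        "year_effects": list(cfg.year_effects),
        "season_effects": list(cfg.season_effects),
        "age_effects": list(cfg.age_effects),
        "incidence_targets": list(cfg.incidence_targets[:t]),
        "seed": cfg.seed,
    }
    return SimulatedDataset(ped, breeding_values, liabilities, records, truth)


def simulate_dataset(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """End-to-end convenience wrapper: pedigree -> breeding values -> records."""
    cfg = cfg or SimulationConfig()
    ped = simulate_pedigree(cfg)
    bv = simulate_breeding_values(ped, cfg.g0, np.random.default_rng(cfg.seed + 2))
    return simulate_records(ped, bv, cfg)
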
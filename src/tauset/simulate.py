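"""Synthetic ranked gene-set / gene-list pairs and benchmark machinery.

The generator reproduces a simple latent-score design for rank data: a gene
set is built by mixing ``m`` *correlated* genes — whose set score S and list
score L are drawn from a standard bivariate normal with correlation ``r`` —
with ``n = round(q * m)`` *noise* genes whose S and L are independent
standard normals.  ``q`` is therefore the noise-to-correlated mixing ratio
(the default grid spans 0.15 to 0.55 in steps of 0.025, with ``r`` in
[-0.8, 0.8]).  The gene list additionally carries independent background
genes that are not members of the set.

On top of the generator the module provides the calibration experiment
(asymptotic versus permutation p-values over a (q, r) design), detection
(positive-rate) experiments, and confusion-matrix performance metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _st
from .io import RankedGeneList, RankedGeneSet

__all__ = [
    "ConfusionMetrics",
    "SimConfig",
    "calibration_experiment",
    "confusion_metrics",
    "log10_p_correlation",
    "positive_rate_table",
    "simulate_pair",
]

#: Default q grid: 0.15 to 0.55 in steps of 0.025.
Q_GRID = tuple(np.round(np.arange(0.15, 0.5501, 0.025), 4))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated set/list pair.

    Attributes
    ----------
    m_correlated : number of correlated genes (set size is ``m * (1 + q)``).
    q : noise-to-correlated mixing ratio; ``round(q * m)`` independent noise
        genes are mixed into the set.
    r : latent correlation between set and list scores of correlated genes,
        in [-0.8, 0.8] by convention (any value in (-1, 1) is accepted).
    n_background : extra gene-list genes that are not set members.
    seed : random seed.
    """

    m_correlated: int = 500
    q: float = 0.25
    r: float = 0.0
    n_background: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_correlated < 2:
            raise ValueError("m_correlated must be >= 2")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        if not -1.0 < self.r < 1.0:
            raise ValueError("r must lie in (-1, 1)")


def _draw_scores(rng: np.random.Generator, m: int, q: float, r: float):
    """Set scores S and list scores L for the ``m + round(q m)`` set genes."""
    n_noise = int(round(q * m))
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    s_corr = z1
    l_corr = r * z1 + math.sqrt(1.0 - r * r) * z2
    s_noise = rng.standard_normal(n_noise)
    l_noise = rng.standard_normal(n_noise)
    return np.concatenate([s_corr, s_noise]), np.concatenate([l_corr, l_noise])


def simulate_pair(cfg: SimConfig | None = None, **overrides):
    """Draw one (RankedGeneSet, RankedGeneList) pair under ``cfg``.

    Deterministic given the seed.  The set members' list scores follow the
    mixture described in the module docstring; the list is padded with
    ``n_background`` independent background genes.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either cfg or keyword parameters, not both")
    rng = np.random.default_rng(cfg.seed)
    s_scores, l_scores = _draw_scores(rng, cfg.m_correlated, cfg.q, cfg.r)
    n_set = s_scores.size
    set_genes = [f"g{i:06d}" for i in range(n_set)]
    bg_genes = [f"bg{i:06d}" for i in range(cfg.n_background)]
    bg_scores = rng.standard_normal(cfg.n_background)
    gene_set = RankedGeneSet("SIM", f"q={cfg.q} r={cfg.r}", set_genes, s_scores)
    gene_list = RankedGeneList(set_genes + bg_genes,
                               np.concatenate([l_scores, bg_scores]))
    return gene_set, gene_list


def _paired_ranks(rng: np.random.Generator, m: int, q: float, r: float):
    """List ranks in set-rank order for one simulated pair (fast path).

    Background genes never enter the statistic because both rankings are
    re-ranked within the overlap, so the experiment functions draw only the
    set members' scores.
    """
    s, l = _draw_scores(rng, m, q, r)
    order = np.argsort(-s, kind="mergesort")
    return np.argsort(np.argsort(-l[order], kind="mergesort")) + 1.0


class _WeightCache:
    """Per-overlap-size cache of weights and null moments (mode=set)."""

    def __init__(self, shape: float):
        self.shape = shape
        self._cache: dict[int, tuple] = {}

    def get(self, n: int):
        if n not in self._cache:
            u = _st.weight_function(np.arange(1, n + 1, dtype=float), n, self.shape)
            i0, i1 = np.triu_indices(n, 1)
            w = u[i0] * u[i1]
            _, var = _st.null_moments(u)
            self._cache[n] = (u, i0, i1, w, float(w.sum()), var)
        return self._cache[n]


def calibration_experiment(q_values=Q_GRID, r_values="uniform", reps: int = 6,
                           n_perm: int = 2000, seed: int = 0,
                           m_correlated: int = 200, shape: float = 0.5,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Asymptotic vs permutation p-values over a (q, r) design.

    For every cell (q, r) and replicate, a pair is simulated, the default
    set-weighted tau test is run, and the asymptotic p, the ``n_perm``-
    permutation p (skipped when ``n_perm == 0``) and the ``p < alpha`` flag
    are recorded.  ``r_values='uniform'`` draws r uniformly from
    [-0.8, 0.8] per replicate (scatter mode); otherwise an explicit grid of
    r values is iterated (grid mode).

    Returns a DataFrame with columns ``q, r, n, tau, z, p_asymptotic,
    p_permutation, detected``.
    """
    rng = np.random.default_rng(seed)
    cache = _WeightCache(shape)
    rows = []
    scatter = isinstance(r_values, str) and r_values == "uniform"
    r_grid = [None] if scatter else list(r_values)
    for q in q_values:
        for r_cell in r_grid:
            for _ in range(reps):
                r = float(rng.uniform(-0.8, 0.8)) if scatter else float(r_cell)
                R = _paired_ranks(rng, m_correlated, q, r)
                n = R.size
                u, i0, i1, w, denom, var = cache.get(n)
                num = float(np.dot(w, np.sign(R[i1] - R[i0])))
                z, p_asym = _st.normal_p_value(num, var)
                if n_perm:
                    p_perm = _permutation_p(rng, R, w, i0, i1, denom,
                                            abs(num) / denom, n_perm)
                else:
                    p_perm = np.nan
                rows.append((q, r, n, num / denom, z, p_asym, p_perm,
                             p_asym < alpha))
    return pd.DataFrame(rows, columns=[
        "q", "r", "n", "tau", "z", "p_asymptotic", "p_permutation", "detected"])


def _permutation_p(rng, R, w, i0, i1, denom, tau_obs, n_perm, batch=250):
    """Fixed-weight permutation p (add-one estimator) for the fast path."""
    w32 = w.astype(np.float32)
    hits = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.tile(R, (b, 1)), axis=1)
        S = np.sign(P[:, i1] - P[:, i0]).astype(np.float32)
        taus = np.abs(S @ w32) / denom
        hits += int((taus >= tau_obs - 1e-12).sum())
        done += b
    return (1 + hits) / (n_perm + 1)


def log10_p_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of log10 asymptotic vs log10 permutation p."""
    sub = table.dropna(subset=["p_permutation"])
    x = np.log10(sub["p_asymptotic"].to_numpy())
    y = np.log10(sub["p_permutation"].to_numpy())
    return float(np.corrcoef(x, y)[0, 1])


def positive_rate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise detection rates: q rows, r columns, mean of ``detected``."""
    return table.pivot_table(index="q", columns="r", values="detected",
                             aggfunc="mean")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the seven derived performance measures.

    Undefined ratios (0/0) follow these conventions: precision and F1 are 0
    when nothing is called; sensitivity with an empty gold set, or
    specificity with an empty negative set, are NaN and the condition is
    recorded in ``flags``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sen: float
    spe: float
    pre: float
    acc: float
    err: float
    f1: float
    sqr_p: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def confusion_metrics(called, gold, universe) -> ConfusionMetrics:
    """Confusion matrix of a call set against a gold set over a universe.

    ``SQR_P`` is the geometric mean of sensitivity and specificity
    (the G-mean "geometry performance" summary).
    """
    called, gold, universe = set(called), set(gold), set(universe)
    if not called <= universe:
        raise ValueError("called set must be contained in the universe")
    if not gold <= universe:
        raise ValueError("gold set must be contained in the universe")
    tp = len(called & gold)
    fp = len(called - gold)
    fn = len(gold - called)
    tn = len(universe) - tp - fp - fn
    flags = []
    if tp + fn > 0:
        sen = tp / (tp + fn)
    else:
        sen = math.nan
        flags.append("sensitivity undefined: empty gold set")
    if tn + fp > 0:
        spe = tn / (tn + fp)
    else:
        spe = math.nan
        flags.append("specificity undefined: no negatives")
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    acc = (tp + tn) / len(universe) if universe else math.nan
    err = 1.0 - acc
    if math.isnan(sen):
        f1 = math.nan
    else:
        f1 = 2 * sen * pre / (sen + pre) if (sen + pre) > 0 else 0.0
    sqr_p = math.sqrt(sen * spe) if not (math.isnan(sen) or math.isnan(spe)) \
        else math.nan
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sen=sen, spe=spe,
                            pre=pre, acc=acc, err=err, f1=f1, sqr_p=sqr_p,
                            flags=tuple(flags))
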
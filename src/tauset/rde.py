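"""Build ranked gene lists from an expression matrix.

Starting from a nonnegative gene-by-sample expression matrix (consensus
nTPM-like values), the workflow is:

1. quantile-normalize the columns so every sample shares one distribution;
2. for each target sample compute the leave-one-out differential expression
   ``DE_i(g) = e_i(g) - mean(e_other(g))``;
3. assess each DE with a one-sample Student t statistic that asks whether
   the held-out observation is consistent with the other samples
   (prediction-interval form): ``t = DE / (s_other * sqrt(1 + 1/(N-1)))``
   with ``df = N - 2``;
4. adjust p-values across genes within the target sample (BH-FDR);
5. convert to a signed rank metric ``RDE = sign(DE) * (-log10(FDR))``, and
   rank genes by descending RDE.

Tissue/cell-line-specific genes are called from the same statistics with a
fold-change and an FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import RankedGeneList, write_gene_list
from .stats import bh_fdr

__all__ = [
    "TissueSpecificity",
    "TissueSpecificityResults",
    "call_specific_genes",
    "de_p_value",
    "de_table",
    "differential_expression",
    "quantile_normalize",
    "rde_score",
]

#: FDR values below this floor are clipped before taking -log10.
RDE_FLOOR = 1e-300


def _as_matrix(mat) -> pd.DataFrame:
    df = pd.DataFrame(mat)
    if df.size == 0:
        raise ValueError("empty expression matrix")
    return df.astype(float)


def quantile_normalize(mat) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    Every column is mapped onto the reference distribution formed by the
    row-wise mean of the sorted columns, so all columns share an identical
    sorted value vector.  Tied values within a column receive the mean of
    their tie group's reference quantiles.
    """
    df = _as_matrix(mat)
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = df.to_numpy()
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the assigned quantile values over tie groups
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def differential_expression(mat, target) -> pd.Series:
    """Leave-one-out DE: target column minus the mean of the other columns."""
    df = _as_matrix(mat)
    if df.shape[1] < 3:
        raise ValueError("differential expression needs at least 3 samples")
    others = df.drop(columns=[target])
    return df[target] - others.mean(axis=1)


def de_p_value(mat, target, method: str = "prediction") -> pd.DataFrame:
    """Per-gene DE, t statistic and two-sided p for one target sample.

    ``method='prediction'`` (default) treats the target as a held-out
    observation from the other samples' distribution:
    ``t = DE / (s * sqrt(1 + 1/(N-1)))``.  ``method='mean'`` instead tests
    the others' mean against the target value as a fixed constant:
    ``t = DE / (s / sqrt(N-1))``.  Both use ``df = N - 2`` (the degrees of
    freedom of ``s``, the standard deviation of the N-1 other samples).

    Genes with zero variance across the other samples get ``p = 1`` and are
    flagged in the ``degenerate`` column rather than raising.
    """
    if method not in ("prediction", "mean"):
        raise ValueError(f"unknown t construction {method!r}")
    df = _as_matrix(mat)
    n_samples = df.shape[1]
    if n_samples < 3:
        raise ValueError("p-value computation needs at least 3 samples")
    others = df.drop(columns=[target])
    de = df[target] - others.mean(axis=1)
    s = others.std(axis=1, ddof=1)
    k = n_samples - 1
    scale = s * np.sqrt(1.0 + 1.0 / k) if method == "prediction" else s / np.sqrt(k)
    degenerate = scale.to_numpy() == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = de.to_numpy() / scale.to_numpy()
    t[degenerate] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df=n_samples - 2)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"DE": de, "t": t, "p": np.minimum(p, 1.0), "degenerate": degenerate},
        index=df.index,
    )


def rde_score(de, p_fdr):
    """Signed rank-of-differential-expression: ``sign(DE) * -log10(FDR)``.

    The FDR is floored at 1e-300 so extreme significance stays finite.
    """
    de = np.asarray(de, dtype=float)
    fdr = np.clip(np.asarray(p_fdr, dtype=float), RDE_FLOOR, 1.0)
    return np.sign(de) * (-np.log10(fdr))


def de_table(mat, method: str = "prediction", normalize: bool = True) -> pd.DataFrame:
    """Full leave-one-out DE statistics for every (gene, sample) pair.

    Returns a long DataFrame with columns ``gene, sample, DE, t, p, fdr,
    rde``; FDR is adjusted across genes within each target sample.
    """
    df = _as_matrix(mat)
    if normalize:
        df = quantile_normalize(df)
    blocks = []
    for sample in df.columns:
        stats = de_p_value(df, sample, method=method)
        fdr = bh_fdr(stats["p"].to_numpy())
        blocks.append(pd.DataFrame({
            "gene": df.index,
            "sample": sample,
            "DE": stats["DE"].to_numpy(),
            "t": stats["t"].to_numpy(),
            "p": stats["p"].to_numpy(),
            "fdr": fdr,
            "rde": rde_score(stats["DE"].to_numpy(), fdr),
        }))
    return pd.concat(blocks, ignore_index=True)


def call_specific_genes(mat, target, fc_threshold: float = 2.0,
                        fdr_threshold: float = 1e-3, pseudocount: float = 1.0,
                        method: str = "prediction",
                        universe=None) -> list[str]:
    """Genes dominantly or recessively expressed in the target sample.

    A gene is called when its pseudocounted fold change
    ``(e_target + 1) / (mean_other + 1)`` exceeds ``fc_threshold`` or falls
    below its reciprocal (strict inequalities) AND its within-sample FDR is
    below ``fdr_threshold``.  ``universe`` optionally restricts the call to
    a supplied gene universe (e.g. transcription factors) before
    thresholding is applied to membership.
    """
    df = _as_matrix(mat)
    stats = de_p_value(df, target, method=method)
    fdr = pd.Series(bh_fdr(stats["p"].to_numpy()), index=df.index)
    others = df.drop(columns=[target])
    ratio = (df[target] + pseudocount) / (others.mean(axis=1) + pseudocount)
    called = ((ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)) & \
        (fdr < fdr_threshold)
    genes = [g for g in df.index[called]]
    if universe is not None:
        allowed = set(universe)
        genes = [g for g in genes if g in allowed]
    return genes


class TissueSpecificity:
    """Model: rank genes by tissue/sample specificity of their expression.

    Parameters
    ----------
    mat : gene-by-sample DataFrame of nonnegative expression values.
    normalize : quantile-normalize the columns first (default True).
    method : t construction, ``'prediction'`` (default) or ``'mean'``.
    """

    def __init__(self, mat, normalize: bool = True, method: str = "prediction"):
        self.raw = _as_matrix(mat)
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.raw.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        self.normalize = normalize
        self.method = method

    def fit(self) -> "TissueSpecificityResults":
        mat = quantile_normalize(self.raw) if self.normalize else self.raw
        table = de_table(mat, method=self.method, normalize=False)
        return TissueSpecificityResults(table, mat, self)


@dataclass
class TissueSpecificityResults:
    """Fitted per-(gene, sample) DE statistics and ranked-list accessors."""

    table: pd.DataFrame
    matrix: pd.DataFrame
    model: TissueSpecificity

    def sample_table(self, sample) -> pd.DataFrame:
        sub = self.table[self.table["sample"] == sample]
        if sub.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return sub.set_index("gene")

    def gene_list(self, sample) -> RankedGeneList:
        """RDE-ranked gene list for one sample."""
        sub = self.sample_table(sample)
        return RankedGeneList(list(sub.index), sub["rde"].to_numpy())

    def to_rnk(self, sample, path) -> None:
        write_gene_list(self.gene_list(sample), path)

    def specific_genes(self, sample, fc_threshold: float = 2.0,
                       fdr_threshold: float = 1e-3, universe=None) -> list[str]:
        return call_specific_genes(
            self.matrix, sample, fc_threshold=fc_threshold,
            fdr_threshold=fdr_threshold, method=self.model.method,
            universe=universe)

    def summary(self) -> str:
        n_genes = self.matrix.shape[0]
        n_samples = self.matrix.shape[1]
        nsig = int((self.table["fdr"] < 1e-3).sum())
        return "\n".join([
            "Tissue-specificity ranking (leave-one-out DE)",
            "=" * 45,
            f"Genes:    {n_genes}",
            f"Samples:  {n_samples}",
            f"(gene, sample) pairs with FDR < 1e-3: {nsig}",
        ])
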
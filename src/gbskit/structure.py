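"""Population structure: realized kinship, LD pre-correction, and PCA.

Kinship is the VanRaden realized-relationship matrix computed from
marker dosages coded {-1, 0, +1}: columns are centred by twice the
deviation of the allele frequency from one half, and the cross-product
is normalised by ``2 * sum(p_j (1 - p_j))``.  Off-diagonal values near
zero indicate unrelated lines; duplicated lines share the maximal
entry.

Because GBS loci cluster tightly on the genetic map, nearby markers
are strongly dependent and distort principal components.  The
``ld_regress`` pre-step replaces each standardized marker by its
least-squares residual on up to ``k`` preceding markers within a map
window before PCA, following the smartpca ldregress convention (window
in Morgans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, ConfigurationError, GenotypeMatrix


@dataclass
class KinshipMatrix:
    """Line x line realized relatedness plus the allele frequencies used
    for centring."""

    values: pd.DataFrame
    allele_freq: pd.Series

    @property
    def lines(self) -> pd.Index:
        return self.values.index


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame          # lines x PCs
    variance_explained: np.ndarray     # percent, per PC
    covariates: pd.DataFrame           # first 4 PCs scaled to [0, 1]


def _dosage_imputed(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """B-dosage with per-locus mean imputation; returns (X, allele freq p)."""
    d = G.dosage().to_numpy()
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    return d, mean / 2.0


def vanraden_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden realized-relationship matrix.

    Genotypes are coded m in {-1, 0, +1} (missing mean-imputed per
    locus), columns centred as ``w = m - (2p - 1)`` with p the B-allele
    frequency, and ``K = W W' / (2 sum p(1-p))``.  Monomorphic and
    all-missing loci are excluded (they contribute no relationship
    information and a zero denominator).
    """
    d = G.dosage().to_numpy()
    called = ~np.isnan(d)
    keep = called.any(axis=0)
    d = d[:, keep]
    mean = np.nanmean(d, axis=0)
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    d, p, mean = d[:, poly], p[poly], mean[:, ][poly]
    if d.shape[1] == 0:
        raise ConfigurationError("no polymorphic loci for kinship")
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    m = d - 1.0                      # {-1, 0, 1} coding
    w = m - (2.0 * p - 1.0)
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = (w @ w.T) / denom
    lines = G.lines
    kept_loci = G.loci[keep][poly]
    return KinshipMatrix(
        values=pd.DataFrame(k, index=lines, columns=lines),
        allele_freq=pd.Series(p, index=kept_loci),
    )


def ld_regress(
    X: pd.DataFrame,
    positions: pd.Series,
    k: int = 10,
    ldlimit_morgans: float = 0.001,
    linkage_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Residualise each marker on up to ``k`` preceding markers.

    ``X`` is a lines x markers matrix of standardized genotypes in map
    order; ``positions`` gives cM positions per marker.  For marker m,
    predecessors within ``ldlimit_morgans`` (map distance, Morgans) on
    the same linkage group — at most ``k``, nearest first — are used as
    regressors (with intercept); the marker's column is replaced by the
    least-squares residual.  ``k = 0`` returns the input unchanged.
    Singular systems fall back to the pseudoinverse solution.
    """
    if k == 0:
        return X.copy()
    cols = list(X.columns)
    pos = positions.reindex(cols).to_numpy(float)
    lg = (
        linkage_groups.reindex(cols).to_numpy()
        if linkage_groups is not None
        else np.zeros(len(cols))
    )
    out = X.to_numpy(float).copy()
    orig = X.to_numpy(float)
    limit_cm = ldlimit_morgans * 100.0
    n = out.shape[0]
    for j in range(1, len(cols)):
        preds = [
            i
            for i in range(j - 1, -1, -1)
            if lg[i] == lg[j] and (pos[j] - pos[i]) <= limit_cm
        ][:k]
        if not preds:
            continue
        A = np.column_stack([np.ones(n)] + [orig[:, i] for i in preds])
        beta, *_ = np.linalg.lstsq(A, orig[:, j], rcond=None)
        out[:, j] = orig[:, j] - A @ beta
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def standardize_markers(G: GenotypeMatrix, scale: bool = True) -> pd.DataFrame:
    """Mean-imputed, centred (and optionally 1/sqrt(p(1-p))-scaled)
    dosage matrix for PCA; monomorphic loci are dropped."""
    d, p = _dosage_imputed(G)
    poly = (p > 0) & (p < 1)
    d, p = d[:, poly], p[poly]
    x = d - 2.0 * p
    if scale:
        x = x / np.sqrt(p * (1.0 - p))
    return pd.DataFrame(x, index=G.lines, columns=G.loci[poly])


def pca_structure(X: pd.DataFrame, n_pc: int = 10, n_covariates: int = 4) -> PCAResult:
    """PCA of a lines x markers matrix (already standardized).

    Returns eigenvalues, line coordinates, percent variance explained,
    and the first ``n_covariates`` components rescaled per component to
    [0, 1] for use as structure covariates.
    """
    if X.shape[0] < 2:
        raise ConfigurationError("PCA requires at least two lines")
    x = X.to_numpy(float)
    x = x - x.mean(axis=0)
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (x.shape[0] - 1)
    total = eig.sum()
    n_pc = min(n_pc, int((s > 1e-10).sum()))
    coords = u[:, :n_pc] * s[:n_pc]
    coord_df = pd.DataFrame(
        coords, index=X.index, columns=[f"PC{i + 1}" for i in range(n_pc)]
    )
    var_exp = 100.0 * eig[:n_pc] / total
    ncov = min(n_covariates, n_pc)
    cov = coord_df.iloc[:, :ncov]
    rng_ = cov.max() - cov.min()
    cov = (cov - cov.min()) / rng_.replace(0.0, 1.0)
    return PCAResult(
        eigenvalues=eig[:n_pc],
        coordinates=coord_df,
        variance_explained=var_exp,
        covariates=cov,
    )
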
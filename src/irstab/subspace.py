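"""PCA subspace of the gene-gene correlation structure and the projected/residual split.

The leading eigenvectors of the gene-gene Pearson correlation matrix define a
set of *metagenes*; their expression profiles across samples span a
low-dimensional subspace S_n.  Every gene's (centered) expression vector is
then split by least squares into a component inside S_n and an orthogonal
residual:  x = x_p + x_r.

The eigendecomposition is computed through an SVD of the row-standardized
matrix, never by forming the n_genes x n_genes correlation matrix; the two
routes have the identical non-null spectrum and this one stays tractable for
thousands of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_prep import ExpressionStudy, ValidationError

__all__ = ["SubspaceModel", "DecomposedExpression", "fit_subspace", "split_expression"]


@dataclass
class SubspaceModel:
    """Top-n eigenpairs of the gene-gene correlation matrix.

    ``loadings_G`` holds one orthonormal eigenvector (gene loadings) per
    column; ``metagene_X`` one metagene expression profile per row, the
    loadings-weighted sum of the standardized gene rows.  ``eigenvalues`` are
    those of the correlation matrix (sum over all = n_genes).
    """

    n: int
    loadings_G: np.ndarray      # (n_fitted_genes, n)
    metagene_X: np.ndarray      # (n, n_samples)
    eigenvalues: np.ndarray     # (n,)
    gene_means: np.ndarray      # (n_genes,) over ALL study genes
    gene_sds: np.ndarray        # (n_genes,) ddof=1; 0 marks a constant gene
    gene_ids: list[str]
    sample_ids: list[str]
    fitted_mask: np.ndarray     # (n_genes,) bool; False for constant genes

    def save(self, path) -> None:
        np.savez(
            path,
            n=self.n,
            loadings_G=self.loadings_G,
            metagene_X=self.metagene_X,
            eigenvalues=self.eigenvalues,
            gene_means=self.gene_means,
            gene_sds=self.gene_sds,
            gene_ids=np.asarray(self.gene_ids, dtype=object),
            sample_ids=np.asarray(self.sample_ids, dtype=object),
            fitted_mask=self.fitted_mask,
        )

    @classmethod
    def load(cls, path) -> "SubspaceModel":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                n=int(z["n"]),
                loadings_G=z["loadings_G"],
                metagene_X=z["metagene_X"],
                eigenvalues=z["eigenvalues"],
                gene_means=z["gene_means"],
                gene_sds=z["gene_sds"],
                gene_ids=[str(g) for g in z["gene_ids"]],
                sample_ids=[str(s) for s in z["sample_ids"]],
                fitted_mask=z["fitted_mask"],
            )


@dataclass
class DecomposedExpression:
    """Per-gene split x = x_p + x_r with x_p inside the metagene span.

    x_p is built from the sample-centered metagene profiles, so it carries no
    gene mean; the mean sits in x_r.  Location (two-sample) tests are
    unaffected by this convention.
    """

    x_p: np.ndarray       # (n_genes, n_samples)
    x_r: np.ndarray       # (n_genes, n_samples)
    coeffs_r: np.ndarray  # (n_genes, n)
    gene_ids: list[str]
    sample_ids: list[str]


def fit_subspace(study: ExpressionStudy, n: int = 4) -> SubspaceModel:
    """Fit the top-n metagene subspace of a study.

    Each gene row is centered and scaled to unit sd; the SVD of the
    standardized matrix yields eigenvalues lambda_k = s_k^2 / (n_samples - 1)
    of the correlation matrix and the loadings as left singular vectors.
    Constant genes cannot be standardized and are dropped from the fit with a
    warning.  Loading signs are fixed so each column's largest-magnitude entry
    is positive.
    """
    expr = study.expr
    n_genes, n_samples = expr.shape
    means = expr.mean(axis=1)
    sds = expr.std(axis=1, ddof=1) if n_samples > 1 else np.zeros(n_genes)
    mask = sds > 0
    n_fit = int(mask.sum())
    if n_fit == 0:
        raise ValidationError("all genes are constant; cannot fit a subspace")
    if not mask.all():
        warnings.warn(
            f"dropping {n_genes - n_fit} constant gene(s) from the subspace fit",
            stacklevel=2,
        )
    if not (1 <= n <= min(n_fit, n_samples - 1)):
        raise ValidationError(
            f"subspace dimension n={n} out of range [1, {min(n_fit, n_samples - 1)}]"
        )
    Z = (expr[mask] - means[mask, None]) / sds[mask, None]
    # economy SVD: Z = U S Vt ; correlation matrix eigenpairs are (U, S^2/(m-1))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = U[:, :n].copy()
    eigenvalues = (s[:n] ** 2) / (n_samples - 1)
    # deterministic sign: largest-|entry| of each loading column positive
    for k in range(n):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    metagene_X = loadings.T @ Z
    return SubspaceModel(
        n=n,
        loadings_G=loadings,
        metagene_X=metagene_X,
        eigenvalues=eigenvalues,
        gene_means=means,
        gene_sds=sds,
        gene_ids=list(study.gene_ids),
        sample_ids=list(study.sample_ids),
        fitted_mask=mask,
    )


def split_expression(study: ExpressionStudy, model: SubspaceModel) -> DecomposedExpression:
    """Split every gene's expression into projected (x_p) and residual (x_r) parts.

    For gene i the coefficient vector r_i solves the least-squares system
    ``X~^T r = x_i - <x_i>`` where X~ are the sample-centered metagene
    profiles; then x_p,i = X~^T r_i and x_r,i = x_i - x_p,i.  The split only
    involves the span of the metagene profiles, so it is invariant under any
    rotation of the subspace basis.
    """
    if model.sample_ids != study.sample_ids:
        raise ValidationError("model was fitted on a different sample set")
    expr = study.expr
    means = expr.mean(axis=1)
    Xc = model.metagene_X - model.metagene_X.mean(axis=1, keepdims=True)
    A = Xc.T                              # (n_samples, n)
    B = (expr - means[:, None]).T         # (n_samples, n_genes)
    rank = np.linalg.matrix_rank(A)
    if rank < model.n:
        warnings.warn(
            "metagene profiles are rank-deficient; using minimum-norm least squares",
            stacklevel=2,
        )
    R, *_ = np.linalg.lstsq(A, B, rcond=None)  # (n, n_genes)
    x_p = (A @ R).T
    x_r = expr - x_p
    return DecomposedExpression(
        x_p=x_p,
        x_r=x_r,
        coeffs_r=R.T,
        gene_ids=list(study.gene_ids),
        sample_ids=list(study.sample_ids),
    )
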
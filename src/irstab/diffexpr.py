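"""Gene-wise differential expression between two classes, in three spaces.

For a binary contrast the chosen two-sample test (Welch's t by default, the
Wilcoxon rank-sum as the nonparametric alternative) is applied gene-wise to
the original expression, the projected component x_p and the residual
component x_r.  p-values are clamped to [1e-300, 1] so their log10 is always
finite; no multiplicity adjustment is applied anywhere -- the downstream
statistics are defined on raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_prep import BinaryContrast, ExpressionStudy, ValidationError
from .subspace import DecomposedExpression

__all__ = ["P_FLOOR", "DifferentialResult", "welch_p", "wilcoxon_p",
           "differential_all_spaces"]

P_FLOOR = 1e-300

_METHODS = ("welch_t", "wilcoxon")


@dataclass
class DifferentialResult:
    """Per-gene p-values (and their log10) in original, projected, residual space."""

    gene_ids: list[str]
    p_orig: np.ndarray
    p_proj: np.ndarray
    p_resid: np.ndarray
    lp_orig: np.ndarray
    lp_proj: np.ndarray
    lp_resid: np.ndarray
    method: str
    contrast_name: str

    @classmethod
    def from_pvalues(cls, gene_ids, p_orig, p_proj, p_resid, method, contrast_name):
        p_orig, p_proj, p_resid = (_clamp(p) for p in (p_orig, p_proj, p_resid))
        return cls(
            gene_ids=list(gene_ids),
            p_orig=p_orig, p_proj=p_proj, p_resid=p_resid,
            lp_orig=np.log10(p_orig), lp_proj=np.log10(p_proj),
            lp_resid=np.log10(p_resid),
            method=method, contrast_name=contrast_name,
        )


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)


def welch_p(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value for two samples.

    Degenerate inputs follow explicit rules: both groups constant with equal
    means -> p = 1 (no evidence of a difference is quantifiable); constant
    with unequal means -> p = P_FLOOR.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch's test needs at least 2 values per group")
    return float(_welch_p_rows(a[None, :], b[None, :])[0])


def _welch_p_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized Welch test over matrix rows (genes)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    # a group is degenerate when its variance vanishes relative to the data
    # scale (exact zeros, and the ~1e-15 numerical dust of in-span residuals)
    scale = np.maximum(1.0, np.maximum(np.abs(A).max(axis=1), np.abs(B).max(axis=1)))
    tol = (1e-9 * scale) ** 2
    degenerate = (va <= tol) & (vb <= tol)
    if degenerate.any():
        equal = np.isclose(A.mean(axis=1), B.mean(axis=1),
                           rtol=1e-9, atol=1e-9 * scale)
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, P_FLOOR, p)
    # zero variance in one group with a mean difference yields t = +-inf, p = 0
    p = np.where(np.isnan(p), 1.0, p)
    return _clamp(p)


def wilcoxon_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution for combined sizes up to 20 and the
    tie-corrected normal approximation above that.  All values tied across
    both groups -> p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Wilcoxon test needs at least 2 values per group")
    return float(_wilcoxon_p_rows(a[None, :], b[None, :])[0])


def _wilcoxon_p_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n_tot = A.shape[1] + B.shape[1]
    method = "exact" if n_tot <= 20 else "asymptotic"
    p = np.empty(A.shape[0], dtype=float)
    for i in range(A.shape[0]):
        row_a, row_b = A[i], B[i]
        if np.all(row_a == row_a[0]) and np.all(row_b == row_a[0]):
            p[i] = 1.0
            continue
        use = method
        if use == "exact" and (np.unique(np.concatenate([row_a, row_b])).size < n_tot):
            use = "asymptotic"  # exact distribution is undefined under ties
        res = stats.mannwhitneyu(row_a, row_b, alternative="two-sided", method=use)
        p[i] = res.pvalue
    return _clamp(np.where(np.isnan(p), 1.0, p))


def differential_all_spaces(study: ExpressionStudy,
                            decomp: DecomposedExpression,
                            contrast: BinaryContrast,
                            method: str = "welch_t") -> DifferentialResult:
    """Run the two-sample test gene-wise on original, projected and residual data."""
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {_METHODS}")
    if decomp.gene_ids != study.gene_ids or decomp.sample_ids != study.sample_ids:
        raise ValidationError("decomposition does not match the study's genes/samples")
    pos = {s: k for k, s in enumerate(study.sample_ids)}
    try:
        idx = np.array([pos[s] for s in contrast.sample_ids], dtype=int)
    except KeyError as exc:
        raise ValidationError(
            f"contrast sample {exc.args[0]!r} not present in study"
        ) from exc
    y = contrast.label_array()
    c1 = idx[y == 1]
    c2 = idx[y == 2]
    runner = _welch_p_rows if method == "welch_t" else _wilcoxon_p_rows
    pvals = [runner(M[:, c1], M[:, c2]) for M in (study.expr, decomp.x_p, decomp.x_r)]
    return DifferentialResult.from_pvalues(
        study.gene_ids, *pvals, method=method, contrast_name=contrast.name
    )
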
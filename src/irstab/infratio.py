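"""The Information Ratio: weight fit, IR computation, dimension scan, typing.

Genome-wide |log10 p| values of differential expression empirically follow an
exponential distribution.  A log-linear fit over a 50-bin histogram yields a
decay rate lambda, and each gene receives the weight w_i = exp(lambda |lp_i|)
-- the inverse of its density -- so gene groups of similar sensitivity
contribute equally in aggregate.  The Information Ratio is then the weighted
mean of the per-gene ratios

    q_i = |lp_resid,i| / (|lp_resid,i| + |lp_proj,i|),

which is 0 when all differential-expression information lies in the leading
PCA subspace and 1 when it all lies in the residual space.  Contrasts with
IR <= 0.25 are classified as the low-IR (Type 1) regime that yields stable,
transferable gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_prep import BinaryContrast, ExpressionStudy, ValidationError
from .diffexpr import DifferentialResult, differential_all_spaces
from .subspace import fit_subspace, split_expression

__all__ = ["IR_THRESHOLD", "WeightModel", "IRResult", "fit_lambda",
           "information_ratio", "ir_for_contrast", "ir_dimension_scan"]

IR_THRESHOLD = 0.25
_DENOM_EPS = 1e-12


@dataclass
class WeightModel:
    """Exponential weight distribution fitted to |log10 p| values."""

    lambda_: float
    n_bins: int
    bin_edges: np.ndarray
    bin_ratios: np.ndarray   # per-bin fraction of genes, sums to 1
    weights: np.ndarray      # per-gene exp(lambda * |lp|)


@dataclass
class IRResult:
    """A single Information Ratio with its provenance."""

    ir: float
    lambda_: float
    n: int
    n_genes_used: int
    type_label: str
    contrast_name: str

    def to_dict(self) -> dict:
        return {
            "ir": self.ir,
            "lambda": self.lambda_,
            "n": self.n,
            "n_genes_used": self.n_genes_used,
            "type_label": self.type_label,
            "contrast_name": self.contrast_name,
        }


def fit_lambda(lp: Sequence[float] | np.ndarray, n_bins: int = 50) -> WeightModel:
    """Fit the exponential decay rate of the |log10 p| distribution.

    |lp| values are spread over ``n_bins`` equidistant bins on [0, max |lp|];
    occupied bins are regressed log(ratio_j) ~ a - lambda * midpoint_j by
    ordinary least squares.  lambda is floored at 0 (weights never decrease
    with significance).
    """
    lp = np.asarray(lp, dtype=float)
    if lp.size < 100:
        raise ValidationError(f"need at least 100 genes to fit weights, got {lp.size}")
    if (lp > 0).any():
        raise ValidationError("lp values must be log10 p-values (<= 0)")
    a = np.abs(lp)
    hi = float(a.max())
    if hi == 0.0:
        raise ValidationError("all p-values equal 1; weight fit is undefined")
    counts, edges = np.histogram(a, bins=n_bins, range=(0.0, hi))
    ratios = counts / counts.sum()
    occupied = counts > 0
    if occupied.sum() < 3:
        raise ValidationError(
            f"only {int(occupied.sum())} occupied histogram bin(s); cannot regress"
        )
    mids = 0.5 * (edges[:-1] + edges[1:])
    fit = stats.linregress(mids[occupied], np.log(ratios[occupied]))
    lam = max(0.0, -float(fit.slope))
    return WeightModel(
        lambda_=lam,
        n_bins=n_bins,
        bin_edges=edges,
        bin_ratios=ratios,
        weights=np.exp(lam * a),
    )


def information_ratio(de: DifferentialResult, wm: WeightModel, *,
                      n: int = 0, ir_threshold: float = IR_THRESHOLD) -> IRResult:
    """Weighted p-value-ratio statistic over all informative genes.

    Genes where both |lp_proj| and |lp_resid| are ~0 carry no information and
    are excluded from numerator and denominator rather than diluting the
    statistic toward 0.5.
    """
    if wm.weights.shape[0] != len(de.gene_ids):
        raise ValidationError("weight model and differential result cover different genes")
    num = np.abs(de.lp_resid)
    den = num + np.abs(de.lp_proj)
    informative = den >= _DENOM_EPS
    if not informative.any():
        raise ValidationError("no informative genes (all p-values ~ 1 in both spaces)")
    q = num[informative] / den[informative]
    w = wm.weights[informative]
    ir = float(np.sum(w * q) / np.sum(w))
    ir = min(1.0, max(0.0, ir))
    return IRResult(
        ir=ir,
        lambda_=wm.lambda_,
        n=n,
        n_genes_used=int(informative.sum()),
        type_label="type1_low" if ir <= ir_threshold else "type2_3_high",
        contrast_name=de.contrast_name,
    )


def _weight_source_lp(de: DifferentialResult, weight_source: str) -> np.ndarray:
    if weight_source == "orig":
        return de.lp_orig
    if weight_source == "min_pr_pp":
        return np.minimum(de.lp_resid, de.lp_proj)  # lp of the smaller p-value
    raise ValidationError(f"unknown weight source {weight_source!r}")


def ir_for_contrast(study: ExpressionStudy, contrast: BinaryContrast,
                    n: int = 4, method: str = "welch_t", *,
                    n_bins: int = 50, weight_source: str = "orig",
                    ir_threshold: float = IR_THRESHOLD,
                    de: DifferentialResult | None = None) -> IRResult:
    """Full pipeline: subspace fit, split, differential tests, weights, IR.

    The subspace is fitted on all study samples; the differential tests use
    only the contrast's samples.  Deterministic given its inputs.  A
    precomputed ``de`` (from :func:`differential_all_spaces`) can be passed to
    avoid refitting.
    """
    if de is None:
        model = fit_subspace(study, n=n)
        decomp = split_expression(study, model)
        de = differential_all_spaces(study, decomp, contrast, method=method)
    wm = fit_lambda(_weight_source_lp(de, weight_source), n_bins=n_bins)
    return information_ratio(de, wm, n=n, ir_threshold=ir_threshold)


def ir_dimension_scan(study: ExpressionStudy, contrast: BinaryContrast,
                      n_range: Iterable[int] = range(1, 11),
                      method: str = "welch_t", **kwargs) -> list[tuple[int, IRResult]]:
    """Recompute the IR for each subspace dimension in ``n_range`` (refit each time)."""
    ns = sorted(set(int(n) for n in n_range))
    if not ns:
        raise ValidationError("n_range is empty")
    if max(ns) > study.n_samples - 1:
        raise ValidationError(
            f"max subspace dimension {max(ns)} exceeds n_samples - 1 = {study.n_samples - 1}"
        )
    return [(n, ir_for_contrast(study, contrast, n=n, method=method, **kwargs))
            for n in ns]
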
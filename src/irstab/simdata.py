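"""Latent-factor simulator for expression studies with controlled signal placement.

The generator emulates the statistical structure of preprocessed (log2)
microarray cohorts: a low-rank latent-factor component (biological
heterogeneity) of controllable intrinsic dimensionality, independent per-gene
noise, and a binary phenotype whose differential signal is placed either

* ``subspace`` mode -- inside the leading-variance span: the first latent
  factor's per-sample scores are shifted for class 2, so the class
  difference is a genome-wide coherent shift lying exactly in the span of
  the latent factor profiles and is captured by a PCA of sufficient
  dimension; the signal genes carry boosted loadings on that factor and so
  top the differential-expression ranking; or
* ``residual`` mode -- orthogonal to it: signal genes receive independent
  per-gene mean shifts with random signs along a class-contrast direction
  that has been orthogonalized against every factor profile, so the class
  difference avoids the leading subspace entirely.

``spread_signal`` distributes a subspace-mode class shift over all ``dim``
factor scores (proportionally to each factor's strength) instead of the
first; with the analysis subspace held fixed this makes the recoverable
information decrease as the intrinsic dimensionality grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_prep import BinaryContrast, ExpressionStudy, ValidationError

__all__ = ["SimConfig", "simulate_study", "simulate_study_pair", "write_study"]

BASELINE_LOG2 = 8.0  # typical array-scale mean expression


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    ``factor_sd`` is the sd of latent-factor scores, ``noise_sd`` the per-gene
    noise sd; loadings have unit variance per gene on average, so each factor
    contributes about ``factor_sd**2`` per-gene variance.  ``effect_size`` is
    the class shift in units of the relevant scale: factor-score sd for
    subspace mode, noise sd for residual mode.
    """

    n_genes: int = 2000
    n_samples: int = 100
    dim: int = 4
    noise_sd: float = 1.0
    factor_sd: float = 3.0
    signal_mode: str = "subspace"
    effect_size: float = 1.0
    n_signal_genes: int = 100
    balance: float = 0.5
    seed: int = 0
    spread_signal: bool = False
    factor_decay: float = 1.0
    signal_boost: float = 6.0
    disease_shift_scale: float = 2.0
    study_id: str = "sim"

    def __post_init__(self) -> None:
        if self.signal_mode not in ("subspace", "residual"):
            raise ValidationError(f"unknown signal_mode {self.signal_mode!r}")
        if not (1 <= self.dim <= min(self.n_genes, self.n_samples) - 1):
            raise ValidationError(
                f"dim={self.dim} out of range [1, {min(self.n_genes, self.n_samples) - 1}]"
            )
        if not (0 < self.n_signal_genes <= self.n_genes):
            raise ValidationError("n_signal_genes must be in [1, n_genes]")
        if not (0.0 < self.balance < 1.0):
            raise ValidationError("balance must be strictly between 0 and 1")
        if self.noise_sd <= 0 or self.factor_sd <= 0:
            raise ValidationError("noise_sd and factor_sd must be positive")


def _draw_labels(rng: np.random.Generator, n_samples: int, balance: float) -> np.ndarray:
    n1 = int(round(balance * n_samples))
    n1 = min(max(n1, 2), n_samples - 2)
    labels = np.full(n_samples, 2, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)
    return labels


def simulate_study(cfg: SimConfig, *, signal_genes: np.ndarray | None = None,
                   disease_pattern: np.ndarray | None = None
                   ) -> tuple[ExpressionStudy, BinaryContrast, frozenset]:
    """Generate one study; returns (study, contrast, truth signal-gene set).

    All randomness comes from ``cfg.seed``; identical configs give
    bit-identical output.  ``signal_genes`` (row indices) and, for subspace
    mode, ``disease_pattern`` (the genome-wide per-gene loadings of the
    disease axis, before the signal-gene boost) can be supplied to share the
    truth signature between paired studies.
    """
    rng = np.random.default_rng(cfg.seed)
    G, S, d = cfg.n_genes, cfg.n_samples, cfg.dim

    labels = _draw_labels(rng, S, cfg.balance)
    class2 = labels == 2

    if signal_genes is None:
        signal_genes = rng.choice(G, size=cfg.n_signal_genes, replace=False)
    signal_genes = np.sort(np.asarray(signal_genes, dtype=int))
    if signal_genes.size != cfg.n_signal_genes:
        raise ValidationError("supplied signal_genes disagrees with cfg.n_signal_genes")

    # latent factors: scores F (d x S), loadings L (G x d) with column norm
    # sqrt(G) so each factor contributes ~factor_sd^2 variance per gene
    factor_sds = cfg.factor_sd * cfg.factor_decay ** np.arange(d)
    F = rng.normal(0.0, 1.0, size=(d, S)) * factor_sds[:, None]
    L = rng.normal(0.0, 1.0, size=(G, d))
    if cfg.signal_mode == "subspace" and not cfg.spread_signal:
        # the first factor is the "disease" axis: its between-class score
        # shift (disease_shift_scale * effect_size score sds) dominates its
        # within-class variance, so it is the leading principal component and
        # the class difference sits in S_n from n = 1 on.  Signal genes load
        # on it signal_boost-fold more strongly and top the gene ranking.
        if disease_pattern is not None:
            if len(disease_pattern) != G:
                raise ValidationError("disease_pattern must have one entry per gene")
            L[:, 0] = np.asarray(disease_pattern, dtype=float)
        L[signal_genes, 0] *= cfg.signal_boost
    L *= np.sqrt(G) / np.linalg.norm(L, axis=0, keepdims=True)

    if cfg.signal_mode == "subspace":
        if cfg.spread_signal:
            # each factor carries a shift proportional to its own score sd,
            # so stronger heterogeneity axes hold more of the phenotype signal
            F[:, class2] += (cfg.effect_size * factor_sds / np.sqrt(d))[:, None]
        else:
            F[0, class2] += cfg.effect_size * cfg.factor_sd * cfg.disease_shift_scale

    noise = rng.normal(0.0, cfg.noise_sd, size=(G, S))
    expr = L @ F + noise

    if cfg.signal_mode == "residual":
        # class contrast direction, orthogonalized against the factor profiles
        z = class2.astype(float)
        z -= z.mean()
        Fc = F - F.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(Fc.T)          # (S, d) orthonormal basis of factor span
        z_orth = z - Q @ (Q.T @ z)
        gap = z_orth[class2].mean() - z_orth[~class2].mean()
        if abs(gap) < 1e-8:
            raise ValidationError(
                "class contrast is degenerate after orthogonalization; "
                "increase n_samples relative to dim"
            )
        z_orth /= gap                       # class-mean difference of exactly 1
        signs = rng.choice([-1.0, 1.0], size=cfg.n_signal_genes)
        delta = np.zeros(G)
        delta[signal_genes] = signs * cfg.effect_size * cfg.noise_sd
        expr += np.outer(delta, z_orth)

    expr += BASELINE_LOG2

    gene_ids = [f"g{i:05d}" for i in range(G)]
    sample_ids = [f"{cfg.study_id}_s{k:04d}" for k in range(S)]
    phenotypes = pd.DataFrame(
        {"group": labels}, index=pd.Index(sample_ids, name="sample_id")
    )
    study = ExpressionStudy(cfg.study_id, expr, gene_ids, sample_ids, phenotypes)
    contrast = BinaryContrast("group1_vs_2", tuple(sample_ids), tuple(int(y) for y in labels))
    truth = frozenset(gene_ids[i] for i in signal_genes)
    return study, contrast, truth


def simulate_study_pair(cfg: SimConfig, shared_signal: bool,
                        seed_a: int, seed_b: int
                        ) -> tuple[tuple[ExpressionStudy, BinaryContrast, frozenset],
                                   tuple[ExpressionStudy, BinaryContrast, frozenset]]:
    """Two independent studies, optionally sharing the truth signature.

    Factor scores, bulk loadings and noise are always drawn independently per
    study; when ``shared_signal`` the signal-gene indices and (for subspace
    mode) the genome-wide disease-axis loading pattern -- the reproducible
    differential-expression signature a pair of comparable cohorts has in
    common -- are drawn once from ``cfg.seed`` and reused in both studies.
    """
    shared = pattern = None
    if shared_signal:
        rng = np.random.default_rng(cfg.seed)
        shared = rng.choice(cfg.n_genes, size=cfg.n_signal_genes, replace=False)
        if cfg.signal_mode == "subspace" and not cfg.spread_signal:
            pattern = rng.normal(0.0, 1.0, size=cfg.n_genes)
    a = simulate_study(replace(cfg, seed=seed_a, study_id=f"{cfg.study_id}_a"),
                       signal_genes=shared, disease_pattern=pattern)
    b = simulate_study(replace(cfg, seed=seed_b, study_id=f"{cfg.study_id}_b"),
                       signal_genes=shared, disease_pattern=pattern)
    return a, b


def write_study(study: ExpressionStudy, expr_path, pheno_path,
                truth: frozenset | None = None, truth_path=None) -> None:
    """Write a study to the TSV formats consumed by :mod:`irstab.io_prep`."""
    study.to_frame().to_csv(expr_path, sep="\t")
    study.phenotypes.to_csv(pheno_path, sep="\t")
    if truth is not None and truth_path is not None:
        with open(truth_path, "w") as fh:
            for g in sorted(truth):
                fh.write(f"{g}\n")
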
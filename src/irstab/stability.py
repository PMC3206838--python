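"""Gene-list stability between studies: top-fraction lists and their overlap.

Gene lists are the head of the full gene ranking by original-space Welch
p-value (ascending; ties break lexicographically on gene id).  Stability of a
study pair is the percentage of overlapping genes (POG) between the two
equal-length top lists -- 100 * |A intersect B| / |A|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_prep import BinaryContrast, ContrastSpec, ExpressionStudy, ValidationError, \
    binarize_phenotype
from .diffexpr import DifferentialResult
from .infratio import ir_for_contrast

__all__ = ["RankedGeneList", "top_gene_list", "pog", "pair_stability",
           "pairwise_stability"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedGeneList:
    """Head of a p-value-ordered gene ranking."""

    gene_ids: tuple[str, ...]
    fraction: float
    source_study: str
    contrast_name: str


def top_gene_list(de: DifferentialResult, fraction: float = 0.05,
                  source_study: str = "") -> RankedGeneList:
    """Top ``fraction`` of genes by ascending p_orig (ties: lexicographic gene id)."""
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    k = max(1, math.floor(fraction * len(de.gene_ids)))
    order = sorted(range(len(de.gene_ids)),
                   key=lambda i: (de.p_orig[i], de.gene_ids[i]))
    return RankedGeneList(
        gene_ids=tuple(de.gene_ids[i] for i in order[:k]),
        fraction=fraction,
        source_study=source_study,
        contrast_name=de.contrast_name,
    )


def pog(list_a: RankedGeneList, list_b: RankedGeneList) -> float:
    """Percentage of overlapping genes between two equal-length lists."""
    if len(list_a.gene_ids) != len(list_b.gene_ids):
        raise ValidationError(
            f"gene lists have different lengths "
            f"({len(list_a.gene_ids)} vs {len(list_b.gene_ids)})"
        )
    overlap = len(set(list_a.gene_ids) & set(list_b.gene_ids))
    return 100.0 * overlap / len(list_a.gene_ids)


def pair_stability(study_a: ExpressionStudy, study_b: ExpressionStudy,
                   contrast_a: BinaryContrast, contrast_b: BinaryContrast,
                   n: int = 4, fraction: float = 0.05,
                   method: str = "welch_t") -> dict:
    """POG and mean IR for one study pair under a shared contrast."""
    if study_a.gene_ids != study_b.gene_ids:
        raise ValidationError("studies must share an identical gene universe")
    rows = []
    for study, contrast in ((study_a, contrast_a), (study_b, contrast_b)):
        from .subspace import fit_subspace, split_expression
        from .diffexpr import differential_all_spaces
        model = fit_subspace(study, n=n)
        decomp = split_expression(study, model)
        de = differential_all_spaces(study, decomp, contrast, method=method)
        ir = ir_for_contrast(study, contrast, n=n, method=method, de=de)
        rows.append((de, ir))
    (de_a, ir_a), (de_b, ir_b) = rows
    lists = [top_gene_list(de, fraction, s.study_id)
             for de, s in ((de_a, study_a), (de_b, study_b))]
    return {
        "study_a": study_a.study_id,
        "study_b": study_b.study_id,
        "contrast": contrast_a.name,
        "ir_a": ir_a.ir,
        "ir_b": ir_b.ir,
        "mean_ir": 0.5 * (ir_a.ir + ir_b.ir),
        "pog": pog(*lists),
    }


def pairwise_stability(studies: Sequence[ExpressionStudy],
                       contrast_specs: Sequence[ContrastSpec | str] | Mapping[str, ContrastSpec],
                       n: int = 4, fraction: float = 0.05,
                       method: str = "welch_t") -> pd.DataFrame:
    """POG and mean IR for every unordered study pair and applicable contrast.

    Pairs where a contrast cannot be built in either study (missing column,
    class too small) are skipped with a logged notice.
    """
    if len(studies) < 2:
        raise ValidationError("need at least 2 studies")
    gene_ref = studies[0].gene_ids
    for s in studies[1:]:
        if s.gene_ids != gene_ref:
            raise ValidationError("studies must share a gene universe (intersect first)")
    if isinstance(contrast_specs, Mapping):
        specs = list(contrast_specs.values())
    else:
        specs = list(contrast_specs)
    rows = []
    for spec in specs:
        contrasts: dict[int, BinaryContrast] = {}
        for i, s in enumerate(studies):
            try:
                contrasts[i] = binarize_phenotype(s, spec)
            except ValidationError as exc:
                log.info("contrast unavailable in study %s: %s", s.study_id, exc)
        for i in range(len(studies)):
            for j in range(i + 1, len(studies)):
                if i not in contrasts or j not in contrasts:
                    continue
                rows.append(pair_stability(studies[i], studies[j],
                                           contrasts[i], contrasts[j],
                                           n=n, fraction=fraction, method=method))
    return pd.DataFrame(rows, columns=["study_a", "study_b", "contrast",
                                       "ir_a", "ir_b", "mean_ir", "pog"])
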
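"""Reading expression studies and phenotype tables, sample/gene hygiene, binary contrasts.

Expression matrices are handled genes x samples throughout (rows are genes,
columns are samples), on a log2 scale.  Phenotype tables are pandas DataFrames
indexed by sample id.  All loaders validate their invariants eagerly so that
downstream numerics never see duplicated identifiers or non-finite values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionStudy",
    "CategoryRule",
    "IntervalRule",
    "ContrastSpec",
    "BinaryContrast",
    "BUILTIN_CONTRASTS",
    "load_expression",
    "load_phenotypes",
    "load_probe_mapping",
    "load_contrast_registry",
    "collapse_probesets",
    "deduplicate_samples",
    "remove_outlier_samples",
    "intersect_genes",
    "binarize_phenotype",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionStudy:
    """A log2 expression matrix with gene/sample identifiers and phenotypes.

    Attributes
    ----------
    study_id : str
        Label for the study (used in stability/transfer reports).
    expr : ndarray, shape (n_genes, n_samples)
        log2 expression values; finite.
    gene_ids, sample_ids : list of str
        Unique, ordered identifiers for rows and columns.
    phenotypes : DataFrame
        Indexed by sample id; every expression column has a row here
        (possibly with missing values).
    """

    study_id: str
    expr: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    phenotypes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.expr.ndim != 2:
            raise ValidationError("expr must be a 2-D genes x samples matrix")
        if self.expr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expr shape {self.expr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {sorted(dup_g)[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {sorted(dup_s)[:5]}")
        bad = ~np.isfinite(self.expr)
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[k]!r}"
            )
        if self.phenotypes is None:
            self.phenotypes = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        missing = set(self.sample_ids) - set(map(str, self.phenotypes.index))
        if missing:
            raise ValidationError(
                f"samples missing from phenotype table: {sorted(missing)[:5]}"
            )

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        """Restrict to the given samples, preserving the given order."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            cols = [pos[str(s)] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc
        return ExpressionStudy(
            study_id=self.study_id,
            expr=self.expr[:, cols],
            gene_ids=list(self.gene_ids),
            sample_ids=[str(s) for s in sample_ids],
            phenotypes=self.phenotypes.loc[[str(s) for s in sample_ids]],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionStudy":
        pos = self.gene_index()
        try:
            rows = [pos[str(g)] for g in gene_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from exc
        return ExpressionStudy(
            study_id=self.study_id,
            expr=self.expr[rows, :],
            gene_ids=[str(g) for g in gene_ids],
            sample_ids=list(self.sample_ids),
            phenotypes=self.phenotypes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ----------------------------------------------------------------------
# Loaders
# ----------------------------------------------------------------------

def load_expression(path, fmt: str = "tsv", *, log2_transform: bool = False,
                    study_id: str | None = None,
                    phenotypes: pd.DataFrame | None = None) -> ExpressionStudy:
    """Load a genes x samples TSV expression matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Values must parse as finite numbers; a malformed cell raises a
    ``ValidationError`` naming the offending gene and sample.  Set
    ``log2_transform`` for raw-scale input (applies log2(x + 1)).
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ValidationError(
            f"malformed numeric cell {raw.iat[i, k]!r} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[k]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    if log2_transform:
        if (values < 0).any():
            raise ValidationError("negative values cannot be log2(x+1) transformed")
        values = np.log2(values + 1.0)
    sid = study_id if study_id is not None else _stem(path)
    return ExpressionStudy(sid, values, gene_ids, sample_ids, phenotypes)


def load_phenotypes(path) -> pd.DataFrame:
    """Load a phenotype TSV keyed by ``sample_id``; empty fields and 'NA' are missing."""
    tbl = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      na_values=["", "NA"])
    if "sample_id" not in tbl.columns:
        raise ValidationError(f"phenotype table {path} lacks a 'sample_id' column")
    tbl["sample_id"] = tbl["sample_id"].astype(str)
    dup = _duplicates(tbl["sample_id"])
    if dup:
        raise ValidationError(f"duplicate sample ids in phenotype table: {sorted(dup)[:5]}")
    return tbl.set_index("sample_id")


def load_probe_mapping(path) -> pd.DataFrame:
    """Load a two-column probe_id -> symbol TSV mapping."""
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if tbl.shape[1] < 2:
        raise ValidationError("probe mapping must have two columns: probe_id, symbol")
    tbl = tbl.iloc[:, :2]
    tbl.columns = ["probe_id", "symbol"]
    return tbl


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


# ----------------------------------------------------------------------
# Hygiene operations
# ----------------------------------------------------------------------

def collapse_probesets(study: ExpressionStudy,
                       mapping: pd.DataFrame | Mapping[str, str]) -> ExpressionStudy:
    """Collapse probe-set rows to one row per gene symbol.

    For a symbol measured by several probe sets the probe with the largest
    mean expression over all samples is kept as representative; ties break to
    the lexicographically smallest probe id.  Probes without a symbol in the
    mapping are dropped.
    """
    if isinstance(mapping, pd.DataFrame):
        pairs = dict(zip(mapping["probe_id"].astype(str), mapping["symbol"].astype(str)))
    else:
        pairs = {str(k): str(v) for k, v in mapping.items()}
    if not pairs:
        raise ValidationError("probe mapping is empty")
    means = study.expr.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(study.gene_ids):
        symbol = pairs.get(probe)
        if symbol is None:
            continue
        cand = (-means[i], probe, i)  # max mean, then lexicographically smallest probe
        if symbol not in best or cand < best[symbol]:
            best[symbol] = cand
    if not best:
        raise ValidationError("no probe in the study maps to a symbol")
    symbols = sorted(best)
    rows = [best[s][2] for s in symbols]
    return ExpressionStudy(study.study_id, study.expr[rows, :], symbols,
                           list(study.sample_ids), study.phenotypes)


def intersect_genes(studies: Sequence[ExpressionStudy]) -> list[ExpressionStudy]:
    """Restrict every study to the shared gene set, rows sorted canonically."""
    if not studies:
        raise ValidationError("need at least one study")
    common = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValidationError("gene sets have an empty intersection")
    order = sorted(common)
    return [s.subset_genes(order) for s in studies]


def deduplicate_samples(studies: Sequence[ExpressionStudy],
                        r2_threshold: float = 0.99) -> list[ExpressionStudy]:
    """Drop redundant samples whose pairwise squared Pearson correlation >= threshold.

    Samples across all studies (which must share a gene set) are scanned in a
    canonical order -- study input order, then lexicographic sample id -- and
    for every correlated pair the later sample in that order is removed.  The
    scan is greedy: once a sample is removed it no longer triggers removals.
    """
    if not studies:
        return []
    gene_ref = studies[0].gene_ids
    for s in studies[1:]:
        if s.gene_ids != gene_ref:
            raise ValidationError(
                "studies must share an identical gene set/order (run intersect_genes first)"
            )
    entries: list[tuple[int, str]] = []
    for si, s in enumerate(studies):
        for sid in sorted(s.sample_ids):
            entries.append((si, sid))
    if len(entries) < 2:
        return list(studies)
    cols = np.column_stack([
        studies[si].expr[:, studies[si].sample_ids.index(sid)] for si, sid in entries
    ])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(cols, rowvar=False)
    r2 = np.nan_to_num(corr, nan=0.0) ** 2
    removed = np.zeros(len(entries), dtype=bool)
    for i in range(len(entries)):
        if removed[i]:
            continue
        for j in range(i + 1, len(entries)):
            if removed[j]:
                continue
            if r2[i, j] >= r2_threshold:
                removed[j] = True
    keep_by_study: dict[int, set[str]] = {si: set() for si in range(len(studies))}
    for flag, (si, sid) in zip(removed, entries):
        if not flag:
            keep_by_study[si].add(sid)
    out = []
    for si, s in enumerate(studies):
        kept = [sid for sid in s.sample_ids if sid in keep_by_study[si]]
        out.append(s.subset_samples(kept))
    return out


def remove_outlier_samples(study: ExpressionStudy, sigma: float = 5.0) -> ExpressionStudy:
    """Drop samples whose mean expression deviates more than ``sigma`` sd from the grand mean.

    The sd is that of the per-sample means over the full sample set, computed
    in a single pass (no re-iteration after removals).
    """
    if study.n_samples < 3:
        raise ValidationError("need at least 3 samples for outlier screening")
    m = study.expr.mean(axis=0)
    sd = float(np.std(m, ddof=1))
    if sd == 0.0 or not math.isfinite(sigma):
        return study
    keep = np.abs(m - m.mean()) <= sigma * sd
    if keep.sum() < 2:
        raise ValidationError("outlier removal would leave fewer than 2 samples")
    if keep.all():
        return study
    kept_ids = [sid for sid, k in zip(study.sample_ids, keep) if k]
    return study.subset_samples(kept_ids)


# ----------------------------------------------------------------------
# Binary contrasts
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryRule:
    """Set-membership rule over a categorical column (case-insensitive strings)."""

    values: frozenset

    @staticmethod
    def of(*values) -> "CategoryRule":
        return CategoryRule(frozenset(_norm_cat(v) for v in values))

    def matches(self, value) -> bool:
        if _is_missing(value):
            return False
        return _norm_cat(value) in self.values


@dataclass(frozen=True)
class IntervalRule:
    """Interval rule over a numeric column; non-numeric values never match."""

    lo: float = -math.inf
    hi: float = math.inf
    lo_inclusive: bool = True
    hi_inclusive: bool = False

    def matches(self, value) -> bool:
        if _is_missing(value):
            return False
        try:
            x = float(value)
        except (TypeError, ValueError):
            return False
        if math.isnan(x):
            return False
        lo_ok = x >= self.lo if self.lo_inclusive else x > self.lo
        hi_ok = x <= self.hi if self.hi_inclusive else x < self.hi
        return lo_ok and hi_ok


def _norm_cat(value) -> str:
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    return str(value).strip().lower()


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() in ("", "NA")


def _rules_disjoint(r1, r2) -> bool:
    if isinstance(r1, CategoryRule) and isinstance(r2, CategoryRule):
        return not (r1.values & r2.values)
    if isinstance(r1, IntervalRule) and isinstance(r2, IntervalRule):
        a, b = (r1, r2) if r1.lo <= r2.lo else (r2, r1)
        if a.hi < b.lo:
            return True
        if a.hi == b.lo:
            return not (a.hi_inclusive and b.lo_inclusive)
        return False
    return True  # mixed rule kinds cannot be checked statically


@dataclass(frozen=True)
class ContrastSpec:
    """Declarative description of how to binarize a phenotype column.

    ``exclude_column``, when present in the phenotype table, removes samples
    with a truthy value there (used e.g. for patients censored before the
    5-year relapse horizon).
    """

    name: str
    variable: str
    class1_rule: CategoryRule | IntervalRule
    class2_rule: CategoryRule | IntervalRule
    exclude_column: str | None = None

    def __post_init__(self) -> None:
        if not _rules_disjoint(self.class1_rule, self.class2_rule):
            raise ValidationError(
                f"contrast {self.name!r}: class rules select overlapping values"
            )


@dataclass(frozen=True)
class BinaryContrast:
    """A resolved two-class partition of (a subset of) a study's samples."""

    name: str
    sample_ids: tuple[str, ...]
    labels: tuple[int, ...]  # 1 or 2, aligned with sample_ids

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels must align")
        for cls in (1, 2):
            n = sum(1 for y in self.labels if y == cls)
            if n < 2:
                raise ValidationError(
                    f"contrast {self.name!r}: class {cls} has {n} samples (< 2)"
                )

    @property
    def class1(self) -> list[str]:
        return [s for s, y in zip(self.sample_ids, self.labels) if y == 1]

    @property
    def class2(self) -> list[str]:
        return [s for s, y in zip(self.sample_ids, self.labels) if y == 2]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


TRUTHY = CategoryRule.of("1", "yes", "true", "y")

BUILTIN_CONTRASTS: dict[str, ContrastSpec] = {
    "grade12_vs_3": ContrastSpec("grade12_vs_3", "grade",
                                 CategoryRule.of(1, 2), CategoryRule.of(3)),
    "grade1_vs_2": ContrastSpec("grade1_vs_2", "grade",
                                CategoryRule.of(1), CategoryRule.of(2)),
    # tumor size: > 25 mm vs < 20 mm; 20-25 mm excluded
    "size_gt25_vs_lt20": ContrastSpec("size_gt25_vs_lt20", "size_mm",
                                      IntervalRule(lo=25.0, lo_inclusive=False),
                                      IntervalRule(hi=20.0, hi_inclusive=False)),
    "er_pos_vs_neg": ContrastSpec("er_pos_vs_neg", "er",
                                  CategoryRule.of("positive", "pos", "+"),
                                  CategoryRule.of("negative", "neg", "-")),
    # relapse/metastasis within 5 years vs relapse-free beyond 5 years
    "relapse5y_vs_free": ContrastSpec("relapse5y_vs_free", "relapse5y",
                                      CategoryRule.of("1", "yes", "relapse", "true"),
                                      CategoryRule.of("0", "no", "free", "false"),
                                      exclude_column="censored_before_5y"),
    "tumor_vs_control": ContrastSpec("tumor_vs_control", "tissue",
                                     CategoryRule.of("tumor", "cancer", "carcinoma"),
                                     CategoryRule.of("control", "normal", "healthy")),
    # boundary: age 55 is assigned to the >= 55 class
    "age_lt55_vs_ge55": ContrastSpec("age_lt55_vs_ge55", "age",
                                     IntervalRule(hi=55.0, hi_inclusive=False),
                                     IntervalRule(lo=55.0, lo_inclusive=True)),
    "smoker_vs_nonsmoker": ContrastSpec("smoker_vs_nonsmoker", "smoking",
                                        CategoryRule.of("smoker", "current", "yes"),
                                        CategoryRule.of("non-smoker", "nonsmoker",
                                                        "never", "no")),
    # synthetic studies label their two groups 1 and 2 in a 'group' column
    "group1_vs_2": ContrastSpec("group1_vs_2", "group",
                                CategoryRule.of(1), CategoryRule.of(2)),
}


def binarize_phenotype(study: ExpressionStudy, spec: ContrastSpec | str) -> BinaryContrast:
    """Apply a contrast spec to a study's phenotype table.

    Samples with a missing value, or a value matching neither class rule, are
    excluded.  Raises if either class ends up with fewer than 2 samples.
    """
    if isinstance(spec, str):
        try:
            spec = BUILTIN_CONTRASTS[spec]
        except KeyError:
            raise ValidationError(f"unknown built-in contrast {spec!r}") from None
    if spec.variable not in study.phenotypes.columns:
        raise ValidationError(
            f"phenotype column {spec.variable!r} not present in study {study.study_id!r}"
        )
    col = study.phenotypes[spec.variable]
    excl = None
    if spec.exclude_column and spec.exclude_column in study.phenotypes.columns:
        excl = study.phenotypes[spec.exclude_column]
    kept: list[str] = []
    labels: list[int] = []
    for sid in study.sample_ids:
        value = col.get(sid)
        if excl is not None and TRUTHY.matches(excl.get(sid)):
            continue
        in1 = spec.class1_rule.matches(value)
        in2 = spec.class2_rule.matches(value)
        if in1 and in2:  # defensive; rules are checked disjoint at construction
            raise ValidationError(
                f"value {value!r} matches both classes of contrast {spec.name!r}"
            )
        if in1:
            kept.append(sid)
            labels.append(1)
        elif in2:
            kept.append(sid)
            labels.append(2)
    return BinaryContrast(spec.name, tuple(kept), tuple(labels))


# ----------------------------------------------------------------------
# YAML contrast registry
# ----------------------------------------------------------------------

def _rule_from_dict(d: Mapping) -> CategoryRule | IntervalRule:
    if "in" in d:
        return CategoryRule.of(*d["in"])
    kw: dict = {}
    if "gt" in d:
        kw.update(lo=float(d["gt"]), lo_inclusive=False)
    if "ge" in d:
        kw.update(lo=float(d["ge"]), lo_inclusive=True)
    if "lt" in d:
        kw.update(hi=float(d["lt"]), hi_inclusive=False)
    if "le" in d:
        kw.update(hi=float(d["le"]), hi_inclusive=True)
    if not kw:
        raise ValidationError(f"cannot interpret rule {dict(d)!r}")
    return IntervalRule(**kw)


def load_contrast_registry(path) -> dict[str, ContrastSpec]:
    """Load a YAML mapping of contrast name -> {variable, class1, class2[, exclude_column]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    registry: dict[str, ContrastSpec] = {}
    for name, entry in doc.items():
        registry[name] = ContrastSpec(
            name=name,
            variable=entry["variable"],
            class1_rule=_rule_from_dict(entry["class1"]),
            class2_rule=_rule_from_dict(entry["class2"]),
            exclude_column=entry.get("exclude_column"),
        )
    return registry
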
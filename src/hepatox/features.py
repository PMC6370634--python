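"""Fold-change and pathway z-score feature construction.

Gene-level features are log2 fold changes of treated samples (or treated
cohorts) against their matched control-cohort mean.  Pathway-level features
standardize a gene set's mean absolute log fold change against the all-gene
distribution of the same profile:

    z = (X_bar - mu0) / (sigma / sqrt(n))

where X_bar is the mean |log2 FC| over the n set genes present in the
profile and mu0, sigma are the mean and population standard deviation of
|log2 FC| over every gene.  By the Central Limit Theorem z is approximately
standard normal under the null of an unremarkable set, and its upper-tail
p-value is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .syndata import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeMatrix:
    """Log2 fold changes, rows = treated samples or treated cohorts."""

    values: pd.DataFrame  # row ids x gene ids
    mode: str             # "per_sample" or "per_cohort"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("fold-change matrix contains non-finite values")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GeneSetScore:
    set_name: str
    n: int
    x_bar: float
    mu0: float
    sigma: float
    z: float
    p_value: float


@dataclass
class FeatureMatrix:
    """Model-ready feature table with fixed column order and provenance."""

    values: pd.DataFrame
    provenance: str           # "gene-level" or "pathway-level"
    feature_set_name: str
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def compute_fold_changes(study: ExpressionStudy,
                         mode: str = "per_sample") -> FoldChangeMatrix:
    """Log2 fold change of treated expression against the matched
    control-cohort mean.

    ``per_sample``: one row per treated sample (sample minus control mean).
    ``per_cohort``: one row per treated cohort (cohort mean minus control
    mean); averaging the per_sample rows of a cohort gives the same row.
    """
    if mode not in ("per_sample", "per_cohort"):
        raise ValueError(f"unknown fold-change mode {mode!r}")
    control_means: dict[str, np.ndarray] = {}
    rows, row_ids = [], []
    seen_cohorts: set[str] = set()
    for i in study.treated_indices():
        s = study.samples[i]
        ctl = s.control_cohort_id
        if ctl not in control_means:
            ctl_rows = study.cohort_rows(ctl)
            if not ctl_rows:
                raise ValueError(f"control cohort {ctl} has no samples")
            control_means[ctl] = study.matrix[ctl_rows].mean(axis=0)
        if mode == "per_sample":
            rows.append(study.matrix[i] - control_means[ctl])
            row_ids.append(s.sample_id)
        elif s.cohort_id not in seen_cohorts:
            seen_cohorts.add(s.cohort_id)
            trt_rows = study.cohort_rows(s.cohort_id)
            rows.append(study.matrix[trt_rows].mean(axis=0)
                        - control_means[ctl])
            row_ids.append(s.cohort_id)
    values = pd.DataFrame(np.array(rows), index=row_ids,
                          columns=study.gene_ids)
    return FoldChangeMatrix(values, mode)


def score_gene_set(fc_row: pd.Series, set_genes: list[str],
                   set_name: str = "") -> GeneSetScore:
    """Standardized expression score of one gene set on one profile.

    ``fc_row`` holds log2 fold changes over the whole gene universe; mu0 and
    sigma describe the profile's |FC| distribution (population sigma), so z
    is invariant under positive rescaling of the profile.
    """
    abs_fc = fc_row.abs()
    present = [g for g in dict.fromkeys(set_genes) if g in abs_fc.index]
    n_dropped = len(set(set_genes)) - len(present)
    if not present:
        raise ValueError(
            f"gene set {set_name!r} has no genes in the profile universe")
    if n_dropped:
        logger.debug("gene set %r: %d gene(s) absent from universe dropped",
                     set_name, n_dropped)
    mu0 = float(abs_fc.mean())
    sigma = float(abs_fc.std(ddof=0))
    n = len(present)
    x_bar = float(abs_fc.loc[present].mean())
    if sigma == 0.0:
        warnings.warn(
            f"degenerate profile (sigma = 0) scoring set {set_name!r}; "
            "z set to 0", RuntimeWarning, stacklevel=2)
        z = 0.0
    else:
        z = (x_bar - mu0) / (sigma / np.sqrt(n))
    p = float(stats.norm.sf(z))
    return GeneSetScore(set_name, n, x_bar, mu0, sigma, z, p)


def pathway_feature_matrix(fc: FoldChangeMatrix,
                           collection: GeneSetCollection) -> FeatureMatrix:
    """One z-score column per gene set, rows aligned with the fold-change
    rows."""
    set_names = list(collection.sets)
    out = np.empty((len(fc.values), len(set_names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, (_, row) in enumerate(fc.values.iterrows()):
            for j, name in enumerate(set_names):
                try:
                    out[i, j] = score_gene_set(
                        row, collection.sets[name], name).z
                except ValueError as exc:
                    raise ValueError(
                        f"scoring set {name!r} failed: {exc}") from exc
    values = pd.DataFrame(out, index=fc.values.index, columns=set_names)
    return FeatureMatrix(values, "pathway-level", collection.name)


def gene_feature_matrix(fc: FoldChangeMatrix, gene_list: list[str],
                        name: str = "gene-list") -> FeatureMatrix:
    """Restrict fold-change columns to a gene list (list order, duplicates
    removed); absent genes are dropped and recorded."""
    wanted = list(dict.fromkeys(gene_list))
    present = [g for g in wanted if g in fc.values.columns]
    dropped = [g for g in wanted if g not in fc.values.columns]
    if not present:
        raise ValueError(
            f"gene list {name!r} shares no genes with the fold-change matrix")
    if dropped:
        logger.info("gene list %r: dropped %d absent gene(s)",
                    name, len(dropped))
    return FeatureMatrix(fc.values[present].copy(), "gene-level", name,
                         dropped_genes=dropped)


def random_gene_list(universe: list[str], k: int, seed: int) -> list[str]:
    """Uniform sample of k distinct genes (no replacement), deterministic
    per seed — the arbitrary feature sets used as curation controls."""
    if k > len(universe):
        raise ValueError(
            f"cannot sample {k} genes from a universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    return [universe[i] for i in
            rng.choice(len(universe), size=k, replace=False)]


def intersect_gene_lists(a: list[str], b: list[str]) -> list[str]:
    """Order-stable (by ``a``) intersection of two gene lists."""
    b_set = set(b)
    out = [g for g in dict.fromkeys(a) if g in b_set]
    if not out:
        warnings.warn("gene-list intersection is empty", stacklevel=2)
    return out


def restrict_collection(collection: GeneSetCollection,
                        gene_list: list[str]) -> GeneSetCollection:
    """Keep only sets overlapping ``gene_list``, and within kept sets only
    the listed genes (e.g. restricting pathway sets to a landmark panel)."""
    keep = set(gene_list)
    sets, descs = {}, {}
    for name, genes in collection.sets.items():
        retained = [g for g in genes if g in keep]
        if retained:
            sets[name] = retained
            if name in collection.descriptions:
                descs[name] = collection.descriptions[name]
    return GeneSetCollection(f"{collection.name}|restricted", sets, descs)


def jaccard_index(a, b) -> float:
    """|a n b| / |a u b|; 0.0 when both sets are empty (convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: set name, description, genes...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields "
                f"(set name, description, genes), got {len(fields)}")
        set_name, desc, *genes = fields
        genes = [g for g in genes if g]
        if set_name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name "
                             f"{set_name!r}")
        sets[set_name] = genes
        if desc:
            descriptions[set_name] = desc
    return GeneSetCollection(name or path.stem, sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for set_name, genes in collection.sets.items():
        desc = collection.descriptions.get(set_name, "na")
        lines.append("\t".join([set_name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
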
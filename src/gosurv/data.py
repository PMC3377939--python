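"""Core domain types and readers/writers for expression, clinical, and annotation data.

All tabular inputs are plain delimited text.  Expression matrices are
genes x samples with gene identifiers in the first column and sample
identifiers in the header.  Clinical tables carry a survival time column,
a binary event column, and optional covariate columns.  Gene-group
annotation is a two-column (gene_id, group_id) mapping, many-to-many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised when an input file or combination of inputs violates a contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with unique identifiers on both axes."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicated gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicated sample ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self, gene_ids: list[str]) -> np.ndarray:
        """Return the (len(gene_ids), n_samples) sub-matrix in the given order."""
        try:
            idx = [self._gene_index[g] for g in gene_ids]
        except KeyError as exc:
            raise DataError(f"unknown gene id: {exc.args[0]}") from None
        return self.values[idx, :]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.gene_rows(list(gene_ids)))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        try:
            idx = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise DataError(f"unknown sample id: {exc.args[0]}") from None
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalResponse:
    """Right-censored survival outcome: positive times and 0/1 event indicators."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != self.event.shape:
            raise DataError("time and event must have the same length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise DataError("survival times must be finite and strictly positive")
        uniq = set(np.unique(self.event).tolist())
        if not uniq <= {0, 1}:
            raise DataError(f"event indicator must be 0/1, got values {sorted(uniq)}")
        self.event = self.event.astype(int)
        if self.sample_ids is not None and len(self.sample_ids) != len(self.time):
            raise DataError("sample_ids length mismatch")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalResponse":
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids is not None else None
        return SurvivalResponse(self.time[idx], self.event[idx], ids)


@dataclass
class ClinicalCovariates:
    """Numeric clinical covariate matrix (samples x q) after deterministic encoding."""

    covariate_names: list[str]
    values: np.ndarray  # shape (n_samples, q)
    sample_ids: list[str] | None = None
    encoding: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.covariate_names):
            raise DataError("clinical matrix shape does not match covariate names")
        if not np.all(np.isfinite(self.values)):
            raise DataError("clinical covariates contain missing or non-finite values")

    @property
    def q(self) -> int:
        return len(self.covariate_names)

    def subset(self, idx: np.ndarray) -> "ClinicalCovariates":
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids is not None else None
        return ClinicalCovariates(list(self.covariate_names), self.values[idx, :], ids, dict(self.encoding))


@dataclass
class GeneGroupMap:
    """Many-to-many mapping from group ids to member gene ids."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.groups = {g: frozenset(m) for g, m in self.groups.items()}

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups)

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out |= members
        return frozenset(out)

    def restrict_to_genes(self, gene_ids) -> "GeneGroupMap":
        """Intersect every group with the given gene universe, dropping empty groups."""
        universe = set(gene_ids)
        kept: dict[str, frozenset[str]] = {}
        for gid in sorted(self.groups):
            matched = self.groups[gid] & universe
            if matched:
                kept[gid] = frozenset(matched)
            else:
                logger.warning("group %s has no genes in the expression matrix; dropped", gid)
        return GeneGroupMap(kept)


@dataclass
class Dataset:
    """Expression, survival, clinical, and annotation components sharing one sample order."""

    expression: ExpressionMatrix
    survival: SurvivalResponse
    clinical: ClinicalCovariates
    groups: GeneGroupMap

    def __post_init__(self) -> None:
        n = self.expression.n_samples
        if len(self.survival) != n or self.clinical.values.shape[0] != n:
            raise DataError("dataset components disagree on sample count")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def subset_samples(self, sample_ids: list[str]) -> "Dataset":
        idx = np.asarray([self.expression._sample_index[s] for s in sample_ids])
        return Dataset(
            self.expression.subset_samples(sample_ids),
            self.survival.subset(idx),
            self.clinical.subset(idx),
            self.groups,
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        # round_trip parser: reading back a %.17g write reproduces doubles exactly
        return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed file {path}: {exc}") from exc


def read_expression(path, sep=None, impute_missing: bool = False) -> ExpressionMatrix:
    """Load a genes x samples delimited text matrix.

    First column holds gene ids, header row holds sample ids.  Duplicated gene
    ids are rejected.  Missing values are rejected unless ``impute_missing``
    is set, in which case per-gene means are substituted.
    """
    df = _read_table(path, sep)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated gene ids in {path}: {dupes[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = df[col].notna() & bad.isna()
        if nonnum.any():
            gene = df.index[np.argmax(nonnum.to_numpy())]
            raise DataError(f"non-numeric cell in {path} at gene={gene}, sample={col}")
        df[col] = bad
    if df.isna().any().any():
        if not impute_missing:
            raise DataError(f"missing expression values in {path} (pass impute_missing=True to mean-impute)")
        row_means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(dtype=float)
    )


def write_expression(expr: ExpressionMatrix, path, sep="\t") -> None:
    # %.17g round-trips doubles exactly
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_clinical(
    path,
    time_col: str,
    event_col: str,
    covariate_cols: list[str] | None = None,
    categorical_cols: list[str] | None = None,
    sep: str = ",",
) -> tuple[SurvivalResponse, ClinicalCovariates]:
    """Load survival outcome plus clinical covariates from one delimited table.

    The first column is the sample id.  Categorical covariates (non-numeric
    columns, or any column listed in ``categorical_cols``) are dummy-encoded
    deterministically: levels sorted, first level dropped.
    """
    df = _read_table(path, sep)
    covariate_cols = list(covariate_cols or [])
    categorical_cols = set(categorical_cols or [])
    for col in [time_col, event_col, *covariate_cols]:
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path}")
    sample_ids = [str(s) for s in df.index]

    time = pd.to_numeric(df[time_col], errors="coerce")
    if time.isna().any() or (time <= 0).any():
        raise DataError(f"column {time_col!r} must be numeric and strictly positive")
    event = df[event_col]
    if not set(pd.unique(event)) <= {0, 1}:
        raise DataError(f"column {event_col!r} must contain only 0/1 codes")
    survival = SurvivalResponse(time.to_numpy(float), event.to_numpy(), sample_ids)

    blocks: list[pd.DataFrame] = []
    encoding: dict[str, list] = {}
    for col in covariate_cols:
        series = df[col]
        if series.isna().any():
            raise DataError(f"missing values in clinical covariate {col!r}")
        is_cat = col in categorical_cols or not pd.api.types.is_numeric_dtype(series)
        if is_cat:
            levels = sorted(pd.unique(series).tolist())
            encoding[col] = levels
            # sorted levels, first dropped: reproducible across splits
            for lev in levels[1:]:
                blocks.append(pd.DataFrame({f"{col}={lev}": (series == lev).astype(float)}))
        else:
            blocks.append(series.astype(float).to_frame(col))
    if blocks:
        mat = pd.concat(blocks, axis=1)
        clinical = ClinicalCovariates(list(mat.columns), mat.to_numpy(float), sample_ids, encoding)
    else:
        clinical = ClinicalCovariates([], np.empty((len(df), 0)), sample_ids, encoding)
    return survival, clinical


def write_clinical(
    survival: SurvivalResponse,
    clinical: ClinicalCovariates,
    path,
    time_col: str = "time",
    event_col: str = "event",
) -> None:
    df = pd.DataFrame({time_col: survival.time, event_col: survival.event})
    for j, name in enumerate(clinical.covariate_names):
        df[name] = clinical.values[:, j]
    ids = survival.sample_ids or [f"s{i}" for i in range(len(survival))]
    df.index = pd.Index(ids, name="sample_id")
    df.to_csv(path, float_format="%.17g")


def read_group_map(path, sep="\t") -> GeneGroupMap:
    """Load a two-column (gene_id, group_id) mapping; duplicate rows collapse."""
    df = pd.read_csv(path, sep=sep, header=None, names=["gene_id", "group_id"], dtype=str)
    df = df.dropna()
    if len(df) == 0:
        raise DataError(f"empty group map file {path}")
    groups: dict[str, set[str]] = {}
    for gene, group in zip(df["gene_id"], df["group_id"]):
        groups.setdefault(group, set()).add(gene)
    return GeneGroupMap({g: frozenset(m) for g, m in groups.items()})


def write_group_map(groups: GeneGroupMap, path, sep="\t") -> None:
    with open(path, "w") as fh:
        for gid in sorted(groups.groups):
            for gene in sorted(groups.groups[gid]):
                fh.write(f"{gene}{sep}{gid}\n")


def assemble_dataset(
    expression: ExpressionMatrix,
    survival: SurvivalResponse,
    clinical: ClinicalCovariates,
    groups: GeneGroupMap,
) -> Dataset:
    """Align all components on the ordered intersection of sample ids.

    Sample order follows the expression file.  Groups are intersected with
    the expression gene universe; empty groups are dropped with a warning.
    """
    if survival.sample_ids is None:
        raise DataError("survival response must carry sample ids for assembly")
    clin_ids = set(survival.sample_ids)
    shared = [s for s in expression.sample_ids if s in clin_ids]
    if not shared:
        raise DataError("no overlapping samples between expression and clinical data")
    if len(shared) < expression.n_samples:
        logger.warning(
            "dropping %d expression samples without clinical data",
            expression.n_samples - len(shared),
        )
    pos = {s: i for i, s in enumerate(survival.sample_ids)}
    idx = np.asarray([pos[s] for s in shared])
    return Dataset(
        expression.subset_samples(shared),
        survival.subset(idx),
        clinical.subset(idx),
        groups.restrict_to_genes(expression.gene_ids),
    )
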
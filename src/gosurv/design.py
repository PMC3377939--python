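"""Build samples x covariates design matrices from genes, groups, or subclusters.

Each gene set (a whole GO group or one of its preclustered subclusters) is
summarized into a single per-sample covariate: member genes are standardized
over the training samples and the first principal component score is
extracted.  The PC sign is arbitrary, so scores are oriented to correlate
positively with a reference profile (the cluster medoid when available,
otherwise the mean member profile).  All transform constants — per-gene
centering/scaling, the loading vector, and the final covariate
standardization — are learned on training samples only and frozen, so
held-out samples are projected without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gosurv.data import Dataset, ExpressionMatrix
from gosurv.precluster import PreclusteredGroups

logger = logging.getLogger(__name__)

MODES = ("genes", "groups", "preclustered")


@dataclass
class CovariateInfo:
    """Provenance and frozen transform constants for one design column."""

    covariate_id: str
    group_id: str | None
    gene_ids: list[str]          # members that survived zero-variance filtering
    medoid_id: str | None
    loadings: np.ndarray         # unit-norm, one weight per member gene
    gene_means: np.ndarray
    gene_sds: np.ndarray
    score_mean: float
    score_sd: float
    cluster_index: int | None = None
    cluster_size: int | None = None


@dataclass
class GenomicDesign:
    mode: str
    sample_ids: list[str]
    X: np.ndarray                # samples x p, standardized on training samples
    covariates: list[CovariateInfo] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.covariates)

    @property
    def covariate_ids(self) -> list[str]:
        return [c.covariate_id for c in self.covariates]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.covariate_ids)

    def write(self, design_path, meta_path, sep="\t") -> None:
        self.to_frame().to_csv(design_path, sep=sep, index_label="sample_id")
        rows = []
        for c in self.covariates:
            rows.append(
                {
                    "covariate_id": c.covariate_id,
                    "group_id": c.group_id or "",
                    "medoid": c.medoid_id or "",
                    "cluster_index": "" if c.cluster_index is None else c.cluster_index,
                    "n_genes": len(c.gene_ids),
                    "genes": ";".join(c.gene_ids),
                }
            )
        pd.DataFrame(rows).to_csv(meta_path, sep=sep, index=False)


def _standardize_rows(values: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (values - means[:, None]) / sds[:, None]


def first_principal_component(
    expr_subset: ExpressionMatrix,
    reference_gene: str | None = None,
) -> tuple[np.ndarray, CovariateInfo]:
    """First-PC summary of a gene set over the provided samples.

    Genes are centered and scaled to unit variance (correlation-scale PCA),
    then the leading right-singular direction of the samples x genes matrix
    gives the loading vector; scores are the projections.  Zero-variance
    genes are dropped with a warning; a single-gene set reduces to the
    standardized gene itself.

    Returns the per-sample scores (not yet re-standardized) and a
    :class:`CovariateInfo` carrying the frozen constants.
    """
    if expr_subset.n_samples < 2:
        raise ValueError("need at least 2 samples for a principal component")
    values = expr_subset.values
    sds = values.std(axis=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all genes in the set have zero variance")
    if not keep.all():
        dropped = [g for g, k in zip(expr_subset.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:5])
    gene_ids = [g for g, k in zip(expr_subset.gene_ids, keep) if k]
    values = values[keep]
    means = values.mean(axis=1)
    sds = values.std(axis=1)
    Gz = _standardize_rows(values, means, sds)    # genes x samples

    A = Gz.T                                      # samples x genes, columns centered
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    loadings = vt[0]
    scores = A @ loadings

    if reference_gene is not None and reference_gene in gene_ids:
        ref = Gz[gene_ids.index(reference_gene)]
    else:
        ref = Gz.mean(axis=0)
    if float(scores @ ref) < 0:
        loadings = -loadings
        scores = -scores

    info = CovariateInfo(
        covariate_id="",
        group_id=None,
        gene_ids=gene_ids,
        medoid_id=reference_gene,
        loadings=loadings,
        gene_means=means,
        gene_sds=sds,
        score_mean=0.0,
        score_sd=1.0,
    )
    return scores, info


def _single_gene_covariate(expr: ExpressionMatrix, gene: str) -> tuple[np.ndarray, CovariateInfo] | None:
    row = expr.gene_rows([gene])[0]
    sd = row.std()
    if sd == 0:
        logger.warning("gene %s has zero variance on training samples; skipped", gene)
        return None
    mean = row.mean()
    scores = (row - mean) / sd
    info = CovariateInfo(
        covariate_id=gene,
        group_id=None,
        gene_ids=[gene],
        medoid_id=None,
        loadings=np.array([1.0]),
        gene_means=np.array([mean]),
        gene_sds=np.array([sd]),
        score_mean=0.0,
        score_sd=1.0,
    )
    return scores, info


def build_design(
    dataset: Dataset,
    mode: str,
    preclustered: PreclusteredGroups | None = None,
    train_sample_ids: list[str] | None = None,
) -> GenomicDesign:
    """Construct the genomic design for training samples.

    mode='genes': one standardized covariate per annotated gene.
    mode='groups': one first-PC covariate per GO group (mean-profile oriented).
    mode='preclustered': one first-PC covariate per (group, cluster) pair,
    oriented by the cluster medoid.  Only genes annotated to at least one
    group enter the design in every mode, keeping covariate universes
    comparable.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    train_ids = list(train_sample_ids) if train_sample_ids is not None else list(dataset.sample_ids)
    expr = dataset.expression.subset_samples(train_ids)

    columns: list[np.ndarray] = []
    infos: list[CovariateInfo] = []

    if mode == "genes":
        for gene in sorted(dataset.groups.annotated_genes):
            made = _single_gene_covariate(expr, gene)
            if made is None:
                continue
            scores, info = made
            columns.append(scores)
            infos.append(info)
    elif mode == "groups":
        for gid in dataset.groups.group_ids:
            genes = sorted(dataset.groups.groups[gid])
            sub = ExpressionMatrix(genes, train_ids, expr.gene_rows(genes))
            try:
                scores, info = first_principal_component(sub, reference_gene=None)
            except ValueError:
                logger.warning("group %s is all zero-variance; skipped", gid)
                continue
            info.covariate_id = gid
            info.group_id = gid
            columns.append(scores)
            infos.append(info)
    else:
        if preclustered is None:
            raise ValueError("mode='preclustered' requires a PreclusteredGroups")
        for gid in sorted(preclustered.by_group):
            asg = preclustered.by_group[gid].assignment
            for k in range(asg.K):
                members = asg.members(k)
                medoid = asg.medoid_ids[k]
                sub = ExpressionMatrix(members, train_ids, expr.gene_rows(members))
                try:
                    scores, info = first_principal_component(sub, reference_gene=medoid)
                except ValueError:
                    logger.warning("cluster %s|c%d is all zero-variance; skipped", gid, k + 1)
                    continue
                info.covariate_id = f"{gid}|c{k + 1}"
                info.group_id = gid
                info.cluster_index = k + 1
                info.cluster_size = len(members)
                columns.append(scores)
                infos.append(info)

    if not columns:
        raise ValueError(f"no usable covariates for mode={mode!r}")

    X = np.column_stack(columns)
    # penalties are scale-sensitive: standardize covariates on training samples
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    X = (X - means) / sds
    for info, m, s in zip(infos, means, sds):
        info.score_mean = float(m)
        info.score_sd = float(s)
    return GenomicDesign(mode=mode, sample_ids=train_ids, X=X, covariates=infos)


def project_design(design: GenomicDesign, dataset: Dataset, sample_ids: list[str]) -> np.ndarray:
    """Transform new samples with the design's frozen training constants."""
    expr = dataset.expression.subset_samples(list(sample_ids))
    cols = []
    for info in design.covariates:
        values = expr.gene_rows(info.gene_ids)
        Gz = _standardize_rows(values, info.gene_means, info.gene_sds)
        scores = Gz.T @ info.loadings
        cols.append((scores - info.score_mean) / info.score_sd)
    return np.column_stack(cols)
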
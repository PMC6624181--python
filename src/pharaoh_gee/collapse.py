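"""Gene-level collapsing of rare variants into a standardized pathway design matrix.

Rare variants are aggregated per gene into burden scores (weighted allele-count
sums), arranged pathway-major into an ``N x (T+1)`` design matrix ``X`` whose
first column is the intercept, and standardized so that each non-intercept
column is mean-centered with sum of squares equal to ``N`` (the conventional
scaling constraint ``diag(X'X) = N I``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PathwayAnnotation",
    "CollapsedDesign",
    "variant_weights",
    "collapse_gene",
    "build_design",
    "standardize_design",
]


class InvalidFrequencyError(ValueError):
    """Raised for minor-allele frequencies outside (0, 0.5]."""


@dataclass
class GenotypeMatrix:
    """Sample-by-variant allele dosages with per-variant minor-allele frequencies.

    Parameters
    ----------
    dosages
        ``N x V`` float array of alternate-allele counts in {0, 1, 2};
        missing genotypes are NaN.
    sample_ids, variant_ids
        Row and column labels.
    maf
        Length-``V`` minor-allele frequencies, strictly in (0, 0.5].
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        n, v = self.dosages.shape
        if n < 2 or v < 1:
            raise ValueError(f"need N >= 2 samples and V >= 1 variants, got {n} x {v}")
        if len(self.sample_ids) != n or len(self.variant_ids) != v:
            raise ValueError("id lists do not match dosage matrix shape")
        if self.maf.shape != (v,):
            raise ValueError("maf length must equal number of variants")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise InvalidFrequencyError("MAF must lie in (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PathwayAnnotation:
    """Variant-to-gene and gene-to-pathway membership maps.

    A gene belonging to several pathways contributes one design column per
    membership: the pathway blocks never share columns.
    """

    variant_to_gene: dict[str, str]
    gene_to_pathways: dict[str, set[str]]
    pathway_order: list[str]
    gene_order_within_pathway: dict[str, list[str]]

    def __post_init__(self) -> None:
        for pw, genes in self.gene_order_within_pathway.items():
            for g in genes:
                if g not in self.gene_to_pathways:
                    raise ValueError(f"gene {g!r} of pathway {pw!r} missing from gene_to_pathways")

    @classmethod
    def from_maps(
        cls,
        variant_to_gene: dict[str, str],
        pathway_to_genes: dict[str, list[str]],
    ) -> "PathwayAnnotation":
        """Build the annotation from a variant->gene map and an ordered pathway->genes map."""
        gene_to_pathways: dict[str, set[str]] = {}
        for pw, genes in pathway_to_genes.items():
            for g in genes:
                gene_to_pathways.setdefault(g, set()).add(pw)
        return cls(
            variant_to_gene=dict(variant_to_gene),
            gene_to_pathways=gene_to_pathways,
            pathway_order=list(pathway_to_genes),
            gene_order_within_pathway={pw: list(genes) for pw, genes in pathway_to_genes.items()},
        )

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_order)


@dataclass
class CollapsedDesign:
    """Standardized gene-burden design matrix with pathway block structure.

    ``X`` is ``N x (T+1)``: column 0 is the intercept (all ones); the remaining
    ``T`` columns are gene burdens ordered pathway-major, each mean-centered and
    scaled so its sum of squares equals ``N``. ``block_index`` records, per
    non-intercept column, its ``(pathway_id, gene_id)`` coordinates. ``X_raw``
    keeps the pre-standardization burdens so that resampling schemes can
    re-standardize on training subsets only.
    """

    X: np.ndarray
    block_index: list[tuple[str, str]]
    pathway_order: list[str]
    X_raw: np.ndarray | None = None
    genes_per_pathway: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes_per_pathway:
            counts: dict[str, int] = {}
            for pw, _ in self.block_index:
                counts[pw] = counts.get(pw, 0) + 1
            self.genes_per_pathway = counts

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1] - 1

    @property
    def K(self) -> int:
        return len(self.pathway_order)

    @property
    def T_k(self) -> list[int]:
        return [self.genes_per_pathway[pw] for pw in self.pathway_order]

    def pathway_of_column(self) -> np.ndarray:
        """Integer pathway index (0-based) per non-intercept column."""
        idx = {pw: k for k, pw in enumerate(self.pathway_order)}
        return np.array([idx[pw] for pw, _ in self.block_index], dtype=int)


def variant_weights(maf: np.ndarray) -> np.ndarray:
    """Collapsing weight per variant: ``|log10 MAF|``, so rarer variants weigh more.

    Raises
    ------
    InvalidFrequencyError
        If any frequency lies outside (0, 0.5].
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise InvalidFrequencyError("MAF must lie in (0, 0.5]")
    return np.abs(np.log10(maf))


def collapse_gene(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted burden score per sample: ``burden_i = sum_j w_j * dosage_ij``.

    Missing dosages must already be imputed (see :func:`build_design`, which
    mean-imputes per variant). A variant column that is entirely missing is
    dropped with a warning.
    """
    dosages = np.asarray(dosages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != weights.shape[0]:
        raise ValueError("dosages must be N x m with one weight per variant")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    all_missing = np.isnan(dosages).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing variant column(s)")
        dosages = dosages[:, ~all_missing]
        weights = weights[~all_missing]
    filled = _mean_impute(dosages)
    return filled @ weights


def _mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-variant mean of observed calls."""
    if not np.isnan(dosages).any():
        return dosages
    filled = dosages.copy()
    col_mean = np.nanmean(filled, axis=0)
    miss_r, miss_c = np.nonzero(np.isnan(filled))
    filled[miss_r, miss_c] = col_mean[miss_c]
    return filled


def standardize_design(
    X_raw: np.ndarray,
    block_index: list[tuple[str, str]],
    pathway_order: list[str],
) -> CollapsedDesign:
    """Standardize burden columns to satisfy ``diag(X'X) = N I``.

    Each non-intercept column is mean-centered then rescaled so its sum of
    squares equals ``N``; the intercept column already satisfies the
    constraint and is left untouched. Centering keeps every component
    orthogonal to the intercept. Zero-variance columns carry no information
    and are dropped with a warning.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    n = X_raw.shape[0]
    if not np.allclose(X_raw[:, 0], 1.0):
        raise ValueError("column 0 of the raw design must be the intercept (all ones)")
    centered = X_raw[:, 1:] - X_raw[:, 1:].mean(axis=0)
    ss = np.einsum("ij,ij->j", centered, centered)
    keep = ss > 1e-12 * max(1.0, float(np.abs(X_raw[:, 1:]).max()) ** 2)
    if not keep.all():
        dropped = [block_index[j] for j in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping {len(dropped)} zero-variance burden column(s): {dropped}")
    centered = centered[:, keep]
    ss = ss[keep]
    kept_index = [bi for bi, k in zip(block_index, keep) if k]
    scaled = centered * np.sqrt(n / ss)
    X = np.column_stack([np.ones(n), scaled])
    raw_kept = np.column_stack([np.ones(n), X_raw[:, 1:][:, keep]])
    kept_pathways = [pw for pw in pathway_order if any(p == pw for p, _ in kept_index)]
    if not kept_index:
        raise ValueError("no informative burden columns remain after standardization")
    return CollapsedDesign(X=X, block_index=kept_index, pathway_order=kept_pathways, X_raw=raw_kept)


def build_design(
    genotypes: GenotypeMatrix,
    annot: PathwayAnnotation,
    maf_threshold: float = 0.05,
    weight_fn: str = "log_maf",
) -> CollapsedDesign:
    """Collapse rare variants into the standardized pathway-major design matrix.

    Variants with MAF above ``maf_threshold`` are excluded (rare-variant
    filter). ``weight_fn`` is ``"log_maf"`` for ``|log10 MAF|`` weights or
    ``"uniform"`` for unit weights. Pathways left with no usable gene are
    dropped with a warning; an empty result is fatal.
    """
    if weight_fn not in ("log_maf", "uniform"):
        raise ValueError(f"unknown weight_fn {weight_fn!r}")
    rare = genotypes.maf <= maf_threshold
    col_of = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    gene_variants: dict[str, list[int]] = {}
    for vid, gene in annot.variant_to_gene.items():
        j = col_of.get(vid)
        if j is not None and rare[j]:
            gene_variants.setdefault(gene, []).append(j)

    burdens: dict[str, np.ndarray] = {}
    for gene, cols in gene_variants.items():
        cols_arr = np.array(sorted(cols), dtype=int)
        if weight_fn == "log_maf":
            w = variant_weights(genotypes.maf[cols_arr])
        else:
            w = np.ones(cols_arr.size)
        burdens[gene] = collapse_gene(genotypes.dosages[:, cols_arr], w)

    columns: list[np.ndarray] = []
    block_index: list[tuple[str, str]] = []
    kept_pathways: list[str] = []
    for pw in annot.pathway_order:
        pw_cols = [(g, burdens[g]) for g in annot.gene_order_within_pathway[pw] if g in burdens]
        if not pw_cols:
            logger.warning("pathway %s has no gene with retained rare variants; dropped", pw)
            continue
        kept_pathways.append(pw)
        for g, b in pw_cols:
            columns.append(b)
            block_index.append((pw, g))
    if not columns:
        raise ValueError("no pathway has any usable gene after rare-variant filtering")
    X_raw = np.column_stack([np.ones(genotypes.n_samples)] + columns)
    return standardize_design(X_raw, block_index, kept_pathways)
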
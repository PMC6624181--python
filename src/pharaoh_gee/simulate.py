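"""Synthetic rare-variant pathway data and the type-I-error / power study harness.

The generator emulates a sequencing-study design: ``K`` pathways of
``genes_per_pathway`` genes each, every gene carrying a handful of rare
variants with minor-allele frequencies drawn from a log-uniform rare
spectrum and Hardy-Weinberg binomial genotypes. Only the first pathway is
causal: its first ``H1`` genes contribute to the latent linear predictor

    eta_iq = beta * sum_{t<=H1} w * sum_j |log10 MAF_tj| * g_itj

and correlated binary phenotypes arise by thresholding a latent
``MVN(0, Sigma_rho)`` draw (exchangeable correlation ``rho``) at ``eta``:
``y_iq = 1`` iff ``Z_iq < eta_iq``, so larger ``eta`` raises case probability
and the null prevalence is 1/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .collapse import GenotypeMatrix, PathwayAnnotation, build_design, variant_weights
from .gee_core import ClusteredPhenotypes, PenaltyConfig
from .inference import bh_fdr, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedReplicate",
    "simulate_variant_pool",
    "simulate_linear_predictor",
    "simulate_phenotypes",
    "simulate_replicate",
    "run_study",
    "StudyResult",
]


@dataclass
class SimulationConfig:
    """Design of one simulated replicate.

    Defaults follow the study design: 1000 individuals, 10 pathways of 10
    genes (only pathway 1 causal), gene-level effect ``w``, pathway-level
    effect ``beta``, exchangeable phenotype correlation ``rho``, and a rare
    MAF spectrum (log-uniform on [1e-4, 0.01], roughly what a kilobase of
    coding sequence yields). ``H1`` is the number of causal genes within the
    causal pathway.
    """

    N: int = 1000
    K: int = 10
    genes_per_pathway: int = 10
    variants_per_gene: tuple[int, int] = (5, 20)
    maf_min: float = 1e-4
    maf_max: float = 0.01
    H1: int = 1
    w: float = 0.5
    beta: float = 0.2
    rho: float = 0.25
    Q: int = 3
    n_replicates: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H1 > self.genes_per_pathway:
            raise ValueError("H1 cannot exceed genes_per_pathway")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("MAF spectrum must lie in (0, 0.5]")
        for name in ("w", "beta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulatedReplicate:
    genotypes: GenotypeMatrix
    annotation: PathwayAnnotation
    Y: np.ndarray
    eta: np.ndarray
    causal_pathway: str
    causal_genes: list[str]
    config: SimulationConfig = field(repr=False, default=None)


def _gene_id(k: int, t: int) -> str:
    return f"P{k + 1}G{t + 1}"


def simulate_variant_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, PathwayAnnotation]:
    """Draw variants, MAFs and Hardy-Weinberg genotypes for every gene.

    MAFs are log-uniform on ``[maf_min, maf_max]`` (degenerate spectra with
    ``maf_min == maf_max`` are allowed); each variant's dosages are
    ``Binomial(2, MAF)`` draws. Genes are unique per pathway, so the
    annotation block structure is exactly pathway-major.
    """
    variant_ids: list[str] = []
    variant_to_gene: dict[str, str] = {}
    pathway_to_genes: dict[str, list[str]] = {}
    lo, hi = config.variants_per_gene
    for k in range(config.K):
        pw = f"pathway{k + 1}"
        pathway_to_genes[pw] = []
        for t in range(config.genes_per_pathway):
            gene = _gene_id(k, t)
            pathway_to_genes[pw].append(gene)
            m = int(rng.integers(lo, hi + 1))
            for j in range(m):
                vid = f"{gene}_v{j + 1}"
                variant_ids.append(vid)
                variant_to_gene[vid] = gene
    if config.maf_min == config.maf_max:
        maf = np.full(len(variant_ids), config.maf_min)
    else:
        maf = np.exp(
            rng.uniform(np.log(config.maf_min), np.log(config.maf_max), size=len(variant_ids))
        )
    dosages = rng.binomial(2, maf[None, :], size=(config.N, len(variant_ids))).astype(float)
    genotypes = GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"s{i + 1}" for i in range(config.N)],
        variant_ids=variant_ids,
        maf=maf,
    )
    annotation = PathwayAnnotation.from_maps(variant_to_gene, pathway_to_genes)
    return genotypes, annotation


def simulate_linear_predictor(
    genotypes: GenotypeMatrix, annotation: PathwayAnnotation, config: SimulationConfig
) -> np.ndarray:
    """Latent ``N x Q`` linear predictor from the causal genes of pathway 1.

    Each causal variant contributes ``beta * w * |log10 MAF| * dosage``; the
    predictor is shared across the Q phenotypes (a common pathway effect).
    """
    eta1 = np.zeros(genotypes.n_samples)
    causal = {_gene_id(0, t) for t in range(config.H1)}
    col_of = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    for vid, gene in annotation.variant_to_gene.items():
        if gene in causal:
            j = col_of[vid]
            gamma = float(variant_weights(genotypes.maf[j : j + 1])[0])
            eta1 += config.w * gamma * genotypes.dosages[:, j]
    return np.tile((config.beta * eta1)[:, None], (1, config.Q))


def simulate_phenotypes(eta: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Binary phenotypes from the liability-threshold mechanism.

    ``Z_i ~ MVN(0, (1-rho) I + rho J)``; ``y_iq = 1`` iff ``Z_iq < eta_iq``.
    Under the null (``eta = 0``) every phenotype has prevalence 1/2 and the
    latent correlation between phenotypes equals ``rho``.
    """
    n, q = eta.shape
    cov = (1.0 - rho) * np.eye(q) + rho * np.ones((q, q))
    Z = rng.multivariate_normal(np.zeros(q), cov, size=n, method="cholesky")
    return (Z < eta).astype(float)


def simulate_replicate(config: SimulationConfig, rng: np.random.Generator) -> SimulatedReplicate:
    """One full replicate: variant pool, latent predictor, binary phenotypes."""
    genotypes, annotation = simulate_variant_pool(config, rng)
    eta = simulate_linear_predictor(genotypes, annotation, config)
    Y = simulate_phenotypes(eta, config.rho, rng)
    return SimulatedReplicate(
        genotypes=genotypes,
        annotation=annotation,
        Y=Y,
        eta=eta,
        causal_pathway="pathway1",
        causal_genes=[_gene_id(0, t) for t in range(config.H1)],
        config=config,
    )


@dataclass
class StudyResult:
    """Replicate-level p/q-values and the summary error rates of the study."""

    p_values: np.ndarray  # n_rep x K
    q_values: np.ndarray  # n_rep x K
    causal_index: int
    alpha: float
    fdr_level: float
    n_failed: int

    @property
    def n_replicates(self) -> int:
        return self.p_values.shape[0]

    @property
    def power(self) -> float:
        """Fraction of replicates where the causal pathway passes FDR control
        (strict q < level, matching the study's discovery rule)."""
        return float(np.mean(self.q_values[:, self.causal_index] < self.fdr_level))

    @property
    def type1_error(self) -> float:
        """Fraction of non-causal pathway tests significant at ``alpha``."""
        null = np.delete(self.p_values, self.causal_index, axis=1)
        return float(np.mean(null < self.alpha))

    @property
    def empirical_fdr(self) -> float:
        """Mean of V/max(R, 1) over replicates — the quantity BH controls."""
        disc = self.q_values < self.fdr_level
        R = disc.sum(axis=1)
        false = np.delete(disc, self.causal_index, axis=1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            ratio = np.where(R > 0, false / np.maximum(R, 1), 0.0)
        return float(ratio.mean())

    def fdr_among_discoveries(self) -> tuple[float, float, int]:
        """V/R averaged over replicates with at least one discovery.

        Returns ``(mean, mc_standard_error, n_replicates_with_discoveries)``;
        (0, 0, 0) when nothing is ever discovered.
        """
        disc = self.q_values < self.fdr_level
        R = disc.sum(axis=1)
        false = np.delete(disc, self.causal_index, axis=1).sum(axis=1)
        has = R > 0
        if not has.any():
            return 0.0, 0.0, 0
        ratios = false[has] / R[has]
        se = float(ratios.std(ddof=1) / np.sqrt(has.sum())) if has.sum() > 1 else 0.0
        return float(ratios.mean()), se, int(has.sum())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_replicates": self.n_replicates,
                    "power": self.power,
                    "type1_error": self.type1_error,
                    "empirical_fdr": self.empirical_fdr,
                    "alpha": self.alpha,
                    "fdr_level": self.fdr_level,
                    "n_failed": self.n_failed,
                }
            ]
        )


def run_study(
    config: SimulationConfig | None = None,
    n_replicates: int = 50,
    n_perm: int = 199,
    penalties: PenaltyConfig | None = None,
    structure: str = "exchangeable",
    alpha: float = 0.01,
    fdr_level: float = 0.05,
    maf_threshold: float = 0.05,
    seed: int | None = None,
) -> StudyResult:
    """Run the simulation study: per replicate, fit all pathways jointly and
    permutation-test them, then summarize power, type-I error and FDR.

    The default scale (50 replicates, ``n_perm=199``) is a desk-scale version
    of the full study; pass a larger ``n_replicates`` and ``config`` for the
    full design. ``seed`` overrides ``config.seed``.
    """
    config = config or SimulationConfig(N=500)
    penalties = penalties or PenaltyConfig(lambda_G=1.0, lambda_P=1.0)
    master_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)

    p_rows, q_rows = [], []
    n_failed = 0
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        try:
            replicate = simulate_replicate(config, rep_rng)
            design = build_design(replicate.genotypes, replicate.annotation, maf_threshold)
            Y = ClusteredPhenotypes(Y=replicate.Y, family="binomial")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                outcome = permutation_test(
                    design,
                    Y,
                    penalties=penalties,
                    structure=structure,
                    n_perm=n_perm,
                    seed=int(rep_rng.integers(0, 2**31 - 1)),
                )
        except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
            logger.warning("replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        p = np.array([r.p_value for r in outcome.pathway_results])
        p_rows.append(p)
        q_rows.append(bh_fdr(p))
        logger.info("replicate %d/%d done (causal p=%.4g)", rep + 1, n_replicates, p[0])
    if not p_rows:
        raise RuntimeError("all replicates failed")
    return StudyResult(
        p_values=np.vstack(p_rows),
        q_values=np.vstack(q_rows),
        causal_index=0,
        alpha=alpha,
        fdr_level=fdr_level,
        n_failed=n_failed,
    )


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``config`` with all causal effects switched off (global null)."""
    config = config or SimulationConfig()
    return replace(config, H1=0, w=0.0, beta=0.0)
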
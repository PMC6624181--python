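"""Readers and writers for the plain-text formats used by the pipeline.

Genotypes come from a VCF (GT field) or a headered TSV dosage matrix
(rows = samples, columns = variants); variant-to-gene maps are 2-column TSV;
pathways are GMT lines (id, description, genes...); phenotypes are a
headered TSV with the sample id in the first column. Writers emit the fit
report, test tables and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .collapse import GenotypeMatrix, PathwayAnnotation
from .gee_core import ClusteredPhenotypes, FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_gmt",
    "read_variant_gene_map",
    "read_dosage_tsv",
    "read_vcf",
    "read_phenotypes",
    "build_annotation",
    "run_pipeline",
    "write_fit_report",
    "write_manifest",
    "write_genotypes_tsv",
    "write_gmt",
]


@dataclass
class RunConfig:
    """Everything one end-to-end analysis needs, with seeds recorded.

    ``penalties`` is a ``(lambda_G, lambda_P)`` pair; set ``cv_grid`` to a
    :class:`~pharaoh_gee.model_selection.CVGrid` to select them by
    cross-validation instead.
    """

    genotypes: Path
    variant_map: Path
    gmt: Path
    phenotypes: Path
    out_dir: Path
    family: str | None = None
    structure: str = "exchangeable"
    penalties: tuple[float, float] = (1.0, 1.0)
    cv_grid: "object | None" = None
    n_perm: int = 1000
    seed: int = 0
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("genotypes", "variant_map", "gmt", "phenotypes"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"[{name}] input path does not exist: {p}")
        self.out_dir = Path(self.out_dir)


def run_pipeline(config: RunConfig) -> dict:
    """Collapse -> (optional CV) -> fit -> permutation test, with outputs on disk.

    Returns a dict with the fitted model, the test outcome and the selected
    penalties; writes the pathway/gene test tables, the fit report and a
    manifest (seeds, penalties, versions) into ``config.out_dir``. Errors are
    re-raised with a stage label so failures are attributable.
    """
    from . import __version__
    from .collapse import build_design
    from .gee_core import PenaltyConfig
    from .inference import permutation_test
    from .model_selection import cross_validate

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage [{name}] failed: {exc}") from exc

    geno = stage(
        "read-genotypes",
        read_vcf if str(config.genotypes).endswith((".vcf", ".vcf.gz")) else read_dosage_tsv,
        config.genotypes,
    )
    v2g = stage("read-variant-map", read_variant_gene_map, config.variant_map)
    pw = stage("read-gmt", read_gmt, config.gmt)
    annot = PathwayAnnotation.from_maps(v2g, pw)
    design = stage("collapse", build_design, geno, annot, config.maf_threshold)
    Y = stage(
        "read-phenotypes",
        read_phenotypes,
        config.phenotypes,
        sample_order=geno.sample_ids,
        family=config.family,
    )

    lam_G, lam_P = config.penalties
    cv_table = None
    if config.cv_grid is not None:
        lam_G, lam_P, cv_table = stage("cv", cross_validate, design, Y, config.cv_grid, config.structure)
    outcome = stage(
        "test",
        permutation_test,
        design,
        Y,
        PenaltyConfig(lambda_G=lam_G, lambda_P=lam_P),
        structure=config.structure,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcome.pathway_table.to_csv(out / "pathway_tests.tsv", sep="\t", index=False, float_format="%.6g")
    outcome.gene_table.to_csv(out / "gene_tests.tsv", sep="\t", index=False, float_format="%.6g")
    if cv_table is not None:
        cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False)
    write_fit_report(out, outcome.fit_obs)
    write_manifest(
        out,
        {
            "command": "run_pipeline",
            "lambda_G": lam_G,
            "lambda_P": lam_P,
            "structure": config.structure,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "maf_threshold": config.maf_threshold,
            "version": __version__,
        },
    )
    return {"design": design, "outcome": outcome, "lambda_G": lam_G, "lambda_P": lam_P}


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into an ordered pathway -> gene-list map."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            pw = fields[0]
            if pw in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pw!r}")
            pathways[pw] = [g for g in fields[2:] if g]
    if not pathways:
        logger.warning("GMT file %s is empty", path)
    return pathways


def read_variant_gene_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column (variant_id, gene_id) TSV, header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("variant-gene map must have two tab-separated columns")
    if df.iloc[0, 0].lower() in ("variant", "variant_id", "snp", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _fold_maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a headered sample x variant dosage TSV (first column sample id).

    MAFs are computed from the observed dosages (allele frequency folded to
    the minor allele); monomorphic variants get a tiny positive placeholder
    frequency and are expected to be removed by the rare-variant filter's
    zero-variance column drop.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=float)
    freq = np.nanmean(dosages, axis=0) / 2.0
    maf = _fold_maf(freq)
    maf = np.where(maf <= 0, 0.5 / (2 * max(dosages.shape[0], 1)), maf)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
        maf=maf,
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from the GT field of a VCF via cyvcf2 (1-based coordinates)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, vids = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        vids.append(vid)
        gts = variant.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.where(gts == 3, 2.0, np.where(gts == 1, 1.0, np.where(gts == 0, 0.0, np.nan)))
        rows.append(dos)
    if not rows:
        raise ValueError(f"no variants in {path}")
    dosages = np.vstack(rows).T
    freq = np.nanmean(dosages, axis=0) / 2.0
    maf = _fold_maf(freq)
    maf = np.where(maf <= 0, 0.5 / (2 * len(samples)), maf)
    return GenotypeMatrix(dosages=dosages, sample_ids=samples, variant_ids=vids, maf=maf)


def build_annotation(
    variant_to_gene: dict[str, str], pathway_to_genes: dict[str, list[str]]
) -> PathwayAnnotation:
    return PathwayAnnotation.from_maps(variant_to_gene, pathway_to_genes)


def read_phenotypes(
    path: str | Path,
    sample_order: list[str] | None = None,
    family: str | None = None,
) -> ClusteredPhenotypes:
    """Read the clustered phenotype TSV and align it to the genotype samples.

    Binary columns ({0,1}-valued) suggest the binomial family; mixing a
    continuous column into a binomial analysis is an error. Samples are
    intersected with ``sample_order`` (complete cases only) and reordered to
    match it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if sample_order is not None:
        common = [s for s in sample_order if s in df.index]
        if not common:
            raise ValueError("no overlapping samples between phenotypes and genotypes")
        dropped = len(df) - len(common)
        if dropped:
            logger.info("dropping %d phenotype rows without genotypes", dropped)
        df = df.loc[common]
    df = df.dropna()
    Y = df.to_numpy(dtype=float)
    all_binary = bool(np.isin(Y, (0.0, 1.0)).all())
    if family is None:
        family = "binomial" if all_binary else "gaussian"
        logger.info("auto-detected %s family for %d phenotype column(s)", family, Y.shape[1])
    if family == "binomial" and not all_binary:
        raise ValueError("binomial family requested but a non-{0,1} phenotype column is present")
    return ClusteredPhenotypes(Y=Y, family=family, phenotype_names=list(df.columns))


def write_fit_report(out_dir: str | Path, fit_result: FitResult) -> None:
    """Write pathway coefficients, gene weights and the convergence log as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    K = len(fit_result.pathway_order)
    Q = fit_result.B.B.shape[1]
    coef = pd.DataFrame(
        fit_result.B.B,
        index=["(intercept)"] + list(fit_result.pathway_order),
        columns=[f"beta_{q + 1}" for q in range(Q)],
    )
    coef.to_csv(out / "pathway_coefficients.tsv", sep="\t", index_label="pathway")
    weights = pd.DataFrame(
        {
            "pathway": [pw for pw, _ in fit_result.block_index],
            "gene": [g for _, g in fit_result.block_index],
            "weight": fit_result.W.w_star,
        }
    )
    weights.to_csv(out / "gene_weights.tsv", sep="\t", index=False)
    with open(out / "convergence.tsv", "w") as fh:
        fh.write("iteration\tobjective\n")
        for i, obj in enumerate(fit_result.objective_trace, start=1):
            fh.write(f"{i}\t{obj:.10g}\n")
    summary = {
        "converged": bool(fit_result.converged),
        "n_iter": int(fit_result.n_iter),
        "phi": float(fit_result.phi),
        "correlation_structure": fit_result.correlation.structure,
        "alpha": [float(a) for a in np.atleast_1d(fit_result.correlation.alpha)],
        "K": K,
    }
    with open(out / "fit_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def write_manifest(out_dir: str | Path, manifest: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def write_genotypes_tsv(path: str | Path, genotypes: GenotypeMatrix) -> None:
    pd.DataFrame(
        genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.variant_ids
    ).to_csv(path, sep="\t", index_label="sample")


def write_gmt(path: str | Path, pathway_to_genes: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for pw, genes in pathway_to_genes.items():
            fh.write("\t".join([pw, pw] + list(genes)) + "\n")
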
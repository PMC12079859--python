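"""Seeded synthetic-study generator with known ground truth.

Generates block-LD genotypes (AR-1 latent Gaussian, double-thresholded
haplotypes), pathway-structured exposure and outcome phenotypes,
per-SNP summary statistics by exact OLS on the simulated cohorts,
planted eQTL panels for colocalization, and category-labelled gene
annotations placed inside instrument LD intervals.  Everything is
reproducible bit-for-bit from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import CategoryConfig, CohortData, GeneAnnotation, LDReference, VariantRecord

_PVAL_FLOOR = 1e-300
_BLOCK_SPACING_BP = 2_000_000
_SNP_SPACING_BP = 5_000


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for one synthetic study; see module docstring."""

    n_individuals: int = 5000
    n_blocks: int = 20
    snps_per_block: int = 5
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    # proportions of causal instruments assigned to P1 / P2 (rest P0)
    prop_p1: float = 0.35
    prop_p2: float = 0.35
    beta_sd: float = 0.08          # per-SNP exposure effect sd (tau)
    exposure_noise_sd: float = 1.0
    theta1: float = 0.1            # outcome direct effect of pathway-1 component
    theta2: float = 0.1
    theta0: float = 0.0
    outcome_noise_sd: float = 1.0
    prevalence: float = 0.2
    eqtl_n: int = 300
    eqtl_effect: float = 0.7       # expression-SD per allele at the causal eQTL
    eqtl_noise_sd: float = 1.0
    # probability that a P_k instrument's interval receives a category-k gene
    gene_specificity: float = 1.0
    n_background_genes: int = 20
    background_term_rate: float = 0.0
    tissues: tuple[str, ...] = ("tissueA", "tissueB")
    # planted colocalization: P1 instruments colocalize in tissues[0],
    # P2 instruments in tissues[1]
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.prop_p1 and 0 <= self.prop_p2
                and self.prop_p1 + self.prop_p2 <= 1):
            raise ValueError("pathway proportions must be in [0,1] and sum <= 1")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 + 1e-12):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class GenotypeData:
    dosages: np.ndarray            # individuals x variants, values in {0,1,2}
    variant_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    mafs: np.ndarray
    block_index: np.ndarray        # block id per variant
    ld: LDReference


@dataclass
class GroundTruth:
    pathway: dict[str, str]        # instrument id -> "P1" | "P2" | "P0"
    betas: dict[str, float]        # per-allele exposure effect of causal SNPs
    thetas: tuple[float, float, float]
    coloc: dict[str, set[str]]     # tissue -> instrument ids planted to colocalize
    sd_exposure: float             # realized SD of the exposure in the cohort
    causal_ids: list[str]


@dataclass
class SimulatedStudy:
    params: SimulationParams
    cohort: CohortData             # exposure cohort (one-sample analyses)
    genotypes: GenotypeData
    exposure_stats: list[VariantRecord]
    outcome_stats: list[VariantRecord]        # continuous outcome, cohort B
    outcome_stats_binary: list[VariantRecord]
    genes: list[GeneAnnotation]
    category_config: CategoryConfig
    eqtl_panels: dict[str, dict[str, list[VariantRecord]]]
    truth: GroundTruth

    @property
    def instrument_ids(self) -> list[str]:
        return self.truth.causal_ids


def _ar1_chol(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr + 1e-12 * np.eye(m))


def simulate_genotypes(params: SimulationParams,
                       rng: np.random.Generator) -> GenotypeData:
    """Block-LD genotypes: per block a latent AR-1 Gaussian is
    thresholded at the MAF quantile twice per individual (two
    haplotypes) and summed to a dosage in {0,1,2}.  The LD reference
    reports the analytic r² = rho^(2|i-j|) within a block and 0 across
    blocks."""
    n, b, m = params.n_individuals, params.n_blocks, params.snps_per_block
    rho = params.ld_rho
    chol = _ar1_chol(m, rho) if m > 1 else np.ones((1, 1))
    dosages = np.empty((n, b * m), dtype=np.int8)
    ids, chroms, poss, mafs, blocks = [], [], [], [], []
    positions: dict[str, tuple[str, int]] = {}
    pairs: dict[frozenset, float] = {}
    for blk in range(b):
        maf = rng.uniform(*params.maf_range, size=m)
        thresh = stats.norm.ppf(maf)
        hap1 = (rng.standard_normal((n, m)) @ chol.T) < thresh
        hap2 = (rng.standard_normal((n, m)) @ chol.T) < thresh
        dosages[:, blk * m:(blk + 1) * m] = hap1.astype(np.int8) + hap2
        for j in range(m):
            vid = f"rs{blk}_{j}"
            pos = 1 + blk * _BLOCK_SPACING_BP + j * _SNP_SPACING_BP
            ids.append(vid)
            chroms.append("1")
            poss.append(pos)
            mafs.append(maf[j])
            blocks.append(blk)
            positions[vid] = ("1", pos)
        for i in range(m):
            for j in range(i + 1, m):
                r2 = rho ** (2 * (j - i))
                if r2 >= 1e-6:
                    pairs[frozenset((f"rs{blk}_{i}", f"rs{blk}_{j}"))] = r2
    ld = LDReference(positions, pairs, window_bp=_BLOCK_SPACING_BP - 1)
    return GenotypeData(
        dosages=dosages, variant_ids=ids, chrom=chroms,
        pos=np.array(poss), mafs=np.array(mafs),
        block_index=np.array(blocks), ld=ld,
    )


def _assign_pathways(params: SimulationParams, n_blocks: int,
                     rng: np.random.Generator) -> list[str]:
    labels = rng.choice(
        ["P1", "P2", "P0"], size=n_blocks,
        p=[params.prop_p1, params.prop_p2, 1 - params.prop_p1 - params.prop_p2],
    )
    return list(labels)


def simulate_phenotypes(
    geno: GenotypeData,
    params: SimulationParams,
    rng: np.random.Generator,
    pathway_labels: list[str] | None = None,
    betas: np.ndarray | None = None,
):
    """Exposure, continuous outcome and binary outcome for one cohort.

    One causal SNP per block (the central SNP) carries the exposure
    effect; its block's pathway label decides which direct effect
    (theta1/theta2/theta0) it transmits to the outcome.  Returns
    (exposure, y_cont, y_bin, truth_dict); pass ``pathway_labels`` and
    ``betas`` to reuse an existing architecture on a new cohort.
    """
    b, m = params.n_blocks, params.snps_per_block
    causal_offset = m // 2
    causal_cols = np.array([blk * m + causal_offset for blk in range(b)])
    causal_ids = [geno.variant_ids[c] for c in causal_cols]
    if pathway_labels is None:
        pathway_labels = _assign_pathways(params, b, rng)
    if betas is None:
        betas = rng.normal(0.0, params.beta_sd, size=b)

    G = geno.dosages[:, causal_cols].astype(float)
    components = {"P1": np.zeros(len(G)), "P2": np.zeros(len(G)),
                  "P0": np.zeros(len(G))}
    for k, (lbl, beta) in enumerate(zip(pathway_labels, betas)):
        components[lbl] += beta * G[:, k]
    exposure = (components["P1"] + components["P2"] + components["P0"]
                + rng.normal(0, params.exposure_noise_sd, size=len(G)))
    linpred = (params.theta1 * components["P1"]
               + params.theta2 * components["P2"]
               + params.theta0 * components["P0"])
    y_cont = linpred + rng.normal(0, params.outcome_noise_sd, size=len(G))

    def _mean_prev(a: float) -> float:
        return float(np.mean(1 / (1 + np.exp(-(a + linpred))))) - params.prevalence

    intercept = optimize.brentq(_mean_prev, -30, 30)
    y_bin = rng.binomial(1, 1 / (1 + np.exp(-(intercept + linpred)))).astype(float)

    truth = {
        "pathway": dict(zip(causal_ids, pathway_labels)),
        "betas": dict(zip(causal_ids, betas)),
        "causal_ids": causal_ids,
        "causal_cols": causal_cols,
        "labels": list(pathway_labels),
        "beta_array": np.asarray(betas, dtype=float),
    }
    return exposure, y_cont, y_bin, truth


def per_snp_summary_stats(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    geno: GenotypeData,
    n: int | None = None,
) -> list[VariantRecord]:
    """Exact per-SNP simple-OLS summary statistics (vectorized)."""
    g = dosages.astype(float)
    y = np.asarray(phenotype, dtype=float)
    nn = n if n is not None else len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    sxx[sxx == 0] = np.nan
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(np.sum(yc**2))
    resid = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(resid / (nn - 2) / sxx)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = np.clip(2 * stats.t.sf(np.abs(tstat), nn - 2), _PVAL_FLOOR, 1.0)
    eaf = g.mean(axis=0) / 2.0
    records = []
    for j, vid in enumerate(geno.variant_ids):
        if not np.isfinite(beta[j]) or not se[j] > 0:
            continue
        records.append(VariantRecord(
            variant_id=vid, chrom=geno.chrom[j], pos=int(geno.pos[j]),
            effect_allele="A", other_allele="G",
            eaf=float(np.clip(eaf[j], 1e-6, 1 - 1e-6)),
            beta=float(beta[j]), se=float(se[j]), pval=float(pval[j]), n=nn,
        ))
    return records


def simulate_eqtl_panels(
    params: SimulationParams,
    geno: GenotypeData,
    truth: dict,
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, list[VariantRecord]]], dict[str, set[str]]]:
    """Per-tissue eQTL summary panels with planted colocalization.

    P1 instruments colocalize in ``tissues[0]`` and P2 instruments in
    ``tissues[1]`` (the gene region shares the instrument as its causal
    eQTL variant); each instrument additionally gets a non-colocalizing
    region in the other tissue whose causal variant is the most distant
    block SNP (low LD with the instrument).  Expression is simulated in
    an independent sample of ``eqtl_n`` individuals.
    """
    m = params.snps_per_block
    tissue_a, tissue_b = params.tissues[0], params.tissues[1]
    panels: dict[str, dict[str, list[VariantRecord]]] = {t: {} for t in params.tissues}
    coloc_truth: dict[str, set[str]] = {t: set() for t in params.tissues}

    eq_params = replace(params, n_individuals=params.eqtl_n)
    eq_geno = simulate_genotypes(eq_params, rng)
    causal_cols = truth["causal_cols"]
    for k, vid in enumerate(truth["causal_ids"]):
        label = truth["pathway"][vid]
        if label == "P0":
            continue
        blk = int(causal_cols[k] // m)
        cols = np.arange(blk * m, (blk + 1) * m)
        block_dosages = eq_geno.dosages[:, cols]
        causal_in_block = int(causal_cols[k] - blk * m)
        coloc_tissue = tissue_a if label == "P1" else tissue_b
        other_tissue = tissue_b if label == "P1" else tissue_a

        # colocalizing region: causal eQTL variant is the instrument itself
        expr = (params.eqtl_effect * block_dosages[:, causal_in_block]
                + rng.normal(0, params.eqtl_noise_sd, size=params.eqtl_n))
        sub = _block_records(block_dosages, expr, eq_geno, cols, params.eqtl_n)
        panels[coloc_tissue][f"GENE_{coloc_tissue}_{vid}"] = sub
        coloc_truth[coloc_tissue].add(vid)

        # non-colocalizing region: a different causal variant in low LD with
        # the instrument, or pure noise when the block offers none
        alt = 0 if causal_in_block >= m // 2 else m - 1
        alt_r2 = params.ld_rho ** (2 * abs(alt - causal_in_block))
        if alt_r2 <= 0.25:
            expr2 = (params.eqtl_effect * block_dosages[:, alt]
                     + rng.normal(0, params.eqtl_noise_sd, size=params.eqtl_n))
        else:
            expr2 = rng.normal(0, params.eqtl_noise_sd, size=params.eqtl_n)
        sub2 = _block_records(block_dosages, expr2, eq_geno, cols, params.eqtl_n)
        panels[other_tissue][f"GENE_{other_tissue}_{vid}"] = sub2
    return panels, coloc_truth


def _block_records(block_dosages, expr, eq_geno, cols, n) -> list[VariantRecord]:
    sub_geno = GenotypeData(
        dosages=block_dosages,
        variant_ids=[eq_geno.variant_ids[c] for c in cols],
        chrom=[eq_geno.chrom[c] for c in cols],
        pos=eq_geno.pos[cols],
        mafs=eq_geno.mafs[cols],
        block_index=eq_geno.block_index[cols],
        ld=eq_geno.ld,
    )
    return per_snp_summary_stats(block_dosages, expr, sub_geno, n=n)


#: ontology terms used by the synthetic annotation generator
TERM_P1 = "TERM:pathway1"
TERM_P2 = "TERM:pathway2"
TERM_BG = "TERM:background"


def default_category_config() -> CategoryConfig:
    return CategoryConfig({"cat1": {TERM_P1}, "cat2": {TERM_P2}})


def simulate_gene_annotations(
    params: SimulationParams,
    geno: GenotypeData,
    truth: dict,
    rng: np.random.Generator,
    gene_halfwidth: int = 200,
) -> tuple[list[GeneAnnotation], CategoryConfig]:
    """Category-labelled genes at instrument positions plus uniform
    background genes.

    A P_k instrument receives a category-k gene centred on it with
    probability ``gene_specificity``; with the complementary probability
    it receives the *other* category's gene (misassignment).  Background
    genes are placed uniformly and carry a category term with
    probability ``background_term_rate``.
    """
    genes: list[GeneAnnotation] = []
    causal_cols = truth["causal_cols"]
    for k, vid in enumerate(truth["causal_ids"]):
        label = truth["pathway"][vid]
        if label == "P0":
            continue
        pos = int(geno.pos[causal_cols[k]])
        term = TERM_P1 if label == "P1" else TERM_P2
        if rng.random() >= params.gene_specificity:
            term = TERM_P2 if term == TERM_P1 else TERM_P1
        genes.append(GeneAnnotation(
            gene_id=f"G_{vid}", chrom="1",
            start=max(1, pos - gene_halfwidth), end=pos + gene_halfwidth,
            term_ids=frozenset({term}),
        ))
    genome_end = int(geno.pos.max()) + _BLOCK_SPACING_BP
    for i in range(params.n_background_genes):
        start = int(rng.integers(1, genome_end))
        terms: set[str] = {TERM_BG}
        if rng.random() < params.background_term_rate:
            terms.add(TERM_P1 if rng.random() < 0.5 else TERM_P2)
        genes.append(GeneAnnotation(
            gene_id=f"BG_{i}", chrom="1",
            start=start, end=start + 2 * gene_halfwidth,
            term_ids=frozenset(terms),
        ))
    return genes, default_category_config()


def _covariate_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {
        "age": rng.normal(55, 8, size=n),
        "sex": rng.binomial(1, 0.5, size=n).astype(float),
        "chip": rng.binomial(1, 0.3, size=n).astype(float),
    }
    for k in range(1, 11):
        cols[f"PC{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cols)


def simulate_study(params: SimulationParams) -> SimulatedStudy:
    """Generate a complete synthetic study.

    Two independent cohorts are generated: cohort A provides the
    exposure summary statistics and the individual-level data for
    one-sample MR; cohort B provides outcome summary statistics, so
    two-sample analyses are free of sample overlap.
    """
    rng = np.random.default_rng(params.seed)
    geno_a = simulate_genotypes(params, rng)
    exposure, y_cont_a, y_bin_a, truth = simulate_phenotypes(geno_a, params, rng)

    geno_b = simulate_genotypes(params, rng)
    _, y_cont_b, y_bin_b, _ = simulate_phenotypes(
        geno_b, params, rng,
        pathway_labels=truth["labels"], betas=truth["beta_array"],
    )

    exposure_stats = per_snp_summary_stats(geno_a.dosages, exposure, geno_a)
    outcome_stats = per_snp_summary_stats(geno_b.dosages, y_cont_b, geno_b)
    outcome_stats_bin = per_snp_summary_stats(geno_b.dosages, y_bin_b, geno_b)

    eqtl_panels, coloc_truth = simulate_eqtl_panels(params, geno_a, truth, rng)
    genes, config = simulate_gene_annotations(params, geno_a, truth, rng)

    cohort = CohortData(
        dosages=pd.DataFrame(geno_a.dosages, columns=geno_a.variant_ids),
        covariates=_covariate_table(params.n_individuals, rng),
        phenotypes=pd.DataFrame({
            "exposure": exposure,
            "outcome_cont": y_cont_a,
            "outcome_bin": y_bin_a,
        }),
    )
    ground = GroundTruth(
        pathway=truth["pathway"],
        betas=truth["betas"],
        thetas=(params.theta1, params.theta2, params.theta0),
        coloc=coloc_truth,
        sd_exposure=float(np.std(exposure)),
        causal_ids=truth["causal_ids"],
    )
    return SimulatedStudy(
        params=params, cohort=cohort, genotypes=geno_a,
        exposure_stats=exposure_stats, outcome_stats=outcome_stats,
        outcome_stats_binary=outcome_stats_bin,
        genes=genes, category_config=config,
        eqtl_panels=eqtl_panels, truth=ground,
    )


def genome_length_map(geno: GenotypeData) -> dict[str, int]:
    """Chromosome lengths implied by the simulated variant positions."""
    out: dict[str, int] = {}
    for chrom, pos in zip(geno.chrom, geno.pos):
        out[chrom] = max(out.get(chrom, 0), int(pos) + _BLOCK_SPACING_BP)
    return out
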
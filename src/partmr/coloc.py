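"""Tissue partitioning via approximate-Bayes-factor colocalization.

Per-SNP Wakefield log-ABFs for each trait are combined into posterior
probabilities for the five sharing hypotheses (H0: no association, H1/H2:
one trait only, H3: two distinct causal variants, H4: one shared causal
variant).  All hypothesis arithmetic is done in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datatypes import (
    ConfigurationError,
    DataError,
    PreconditionError,
    VariantRecord,
)
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

#: default hypothesis priors: per-SNP association for each trait, shared
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass(frozen=True)
class ColocResult:
    lead: str | None
    tissue: str | None
    gene: str | None
    pp: tuple[float, float, float, float, float]
    n_snps_region: int
    labf1: np.ndarray | None = field(default=None, compare=False)
    labf2: np.ndarray | None = field(default=None, compare=False)

    @property
    def pp_h4(self) -> float:
        return self.pp[4]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HYPOTHESES, self.pp))


@dataclass
class TissueAssignment:
    """Per-variant max PP_H4 by tissue group and threshold membership."""

    pp4: dict[str, dict[str, float]]  # variant_id -> {group -> max PP_H4}
    threshold: float
    best: dict[str, dict[str, ColocResult]] = field(default_factory=dict)

    def members(self, group: str) -> set[str]:
        # strict >: ties at the threshold resolve to non-membership
        return {v for v, per in self.pp4.items()
                if per.get(group, 0.0) > self.threshold}

    def groups(self) -> set[str]:
        return {g for per in self.pp4.values() for g in per}


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one association statistic.

    ``log[ sqrt(se^2/(se^2+prior_sd^2)) * exp(z^2 * prior_sd^2 /
    (2*(se^2+prior_sd^2))) ]`` with ``z = beta/se``.
    """
    if not (math.isfinite(beta) and math.isfinite(se) and math.isfinite(prior_sd)):
        raise DataError("wakefield_labf: non-finite input")
    if se <= 0 or prior_sd <= 0:
        raise PreconditionError("wakefield_labf: se and prior_sd must be > 0")
    z = beta / se
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * math.log(1 - r) + 0.5 * z**2 * r


def _labf_vector(records: list[VariantRecord], prior_sd: float) -> np.ndarray:
    return np.array([wakefield_labf(r.beta, r.se, prior_sd) for r in records])


def _logdiff(lx: float, ly: float) -> float:
    """log(exp(lx) - exp(ly)) for lx > ly, guarded."""
    if ly >= lx:
        return -np.inf
    return lx + math.log1p(-math.exp(ly - lx))


def coloc_abf(
    region1: list[VariantRecord],
    region2: list[VariantRecord],
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    lead: str | None = None,
    tissue: str | None = None,
    gene: str | None = None,
    keep_labf: bool = False,
) -> ColocResult:
    """ABF colocalization of two regional association signals.

    Only variants present in both regions are used; the posterior over
    H0..H4 is computed in log space with log-sum-exp.
    """
    p1, p2, p12 = priors
    ids1 = {r.variant_id: r for r in region1}
    ids2 = {r.variant_id: r for r in region2}
    shared = sorted(set(ids1) & set(ids2))
    if not shared:
        raise DataError("coloc_abf: regions share no variant ids")

    l1 = _labf_vector([ids1[v] for v in shared], prior_sd1)
    l2 = _labf_vector([ids2[v] for v in shared], prior_sd2)

    s1 = logsumexp(l1)               # log sum BF1
    s2 = logsumexp(l2)               # log sum BF2
    s12 = logsumexp(l1 + l2)         # log sum BF1*BF2 (H4)
    # H3: sum_{i != j} BF1_i * BF2_j = S1*S2 - S12
    s3 = _logdiff(s1 + s2, s12)

    lh = np.array([
        0.0,
        math.log(p1) + s1,
        math.log(p2) + s2,
        math.log(p1) + math.log(p2) + s3,
        math.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    assert abs(pp.sum() - 1.0) < 1e-9
    return ColocResult(
        lead=lead, tissue=tissue, gene=gene,
        pp=tuple(float(x) for x in pp),
        n_snps_region=len(shared),
        labf1=l1 if keep_labf else None,
        labf2=l2 if keep_labf else None,
    )


def assign_tissues(
    instruments: InstrumentSet,
    eqtl_panels: dict[str, dict[str, list[VariantRecord]]],
    exposure_stats: list[VariantRecord],
    window_bp: int = 100_000,
    pp4_thresh: float = 0.9,
    tissue_groups: dict[str, set[str]] | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
) -> TissueAssignment:
    """Colocalize each instrument's +/- ``window_bp`` region with every
    overlapping eQTL gene region in every tissue.

    An instrument joins a tissue group when its maximum PP_H4 over the
    group's tissues and genes strictly exceeds ``pp4_thresh``.  Tissue
    groups may be unions of sub-tissues (e.g. artery = aorta + coronary);
    the default maps each tissue to itself.  ``exposure_stats`` must
    contain the regional (not just instrument) exposure summary stats.
    """
    for tissue, genes in eqtl_panels.items():
        if not genes:
            raise ConfigurationError(f"assign_tissues: empty eQTL panel {tissue!r}")
    if tissue_groups is None:
        tissue_groups = {t: {t} for t in eqtl_panels}

    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in exposure_stats:
        by_chrom.setdefault(r.chrom, []).append(r)

    pp4_by_tissue: dict[str, dict[str, float]] = {}
    best_by_tissue: dict[str, dict[str, ColocResult]] = {}
    for inst in instruments:
        lo, hi = inst.pos - window_bp, inst.pos + window_bp
        region1 = [r for r in by_chrom.get(inst.chrom, [])
                   if lo <= r.pos <= hi]
        per_tissue: dict[str, float] = {}
        per_best: dict[str, ColocResult] = {}
        for tissue, genes in eqtl_panels.items():
            for gene, region2 in genes.items():
                if not region2:
                    continue
                positions = [r.pos for r in region2
                             if r.chrom == inst.chrom]
                if not positions or min(positions) > hi or max(positions) < lo:
                    continue
                try:
                    res = coloc_abf(
                        region1, region2, priors=priors,
                        prior_sd1=prior_sd1, prior_sd2=prior_sd2,
                        lead=inst.variant_id, tissue=tissue, gene=gene,
                    )
                except DataError:
                    continue
                if res.pp_h4 > per_tissue.get(tissue, -1.0):
                    per_tissue[tissue] = res.pp_h4
                    per_best[tissue] = res
        pp4_by_tissue[inst.variant_id] = per_tissue
        best_by_tissue[inst.variant_id] = per_best

    # aggregate sub-tissues into groups by maximum PP_H4
    pp4: dict[str, dict[str, float]] = {}
    best: dict[str, dict[str, ColocResult]] = {}
    for vid, per_tissue in pp4_by_tissue.items():
        per_group: dict[str, float] = {}
        group_best: dict[str, ColocResult] = {}
        for group, members in tissue_groups.items():
            vals = {t: per_tissue[t] for t in members if t in per_tissue}
            if vals:
                top = max(vals, key=vals.get)
                per_group[group] = vals[top]
                group_best[group] = best_by_tissue[vid][top]
        pp4[vid] = per_group
        best[vid] = group_best
    return TissueAssignment(pp4=pp4, threshold=pp4_thresh, best=best)
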
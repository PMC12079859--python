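"""Pathway partitioning: LD intervals around lead variants, gene
overlap, interval-relocation term enrichment, and category assignment.

The enrichment null relocates each interval uniformly (length
preserved, chromosome chosen proportional to length) and recounts term
hits; the empirical p is (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CategoryConfig,
    GeneAnnotation,
    LDReference,
    PreconditionError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDInterval:
    """Genomic interval spanned by variants in LD with a lead variant."""

    lead: str
    chrom: str
    start: int
    end: int
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval for {self.lead}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    observed_count: int
    expected_count: float
    p: float
    n_permutations: int


@dataclass
class CategoryAssignment:
    """Per-variant category membership plus per-pair 'specific' flags."""

    categories: dict[str, set[str]]  # variant_id -> category names
    config_names: list[str]

    def members(self, category: str) -> set[str]:
        return {v for v, cats in self.categories.items() if category in cats}

    def specific_members(self, category: str) -> set[str]:
        """Variants assigned to this category and no other."""
        return {v for v, cats in self.categories.items()
                if cats == {category}}

    def is_specific(self, variant_id: str, category: str) -> bool:
        return self.categories.get(variant_id) == {category}

    def overlap_fraction(self, cat_a: str, cat_b: str) -> float:
        a, b = self.members(cat_a), self.members(cat_b)
        union = a | b
        return len(a & b) / len(union) if union else 0.0


def build_ld_interval(
    lead: str,
    ld: LDReference,
    min_r2: float = 0.8,
    window_bp: int = 1_000_000,
) -> LDInterval:
    """Interval delimited by the most distant variants with
    r² >= ``min_r2`` to the lead within ``window_bp`` either side.

    Degenerates to the lead position alone when no partner qualifies.
    """
    chrom, pos = ld.position(lead)  # raises KeyError for unknown variant
    members = {lead}
    lo = hi = pos
    for other in ld.partners(lead, min_r2):
        ochrom, opos = ld.position(other)
        if ochrom != chrom or abs(opos - pos) > window_bp:
            continue
        members.add(other)
        lo = min(lo, opos)
        hi = max(hi, opos)
    return LDInterval(lead=lead, chrom=chrom, start=lo, end=hi,
                      members=frozenset(members))


def overlap_genes(
    interval: LDInterval,
    genes: list[GeneAnnotation],
    flank_bp: int = 1000,
) -> set[str]:
    """Gene ids whose flank-extended span intersects the interval
    (closed-interval intersection)."""
    hits = set()
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        if g.start - flank_bp <= interval.end and g.end + flank_bp >= interval.start:
            hits.add(g.gene_id)
    return hits


def _gene_arrays(genes: list[GeneAnnotation], flank_bp: int):
    """Per-chromosome flank-extended gene bounds and a gene x term mask."""
    terms = sorted({t for g in genes for t in g.term_ids})
    term_index = {t: i for i, t in enumerate(terms)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = [g for g in genes if g.chrom == chrom]
        starts = np.array([g.start - flank_bp for g in sub], dtype=np.int64)
        ends = np.array([g.end + flank_bp for g in sub], dtype=np.int64)
        mask = np.zeros((len(sub), len(terms)), dtype=bool)
        for i, g in enumerate(sub):
            for t in g.term_ids:
                mask[i, term_index[t]] = True
        by_chrom[chrom] = (starts, ends, mask)
    return terms, by_chrom


def _terms_hit(chrom, start, end, by_chrom, n_terms) -> np.ndarray:
    entry = by_chrom.get(chrom)
    if entry is None:
        return np.zeros(n_terms, dtype=bool)
    starts, ends, mask = entry
    overlap = (starts <= end) & (ends >= start)
    if not overlap.any():
        return np.zeros(n_terms, dtype=bool)
    return mask[overlap].any(axis=0)


def enrich_terms(
    intervals: list[LDInterval],
    genes: list[GeneAnnotation],
    genome_length_map: dict[str, int],
    n_perm: int = 10_000,
    seed: int | None = None,
    flank_bp: int = 1000,
) -> list[EnrichmentResult]:
    """Interval-relocation enrichment of ontology terms.

    Observed count for a term = number of intervals overlapping at least
    one gene carrying it.  The null relocates every interval
    (length-preserving, chromosome chosen proportional to its length,
    uniform placement) and recounts, ``n_perm`` times.
    """
    if not intervals:
        raise PreconditionError("enrich_terms: need at least one interval")
    missing = {iv.chrom for iv in intervals} - set(genome_length_map)
    if missing:
        raise PreconditionError(f"enrich_terms: genome lengths missing for {missing}")
    if n_perm < 100:
        logger.warning("enrich_terms: n_perm=%d < 100 gives unstable p", n_perm)

    terms, by_chrom = _gene_arrays(genes, flank_bp)
    n_terms = len(terms)
    if n_terms == 0:
        return []

    observed = np.zeros(n_terms, dtype=np.int64)
    for iv in intervals:
        observed += _terms_hit(iv.chrom, iv.start, iv.end, by_chrom, n_terms)

    rng = np.random.default_rng(seed)
    chroms = list(genome_length_map)
    lengths = np.array([genome_length_map[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    null_ge = np.zeros(n_terms, dtype=np.int64)
    null_sum = np.zeros(n_terms, dtype=float)
    for _ in range(n_perm):
        count = np.zeros(n_terms, dtype=np.int64)
        for iv in intervals:
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            clen = int(lengths[ci])
            span = min(iv.length, clen)
            start = int(rng.integers(1, clen - span + 2))
            count += _terms_hit(chrom, start, start + span - 1, by_chrom, n_terms)
        null_ge += count >= observed
        null_sum += count

    results = []
    for i, term in enumerate(terms):
        results.append(
            EnrichmentResult(
                term_id=term,
                observed_count=int(observed[i]),
                expected_count=float(null_sum[i] / n_perm),
                p=float((1 + null_ge[i]) / (n_perm + 1)),
                n_permutations=n_perm,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def assign_categories(
    intervals: list[LDInterval],
    genes: list[GeneAnnotation],
    config: CategoryConfig,
    enrichment: list[EnrichmentResult],
    enrich_p_max: float = 0.05,
    flank_bp: int = 1000,
) -> CategoryAssignment:
    """Assign each lead variant to categories whose enriched terms its
    interval's genes carry.

    A variant joins category C iff its interval overlaps >=1 gene
    carrying >=1 term of C AND at least one of C's terms passes the
    enrichment gate.  Variants may join multiple categories.
    """
    enriched_p = {r.term_id: r.p for r in enrichment}
    gene_terms = {g.gene_id: g.term_ids for g in genes}

    cat_active: dict[str, bool] = {}
    for name, cat_terms in config.items():
        active = any(enriched_p.get(t, 1.0) <= enrich_p_max for t in cat_terms)
        if not active:
            logger.warning("assign_categories: category %r has no enriched term; "
                           "emitted empty", name)
        cat_active[name] = active

    assignment: dict[str, set[str]] = {}
    for iv in intervals:
        hit_terms: set[str] = set()
        for gid in overlap_genes(iv, genes, flank_bp=flank_bp):
            hit_terms |= gene_terms.get(gid, frozenset())
        cats = {
            name for name, cat_terms in config.items()
            if cat_active[name] and (cat_terms & hit_terms)
        }
        assignment[iv.lead] = cats
    return CategoryAssignment(categories=assignment, config_names=config.names)
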
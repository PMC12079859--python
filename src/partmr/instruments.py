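"""Instrument selection: greedy LD clumping, proxy lookup and
exposure/outcome allele harmonization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datatypes import (
    DataError,
    LDReference,
    PreconditionError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(allele)) \
        if len(allele) > 1 else _COMPLEMENT.get(allele, "N")


@dataclass
class InstrumentSet:
    """Independent genome-wide-significant instruments (exposure scale)."""

    records: list[VariantRecord]
    p_threshold: float
    clump_r2: float
    clump_window_bp: int

    def __post_init__(self) -> None:
        self.audit = None  # set by audit_independence

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def audit_independence(self, ld: LDReference) -> None:
        """Assert the set's own invariant: all pairwise r² < clump r²."""
        ids = self.variant_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r2 = ld.r2(ids[i], ids[j])
                if r2 >= self.clump_r2:
                    raise AssertionError(
                        f"instrument pair ({ids[i]}, {ids[j]}) has r2={r2} "
                        f">= clump threshold {self.clump_r2}"
                    )
        self.audit = "passed"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome statistics aligned to one effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    beta_out: float
    se_out: float
    eaf_out: float | None
    flipped: bool = False
    proxy_of: str | None = None


def clump(
    records: list[VariantRecord],
    ld: LDReference,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_bp: int = 10_000_000,
) -> InstrumentSet:
    """Greedy p-value-ordered LD clumping.

    Significant variants are sorted ascending by p (ties broken by
    chromosome, position, then id); the top variant is kept and every
    other variant with r² >= ``r2_thresh`` within ``window_bp`` of it is
    removed, repeatedly.  Output is sorted by chromosome and position.
    """
    if not records:
        raise PreconditionError("clump: records must be non-empty")
    sig = [r for r in records if r.pval < p_thresh]
    if not sig:
        logger.warning("clump: no variant below p threshold %.3g", p_thresh)
    missing = [r.variant_id for r in sig if r.variant_id not in ld]
    if missing:
        raise PreconditionError(
            f"clump: LD reference lacks {len(missing)} significant variant(s), "
            f"e.g. {missing[:3]}"
        )
    pending = sorted(sig, key=lambda r: (r.pval, r.chrom, r.pos, r.variant_id))
    kept: list[VariantRecord] = []
    while pending:
        top = pending.pop(0)
        kept.append(top)
        survivors = []
        for r in pending:
            if r.chrom == top.chrom and abs(r.pos - top.pos) <= window_bp \
                    and ld.r2(top.variant_id, r.variant_id) >= r2_thresh:
                continue
            survivors.append(r)
        pending = survivors
    kept.sort(key=lambda r: (r.chrom, r.pos, r.variant_id))
    out = InstrumentSet(
        records=kept, p_threshold=p_thresh,
        clump_r2=r2_thresh, clump_window_bp=window_bp,
    )
    out.audit_independence(ld)
    return out


def find_proxy(
    target: str,
    outcome_ids: set[str],
    ld: LDReference,
    min_r2: float = 0.8,
) -> str | None:
    """Best outcome-present proxy for a missing target variant.

    Returns the variant with maximal r² to ``target`` when that r²
    exceeds ``min_r2``; ties broken by smaller chromosomal distance,
    then lexicographic id.  ``None`` when no candidate qualifies.
    """
    if target in outcome_ids:
        raise PreconditionError(f"find_proxy: target {target!r} present in outcome")
    _, tpos = ld.position(target)
    best: tuple[float, int, str] | None = None
    for cand in outcome_ids:
        if cand not in ld:
            continue
        r2 = ld.r2(target, cand)
        if r2 <= min_r2:
            continue
        _, cpos = ld.position(cand)
        key = (-r2, abs(cpos - tpos), cand)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def _orient(exp: VariantRecord, out: VariantRecord,
            palindrome_eaf_window: float) -> tuple[bool, str] | None:
    """Decide whether the outcome record must be flipped.

    Returns (flipped, reason) or None when the pair must be dropped.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    if exp.is_palindromic():
        if {o_ea, o_oa} != {ea, oa}:
            return None
        if exp.eaf is None or out.eaf is None:
            return None
        lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None  # ambiguous frequency
        # strand is unknowable; align by which side of 0.5 each eaf falls
        exp_minor = exp.eaf < 0.5
        out_minor = out.eaf < 0.5
        return (exp_minor != out_minor, "palindromic-eaf")
    if (o_ea, o_oa) == (ea, oa):
        return (False, "match")
    if (o_ea, o_oa) == (oa, ea):
        return (True, "swap")
    cea, coa = _complement(ea), _complement(oa)
    if (o_ea, o_oa) == (cea, coa):
        return (False, "strand-flip")
    if (o_ea, o_oa) == (coa, cea):
        return (True, "strand-flip-swap")
    return None


def harmonize(
    exposure: InstrumentSet | list[VariantRecord],
    outcome: list[VariantRecord],
    palindrome_eaf_window: float = 0.08,
    ld: LDReference | None = None,
    proxy_min_r2: float = 0.8,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles negate the outcome beta and complement its eaf;
    strand flips are detected via complement alleles; palindromic SNPs
    are resolved by EAF when informative and dropped otherwise.  When an
    exposure variant is missing from the outcome and an LD reference is
    supplied, a proxy with r² > ``proxy_min_r2`` substitutes the
    outcome-side statistics (logged per proxy).
    """
    exp_records = list(exposure.records if isinstance(exposure, InstrumentSet)
                       else exposure)
    _check_unique([r.variant_id for r in exp_records], "exposure")
    _check_unique([r.variant_id for r in outcome], "outcome")
    out_by_id = {r.variant_id: r for r in outcome}
    out_ids = set(out_by_id)

    pairs: list[HarmonizedPair] = []
    n_dropped = 0
    for exp in exp_records:
        proxy_of = None
        out = out_by_id.get(exp.variant_id)
        if out is None and ld is not None and exp.variant_id in ld:
            proxy_id = find_proxy(exp.variant_id, out_ids, ld, min_r2=proxy_min_r2)
            if proxy_id is not None:
                out = out_by_id[proxy_id]
                proxy_of = exp.variant_id
                logger.info(
                    "harmonize: proxy %s (r2=%.3f) substitutes %s",
                    proxy_id, ld.r2(exp.variant_id, proxy_id), exp.variant_id,
                )
        if out is None:
            n_dropped += 1
            continue
        if proxy_of is None:
            decision = _orient(exp, out, palindrome_eaf_window)
        else:
            decision = _orient_proxy(exp, out, palindrome_eaf_window)
        if decision is None:
            n_dropped += 1
            continue
        flipped, _ = decision
        beta_out = -out.beta if flipped else out.beta
        eaf_out = None if out.eaf is None else (1 - out.eaf if flipped else out.eaf)
        pairs.append(
            HarmonizedPair(
                variant_id=exp.variant_id,
                beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
                beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
                flipped=flipped, proxy_of=proxy_of,
            )
        )
    if n_dropped:
        logger.warning("harmonize: dropped %d unresolvable pair(s)", n_dropped)
    return pairs


def _orient_proxy(exp: VariantRecord, out: VariantRecord,
                  palindrome_eaf_window: float) -> tuple[bool, str] | None:
    """Align a proxy to its target by EAF matching (alleles differ)."""
    if exp.eaf is None or out.eaf is None:
        return None
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
    if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
        return None
    return ((exp.eaf < 0.5) != (out.eaf < 0.5), "proxy-eaf")


def _check_unique(ids: list[str], label: str) -> None:
    if len(ids) != len(set(ids)):
        seen, dupes = set(), set()
        for i in ids:
            if i in seen:
                dupes.add(i)
            seen.add(i)
        raise DataError(f"duplicate variant ids in {label}: {sorted(dupes)[:5]}")
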
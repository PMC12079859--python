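"""Shared domain types flowing through every pipeline stage.

All genomic coordinates are 1-based closed intervals; BED input is
converted on read.  Variant effect sizes are per effect allele on the
scale of the originating GWAS (exposure SD or log-odds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "LDReference",
    "GeneAnnotation",
    "CategoryConfig",
    "CohortData",
    "PartmrError",
    "ConfigurationError",
    "DataError",
    "PreconditionError",
]

_VALID_BASES = frozenset("ACGT")


class PartmrError(Exception):
    """Base class for toolkit errors."""


class ConfigurationError(PartmrError):
    """Bad configuration (missing column, empty panel, ...)."""


class DataError(PartmrError):
    """Malformed or inconsistent input data."""


class PreconditionError(PartmrError):
    """An operation precondition was violated."""


@dataclass(frozen=True)
class VariantRecord:
    """One harmonizable GWAS summary-statistic row.

    Parameters
    ----------
    variant_id : str
        Unique variant identifier (e.g. rs id).
    chrom : str
        Chromosome name.
    pos : int
        1-based position.
    effect_allele, other_allele : str
        Upper-case alleles; indels are explicit strings.
    eaf : float or None
        Effect-allele frequency in (0, 1).  ``None`` is permitted on
        read but operations requiring EAF raise :class:`PreconditionError`.
    beta, se : float
        Per-allele effect and its standard error (``se > 0``).
    pval : float
        Two-sided p-value in (0, 1].
    n : int
        Sample size.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.variant_id:
            problems.append("empty variant_id")
        if self.pos < 1:
            problems.append("pos must be >= 1")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele == other_allele")
        for allele in (self.effect_allele, self.other_allele):
            if not allele or (len(allele) == 1 and allele not in _VALID_BASES):
                problems.append(f"invalid allele {allele!r}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            problems.append("eaf outside (0,1)")
        if not (self.se > 0 and math.isfinite(self.se)):
            problems.append("se must be positive and finite")
        if not math.isfinite(self.beta):
            problems.append("beta not finite")
        if not (0.0 < self.pval <= 1.0):
            problems.append("pval outside (0,1]")
        if self.n <= 0:
            problems.append("n must be positive")
        return problems

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with attached ontology-term labels.

    ``start``/``end`` are 1-based closed; ``term_ids`` may be empty.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    term_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class CategoryConfig:
    """Mapping of category name -> non-empty set of ontology term ids."""

    def __init__(self, categories: dict[str, set[str]]):
        for name, terms in categories.items():
            if not terms:
                raise ConfigurationError(f"category {name!r} has an empty term set")
        self._categories = {k: frozenset(v) for k, v in categories.items()}

    @property
    def names(self) -> list[str]:
        return list(self._categories)

    def terms(self, name: str) -> frozenset[str]:
        return self._categories[name]

    def items(self):
        return self._categories.items()

    def __contains__(self, name: str) -> bool:
        return name in self._categories

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CategoryConfig)
            and self._categories == other._categories
        )

    def __repr__(self) -> str:
        return f"CategoryConfig({dict(self._categories)!r})"


class LDReference:
    """Window-limited sparse pairwise r² lookup.

    Stores positions for each variant and r² for pairs within
    ``window_bp`` on the same chromosome; absent pairs report 0 and the
    diagonal reports 1.
    """

    def __init__(
        self,
        positions: dict[str, tuple[str, int]],
        r2_pairs: dict[frozenset, float] | None = None,
        window_bp: int = 10_000_000,
    ):
        self._pos = dict(positions)
        self._r2: dict[frozenset, float] = {}
        self.window_bp = int(window_bp)
        if r2_pairs:
            for key, val in r2_pairs.items():
                a, b = tuple(key)
                self.set_r2(a, b, val)

    @classmethod
    def from_long_table(
        cls, df: pd.DataFrame, positions: dict[str, tuple[str, int]],
        window_bp: int = 10_000_000,
    ) -> "LDReference":
        ref = cls(positions, window_bp=window_bp)
        for id1, id2, r2 in df[["id1", "id2", "r2"]].itertuples(index=False):
            ref.set_r2(str(id1), str(id2), float(r2))
        return ref

    @classmethod
    def from_dense(
        cls, matrix: np.ndarray, ids: list[str],
        positions: dict[str, tuple[str, int]], window_bp: int = 10_000_000,
        min_store: float = 1e-6,
    ) -> "LDReference":
        ref = cls(positions, window_bp=window_bp)
        m = np.asarray(matrix, dtype=float)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if m[i, j] >= min_store:
                    ref.set_r2(ids[i], ids[j], m[i, j])
        return ref

    def set_r2(self, id1: str, id2: str, r2: float) -> None:
        if id1 == id2:
            return
        if not (0.0 <= r2 <= 1.0):
            raise DataError(f"r2 {r2} outside [0,1] for pair ({id1},{id2})")
        self._r2[frozenset((id1, id2))] = float(r2)

    def position(self, variant_id: str) -> tuple[str, int]:
        try:
            return self._pos[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in LD reference") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    @property
    def variant_ids(self) -> list[str]:
        return list(self._pos)

    def r2(self, id1: str, id2: str) -> float:
        """Pairwise r²; 1 on the diagonal, 0 beyond the window."""
        if id1 == id2:
            return 1.0
        c1, p1 = self.position(id1)
        c2, p2 = self.position(id2)
        if c1 != c2 or abs(p1 - p2) > self.window_bp:
            return 0.0
        return self._r2.get(frozenset((id1, id2)), 0.0)

    def partners(self, variant_id: str, min_r2: float) -> list[str]:
        """All variants with r²(variant, other) >= min_r2 (excluding self)."""
        out = []
        for key, val in self._r2.items():
            if variant_id in key and val >= min_r2:
                (other,) = key - {variant_id}
                out.append(other)
        return out

    def to_long_table(self) -> pd.DataFrame:
        rows = []
        for key, val in self._r2.items():
            a, b = sorted(key)
            rows.append((a, b, val))
        return pd.DataFrame(rows, columns=["id1", "id2", "r2"])


@dataclass
class CohortData:
    """Individual-level data for one-sample MR.

    ``dosages`` is individuals x variants with values in [0, 2];
    covariates and phenotypes are column tables over the same rows.
    """

    dosages: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.dosages)
        if len(self.covariates) != n or len(self.phenotypes) != n:
            raise DataError("cohort tables have inconsistent row counts")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise DataError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    def binary_phenotypes(self) -> list[str]:
        out = []
        for col in self.phenotypes:
            vals = self.phenotypes[col].dropna().unique()
            if set(np.asarray(vals).tolist()) <= {0, 1}:
                out.append(col)
        return out
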
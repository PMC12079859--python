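"""Readers and writers for the delimited-text formats the toolkit touches.

All downstream modules consume the domain types produced here; no stage
re-parses files.  Round-trips are lossless at full float precision.
"""

from __future__ import annotations

import logging
import math
from os import PathLike

import pandas as pd

from .datatypes import (
    ConfigurationError,
    DataError,
    GeneAnnotation,
    LDReference,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: default column names for GWAS summary statistics
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_REQUIRED_FIELDS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "n",
]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise DataError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | PathLike,
    column_map: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read GWAS summary statistics from a delimited text file.

    Rows violating :class:`VariantRecord` invariants are dropped with a
    logged count.  Missing EAF is permitted (``eaf=None``) but flagged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise DataError(f"{path}: no data rows")
    missing = [cmap[f] for f in _REQUIRED_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    has_eaf = cmap["eaf"] in df.columns

    records: list[VariantRecord] = []
    n_dropped = 0
    n_missing_eaf = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        eaf = None
        if has_eaf:
            raw = d[cmap["eaf"]]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                eaf = float(raw)
        if eaf is None:
            n_missing_eaf += 1
        try:
            rec = VariantRecord(
                variant_id=str(d[cmap["variant_id"]]),
                chrom=str(d[cmap["chrom"]]),
                pos=int(d[cmap["pos"]]),
                effect_allele=str(d[cmap["effect_allele"]]).upper(),
                other_allele=str(d[cmap["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(d[cmap["beta"]]),
                se=float(d[cmap["se"]]),
                pval=float(d[cmap["pval"]]),
                n=int(d[cmap["n"]]),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.validate():
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) failing invariants", path, n_dropped)
    if n_missing_eaf:
        logger.warning("%s: %d row(s) missing EAF", path, n_missing_eaf)
    return records


def write_summary_stats(
    records: list[VariantRecord],
    path: str | PathLike,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> None:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rows = [
        {
            cmap["variant_id"]: r.variant_id,
            cmap["chrom"]: r.chrom,
            cmap["pos"]: r.pos,
            cmap["effect_allele"]: r.effect_allele,
            cmap["other_allele"]: r.other_allele,
            cmap["eaf"]: r.eaf,
            cmap["beta"]: repr(r.beta),
            cmap["se"]: repr(r.se),
            cmap["pval"]: repr(r.pval),
            cmap["n"]: r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_gene_bed(
    path: str | PathLike,
    term_map_path: str | PathLike | None = None,
) -> list[GeneAnnotation]:
    """Read BED4 gene intervals plus an optional gene->term map.

    BED coordinates (0-based half-open) are converted to the internal
    1-based closed convention.  Genes absent from the term map get empty
    term sets.
    """
    term_map: dict[str, set[str]] = {}
    if term_map_path is not None:
        tm = pd.read_csv(term_map_path, sep=None, engine="python", header=None,
                         names=["gene_id", "term_id"], comment="#")
        for gene_id, term_id in tm.itertuples(index=False):
            term_map.setdefault(str(gene_id), set()).add(str(term_id))

    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise DataError(f"{path}:{lineno}: expected >=4 BED fields")
            chrom, start_s, end_s, gene_id = fields[:4]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: malformed coordinate {start_s!r}/{end_s!r}"
                ) from None
            if start0 < 0 or end0 <= start0:
                raise DataError(f"{path}:{lineno}: invalid BED interval")
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    term_ids=frozenset(term_map.get(gene_id, set())),
                )
            )
    return genes


def write_gene_bed(
    genes: list[GeneAnnotation],
    path: str | PathLike,
    term_map_path: str | PathLike | None = None,
) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    if term_map_path is not None:
        with open(term_map_path, "w") as fh:
            for g in genes:
                for term in sorted(g.term_ids):
                    fh.write(f"{g.gene_id}\t{term}\n")


def read_eqtl_panels(
    path: str | PathLike,
    column_map: dict[str, str] | None = None,
) -> dict[str, dict[str, list[VariantRecord]]]:
    """Read per-tissue cis-eQTL summary statistics.

    Same layout as GWAS summary stats plus ``tissue`` and ``gene_id``
    columns; returns {tissue: {gene: [records]}}.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("tissue", "gene_id"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing eQTL column {col!r}")
    panels: dict[str, dict[str, list[VariantRecord]]] = {}
    for (tissue, gene), sub in df.groupby(["tissue", "gene_id"], sort=True):
        records = []
        for row in sub.itertuples(index=False):
            d = dict(zip(sub.columns, row))
            eaf = d.get(cmap["eaf"])
            records.append(VariantRecord(
                variant_id=str(d[cmap["variant_id"]]),
                chrom=str(d[cmap["chrom"]]),
                pos=int(d[cmap["pos"]]),
                effect_allele=str(d[cmap["effect_allele"]]).upper(),
                other_allele=str(d[cmap["other_allele"]]).upper(),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                beta=float(d[cmap["beta"]]),
                se=float(d[cmap["se"]]),
                pval=float(d[cmap["pval"]]),
                n=int(d[cmap["n"]]),
            ))
        panels.setdefault(str(tissue), {})[str(gene)] = records
    return panels


def write_eqtl_panels(
    panels: dict[str, dict[str, list[VariantRecord]]],
    path: str | PathLike,
) -> None:
    cmap = DEFAULT_COLUMN_MAP
    rows = []
    for tissue in sorted(panels):
        for gene in sorted(panels[tissue]):
            for r in panels[tissue][gene]:
                rows.append({
                    "tissue": tissue, "gene_id": gene,
                    cmap["variant_id"]: r.variant_id, cmap["chrom"]: r.chrom,
                    cmap["pos"]: r.pos, cmap["effect_allele"]: r.effect_allele,
                    cmap["other_allele"]: r.other_allele, cmap["eaf"]: r.eaf,
                    cmap["beta"]: repr(r.beta), cmap["se"]: repr(r.se),
                    cmap["pval"]: repr(r.pval), cmap["n"]: r.n,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ld_reference(
    path: str | PathLike,
    positions: dict[str, tuple[str, int]],
    window_bp: int = 10_000_000,
) -> LDReference:
    """Read LD from three-column long format (id1, id2, r2)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("id1", "id2", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing LD column {col!r}")
    return LDReference.from_long_table(df, positions, window_bp=window_bp)


def write_ld_reference(ld: LDReference, path: str | PathLike) -> None:
    ld.to_long_table().to_csv(path, sep="\t", index=False)
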
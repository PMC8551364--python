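"""Readers and writers for every external table the pipeline touches.

Dialects: MetaPhlAn-style merged taxonomic profiles (first column of
pipe-delimited lineages, values in percent), HUMAnN-style pathway-abundance
tables (optionally stratified by contributing species), plain KO gene-family
tables, a two-column KEGG pathway→KO map, the clinical metadata TSV and an
IMG-style species isolation-metadata snapshot.  Result tables are written
through a small schema registry with deterministic row order and 6
significant digit reals so repeated writes are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metadata import CLINICAL_INDICES, Cohort, MetadataError, REQUIRED_COLUMNS
from .tables import AbundanceTable, parse_lineage


class TableFormatError(ValueError):
    """Raised when an input table violates its dialect."""


# ---------------------------------------------------------------------------
# taxonomic / functional profile readers
# ---------------------------------------------------------------------------

def read_taxonomic_profile(path: str | Path, wanted_rank: str) -> AbundanceTable:
    """Read a merged taxonomic profile and keep rows at one rank.

    The merged-profile dialect lists every rank of every clade on its own
    row; rows are selected by *deepest rank*, never aggregated, so the
    format's internal sum-consistency is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate lineage rows: {dup[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
            raise TableFormatError(
                f"non-numeric cell in column {col!r}, row(s) {bad_rows[:3]}"
            )
        df[col] = coerced
    keep = [fid for fid in df.index if parse_lineage(fid).deepest_rank == wanted_rank]
    return AbundanceTable(df.loc[keep].astype(float), wanted_rank)


_EXCLUDED_PATHWAY_ROWS = ("UNMAPPED", "UNINTEGRATED", "UnMapped", "UnIntegrated")


def read_pathway_table(path: str | Path, drop_stratified: bool = True,
                       level: str = "pathway") -> AbundanceTable:
    """Read a pathway-abundance table in the HUMAnN dialect.

    Community-level rows look like ``PWY-ID: description``; stratified rows
    carry a ``|species`` suffix and are dropped when ``drop_stratified``.
    UNMAPPED / UNINTEGRATED bookkeeping rows are always excluded.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    keep = ~df.index.str.split("|").str[0].str.split(":").str[0].str.strip().isin(
        _EXCLUDED_PATHWAY_ROWS)
    df = df.loc[keep]
    if drop_stratified:
        df = df.loc[~df.index.str.contains(r"\|", regex=True)]
    if df.index.has_duplicates:
        raise TableFormatError("duplicate pathway rows")
    if df.empty:
        raise TableFormatError(f"no usable rows left in {path}")
    return AbundanceTable(df.astype(float), level)


def read_gene_family_table(path: str | Path) -> AbundanceTable:
    """Read a plain KO / gene-family abundance table (id column + samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise TableFormatError("duplicate gene-family rows")
    return AbundanceTable(df.astype(float), "gene_family")


def read_kegg_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column pathway_id <tab> KO map into pathway → KO list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "ko"],
                     dtype=str, comment="#")
    if df.isna().any().any():
        raise TableFormatError("malformed KEGG map line (expected 2 columns)")
    out: dict[str, list[str]] = {}
    for pw, ko in df.itertuples(index=False):
        out.setdefault(pw, [])
        if ko not in out[pw]:
            out[pw].append(ko)
    return out


def write_kegg_map(kegg_map: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{pw}\t{ko}" for pw in sorted(kegg_map) for ko in kegg_map[pw]]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# clinical metadata
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> Cohort:
    """Read the clinical/sample metadata TSV into a validated cohort.

    Blank clinical cells become NaN (missing), never zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in REQUIRED_COLUMNS})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MetadataError(f"missing required column {col!r}")
    df = df.set_index("sample_id")
    for col in CLINICAL_INDICES:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return Cohort(df)


def write_clinical_table(cohort: Cohort, path: str | Path) -> None:
    df = cohort.df.reset_index()
    if "index" in df.columns:
        df = df.rename(columns={"index": "sample_id"})
    _write_formatted(df, path)


# ---------------------------------------------------------------------------
# species origin classification (IMG-style isolation metadata)
# ---------------------------------------------------------------------------

ORAL_KEYWORDS = ("saliva", "dental plaque", "nasopharynx", "oral")
GUT_KEYWORDS = ("feces", "gastrointestinal tract", "gut", "stool")


@dataclass(frozen=True)
class OriginRecord:
    species: str
    host_name: str
    isolation: str
    origin: str  # oral | gut | other_unknown


def classify_origin(host_name: str | None, isolation: str | None,
                    oral_keywords=ORAL_KEYWORDS,
                    gut_keywords=GUT_KEYWORDS) -> str:
    """Classify a species' habitat from isolation metadata.

    A species counts as oral or gut only when its recorded host is
    Homo sapiens; the isolation text is matched case-insensitively as a
    substring, oral keywords checked before gut keywords.
    """
    if not host_name or not isolation:
        return "other_unknown"
    if host_name.strip().lower() != "homo sapiens":
        return "other_unknown"
    iso = isolation.lower()
    if any(k.lower() in iso for k in oral_keywords):
        return "oral"
    if any(k.lower() in iso for k in gut_keywords):
        return "gut"
    return "other_unknown"


def read_origin_table(path: str | Path, oral_keywords=ORAL_KEYWORDS,
                      gut_keywords=GUT_KEYWORDS) -> list[OriginRecord]:
    """Read an IMG-style snapshot (species, Host Name, Isolation columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    try:
        sp_col, host_col, iso_col = (cols[k] for k in ("species", "host_name", "isolation"))
    except KeyError as exc:
        raise TableFormatError(f"origin table missing column {exc}") from exc
    records = []
    for _, row in df.iterrows():
        records.append(OriginRecord(
            species=row[sp_col], host_name=row[host_col], isolation=row[iso_col],
            origin=classify_origin(row[host_col], row[iso_col], oral_keywords, gut_keywords),
        ))
    return records


def write_origin_table(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.species, r.host_name, r.isolation, r.origin) for r in records],
        columns=["species", "host_name", "isolation", "origin"],
    ).sort_values("species", kind="mergesort").reset_index(drop=True)
    _write_formatted(df, path)


# ---------------------------------------------------------------------------
# result-table schema registry
# ---------------------------------------------------------------------------

RESULT_SCHEMAS: dict[str, tuple[str, ...]] = {
    "differential": ("feature_id", "level", "mean_group1", "mean_group2",
                     "p_value", "q_value", "direction", "significant"),
    "trend": ("feature_id", "arm", "statistic", "p_value", "q_value",
              "trend_direction", "significant"),
    "triangle": ("side", "a_id", "b_id", "rho", "p_value", "q_value", "sign",
                 "a_annotation", "b_annotation"),
    "enterotype": ("sample_id", "cluster", "dominant_genus"),
    "selection": ("rank", "feature_id", "importance"),
    "reporter": ("pathway_id", "n_kos", "raw_z", "corrected_score",
                 "direction", "significant"),
    "enrichment": ("set_label", "stratum", "count", "percent", "denominator"),
    "timepoint": ("index", "arm", "timepoint", "statistic", "p_value", "stars"),
    "alpha": ("sample_id", "shannon", "richness"),
    "ch_curve": ("k", "ch"),
}


def write_result_table(records, path: str | Path, schema_name: str) -> None:
    """Write result rows as TSV: fixed column order, %.6g reals, rows sorted
    by the leading id columns, so equal inputs give byte-identical files."""
    if schema_name not in RESULT_SCHEMAS:
        raise KeyError(f"unregistered result schema {schema_name!r}")
    columns = list(RESULT_SCHEMAS[schema_name])
    df = pd.DataFrame(list(records), columns=columns) if not isinstance(records, pd.DataFrame) \
        else records.loc[:, columns].copy()
    sort_cols = columns[: min(2, len(columns))]
    if len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    _write_formatted(df, path)


def read_result_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    if schema_name not in RESULT_SCHEMAS:
        raise KeyError(f"unregistered result schema {schema_name!r}")
    df = pd.read_csv(path, sep="\t")
    expected = list(RESULT_SCHEMAS[schema_name])
    if list(df.columns) != expected:
        raise TableFormatError(
            f"columns {list(df.columns)} do not match schema {schema_name!r}")
    return df


def _fmt_cell(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return format(float(v), ".6g")
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    return str(v)


def _write_formatted(df: pd.DataFrame, path: str | Path) -> None:
    lines = ["\t".join(map(str, df.columns))]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_fmt_cell(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          id_column: str = "#feature_id") -> None:
    """Write an abundance table in the dialect its reader expects."""
    df = table.data
    lines = ["\t".join([id_column, *map(str, df.columns)])]
    for fid, row in zip(df.index, df.to_numpy()):
        lines.append("\t".join([str(fid), *(format(float(v), ".10g") for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_distance_matrix(sample_ids, matrix: np.ndarray, path: str | Path) -> None:
    lines = ["\t".join(["sample_id", *map(str, sample_ids)])]
    for sid, row in zip(sample_ids, matrix):
        lines.append("\t".join([str(sid), *(format(float(v), ".10g") for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")
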
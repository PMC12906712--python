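"""Reading, filtering and summarising DIA-NN long-format reports.

A DIA-NN report is a tab-separated table with one row per precursor
(modified peptide sequence + charge) per run, carrying run-level and
global q-values and a precursor quantity.  This module parses such
reports into a canonical :class:`pandas.DataFrame`, removes common
laboratory contaminants (cRAP-style FASTA lists) and rows above the
q-value acceptance thresholds, and summarises per-run identification
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical column names used throughout the package.
CANONICAL_COLUMNS = (
    "run_id",
    "protein_group",
    "genes",
    "precursor_id",
    "modified_sequence",
    "charge",
    "q_value",
    "pg_q_value",
    "global_q_value",
    "global_pg_q_value",
    "quantity",
)

#: Default mapping canonical name -> DIA-NN report column header.
#: Column headers drift between DIA-NN versions, so every name is remappable.
DIANN_DIALECT: dict[str, str] = {
    "run_id": "Run",
    "protein_group": "Protein.Group",
    "genes": "Genes",
    "precursor_id": "Precursor.Id",
    "modified_sequence": "Modified.Sequence",
    "charge": "Precursor.Charge",
    "q_value": "Q.Value",
    "pg_q_value": "PG.Q.Value",
    "global_q_value": "Global.Q.Value",
    "global_pg_q_value": "Global.PG.Q.Value",
    "quantity": "Precursor.Quantity",
}

_NUMERIC_COLUMNS = ("q_value", "pg_q_value", "global_q_value", "global_pg_q_value")

VALID_GROUPS = ("Dep", "NonDep")


class ReportError(ValueError):
    """Malformed or unusable DIA-NN report."""


class EmptyReportError(ReportError):
    """Report contains a header but no data rows (or nothing at all)."""


class MissingColumnError(ReportError):
    """A mandatory report column is absent."""


@dataclass(frozen=True)
class FilterConfig:
    """Record-level filter settings.

    Parameters
    ----------
    q_max : float
        Inclusive acceptance threshold applied to ``q_value``,
        ``pg_q_value`` and ``global_q_value`` (the three statistics the
        standard workflow filters at 0.01, i.e. 1 % FDR).
    contaminant_accessions : frozenset of str
        Accessions to treat as contaminants.  A precursor is dropped if
        *any* accession of its protein group is in this set.
    drop_contaminants : bool
        Whether the contaminant filter is applied at all.
    filter_global_pg : bool
        Also filter on ``global_pg_q_value``; off by default since the
        standard workflow names exactly three filter columns.
    """

    q_max: float = 0.01
    contaminant_accessions: frozenset[str] = field(default_factory=frozenset)
    drop_contaminants: bool = True
    filter_global_pg: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.q_max <= 1.0:
            raise ValueError(f"q_max must be in (0, 1], got {self.q_max}")


def read_report(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a DIA-NN long-format report into canonical columns.

    Parameters
    ----------
    path : path-like
        Tab-separated report with a header row.
    dialect : dict, optional
        Mapping of canonical column name -> header in the file.
        Defaults to the DIA-NN names (:data:`DIANN_DIALECT`).

    Returns
    -------
    pandas.DataFrame
        One row per report row, canonical column names, q-values and
        quantity as floats, charge as int.  Rows with unparseable
        numerics raise rather than being coerced silently.
    """
    dialect = dict(DIANN_DIALECT if dialect is None else dialect)
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyReportError(f"{path}: no content") from None

    missing = [col for col in CANONICAL_COLUMNS if dialect.get(col) not in raw.columns]
    # global_pg_q_value and genes are tolerated as absent: older reports omit them
    fatal = [c for c in missing if c not in ("global_pg_q_value", "genes")]
    if fatal:
        names = ", ".join(f"{c} (expected header {dialect.get(c)!r})" for c in fatal)
        raise MissingColumnError(f"{path}: missing mandatory column(s): {names}")
    if raw.empty:
        raise EmptyReportError(f"{path}: report has a header but no rows")

    out = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        header = dialect.get(canon)
        if header in raw.columns:
            out[canon] = raw[header]
        elif canon == "genes":
            out[canon] = ""
        else:  # absent global_pg_q_value: mirror global_q_value
            out[canon] = raw[dialect["global_q_value"]]

    for col in _NUMERIC_COLUMNS + ("quantity", "charge"):
        converted = pd.to_numeric(out[col].replace("", None), errors="coerce")
        bad = converted.isna() & out[col].ne("") & out[col].notna()
        if col == "quantity":
            # missing quantity is tolerated (kept for detection, dropped from quant)
            bad &= out[col].ne("NA")
        if bad.any():
            rows = ", ".join(str(i + 2) for i in out.index[bad][:10])  # +2: header + 1-based
            raise ReportError(f"{path}: unparseable {col} at file line(s) {rows}")
        out[col] = converted
    if out[list(_NUMERIC_COLUMNS)].isna().any().any():
        col = next(c for c in _NUMERIC_COLUMNS if out[c].isna().any())
        rows = ", ".join(str(i + 2) for i in out.index[out[col].isna()][:10])
        raise ReportError(f"{path}: missing {col} at file line(s) {rows}")
    for col in _NUMERIC_COLUMNS:
        outside = (out[col] < 0) | (out[col] > 1)
        if outside.any():
            raise ReportError(f"{path}: {col} outside [0, 1]")
    out["charge"] = out["charge"].astype(int)

    dup = out.duplicated(subset=["run_id", "precursor_id"])
    if dup.any():
        raise ReportError(f"{path}: duplicate (run_id, precursor_id) pairs ({int(dup.sum())})")

    logger.info("read_report: parsed %d rows from %s", len(out), path)
    return out


def write_report(records: pd.DataFrame, path: str | Path, dialect: dict[str, str] | None = None) -> None:
    """Write canonical records back to a report TSV in the given dialect."""
    dialect = dict(DIANN_DIALECT if dialect is None else dialect)
    out = records.loc[:, list(CANONICAL_COLUMNS)].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata CSV (run_id, animal_id, group, sex).

    ``group`` must be one of ``Dep``/``NonDep``; run_ids must be unique.
    """
    meta = pd.read_csv(path, dtype=str)
    required = {"run_id", "animal_id", "group", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise MissingColumnError(f"{path}: metadata missing column(s): {sorted(missing)}")
    if meta["run_id"].duplicated().any():
        raise ReportError(f"{path}: duplicate run_id in metadata")
    bad_groups = set(meta["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ReportError(
            f"{path}: unknown group label(s) {sorted(bad_groups)}; this is a two-group "
            f"design, expected {VALID_GROUPS}"
        )
    return meta


def load_contaminants(fasta_path: str | Path) -> frozenset[str]:
    """Parse a contaminant FASTA (cRAP-style) into a set of accessions.

    The accession is the token between the first and second ``|`` for
    UniProt-style headers (``>sp|P04264|K2C1_HUMAN``), otherwise the first
    whitespace-delimited token of the header.
    """
    fasta_path = Path(fasta_path)
    accessions: set[str] = set()
    with open(fasta_path) as handle:
        first = handle.read(1)
        if first != ">":
            raise ReportError(f"{fasta_path}: not FASTA (does not start with '>')")
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.id  # first whitespace-delimited token
        if "|" in header:
            parts = header.split("|")
            accessions.add(parts[1] if len(parts) > 1 and parts[1] else parts[0])
        else:
            accessions.add(header)
    return frozenset(accessions)


def _is_contaminant(protein_group: pd.Series, contaminants: frozenset[str]) -> pd.Series:
    if not contaminants:
        return pd.Series(False, index=protein_group.index)
    return protein_group.map(lambda pg: any(acc in contaminants for acc in str(pg).split(";")))


def apply_filters(records: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Apply q-value and contaminant filters; idempotent.

    Keeps rows with ``q_value``, ``pg_q_value`` and ``global_q_value`` all
    ≤ ``cfg.q_max`` (inclusive) whose protein group shares no accession
    with the contaminant set.
    """
    cfg = cfg or FilterConfig()
    keep = (
        (records["q_value"] <= cfg.q_max)
        & (records["pg_q_value"] <= cfg.q_max)
        & (records["global_q_value"] <= cfg.q_max)
    )
    if cfg.filter_global_pg:
        keep &= records["global_pg_q_value"] <= cfg.q_max
    if cfg.drop_contaminants:
        keep &= ~_is_contaminant(records["protein_group"], cfg.contaminant_accessions)
    out = records.loc[keep].reset_index(drop=True)
    logger.info("apply_filters: kept %d of %d rows", len(out), len(records))
    return out


def per_run_counts(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Distinct precursor and protein-group counts per run.

    Every run in ``meta`` appears (zero counts if it lost all rows to
    filtering); a run present in ``records`` but absent from ``meta`` is
    an error.
    """
    unknown = set(records["run_id"]) - set(meta["run_id"])
    if unknown:
        raise ReportError(f"run(s) without metadata: {sorted(unknown)}")
    grouped = records.groupby("run_id").agg(
        n_precursors=("precursor_id", "nunique"),
        n_proteins=("protein_group", "nunique"),
    )
    out = meta[["run_id", "group"]].merge(grouped, on="run_id", how="left")
    out[["n_precursors", "n_proteins"]] = out[["n_precursors", "n_proteins"]].fillna(0).astype(int)
    return out
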
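"""Readers and writers for the tabular formats the pipeline touches.

All files are UTF-8 tab-separated text with ``NA`` as the missing-value
token and ``.`` as the decimal separator.  Quantification matrices carry
``accession``, ``symbol`` and ``length_aa`` columns followed by one column
per sample; a companion sample sheet maps sample_id to condition.  Gene
sets use the standard GMT line format.  Survival tables carry
``patient_id``, ``time``, ``event`` and one expression column per protein.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITIONS,
    CandidateReport,
    GeneSet,
    QuantDataset,
    SurvivalCohort,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
_META_COLS = ("accession", "symbol", "length_aa")


def read_quant_table(
    path: str | Path,
    sample_sheet_path: str | Path,
    dataset_id: str | None = None,
) -> QuantDataset:
    """Read a quantification matrix plus its sample sheet.

    Duplicate gene symbols are collapsed to the row with the highest total
    abundance (one ranked entry per protein), with a logged warning.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "symbol": str},
                     na_values=[NA_TOKEN], keep_default_na=False)
    for col in _META_COLS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    lengths = pd.to_numeric(df["length_aa"], errors="coerce")
    if lengths.isna().any() or (lengths % 1 != 0).any():
        raise ValidationError(f"{path}: non-integer length_aa")
    df["length_aa"] = lengths.astype(np.int64)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str,
                        na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("sample_id", "condition"):
        if col not in sheet.columns:
            raise ValidationError(f"{sample_sheet_path}: missing column {col!r}")
    conditions = pd.Series(
        sheet["condition"].to_numpy(), index=sheet["sample_id"].to_numpy()
    )
    bad = set(conditions) - CONDITIONS
    if bad:
        raise ValidationError(f"{sample_sheet_path}: unknown conditions {sorted(bad)}")

    sample_cols = [c for c in df.columns if c not in _META_COLS]
    absent = [c for c in sample_cols if c not in conditions.index]
    if absent:
        raise ValidationError(f"{path}: sample {absent[0]!r} absent from sheet")
    abundance = df[sample_cols].astype(float)
    if (abundance.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative abundance")

    # collapse duplicate symbols: keep the highest-total-abundance row
    if df["symbol"].duplicated().any():
        totals = abundance.sum(axis=1, skipna=True)
        order = np.lexsort((-totals.to_numpy(), df["symbol"].to_numpy()))
        keep = ~df["symbol"].iloc[order].duplicated().sort_index()
        n_dropped = int((~keep).sum())
        logger.warning(
            "%s: collapsed %d duplicate-symbol rows (kept highest total abundance)",
            dataset_id, n_dropped,
        )
        df = df[keep.to_numpy()]
        abundance = abundance[keep.to_numpy()]

    proteins = df[["accession", "length_aa"]].copy()
    proteins.index = pd.Index(df["symbol"], name="symbol")
    abundance.index = proteins.index
    return QuantDataset(
        dataset_id=dataset_id,
        proteins=proteins,
        abundance=abundance,
        conditions=conditions.loc[sample_cols],
    )


def write_quant_table(
    dataset: QuantDataset, path: str | Path, sample_sheet_path: str | Path
) -> None:
    """Write a QuantDataset back to matrix + sample-sheet TSVs."""
    out = dataset.proteins.reset_index()[["accession", "symbol", "length_aa"]]
    out = pd.concat([out, dataset.abundance.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
    sheet = pd.DataFrame(
        {"sample_id": dataset.conditions.index, "condition": dataset.conditions.values}
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> GeneSet:
    """Read the first gene set from a GMT file.

    Each GMT line is ``name<TAB>description<TAB>member...``; duplicate
    members are dropped (and counted in the log).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines()
             if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty GMT file")
    if len(lines) > 1:
        logger.info("%s: %d sets in file, using the first", path, len(lines))
    fields = lines[0].split("\t")
    if len(fields) < 3:
        raise ValidationError(
            f"{path}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
        )
    name, _desc, *members = fields
    members = [m for m in members if m]
    unique = frozenset(members)
    n_dup = len(members) - len(unique)
    if n_dup:
        logger.info("%s: removed %d duplicate members from %s", path, n_dup, name)
    if not unique:
        raise ValidationError(f"{path}: gene set {name!r} has an empty member list")
    return GeneSet(name=name, members=unique)


def write_gene_set(gene_set: GeneSet, path: str | Path, description: str = "") -> None:
    line = "\t".join([gene_set.name, description or gene_set.name,
                      *sorted(gene_set.members)])
    Path(path).write_text(line + "\n", encoding="utf-8")


def read_survival_table(
    path: str | Path,
    cohort_id: str | None = None,
    endpoint: str = "OS",
) -> SurvivalCohort:
    """Read a survival cohort TSV (patient_id, time, event, proteins...)."""
    path = Path(path)
    if cohort_id is None:
        cohort_id = path.stem
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["patient_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate patient_id")
    df = df.set_index("patient_id")
    if df["event"].isna().any() or not df["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event values must be 0 or 1")
    df["event"] = df["event"].astype(np.int64)
    df["time"] = df["time"].astype(float)
    if (df["time"] <= 0).any() or df["time"].isna().any():
        raise ValidationError(f"{path}: time must be > 0")
    protein_cols = [c for c in df.columns if c not in ("time", "event")]
    df[protein_cols] = df[protein_cols].astype(float)
    return SurvivalCohort(cohort_id=cohort_id, endpoint=endpoint, data=df)


def write_survival_table(cohort: SurvivalCohort, path: str | Path) -> None:
    out = cohort.data.reset_index()
    if "index" in out.columns:  # unnamed index
        out = out.rename(columns={"index": "patient_id"})
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def filter_to_gene_set(dataset: QuantDataset, gene_set: GeneSet) -> QuantDataset:
    """Restrict a dataset to proteins whose symbol is in the gene set.

    Original row order is preserved; an empty result is legal (logged).
    """
    mask = dataset.proteins.index.isin(gene_set.members)
    if not mask.any():
        logger.warning(
            "%s: no proteins overlap gene set %s", dataset.dataset_id, gene_set.name
        )
    return QuantDataset(
        dataset_id=dataset.dataset_id,
        proteins=dataset.proteins[mask],
        abundance=dataset.abundance[mask],
        conditions=dataset.conditions,
    )


def write_candidate_report(report: CandidateReport, path: str | Path) -> None:
    """Write the final report TSV with '#'-prefixed provenance lines."""
    path = Path(path)
    if len(report.table) and report.table["Rscore"].isna().any():
        raise ValidationError("report contains NaN Rscore; refuse to write")
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(report.provenance):
            fh.write(f"# {key}: {report.provenance[key]}\n")
        report.table.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN)


def read_candidate_report(path: str | Path) -> CandidateReport:
    """Read a report written by :func:`write_candidate_report`."""
    path = Path(path)
    provenance: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            provenance[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", na_values=[NA_TOKEN],
                            keep_default_na=False)
    if "symbol" in table.columns:
        table["symbol"] = table["symbol"].astype(str)
    if "accession" in table.columns:
        table["accession"] = table["accession"].astype(str)
    return CandidateReport(table=table, provenance=provenance)
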
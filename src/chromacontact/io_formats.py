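"""Readers and writers for the tabular formats the pipeline touches.

Protein-group and peptide tables follow the MaxQuant TSV conventions by
default (``Reverse`` / ``Potential contaminant`` flags written as ``+``,
absent intensities written as ``0``); a small dialect mapping lets
non-MaxQuant tables be used.  Domain/IDR annotations follow the
InterProScan TSV column order.  All residue coordinates are 1-based
inclusive (UniProt convention) throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

# Column-name dialect matching MaxQuant 1.6 proteinGroups.txt / peptides.txt.
MAXQUANT_DIALECT = {
    "protein_id": "Protein IDs",
    "gene_name": "Gene names",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_site": "Only identified by site",
    "ratio_prefix": "Ratio H/L ",
    "ibaq_prefix": "iBAQ ",
    # peptide tables
    "peptide_id": "Sequence",
    "sequence": "Sequence",
    "start": "Start position",
    "end": "End position",
    "intensity_prefix": "Intensity ",
}


@dataclass
class ProteinQuantTable:
    """Per-protein quantification across experiments.

    ``data`` is indexed by ``protein_id`` and holds ``gene_name``, the three
    boolean MaxQuant flags, one ``ratio_<experiment>`` column per SILAC
    experiment (heavy/light, dimensionless) and one ``ibaq_<sample>`` column
    per sample.  Missing quantities are NaN, never 0.
    """

    data: pd.DataFrame
    ratio_columns: list[str] = field(default_factory=list)
    ibaq_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataError(f"duplicate protein ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PeptideQuantTable:
    """Per-peptide intensities across replicates of two fractions.

    ``data`` is indexed by ``peptide_id`` and holds ``protein_id``,
    ``sequence``, ``start``, ``end`` (1-based inclusive coordinates in the
    parent protein) and one intensity column per replicate per fraction.
    ``fraction_columns`` maps each fraction name (``crosslinked`` /
    ``released``) to its replicate columns.
    """

    data: pd.DataFrame
    fraction_columns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.data[(self.data["start"] < 1) | (self.data["start"] > self.data["end"])]
        if len(bad):
            raise DataError(f"invalid peptide coordinates for {bad.index[:5].tolist()}")
        lengths = self.data["sequence"].str.len()
        mismatch = self.data[lengths != self.data["end"] - self.data["start"] + 1]
        if len(mismatch):
            raise DataError(
                f"sequence length inconsistent with coordinates for {mismatch.index[:5].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def intensity_columns(self) -> list[str]:
        return [c for cols in self.fraction_columns.values() for c in cols]


@dataclass(frozen=True)
class RegionAnnotation:
    """A domain or IDR interval on a protein, 1-based inclusive."""

    region_id: str
    protein_id: str
    start: int
    end: int
    region_class: str  # "domain" | "IDR"
    name: str
    source_signature: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"region {self.region_id}: invalid interval {self.start}-{self.end}"
            )
        if self.region_class not in ("domain", "IDR"):
            raise DataError(f"region {self.region_id}: bad class {self.region_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _parse_flag(series: pd.Series) -> pd.Series:
    """MaxQuant marks flags with '+'; anything else (NaN, '') is False."""
    return series.fillna("").astype(str).str.strip().eq("+")


def _zeros_to_nan(frame: pd.DataFrame, columns: list[str]) -> None:
    # MaxQuant writes 0 for an absent quantification; downstream imputation
    # rules are defined on missing values, so 0 becomes NaN at the door.
    for col in columns:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
        frame.loc[frame[col] <= 0, col] = np.nan


def read_protein_groups(path, dialect: dict | None = None) -> ProteinQuantTable:
    """Read a MaxQuant-style proteinGroups TSV.

    Zeros in ratio/iBAQ columns become missing values.  Raises
    :class:`ConfigurationError` naming the missing column when the header
    lacks a mandatory column.
    """
    d = {**MAXQUANT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("protein_id",):
        if d[key] not in raw.columns:
            raise ConfigurationError(
                f"input table lacks the protein id column {d[key]!r}"
            )
    ratio_cols = [c for c in raw.columns if c.startswith(d["ratio_prefix"])]
    ibaq_cols = [c for c in raw.columns if c.startswith(d["ibaq_prefix"])]

    out = pd.DataFrame(index=pd.Index(raw[d["protein_id"]], name="protein_id"))
    out["gene_name"] = (
        raw[d["gene_name"]].values if d["gene_name"] in raw.columns else ""
    )
    for attr, key in (
        ("is_reverse_decoy", "reverse"),
        ("is_contaminant", "contaminant"),
        ("only_identified_by_site", "only_site"),
    ):
        if d[key] in raw.columns:
            out[attr] = _parse_flag(raw[d[key]]).values
        else:
            out[attr] = False

    new_ratio, new_ibaq = [], []
    for c in ratio_cols:
        name = "ratio_" + c[len(d["ratio_prefix"]):].strip()
        out[name] = raw[c].values
        new_ratio.append(name)
    for c in ibaq_cols:
        name = "ibaq_" + c[len(d["ibaq_prefix"]):].strip()
        out[name] = raw[c].values
        new_ibaq.append(name)
    _zeros_to_nan(out, new_ratio + new_ibaq)
    return ProteinQuantTable(out, ratio_columns=new_ratio, ibaq_columns=new_ibaq)


def write_protein_groups(table: ProteinQuantTable, path, dialect: dict | None = None) -> None:
    """Write a :class:`ProteinQuantTable` back to MaxQuant-style TSV.

    Missing intensities are written as 0 and flags as '+'/'', so a
    write/read round trip through the same dialect is lossless.
    """
    d = {**MAXQUANT_DIALECT, **(dialect or {})}
    out = pd.DataFrame()
    out[d["protein_id"]] = table.data.index
    out[d["gene_name"]] = table.data["gene_name"].values
    for attr, key in (
        ("is_reverse_decoy", "reverse"),
        ("is_contaminant", "contaminant"),
        ("only_identified_by_site", "only_site"),
    ):
        out[d[key]] = np.where(table.data[attr].values, "+", "")
    for c in table.ratio_columns:
        out[d["ratio_prefix"] + c[len("ratio_"):]] = table.data[c].fillna(0).values
    for c in table.ibaq_columns:
        out[d["ibaq_prefix"] + c[len("ibaq_"):]] = table.data[c].fillna(0).values
    out.to_csv(path, sep="\t", index=False)


def read_peptides(path, dialect: dict | None = None) -> PeptideQuantTable:
    """Read a peptide TSV with fraction intensity columns.

    Intensity columns are recognised by the dialect's ``intensity_prefix``
    followed by ``<fraction>_<replicate>``; zeros become missing.
    """
    d = {**MAXQUANT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("peptide_id", "protein_id", "start", "end"):
        col = d[key] if key != "peptide_id" else ("Peptide ID" if "Peptide ID" in raw.columns else d[key])
        if col not in raw.columns and key == "protein_id":
            raise ConfigurationError(f"peptide table lacks the protein id column {d[key]!r}")

    pep_id_col = "Peptide ID" if "Peptide ID" in raw.columns else d["peptide_id"]
    out = pd.DataFrame(index=pd.Index(raw[pep_id_col], name="peptide_id"))
    out["protein_id"] = raw[d["protein_id"]].values
    out["sequence"] = raw[d["sequence"]].values
    out["start"] = raw[d["start"]].astype(int).values
    out["end"] = raw[d["end"]].astype(int).values

    prefix = d["intensity_prefix"]
    fraction_columns: dict[str, list[str]] = {}
    for c in raw.columns:
        if c.startswith(prefix):
            label = c[len(prefix):].strip()
            fraction = label.rsplit("_", 1)[0]
            name = "intensity_" + label
            out[name] = raw[c].values
            fraction_columns.setdefault(fraction, []).append(name)
    _zeros_to_nan(out, [c for cols in fraction_columns.values() for c in cols])
    return PeptideQuantTable(out, fraction_columns=fraction_columns)


def write_peptides(table: PeptideQuantTable, path, dialect: dict | None = None) -> None:
    d = {**MAXQUANT_DIALECT, **(dialect or {})}
    out = pd.DataFrame()
    out["Peptide ID"] = table.data.index
    out[d["protein_id"]] = table.data["protein_id"].values
    out[d["sequence"]] = table.data["sequence"].values
    out[d["start"]] = table.data["start"].values
    out[d["end"]] = table.data["end"].values
    for cols in table.fraction_columns.values():
        for c in cols:
            out[d["intensity_prefix"] + c[len("intensity_"):]] = (
                table.data[c].fillna(0).values
            )
    out.to_csv(path, sep="\t", index=False)


def filter_quant_records(table: ProteinQuantTable) -> ProteinQuantTable:
    """Drop reverse decoys, contaminants, and site-only identifications.

    Idempotent; the number of removed records is logged.
    """
    mask = ~(
        table.data["is_reverse_decoy"]
        | table.data["is_contaminant"]
        | table.data["only_identified_by_site"]
    )
    removed = int((~mask).sum())
    logger.info("filter_quant_records: removed %d of %d records", removed, len(table))
    return replace(table, data=table.data[mask])


# InterProScan member-database analyses that predict disorder rather than
# domains; configurable because predictor names change between releases.
IDR_ANALYSES = frozenset({"MobiDBLite", "mobidb-lite", "MobiDB-lite"})

# Analyses whose matches represent neither domains nor IDRs and are dropped.
EXCLUDED_ANALYSES = frozenset({"Coils", "SignalP", "SignalP_EUK", "Phobius", "TMHMM"})

# 0-based column indices in the InterProScan TSV (headerless) format:
# accession, md5, length, analysis, signature accession, description, start, stop.
INTERPROSCAN_COLUMNS = {
    "protein_id": 0,
    "analysis": 3,
    "signature": 4,
    "description": 5,
    "start": 6,
    "end": 7,
}


def read_region_annotations(
    path,
    idr_analyses=IDR_ANALYSES,
    excluded_analyses=EXCLUDED_ANALYSES,
    columns: dict | None = None,
) -> list[RegionAnnotation]:
    """Read InterProScan-style matches into :class:`RegionAnnotation` records.

    ``region_class`` is assigned from ``idr_analyses`` (IDR predictors → IDR,
    everything else → domain); matches from ``excluded_analyses`` are dropped;
    records with start > end are rejected with a warning.
    """
    idx = {**INTERPROSCAN_COLUMNS, **(columns or {})}
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    regions: list[RegionAnnotation] = []
    n_excluded = 0
    for i, row in enumerate(raw.itertuples(index=False)):
        analysis = str(row[idx["analysis"]])
        if analysis in excluded_analyses:
            n_excluded += 1
            continue
        start, end = int(row[idx["start"]]), int(row[idx["end"]])
        if start > end:
            logger.warning(
                "read_region_annotations: line %d rejected (start %d > end %d)",
                i + 1, start, end,
            )
            continue
        desc = row[idx["description"]]
        regions.append(
            RegionAnnotation(
                region_id=f"{row[idx['protein_id']]}:{row[idx['signature']]}:{start}-{end}",
                protein_id=str(row[idx["protein_id"]]),
                start=start,
                end=end,
                region_class="IDR" if analysis in idr_analyses else "domain",
                name=str(desc) if pd.notna(desc) else str(row[idx["signature"]]),
                source_signature=str(row[idx["signature"]]),
            )
        )
    if n_excluded:
        logger.info("read_region_annotations: dropped %d non-domain/IDR matches", n_excluded)
    return regions


def write_region_annotations(regions: list[RegionAnnotation], path) -> None:
    """Write regions in the InterProScan column order (headerless TSV)."""
    rows = []
    for r in regions:
        analysis = "MobiDBLite" if r.region_class == "IDR" else "Pfam"
        rows.append(
            [r.protein_id, "-", "-", analysis, r.source_signature or r.name,
             r.name, r.start, r.end]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def regions_to_frame(regions: list[RegionAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "protein_id": r.protein_id,
                "start": r.start,
                "end": r.end,
                "region_class": r.region_class,
                "name": r.name,
                "source_signature": r.source_signature,
            }
            for r in regions
        ]
    )


def read_category_annotations(path) -> pd.DataFrame:
    """Read a per-protein GO/keyword annotation TSV.

    Expected header: ``protein_id``, ``go_terms``, ``keywords`` with
    semicolon-separated term lists.  Returns a DataFrame indexed by
    protein_id with ``go_terms`` and ``keywords`` as frozensets of strings.
    Categorization semantics live in :mod:`chromacontact.classify`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in raw.columns:
        raise ConfigurationError("annotation table lacks the protein id column 'protein_id'")

    def _split(cell) -> frozenset:
        if pd.isna(cell) or not str(cell).strip():
            return frozenset()
        return frozenset(t.strip() for t in str(cell).split(";") if t.strip())

    out = pd.DataFrame(index=pd.Index(raw["protein_id"], name="protein_id"))
    out["go_terms"] = [_split(c) for c in raw.get("go_terms", pd.Series([""] * len(raw)))]
    out["keywords"] = [_split(c) for c in raw.get("keywords", pd.Series([""] * len(raw)))]
    return out


def write_category_annotations(annotations: pd.DataFrame, path) -> None:
    out = pd.DataFrame(index=annotations.index)
    out["go_terms"] = [";".join(sorted(s)) for s in annotations["go_terms"]]
    out["keywords"] = [";".join(sorted(s)) for s in annotations["keywords"]]
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
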
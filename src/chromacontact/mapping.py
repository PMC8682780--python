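"""Map crosslinked-fraction-enriched peptides to domains and IDRs.

A peptide matches a region if the two intervals overlap or lie at most
``max_gap`` (default 10) residues apart — the proximity allowance exists
because some DNA-binding domains are rich in arginine/lysine, so their
tryptic peptides are too short for MS and the observable peptide sits just
outside the domain boundary.  The gap between two 1-based inclusive
intervals is ``max(0, region.start - peptide.end, peptide.start -
region.end)`` — the coordinate difference between the facing boundaries,
equal to the minimal residue-to-residue distance between the intervals
(a peptide ending at 87 is gap 9 from a region starting at 96).

Also here: consensus merging of highly overlapping annotation matches,
per-protein contact summaries (domain only / IDR only / both / unmapped),
ranking of general domain types, and residue-level amino-acid composition
enrichment between peptide sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._errors import DataError
from .io_formats import RegionAnnotation
from .synthetic_data import AMINO_ACIDS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchRecord:
    """A peptide↔region match: overlap (gap 0) or proximal (gap 1–max_gap)."""

    peptide_id: str
    region_id: str
    relation: str  # "overlap" | "proximal"
    gap: int


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Minimal residue distance between two 1-based intervals (0 if overlapping)."""
    return max(0, b_start - a_end, a_start - b_end)


def consensus_merge(
    regions: list[RegionAnnotation], overlap_fraction: float = 0.7
) -> list[RegionAnnotation]:
    """Merge highly overlapping same-protein, same-class regions.

    Two regions merge to their union when their overlap covers at least
    ``overlap_fraction`` of the shorter region; merging iterates to a
    fixpoint, so the result is idempotent and independent of input order.
    Names of merged regions are concatenated with '+'.  Regions of
    different classes are never merged.
    """
    by_key: dict[tuple[str, str], list[RegionAnnotation]] = {}
    for r in regions:
        by_key.setdefault((r.protein_id, r.region_class), []).append(r)

    merged: list[RegionAnnotation] = []
    for (pid, cls), group in sorted(by_key.items()):
        # canonical order makes the fixpoint independent of input order
        current = sorted(group, key=lambda r: (r.start, r.end, r.region_id))
        changed = True
        while changed:
            changed = False
            nxt: list[RegionAnnotation] = []
            for r in current:
                if nxt:
                    prev = nxt[-1]
                    ov = min(prev.end, r.end) - max(prev.start, r.start) + 1
                    shorter = min(prev.length, r.length)
                    if ov > 0 and ov >= overlap_fraction * shorter:
                        names = sorted(set(prev.name.split("+")) | set(r.name.split("+")))
                        nxt[-1] = replace(
                            prev,
                            region_id=f"{pid}:{cls}:{min(prev.start, r.start)}",
                            start=min(prev.start, r.start),
                            end=max(prev.end, r.end),
                            name="+".join(names),
                            source_signature=prev.source_signature,
                        )
                        changed = True
                        continue
                nxt.append(r)
            current = sorted(nxt, key=lambda r: (r.start, r.end, r.region_id))
        merged.extend(current)
    return merged


def match_peptide_to_regions(
    peptide_id: str,
    start: int,
    end: int,
    regions: list[RegionAnnotation],
    max_gap: int = 10,
) -> list[MatchRecord]:
    """All regions matching a peptide interval on the same protein.

    A peptide may match several regions at once (e.g. a domain and an IDR).
    """
    out = []
    for r in regions:
        gap = interval_gap(start, end, r.start, r.end)
        if gap <= max_gap:
            out.append(
                MatchRecord(
                    peptide_id=peptide_id,
                    region_id=r.region_id,
                    relation="overlap" if gap == 0 else "proximal",
                    gap=gap,
                )
            )
    return out


def match_peptide_table(
    peptides: pd.DataFrame,
    regions: list[RegionAnnotation],
    max_gap: int = 10,
) -> pd.DataFrame:
    """Match every peptide row (protein_id, start, end) against the regions.

    Returns a long DataFrame with one row per (peptide, region) match,
    carrying the region class and name for downstream summaries.
    """
    by_protein: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    rows = []
    for pep in peptides.itertuples():
        for m in match_peptide_to_regions(
            pep.Index, pep.start, pep.end, by_protein.get(pep.protein_id, []), max_gap
        ):
            region = next(r for r in by_protein[pep.protein_id] if r.region_id == m.region_id)
            rows.append(
                {
                    "peptide_id": m.peptide_id,
                    "protein_id": pep.protein_id,
                    "region_id": m.region_id,
                    "region_class": region.region_class,
                    "region_name": region.name,
                    "relation": m.relation,
                    "gap": m.gap,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "protein_id", "region_id", "region_class",
            "region_name", "relation", "gap",
        ],
    )


def summarize_protein_contacts(
    enriched_peptides: pd.DataFrame,
    matches: pd.DataFrame,
    intersect_set: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-protein mapping status and aggregate mapped-peptide fractions.

    ``enriched_peptides`` holds the crosslinked-fraction-enriched peptides
    (index peptide_id, column protein_id); ``matches`` comes from
    :func:`match_peptide_table`.  ``intersect_set`` optionally restricts to
    proteins supported by both the protein-level analysis and the
    crosslinked fraction.  Status is ``domain_only`` / ``IDR_only`` /
    ``both`` / ``unmapped``; a protein counts as ``both`` when its peptides
    reach both classes (possibly via a single peptide matching both).
    """
    peptides = enriched_peptides
    if intersect_set is not None:
        peptides = peptides[peptides["protein_id"].isin(intersect_set)]
    relevant = matches[matches["peptide_id"].isin(peptides.index)]

    classes_by_protein = relevant.groupby("protein_id")["region_class"].agg(set)
    rows = []
    for pid, group in peptides.groupby("protein_id"):
        classes = classes_by_protein.get(pid, set())
        if classes == {"domain"}:
            status = "domain_only"
        elif classes == {"IDR"}:
            status = "IDR_only"
        elif classes >= {"domain", "IDR"}:
            status = "both"
        else:
            status = "unmapped"
        rows.append(
            {
                "protein_id": pid,
                "n_crosslinked_peptides": len(group),
                "mapped_classes": ",".join(sorted(classes)),
                "mapping_status": status,
            }
        )
    summary = pd.DataFrame(
        rows, columns=["protein_id", "n_crosslinked_peptides", "mapped_classes",
                       "mapping_status"]
    ).set_index("protein_id")

    n_pep = len(peptides)
    classes_by_peptide = relevant.groupby("peptide_id")["region_class"].agg(set)
    pep_mapped = peptides.index.isin(classes_by_peptide.index)

    def _pep_frac(wanted: set[str]) -> float:
        if n_pep == 0:
            return float("nan")
        hits = sum(1 for p in peptides.index if classes_by_peptide.get(p, set()) == wanted)
        return hits / n_pep

    n_prot = len(summary)
    aggregates = {
        "n_peptides": float(n_pep),
        "n_proteins": float(n_prot),
        "frac_peptides_mapped": float(pep_mapped.mean()) if n_pep else float("nan"),
        "frac_peptides_domain_only": _pep_frac({"domain"}),
        "frac_peptides_idr_only": _pep_frac({"IDR"}),
        "frac_peptides_both": _pep_frac({"domain", "IDR"}),
        "frac_proteins_idr_contact": (
            float(summary["mapping_status"].isin(["IDR_only", "both"]).mean())
            if n_prot else float("nan")
        ),
    }
    return summary, aggregates


_NUMERIC_SUFFIX = re.compile(r"[_\-\s]*\d+$")


def normalize_domain_name(name: str) -> str:
    """Default domain-type clustering: case-fold and strip numeric suffixes."""
    return _NUMERIC_SUFFIX.sub("", name.strip().casefold())


def rank_domain_types(
    matches: pd.DataFrame,
    clustering_map: dict[str, str] | None = None,
    region_class: str | None = None,
) -> pd.DataFrame:
    """Counts of distinct proteins per general domain type, ranked.

    Region names are clustered into types via ``clustering_map`` when given,
    else by :func:`normalize_domain_name`; an unmapped name becomes its own
    singleton type with a warning.  Sorted by descending protein count,
    ties broken lexicographically by type name.
    """
    m = matches
    if region_class is not None:
        m = m[m["region_class"] == region_class]
    if m.empty:
        return pd.DataFrame(columns=["domain_type", "n_proteins"]).set_index("domain_type")

    def _type(name: str) -> str:
        if clustering_map is not None:
            if name in clustering_map:
                return clustering_map[name]
            logger.warning("rank_domain_types: name %r not in clustering map, kept as is", name)
            return name
        return normalize_domain_name(name)

    typed = m.assign(domain_type=m["region_name"].map(_type))
    counts = (
        typed.groupby("domain_type")["protein_id"].nunique().rename("n_proteins")
    )
    out = counts.reset_index().sort_values(
        ["n_proteins", "domain_type"], ascending=[False, True], kind="stable"
    )
    return out.set_index("domain_type")


def composition_enrichment(
    query_peptides: list[str],
    reference_peptides: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Residue-level amino-acid composition enrichment of query vs reference.

    Frequencies are computed over the concatenated residues of each set
    (length-weighted) with ``pseudocount`` added per amino acid, and the
    log2 ratio of smoothed frequencies is reported.  Frequency vectors sum
    to 1.
    """
    if not query_peptides or not reference_peptides:
        raise DataError("composition_enrichment needs two non-empty peptide sets")

    def _freq(peps: list[str]) -> np.ndarray:
        joined = "".join(peps).upper()
        counts = np.array([joined.count(a) for a in AMINO_ACIDS], dtype=float)
        counts += pseudocount
        return counts / counts.sum()

    fq, fr = _freq(query_peptides), _freq(reference_peptides)
    return pd.DataFrame(
        {
            "freq_query": fq,
            "freq_reference": fr,
            "log2_enrichment": np.log2(fq / fr),
        },
        index=pd.Index(list(AMINO_ACIDS), name="amino_acid"),
    )
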
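"""Categorize enriched proteins and compare datasets.

Three-way category (known DNA/chromatin binder > present in nucleus >
unexpected, assigned with that precedence), potential true/false positive
(PTP/PFP) by chromatin-relatedness of GO annotations, RBP flagging from GO
molecular function, abundance summaries weighted by relative iBAQ,
chromatin-enrichment ratio quartile classes, pairwise Fisher comparisons of
category composition, and fold-change correlation between analyses.

The keyword lists are editable configuration: they are reasonable defaults
for GO-style annotations, matched case-insensitively as substrings, and can
be replaced wholesale from a YAML document.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from ._errors import DataError
from .enrichment import fisher_2x2

logger = logging.getLogger(__name__)

CAT_BINDER = "known_binder"
CAT_NUCLEAR = "nuclear"
CAT_UNEXPECTED = "unexpected"
CATEGORIES = (CAT_BINDER, CAT_NUCLEAR, CAT_UNEXPECTED)


@dataclass(frozen=True)
class KeywordConfig:
    """Named keyword sets driving the deterministic categorization."""

    dna_chromatin_binding: tuple[str, ...] = (
        "chromatin binding", "dna binding", "chromatin dna binding",
        "nucleosome", "histone", "transcription factor", "chromatin remodeling",
        "dna repair", "dna replication",
    )
    nuclear_localization: tuple[str, ...] = (
        "nucleus", "nucleolus", "nuclear", "nucleoplasm", "spliceosom",
        "rna processing", "rna splicing",
    )
    rbp: tuple[str, ...] = ("rna binding", "rrna binding", "mrna binding")
    chromatin_process: tuple[str, ...] = (
        "chromatin", "chromosome", "dna binding", "transcription", "histone",
        "nucleosome", "dna repair", "dna replication", "rna splicing",
        "rna processing",
    )
    pfp_processes: tuple[str, ...] = (
        "translation", "metabolic process", "cell adhesion",
        "protein folding", "protein transport",
    )

    @classmethod
    def from_yaml(cls, path) -> "KeywordConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown keyword sets in config: {sorted(unknown)}")
        return cls(**{k: tuple(v) for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: list(getattr(self, f.name)) for f in fields(self)}, fh)


DEFAULT_KEYWORDS = KeywordConfig()


def _hits(terms: frozenset, keywords: tuple[str, ...]) -> bool:
    lowered = [t.casefold() for t in terms]
    return any(any(kw in t for t in lowered) for kw in keywords)


def categorize_proteins(
    annotations: pd.DataFrame, config: KeywordConfig = DEFAULT_KEYWORDS
) -> pd.DataFrame:
    """Assign category3, PTP/PFP and the RBP flag per protein.

    Precedence for the three-way category: any DNA/chromatin-binding
    keyword hit → known_binder; else any nuclear keyword hit → nuclear;
    else unexpected.  PTP if any chromatin-related keyword hits; PFP if
    only the listed non-chromatin processes hit; NA otherwise.  The RBP
    flag is independent of the three-way category.  Pure function of
    (annotations, config).
    """
    rows = []
    for pid, row in annotations.iterrows():
        terms = frozenset(row["go_terms"]) | frozenset(row.get("keywords", frozenset()))
        if _hits(terms, config.dna_chromatin_binding):
            cat = CAT_BINDER
        elif _hits(terms, config.nuclear_localization):
            cat = CAT_NUCLEAR
        else:
            cat = CAT_UNEXPECTED
        if _hits(terms, config.chromatin_process):
            ptp_pfp = "PTP"
        elif _hits(terms, config.pfp_processes):
            ptp_pfp = "PFP"
        else:
            ptp_pfp = "NA"
        rows.append(
            {
                "protein_id": pid,
                "category3": cat,
                "ptp_pfp": ptp_pfp,
                "is_rbp": _hits(terms, config.rbp),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def relative_ibaq_summary(
    ibaq: pd.Series, categories: pd.Series
) -> pd.DataFrame:
    """Category fractions by protein count and by relative iBAQ.

    Relative iBAQ of protein i is its iBAQ share of the summarized set's
    total; both fraction columns sum to 1.
    """
    ibaq = ibaq.dropna()
    if ibaq.empty:
        raise DataError("no iBAQ values to summarize")
    cats = categories.reindex(ibaq.index)
    total = float(ibaq.sum())
    rows = []
    for cat in sorted(cats.dropna().unique()):
        in_cat = cats == cat
        rows.append(
            {
                "category": cat,
                "n_proteins": int(in_cat.sum()),
                "count_fraction": float(in_cat.mean()),
                "ibaq_fraction": float(ibaq[in_cat].sum() / total),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def ratio_classes(
    space_ibaq: pd.Series, total_ibaq: pd.Series, k: int = 4
) -> pd.DataFrame:
    """Quartile classes of the enrichment/total iBAQ ratio.

    Proteins present with positive iBAQ in both tables are ranked by
    log(space/total) and split into k near-equal classes (sizes differing
    by at most 1), class k being the highest ratio.  Ties are broken by
    stable protein-id order.
    """
    shared = space_ibaq.dropna().index.intersection(total_ibaq.dropna().index)
    excluded = len(space_ibaq.dropna()) - len(shared)
    if excluded:
        logger.info("ratio_classes: %d proteins absent from the total proteome excluded", excluded)
    if len(shared) < k:
        raise DataError(f"need at least {k} shared proteins, got {len(shared)}")
    ratio = np.log(space_ibaq[shared].astype(float) / total_ibaq[shared].astype(float))
    frame = pd.DataFrame({"ratio": ratio}).sort_index(kind="stable")
    frame = frame.sort_values("ratio", kind="stable")
    n = len(frame)
    # class sizes differ by <= 1: first (n % k) classes get the extra member
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    frame["ratio_class"] = labels
    frame["ratio"] = np.exp(frame["ratio"])
    return frame


STAR_CUTOFFS = (("***", 0.001, "lt"), ("**", 0.01, "le"), ("*", 0.05, "le"))


def star_annotation(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<=0.01, * p<=0.05, else ''."""
    if p < 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_datasets(categories: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Fisher tests on category composition between datasets.

    For each dataset pair and each category, a category-vs-rest 2x2 table
    is tested two-sided; empty datasets are skipped with a warning.
    """
    usable = {}
    for name, cats in categories.items():
        if len(cats) == 0:
            logger.warning("compare_datasets: dataset %r is empty, skipped", name)
            continue
        usable[name] = cats
    names = sorted(usable)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for cat in CATEGORIES:
                a_in = int((usable[a] == cat).sum())
                b_in = int((usable[b] == cat).sum())
                table = [
                    [a_in, len(usable[a]) - a_in],
                    [b_in, len(usable[b]) - b_in],
                ]
                p = fisher_2x2(table)
                rows.append(
                    {
                        "dataset_a": a,
                        "dataset_b": b,
                        "category": cat,
                        "count_a": a_in,
                        "count_b": b_in,
                        "p": p,
                        "stars": star_annotation(p),
                    }
                )
    return pd.DataFrame(
        rows, columns=["dataset_a", "dataset_b", "category", "count_a",
                       "count_b", "p", "stars"]
    )


def correlate_fold_changes(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    tier_column: str = "tier",
) -> tuple[float, pd.DataFrame]:
    """Pearson r of log2 fold-changes on shared features, plus divergences.

    The divergence table lists features significant in A but not in B —
    regulation visible at the chromatin-binding level beyond what protein
    expression explains.  Requires >= 3 shared features.
    """
    shared = results_a.index.intersection(results_b.index)
    if len(shared) < 3:
        raise DataError(f"need >= 3 shared features, got {len(shared)}")
    fa = results_a.loc[shared, "log2fc"].astype(float)
    fb = results_b.loc[shared, "log2fc"].astype(float)
    ok = fa.notna() & fb.notna()
    if ok.sum() < 3:
        raise DataError("need >= 3 shared features with finite fold-changes")
    r = float(np.corrcoef(fa[ok], fb[ok])[0, 1])

    div = pd.DataFrame(index=shared)
    div["log2fc_a"] = fa
    div["log2fc_b"] = fb
    if tier_column in results_a.columns and tier_column in results_b.columns:
        sig_a = results_a.loc[shared, tier_column] != "not_significant"
        sig_b = results_b.loc[shared, tier_column] != "not_significant"
        div = div[sig_a & ~sig_b]
    else:
        div = div.iloc[0:0]
    return r, div
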
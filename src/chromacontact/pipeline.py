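"""End-to-end orchestration of the analysis under a single scenario config.

A :class:`PipelineConfig` (usually loaded from YAML) names the mode, the
inputs (either files or a simulation block), the thresholds and the seed.
``run_pipeline`` executes the stages of the chosen mode, records every
filter count in a :class:`RunLog`, and writes result tables atomically: the
run happens in a temporary sibling directory that is renamed into place
only on success, so a failed run leaves no partial outputs.

Modes
-----
``space_silac``        forward/reverse SILAC ratios, one-sample moderated t,
                       the ≥1-forward + ≥1-reverse evidence rule, two tiers.
``comparative_silac``  SILAC condition comparison (e.g. ground-state vs
                       metastable medium), tier-2-only calls.
``sicap_ibaq``         two-group iBAQ with quantile normalization per
                       condition and the mean / minimum-iBAQ imputation.
``chip_space`` /       two-group label-free iBAQ, minimum-intensity
``two_group_labelfree``  imputation of an all-missing control, tier-2 calls.
``spacemap``           crosslinked vs released fraction peptide intensities,
                       then region matching, contact summaries, domain-type
                       ranking and composition enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ChromacontactError, ConfigurationError, DataError
from . import enrichment, io_formats, mapping, synthetic_data
from .classify import DEFAULT_KEYWORDS, KeywordConfig, categorize_proteins, relative_ibaq_summary

logger = logging.getLogger(__name__)

MODES = (
    "space_silac",
    "sicap_ibaq",
    "spacemap",
    "comparative_silac",
    "chip_space",
    "two_group_labelfree",
)


@dataclass
class PipelineConfig:
    """Validated scenario configuration."""

    mode: str
    outdir: str
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    protein_table: str | None = None
    peptide_table: str | None = None
    regions: str | None = None
    annotations: str | None = None
    design: dict[str, str] = field(default_factory=dict)  # ratio column -> orientation
    fc_threshold: float = 1.0
    tier1_alpha: float = 0.01
    tier2_alpha: float = 0.1
    max_gap: int = 10
    merge_overlap_fraction: float = 0.7
    keyword_config: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(
                f"unknown mode {self.mode!r}; expected one of {MODES}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass
class RunLog:
    """Per-stage input/output counts; counts never increase across filters."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, **params) -> None:
        self.stages.append(
            {
                "stage": stage,
                "n_in": int(n_in),
                "n_out": int(n_out),
                "params": params,
                "wall_stamp": time.time(),
            }
        )
        logger.info("stage %s: %d -> %d %s", stage, n_in, n_out, params or "")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2)


def _infer_orientation(column: str, design: dict[str, str]) -> str:
    if column in design:
        return design[column]
    if "forward" in column:
        return "forward"
    if "reverse" in column:
        return "reverse"
    raise ConfigurationError(f"cannot infer orientation of ratio column {column!r}")


def _ibaq_groups(columns: list[str]) -> dict[str, str]:
    """Group iBAQ columns named ibaq_<condition>_<replicate> by condition."""
    groups = {}
    for c in columns:
        parts = c.split("_")
        if len(parts) < 3:
            raise ConfigurationError(
                f"cannot infer condition of column {c!r}; expected ibaq_<condition>_<rep>"
            )
        groups[c] = "_".join(parts[1:-1])
    return groups


def _simulate_inputs(config: PipelineConfig, workdir: Path, log: RunLog) -> None:
    """Generate inputs from the simulate block and point the config at them."""
    sim = dict(config.simulate)
    design = sim.pop("design", [["forward", "1"], ["forward", "2"],
                                ["reverse", "1"], ["reverse", "2"],
                                ["reverse", "3"], ["reverse", "4"]])
    n_replicates = sim.pop("n_replicates", 3)
    noise_keys = {f.name for f in dataclasses.fields(synthetic_data.NoiseModel)}
    noise = synthetic_data.NoiseModel(**{k: sim.pop(k) for k in list(sim) if k in noise_keys})
    proteome_cfg = synthetic_data.ProteomeConfig(noise=noise, **sim)
    seed = config.seed
    sequences, regions, truth = synthetic_data.generate_proteome(
        proteome_cfg, seed=synthetic_data.child_seed(seed, "proteome")
    )
    log.record("simulate_proteome", proteome_cfg.n_proteins, len(sequences),
               n_regions=len(regions), n_planted=len(truth.chromatin_protein_ids))

    io_formats.write_fasta(sequences, workdir / "proteome.fasta")
    io_formats.write_region_annotations(regions, workdir / "regions.tsv")
    annotations = synthetic_data.generate_annotations(
        truth, seed=synthetic_data.child_seed(seed, "annotations")
    )
    io_formats.write_category_annotations(annotations, workdir / "annotations.tsv")
    config.regions = str(workdir / "regions.tsv")
    config.annotations = str(workdir / "annotations.tsv")

    with open(workdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "chromatin_protein_ids": sorted(truth.chromatin_protein_ids),
                "contact_regions": truth.contact_regions,
                "protein_effects": truth.protein_effects,
            },
            fh, indent=2,
        )

    if config.mode in ("space_silac", "comparative_silac"):
        table = synthetic_data.simulate_space_experiment(
            truth, [tuple(d) for d in design],
            seed=synthetic_data.child_seed(seed, "space"),
        )
        io_formats.write_protein_groups(table, workdir / "proteinGroups.tsv")
        config.protein_table = str(workdir / "proteinGroups.tsv")
        config.design = {
            f"ratio_{o}_{r}": o for o, r in (tuple(d) for d in design)
        }
    elif config.mode in ("sicap_ibaq", "chip_space", "two_group_labelfree"):
        table = synthetic_data.simulate_labelfree_experiment(
            truth, n_replicates=n_replicates,
            seed=synthetic_data.child_seed(seed, "labelfree"),
        )
        io_formats.write_protein_groups(table, workdir / "proteinGroups.tsv")
        config.protein_table = str(workdir / "proteinGroups.tsv")
    elif config.mode == "spacemap":
        peptides = synthetic_data.digest_proteome(sequences)
        table = synthetic_data.simulate_spacemap_experiment(
            truth, peptides, n_replicates=n_replicates,
            seed=synthetic_data.child_seed(seed, "spacemap"),
        )
        io_formats.write_peptides(table, workdir / "peptides.tsv")
        config.peptide_table = str(workdir / "peptides.tsv")


def _run_silac(config: PipelineConfig, workdir: Path, log: RunLog) -> dict[str, pd.DataFrame]:
    table = io_formats.read_protein_groups(config.protein_table)
    log.record("read_protein_groups", len(table), len(table))
    filtered = io_formats.filter_quant_records(table)
    log.record("filter_quant_records", len(table), len(filtered))

    design = [(c, _infer_orientation(c, config.design)) for c in filtered.ratio_columns]
    ratios = enrichment.assemble_log_ratios(filtered, design)
    orientations = dict(design)
    if config.mode == "space_silac":
        kept = enrichment.filter_min_evidence(
            ratios, "forward_and_reverse", orientations=orientations
        )
        rule = "forward_and_reverse"
    else:
        kept = enrichment.filter_min_evidence(ratios, "min_k_replicates", min_k=2)
        rule = "min_k_replicates(2)"
    log.record("filter_min_evidence", len(ratios), len(kept), rule=rule)

    results = enrichment.moderated_t_test(kept, mode="one_sample_ratio")
    results["tier"] = enrichment.classify_tiers(
        results,
        fc_threshold=config.fc_threshold,
        tier1_alpha=config.tier1_alpha,
        tier2_alpha=config.tier2_alpha,
        tier2_only=(config.mode == "comparative_silac"),
    )
    log.record("moderated_t_test", len(kept), len(results), mode="one_sample_ratio")
    results.to_csv(workdir / "enrichment_results.tsv", sep="\t")
    tables = {"enrichment_results": results}
    tables.update(_maybe_classify(config, table, results, workdir, log))
    return tables


def _run_two_group_protein(config: PipelineConfig, workdir: Path, log: RunLog) -> dict[str, pd.DataFrame]:
    table = io_formats.read_protein_groups(config.protein_table)
    log.record("read_protein_groups", len(table), len(table))
    filtered = io_formats.filter_quant_records(table)
    log.record("filter_quant_records", len(table), len(filtered))

    intensities = np.log2(filtered.data[filtered.ibaq_columns].astype(float))
    groups = _ibaq_groups(filtered.ibaq_columns)
    labels = list(dict.fromkeys(groups.values()))
    if len(labels) != 2:
        raise ConfigurationError(f"expected 2 conditions, found {labels}")
    treatment, control = labels

    kept = enrichment.filter_min_evidence(intensities, "min_k_replicates", min_k=2)
    log.record("filter_min_evidence", len(intensities), len(kept), rule="min_k_replicates(2)")
    normalized = enrichment.quantile_normalize(kept, groups)
    rule = "sicap_protein" if config.mode == "sicap_ibaq" else "spacemap_peptide"
    imputed = enrichment.impute(normalized, rule, groups, control_group=control)
    log.record("normalize_impute", len(kept), len(imputed), rule=rule)

    results = enrichment.moderated_t_test(imputed, mode="two_group", groups=groups)
    results["tier"] = enrichment.classify_tiers(
        results,
        fc_threshold=config.fc_threshold,
        tier1_alpha=config.tier1_alpha,
        tier2_alpha=config.tier2_alpha,
        tier2_only=(config.mode in ("chip_space", "two_group_labelfree")),
    )
    log.record("moderated_t_test", len(imputed), len(results),
               mode="two_group", treatment=treatment, control=control)
    results.to_csv(workdir / "enrichment_results.tsv", sep="\t")
    tables = {"enrichment_results": results}
    tables.update(_maybe_classify(config, table, results, workdir, log))
    return tables


def _run_spacemap(config: PipelineConfig, workdir: Path, log: RunLog) -> dict[str, pd.DataFrame]:
    table = io_formats.read_peptides(config.peptide_table)
    log.record("read_peptides", len(table), len(table))
    if set(table.fraction_columns) != {"crosslinked", "released"}:
        raise DataError(
            f"spacemap mode needs crosslinked and released fractions, got {sorted(table.fraction_columns)}"
        )
    cols = table.intensity_columns
    groups = {c: frac for frac, cc in table.fraction_columns.items() for c in cc}
    intensities = np.log2(table.data[cols].astype(float))
    kept = enrichment.filter_min_evidence(intensities, "min_k_replicates", min_k=2)
    log.record("filter_min_evidence", len(intensities), len(kept), rule="min_k_replicates(2)")

    normalized = enrichment.quantile_normalize(kept, groups)
    imputed = enrichment.impute(normalized, "spacemap_peptide", groups)
    log.record("normalize_impute", len(kept), len(imputed), rule="spacemap_peptide")

    # order columns so the crosslinked group defines the fold-change sign
    ordered = table.fraction_columns["crosslinked"] + table.fraction_columns["released"]
    results = enrichment.moderated_t_test(imputed[ordered], mode="two_group", groups=groups)
    results["tier"] = enrichment.classify_tiers(
        results,
        fc_threshold=config.fc_threshold,
        tier1_alpha=config.tier1_alpha,
        tier2_alpha=config.tier2_alpha,
        tier2_only=True,
    )
    meta = table.data[["protein_id", "sequence", "start", "end"]]
    results = meta.join(results, how="right")
    results.to_csv(workdir / "peptide_results.tsv", sep="\t")
    log.record("moderated_t_test", len(imputed), len(results), mode="two_group")

    tables = {"peptide_results": results}
    if config.regions:
        regions = io_formats.read_region_annotations(config.regions)
        merged = mapping.consensus_merge(regions, config.merge_overlap_fraction)
        log.record("consensus_merge", len(regions), len(merged),
                   overlap_fraction=config.merge_overlap_fraction)
        enriched = results[results["tier"] != enrichment.TIER_NS]
        matches = mapping.match_peptide_table(enriched, merged, max_gap=config.max_gap)
        log.record("match_peptides", len(enriched), len(matches), max_gap=config.max_gap)
        summary, aggregates = mapping.summarize_protein_contacts(enriched, matches)
        ranked = mapping.rank_domain_types(matches, region_class="domain")

        released = results[
            (results["tier"] == enrichment.TIER_NS) & (results["log2fc"] < 0)
        ]
        released_matches = mapping.match_peptide_table(released, merged, max_gap=config.max_gap)
        comp_tables = {}
        for cls, label in (("domain", "domain"), ("IDR", "idr")):
            q = enriched.loc[
                enriched.index.isin(matches.loc[matches["region_class"] == cls, "peptide_id"]),
                "sequence",
            ].tolist()
            ref = released.loc[
                released.index.isin(
                    released_matches.loc[released_matches["region_class"] == cls, "peptide_id"]
                ),
                "sequence",
            ].tolist()
            if q and ref:
                comp_tables[f"composition_{label}"] = mapping.composition_enrichment(q, ref)

        matches.to_csv(workdir / "peptide_region_matches.tsv", sep="\t", index=False)
        summary.to_csv(workdir / "protein_contact_summary.tsv", sep="\t")
        ranked.to_csv(workdir / "domain_type_ranking.tsv", sep="\t")
        with open(workdir / "contact_aggregates.json", "w") as fh:
            json.dump(aggregates, fh, indent=2)
        for name, comp in comp_tables.items():
            comp.to_csv(workdir / f"{name}.tsv", sep="\t")
        tables.update(
            {"matches": matches, "contact_summary": summary,
             "domain_type_ranking": ranked, **comp_tables}
        )
    return tables


def _maybe_classify(config, table, results, workdir: Path, log: RunLog) -> dict[str, pd.DataFrame]:
    if not config.annotations:
        return {}
    annotations = io_formats.read_category_annotations(config.annotations)
    keywords = (
        KeywordConfig.from_yaml(config.keyword_config)
        if config.keyword_config else DEFAULT_KEYWORDS
    )
    enriched_ids = results.index[results["tier"] != enrichment.TIER_NS]
    missing = enriched_ids.difference(annotations.index)
    if len(missing):
        logger.warning("classify: %d enriched proteins lack annotations", len(missing))
        extra = pd.DataFrame(
            {"go_terms": [frozenset()] * len(missing), "keywords": [frozenset()] * len(missing)},
            index=missing,
        )
        annotations = pd.concat([annotations, extra])
    categories = categorize_proteins(annotations.loc[enriched_ids], keywords)
    log.record("categorize_proteins", len(enriched_ids), len(categories))
    categories.to_csv(workdir / "protein_categories.tsv", sep="\t")

    out = {"protein_categories": categories}
    ibaq_cols = getattr(table, "ibaq_columns", [])
    if ibaq_cols:
        ibaq = table.data.loc[
            table.data.index.intersection(enriched_ids), ibaq_cols
        ].mean(axis=1, skipna=True)
        if ibaq.notna().any():
            summary = relative_ibaq_summary(ibaq, categories["category3"])
            summary.to_csv(workdir / "category_summary.tsv", sep="\t")
            out["category_summary"] = summary
    return out


def run_pipeline(config: PipelineConfig) -> tuple[dict[str, pd.DataFrame], RunLog]:
    """Run the configured mode end to end; deterministic under (config, seed).

    Outputs are written to ``config.outdir`` atomically; on any mid-run
    failure the partial outputs are removed and the error re-raised.
    """
    log = RunLog()
    outdir = Path(config.outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    tmpdir = Path(tempfile.mkdtemp(prefix=".chromacontact-", dir=outdir.parent))
    try:
        if config.simulate:
            _simulate_inputs(config, tmpdir, log)
        if config.mode in ("space_silac", "comparative_silac"):
            if not config.protein_table:
                raise ConfigurationError("SILAC modes need a protein_table or simulate block")
            tables = _run_silac(config, tmpdir, log)
        elif config.mode in ("sicap_ibaq", "chip_space", "two_group_labelfree"):
            if not config.protein_table:
                raise ConfigurationError("two-group modes need a protein_table or simulate block")
            tables = _run_two_group_protein(config, tmpdir, log)
        else:  # spacemap
            if not config.peptide_table:
                raise ConfigurationError("spacemap mode needs a peptide_table or simulate block")
            tables = _run_spacemap(config, tmpdir, log)
        report = make_report(tables)
        for name, frame in report.items():
            frame.to_csv(tmpdir / f"report_{name}.tsv", sep="\t")
        tables.update({f"report_{k}": v for k, v in report.items()})
        log.to_json(tmpdir / "run_log.json")
        if outdir.exists():
            shutil.rmtree(outdir)
        os.replace(tmpdir, outdir)
    except ChromacontactError:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise
    except Exception:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise
    return tables, log


def make_report(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Summary tables recomputable from the result tables alone.

    Tier counts from the enrichment results, category summaries when
    present, top domain types, and the composition tables.  Missing inputs
    yield a partial report with a warning.
    """
    report: dict[str, pd.DataFrame] = {}
    results = tables.get("enrichment_results", tables.get("peptide_results"))
    if results is None:
        logger.warning("make_report: no enrichment results available")
    else:
        counts = results["tier"].value_counts()
        report["tier_counts"] = (
            counts.reindex(
                [enrichment.TIER_HIGH, enrichment.TIER_SIG, enrichment.TIER_NS],
                fill_value=0,
            )
            .rename_axis("tier")
            .to_frame("n_features")
        )
    if "category_summary" in tables:
        report["category_summary"] = tables["category_summary"]
    if "domain_type_ranking" in tables:
        report["top_domain_types"] = tables["domain_type_ranking"].head(5)
    for key in ("composition_domain", "composition_idr"):
        if key in tables:
            report[key] = tables[key]
    return report
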
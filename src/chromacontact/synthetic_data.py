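"""Synthetic proteomes and quantification tables with known ground truth.

Every downstream stage of the pipeline (filtering, normalization,
imputation, moderated testing, peptide-to-region mapping, classification)
is tested against data generated here, where the set of chromatin-enriched
proteins, their chromatin-contact regions and all effect sizes are planted
and recorded in a :class:`SyntheticTruth` object.

The simulators emulate the experimental designs of crosslinked-chromatin
enrichment studies: forward/reverse SILAC protein-level experiments
(heavy/light ratio centred on 2**effect for a planted protein in a forward
experiment and 2**(-effect) in a reverse experiment), and a two-fraction
peptide-level experiment in which peptides at planted contact regions get
elevated crosslinked-fraction intensities while all other peptides are
elevated in the released fraction.  Noise is log-normal with per-feature
variances drawn from a scaled inverse-chi-square law (prior df ``d0_true``,
prior variance ``s0sq_true``) — the same family the empirical-Bayes
moderation assumes — and cells go missing with probability logistic in
minus log-intensity, so low-abundance features drop out more often.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .io_formats import PeptideQuantTable, ProteinQuantTable, RegionAnnotation

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Approximate UniProt-wide residue frequencies; renormalised in code.
_BACKGROUND = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.022, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.068,
}

# Disordered segments are biased toward the disorder-promoting residues
# P/E/S/G (and depleted in bulky hydrophobics); structured domains are
# biased toward hydrophobics.  The biases are deliberately strong enough
# that composition-enrichment recovery is a meaningful test.
_IDR_BIAS = {"P": 2.6, "E": 2.2, "S": 1.8, "G": 1.6, "Q": 1.3,
             "L": 0.4, "I": 0.4, "V": 0.45, "F": 0.35, "W": 0.3, "C": 0.3, "M": 0.5}
_DOMAIN_BIAS = {"L": 1.5, "V": 1.5, "A": 1.4, "I": 1.5, "F": 1.4,
                "P": 0.6, "E": 0.7, "S": 0.8, "G": 0.8}


def _freqs(bias: dict[str, float] | None = None) -> np.ndarray:
    w = np.array([_BACKGROUND[a] * (bias or {}).get(a, 1.0) for a in AMINO_ACIDS])
    return w / w.sum()

BACKGROUND_FREQS = _freqs()
IDR_FREQS = _freqs(_IDR_BIAS)
DOMAIN_FREQS = _freqs(_DOMAIN_BIAS)

# Fixed per-stage offsets so each stage is independently reproducible from
# the master seed.
_STAGE_OFFSETS = {
    "proteome": 11,
    "space": 23,
    "spacemap": 37,
    "labelfree": 41,
    "annotations": 53,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by a fixed offset."""
    if stage not in _STAGE_OFFSETS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    return (master_seed * 1_000_003 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


class Peptide(NamedTuple):
    """A proteolytic peptide with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    n_missed: int


@dataclass(frozen=True)
class DigestionSpec:
    """Enzyme specificity for in-silico digestion.

    Trypsin/P cleaves C-terminal to K and R (including before proline);
    LysC cleaves C-terminal to K, a subset of the Trypsin/P sites, so the
    union of the two is the Trypsin/P site set.  Default length bounds
    7–35 residues reflect typical MS detectability.
    """

    enzymes: tuple[str, ...] = ("trypsin_P", "lysC")
    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 35

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ConfigurationError("min_length must be <= max_length")
        if self.max_missed_cleavages < 0:
            raise ConfigurationError("max_missed_cleavages must be >= 0")
        unknown = set(self.enzymes) - {"trypsin_P", "lysC"}
        if unknown:
            raise ConfigurationError(f"unknown enzymes: {sorted(unknown)}")

    @property
    def cleavage_residues(self) -> frozenset:
        sites: set[str] = set()
        if "trypsin_P" in self.enzymes:
            sites |= {"K", "R"}
        if "lysC" in self.enzymes:
            sites |= {"K"}
        return frozenset(sites)


def digest(sequence: str, spec: DigestionSpec = DigestionSpec()) -> list[Peptide]:
    """Exhaustive proteolytic digestion of ``sequence``.

    Returns every peptide whose boundaries are valid cleavage sites (or the
    protein termini) with at most ``max_missed_cleavages`` internal sites
    and length within the spec bounds.  Coordinates are 1-based inclusive.
    """
    if not sequence:
        raise DataError("cannot digest an empty sequence")
    sites = spec.cleavage_residues
    n = len(sequence)
    # cut points: index i means a cut between residue i and i+1 (1-based)
    cuts = [i for i in range(1, n) if sequence[i - 1] in sites]
    boundaries = [0] + cuts + [n]
    peptides: list[Peptide] = []
    for i in range(len(boundaries) - 1):
        for missed in range(spec.max_missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(boundaries):
                break
            start, end = boundaries[i] + 1, boundaries[j]
            length = end - start + 1
            if spec.min_length <= length <= spec.max_length:
                peptides.append(
                    Peptide(sequence[start - 1:end], start, end, missed)
                )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


@dataclass
class NoiseModel:
    """Per-feature variance prior and intensity-dependent missingness.

    Feature variances (on the log2 scale) are drawn from a scaled
    inverse-chi-square distribution with ``d0_true`` prior degrees of
    freedom and prior variance ``s0sq_true``; setting ``s0sq_true = 0``
    switches noise off entirely.  A cell with log2 intensity x is missing
    with probability ``p_max / (1 + exp(slope * (x - midpoint)))``.
    """

    d0_true: float = 4.0
    s0sq_true: float = 0.09
    missing_p_max: float = 0.6
    missing_midpoint: float = 21.0
    missing_slope: float = 1.0

    def draw_variances(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.s0sq_true == 0:
            return np.zeros(n)
        chi2 = rng.chisquare(self.d0_true, size=n)
        return self.d0_true * self.s0sq_true / chi2

    def missing_probability(self, log2_intensity: np.ndarray) -> np.ndarray:
        if self.missing_p_max == 0:
            return np.zeros_like(np.asarray(log2_intensity, dtype=float))
        z = self.missing_slope * (np.asarray(log2_intensity, float) - self.missing_midpoint)
        return self.missing_p_max / (1.0 + np.exp(z))


@dataclass
class ProteomeConfig:
    """Layout of the synthetic proteome and the planted ground truth."""

    n_proteins: int = 500
    length_log_mean: float = float(np.log(420.0))
    length_log_sigma: float = 0.35
    min_length: int = 120
    max_length: int = 2500
    max_regions_per_protein: int = 3
    region_length_range: tuple[int, int] = (50, 150)
    region_gap: int = 10
    chromatin_fraction: float = 0.10
    effect_log2fc: float = 2.0
    released_log2fc: float = 1.0
    contact_region_class: str = "IDR"
    contact_length_range: tuple[int, int] = (15, 40)
    rbp_fraction_of_planted: float = 0.5
    base_log2_intensity: float = 25.0
    base_log2_intensity_sd: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study: the recovery oracle.

    ``contact_regions`` always lie inside a planted annotation of the
    configured class; effect sizes of non-planted features are 0.
    """

    seed: int
    config: ProteomeConfig
    chromatin_protein_ids: set[str]
    contact_regions: list[tuple[str, int, int, str]]
    protein_effects: dict[str, float]
    sequences: dict[str, str] = field(repr=False, default_factory=dict)

    def protein_effect(self, protein_id: str) -> float:
        return self.protein_effects.get(protein_id, 0.0)

    def peptide_effect(self, protein_id: str, start: int, end: int,
                       max_gap: int = 10) -> float:
        """Planted crosslink effect for a peptide interval (0 if none).

        A peptide carries the contact effect if it overlaps a planted
        contact region of its protein or lies within ``max_gap`` residues
        of it — the same proximity rule the mapping stage uses.
        """
        for pid, rstart, rend, _cls in self.contact_regions:
            if pid != protein_id:
                continue
            gap = max(0, rstart - end, start - rend)
            if gap <= max_gap:
                return self.config.effect_log2fc
        return 0.0


def _random_sequence(length: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=freqs))


def generate_proteome(
    config: ProteomeConfig = ProteomeConfig(), seed: int = 0
) -> tuple[dict[str, str], list[RegionAnnotation], SyntheticTruth]:
    """Generate protein sequences, domain/IDR annotations and ground truth.

    Each protein gets 0–3 non-overlapping regions; IDR segments are drawn
    with elevated P/E/S/G composition and domains with elevated hydrophobic
    composition.  A ``chromatin_fraction`` of proteins is planted as
    chromatin-enriched; each planted protein is guaranteed one region of
    ``contact_region_class`` containing a planted contact sub-interval.
    Deterministic under ``seed``.
    """
    if config.n_proteins < 1:
        raise ConfigurationError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    n_planted = int(round(config.n_proteins * config.chromatin_fraction))
    planted_idx = set(
        rng.choice(config.n_proteins, size=n_planted, replace=False).tolist()
    )

    sequences: dict[str, str] = {}
    regions: list[RegionAnnotation] = []
    contact_regions: list[tuple[str, int, int, str]] = []
    protein_effects: dict[str, float] = {}
    chromatin_ids: set[str] = set()

    rlo, rhi = config.region_length_range
    clo, chi = config.contact_length_range

    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        length = int(np.clip(
            rng.lognormal(config.length_log_mean, config.length_log_sigma),
            config.min_length, config.max_length,
        ))
        planted = i in planted_idx

        n_regions = int(rng.integers(0, config.max_regions_per_protein + 1))
        if planted:
            n_regions = max(n_regions, 1)

        # lay out non-overlapping regions left to right
        layout: list[tuple[int, int, str]] = []
        cursor = 1
        for k in range(n_regions):
            rlen = int(rng.integers(rlo, rhi + 1))
            max_start = length - rlen + 1
            if cursor > max_start:
                logger.warning(
                    "generate_proteome: %s too short for %d regions, placed %d",
                    pid, n_regions, len(layout),
                )
                break
            start = int(rng.integers(cursor, max_start + 1))
            cls = "IDR" if rng.random() < 0.5 else "domain"
            layout.append((start, start + rlen - 1, cls))
            cursor = start + rlen + config.region_gap
        if planted and not any(c == config.contact_region_class for _, _, c in layout):
            if layout:
                s, e, _ = layout[int(rng.integers(len(layout)))]
                layout = [
                    (s2, e2, config.contact_region_class if (s2, e2) == (s, e) else c2)
                    for s2, e2, c2 in layout
                ]
            else:
                rlen = min(int(rng.integers(rlo, rhi + 1)), length)
                layout = [(1, rlen, config.contact_region_class)]

        # build the sequence segment-wise
        seq_parts: list[str] = []
        pos = 1
        for start, end, cls in layout:
            if start > pos:
                seq_parts.append(_random_sequence(start - pos, BACKGROUND_FREQS, rng))
            freqs = IDR_FREQS if cls == "IDR" else DOMAIN_FREQS
            seq_parts.append(_random_sequence(end - start + 1, freqs, rng))
            pos = end + 1
        if pos <= length:
            seq_parts.append(_random_sequence(length - pos + 1, BACKGROUND_FREQS, rng))
        sequences[pid] = "".join(seq_parts)

        for j, (start, end, cls) in enumerate(layout):
            name = ("Disordered_region" if cls == "IDR" else
                    rng.choice(["RRM_1", "RRM_2", "Helicase_C", "HTH_1", "P-loop_NTPase", "HMG_box"]))
            regions.append(
                RegionAnnotation(
                    region_id=f"{pid}:R{j}",
                    protein_id=pid,
                    start=start,
                    end=end,
                    region_class=cls,
                    name=str(name),
                    source_signature=("mobidb_lite" if cls == "IDR" else f"PF{j:05d}"),
                )
            )

        if planted:
            chromatin_ids.add(pid)
            protein_effects[pid] = config.effect_log2fc
            hosts = [(s, e) for s, e, c in layout if c == config.contact_region_class]
            s, e = hosts[int(rng.integers(len(hosts)))]
            clen = min(int(rng.integers(clo, chi + 1)), e - s + 1)
            cstart = int(rng.integers(s, e - clen + 2))
            contact_regions.append((pid, cstart, cstart + clen - 1, config.contact_region_class))

    truth = SyntheticTruth(
        seed=seed,
        config=config,
        chromatin_protein_ids=chromatin_ids,
        contact_regions=contact_regions,
        protein_effects=protein_effects,
        sequences=sequences,
    )
    return sequences, regions, truth


def simulate_space_experiment(
    truth: SyntheticTruth,
    design: Sequence[tuple[str, str]],
    seed: int = 0,
) -> ProteinQuantTable:
    """Simulate a forward/reverse SILAC protein-level experiment set.

    ``design`` is a list of (orientation, replicate id) pairs with
    orientation ``forward`` (heavy channel crosslinked) or ``reverse``
    (light channel crosslinked).  For a planted protein the heavy/light
    ratio is centred on ``2**effect`` in forward and ``2**(-effect)`` in
    reverse experiments; non-planted proteins are centred on 1.  Per-protein
    log-normal noise and intensity-dependent missingness are applied, and
    per-experiment iBAQ columns are generated.
    """
    if not design:
        raise ConfigurationError("design must be non-empty")
    for orientation, _ in design:
        if orientation not in ("forward", "reverse"):
            raise ConfigurationError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    noise = cfg.noise
    pids = sorted(truth.sequences)
    n = len(pids)
    effects = np.array([truth.protein_effect(p) for p in pids])
    variances = noise.draw_variances(n, rng)
    sd = np.sqrt(variances)

    data = pd.DataFrame(index=pd.Index(pids, name="protein_id"))
    data["gene_name"] = [f"Gene_{p}" for p in pids]
    data["is_reverse_decoy"] = False
    data["is_contaminant"] = False
    data["only_identified_by_site"] = False

    base_abundance = rng.normal(cfg.base_log2_intensity, cfg.base_log2_intensity_sd, n)
    ratio_cols, ibaq_cols = [], []
    for orientation, rep in design:
        sign = 1.0 if orientation == "forward" else -1.0
        eps = rng.normal(0.0, 1.0, n) * sd if variances.any() else np.zeros(n)
        log2_ratio_hl = sign * (effects + eps)
        intensity = base_abundance + rng.normal(0.0, 0.5, n)
        missing = rng.random(n) < noise.missing_probability(intensity)
        ratio = np.power(2.0, log2_ratio_hl)
        ratio[missing] = np.nan
        rcol = f"ratio_{orientation}_{rep}"
        icol = f"ibaq_{orientation}_{rep}"
        data[rcol] = ratio
        ibaq = np.power(2.0, intensity)
        ibaq[missing] = np.nan
        data[icol] = ibaq
        ratio_cols.append(rcol)
        ibaq_cols.append(icol)
    return ProteinQuantTable(data, ratio_columns=ratio_cols, ibaq_columns=ibaq_cols)


def simulate_spacemap_experiment(
    truth: SyntheticTruth,
    peptides: dict[str, list[Peptide]],
    n_replicates: int = 3,
    seed: int = 0,
    max_gap: int = 10,
) -> PeptideQuantTable:
    """Simulate crosslinked/released fraction intensities per peptide.

    Peptides overlapping (or within ``max_gap`` residues of) a planted
    contact region get crosslinked-fraction intensities elevated by the
    planted effect; all other peptides get released-fraction intensities
    elevated by ``released_log2fc``.  Noise and missingness follow the
    truth's noise model.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    noise = cfg.noise

    rows = []
    for pid in sorted(peptides):
        for pep in peptides[pid]:
            rows.append((f"{pid}:{pep.start}-{pep.end}", pid, pep.sequence,
                         pep.start, pep.end))
    if not rows:
        raise DataError("no peptides to simulate")
    data = pd.DataFrame(
        rows, columns=["peptide_id", "protein_id", "sequence", "start", "end"]
    ).drop_duplicates("peptide_id").set_index("peptide_id")

    n = len(data)
    effect = np.array([
        truth.peptide_effect(r.protein_id, r.start, r.end, max_gap=max_gap)
        for r in data.itertuples()
    ])
    is_contact = effect > 0
    variances = noise.draw_variances(n, rng)
    sd = np.sqrt(variances)
    base = rng.normal(cfg.base_log2_intensity, cfg.base_log2_intensity_sd, n)

    cross_mean = base + np.where(is_contact, effect, 0.0)
    rel_mean = base + np.where(is_contact, 0.0, cfg.released_log2fc)

    fraction_columns: dict[str, list[str]] = {"crosslinked": [], "released": []}
    for fraction, mean in (("crosslinked", cross_mean), ("released", rel_mean)):
        for rep in range(1, n_replicates + 1):
            eps = rng.normal(0.0, 1.0, n) * sd if variances.any() else np.zeros(n)
            log2_int = mean + eps
            missing = rng.random(n) < noise.missing_probability(log2_int)
            values = np.power(2.0, log2_int)
            values[missing] = np.nan
            col = f"intensity_{fraction}_{rep}"
            data[col] = values
            fraction_columns[fraction].append(col)
    return PeptideQuantTable(data, fraction_columns=fraction_columns)


def simulate_labelfree_experiment(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    seed: int = 0,
    condition_names: tuple[str, str] = ("crosslinked", "control"),
) -> ProteinQuantTable:
    """Simulate a two-group label-free iBAQ experiment at protein level.

    Planted proteins have iBAQ elevated by their effect in the first
    condition; used for double-purification and ChIP-style two-group modes.
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    noise = cfg.noise
    pids = sorted(truth.sequences)
    n = len(pids)
    effects = np.array([truth.protein_effect(p) for p in pids])
    sd = np.sqrt(noise.draw_variances(n, rng))
    base = rng.normal(cfg.base_log2_intensity, cfg.base_log2_intensity_sd, n)

    data = pd.DataFrame(index=pd.Index(pids, name="protein_id"))
    data["gene_name"] = [f"Gene_{p}" for p in pids]
    data["is_reverse_decoy"] = False
    data["is_contaminant"] = False
    data["only_identified_by_site"] = False
    ibaq_cols = []
    for cond, shift in ((condition_names[0], effects), (condition_names[1], 0.0)):
        for rep in range(1, n_replicates + 1):
            eps = rng.normal(0.0, 1.0, n) * sd if sd.any() else np.zeros(n)
            log2_int = base + shift + eps
            missing = rng.random(n) < noise.missing_probability(log2_int)
            values = np.power(2.0, log2_int)
            values[missing] = np.nan
            col = f"ibaq_{cond}_{rep}"
            data[col] = values
            ibaq_cols.append(col)
    return ProteinQuantTable(data, ratio_columns=[], ibaq_columns=ibaq_cols)


# GO terms used by the annotation generator; planted chromatin proteins are
# guaranteed a chromatin-binding term so categorization recall is 1 by
# construction (a config sanity check, not a biological claim).
_CHROMATIN_TERMS = frozenset({"chromatin binding", "DNA binding", "nucleus"})
_NUCLEAR_TERMS = frozenset({"nucleus", "RNA processing"})
_CYTO_TERM_SETS = (
    frozenset({"translation", "cytoplasm"}),
    frozenset({"metabolic process", "cytoplasm"}),
    frozenset({"cell adhesion"}),
    frozenset({"protein folding", "cytoplasm"}),
    frozenset({"protein transport"}),
)


def generate_annotations(truth: SyntheticTruth, seed: int = 0) -> pd.DataFrame:
    """Generate GO-style annotations consistent with the planted truth.

    Planted chromatin proteins receive chromatin-binding GO terms; a
    configured fraction of them are additionally RNA binding.  Non-planted
    proteins split between nuclear and cytoplasmic term sets.
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    rows = []
    for pid in sorted(truth.sequences):
        if pid in truth.chromatin_protein_ids:
            terms = set(_CHROMATIN_TERMS)
            if rng.random() < cfg.rbp_fraction_of_planted:
                terms.add("RNA binding")
        elif rng.random() < 0.5:
            terms = set(_NUCLEAR_TERMS)
            if rng.random() < 0.3:
                terms.add("RNA binding")
        else:
            terms = set(_CYTO_TERM_SETS[int(rng.integers(len(_CYTO_TERM_SETS)))])
        rows.append((pid, frozenset(terms), frozenset()))
    out = pd.DataFrame(rows, columns=["protein_id", "go_terms", "keywords"])
    return out.set_index("protein_id")


def digest_proteome(
    sequences: dict[str, str], spec: DigestionSpec = DigestionSpec()
) -> dict[str, list[Peptide]]:
    """Digest every protein; convenience wrapper over :func:`digest`."""
    return {pid: digest(seq, spec) for pid, seq in sequences.items()}
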
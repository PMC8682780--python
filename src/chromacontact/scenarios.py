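"""Packaged synthetic scenarios.

The reference recovery scenario mirrors the study design at desk scale:
500 proteins, 10% planted chromatin-binders whose contact regions lie in
IDRs, a planted enrichment of log2FC = 2, SILAC protein-level experiments
(three forward + three reverse) and three replicates per fraction at the
peptide level.  Both the test suite and the reproduction script drive the
pipeline through these configurations.
"""

from __future__ import annotations

from .pipeline import PipelineConfig

RECOVERY_N_PROTEINS = 500
RECOVERY_CHROMATIN_FRACTION = 0.10
RECOVERY_EFFECT_LOG2FC = 2.0
RECOVERY_DESIGN = [
    ["forward", "1"], ["forward", "2"], ["forward", "3"],
    ["reverse", "1"], ["reverse", "2"], ["reverse", "3"],
]


def _simulate_block() -> dict:
    return {
        "n_proteins": RECOVERY_N_PROTEINS,
        "chromatin_fraction": RECOVERY_CHROMATIN_FRACTION,
        "effect_log2fc": RECOVERY_EFFECT_LOG2FC,
        "contact_region_class": "IDR",
        "n_replicates": 3,
        "design": [list(d) for d in RECOVERY_DESIGN],
    }


def recovery_protein_scenario(outdir, seed: int) -> PipelineConfig:
    """Protein-level forward/reverse SILAC recovery scenario."""
    return PipelineConfig(
        mode="space_silac", outdir=str(outdir), seed=seed,
        simulate=_simulate_block(),
    )


def recovery_peptide_scenario(outdir, seed: int) -> PipelineConfig:
    """Peptide-level crosslinked/released fraction recovery scenario."""
    return PipelineConfig(
        mode="spacemap", outdir=str(outdir), seed=seed,
        simulate=_simulate_block(),
    )
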
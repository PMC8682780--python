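"""Worked-example fixtures: pluripotency factors with known contact regions.

UniProt coordinates of the DNA-binding domains of mouse Oct4 (Pou5f1),
Nanog and Sox2, together with the peptides observed enriched in the
crosslinked fraction of the two-step digestion experiment.  These encode
the published assignments: both Oct4 crosslinked peptides overlap the
POU-specific domain; all three Nanog crosslinked peptides fall in the IDR
N-terminal of the homeodomain (51–66 lies well outside the 10-residue
allowance, 76–87 and 76–89 are proximal to it); Sox2 peptide 83–97
overlaps the HMG box while 274–293 lies in the C-terminal IDR.
"""

from __future__ import annotations

from .io_formats import RegionAnnotation

OCT4 = "Oct4"
NANOG = "Nanog"
SOX2 = "Sox2"

# DNA-binding domains (UniProt coordinates, 1-based inclusive).
DOMAIN_REGIONS = {
    OCT4: RegionAnnotation(
        region_id="Oct4:POU_specific", protein_id=OCT4, start=131, end=205,
        region_class="domain", name="POU-specific", source_signature="PF00157",
    ),
    NANOG: RegionAnnotation(
        region_id="Nanog:Homeobox", protein_id=NANOG, start=96, end=155,
        region_class="domain", name="Homeobox", source_signature="PF00046",
    ),
    SOX2: RegionAnnotation(
        region_id="Sox2:HMG_box", protein_id=SOX2, start=43, end=111,
        region_class="domain", name="HMG_box", source_signature="PF00505",
    ),
}

# IDR annotations adjacent to / outside the domains, covering the regions
# the narrative assigns the non-domain crosslinked peptides to.
IDR_REGIONS = {
    NANOG: RegionAnnotation(
        region_id="Nanog:IDR_N", protein_id=NANOG, start=1, end=95,
        region_class="IDR", name="Disordered_N", source_signature="mobidb_lite",
    ),
    SOX2: RegionAnnotation(
        region_id="Sox2:IDR_C", protein_id=SOX2, start=235, end=319,
        region_class="IDR", name="Disordered_C", source_signature="mobidb_lite",
    ),
}

# Crosslinked-fraction-enriched peptides: (peptide_id, start, end).
CROSSLINKED_PEPTIDES = {
    OCT4: [("Oct4:151-170", 151, 170), ("Oct4:180-188", 180, 188)],
    NANOG: [("Nanog:51-66", 51, 66), ("Nanog:76-87", 76, 87), ("Nanog:76-89", 76, 89)],
    SOX2: [("Sox2:83-97", 83, 97), ("Sox2:274-293", 274, 293)],
}

ALL_REGIONS = list(DOMAIN_REGIONS.values()) + list(IDR_REGIONS.values())
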
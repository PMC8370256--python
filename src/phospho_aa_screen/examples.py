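"""Worked-example data: a goat fetal fibroblast amino-acid signaling screen.

Small published summary tables from a five-condition phosphoproteomics
experiment (non-treated, serum-starved, amino-acid-starved, leucine
restimulated, all-amino-acid restimulated goat fetal fibroblasts).
They serve as ready-made inputs for the screening operations: the
fold-change rows feed frame classification directly, and the count
tables feed the percentage and multiplicity summaries.

Protein accessions use the ``chx:`` (Capra hircus) prefix; site tokens
are ``Ser722``-style residue+position labels.
"""

from __future__ import annotations

from .frame_screen import (
    CONTRAST_AAS_SS,
    CONTRAST_ALLS_AAS,
    CONTRAST_LEUS_AAS,
    ContrastRatio,
)
from .quant_io import SiteKey, parse_site_token

#: Phosphosites responding to the leucine signal:
#: (protein name, accession, site token, fc AAS/SS, fc LeuS/AAS).
LEUCINE_RESPONSE_SITES: tuple[tuple[str, str, str, float, float], ...] = (
    ("EPB41L2", "chx:102190693", "Ser722", 2.35, 0.06),
    ("SRRM1", "chx:102175909", "Thr220", 2.26, 0.11),
    ("HSP90A", "chx:100860851", "Ser252", 0.01, 6.11),
    ("CALD1", "chx:102188560", "Ser784", 0.22, 2.33),
)

#: Phosphosites strongly responding to the all-amino-acid signal
#: (|log10 FC| > 1 tier): (protein name, accession, site token,
#: fc AAS/SS, fc AllS/AAS).
ALL_AA_RESPONSE_SITES: tuple[tuple[str, str, str, float, float], ...] = (
    ("AAK1", "chx:102187599", "Ser646", 0.02, 41.89),
    ("AIM1", "chx:102180395", "Ser1499", 0.06, 14.38),
    ("MAP1", "chx:102176074", "Ser1782", 0.02, 33.16),
    ("MAP1", "chx:102176074", "Ser1779", 0.04, 16.53),
    ("BCLAF1", "chx:102180497", "Ser512", 0.02, 26.17),
    ("CCDC6", "chx:102172968", "Ser246", 0.06, 24.07),
    ("CCDC6", "chx:102172968", "Ser242", 0.06, 14.31),
    ("FLNA", "chx:102176601", "Ser969", 0.08, 13.53),
    ("HSP90A", "chx:100860851", "Ser252", 0.01, 23.49),
    ("HSP90A", "chx:100860851", "Ser231", 0.08, 12.89),
    ("MAPK1", "chx:102186040", "Tyr187", 0.06, 12.80),
    ("MYH10", "chx:102177371", "Ser1987", 0.05, 16.61),
    ("PDXDC1", "chx:102176932", "Thr688", 0.02, 44.23),
    ("STMN1", "chx:102173139", "Ser25", 0.02, 113.30),
    ("TGFB1I1", "chx:100861032", "Ser173", 0.04, 147.26),
    ("TGFB1I1", "chx:100861032", "Ser167", 0.02, 11.80),
    ("TGFB1I1", "chx:100861032", "Ser171", 0.02, 10.71),
)

#: Phosphosites-per-protein histogram of the all-amino-acid-responsive
#: set: {sites per protein: number of proteins}.
AA_RESPONSIVE_MULTIPLICITY: dict[int, int] = {7: 1, 4: 3, 3: 6, 2: 15, 1: 77}

#: Per-condition (phosphopeptides, total peptides) counts.
PEPTIDE_COUNTS: dict[str, tuple[int, int]] = {
    "NT": (2102, 3631),
    "SS": (2657, 5806),
    "AAS": (337, 528),
    "LeuS": (127, 202),
    "AllS": (1727, 2958),
}

#: Per-condition (phosphoproteins, total proteins) counts.
PROTEIN_COUNTS: dict[str, tuple[int, int]] = {
    "NT": (881, 1230),
    "SS": (925, 1461),
    "AAS": (184, 266),
    "LeuS": (72, 112),
    "AllS": (702, 989),
}

#: Per-condition unique-phosphosite counts by residue class.
RESIDUE_COMPOSITION: dict[str, dict[str, int]] = {
    "NT": {"S": 1267, "T": 135, "Y": 5},
    "SS": {"S": 1396, "T": 170, "Y": 7},
    "AAS": {"S": 242, "T": 24, "Y": 3},
    "LeuS": {"S": 86, "T": 12, "Y": 0},
    "AllS": {"S": 1011, "T": 111, "Y": 7},
}

#: Residue composition of the all-amino-acid-responsive site set.
AA_RESPONSIVE_COMPOSITION: dict[str, int] = {"S": 134, "T": 8, "Y": 2}


def _site_key(accession: str, token: str) -> SiteKey:
    residue, position = parse_site_token(token)
    return SiteKey(protein_id=accession, residue=residue, position=position)


def leucine_response_ratios() -> list[ContrastRatio]:
    """The leucine-response rows as contrast ratios (both contrasts)."""
    ratios = []
    for _, accession, token, fc_aas_ss, fc_leus_aas in LEUCINE_RESPONSE_SITES:
        site = _site_key(accession, token)
        ratios.append(ContrastRatio(site=site, contrast=CONTRAST_AAS_SS, fc=fc_aas_ss))
        ratios.append(ContrastRatio(site=site, contrast=CONTRAST_LEUS_AAS, fc=fc_leus_aas))
    return ratios


def all_aa_response_ratios() -> list[ContrastRatio]:
    """The all-amino-acid-response rows as contrast ratios (both contrasts)."""
    ratios = []
    for _, accession, token, fc_aas_ss, fc_alls_aas in ALL_AA_RESPONSE_SITES:
        site = _site_key(accession, token)
        ratios.append(ContrastRatio(site=site, contrast=CONTRAST_AAS_SS, fc=fc_aas_ss))
        ratios.append(ContrastRatio(site=site, contrast=CONTRAST_ALLS_AAS, fc=fc_alls_aas))
    return ratios
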
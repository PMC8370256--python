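"""The core screening procedure: contrast ratios and frame classification.

Sites quantified in both conditions of a contrast get a fold change
(numerator / denominator).  Sites are then binned into four "frames" by
how they respond to amino-acid starvation and restimulation:

* Frame 1 - phosphorylation up under amino-acid starvation (AAS vs SS)
  and down under leucine restimulation (LeuS vs AAS): negatively
  regulated by leucine.
* Frame 2 - down under starvation, up under leucine: positively
  regulated by leucine.
* Frame 3 - up under starvation, down under all-amino-acid
  restimulation (AllS vs AAS): negatively regulated by amino acids.
* Frame 4 - down under starvation, up under all-amino-acid
  restimulation: positively regulated by amino acids.

The default thresholds are fold change > 2 ("up") or < 0.5 ("down"),
i.e. |log2 FC| > 1, with strict inequalities.  A stricter tier keeps
only sites with |log10 FC| > 1 (10x in both defining contrasts).
Frames are not mutually exclusive: one site may satisfy several rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .quant_io import PhosphoPeptideRecord, SiteKey
from .site_assembly import (
    NormalizationMethod,
    SiteQuantTable,
    filter_reliable,
    merge_to_sites,
    normalize,
)

logger = logging.getLogger(__name__)

Contrast = tuple[str, str]  # (numerator condition, denominator condition)

#: The three contrasts of the five-condition design.
CONTRAST_AAS_SS: Contrast = ("AAS", "SS")
CONTRAST_LEUS_AAS: Contrast = ("LeuS", "AAS")
CONTRAST_ALLS_AAS: Contrast = ("AllS", "AAS")
STANDARD_CONTRASTS: tuple[Contrast, ...] = (
    CONTRAST_AAS_SS,
    CONTRAST_LEUS_AAS,
    CONTRAST_ALLS_AAS,
)


@dataclass(frozen=True)
class FrameRule:
    """A frame's defining contrasts: one must be up, the other down."""

    up: Contrast
    down: Contrast


FRAME_RULES: Mapping[int, FrameRule] = {
    1: FrameRule(up=CONTRAST_AAS_SS, down=CONTRAST_LEUS_AAS),
    2: FrameRule(up=CONTRAST_LEUS_AAS, down=CONTRAST_AAS_SS),
    3: FrameRule(up=CONTRAST_AAS_SS, down=CONTRAST_ALLS_AAS),
    4: FrameRule(up=CONTRAST_ALLS_AAS, down=CONTRAST_AAS_SS),
}


@dataclass(frozen=True)
class ContrastRatio:
    """Fold change of one site in one condition contrast."""

    site: SiteKey
    contrast: Contrast
    fc: float

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ValueError("fold change must be positive")


@dataclass(frozen=True)
class SharedSites:
    """Sites present in both conditions of a pair, with the protein count."""

    sites: frozenset[str]
    n_proteins: int


def intersect_sites(table: SiteQuantTable, cond_a: str, cond_b: str) -> SharedSites:
    """Sites with a present, positive cell in both conditions.

    Also reports the number of distinct proteins carrying at least one
    shared site (the unit used by Venn-style protein overlaps).
    """
    shared = table.present_sites(cond_a) & table.present_sites(cond_b)
    proteins = {site.rpartition(":")[0] for site in shared}
    return SharedSites(sites=frozenset(shared), n_proteins=len(proteins))


def compute_ratios(table: SiteQuantTable, contrast: Contrast) -> list[ContrastRatio]:
    """Fold changes numerator/denominator over the intersected sites.

    Zero abundances are treated as absent (a zero denominator would give
    an infinite fold change), so only sites positive in both conditions
    contribute.  Output is sorted by site key for determinism.
    """
    numerator, denominator = contrast
    shared = intersect_sites(table, numerator, denominator).sites
    ratios = [
        ContrastRatio(
            site=SiteKey.from_string(site),
            contrast=contrast,
            fc=table.cell(site, numerator) / table.cell(site, denominator),
        )
        for site in sorted(shared)
    ]
    return ratios


@dataclass(frozen=True)
class FrameAssignment:
    """A site's frame memberships and the fold changes behind them."""

    site: SiteKey
    frames: frozenset[int]
    fc: Mapping[Contrast, float]
    top_flag: bool

    @property
    def fc_aas_ss(self) -> float | None:
        return self.fc.get(CONTRAST_AAS_SS)

    @property
    def fc_leus_aas(self) -> float | None:
        return self.fc.get(CONTRAST_LEUS_AAS)

    @property
    def fc_alls_aas(self) -> float | None:
        return self.fc.get(CONTRAST_ALLS_AAS)


def _passes_top(
    fc: Mapping[Contrast, float], rule: FrameRule, log10_threshold: float
) -> bool:
    up, down = fc.get(rule.up), fc.get(rule.down)
    if up is None or down is None:
        return False
    return up > 10.0**log10_threshold and down < 10.0**-log10_threshold


def assign_frames(
    ratios: Iterable[ContrastRatio],
    theta_up: float = 2.0,
    theta_down: float = 0.5,
    log10_threshold: float = 1.0,
) -> list[FrameAssignment]:
    """Classify sites into frames 1-4 from their contrast fold changes.

    ``ratios`` may mix all three contrasts; they are grouped per site.
    Each site receives every frame whose rule it satisfies (strict
    inequalities); sites satisfying no rule are omitted.  ``top_flag``
    marks sites passing the stricter |log10 FC| > ``log10_threshold``
    tier for at least one of their frames.
    """
    if not (theta_up > 1.0 > theta_down > 0.0):
        raise ValueError("need theta_up > 1 > theta_down > 0")
    fc_by_site: dict[SiteKey, dict[Contrast, float]] = {}
    for ratio in ratios:
        fc_by_site.setdefault(ratio.site, {})[ratio.contrast] = ratio.fc

    assignments: list[FrameAssignment] = []
    for site in sorted(fc_by_site):
        fc = fc_by_site[site]
        frames = frozenset(
            number
            for number, rule in FRAME_RULES.items()
            if rule.up in fc
            and rule.down in fc
            and fc[rule.up] > theta_up
            and fc[rule.down] < theta_down
        )
        if not frames:
            continue
        top = any(
            _passes_top(fc, FRAME_RULES[number], log10_threshold) for number in frames
        )
        assignments.append(
            FrameAssignment(site=site, frames=frames, fc=dict(fc), top_flag=top)
        )
    return assignments


@dataclass(frozen=True)
class TopSubset:
    """The |log10 FC| tier of one frame, with its distinct-protein count."""

    frame: int
    assignments: tuple[FrameAssignment, ...]
    n_proteins: int


def top_subset(
    assignments: Sequence[FrameAssignment],
    frame: int,
    log10_threshold: float = 1.0,
) -> TopSubset:
    """Sites of ``frame`` whose defining fold changes both exceed 10x.

    Keeps assignments with ``frame`` in their memberships whose up-contrast
    fold change is > ``10**log10_threshold`` and down-contrast fold change
    is < ``10**-log10_threshold``.
    """
    if frame not in FRAME_RULES:
        raise ValueError(f"frame must be one of {sorted(FRAME_RULES)}")
    rule = FRAME_RULES[frame]
    selected = tuple(
        a
        for a in assignments
        if frame in a.frames and _passes_top(a.fc, rule, log10_threshold)
    )
    proteins = {a.site.protein_id for a in selected}
    return TopSubset(frame=frame, assignments=selected, n_proteins=len(proteins))


def screen_records(
    records: Sequence[PhosphoPeptideRecord],
    min_reliability: float = 0.75,
    normalization: NormalizationMethod = "median",
    theta_up: float = 2.0,
    theta_down: float = 0.5,
    log10_threshold: float = 1.0,
    contrasts: Sequence[Contrast] = STANDARD_CONTRASTS,
) -> tuple[SiteQuantTable, dict[Contrast, list[ContrastRatio]], list[FrameAssignment]]:
    """Run the whole screen on peptide records.

    Convenience composition of reliability filtering, site merging,
    normalization, ratio computation over the standard contrasts and
    frame assignment.  Returns the normalized site table, the ratios per
    contrast, and the frame assignments.
    """
    reliable = filter_reliable(records, min_reliability=min_reliability)
    table = normalize(merge_to_sites(reliable), method=normalization)
    available = set(table.conditions)
    ratios = {
        contrast: compute_ratios(table, contrast)
        for contrast in contrasts
        if set(contrast) <= available
    }
    flat = [r for contrast_ratios in ratios.values() for r in contrast_ratios]
    assignments = assign_frames(
        flat,
        theta_up=theta_up,
        theta_down=theta_down,
        log10_threshold=log10_threshold,
    )
    return table, ratios, assignments


def assignments_to_rows(assignments: Sequence[FrameAssignment]) -> list[dict]:
    """Flatten assignments into one row per (frame, site) for TSV output."""
    rows = []
    for a in assignments:
        for frame in sorted(a.frames):
            rows.append(
                {
                    "frame": frame,
                    "protein_id": a.site.protein_id,
                    "site": a.site.token,
                    "site_key": str(a.site),
                    "fc_aas_ss": a.fc_aas_ss,
                    "fc_leus_aas": a.fc_leus_aas,
                    "fc_alls_aas": a.fc_alls_aas,
                    "top_flag": a.top_flag,
                }
            )
    return rows
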
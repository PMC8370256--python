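"""Collapse peptide-level records into residue-level phosphosite abundances.

Several quantified peptides can cover the same phosphosite (missed
cleavages, charge states, redundant exports).  This module removes
unreliable and exactly duplicated records, merges what remains to one
abundance per (site, condition), and normalizes per condition.

Merging uses the SUM of contributing peptide abundances by default: it
preserves the total signal attributed to a site and is the common
convention for site-level collapsing (configurable to the mean).  A
peptide carrying several phosphosites contributes its full abundance to
each site it covers; sites are counted, not fractionally occupied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .quant_io import PhosphoPeptideRecord, SiteKey
from .summary_stats import percent

logger = logging.getLogger(__name__)

MergeStatistic = Literal["sum", "mean"]
NormalizationMethod = Literal["median", "total", "none"]


class SiteConsistencyError(ValueError):
    """Two records disagree on the residue letter at one (protein, position)."""


class NormalizationError(ValueError):
    """A condition column cannot be normalized (no positive cells)."""


class SiteQuantTable:
    """Residue-level phosphosite abundances: sites x conditions.

    ``abundance`` is a DataFrame indexed by canonical site keys
    (``protein:S25``-style strings) with one column per condition; NaN
    means the site was not observed in that condition.  ``residues`` maps
    each site key to its S/T/Y class.
    """

    def __init__(self, abundance: pd.DataFrame, residues: pd.Series):
        if not abundance.index.equals(residues.index):
            residues = residues.reindex(abundance.index)
        if residues.isna().any():
            raise ValueError("every site needs a residue class")
        self.abundance = abundance.astype(float)
        self.residues = residues.astype(str)

    @property
    def conditions(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.abundance.index)

    def site_keys(self) -> list[SiteKey]:
        return [SiteKey.from_string(s) for s in self.sites]

    def present_sites(self, condition: str) -> set[str]:
        """Sites with a present, positive cell in ``condition``."""
        if condition not in self.abundance.columns:
            raise KeyError(f"unknown condition {condition!r}")
        col = self.abundance[condition]
        return set(col.index[col.notna() & (col > 0)])

    def cell(self, site: str, condition: str) -> float:
        return float(self.abundance.at[site, condition])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteQuantTable):
            return NotImplemented
        return self.abundance.equals(other.abundance) and self.residues.equals(
            other.residues
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.abundance.copy()
        out.insert(0, "residue", self.residues)
        out.to_csv(path, sep="\t", index_label="site_key", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteQuantTable":
        frame = pd.read_csv(path, sep="\t", index_col="site_key")
        residues = frame.pop("residue")
        return cls(frame, residues)


def filter_reliable(
    records: Sequence[PhosphoPeptideRecord],
    min_reliability: float = 0.75,
    missing_policy: Literal["keep", "drop"] = "keep",
) -> list[PhosphoPeptideRecord]:
    """Drop records whose reliability score falls below ``min_reliability``.

    Records without a score are kept or dropped according to
    ``missing_policy`` (default: keep, since an absent score is not
    evidence against the record).
    """
    if not 0.0 <= min_reliability <= 1.0:
        raise ValueError("min_reliability must lie in [0, 1]")
    kept: list[PhosphoPeptideRecord] = []
    for record in records:
        if record.reliability is None:
            if missing_policy == "keep":
                kept.append(record)
        elif record.reliability >= min_reliability:
            kept.append(record)
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_reliable: removed %d of %d records", removed, len(records))
    return kept


def _dedupe(records: Iterable[PhosphoPeptideRecord]) -> list[PhosphoPeptideRecord]:
    # Exact duplicates (same condition, peptide, protein, positions and
    # abundance) are redundant exports of one observation; keep one.
    seen: set[tuple] = set()
    unique: list[PhosphoPeptideRecord] = []
    for rec in records:
        key = (
            rec.condition,
            rec.peptide,
            rec.protein_id,
            rec.mod_positions,
            rec.residues,
            rec.abundance,
        )
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return unique


def merge_to_sites(
    records: Sequence[PhosphoPeptideRecord],
    statistic: MergeStatistic = "sum",
) -> SiteQuantTable:
    """Merge peptide records covering the same phosphosite per condition.

    Exact duplicate records are collapsed first; a multi-site peptide
    contributes to every site it covers.  Conflicting residue letters at
    one (protein, position) raise :class:`SiteConsistencyError`.
    """
    records = _dedupe(records)
    residue_at: dict[tuple[str, int], str] = {}
    values: dict[tuple[str, str], list[float]] = {}
    conditions: list[str] = []
    for rec in records:
        if rec.condition not in conditions:
            conditions.append(rec.condition)
        for site in rec.sites:
            anchor = (site.protein_id, site.position)
            known = residue_at.setdefault(anchor, site.residue)
            if known != site.residue:
                raise SiteConsistencyError(
                    f"{site.protein_id} position {site.position}: residue "
                    f"{site.residue!r} conflicts with {known!r}"
                )
            values.setdefault((str(site), rec.condition), []).append(rec.abundance)

    site_keys = sorted(
        {f"{prot}:{res}{pos}" for (prot, pos), res in residue_at.items()}
    )
    abundance = pd.DataFrame(np.nan, index=site_keys, columns=conditions)
    for (site, condition), cell_values in values.items():
        total = sum(cell_values)
        abundance.at[site, condition] = (
            total if statistic == "sum" else total / len(cell_values)
        )
    residues = pd.Series(
        {f"{prot}:{res}{pos}": res for (prot, pos), res in residue_at.items()}
    ).reindex(site_keys)
    return SiteQuantTable(abundance, residues)


def normalize(
    table: SiteQuantTable, method: NormalizationMethod = "median"
) -> SiteQuantTable:
    """Scale each condition column to a common level.

    ``median``: divide by the column's median positive cell (the median
    becomes 1); ``total``: divide by the column sum; ``none``: identity.
    """
    if method == "none":
        return SiteQuantTable(table.abundance.copy(), table.residues.copy())
    scaled = table.abundance.copy()
    for condition in scaled.columns:
        col = scaled[condition]
        positive = col[col > 0]
        if positive.empty:
            raise NormalizationError(
                f"condition {condition!r} has no positive cells to normalize"
            )
        divisor = positive.median() if method == "median" else positive.sum()
        scaled[condition] = col / divisor
    return SiteQuantTable(scaled, table.residues.copy())


@dataclass(frozen=True)
class CompositionSummary:
    """Residue-class composition of the sites observed in one condition."""

    condition: str
    counts: dict[str, int]          # residue class -> number of sites
    percentages: dict[str, float]   # residue class -> half-up 2-decimal %
    n_sites: int
    n_proteins: int


def composition_summary(table: SiteQuantTable, condition: str) -> CompositionSummary:
    """Counts and percentages of S/T/Y sites, and distinct proteins, in one condition."""
    present = table.present_sites(condition)
    counts = {"S": 0, "T": 0, "Y": 0}
    proteins: set[str] = set()
    for site in present:
        counts[str(table.residues[site])] += 1
        protein_id, _, _ = site.rpartition(":")
        proteins.add(protein_id)
    n_sites = len(present)
    percentages = {
        res: (percent(n, n_sites) if n_sites else 0.0) for res, n in counts.items()
    }
    return CompositionSummary(
        condition=condition,
        counts=counts,
        percentages=percentages,
        n_sites=n_sites,
        n_proteins=len(proteins),
    )
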
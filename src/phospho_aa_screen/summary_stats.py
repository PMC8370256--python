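"""Descriptive summaries of a phosphosite screen.

Percentages throughout the package are rounded half-up to two decimals
(so complementary percentages sum to 100 within +/- 0.02), matching the
convention of the tabulated summaries this pipeline reproduces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .frame_screen import ContrastRatio, FrameAssignment


def percent(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals.

    Half-up (not banker's) rounding is used so that e.g. 0.125 -> 0.13.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator must be non-zero")
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class UpDownCounts:
    """Counts of up- and down-regulated sites in one condition contrast."""

    n_up: int
    n_down: int


def updown_counts(
    ratios: Iterable["ContrastRatio"],
    theta_up: float = 2.0,
    theta_down: float = 0.5,
) -> UpDownCounts:
    """Count sites with fold change above ``theta_up`` / below ``theta_down``.

    Inequalities are strict: a fold change sitting exactly on a threshold
    is neither up nor down.
    """
    n_up = n_down = 0
    for ratio in ratios:
        if ratio.fc > theta_up:
            n_up += 1
        elif ratio.fc < theta_down:
            n_down += 1
    return UpDownCounts(n_up=n_up, n_down=n_down)


@dataclass(frozen=True)
class MultiplicityDistribution:
    """Histogram of distinct phosphosites per protein.

    ``counts[k]`` is the number of proteins carrying exactly ``k`` sites.
    """

    counts: Mapping[int, int]

    @property
    def total_sites(self) -> int:
        return sum(k * n for k, n in self.counts.items())

    @property
    def total_proteins(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        if any(k < 1 or n < 0 for k, n in self.counts.items()):
            raise ValueError("multiplicities must be >= 1 with counts >= 0")


def multiplicity(assignments: Sequence["FrameAssignment"]) -> MultiplicityDistribution:
    """Distribution of distinct sites per protein over a list of assignments.

    Distinctness is at the (protein, residue, position) level, so the same
    site listed twice contributes once.
    """
    sites_per_protein: dict[str, set[str]] = {}
    for assignment in assignments:
        site = assignment.site
        sites_per_protein.setdefault(site.protein_id, set()).add(str(site))
    histogram = Counter(len(sites) for sites in sites_per_protein.values())
    return MultiplicityDistribution(counts=dict(histogram))


def shared_protein_count(site_keys: Iterable) -> int:
    """Number of distinct proteins carrying at least one of the given sites."""
    return len({getattr(k, "protein_id", None) or _protein_of(str(k)) for k in site_keys})


def _protein_of(site_key_text: str) -> str:
    protein_id, _, _ = site_key_text.rpartition(":")
    return protein_id
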
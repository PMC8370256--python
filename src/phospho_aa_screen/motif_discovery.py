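"""Sequence-window extraction and iterative motif discovery.

Windows are fixed-width (default 13 residues) stretches of protein
sequence centered on a phosphosite, padded with ``_`` past the protein
termini.  Motifs are found with the motif-x strategy: repeatedly fix
the (position, residue) pair with the most extreme binomial enrichment
of the foreground over the background, restrict both sets to matching
windows, and once no pair passes the significance and occurrence
thresholds, emit the motif, remove its windows and start over.  Motif
classes are therefore disjoint, so their proportions of the original
foreground sum to at most 100%.

Padded positions are excluded from the binomial counting on both sides:
a window padded at some offset contributes neither a trial nor a
success there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .quant_io import PHOSPHO_RESIDUES, SiteKey
from .summary_stats import percent

logger = logging.getLogger(__name__)

PAD = "_"
WILDCARD = "x"
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-width window of protein sequence centered on a phosphosite."""

    site: SiteKey
    window: str

    def __post_init__(self) -> None:
        center = len(self.window) // 2
        if len(self.window) % 2 == 0:
            raise ValueError("window width must be odd")
        if self.window[center] != self.site.residue:
            raise ValueError(
                f"window center {self.window[center]!r} does not match site "
                f"residue {self.site.residue!r}"
            )


def extract_windows(
    sites: Iterable[SiteKey],
    proteome: Mapping[str, str],
    width: int = 13,
) -> list[SequenceWindow]:
    """Extract termini-padded windows around sites from a proteome.

    Sites whose protein is missing from the proteome, whose position
    falls outside the sequence, or whose recorded residue disagrees with
    the sequence are skipped with a logged warning.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be a positive odd number")
    flank = width // 2
    windows: list[SequenceWindow] = []
    for site in sites:
        sequence = proteome.get(site.protein_id)
        if sequence is None:
            logger.warning("site %s: protein not in proteome; skipped", site)
            continue
        index = site.position - 1
        if not 0 <= index < len(sequence):
            logger.warning("site %s: position beyond sequence end; skipped", site)
            continue
        if sequence[index] != site.residue:
            logger.warning(
                "site %s: sequence residue %r does not match; skipped",
                site,
                sequence[index],
            )
            continue
        left = sequence[max(0, index - flank) : index]
        right = sequence[index + 1 : index + 1 + flank]
        window = PAD * (flank - len(left)) + left + site.residue + right
        window += PAD * (flank - len(right))
        windows.append(SequenceWindow(site=site, window=window))
    return windows


def proteome_windows(
    proteome: Mapping[str, str], residue: str, width: int = 13
) -> list[str]:
    """All windows centered on every residue of one class in a proteome.

    The usual background for motif discovery: the sequence context of
    every potential acceptor of the same residue class.
    """
    if residue not in PHOSPHO_RESIDUES:
        raise ValueError(f"residue must be one of {PHOSPHO_RESIDUES}")
    flank = width // 2
    windows: list[str] = []
    for sequence in proteome.values():
        padded = PAD * flank + sequence + PAD * flank
        for index, letter in enumerate(sequence):
            if letter == residue:
                windows.append(padded[index : index + width])
    return windows


@dataclass(frozen=True)
class Motif:
    """A discovered motif: fixed positions over a window, with statistics.

    ``pattern`` is the full-width string with ``x`` at unfixed positions;
    ``core`` is the compact +/-3 rendering with the central residue set
    off by underscores (e.g. ``xxx_S_Pxx`` for proline at +1).
    ``proportion`` is the percentage of the original foreground matched;
    ``score`` is -log10 of the binomial p-value of the last fixed
    position.
    """

    pattern: str
    core: str
    fixed: Mapping[int, str]  # offset from center -> residue
    center_residue: str
    foreground_matches: int
    proportion: float
    score: float


def _render(fixed: Mapping[int, str], center_residue: str, width: int) -> tuple[str, str]:
    center = width // 2
    letters = [WILDCARD] * width
    letters[center] = center_residue
    for offset, residue in fixed.items():
        letters[center + offset] = residue
    pattern = "".join(letters)
    core = (
        pattern[center - 3 : center]
        + f"{PAD}{center_residue}{PAD}"
        + pattern[center + 1 : center + 4]
    )
    return pattern, core


def _as_matrix(windows: Sequence[str]) -> np.ndarray:
    return np.array([list(w) for w in windows], dtype="<U1")


def _best_pair(
    fg: np.ndarray,
    bg: np.ndarray,
    open_offsets: Sequence[int],
    center: int,
    min_occurrences: int,
) -> tuple[float, int, str, int] | None:
    """The (position, residue) pair with the smallest binomial tail p.

    Returns (p, offset, residue, successes) or None if no residue occurs
    at least ``min_occurrences`` times.  Ties break toward more
    occurrences, then smaller offset, then alphabetical residue.
    """
    best: tuple[float, int, int, str] | None = None  # (p, -k, |offset| order key...)
    best_result: tuple[float, int, str, int] | None = None
    for offset in open_offsets:
        column_fg = fg[:, center + offset]
        column_bg = bg[:, center + offset]
        fg_valid = column_fg != PAD
        bg_valid = column_bg != PAD
        n = int(fg_valid.sum())
        n_bg = int(bg_valid.sum())
        if n == 0 or n_bg == 0:
            continue
        for residue in AMINO_ACIDS:
            k = int((column_fg == residue).sum())
            if k < min_occurrences:
                continue
            p0 = float((column_bg == residue).sum()) / n_bg
            if p0 <= 0.0:
                p0 = 1.0 / (n_bg + 1)  # unseen in background: pseudo-frequency
            p = float(stats.binom.sf(k - 1, n, p0))
            key = (p, -k, offset, residue)
            if best is None or key < best:
                best = key
                best_result = (p, offset, residue, k)
    return best_result


def discover_motifs(
    foreground: Sequence[SequenceWindow | str],
    background: Sequence[SequenceWindow | str],
    p_threshold: float = 1e-6,
    min_occurrences: int = 20,
) -> list[Motif]:
    """Iterative motif-x style discovery of over-represented motifs.

    ``foreground`` and ``background`` must be windows of one width with
    the same central residue class (analyze S/T/Y separately).  Motifs
    are grown greedily one fixed position at a time, each fix requiring
    binomial tail probability <= ``p_threshold`` and at least
    ``min_occurrences`` foreground matches; matched foreground and
    background windows are removed between motifs.  Proportions refer to
    the original foreground size.
    """
    fg_windows = [w.window if isinstance(w, SequenceWindow) else w for w in foreground]
    bg_windows = [w.window if isinstance(w, SequenceWindow) else w for w in background]
    if not fg_windows:
        raise ValueError("foreground is empty")
    if not bg_windows:
        raise ValueError("background is empty")
    widths = {len(w) for w in fg_windows} | {len(w) for w in bg_windows}
    if len(widths) != 1:
        raise ValueError("all windows must share one width")
    width = widths.pop()
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    center = width // 2
    n_original = len(fg_windows)

    fg = _as_matrix(fg_windows)
    bg = _as_matrix(bg_windows)
    center_residue = str(fg[0, center])
    motifs: list[Motif] = []

    while len(fg):
        working_fg = fg
        working_bg = bg
        fixed: dict[int, str] = {}
        last_p = math.nan
        offsets = [o for o in range(-center, center + 1) if o != 0]
        while True:
            found = _best_pair(working_fg, working_bg, offsets, center, min_occurrences)
            if found is None or found[0] > p_threshold:
                break
            p, offset, residue, _ = found
            fixed[offset] = residue
            last_p = p
            offsets.remove(offset)
            working_fg = working_fg[working_fg[:, center + offset] == residue]
            working_bg = working_bg[working_bg[:, center + offset] == residue]
            if working_bg.size == 0:
                break
        if not fixed:
            break
        pattern, core = _render(fixed, center_residue, width)
        matches = len(working_fg)
        motifs.append(
            Motif(
                pattern=pattern,
                core=core,
                fixed=dict(fixed),
                center_residue=center_residue,
                foreground_matches=matches,
                proportion=percent(matches, n_original),
                score=-math.log10(last_p) if last_p > 0 else math.inf,
            )
        )
        # A window matching *all* fixed positions belongs to the motif;
        # remove exactly those from both sets before the next round.
        match_fg = np.ones(len(fg), dtype=bool)
        match_bg = np.ones(len(bg), dtype=bool)
        for offset, residue in fixed.items():
            match_fg &= fg[:, center + offset] == residue
            match_bg &= bg[:, center + offset] == residue
        fg = fg[~match_fg]
        bg = bg[~match_bg]
    return motifs


def motif_proportions(motifs: Sequence[Motif], n_foreground: int) -> list[float]:
    """Percentages of the foreground matched by each motif (half-up, 2 dp)."""
    return [percent(m.foreground_matches, n_foreground) for m in motifs]
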
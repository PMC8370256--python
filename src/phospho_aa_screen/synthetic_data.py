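"""Synthetic five-condition phosphoproteomics data with recorded ground truth.

The generator emulates what a quantification export looks like
*downstream* of database search: peptide-level abundances per condition
(NT, SS, AAS, LeuS, AllS by default) with planted regulation classes,
redundant peptides covering the same site, exact duplicate rows, a
fraction of unreliable records, and multiplicative log-normal noise.
A matching proteome (FASTA) carries planted sequence-motif context
around a mixture of the regulated sites, and the full truth (classes,
planted means, expected frame memberships) is recorded so that every
pipeline stage can be scored against it.

Design choices
--------------
* One pooled sample per condition, no replicates — the screen operates
  on fold changes of single columns.
* Planted effects default to 16x so that both the |log2 FC| > 1 and the
  stricter |log10 FC| > 1 tiers are exercised by the same sites.
* A planted site is absent from the restimulation condition that does
  not define its class (e.g. a leucine-responsive site is not observed
  in AllS), so a site's planted class coincides with its expected frame
  membership; expected memberships are nevertheless recomputed from the
  planted means rather than trusted from the label.
* No global between-condition intensity bias is planted, so the
  generated columns are already on a common scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .frame_screen import FRAME_RULES, FrameAssignment
from .quant_io import (
    DEFAULT_CONDITIONS,
    PhosphoPeptideRecord,
    write_fasta,
    write_gmt,
    write_edge_list,
    write_peptide_table,
)

SITE_CLASSES = ("frame1", "frame2", "frame3", "frame4", "null")
MOTIF_CLASSES = ("proline_directed", "plus3_E", "plus2_D", "none")

#: Offset from the phosphosite written into the protein sequence per motif
#: class: proline-directed kinases prefer P at +1; CK2-style acidophilic
#: contexts carry E at +3 or D at +2.
_MOTIF_PLANT = {"proline_directed": (1, "P"), "plus3_E": (3, "E"), "plus2_D": (2, "D")}

# Rough vertebrate proteome amino-acid frequencies for background sequence.
_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_FREQS = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.6, 6.6, 2.6, 4.3, 5.7, 9.9,
     2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.3, 6.0, 1.2, 2.7]
)
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study design.

    Site-class counts, effect sizes and noise level define the planted
    conditions; the dropout entries thin null sites out of the sparse
    starvation/restimulation columns, emulating their small site counts
    in real acquisitions.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {
            "frame1": 20, "frame2": 20, "frame3": 20, "frame4": 200, "null": 500
        }
    )
    effect_up: float = 16.0
    effect_down: float = 1.0 / 16.0
    noise_cv: float = 0.2
    motif_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"proline_directed": 0.45, "plus3_E": 0.19, "plus2_D": 0.16}
    )
    residue_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.90, "T": 0.09, "Y": 0.01}
    )
    n_proteins: int = 380
    protein_length: tuple[int, int] = (150, 600)
    max_peptides_per_site: int = 3
    duplicate_fraction: float = 0.10
    unreliable_fraction: float = 0.05
    dropout: Mapping[str, float] = field(
        default_factory=lambda: {"AAS": 0.70, "LeuS": 0.90}
    )
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sigma: float = 0.8

    def validate(self) -> None:
        if set(self.n_sites) - set(SITE_CLASSES):
            raise ValueError(f"site classes must be among {SITE_CLASSES}")
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be non-negative")
        if not self.effect_up > 1.0:
            raise ValueError("effect_up must exceed 1")
        if not 0.0 < self.effect_down < 1.0:
            raise ValueError("effect_down must lie in (0, 1)")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be non-negative")
        if sum(self.motif_mixture.values()) > 1.0 + 1e-9:
            raise ValueError("motif mixture fractions must sum to <= 1")
        if set(self.motif_mixture) - set(MOTIF_CLASSES):
            raise ValueError(f"motif classes must be among {MOTIF_CLASSES}")
        if abs(sum(self.residue_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("residue frequencies must sum to 1")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must lie in [0, 1]")
        if not 0.0 <= self.unreliable_fraction <= 1.0:
            raise ValueError("unreliable_fraction must lie in [0, 1]")
        if any(not 0.0 <= d <= 1.0 for d in self.dropout.values()):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if len(self.conditions) < 5:
            raise ValueError("the design needs the five standard conditions")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["n_sites"] = dict(self.n_sites)
        raw["motif_mixture"] = dict(self.motif_mixture)
        raw["residue_freqs"] = dict(self.residue_freqs)
        raw["dropout"] = dict(self.dropout)
        raw["protein_length"] = list(self.protein_length)
        raw["conditions"] = list(self.conditions)
        return raw


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-site classes, means and bookkeeping totals."""

    sites: pd.DataFrame
    record_totals: dict[str, float]
    config: SimConfig
    seed: int

    def expected_members(self, frame: int) -> set[str]:
        """Site keys whose noiseless evaluation places them in ``frame``."""
        mask = self.sites["expected_frames"].apply(lambda fs: str(frame) in fs.split(";"))
        return set(self.sites.loc[mask, "site_key"])

    def class_members(self, site_class: str) -> set[str]:
        return set(self.sites.loc[self.sites["site_class"] == site_class, "site_key"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "record_totals": self.record_totals,
            "config": self.config.to_dict(),
        }
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


@dataclass
class SyntheticDataset:
    """A generated study: peptide records, proteome and the truth behind them."""

    records: list[PhosphoPeptideRecord]
    proteome: dict[str, str]
    truth: SyntheticTruth

    def records_for(self, condition: str) -> list[PhosphoPeptideRecord]:
        return [r for r in self.records if r.condition == condition]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peptide_table(self.records, outdir / "peptides.tsv")
        for condition in self.truth.config.conditions:
            write_peptide_table(
                self.records_for(condition), outdir / f"peptides_{condition}.tsv"
            )
        write_fasta(self.proteome, outdir / "proteome.fasta")
        self.truth.write(outdir)


def _largest_remainder_counts(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer class counts matching fractional targets as closely as possible.

    The fractions may sum to less than 1; whatever they do not claim is
    left unallocated (the caller's "none" class).
    """
    raw = {name: frac * total for name, frac in fractions.items()}
    counts = {name: int(math.floor(x)) for name, x in raw.items()}
    leftover = int(round(sum(raw.values()))) - sum(counts.values())
    order = sorted(raw, key=lambda name: raw[name] - counts[name], reverse=True)
    for name in order[:max(leftover, 0)]:
        counts[name] += 1
    return counts


def _condition_means(
    site_class: str, baseline: float, cfg: SimConfig
) -> dict[str, float | None]:
    """Planted mean abundance per condition; None marks a planned absence."""
    up, down = cfg.effect_up, cfg.effect_down
    means: dict[str, float | None] = {c: baseline for c in cfg.conditions}
    if site_class == "frame1":
        means["AAS"] = baseline * up
        means["LeuS"] = baseline * up * down
        means["AllS"] = None
    elif site_class == "frame2":
        means["AAS"] = baseline * down
        means["LeuS"] = baseline * down * up
        means["AllS"] = None
    elif site_class == "frame3":
        means["AAS"] = baseline * up
        means["AllS"] = baseline * up * down
        means["LeuS"] = None
    elif site_class == "frame4":
        means["AAS"] = baseline * down
        means["AllS"] = baseline * down * up
        means["LeuS"] = None
    return means


def _expected_frames(means: Mapping[str, float | None]) -> str:
    """Frame memberships implied by noiseless ratios at the default thresholds."""
    frames = []
    for number, rule in FRAME_RULES.items():
        up_num, up_den = rule.up
        down_num, down_den = rule.down
        cells = [means.get(c) for c in (up_num, up_den, down_num, down_den)]
        if any(v is None or v <= 0 for v in cells):
            continue
        if cells[0] / cells[1] > 2.0 and cells[2] / cells[3] < 0.5:
            frames.append(str(number))
    return ";".join(frames)


def generate(config: SimConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a five-condition synthetic phosphoproteomics study.

    Identical ``(config, seed)`` pairs yield identical datasets,
    byte-for-byte after writing.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    # --- proteome scaffold -------------------------------------------------
    lengths = rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1,
                           size=cfg.n_proteins)
    protein_ids = [f"syn:P{i + 1:04d}" for i in range(cfg.n_proteins)]
    sequences = {
        pid: rng.choice(list(_AA), size=n, p=_AA_FREQS)
        for pid, n in zip(protein_ids, lengths)
    }

    # Candidate site slots spaced 9 apart so planted motif context never
    # overlaps a neighboring site.
    slots: list[tuple[str, int]] = []
    for pid, n in zip(protein_ids, lengths):
        slots.extend((pid, pos) for pos in range(8, int(n) - 7, 9))
    rng.shuffle(slots)
    n_total = sum(cfg.n_sites.values())
    if n_total > len(slots):
        raise ValueError(
            f"requested {n_total} sites but the proteome offers only "
            f"{len(slots)} slots; increase n_proteins or protein_length"
        )

    classes = [c for c in SITE_CLASSES for _ in range(cfg.n_sites.get(c, 0))]
    residues = rng.choice(
        list(cfg.residue_freqs), size=n_total, p=list(cfg.residue_freqs.values())
    )

    # Motif classes for frame-4 sites, with exact largest-remainder counts
    # of the configured mixture; motif-carrying sites are serine-centered
    # (the planted contexts are serine kinase preferences), the rest keep
    # their drawn residue class.
    frame4_idx = [i for i, c in enumerate(classes) if c == "frame4"]
    motif_counts = _largest_remainder_counts(cfg.motif_mixture, len(frame4_idx))
    motif_classes = ["none"] * n_total
    cursor = 0
    shuffled_frame4 = list(frame4_idx)
    rng.shuffle(shuffled_frame4)
    for motif_class in ("proline_directed", "plus3_E", "plus2_D"):
        for _ in range(motif_counts.get(motif_class, 0)):
            index = shuffled_frame4[cursor]
            motif_classes[index] = motif_class
            residues[index] = "S"
            cursor += 1

    # Plant residues and motif context into the sequences.
    site_rows: list[dict] = []
    for i in range(n_total):
        pid, pos = slots[i]
        seq = sequences[pid]
        seq[pos - 1] = residues[i]
        plant = _MOTIF_PLANT.get(motif_classes[i])
        if plant is not None:
            offset, letter = plant
            seq[pos - 1 + offset] = letter
        site_rows.append(
            {
                "site_key": f"{pid}:{residues[i]}{pos}",
                "protein_id": pid,
                "position": pos,
                "residue": str(residues[i]),
                "site_class": classes[i],
                "motif_class": motif_classes[i],
            }
        )
    proteome = {pid: "".join(seq) for pid, seq in sequences.items()}

    # --- abundances and peptide records ------------------------------------
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    records: list[PhosphoPeptideRecord] = []
    for row in site_rows:
        baseline = float(rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma))
        means = _condition_means(row["site_class"], baseline, cfg)
        if row["site_class"] == "null":
            for condition, p_drop in cfg.dropout.items():
                if means.get(condition) is not None and rng.random() < p_drop:
                    means[condition] = None
        row["expected_frames"] = _expected_frames(means)
        for condition in cfg.conditions:
            row[f"mean_{condition}"] = means.get(condition, None)

        pid, pos, residue = row["protein_id"], row["position"], row["residue"]
        sequence = proteome[pid]
        for condition in cfg.conditions:
            mean = means.get(condition)
            if mean is None:
                continue
            noise = math.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma else 1.0
            value = mean * noise
            n_peptides = int(rng.integers(1, cfg.max_peptides_per_site + 1))
            weights = (
                rng.dirichlet(np.ones(n_peptides)) if n_peptides > 1 else np.array([1.0])
            )
            for weight in weights:
                left = int(rng.integers(4, 8))
                right = int(rng.integers(4, 8))
                start = max(0, pos - 1 - left)
                stop = min(len(sequence), pos + right)
                record = PhosphoPeptideRecord(
                    condition=condition,
                    peptide=sequence[start:stop],
                    protein_id=pid,
                    mod_positions=(pos,),
                    residues=(residue,),
                    abundance=float(value * weight),
                    reliability=float(rng.uniform(0.80, 1.0)),
                )
                records.append(record)
                if rng.random() < cfg.duplicate_fraction:
                    records.append(record)  # exact redundant export

    # Unreliable decoy records: spurious low-confidence observations whose
    # abundance carries no planted signal; reliability filtering removes them.
    n_decoys = int(round(cfg.unreliable_fraction * len(records)))
    for _ in range(n_decoys):
        row = site_rows[int(rng.integers(0, n_total))]
        condition = cfg.conditions[int(rng.integers(0, len(cfg.conditions)))]
        pid, pos, residue = row["protein_id"], row["position"], row["residue"]
        sequence = proteome[pid]
        start = max(0, pos - 1 - int(rng.integers(4, 8)))
        stop = min(len(sequence), pos + int(rng.integers(4, 8)))
        records.append(
            PhosphoPeptideRecord(
                condition=condition,
                peptide=sequence[start:stop],
                protein_id=pid,
                mod_positions=(pos,),
                residues=(residue,),
                abundance=float(rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma)),
                reliability=float(rng.uniform(0.0, 0.70)),
            )
        )

    totals: dict[str, float] = {c: 0.0 for c in cfg.conditions}
    for record in records:
        totals[record.condition] += record.abundance

    truth = SyntheticTruth(
        sites=pd.DataFrame(site_rows),
        record_totals=totals,
        config=cfg,
        seed=seed,
    )
    return SyntheticDataset(records=records, proteome=proteome, truth=truth)


def generate_annotations(
    truth: SyntheticTruth, seed: int = 0, n_terms: int = 15
) -> dict[str, set[str]]:
    """GMT-style term sets over the synthetic proteins.

    Three terms are enriched in the amino-acid-responsive (frame 4)
    proteins; the remainder are random draws from all proteins.
    """
    rng = np.random.default_rng(seed)
    all_proteins = sorted(set(truth.sites["protein_id"]))
    frame4_proteins = sorted(
        {key.rpartition(":")[0] for key in truth.expected_members(4)}
    )
    terms: dict[str, set[str]] = {}
    for i in range(min(3, n_terms)):
        size = min(len(frame4_proteins), int(rng.integers(12, 25)))
        core = rng.choice(frame4_proteins, size=size, replace=False)
        noise = rng.choice(all_proteins, size=int(rng.integers(2, 6)), replace=False)
        terms[f"aa_response_module_{i + 1}"] = set(map(str, core)) | set(map(str, noise))
    for i in range(max(0, n_terms - 3)):
        size = int(rng.integers(8, 31))
        members = rng.choice(all_proteins, size=min(size, len(all_proteins)), replace=False)
        terms[f"random_term_{i + 1}"] = set(map(str, members))
    return terms


def generate_network(
    truth: SyntheticTruth, seed: int = 0, extra_edges: int = 150
) -> list[tuple[str, str, float]]:
    """A scored interaction edge list over the frame-4 proteins.

    One hub protein is wired to many partners on top of random edges;
    a fraction of edges carry sub-threshold confidence scores so that
    score filtering is exercised.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted({key.rpartition(":")[0] for key in truth.expected_members(4)})
    if len(proteins) < 3:
        raise ValueError("need at least 3 frame-4 proteins for a network")
    hub = proteins[int(rng.integers(0, len(proteins)))]
    edges: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()

    def add(a: str, b: str, score: float) -> None:
        key = frozenset((a, b))
        if a != b and key not in seen:
            seen.add(key)
            edges.append((a, b, round(score, 3)))

    partners = [p for p in proteins if p != hub]
    rng.shuffle(partners)
    for partner in partners[: min(17, len(partners))]:
        add(hub, partner, float(rng.uniform(0.6, 0.999)))
    for _ in range(extra_edges):
        a, b = rng.choice(proteins, size=2, replace=False)
        add(str(a), str(b), float(rng.uniform(0.15, 0.999)))
    return edges


@dataclass(frozen=True)
class RecoveryMetrics:
    """Frame-recovery performance of a screen against the planted truth."""

    sensitivity: float
    specificity: float
    per_frame: Mapping[int, dict[str, int]]


def evaluate_recovery(
    truth: SyntheticTruth, assignments: Sequence[FrameAssignment]
) -> RecoveryMetrics:
    """Score recovered frame memberships against expected memberships.

    Sensitivity pools true positives over all four frames; specificity
    pools true negatives over all (site, frame) pairs not expected to be
    members.
    """
    universe = set(truth.sites["site_key"])
    predicted: dict[int, set[str]] = {f: set() for f in FRAME_RULES}
    for assignment in assignments:
        for frame in assignment.frames:
            predicted[frame].add(str(assignment.site))
    tp = fn = fp = tn = 0
    per_frame: dict[int, dict[str, int]] = {}
    for frame in FRAME_RULES:
        expected = truth.expected_members(frame)
        found = predicted[frame] & universe
        frame_tp = len(found & expected)
        frame_fn = len(expected - found)
        frame_fp = len(found - expected)
        frame_tn = len(universe) - frame_tp - frame_fn - frame_fp
        per_frame[frame] = {
            "tp": frame_tp, "fn": frame_fn, "fp": frame_fp, "tn": frame_tn
        }
        tp += frame_tp
        fn += frame_fn
        fp += frame_fp
        tn += frame_tn
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return RecoveryMetrics(
        sensitivity=sensitivity, specificity=specificity, per_frame=per_frame
    )


def write_companions(truth: SyntheticTruth, outdir: str | Path, seed: int = 0) -> None:
    """Write the GMT annotation and edge-list companions for a dataset."""
    outdir = Path(outdir)
    write_gmt(generate_annotations(truth, seed=seed), outdir / "annotations.gmt")
    write_edge_list(generate_network(truth, seed=seed), outdir / "network_edges.tsv")
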
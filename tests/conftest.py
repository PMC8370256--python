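"""Shared fixtures: hand-built record sets, random fixtures and oracles.

The brute-force helpers here are independent re-implementations (plain
dict/set arithmetic) of the pipeline's aggregation operations, used as
oracles in the property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phospho_aa_screen import PhosphoPeptideRecord, screen_records
from phospho_aa_screen import synthetic_data as sd


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study (16x effects, 20% CV)."""
    return sd.generate(seed=5)


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """The screen run on the default dataset (generator output is already
    on a common scale, so no normalization is applied)."""
    return screen_records(default_dataset.records, normalization="none")


@pytest.fixture
def handmade_records() -> list[PhosphoPeptideRecord]:
    """A small record set covering redundancy, multi-site peptides and
    missing reliability."""
    return [
        PhosphoPeptideRecord("NT", "AASPK", "px:1", (10,), ("S",), 3.0, 0.9),
        PhosphoPeptideRecord("NT", "LLSPK", "px:1", (10,), ("S",), 5.0, 0.95),
        PhosphoPeptideRecord("NT", "MSPTK", "px:1", (10, 14), ("S", "T"), 4.0, None),
        PhosphoPeptideRecord("SS", "AASPK", "px:1", (10,), ("S",), 2.0, 0.8),
        PhosphoPeptideRecord("SS", "QQYQK", "px:2", (7,), ("Y",), 1.5, 0.99),
    ]


def make_random_records(seed: int, n: int = 250) -> list[PhosphoPeptideRecord]:
    """Random but internally consistent records (residue is a function of
    position, so no residue conflicts arise)."""
    rng = np.random.default_rng(seed)
    residues = "STY"
    records = []
    for _ in range(n):
        protein = f"p:{int(rng.integers(1, 15))}"
        pos = int(rng.integers(2, 40))
        positions = [pos]
        if rng.random() < 0.2:
            positions.append(pos + 1 + int(rng.integers(0, 3)))
        condition = ["NT", "SS", "AAS", "LeuS", "AllS"][int(rng.integers(0, 5))]
        reliability = None if rng.random() < 0.3 else float(rng.uniform(0, 1))
        record = PhosphoPeptideRecord(
            condition=condition,
            peptide="PEPTIDEK",
            protein_id=protein,
            mod_positions=tuple(positions),
            residues=tuple(residues[p % 3] for p in positions),
            abundance=float(round(rng.uniform(0.1, 10.0), 3)),
            reliability=reliability,
        )
        records.append(record)
        if rng.random() < 0.15:
            records.append(record)  # exact duplicate
    return records


def brute_force_merge(records) -> dict[tuple[str, str], float]:
    """Dedupe + per-(site, condition) abundance sums, with plain dicts."""
    seen = set()
    unique = []
    for r in records:
        key = (r.condition, r.peptide, r.protein_id, r.mod_positions, r.residues,
               r.abundance)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    cells: dict[tuple[str, str], float] = {}
    for r in unique:
        for pos, res in zip(r.mod_positions, r.residues):
            site = f"{r.protein_id}:{res}{pos}"
            cells[(site, r.condition)] = cells.get((site, r.condition), 0.0) + r.abundance
    return cells
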
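from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cphotspot.simulate import SimulationConfig, build_ancestor, evolve


def make_genbank(path: Path, sequence: str, features: list[str], locus: str = "TOY") -> Path:
    """Write a minimal GenBank flat file with the given feature lines."""
    lines = [
        f"LOCUS       {locus}            {len(sequence)} bp    DNA     circular PLN 01-JAN-2020",
        f"DEFINITION  toy record {locus}.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(sequence)}",
    ]
    lines.extend(features)
    lines.append("ORIGIN")
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60].lower()
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20160902)


@pytest.fixture
def random_dna(rng):
    def make(n: int, with_n: bool = False) -> str:
        alphabet = "ACGTN" if with_n else "ACGT"
        probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
        return "".join(rng.choice(list(alphabet), size=n, p=probs))

    return make


@pytest.fixture(scope="session")
def small_simulation():
    """One evolved desk-scale simulation shared across tests."""
    config = SimulationConfig.small(seed=11)
    ancestor, truth = build_ancestor(config)
    leaves, truth = evolve(ancestor, truth, config)
    return config, ancestor, leaves, truth
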
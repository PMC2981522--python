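"""Shared fixtures: tiny hand-built trios and simulated samples."""

from __future__ import annotations

import numpy as np
import pytest

from trioassoc import SnpRecord, TrioGenotypes, default_config, simulate_trios


def make_trio(family_id: str, snps, father, mother, child) -> TrioGenotypes:
    """Build a trio from per-member allele-pair strings like ["AG", "GG"]
    (one string per SNP; "--" = missing)."""
    m = len(snps)
    g = np.zeros((3, m, 2), dtype=np.int8)
    for mi, member in enumerate((father, mother, child)):
        assert len(member) == m
        for j, pair in enumerate(member):
            rec = snps[j]
            for a in range(2):
                ch = pair[a]
                if ch == "-":
                    g[mi, j, a] = -1
                elif ch == rec.allele_a:
                    g[mi, j, a] = 0
                elif ch == rec.allele_b:
                    g[mi, j, a] = 1
                else:
                    raise ValueError(f"allele {ch!r} invalid for {rec.snp_id}")
    return TrioGenotypes(family_id, g)


@pytest.fixture(scope="session")
def two_snps() -> list[SnpRecord]:
    return [
        SnpRecord("snp1", "18", 56_035_730, "A", "G"),
        SnpRecord("snp2", "18", 56_237_438, "G", "T"),
    ]


@pytest.fixture(scope="session")
def study_sample():
    """One medium simulated sample under the study-like configuration."""
    cfg = default_config(n_trios=400, seed=20_240)
    trios, table, truth = simulate_trios(cfg)
    return cfg.snp_map, trios, table, truth


@pytest.fixture(scope="session")
def null_sample():
    """One simulated sample with no association."""
    from trioassoc import null_config

    cfg = null_config(n_trios=400, seed=777)
    trios, _, truth = simulate_trios(cfg)
    return cfg.snp_map, trios, truth
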
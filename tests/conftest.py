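"""Shared fixtures: small oracle helpers and the simulated-corpus fixture.

The session-scoped ``sim_corpus`` fixture generates one scaled synthetic
dataset (90 miRNA-like / 60 ncRNA-like / 300 pseudo-hairpin records) and
extracts the full 125-feature table with a reduced shuffle-cohort and
self-containment budget; the directional and end-to-end checks share it.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirvote.features import FeatureConfig, extract_table
from mirvote.simulate import SimConfig, simulate_dataset
from mirvote.structure import MIN_LOOP, ReferenceBackend, ViennaBackend, can_pair

SIM_SEED = 11
EXTRACT_SEED = 7


@pytest.fixture(scope="session")
def reference_backend():
    return ReferenceBackend()


@pytest.fixture(scope="session")
def vienna_backend():
    return ViennaBackend()


def enumerate_structures(s: str) -> list[tuple[tuple[int, int], ...]]:
    """All nested structures (0-based pair sets) with the minimum-loop
    constraint — the brute-force ensemble oracle for the reference model."""

    def region(avail: tuple[int, ...]):
        out = [()]
        if not avail:
            return out
        i = avail[0]
        rest = tuple(avail[1:])
        out = [p for p in region(rest)]
        for j in rest:
            if j - i > MIN_LOOP and can_pair(s[i], s[j]):
                inner = tuple(k for k in rest if k < j)
                outer = tuple(k for k in rest if k > j)
                for a in region(inner):
                    for b in region(outer):
                        out.append(((i, j),) + a + b)
        return out

    return region(tuple(range(len(s))))


def boltzmann_summary(s: str):
    """Oracle MFE / partition function / pair probabilities / MFE-structure
    frequency under the reference energy model (−1 per pair, kT = 1)."""
    structs = enumerate_structures(s)
    n = len(s)
    best = max(len(p) for p in structs)
    Z = sum(math.exp(len(p)) for p in structs)
    prob = np.zeros((n, n))
    for p in structs:
        w = math.exp(len(p)) / Z
        for i, j in p:
            prob[i, j] += w
    return {
        "mfe": -float(best) if best else 0.0,
        "efe": -math.log(Z),
        "prob": prob + prob.T,
        "freq_mfe": math.exp(best) / Z,
    }


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def sim_corpus(vienna_backend):
    """Simulated dataset + extracted feature table (scaled problem size)."""
    config = SimConfig(n_mirna=90, n_ncrna=60, n_pseudo=300)
    manifest = simulate_dataset(config, seed=SIM_SEED, backend=vienna_backend)
    feat_config = FeatureConfig().scaled(n_shuffles=10, n_contexts=6, flank_len=40)
    frame = extract_table(
        manifest.sequences(),
        backend=vienna_backend,
        config=feat_config,
        seed=EXTRACT_SEED,
    )
    return {
        "manifest": manifest,
        "frame": frame,
        "labels": manifest.labels(),
        "tags": manifest.tags(),
    }
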
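"""Shared fixtures: hand-built contig geometries and small simulated truths."""

from __future__ import annotations

import numpy as np
import pytest

from bacmap.fingerprint import BandProfile, Method, ScoreParams
from bacmap.simulate import SimConfig, make_profiles, simulate_genome, simulate_library


def profile(clone_id, bands, method=Method.AGAROSE, **kw):
    return BandProfile(clone_id, method, tuple(sorted(bands)), **kw)


GRID = [100 + 25 * i for i in range(60)]  # distinct values, 25 > any tolerance


@pytest.fixture
def two_contig_bridge():
    """Two 2-clone contigs whose inner terminal pair shares exactly 11 of 18
    bands — below the base cutoffs, inside the two-denary-relaxed window.

    Layout (all values from GRID, spacing 25):
      A1 = X(13) + W(5);  A2 = X(13) + Y(5)
      B1 = Y(5) + X[:6] + Z(7);  B2 = Z(7) + X[:6] + V(5)
    giving |A1&A2| = 13, |A2&B1| = 11, |B1&B2| = 13, all cross pairs 6.
    """
    X, W, Y, Z, V = (GRID[0:13], GRID[13:18], GRID[18:23], GRID[23:30],
                     GRID[30:35])
    profiles = {
        "A1": profile("A1", X + W, well_col=0),
        "A2": profile("A2", X + Y, well_col=4),
        "B1": profile("B1", Y + X[:6] + Z, well_col=8),
        "B2": profile("B2", Z + X[:6] + V, well_col=12),
    }
    return profiles


@pytest.fixture
def fig1c(two_contig_bridge):
    """The bridge fixture plus HICF profiles in which the terminal pair
    (A2, B1) is identical and everything else is disjoint."""
    span = 2000

    def hicf(cid, offset):
        bands = []
        for ch in range(5):
            bands.extend(ch * span + 50 + 12 * k + offset for k in range(30))
        return profile(cid, bands, Method.HICF)

    hicf_profiles = {
        "A1": hicf("A1", 4),
        "A2": hicf("A2", 0),
        "B1": hicf("B1", 0),
        "B2": hicf("B2", 8),
    }
    return two_contig_bridge, hicf_profiles


@pytest.fixture
def chimera_contig():
    """Two clean 3-clone staircases falsely merged through two chimeric
    36-band clones; the chimeras are the contig's only Q clones."""
    GA = [100 + 25 * k for k in range(26)]
    GB = [1500 + 25 * k for k in range(26)]
    U1 = [3000 + 25 * k for k in range(6)]
    U2 = [3500 + 25 * k for k in range(6)]
    profiles = {
        "A1": profile("A1", GA[0:18]),
        "A2": profile("A2", GA[4:22]),
        "A3": profile("A3", GA[8:26]),
        "B1": profile("B1", GB[0:18]),
        "B2": profile("B2", GB[4:22]),
        "B3": profile("B3", GB[8:26]),
        "X1": profile("X1", GA[0:15] + GB[0:15] + U1),
        "X2": profile("X2", GA[11:26] + GB[11:26] + U2),
    }
    return profiles


@pytest.fixture(scope="session")
def small_truth():
    """5-Mb noise-free truth with library and agarose profiles."""
    cfg = SimConfig(genome_bp=5_000_000)
    truth = simulate_genome(cfg, 7)
    simulate_library(truth, 7)
    profiles = make_profiles(truth, Method.AGAROSE, 7)
    return truth, profiles


@pytest.fixture(scope="session")
def score_params():
    return ScoreParams(7, 5000, 1e-12)
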
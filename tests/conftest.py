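"""Shared fixtures: a small host/phage pair with the 17-bp att core.

The toy genomes are deliberately small (100 kb host, 20 kb phage) so the
whole integration-classification round trip runs in seconds; tests that
probe kb-scale inference build their own frames at realistic sizes.
"""

import numpy as np
import pytest

from pacwave.genome import (AttSite, ReplicatedGenome, DEFAULT_ATT_CORE,
                            build_lysogen, plant_att_core, random_genome,
                            revcomp)

CORE = DEFAULT_ATT_CORE


@pytest.fixture(scope="session")
def toy_frames():
    host = plant_att_core(
        random_genome(100_000, 0.6, seed=101, name="host"), CORE, 60_000)
    phage = plant_att_core(
        random_genome(20_000, 0.6, seed=102, name="phage"), revcomp(CORE), 15_000)
    att = AttSite(CORE, 60_000, 15_000, "reverse")
    return host, phage, att


@pytest.fixture(scope="session")
def toy_lysogen(toy_frames):
    host, phage, att = toy_frames
    return build_lysogen(host, phage, att)


@pytest.fixture(scope="session")
def study_frames():
    """Frames at the study's scale: 2-Mb host, 65,149-bp phage, reverse
    orientation, attP at 62,750 and attB at 1.2 Mb."""
    host = plant_att_core(
        random_genome(2_000_000, 0.635, seed=11, name="host"), CORE, 1_200_000)
    phage = plant_att_core(
        random_genome(65_149, 0.635, seed=12, name="phage"), revcomp(CORE), 62_750)
    att = AttSite(CORE, 1_200_000, 62_750, "reverse")
    return host, phage, att


@pytest.fixture(scope="session")
def toy_classifier(toy_frames):
    from pacwave.classify import ReadOriginClassifier

    host, phage, att = toy_frames
    return ReadOriginClassifier().fit({"host": host, "phage": phage}, att)


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
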
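import numpy as np
import pytest

from hzkit.genotypes import GenotypeMatrix, LocusInfo, SampleInfo


def make_gm(calls, positions=None, chromosome="1", populations=None, sexes=None):
    """Build a GenotypeMatrix from a 2-D call array (samples x loci)."""
    calls = np.asarray(calls, dtype=np.uint8)
    n_s, n_l = calls.shape
    if positions is None:
        positions = np.arange(1, n_l + 1) * 1000
    loci = [LocusInfo(f"rs{j + 1}", chromosome, int(positions[j]), ("A", "G"))
            for j in range(n_l)]
    pops = populations or ["POP"] * n_s
    sexes = sexes or ["unknown"] * n_s
    samples = [SampleInfo(f"S{i}", pops[i], sexes[i]) for i in range(n_s)]
    return GenotypeMatrix(calls, loci, samples)


@pytest.fixture
def tiny_gm():
    # 4 samples x 6 loci with a het column and a missing call
    calls = np.array([
        [0, 0, 2, 1, 0, 0],
        [0, 3, 0, 0, 0, 2],
        [1, 1, 1, 1, 1, 1],
        [2, 2, 2, 2, 2, 2],
    ])
    return make_gm(calls)


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderately sized two-population panel used by several test modules."""
    from hzkit.synth import SimConfig, simulate_panel, panel_arm_rates

    cfg = SimConfig(n_loci=1500, populations={"POPA": 20, "POPB": 20}, seed=11)
    gm, panel, truth = simulate_panel(cfg)
    return cfg, gm, panel, truth, panel_arm_rates(cfg, gm)
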
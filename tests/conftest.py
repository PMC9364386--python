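import numpy as np
import pandas as pd
import pytest

from methylnorm import IntensityMatrix, ProbeAnnotation, SampleSheet, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed-sex simulated dataset, small enough for fast unit tests."""
    cfg = SimConfig(n_female=6, n_male=6, n_auto=4000, n_x=120, n_y=24, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotation(n_auto, n_x=0, n_y=0, design="II", rng=None):
    """Hand-rolled annotation for tiny constructed examples."""
    ids = [f"a{i}" for i in range(n_auto)] + [f"x{i}" for i in range(n_x)] + \
          [f"y{i}" for i in range(n_y)]
    chrom = [str(1 + i % 22) for i in range(n_auto)] + ["X"] * n_x + ["Y"] * n_y
    if rng is None:
        dt = [design] * len(ids)
    else:
        dt = rng.choice(["I", "II"], size=len(ids)).tolist()
    return ProbeAnnotation(pd.DataFrame({"chromosome": chrom, "design_type": dt},
                                        index=pd.Index(ids, name="probe_id")))


def make_intensities(meth, unmeth, probe_ids=None, sample_ids=None):
    meth = np.asarray(meth, dtype=float)
    probe_ids = probe_ids or [f"a{i}" for i in range(meth.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(meth.shape[1])]
    idx, cols = pd.Index(probe_ids, name="probe_id"), pd.Index(sample_ids, name="sample_id")
    return IntensityMatrix(pd.DataFrame(meth, index=idx, columns=cols),
                           pd.DataFrame(np.asarray(unmeth, dtype=float), index=idx, columns=cols))


def make_sheet(sexes, sample_ids=None, chip_rows=None):
    sample_ids = sample_ids or [f"s{j}" for j in range(len(sexes))]
    data = {"sex": list(sexes)}
    if chip_rows is not None:
        data["chip_row"] = list(chip_rows)
    return SampleSheet(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))
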
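import numpy as np
import pandas as pd
import pytest

import nanoepisig as ne


def make_beta_matrix(columns: dict[str, list[float] | np.ndarray],
                     groups: dict[str, str] | None = None,
                     platforms: dict[str, str] | None = None,
                     probes: list[str] | None = None) -> ne.BetaMatrix:
    """Build a small annotated BetaMatrix from plain column vectors."""
    first = next(iter(columns.values()))
    if probes is None:
        probes = [f"p{i}" for i in range(len(first))]
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                          index=probes)
    ids = list(columns)
    samples = pd.DataFrame(
        {
            "group": [(groups or {}).get(s, "unknown") for s in ids],
            "platform": [(platforms or {}).get(s, "array") for s in ids],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return ne.BetaMatrix(values, samples)


@pytest.fixture(scope="session")
def small_cohort() -> ne.SimulatedCohort:
    """300-probe, 5+20-sample cohort shared by read-only tests."""
    return ne.simulate_cohort(ne.SimulationConfig(n_probes_total=300, seed=11))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Same cohort written to disk (bedMethyl files, manifest, reference)."""
    out = tmp_path_factory.mktemp("cohort")
    cohort = ne.simulate_cohort(ne.SimulationConfig(n_probes_total=300, seed=11), out_dir=out)
    return cohort, out
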
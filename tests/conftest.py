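import numpy as np
import pandas as pd
import pytest

import aacidcest as ac


@pytest.fixture(scope="session")
def system():
    return ac.default_pool_system()


@pytest.fixture(scope="session")
def cest_sched():
    return ac.cest_schedule()


@pytest.fixture(scope="session")
def wassr_sched():
    return ac.wassr_schedule()


@pytest.fixture(scope="session")
def two_class_spec():
    """Small noiseless two-region phantom: alkaline tumor in neutral tissue."""
    return ac.PhantomSpec(
        nx=8,
        ny=8,
        classes=(
            ac.TissueClass("contralateral", ph=7.1),
            ac.TissueClass("tumor", ph=6.8, shape=("ellipse", 0.4, 0.5, 0.25, 0.3)),
        ),
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_class_phantom(two_class_spec, cest_sched, wassr_sched):
    return ac.generate_phantom(two_class_spec, cest_sched, wassr_sched, n_repeats=1)


@pytest.fixture(scope="session")
def rm_table():
    """Deterministic 6-subject × 2-side × 4-time table (R oracle frozen on it)."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(6):
        for a, name in enumerate(["contra", "tumor"]):
            for b in range(4):
                rows.append(
                    (s, name, b, round(rng.normal(1.3 + 0.04 * a + 0.015 * b + 0.01 * a * b, 0.05), 6))
                )
    return pd.DataFrame(rows, columns=["subject", "side", "time", "value"])
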
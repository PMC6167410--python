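import numpy as np
import pandas as pd
import pytest

from ridqtl.simulate import GenotypeMatrix, simulate_ri_genotypes


def geno_from_calls(calls, positions=None, chromosome=1, strains=None,
                    chromosomes=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from an explicit call matrix (strains x markers)."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(m, dtype=float)
    if chromosomes is None:
        chromosomes = [chromosome] * m
    markers = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chromosome": chromosomes,
        "position_mb": positions,
    })
    if strains is None:
        strains = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(strains=list(strains), markers=markers, calls=calls)


@pytest.fixture(scope="session")
def panel_geno() -> GenotypeMatrix:
    """A 40-strain panel over five 100 Mb chromosomes (200 markers)."""
    spec = {c: (40, 100.0) for c in range(1, 6)}
    return simulate_ri_genotypes(40, spec, seed=11)
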
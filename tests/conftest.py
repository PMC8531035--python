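import numpy as np
import pandas as pd
import pytest

from targetmr.simulate import make_fixtures
from targetmr.sumstats import LDMatrix, VariantKey


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def study():
    """The bundled synthetic study (session-scoped: ~4 s to build)."""
    return make_fixtures(seed=1)


def make_keys(n, chrom="1", start=1_000_000, step=2_000, alleles=("A", "G")):
    return [VariantKey(chrom, start + j * step, *alleles) for j in range(n)]


def identity_ld(keys):
    return LDMatrix(keys, np.eye(len(keys)))


def pairs_frame(keys, bx, sx, by, sy, px=None, eaf=0.3):
    """Assemble a harmonized-pairs table from arrays (test helper)."""
    bx, sx, by, sy = map(np.asarray, (bx, sx, by, sy))
    from scipy import stats

    px = 2 * stats.norm.sf(np.abs(bx / sx)) if px is None else np.asarray(px)
    return pd.DataFrame({
        "chrom": [k.chrom for k in keys], "pos": [k.pos for k in keys],
        "effect_allele": [k.effect_allele for k in keys],
        "other_allele": [k.other_allele for k in keys], "rsid": None,
        "beta_x": bx, "se_x": sx, "pvalue_x": px,
        "eaf_x": eaf, "n_x": 10_000.0,
        "beta_y": by, "se_y": sy,
        "pvalue_y": 2 * stats.norm.sf(np.abs(by / sy)), "eaf_y": eaf,
        "n_y": 10_000.0,
    })


def instrument_set(keys, bx, sx, by, sy, ld=None, px=None, unit="test"):
    from targetmr.instruments import InstrumentSet

    ld = identity_ld(keys) if ld is None else ld
    return InstrumentSet(unit=unit, exposure_trait="exposure",
                         outcome_trait="outcome",
                         pairs=pairs_frame(keys, bx, sx, by, sy, px), ld=ld)
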
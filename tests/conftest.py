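import numpy as np
import pytest
from scipy import stats

from partmr.datatypes import VariantRecord
from partmr.instruments import HarmonizedPair
from partmr.simulate import SimulationParams, simulate_study


def make_record(
    variant_id="rs1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
    eaf=0.3, beta=0.1, se=0.02, n=10000, pval=None,
):
    """VariantRecord with p consistent with beta/se unless overridden."""
    if pval is None:
        pval = float(np.clip(2 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))
    return VariantRecord(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_pair(variant_id="rs1", beta_exp=0.1, se_exp=0.01, eaf_exp=0.3,
              beta_out=0.05, se_out=0.01, eaf_out=0.3, **kw):
    return HarmonizedPair(
        variant_id=variant_id, beta_exp=beta_exp, se_exp=se_exp,
        eaf_exp=eaf_exp, beta_out=beta_out, se_out=se_out, eaf_out=eaf_out,
        **kw,
    )


def pairs_from_arrays(bx, by, sy, sx=None, ids=None, eaf=0.3):
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 1e-4, dtype=float) if sx is None else np.asarray(sx)
    ids = ids or [f"rs{i}" for i in range(len(bx))]
    return [
        make_pair(variant_id=ids[i], beta_exp=float(bx[i]), se_exp=float(sx[i]),
                  beta_out=float(by[i]), se_out=float(sy[i]), eaf_exp=eaf,
                  eaf_out=eaf)
        for i in range(len(bx))
    ]


@pytest.fixture(scope="session")
def small_study():
    """Modest study with both pathway effects present."""
    return simulate_study(SimulationParams(
        n_individuals=4000, n_blocks=20, snps_per_block=5,
        theta1=0.15, theta2=0.0, theta0=0.05, seed=11,
    ))


@pytest.fixture(scope="session")
def strong_study():
    """Large-n, strong-instrument study for colocalization/partition tests."""
    return simulate_study(SimulationParams(
        n_individuals=20000, n_blocks=20, snps_per_block=5,
        beta_sd=0.15, theta1=0.15, theta2=0.0, seed=3,
    ))
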
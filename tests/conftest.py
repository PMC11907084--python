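import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrmediate import HarmonizedSet, VariantAssociation

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def mk_assoc():
    """Factory for association records with sensible defaults."""

    def _mk(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01,
            pval=1e-9, chrom=None, pos=None, eaf=0.3, n=None):
        return VariantAssociation(
            snp_id=snp_id,
            effect_allele=effect_allele,
            other_allele=other_allele,
            beta=beta,
            se=se,
            pval=pval,
            chrom=chrom,
            pos=pos,
            eaf=eaf,
            n=n,
        )

    return _mk


@pytest.fixture
def three_snp_set():
    """The canonical 3-SNP set with hand-computable IVW beta 7/30 and Q 1/4."""
    return HarmonizedSet.from_arrays(
        bx=[0.1, 0.2, 0.4],
        sex=[0.01, 0.01, 0.02],
        by=[0.02, 0.05, 0.09],
        sey=[0.01, 0.01, 0.02],
    )


@pytest.fixture
def random_hset():
    """Factory for seeded random harmonised sets with positive-signal bx."""

    def _mk(n=50, seed=0, k=1):
        rng = np.random.default_rng(seed)
        sex = rng.uniform(0.002, 0.01, size=(n, k))
        bx = rng.normal(0.0, 0.05, size=(n, k)) + np.sign(rng.standard_normal((n, k))) * 0.02
        sey = rng.uniform(0.005, 0.02, size=n)
        theta = rng.uniform(-0.3, 0.3, size=k)
        by = bx @ theta + sey * rng.standard_normal(n)
        names = ["exposure"] if k == 1 else ["exposure", "mediator"]
        return HarmonizedSet.from_arrays(bx, sex, by, sey, exposure_names=names)

    return _mk
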
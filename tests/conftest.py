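import numpy as np
import pandas as pd
import pytest

from poolseq import PanelVariant, Pool, SimulationConfig


@pytest.fixture
def smoke_config():
    """Small, fast end-to-end configuration (seconds to run)."""
    return SimulationConfig(
        n_cases=30, n_controls=24,
        n_background_variants=40, n_spiked_variants=50,
        seed=7,
    )


def make_variant(vid="v1", gene="APC", consequence="nonsynonymous",
                 maf=None, **kwargs):
    """Minimal panel variant with sensible site fields."""
    defaults = dict(chrom="chr1", pos=1000, ref="A", alt="G")
    defaults.update(kwargs)
    return PanelVariant(variant_id=vid, gene=gene, consequence=consequence,
                        ref_db_maf=maf, **defaults)


def one_carrier_genotypes(member_ids, variant_ids, carrier, dosage=1):
    """Genotype matrix with one carrier heterozygous at every variant."""
    g = pd.DataFrame(
        np.zeros((len(member_ids), len(variant_ids)), dtype=np.int8),
        index=pd.Index(member_ids, name="subject_id"), columns=variant_ids,
    )
    g.loc[carrier, :] = dosage
    return g


@pytest.fixture
def trio_pool():
    return Pool("CP0000", "case", ["A", "B", "C"])
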
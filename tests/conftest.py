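import numpy as np
import pandas as pd
import pytest

from metaqtl.consensus import GeneticMap
from metaqtl.qtl_data import QTLRecord, default_trait_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_trait_vocabulary()


def make_map(map_id, markers, chrom="1H"):
    """GeneticMap from {marker: pos} or [(marker, pos)] on one chromosome."""
    items = markers.items() if isinstance(markers, dict) else markers
    rows = [{"marker": m, "chrom": chrom, "pos_cM": p} for m, p in items]
    return GeneticMap(map_id, pd.DataFrame(rows))


def make_qtl(
    position,
    ci_lo=None,
    ci_hi=None,
    chrom="1H",
    study="S1",
    qtl_id="Q1",
    pop_type="DH",
    pop_size=150,
    trait="plant height",
    lod=3.5,
    pve=8.0,
    **kw,
):
    if ci_lo is None:
        ci_lo = position - 1.0
    if ci_hi is None:
        ci_hi = position + 1.0
    return QTLRecord(
        qtl_id=qtl_id,
        study_id=study,
        population_type=pop_type,
        population_size=pop_size,
        trait_raw=trait,
        trait_class="PH",
        chromosome=chrom,
        position=position,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        lod=lod,
        pve=pve,
        **kw,
    )
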
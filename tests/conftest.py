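import numpy as np
import pytest

from wsmeth.array_io import BetaMatrix, Group, ProbeAnnotation, Relation


def make_matrix(values, n_case=None, probe_ids=None):
    """BetaMatrix from an array; first half of the columns are cases."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    n_case = n_case if n_case is not None else n // 2
    sample_ids = [f"WS{i}" for i in range(n_case)] + [f"CTR{i}" for i in range(n - n_case)]
    groups = {s: (Group.CASE if s.startswith("WS") else Group.CTRL) for s in sample_ids}
    return BetaMatrix(
        probe_ids=probe_ids or [f"cg{i:08d}" for i in range(values.shape[0])],
        sample_ids=sample_ids,
        values=values,
        groups=groups,
    )


def island_probes(island, chrom, start, n, genes=("GENEA",), relation=Relation.ISLAND, prefix="cg"):
    """n annotated probes sharing one island, 100 bp apart."""
    return [
        ProbeAnnotation(
            probe_id=f"{prefix}{start + 100 * i}",
            chrom=chrom,
            position=start + 100 * i,
            genes=frozenset(genes),
            island_name=island,
            relation=relation,
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20170830)


@pytest.fixture(scope="session")
def paperlike():
    from wsmeth.synthetic import paperlike_scene

    return paperlike_scene(seed=11)
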
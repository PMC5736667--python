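import numpy as np
import pandas as pd
import pytest

import methylsub as ms


def make_annotation(
    probe_ids,
    chrom="chr1",
    cgi_relation="open_sea",
    island_id=None,
    feature="intron",
    snp_distance=np.nan,
    blacklist_distance=np.nan,
):
    """Small helper to build a valid ProbeAnnotation from scalars or lists."""
    n = len(probe_ids)

    def col(v):
        return [v] * n if np.isscalar(v) or v is None else list(v)

    df = pd.DataFrame(
        {
            "chrom": col(chrom),
            "pos": np.arange(n) * 100,
            "strand": "+",
            "cgi_relation": col(cgi_relation),
            "island_id": col(island_id),
            "feature": col(feature),
            "gene": None,
            "snp_distance": col(snp_distance),
            "blacklist_distance": col(blacklist_distance),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ms.ProbeAnnotation(df)


@pytest.fixture(scope="session")
def small_cfg():
    return ms.SimulationConfig(
        n_probes=3000, n_per_group=8, n_replicates=5, seed=2
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """A compact synthetic world shared by the module tests."""
    panel, ann, hem = ms.generate_reference(small_cfg)
    panel_beta, panel_labels = ms.generate_reference_samples(small_cfg, panel)
    beta, sheet, fractions, truth_dmp, labels = ms.generate_cohort(small_cfg, panel)
    return {
        "cfg": small_cfg,
        "panel": panel,
        "ann": ann,
        "hem": hem,
        "panel_beta": panel_beta,
        "panel_labels": panel_labels,
        "beta": beta,
        "sheet": sheet,
        "fractions": fractions,
        "truth_dmp": truth_dmp,
        "labels": labels,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
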
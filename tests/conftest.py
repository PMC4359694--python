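"""Shared fixtures: small synthetic cohorts and engineered catalog inputs.

Everything is generated programmatically at collection time; no data files.
Session scope keeps the heavier fixtures (cohort genotypes, demo catalog)
to a single construction.
"""

import io

import numpy as np
import pandas as pd
import pytest

from famgrs.cohort import CohortConfig, generate_pedigrees
from famgrs.demo import make_demo_genotypes, make_demo_inputs
from famgrs.panel import (
    SNPPanel,
    filter_records,
    ld_prune,
    merge_supplemental,
    panels_from_records,
    parse_catalog,
)


def small_cohort_config(**overrides) -> CohortConfig:
    """A scaled-down analogue of the default cohort (~320 people, 40 families)."""
    kw = dict(
        n_families=40,
        g1_sibs_per_family={"kind": "multinomial_total", "total": 55},
        g1_spouses_total=12,
        g2_offspring_per_family={"kind": "multinomial_total", "total": 128},
        spouse_fraction_g2=0.4,
        missing_rate=0.01,
        seed=2014,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_config():
    return small_cohort_config()


@pytest.fixture(scope="session")
def small_pedigree(small_config):
    return generate_pedigrees(small_config)


@pytest.fixture(scope="session")
def demo_inputs():
    return make_demo_inputs(seed=42)


@pytest.fixture(scope="session")
def demo_genotypes(small_pedigree, demo_inputs, small_config):
    return make_demo_genotypes(small_pedigree, demo_inputs, small_config)


@pytest.fixture(scope="session")
def demo_panels(demo_inputs, demo_genotypes):
    """LD-pruned panels built through the real parse/filter/merge/prune path."""
    buf = io.StringIO()
    demo_inputs.catalog.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    records = parse_catalog(buf)
    kept, _ = filter_records(records)
    merged = merge_supplemental(kept, demo_inputs.literature)
    panels = panels_from_records(merged)
    return {g: ld_prune(p, demo_genotypes, 0.8, seed=5) for g, p in panels.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def trio_pedigree() -> pd.DataFrame:
    """Founder couple plus one child, all genotyped."""
    return pd.DataFrame(
        {
            "family_id": ["F1"] * 3,
            "individual_id": ["dad", "mom", "kid"],
            "father_id": ["0", "0", "dad"],
            "mother_id": ["0", "0", "mom"],
            "sex": ["M", "F", "F"],
            "generation": [1, 1, 2],
            "role": ["proband", "spouse_g1", "offspring"],
            "longevity_member": [1, 0, 1],
        }
    )


def founders_pedigree(n: int) -> pd.DataFrame:
    """n unrelated genotyped founders (singleton families)."""
    return pd.DataFrame(
        {
            "family_id": [f"F{i}" for i in range(n)],
            "individual_id": [f"I{i}" for i in range(n)],
            "father_id": "0",
            "mother_id": "0",
            "sex": "F",
            "generation": 1,
            "role": "proband",
            "longevity_member": 1,
        }
    )


def panel_from_genotypes(gm, group="alzheimers") -> SNPPanel:
    return SNPPanel(
        disease_group=group,
        snps=pd.DataFrame({"snp_id": gm.snps, "risk_allele": gm.risk_allele}),
    )
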
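"""Shared fixtures: tiny hand-checkable tables and a small simulated cohort."""

import io

import numpy as np
import pandas as pd
import pytest

from famprs import pedigree, scoring, simdata

WEIGHTS_TSV = """\
# toy weight file
rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight
rs1\t1\t1000\tA\tG\t0.1
rs2\t2\t2000\tC\tA\t-0.2
rs3\t3\t3000\tT\tC\t0.3
"""

# samples s1..s3 x variants rs1..rs3; counted alleles match effect alleles
DOSAGES_TSV = """\
sample_id\trs1\trs2\trs3
s1\t1\t2\t0
s2\t0\t0\t0
s3\t2\t1\tNA
"""

VARIANTS_TSV = """\
variant_id\tcounted_allele\talternate_allele\tchromosome\tposition
rs1\tA\tG\t1\t1000
rs2\tC\tA\t2\t2000
rs3\tT\tC\t3\t3000
"""

# 3-generation family of 7: grandparents GF+GM -> A; A + spouse H -> D1, D2;
# S married to D1.  Founders: GF, GM, H, S (4).
FAM_7 = """\
FAM1 GF 0 0 1 1
FAM1 GM 0 0 2 1
FAM1 A GF GM 2 2
FAM1 H 0 0 1 1
FAM1 D1 H A 2 1
FAM1 D2 H A 2 1
FAM1 S 0 0 1 1
"""


@pytest.fixture
def score_file():
    return scoring.load_score_file(io.StringIO(WEIGHTS_TSV), name="toy")


@pytest.fixture
def panel():
    return scoring.GenotypePanel.from_dosage_tsv(
        io.StringIO(DOSAGES_TSV), io.StringIO(VARIANTS_TSV)
    )


@pytest.fixture
def ped7():
    return pedigree.parse_pedigree(io.StringIO(FAM_7))


def make_panel(dosages: dict, alleles: dict | None = None) -> scoring.GenotypePanel:
    """Panel from {variant_id: {sample: dosage}}; alleles default A/G."""
    df = pd.DataFrame(dosages, dtype=float)
    df.index.name = "sample_id"
    if alleles is None:
        alleles = {v: ("A", "G") for v in df.columns}
    meta = pd.DataFrame(
        {
            "variant_id": list(df.columns),
            "counted_allele": [alleles[v][0] for v in df.columns],
            "alternate_allele": [alleles[v][1] for v in df.columns],
            "chromosome": "1",
            "position": range(100, 100 + len(df.columns)),
        }
    ).set_index("variant_id")
    return scoring.GenotypePanel(df, meta)


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderately sized cohort with an elevated prevalence so every
    relative group is populated; shared across tests that only read it."""
    cfg = simdata.SimConfig(
        n_families=80,
        n_prs_variants=60,
        or_per_sd=None,
        beta_prs=0.25,
        target_prevalence=0.10,
        n_lof_variants=10,
        seed=42,
    )
    return simdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_prs(sim_cohort):
    report = scoring.harmonize(sim_cohort.score, sim_cohort.panel)
    return scoring.standardize(
        scoring.compute_prs(sim_cohort.score, sim_cohort.panel, report)
    )
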
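"""Shared fixtures and dataset builders for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpepi.data import Dataset, SAMPLE_COLUMNS


def build_dataset(
    genotypes,
    phenotype,
    subtype=None,
    age=None,
    sex=None,
    country=None,
    snp_ids=None,
    alleles=None,
) -> Dataset:
    """Construct a Dataset from plain arrays with sensible defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.ndim == 1:
        g = g[:, None]
    n, m = g.shape
    phenotype = np.asarray(phenotype, dtype=int)
    if subtype is None:
        subtype = np.where(phenotype == 1, "cPTC", "control")
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": phenotype,
            "subtype": subtype,
            "age": age if age is not None else 50.0,
            "sex": sex if sex is not None else "female",
            "country": country if country is not None else "ES",
        }
    )
    if snp_ids is None:
        snp_ids = [f"rs{j+1}" for j in range(m)]
    maj, mnr = ("G", "A") if alleles is None else alleles
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene": [f"GENE{j+1}" for j in range(m)],
            "allele_major": maj,
            "allele_minor": mnr,
            "functional_note": None,
        }
    )
    return Dataset(g, samples[SAMPLE_COLUMNS], snps)


def table_2x2_dataset(case_exposed, case_unexposed, ctrl_exposed, ctrl_unexposed, coding="dominant"):
    """Dataset realizing a 2x2 exposure table under the given coding."""
    if coding == "dominant":
        exposed_geno, unexposed_geno = 1, 0
    elif coding == "recessive":
        exposed_geno, unexposed_geno = 2, 0
    else:
        raise ValueError(coding)
    g = np.concatenate(
        [
            np.full(case_exposed, exposed_geno),
            np.full(case_unexposed, unexposed_geno),
            np.full(ctrl_exposed, exposed_geno),
            np.full(ctrl_unexposed, unexposed_geno),
        ]
    )
    y = np.concatenate(
        [
            np.ones(case_exposed + case_unexposed, dtype=int),
            np.zeros(ctrl_exposed + ctrl_unexposed, dtype=int),
        ]
    )
    return build_dataset(g, y)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Seeded 6-SNP null dataset (no genotype-phenotype association)."""
    rng = np.random.default_rng(42)
    n = 400
    g = rng.binomial(2, 0.3, size=(n, 6))
    y = np.concatenate([np.ones(200, dtype=int), np.zeros(200, dtype=int)])
    return build_dataset(g, y, sex=np.where(rng.random(n) < 0.8, "female", "male"))
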
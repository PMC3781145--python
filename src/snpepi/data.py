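"""Data model and IO for case-control SNP panels.

The single currency of the pipeline is the :class:`Dataset`: a samples x
SNPs genotype matrix coded as minor-allele counts (0/1/2, ``MISSING`` = -1),
a sample table (phenotype, disease subtype, age, sex, country) and a SNP
annotation table.  The minor allele is defined from the *controls* of the
full dataset, so genotype 0 is always the homozygote of the most frequent
control allele — the reference group of every downstream odds ratio — and
stratified subsets inherit that coding unchanged.

Two text dialects are supported: PLINK .ped/.map and a two-file CSV layout
(genotype matrix + sample table).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

SUBTYPES: tuple[str, ...] = ("control", "cPTC", "fvPTC", "otherPTC", "FTC")
CASE_SUBTYPES: tuple[str, ...] = ("cPTC", "fvPTC", "otherPTC", "FTC")
PTC_SUBTYPES: tuple[str, ...] = ("cPTC", "fvPTC", "otherPTC")

#: Named case groups for stratified analyses.
CASE_GROUPS: dict[str, tuple[str, ...]] = {
    "PTC": PTC_SUBTYPES,
    "cPTC": ("cPTC",),
    "fvPTC": ("fvPTC",),
    "FTC": ("FTC",),
    "all": CASE_SUBTYPES,
}

_VALID_ALLELES = set("ACGT")

SAMPLE_COLUMNS = ["sample_id", "phenotype", "subtype", "age", "sex", "country"]
SNP_COLUMNS = ["snp_id", "gene", "allele_major", "allele_minor", "functional_note"]


@dataclass(frozen=True)
class SnpInfo:
    """Annotation for one biallelic SNP (alleles as seen in controls)."""

    snp_id: str
    gene: str = ""
    allele_major: str = "A"
    allele_minor: str = "C"
    functional_note: str | None = None

    def __post_init__(self):
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor allele must differ")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    phenotype: int
    subtype: str
    age: float = np.nan
    sex: str = "female"
    country: str = ""

    def __post_init__(self):
        if self.phenotype not in (0, 1):
            raise ValueError("phenotype must be 0 (control) or 1 (case)")
        if (self.phenotype == 0) != (self.subtype == "control"):
            raise ValueError("phenotype=0 iff subtype=control")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


class Dataset:
    """Genotype matrix + sample table + SNP annotations.

    Parameters
    ----------
    genotypes : (n_samples, n_snps) integer array of minor-allele counts
        with ``MISSING`` (-1) for no-calls.
    samples : DataFrame with columns ``sample_id, phenotype, subtype, age,
        sex, country`` (one row per genotype row).
    snps : DataFrame with columns ``snp_id, gene, allele_major,
        allele_minor, functional_note`` (one row per genotype column).
    """

    def __init__(self, genotypes: np.ndarray, samples: pd.DataFrame, snps: pd.DataFrame):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x SNPs)")
        bad = ~np.isin(genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2,MISSING}")
        samples = samples.reset_index(drop=True)
        snps = snps.reset_index(drop=True)
        if genotypes.shape[0] != len(samples):
            raise ValueError("genotype rows != number of samples")
        if genotypes.shape[1] != len(snps):
            raise ValueError("genotype columns != number of SNPs")
        if samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        if snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id")
        ph = samples["phenotype"].to_numpy()
        if not np.isin(ph, (0, 1)).all():
            raise ValueError("phenotype must be 0/1")
        if ((ph == 0) != (samples["subtype"] == "control").to_numpy()).any():
            raise ValueError("phenotype=0 iff subtype='control'")
        self.genotypes = genotypes
        self.samples = samples
        self.snps = snps
        self._snp_index = {s: i for i, s in enumerate(snps["snp_id"])}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy() == 1

    @property
    def is_control(self) -> np.ndarray:
        return ~self.is_case

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def genotype_column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_cases = int(self.is_case.sum())
        return (
            f"<Dataset {self.n_samples} samples ({n_cases} cases / "
            f"{self.n_samples - n_cases} controls), {self.n_snps} SNPs>"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and _frames_equal(self.samples, other.samples)
            and _frames_equal(self.snps, other.snps)
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for c in a.columns:
        x, y = a[c], b[c]
        if x.dtype.kind == "f" or y.dtype.kind == "f":
            if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                return False
        elif not (x.fillna("").astype(str) == y.fillna("").astype(str)).all():
            return False
    return True


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _resolve_minor(allele_counts_controls: dict[str, int], allele_counts_all: dict[str, int], snp_id: str):
    """Major/minor call from control allele counts (full-sample fallback).

    Tie at 0.5 -> lexicographically smaller character is minor.  If only one
    allele was ever observed the minor allele is unobserved; a placeholder
    (first ACGT character differing from the major) keeps major != minor.
    """
    observed = sorted(a for a, c in allele_counts_all.items() if c > 0)
    if len(observed) > 2:
        raise ValueError(f"{snp_id}: more than two alleles observed")
    counts = allele_counts_controls if sum(allele_counts_controls.values()) else allele_counts_all
    alleles = sorted(a for a, c in counts.items() if c > 0)
    if len(alleles) < 2 and len(observed) == 2:
        # allele seen only in cases: control frequency 0, so it is minor
        counts = allele_counts_all
        major = max(observed, key=lambda a: (allele_counts_controls.get(a, 0), a))
        minor = next(a for a in observed if a != major)
        return major, minor
    if len(alleles) == 0:
        return "A", "C"
    if len(alleles) == 1:
        major = alleles[0]
        minor = next(a for a in "ACGT" if a != major)
        return major, minor
    a, b = alleles  # a < b lexicographically
    if counts[a] == counts[b]:
        return b, a
    return (a, b) if counts[a] > counts[b] else (b, a)


def read_plink(ped_path, map_path, sample_table: pd.DataFrame | None = None) -> Dataset:
    """Read PLINK text .ped/.map into a :class:`Dataset`.

    Genotypes are recoded to minor-allele counts with the minor allele
    determined from controls (PLINK phenotype 1=control, 2=case); the
    allele pair ``0 0`` becomes ``MISSING``.  PLINK text carries no subtype
    or covariates beyond sex; an optional ``sample_table`` (same columns as
    the tabular dialect, matched on sample_id) supplies them and overrides
    the .ped sex field.  Without it cases are recorded as subtype
    ``otherPTC``, age/country missing, and .ped sex 1=male / 2=female.
    """
    snps_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"snp_id": str},
    )
    n_snps = len(snps_map)
    sample_ids: list[str] = []
    sexes: list[str] = []
    phenos: list[int] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path} line {line_no}: expected {6 + 2 * n_snps} fields, got {len(tok)}"
                )
            sample_ids.append(tok[1])
            sexes.append({"1": "male", "2": "female"}.get(tok[4], "female"))
            ph = tok[5]
            if ph not in ("1", "2"):
                raise ValueError(f"{ped_path} line {line_no}: phenotype must be 1/2, got {ph!r}")
            phenos.append(0 if ph == "1" else 1)
            alleles = tok[6:]
            for a in alleles:
                if a not in _VALID_ALLELES and a != "0":
                    raise ValueError(f"{ped_path} line {line_no}: invalid allele {a!r}")
            rows.append(alleles)
    allele_arr = np.array(rows, dtype="U1").reshape(len(rows), n_snps, 2)
    pheno_arr = np.array(phenos)
    is_control = pheno_arr == 0

    geno = np.full((len(rows), n_snps), MISSING, dtype=np.int8)
    majors, minors = [], []
    for j in range(n_snps):
        pair = allele_arr[:, j, :]
        called = (pair != "0").all(axis=1)
        if ((pair == "0").sum(axis=1) == 1).any():
            raise ValueError(f"SNP {snps_map['snp_id'][j]}: half-missing genotype call")
        cc: dict[str, int] = {}
        ca: dict[str, int] = {}
        for a in np.unique(pair[called]):
            ca[a] = int((pair[called] == a).sum())
            cc[a] = int((pair[called & is_control] == a).sum())
        major, minor = _resolve_minor(cc, ca, str(snps_map["snp_id"][j]))
        majors.append(major)
        minors.append(minor)
        geno[called, j] = (pair[called] == minor).sum(axis=1)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": pheno_arr,
            "subtype": np.where(is_control, "control", "otherPTC"),
            "age": np.nan,
            "sex": sexes,
            "country": "",
        }
    )
    if sample_table is not None:
        st = sample_table.set_index("sample_id")
        missing_ids = [s for s in sample_ids if s not in st.index]
        if missing_ids:
            raise ValueError(f"sample table missing ids: {missing_ids[:5]}")
        st = st.loc[sample_ids].reset_index()
        if (st["phenotype"].to_numpy() != pheno_arr).any():
            raise ValueError("phenotype mismatch between .ped and sample table")
        samples = st[SAMPLE_COLUMNS]
    snps = pd.DataFrame(
        {
            "snp_id": snps_map["snp_id"],
            "gene": "",
            "allele_major": majors,
            "allele_minor": minors,
            "functional_note": None,
        }
    )
    return Dataset(geno, samples, snps)


def write_plink(dataset: Dataset, ped_path, map_path) -> None:
    """Write a Dataset as PLINK text (.ped/.map)."""
    with open(map_path, "w") as fh:
        for _, row in dataset.snps.iterrows():
            fh.write(f"1\t{row['snp_id']}\t0\t0\n")
    maj = dataset.snps["allele_major"].to_numpy()
    mnr = dataset.snps["allele_minor"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, row in dataset.samples.iterrows():
            sex = "1" if row["sex"] == "male" else "2"
            ph = "2" if row["phenotype"] == 1 else "1"
            fields = [str(row["sample_id"]), str(row["sample_id"]), "0", "0", sex, ph]
            g = dataset.genotypes[i]
            for j, gj in enumerate(g):
                if gj == MISSING:
                    fields += ["0", "0"]
                elif gj == 0:
                    fields += [maj[j], maj[j]]
                elif gj == 1:
                    fields += [maj[j], mnr[j]]
                else:
                    fields += [mnr[j], mnr[j]]
            fh.write(" ".join(fields) + "\n")


def read_tabular(genotype_csv, sample_csv, snp_table: pd.DataFrame | None = None) -> Dataset:
    """Read the two-file CSV dialect.

    ``genotype_csv``: samples x SNPs matrix of {0,1,2,NA} with a
    ``sample_id`` first column and snp_ids as header.  ``sample_csv``:
    columns ``sample_id, phenotype, subtype, age, sex, country``.  Rows are
    aligned on sample_id; an id present in only one file is an error.
    """
    gdf = pd.read_csv(genotype_csv, dtype={"sample_id": str})
    sdf = pd.read_csv(sample_csv, dtype={"sample_id": str})
    for col in SAMPLE_COLUMNS:
        if col not in sdf.columns:
            raise ValueError(f"sample file missing column {col!r}")
    gids, sids = set(gdf["sample_id"]), set(sdf["sample_id"])
    if gids != sids:
        odd = sorted((gids ^ sids))[:5]
        raise ValueError(f"sample_id mismatch between files: {odd}")
    sdf = sdf.set_index("sample_id").loc[gdf["sample_id"]].reset_index()
    snp_ids = [c for c in gdf.columns if c != "sample_id"]
    raw = gdf[snp_ids]
    arr = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    unparsable = np.isnan(arr) & raw.notna().to_numpy()
    bad_value = ~np.isnan(arr) & ~np.isin(arr, (0.0, 1.0, 2.0))
    if unparsable.any() or bad_value.any():
        i, j = np.argwhere(unparsable | bad_value)[0]
        raise ValueError(
            f"invalid genotype token {raw.iat[i, j]!r} for {snp_ids[j]} (must be 0/1/2/NA)"
        )
    geno = np.where(np.isnan(arr), MISSING, arr).astype(np.int8)
    sdf["age"] = pd.to_numeric(sdf["age"], errors="coerce")
    sdf["country"] = sdf["country"].fillna("")
    if snp_table is not None:
        snps = snp_table.set_index("snp_id").loc[snp_ids].reset_index()[SNP_COLUMNS]
    else:
        snps = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "gene": "",
                "allele_major": "A",
                "allele_minor": "C",
                "functional_note": None,
            }
        )
    return Dataset(geno, sdf[SAMPLE_COLUMNS], snps)


def write_tabular(dataset: Dataset, genotype_csv, sample_csv) -> None:
    """Write the two-file CSV dialect (NA for missing genotypes)."""
    g = dataset.genotypes.astype(object)
    gdf = pd.DataFrame(
        np.where(g == MISSING, np.nan, g),
        columns=dataset.snps["snp_id"],
    )
    gdf.insert(0, "sample_id", dataset.samples["sample_id"])
    gdf.to_csv(genotype_csv, index=False, float_format="%.0f")
    dataset.samples.to_csv(sample_csv, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _group_mask(dataset: Dataset, group) -> np.ndarray:
    if group is None:
        return np.ones(dataset.n_samples, dtype=bool)
    if isinstance(group, str):
        if group == "all":
            return np.ones(dataset.n_samples, dtype=bool)
        if group == "controls":
            return dataset.is_control
        if group == "cases":
            return dataset.is_case
        if group in SUBTYPES:
            return (dataset.samples["subtype"] == group).to_numpy()
        raise ValueError(f"unknown group {group!r}")
    return np.asarray(group, dtype=bool)


def minor_allele_freq(dataset: Dataset, snp_id: str, group=None) -> float:
    """Minor-allele frequency in a sample group (missing excluded)."""
    g = dataset.genotype_column(snp_id)[_group_mask(dataset, group)]
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError(f"{snp_id}: no non-missing genotypes in group")
    return float(g.sum()) / (2.0 * g.size)


def stratify(dataset: Dataset, case_group: Iterable[str] | str) -> Dataset:
    """All controls plus only cases whose subtype is in ``case_group``.

    ``case_group`` may be a named group ("PTC", "cPTC", ...) or an iterable
    of case subtypes.  Genotype coding is inherited unchanged (the minor
    allele stays anchored to the full control set).
    """
    if isinstance(case_group, str):
        subtypes = CASE_GROUPS.get(case_group, (case_group,))
    else:
        subtypes = tuple(case_group)
    if len(subtypes) == 0:
        raise ValueError("case_group must be nonempty")
    bad = [s for s in subtypes if s not in CASE_SUBTYPES]
    if bad:
        raise ValueError(f"not case subtypes: {bad}")
    keep = dataset.is_control | dataset.samples["subtype"].isin(subtypes).to_numpy()
    if not (dataset.samples["subtype"].isin(subtypes)).any():
        raise ValueError(f"no cases with subtype in {subtypes}")
    return Dataset(
        dataset.genotypes[keep],
        dataset.samples.loc[keep],
        dataset.snps.copy(),
    )


def concat_datasets(datasets: Sequence[Dataset], series_labels: Sequence[str] | None = None) -> Dataset:
    """Stack datasets sharing an identical SNP panel, adding a ``series`` column."""
    first = datasets[0]
    for d in datasets[1:]:
        if list(d.snps["snp_id"]) != list(first.snps["snp_id"]):
            raise ValueError("SNP panels differ")
        if not (
            (d.snps["allele_major"] == first.snps["allele_major"]).all()
            and (d.snps["allele_minor"] == first.snps["allele_minor"]).all()
        ):
            raise ValueError("allele coding differs between datasets")
    if series_labels is None:
        series_labels = [f"S{i+1}" for i in range(len(datasets))]
    geno = np.vstack([d.genotypes for d in datasets])
    tabs = []
    for d, lab in zip(datasets, series_labels):
        t = d.samples.copy()
        t["series"] = lab
        t["sample_id"] = lab + ":" + t["sample_id"].astype(str)
        tabs.append(t)
    samples = pd.concat(tabs, ignore_index=True)
    out = Dataset(geno, samples[SAMPLE_COLUMNS], first.snps.copy())
    out.samples["series"] = samples["series"].to_numpy()
    return out
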
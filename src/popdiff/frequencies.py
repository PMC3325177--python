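"""Per-population allele frequencies, region pooling, and frequency matching.

The central container is :class:`FrequencyTable`, a long-format table of
per-population allele frequencies (one row per SNP x population) emulating
the multi-population reference panels (HapMap-style 11-population and
HGDP-style 53-population) that risk-allele analyses are run against.

A SNP is described by its two alleles ``allele_a``/``allele_b`` and the
frequency of ``allele_a``; the risk-allele frequency (RAF) is obtained by
orienting the stored frequency to whichever allele plays the risk role.
Populations are pooled into continental regions (Sub-Saharan Africa, Europe,
East Asia, ...) via a :class:`RegionMap`; pooling is allele-count weighted
whenever chromosome counts are known, which is equivalent to pooling the
underlying genotypes.

Frequency-matched control pools — the backbone of the empirical null used
throughout the differentiation tests — are built here: for a target risk
allele at reference-region frequency ``t``, every other SNP contributes the
allele (if any) whose reference-region frequency lies within ``t ± tol``.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    IncompatibleAllelesError,
    InsufficientControlsError,
    MissingDataError,
    ParameterError,
    SchemaError,
)

VALID_BASES = frozenset("ACGT")

FREQ_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "allele_a",
    "allele_b",
    "population",
    "freq_a",
    "n_chromosomes",
]

#: Default grouping of reference-panel populations into continental regions.
#: The ``hapmap`` scheme follows the 11-population panel convention
#: (African = ASW/MKK/LWK/YRI, European = TSI/CEU, Asian = JPT/CHB/CHD);
#: the ``hgdp`` scheme lists the indigenous populations conventionally
#: assigned to the three major continental regions.  Users may override
#: either via a YAML region map.
DEFAULT_SCHEMES: dict[str, dict[str, list[str]]] = {
    "hapmap": {
        "African": ["ASW", "MKK", "LWK", "YRI"],
        "European": ["TSI", "CEU"],
        "Asian": ["JPT", "CHB", "CHD"],
    },
    "hgdp": {
        "Sub-Saharan Africa": [
            "BantuSouthAfrica",
            "BiakaPygmies",
            "Mandenka",
            "MbutiPygmies",
            "San",
            "Yoruba",
            "BantuKenya",
        ],
        "East Asia": [
            "Cambodian",
            "Dai",
            "Daur",
            "Han",
            "Han-NChina",
            "Hezhen",
            "Japanese",
            "Lahu",
            "Miao",
            "Mongola",
            "Naxi",
            "Oroqen",
            "She",
            "Tu",
            "Tujia",
            "Uygur",
            "Xibo",
            "Yakut",
            "Yi",
        ],
        "Europe": [
            "Adygei",
            "Basque",
            "French",
            "Italian",
            "Orcadian",
            "Russian",
            "Sardinian",
            "Tuscan",
        ],
    },
}


class RegionMap:
    """Maps populations to geographic regions (one region per population)."""

    def __init__(self, regions: Mapping[str, Sequence[str]]):
        self.regions: dict[str, list[str]] = {r: list(p) for r, p in regions.items()}
        self._pop2region: dict[str, str] = {}
        for region, pops in self.regions.items():
            for pop in pops:
                if pop in self._pop2region and self._pop2region[pop] != region:
                    raise SchemaError(
                        f"population {pop!r} assigned to both "
                        f"{self._pop2region[pop]!r} and {region!r}"
                    )
                self._pop2region[pop] = region

    @classmethod
    def default(cls, scheme: str = "hapmap") -> "RegionMap":
        try:
            return cls(DEFAULT_SCHEMES[scheme])
        except KeyError:
            raise ParameterError(
                f"unknown region scheme {scheme!r}; available: {sorted(DEFAULT_SCHEMES)}"
            ) from None

    @classmethod
    def from_yaml(cls, path, scheme: str | None = None) -> "RegionMap":
        """Load ``scheme -> region -> [population...]`` (or a bare region map)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise SchemaError(f"{path}: region map must be a mapping")
        if scheme is not None:
            if scheme not in doc:
                raise SchemaError(f"{path}: scheme {scheme!r} not found")
            doc = doc[scheme]
        # accept either {region: [pops]} directly or a single-scheme wrapper
        if doc and all(isinstance(v, dict) for v in doc.values()):
            if len(doc) != 1:
                raise SchemaError(f"{path}: multiple schemes present; pass scheme=")
            doc = next(iter(doc.values()))
        return cls(doc)

    @property
    def region_names(self) -> list[str]:
        return list(self.regions)

    def populations_in(self, region: str) -> list[str]:
        try:
            return self.regions[region]
        except KeyError:
            raise MissingDataError(f"unknown region {region!r}") from None

    def region_of(self, population: str) -> str | None:
        return self._pop2region.get(population)

    def __contains__(self, region: str) -> bool:
        return region in self.regions


@dataclasses.dataclass
class ControlPool:
    """Frequency-matched control alleles for one target risk allele.

    ``members[i]`` is matched through the orientation given by
    ``orient_a[i]``: when True the SNP's ``allele_a`` plays the risk role,
    otherwise ``allele_b``.  ``member_freq`` holds the matched (oriented)
    frequency in the matching region.
    """

    target_rsid: str
    matching_region: str
    tolerance: float
    members: np.ndarray  # rsids, dtype=object
    orient_a: np.ndarray  # bool
    member_freq: np.ndarray  # float, oriented frequency in matching region
    target_freq: float

    @property
    def size(self) -> int:
        return len(self.members)


class FrequencyTable:
    """Long-format per-population allele-frequency table.

    Parameters
    ----------
    df
        Columns ``rsid, chrom, pos, allele_a, allele_b, population, freq_a,
        n_chromosomes``.  Rows with ``freq_a`` outside [0, 1] are rejected
        with a warning; duplicate (rsid, population) rows resolve last-wins
        with a warning.  ``n_chromosomes == 0`` means "count unknown".
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FREQ_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"frequency table missing columns: {missing}")
        df = df.loc[:, FREQ_COLUMNS].copy()
        df["freq_a"] = pd.to_numeric(df["freq_a"], errors="coerce")
        df["n_chromosomes"] = (
            pd.to_numeric(df["n_chromosomes"], errors="coerce").fillna(0).astype(int)
        )
        bad = ~df["freq_a"].between(0.0, 1.0)
        if bad.any():
            warnings.warn(
                f"rejected {int(bad.sum())} row(s) with freq_a outside [0, 1]",
                stacklevel=2,
            )
            df = df.loc[~bad]
        dup = df.duplicated(subset=["rsid", "population"], keep="last")
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate (rsid, population) row(s); keeping last",
                stacklevel=2,
            )
            df = df.loc[~dup]
        self.df = df.reset_index(drop=True)
        self._freq_wide: pd.DataFrame | None = None
        self._count_wide: pd.DataFrame | None = None
        self._alleles: pd.DataFrame | None = None
        self._pooled_cache: dict[tuple, tuple[pd.Series, pd.Series, bool]] = {}

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "population": str, "chrom": str})
        return cls(df)

    @classmethod
    def from_vcf(cls, path) -> "FrequencyTable":
        """Read per-population frequencies from INFO tags ``AF_<pop>``/``AN_<pop>``.

        ``allele_a`` is the ALT allele (matching the VCF AF convention),
        ``allele_b`` the REF allele.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        af_keys = [
            h["ID"]
            for h in (vcf.header_iter())
            if h["HeaderType"] == "INFO" and str(h["ID"]).startswith("AF_")
        ]
        pops = [k[3:] for k in af_keys]
        if not pops:
            raise SchemaError(f"{path}: no AF_<population> INFO tags found")
        rows = []
        for v in vcf:
            for pop in pops:
                af = v.INFO.get(f"AF_{pop}")
                if af is None:
                    continue
                an = v.INFO.get(f"AN_{pop}") or 0
                rows.append(
                    (v.ID, v.CHROM, v.POS, v.ALT[0], v.REF, pop, float(af), int(an))
                )
        return cls(pd.DataFrame(rows, columns=FREQ_COLUMNS))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    # -- basic access -----------------------------------------------------

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    @property
    def rsids(self) -> list[str]:
        return list(self._allele_frame().index)

    def _allele_frame(self) -> pd.DataFrame:
        if self._alleles is None:
            self._alleles = (
                self.df.drop_duplicates("rsid")
                .set_index("rsid")[["allele_a", "allele_b", "chrom", "pos"]]
            )
        return self._alleles

    def freq_matrix(self) -> pd.DataFrame:
        """SNP x population matrix of ``freq_a`` (NaN where unobserved)."""
        if self._freq_wide is None:
            self._freq_wide = self.df.pivot(
                index="rsid", columns="population", values="freq_a"
            ).reindex(self._allele_frame().index)
        return self._freq_wide

    def count_matrix(self) -> pd.DataFrame:
        if self._count_wide is None:
            self._count_wide = (
                self.df.pivot(index="rsid", columns="population", values="n_chromosomes")
                .reindex(self._allele_frame().index)
                .fillna(0)
                .astype(int)
            )
        return self._count_wide

    def alleles(self, rsid: str) -> tuple[str, str]:
        try:
            row = self._allele_frame().loc[rsid]
        except KeyError:
            raise MissingDataError(f"rsid {rsid!r} not in frequency table") from None
        return str(row["allele_a"]), str(row["allele_b"])

    def freq_a(self, rsid: str, population: str) -> float:
        mat = self.freq_matrix()
        if rsid not in mat.index:
            raise MissingDataError(f"rsid {rsid!r} not in frequency table")
        if population not in mat.columns:
            raise MissingDataError(f"population {population!r} not in frequency table")
        val = mat.at[rsid, population]
        if pd.isna(val):
            raise MissingDataError(f"no frequency for {rsid!r} in {population!r}")
        return float(val)

    # -- pooling ----------------------------------------------------------

    def pooled(
        self, region_map: RegionMap, region: str
    ) -> tuple[pd.Series, pd.Series, bool]:
        """Pool member populations of ``region`` for every SNP.

        Returns ``(freq, n_chromosomes, weighted)``.  The pooled frequency is
        the allele-count-weighted mean of ``freq_a`` when chromosome counts
        are known for every member population observed in the table, and the
        unweighted mean otherwise (``weighted`` records which).  Populations
        missing a SNP are ignored for that SNP.
        """
        key = (id(region_map), region)
        if key in self._pooled_cache:
            return self._pooled_cache[key]
        pops = [p for p in region_map.populations_in(region) if p in self.freq_matrix().columns]
        if not pops:
            raise MissingDataError(
                f"no member population of region {region!r} present in table"
            )
        freq = self.freq_matrix()[pops]
        counts = self.count_matrix()[pops]
        observed = freq.notna()
        weighted = bool((counts.values[observed.values] > 0).all())
        if weighted:
            w = counts.where(observed, 0)
            tot = w.sum(axis=1)
            pooled = (freq.fillna(0) * w).sum(axis=1) / tot.replace(0, np.nan)
            n = tot
        else:
            pooled = freq.mean(axis=1)
            n = counts.where(observed, 0).sum(axis=1)
        out = (pooled, n, weighted)
        self._pooled_cache[key] = out
        return out

    def region_matrix(
        self, region_map: RegionMap, regions: Sequence[str]
    ) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
        """Pooled ``freq_a`` and chromosome counts, SNP x region."""
        freqs, counts, weighted = {}, {}, True
        for r in regions:
            f, n, w = self.pooled(region_map, r)
            freqs[r], counts[r] = f, n
            weighted = weighted and w
        return pd.DataFrame(freqs), pd.DataFrame(counts), weighted

    # -- risk-allele orientation ------------------------------------------

    def _orient(self, rsid: str, risk_allele: str, freq_a: float) -> float:
        a, b = self.alleles(rsid)
        if risk_allele == a:
            return freq_a
        if risk_allele == b:
            return 1.0 - freq_a
        raise IncompatibleAllelesError(
            f"risk allele {risk_allele!r} not among alleles ({a}, {b}) of {rsid!r}"
        )

    def raf(
        self,
        rsid: str,
        risk_allele: str,
        where: str,
        region_map: RegionMap | None = None,
    ) -> float:
        """Risk-allele frequency in a population or a pooled region.

        ``where`` is tried first as a region of ``region_map`` (pooled
        frequency over member populations), then as a population label.
        """
        if region_map is not None and where in region_map:
            pooled, _, _ = self.pooled(region_map, where)
            val = pooled.get(rsid)
            if val is None or pd.isna(val):
                raise MissingDataError(f"no pooled frequency for {rsid!r} in region {where!r}")
            return self._orient(rsid, risk_allele, float(val))
        return self._orient(rsid, risk_allele, self.freq_a(rsid, where))


def pool_region(
    table: FrequencyTable, region_map: RegionMap, region: str
) -> tuple[pd.Series, pd.Series, bool]:
    """Functional alias for :meth:`FrequencyTable.pooled`."""
    return table.pooled(region_map, region)


def load_frequencies(path) -> FrequencyTable:
    """Load a frequency table from TSV (``.tsv``/``.txt``) or VCF."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return FrequencyTable.from_vcf(p)
    return FrequencyTable.from_tsv(p)


def maf_bin(freq):
    """5%-wide minor-allele-frequency bin index, 0..9.

    MAF = min(freq, 1 - freq); bins are half-open [0, 0.05), ..., [0.45, 0.5)
    with the boundary MAF = 0.5 assigned to the top bin.
    """
    arr = np.asarray(freq, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("frequency outside [0, 1]")
    maf = np.minimum(arr, 1.0 - arr)
    bins = np.minimum(np.floor(maf / 0.05).astype(int), 9)
    if np.ndim(freq) == 0:
        return int(bins)
    return bins


def build_control_pool(
    table: FrequencyTable,
    target_rsid: str,
    matching_region: str,
    tolerance: float,
    region_map: RegionMap,
    exclusions: Iterable[str] = (),
    risk_allele: str | None = None,
    min_pool: int = 50,
    allele_level: bool = True,
    candidates: Sequence[str] | None = None,
) -> ControlPool:
    """All alleles frequency-matched to a target risk allele in one region.

    With ``allele_level=True`` (default) each candidate SNP contributes the
    allele whose pooled ``matching_region`` frequency lies within
    ``target ± tolerance`` (if both alleles match — possible only near 0.5 —
    the closer one is used).  With ``allele_level=False`` matching is on the
    SNP's minor-allele frequency instead, and the member is oriented to the
    same side of 0.5 as the target.

    ``candidates`` restricts the pool (e.g. to risk alleles of other
    diseases); the target and ``exclusions`` are never members.
    """
    if not (0 < tolerance) and tolerance != 0.0:
        raise ParameterError("tolerance must be >= 0")
    if risk_allele is None:
        risk_allele = table.alleles(target_rsid)[0]
    pooled, _, _ = table.pooled(region_map, matching_region)
    tval = pooled.get(target_rsid)
    if tval is None or pd.isna(tval):
        raise MissingDataError(
            f"target {target_rsid!r} has no frequency in region {matching_region!r}"
        )
    target = table._orient(target_rsid, risk_allele, float(tval))

    if candidates is not None:
        pooled = pooled.reindex([c for c in candidates if c in pooled.index])
    excl = set(exclusions) | {target_rsid}
    pooled = pooled[~pooled.index.isin(excl)].dropna()
    fa = pooled.to_numpy(dtype=float)
    rsids = pooled.index.to_numpy(dtype=object)

    if allele_level:
        da = np.abs(fa - target)
        db = np.abs((1.0 - fa) - target)
        match_a = da <= tolerance
        match_b = db <= tolerance
        keep = match_a | match_b
        orient_a = np.where(match_a & match_b, da <= db, match_a)[keep]
    else:
        maf_t = min(target, 1.0 - target)
        maf = np.minimum(fa, 1.0 - fa)
        keep = np.abs(maf - maf_t) <= tolerance
        # orient the member to the target's side of 0.5
        orient_a = ((fa > 0.5) if target > 0.5 else (fa <= 0.5))[keep]

    members = rsids[keep]
    freqs = np.where(orient_a, fa[keep], 1.0 - fa[keep])
    if len(members) < min_pool:
        raise InsufficientControlsError(
            f"control pool for {target_rsid!r} has {len(members)} member(s) "
            f"(< {min_pool}); consider widening the tolerance (±{tolerance})"
        )
    return ControlPool(
        target_rsid=target_rsid,
        matching_region=matching_region,
        tolerance=float(tolerance),
        members=members,
        orient_a=orient_a,
        member_freq=freqs,
        target_freq=float(target),
    )
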
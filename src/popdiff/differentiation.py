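"""Directional population differentiation of risk-allele frequencies.

Three complementary views of how unusual a set of risk alleles is, relative
to the genome, in its frequency differences between continental regions:

* **Per-SNP joint tail** (:func:`snp_directional_p`): among all genomic
  alleles matched on the European (reference-region) frequency of the risk
  allele, the fraction showing *both* a higher frequency in the high region
  (e.g. Africa) *and* a lower frequency in the low region (e.g. East Asia)
  than observed.

* **Ensemble resampling** (:func:`ensemble_test`): the mean frequency
  increase of the k risk alleles in one region versus the reference region,
  compared against a null distribution obtained by repeatedly drawing one
  frequency-matched allele per risk allele — from the genome, or from the
  risk alleles of other diseases — and recording the resampled mean.

* **FST** (:func:`genome_fst`, :func:`fst_enrichment`): Nei-style fixation
  index on pooled regions, compared per 5% MAF bin against the genome-wide
  distribution (empirical percentiles and a one-sided Mann-Whitney U test
  on bin-normalized values).

Directionality is the point: FST ignores the *sign* of the frequency
differences, while the joint-tail and ensemble statistics reward alleles
shifting consistently along the same geographic axis.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    InsufficientDataError,
    MissingDataError,
    ParameterError,
)
from .frequencies import (
    ControlPool,
    FrequencyTable,
    RegionMap,
    build_control_pool,
    maf_bin,
)

# ---------------------------------------------------------------------------
# per-SNP joint-tail test


@dataclasses.dataclass
class SnpDirectionalResult:
    rsid: str
    risk_allele: str
    p_value: float
    pool_size: int
    n_extreme: int
    raf_high: float
    raf_low: float
    raf_ref: float


def snp_directional_p(
    table: FrequencyTable,
    rsid: str,
    risk_allele: str,
    region_map: RegionMap,
    region_high: str,
    region_low: str,
    region_ref: str,
    tolerance: float = 0.01,
    min_pool: int = 50,
    exclusions: Sequence[str] = (),
    allele_level: bool = True,
) -> SnpDirectionalResult:
    """Joint-tail empirical p for one risk allele.

    p = (# matched control alleles with ``region_high`` frequency strictly
    above the observed RAF_high AND ``region_low`` frequency strictly below
    the observed RAF_low) / pool size, floored at ``1 / (pool size + 1)``
    when the count is zero.  Matching is on the reference-region frequency
    (± ``tolerance``) of the allele playing the risk role.
    """
    pool = build_control_pool(
        table,
        rsid,
        region_ref,
        tolerance,
        region_map,
        exclusions=exclusions,
        risk_allele=risk_allele,
        min_pool=min_pool,
        allele_level=allele_level,
    )
    obs_high = table.raf(rsid, risk_allele, region_high, region_map)
    obs_low = table.raf(rsid, risk_allele, region_low, region_map)

    f_high, f_low = _oriented_member_freqs(table, region_map, pool, (region_high, region_low))
    ok = ~(np.isnan(f_high) | np.isnan(f_low))
    f_high, f_low = f_high[ok], f_low[ok]
    size = int(ok.sum())
    if size == 0:
        raise InsufficientDataError(
            f"{rsid}: no pool member has frequencies in both contrast regions"
        )
    n_extreme = int(np.sum((f_high > obs_high) & (f_low < obs_low)))
    p = n_extreme / size if n_extreme > 0 else 1.0 / (size + 1)
    return SnpDirectionalResult(
        rsid=rsid,
        risk_allele=risk_allele,
        p_value=p,
        pool_size=size,
        n_extreme=n_extreme,
        raf_high=obs_high,
        raf_low=obs_low,
        raf_ref=pool.target_freq,
    )


def _oriented_member_freqs(
    table: FrequencyTable,
    region_map: RegionMap,
    pool: ControlPool,
    regions: Sequence[str],
) -> list[np.ndarray]:
    """Pooled regional frequencies of each pool member, in matched orientation."""
    out = []
    for region in regions:
        pooled, _, _ = table.pooled(region_map, region)
        fa = pooled.reindex(pool.members).to_numpy(dtype=float)
        out.append(np.where(pool.orient_a, fa, 1.0 - fa))
    return out


# ---------------------------------------------------------------------------
# ensemble resampling test


@dataclasses.dataclass
class DirectionalResult:
    """Observed mean frequency increase of an ensemble and its resampling null."""

    snps: list[str]
    risk_alleles: list[str]
    contrast: tuple[str, str]  # (region, reference region)
    observed_delta: float
    null_deltas: np.ndarray
    p_two_sided: float
    null_source: str
    n_resamples: int
    seed: int
    pool_sizes: list[int]
    dropped: list[str]

    def to_provenance(self) -> dict:
        return {
            "snps": self.snps,
            "risk_alleles": self.risk_alleles,
            "contrast": list(self.contrast),
            "observed_delta": self.observed_delta,
            "p_two_sided": self.p_two_sided,
            "null_source": self.null_source,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "pool_sizes": self.pool_sizes,
            "dropped": self.dropped,
        }


def build_ensemble_pools(
    table: FrequencyTable,
    targets: Sequence[tuple[str, str]],
    region_map: RegionMap,
    region_ref: str,
    tolerance: float = 0.05,
    source_alleles: Sequence[tuple[str, str]] | None = None,
    min_pool: int = 1,
    allele_level: bool = True,
) -> list[ControlPool]:
    """One frequency-matched control pool per target ``(rsid, risk_allele)``.

    ``source_alleles=None`` draws from the whole genome table (both
    orientations of every SNP eligible); a list of ``(rsid, risk_allele)``
    pairs restricts the pool to those alleles with their stated orientation
    (the other-diseases null).  All target rsids are excluded from every
    pool.
    """
    exclusions = [rsid for rsid, _ in targets]
    if source_alleles is None:
        return [
            build_control_pool(
                table,
                rsid,
                region_ref,
                tolerance,
                region_map,
                exclusions=exclusions,
                risk_allele=risk,
                min_pool=min_pool,
                allele_level=allele_level,
            )
            for rsid, risk in targets
        ]

    # fixed-orientation candidate list
    pooled, _, _ = table.pooled(region_map, region_ref)
    cand = [(r, a) for r, a in source_alleles if r in pooled.index and r not in set(exclusions)]
    if not cand:
        raise DataError("no source allele present in the frequency table")
    rsids = np.array([r for r, _ in cand], dtype=object)
    fa = pooled.reindex([r for r, _ in cand]).to_numpy(dtype=float)
    is_a = np.array([a == table.alleles(r)[0] for r, a in cand])
    oriented = np.where(is_a, fa, 1.0 - fa)
    valid = ~np.isnan(oriented)

    pools = []
    for rsid, risk in targets:
        target = table.raf(rsid, risk, region_ref, region_map)
        keep = valid & (np.abs(oriented - target) <= tolerance)
        if keep.sum() < min_pool:
            raise DataError(
                f"source pool for {rsid!r} has {int(keep.sum())} member(s) (< {min_pool})"
            )
        pools.append(
            ControlPool(
                target_rsid=rsid,
                matching_region=region_ref,
                tolerance=float(tolerance),
                members=rsids[keep],
                orient_a=is_a[keep],
                member_freq=oriented[keep],
                target_freq=float(target),
            )
        )
    return pools


def ensemble_null(
    table: FrequencyTable,
    pools: Sequence[ControlPool],
    region_map: RegionMap,
    contrast: tuple[str, str],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the resampled mean frequency increase.

    Each resample draws one member per pool (uniformly, independently across
    pools, with replacement across resamples) and records the mean of the
    members' own ``region - reference`` frequency differences, in matched
    orientation.
    """
    if not pools:
        raise ParameterError("no control pools supplied")
    region, region_ref = contrast
    rng = np.random.default_rng(seed)
    total = np.zeros(n_resamples)
    for pool in pools:
        f_reg, f_ref = _oriented_member_freqs(table, region_map, pool, (region, region_ref))
        delta = f_reg - f_ref
        delta = delta[~np.isnan(delta)]
        if delta.size == 0:
            raise DataError(
                f"control pool for {pool.target_rsid!r} has no member with "
                f"frequencies in both contrast regions"
            )
        total += delta[rng.integers(0, delta.size, size=n_resamples)]
    return total / len(pools)


def empirical_two_sided_p(null: np.ndarray, observed: float) -> float:
    """Doubled smaller tail with +1 continuity on numerator and denominator."""
    n = len(null)
    tail_ge = int(np.sum(null >= observed)) + 1
    tail_le = int(np.sum(null <= observed)) + 1
    return min(1.0, 2.0 * min(tail_ge, tail_le) / (n + 1))


def ensemble_test(
    table: FrequencyTable,
    snps: Sequence[tuple[str, str]],
    region_map: RegionMap,
    contrast: tuple[str, str],
    null_source: str = "genome",
    source_alleles: Sequence[tuple[str, str]] | None = None,
    n_resamples: int = 10_000,
    tolerance: float = 0.05,
    seed: int = 0,
    min_pool: int = 1,
    allele_level: bool = True,
) -> DirectionalResult:
    """Directional differentiation of a risk-allele ensemble in one contrast.

    ``snps`` is a list of ``(rsid, risk_allele)``.  SNPs lacking a frequency
    in either contrast region are dropped with a named warning; at least two
    must remain.  The two-sided p doubles the smaller continuity-corrected
    tail of the resampling null and is capped at 1.
    """
    if null_source not in ("genome", "diseases"):
        raise ParameterError(f"null_source must be 'genome' or 'diseases', got {null_source!r}")
    if null_source == "diseases" and source_alleles is None:
        raise ParameterError("null_source='diseases' requires source_alleles")
    region, region_ref = contrast
    usable: list[tuple[str, str]] = []
    deltas: list[float] = []
    dropped: list[str] = []
    for rsid, risk in snps:
        try:
            d = table.raf(rsid, risk, region, region_map) - table.raf(
                rsid, risk, region_ref, region_map
            )
        except MissingDataError:
            dropped.append(rsid)
            continue
        usable.append((rsid, risk))
        deltas.append(d)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} SNP(s) lacking frequency data: {dropped}",
            stacklevel=2,
        )
    if not usable:
        raise DataError(f"all SNPs lack frequency data: {dropped}")
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 SNPs with frequencies in both regions, have {len(usable)}"
        )
    observed = float(np.mean(deltas))
    pools = build_ensemble_pools(
        table,
        usable,
        region_map,
        region_ref,
        tolerance=tolerance,
        source_alleles=source_alleles if null_source == "diseases" else None,
        min_pool=min_pool,
        allele_level=allele_level,
    )
    null = ensemble_null(table, pools, region_map, contrast, n_resamples, seed)
    return DirectionalResult(
        snps=[r for r, _ in usable],
        risk_alleles=[a for _, a in usable],
        contrast=(region, region_ref),
        observed_delta=observed,
        null_deltas=null,
        p_two_sided=empirical_two_sided_p(null, observed),
        null_source=null_source,
        n_resamples=n_resamples,
        seed=seed,
        pool_sizes=[p.size for p in pools],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# FST


@dataclasses.dataclass
class FstResult:
    rsid: str
    fst_global: float
    fst_pairwise: dict[str, float]


def fst_nei(freqs: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Nei GST on pooled subpopulation frequencies (vectorized on axis -1).

    H_T = 2 p̄ (1 - p̄) with p̄ the (weighted) mean frequency; H_S the
    (weighted) mean of 2 p_i (1 - p_i); FST = (H_T - H_S) / H_T, defined as
    0 when H_T = 0 and clamped at 0 from below.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape[-1] < 2:
        raise ParameterError("FST requires >= 2 (pooled) populations")
    if weights is None:
        w = np.ones_like(f)
    else:
        w = np.asarray(weights, dtype=float)
        w = np.broadcast_to(w, f.shape).copy()
    wsum = w.sum(axis=-1, keepdims=True)
    pbar = (w * f).sum(axis=-1, keepdims=True) / wsum
    h_t = (2 * pbar * (1 - pbar))[..., 0]
    h_s = (w * 2 * f * (1 - f)).sum(axis=-1) / wsum[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return np.clip(fst, 0.0, 1.0)


def fst_weir_cockerham(freqs: np.ndarray, n_chromosomes: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta from pooled frequencies, assuming HWE genotypes.

    Sample heterozygosity is taken at its HWE expectation 2 p_i (1 - p_i)
    since only pooled frequencies (not genotypes) are available.
    """
    p = np.asarray(freqs, dtype=float)
    if p.shape[-1] < 2:
        raise ParameterError("FST requires >= 2 (pooled) populations")
    n = np.broadcast_to(np.asarray(n_chromosomes, dtype=float) / 2.0, p.shape)  # individuals
    r = p.shape[-1]
    nbar = n.mean(axis=-1)
    nc = (r * nbar - (n**2).sum(axis=-1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=-1) / (r * nbar)
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * nbar)
    hbar = (n * 2 * p * (1 - p)).sum(axis=-1) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(theta, 0.0, 1.0)


def snp_fst(
    freqs: Mapping[str, float],
    n_chromosomes: Mapping[str, float] | None = None,
    estimator: str = "nei",
) -> FstResult:
    """Global and pairwise FST for one SNP from per-region pooled frequencies."""
    regions = list(freqs)
    if len(regions) < 2:
        raise ParameterError("FST requires >= 2 regions")
    f = np.array([freqs[r] for r in regions], dtype=float)
    w = (
        np.array([n_chromosomes[r] for r in regions], dtype=float)
        if n_chromosomes
        else None
    )
    est = _fst_estimator(estimator)
    pair = {}
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            wij = w[[i, j]] if w is not None else None
            pair[f"{regions[i]}-{regions[j]}"] = float(_apply_fst(est, f[[i, j]], wij))
    return FstResult(
        rsid="",
        fst_global=float(_apply_fst(est, f, w)),
        fst_pairwise=pair,
    )


def _fst_estimator(name: str):
    if name == "nei":
        return fst_nei
    if name == "weir-cockerham":
        return fst_weir_cockerham
    raise ParameterError(f"unknown FST estimator {name!r}")


def _apply_fst(est, f, w):
    if est is fst_nei:
        return est(f, w)
    if w is None:
        w = np.full_like(np.asarray(f, dtype=float), 100.0)
    return est(f, w)


def genome_fst(
    table: FrequencyTable,
    region_map: RegionMap,
    regions: Sequence[str],
    estimator: str = "nei",
) -> pd.DataFrame:
    """Global + pairwise FST for every SNP, on pooled regional frequencies.

    Returns a DataFrame indexed by rsid with a ``global`` column and one
    column per region pair (``A-B``).  SNPs missing any region are NaN.
    """
    freq, counts, weighted = table.region_matrix(region_map, regions)
    f = freq.to_numpy(dtype=float)
    w = counts.to_numpy(dtype=float) if weighted else None
    est = _fst_estimator(estimator)
    out = {"global": _apply_fst(est, f, w if w is not None else None)}
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            wij = w[:, [i, j]] if w is not None else None
            out[f"{regions[i]}-{regions[j]}"] = _apply_fst(est, f[:, [i, j]], wij)
    df = pd.DataFrame(out, index=freq.index)
    df[freq.isna().any(axis=1).to_numpy()] = np.nan
    return df


@dataclasses.dataclass
class FstEnrichmentResult:
    """MAF-bin-matched comparison of disease FST against the genome."""

    per_snp: pd.DataFrame  # rsid x (bin, and per contrast: fst, percentile, normalized)
    p_values: dict[str, float]  # one-sided Mann-Whitney U p per contrast
    excluded: list[str]  # disease SNPs in zero-variance bins


def fst_enrichment(
    disease_rsids: Sequence[str],
    table: FrequencyTable,
    region_map: RegionMap,
    regions: Sequence[str],
    maf_region: str,
    estimator: str = "nei",
) -> FstEnrichmentResult:
    """Are disease-SNP FST values elevated relative to MAF-matched genome SNPs?

    Every SNP is assigned a 5% MAF bin from its pooled ``maf_region``
    (European) frequency.  Within each bin the genome FST distribution gives
    each disease SNP an empirical percentile, and normalized values
    ((FST - bin mean) / bin SD) feed a one-sided Mann-Whitney U test
    (disease > genome) per contrast (global + pairwise).  Disease SNPs in
    bins with zero FST variance are excluded with a warning.
    """
    fst_df = genome_fst(table, region_map, regions, estimator=estimator)
    pooled_ref, _, _ = table.pooled(region_map, maf_region)
    valid = fst_df.notna().all(axis=1) & pooled_ref.notna()
    fst_df = fst_df[valid]
    bins = pd.Series(maf_bin(pooled_ref[valid].to_numpy()), index=fst_df.index)

    missing = [r for r in disease_rsids if r not in fst_df.index]
    if missing:
        raise MissingDataError(f"no usable FST for disease SNP(s): {missing}")

    contrasts = list(fst_df.columns)
    grp = fst_df.groupby(bins)
    bin_mean = grp.transform("mean")
    bin_sd = grp.transform("std", ddof=0)

    rows: dict[str, pd.Series] = {"bin": bins.loc[list(disease_rsids)]}
    p_values: dict[str, float] = {}
    excluded: set[str] = set()
    normalized_all = (fst_df - bin_mean) / bin_sd.replace(0.0, np.nan)
    for c in contrasts:
        genome_norm = normalized_all[c]
        d_norm = genome_norm.loc[list(disease_rsids)]
        bad = d_norm.index[d_norm.isna()]
        excluded.update(bad)
        # percentile: share of same-bin genome SNPs at or below the disease value
        pct = []
        for rsid in disease_rsids:
            in_bin = fst_df[c][bins == bins.loc[rsid]]
            pct.append(100.0 * float((in_bin <= fst_df.at[rsid, c]).mean()))
        rows[f"fst_{c}"] = fst_df[c].loc[list(disease_rsids)]
        rows[f"percentile_{c}"] = pd.Series(pct, index=list(disease_rsids))
        rows[f"normalized_{c}"] = d_norm
        d_use = d_norm.dropna().to_numpy()
        g_use = genome_norm.dropna().to_numpy()
        if d_use.size == 0:
            p_values[c] = float("nan")
        else:
            p_values[c] = float(
                stats.mannwhitneyu(d_use, g_use, alternative="greater").pvalue
            )
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} disease SNP(s) in zero-variance MAF bins: "
            f"{sorted(excluded)}",
            stacklevel=2,
        )
    return FstEnrichmentResult(
        per_snp=pd.DataFrame(rows),
        p_values=p_values,
        excluded=sorted(excluded),
    )
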
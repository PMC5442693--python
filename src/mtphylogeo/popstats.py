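"""Population-genetic summaries and permutation tests.

Haplotype diversity, richness and exclusivity on per-region haplotype
spectra; Nei's standard identity and distance on frequency profiles;
distance-based two-level AMOVA (among regions vs. within, with Phi_RT and a
permutation p-value obtained by reassigning populations to regions); Mantel
matrix-correlation tests; Pearson correlations of regional values against
coordinates; covariance PCA of frequency tables; and exact/approximate
two-proportion tests.

All permutation procedures take an explicit seed and permutation count and
report both, so results are bit-reproducible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylogeography import GeoPoint


# ---------------------------------------------------------------------------
# spectra


class HaplotypeCounts(dict):
    """Per-region mapping haplotype-key -> count (a thin dict wrapper)."""

    @property
    def n(self) -> int:
        return sum(self.values())


def haplotype_diversity(counts: Mapping[str, int], unbiased: bool = True) -> float:
    """h = (1 - sum p_i^2), with the n/(n-1) small-sample correction by default."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty spectrum")
    if unbiased and n < 2:
        raise ValueError("unbiased estimator needs n >= 2")
    p2 = sum((c / n) ** 2 for c in counts.values())
    h = 1.0 - p2
    return h * n / (n - 1) if unbiased else h


def haplotypic_richness(counts: Mapping[str, int]) -> float:
    """Percent of distinct haplotypes among sampled sequences: 100 k / n."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty spectrum")
    k = sum(1 for c in counts.values() if c > 0)
    return 100.0 * k / n


def exclusive_haplotypes(
    all_regions: Mapping[str, Mapping[str, int]]
) -> dict[str, float]:
    """Percent of each region's distinct haplotypes found in no other region."""
    if len(all_regions) < 2:
        raise ValueError("need at least two regions")
    present = {
        r: {h for h, c in spect.items() if c > 0} for r, spect in all_regions.items()
    }
    out = {}
    for r, haps in present.items():
        others = set().union(*(h for rr, h in present.items() if rr != r))
        out[r] = 100.0 * len(haps - others) / len(haps) if haps else 0.0
    return out


def spectrum_from_haplotypes(haps, key=lambda h: h.key()) -> dict[str, Counter]:
    """Group haplotypes by region into per-region haplotype-key spectra."""
    out: dict[str, Counter] = {}
    for h in haps:
        out.setdefault(h.region, Counter())[key(h)] += 1
    return out


# ---------------------------------------------------------------------------
# Nei identity / distance


def nei_identity(p: Sequence[float], q: Sequence[float]) -> float:
    """Nei's standard genetic identity on matched frequency profiles."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must share the same haplotype universe")
    denom = math.sqrt(float((p * p).sum()) * float((q * q).sum()))
    if denom == 0:
        raise ValueError("profiles must be non-degenerate")
    return float((p * q).sum()) / denom


def nei_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """D = -ln I; +inf for disjoint profiles."""
    i = nei_identity(p, q)
    return math.inf if i == 0 else -math.log(i)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class AmovaResult:
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi_rt: float
    p_value: float
    permutations: int
    seed: int


def _amova_components(
    sq_dist: np.ndarray, region_of_sample: np.ndarray
) -> tuple[float, float, float, float]:
    """Variance components from squared distances and a region label vector."""
    n = len(sq_dist)
    regions, counts = np.unique(region_of_sample, return_counts=True)
    r = len(regions)
    ss_total = sq_dist[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in regions:
        idx = np.where(region_of_sample == g)[0]
        if len(idx) > 1:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = r - 1, n - r
    ms_within = ss_within / df_within if df_within else 0.0
    n0 = (n - (counts**2).sum() / n) / df_among if df_among else 1.0
    ms_among = ss_among / df_among if df_among else 0.0
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0 if n0 else 0.0
    return ss_among, ss_within, var_among, var_within


def amova_two_level(
    distances: np.ndarray,
    populations: Sequence[str],
    regions_of: Mapping[str, str],
    permutations: int = 9999,
    seed: int = 0,
    squared: bool = False,
) -> AmovaResult:
    """Distance-based AMOVA: among-region vs. within variance components.

    ``distances`` is a sample-by-sample matrix of pairwise mutation
    differences; under presence/absence site coding these counts already are
    squared Euclidean distances, so ``squared=False`` (the default) uses them
    directly as the AMOVA squared distances.  ``populations[i]`` names sample
    i's population; ``regions_of`` maps population -> region.  The p-value
    permutes whole populations across regions (sample membership intact).
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(populations) != d.shape[0]:
        raise ValueError("one population label per sample is required")
    sq = d**2 if squared else d
    pops = np.asarray(populations)
    pop_names = sorted(set(populations))
    region_names = sorted(set(regions_of.values()))
    if len(region_names) < 2:
        raise ValueError("AMOVA needs at least two regions")
    region_idx = {g: i for i, g in enumerate(region_names)}
    pop_region = np.array([region_idx[regions_of[p]] for p in pops])

    ss_among, ss_within, var_among, var_within = _amova_components(sq, pop_region)
    total_var = var_among + var_within
    if total_var <= 0:
        # degenerate (all haplotypes identical): report 0 among / 100 within
        return AmovaResult(ss_among, ss_within, 0.0, 0.0, 0.0, 100.0, 0.0, 1.0,
                           permutations, seed)
    pct_among = 100.0 * var_among / total_var
    phi = var_among / total_var

    rng = np.random.default_rng(seed)
    pop_to_region = np.array([region_idx[regions_of[p]] for p in pop_names])
    sample_pop = np.array([pop_names.index(p) for p in pops])
    hits = 0
    for _ in range(permutations):
        permuted = pop_to_region[rng.permutation(len(pop_names))]
        labels = permuted[sample_pop]
        if len(np.unique(labels)) < 2:
            hits += 1
            continue
        _, _, va, vw = _amova_components(sq, labels)
        phi_perm = va / (va + vw) if (va + vw) > 0 else 0.0
        if phi_perm >= phi - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return AmovaResult(
        ss_among, ss_within, var_among, var_within,
        pct_among, 100.0 - pct_among, phi, p, permutations, seed,
    )


def pairwise_mutation_distances(haps) -> np.ndarray:
    """Symmetric-difference mutation counts between samples."""
    sets = [set(h.mutations) for h in haps]
    n = len(sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(sets[i] ^ sets[j])
    return d


# ---------------------------------------------------------------------------
# Mantel


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    permutations: int
    seed: int


def mantel(
    a: np.ndarray,
    b: np.ndarray,
    permutations: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel matrix correlation with a two-tailed permutation p-value.

    r is the Pearson correlation over upper-triangle pairs; the null
    distribution permutes rows and columns of ``b`` simultaneously;
    p = (1 + #{|r*| >= |r|}) / (1 + permutations).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x = a[iu]
    if x.std() == 0 or b[iu].std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = float(np.corrcoef(x, b[np.ix_(perm, perm)][iu])[0, 1])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r_obs, (1 + hits) / (1 + permutations), permutations, seed)


# ---------------------------------------------------------------------------
# correlations, PCA, proportions


def pearson_with_coordinates(
    values: Sequence[float], coords: Sequence[GeoPoint]
) -> dict[str, tuple[float, float]]:
    """Pearson r (and two-tailed t-based p) of regional values against
    latitude and longitude."""
    if len(values) != len(coords):
        raise ValueError("one value per coordinate required")
    if len(values) < 3:
        raise ValueError("need at least three regions")
    v = np.asarray(values, dtype=float)
    if v.std() == 0:
        raise ValueError("values have zero variance")
    out = {}
    for axis, xs in (
        ("latitude", np.array([c.lat for c in coords])),
        ("longitude", np.array([c.lon for c in coords])),
    ):
        if xs.std() == 0:
            raise ValueError(f"{axis} has zero variance")
        r, p = stats.pearsonr(v, xs)
        out[axis] = (float(r), float(p))
    return out


@dataclass(frozen=True)
class PcaResult:
    explained_pct: np.ndarray  # over all components, sums to 100
    scores: np.ndarray         # units x components
    loadings: np.ndarray       # variables x components


def frequency_pca(table: pd.DataFrame, correlation: bool = False) -> PcaResult:
    """Centered covariance PCA of a units-by-haplogroup frequency matrix
    (correlation-based behind the flag).  Scores are reproducible up to sign."""
    x = np.asarray(table, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least two units and two haplogroup columns")
    x = x - x.mean(axis=0)
    if correlation:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column under correlation scaling")
        x = x / sd
    if not x.any():
        raise ValueError("constant matrix: PCA undefined")
    cov = np.cov(x, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    explained = 100.0 * evals / evals.sum()
    return PcaResult(explained, x @ evecs, evecs)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "fisher"
) -> float:
    """Two-tailed p for a difference of two proportions (Fisher exact by
    default; ``method='z'`` for the pooled normal approximation)."""
    if min(n1, n2) < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if method == "fisher":
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "z":
        p_pool = (k1 + k2) / (n1 + n2)
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        if se == 0:
            return 1.0
        z = (k1 / n1 - k2 / n2) / se
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")
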
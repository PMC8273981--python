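"""Mapping a sex-linked region (SLR) from population genotypes and X/Y haplotypes.

On a young XY pair, sites inside the non-recombining region are carried by the
Y only, so they appear heterozygous in every male and homozygous in every
female. The scan finds such sex-specific sites, computes their density in
fixed windows, measures male-female differentiation (Hudson-type F_ST) and
per-site association (exact allele-count test), demarcates the SLR as the
longest dense run of windows, and segments it into evolutionary strata from
windowed X-Y intronic divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import encode
from .windows import WindowTrack, tile_windows, windowed_counts

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantTable:
    """Biallelic sites x samples genotype matrix with sex labels.

    ``sites``: DataFrame with columns chrom, pos (1-based), ref, alt, sorted by
    position within chromosome. ``genotypes``: int8 array (n_sites, n_samples)
    coded 0=hom-ref, 1=het, 2=hom-alt, -1=missing.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    sex: dict[str, str]

    def __post_init__(self):
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites x samples")
        if not set(self.sex.values()) <= {"male", "female"}:
            raise ValueError("sex labels must be 'male' or 'female'")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"sites not position-sorted on {chrom}")

    @property
    def male_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.sex[s] == "male"])

    @property
    def female_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.sex[s] == "female"])


@dataclass
class SLRCall:
    chromosome: str | None
    interval: tuple[int, int] | None
    strata: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    par_intervals: list[tuple[int, int]] = field(default_factory=list)
    wilcoxon_p: float | None = None

    @property
    def length(self) -> int:
        return 0 if self.interval is None else self.interval[1] - self.interval[0]


def call_sex_specific_snps(
    vt: VariantTable, mode: str = "male", max_missing: float = 0.2
) -> pd.DataFrame:
    """Sites where every non-missing sample of one sex is het and every
    non-missing sample of the other is homozygous.

    Sites with > ``max_missing`` missingness (or all-missing in either sex)
    are excluded. Returns the subset of ``vt.sites`` (original index kept).
    """
    if mode not in ("male", "female"):
        raise ValueError("mode must be 'male' or 'female'")
    het_idx = vt.male_idx if mode == "male" else vt.female_idx
    hom_idx = vt.female_idx if mode == "male" else vt.male_idx
    if len(het_idx) == 0 or len(hom_idx) == 0:
        raise ValueError("need at least one sample of each sex")
    g = vt.genotypes
    miss = g == MISSING
    ok_miss = miss.mean(axis=1) <= max_missing
    g_het = g[:, het_idx]
    g_hom = g[:, hom_idx]
    het_ok = np.all((g_het == HET) | (g_het == MISSING), axis=1) & np.any(
        g_het != MISSING, axis=1
    )
    hom_ok = np.all(
        (g_hom == HOM_REF) | (g_hom == HOM_ALT) | (g_hom == MISSING), axis=1
    ) & np.any(g_hom != MISSING, axis=1)
    return vt.sites[ok_miss & het_ok & hom_ok]


def window_counts(
    sites: pd.DataFrame, chrom_lengths: dict[str, int], window: int = 50_000
) -> WindowTrack:
    """Count of (selected) sites per tiling window; positions are 1-based."""
    pos0 = sites.assign(pos=sites["pos"] - 1)
    return windowed_counts(chrom_lengths, pos0, window)


def _allele_freqs(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt-allele count and total allele count over a genotype block."""
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return alt.astype(float), n.astype(float)


def window_fst(
    vt: VariantTable,
    chrom_lengths: dict[str, int],
    window: int = 50_000,
    min_variants: int = 40,
) -> WindowTrack:
    """Hudson-type ratio-of-averages F_ST between the sexes in tiling windows.

    Per site, H_within is the mean of the two sample-size-corrected expected
    heterozygosities (2*n*p*(1-p)/(n-1) with n alleles) and
    H_between = p_m(1-p_f) + p_f(1-p_m); the window value is
    1 - sum(H_within)/sum(H_between). Windows with fewer than ``min_variants``
    sites, or with zero between-sex heterozygosity, are missing.
    """
    am, nm = _allele_freqs(vt.genotypes[:, vt.male_idx])
    af, nf = _allele_freqs(vt.genotypes[:, vt.female_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(nm > 0, am / nm, np.nan)
        pf = np.where(nf > 0, af / nf, np.nan)
        # sample-size-corrected expected het: n/(n-1) * 2p(1-p)
        hw_m = np.where(nm > 1, nm / (nm - 1) * 2 * pm * (1 - pm), np.nan)
        hw_f = np.where(nf > 1, nf / (nf - 1) * 2 * pf * (1 - pf), np.nan)
    hw = (hw_m + hw_f) / 2.0
    hb = pm * (1 - pf) + pf * (1 - pm)
    valid = ~(np.isnan(hw) | np.isnan(hb))

    win = tile_windows(chrom_lengths, window)
    win["value"] = np.nan
    win["n_variants"] = 0
    key = {}
    for i, row in win.iterrows():
        key[(row.chrom, row.start // window)] = i
    sites = vt.sites
    widx = np.array(
        [key.get((c, (p - 1) // window), -1) for c, p in zip(sites.chrom, sites.pos)]
    )
    sum_hw = np.zeros(len(win))
    sum_hb = np.zeros(len(win))
    nvar = np.zeros(len(win), dtype=int)
    ok = (widx >= 0) & valid
    np.add.at(sum_hw, widx[ok], hw[ok])
    np.add.at(sum_hb, widx[ok], hb[ok])
    np.add.at(nvar, widx[(widx >= 0)], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = 1.0 - sum_hw / sum_hb
    fst[(nvar < min_variants) | (sum_hb <= 0)] = np.nan
    win["value"] = fst
    win["n_variants"] = nvar
    return WindowTrack(win, window_size=window)


def _fisher_two_sided(k: int, n_focal: int, n_other: int, k_total: int) -> float:
    """Two-sided exact hypergeometric p for a 2x2 allele-count table.

    ``k`` alt alleles among ``n_focal`` alleles in the focal sex, ``k_total``
    alt alleles among ``n_focal + n_other`` overall. Two-sided by summing the
    probabilities of all tables at most as likely as the observed one.
    """
    total = n_focal + n_other
    lo = max(0, k_total - n_other)
    hi = min(n_focal, k_total)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, total, k_total, n_focal)
    obs = pmf[k - lo]
    p = float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))
    return 1.0 if p > 1.0 - 1e-12 else p


def assoc_scan(vt: VariantTable) -> pd.DataFrame:
    """Per-site two-sided exact test of allele counts vs sex.

    Returns ``vt.sites`` with an added ``neglog10_p`` column. Monomorphic
    sites get p = 1.
    """
    am, nm = _allele_freqs(vt.genotypes[:, vt.male_idx])
    af, nf = _allele_freqs(vt.genotypes[:, vt.female_idx])
    p = np.ones(len(vt.sites))
    for i in range(len(p)):
        n_m, n_f = int(nm[i]), int(nf[i])
        k_tot = int(am[i] + af[i])
        if n_m == 0 or n_f == 0 or k_tot == 0 or k_tot == n_m + n_f:
            continue
        p[i] = _fisher_two_sided(int(am[i]), n_m, n_f, k_tot)
    out = vt.sites.copy()
    with np.errstate(divide="ignore"):
        out["neglog10_p"] = np.maximum(0.0, -np.log10(np.minimum(1.0, p)))
    return out


def demarcate_slr(
    density: WindowTrack,
    chromosome: str | None = None,
    min_count: int = 3,
    max_gap_windows: int = 5,
) -> SLRCall:
    """Demarcate the SLR as the longest run of dense windows.

    Windows with count >= ``min_count`` are marked; marked runs separated by
    <= ``max_gap_windows`` unmarked windows are merged; the SLR spans the
    first to the last marked window of the longest merged run. PARs are the
    complement on that chromosome.
    """
    best: SLRCall = SLRCall(None, None)
    chroms = [chromosome] if chromosome else density.df.chrom.unique()
    for chrom in chroms:
        d = density.on(chrom)
        marked = np.flatnonzero(d.value.to_numpy() >= min_count)
        if len(marked) == 0:
            continue
        runs: list[list[int]] = [[marked[0], marked[0]]]
        for m in marked[1:]:
            if m - runs[-1][1] - 1 <= max_gap_windows:
                runs[-1][1] = m
            else:
                runs.append([m, m])
        i0, i1 = max(runs, key=lambda r: d.end[r[1]] - d.start[r[0]])
        interval = (int(d.start[i0]), int(d.end[i1]))
        if best.interval is None or interval[1] - interval[0] > best.length:
            chrom_len = int(d.end.iloc[-1])
            pars = [
                iv
                for iv in [(0, interval[0]), (interval[1], chrom_len)]
                if iv[1] > iv[0]
            ]
            best = SLRCall(chrom, interval, par_intervals=pars)
    return best


def xy_window_similarity(
    x_seq,
    y_seq,
    intron_intervals,
    window: int = 100_000,
    min_bases: int = 1000,
    chrom: str = "chrY",
) -> WindowTrack:
    """Windowed X-Y sequence identity restricted to intronic positions.

    The two haplotypes must be coordinate-matched (collinear, equal length;
    indels are not handled). Windows with fewer than ``min_bases`` compared
    intronic bases are missing.
    """
    x = encode(x_seq)
    y = encode(y_seq)
    if len(x) != len(y):
        raise ValueError("X and Y haplotypes differ in length (not coordinate-matched)")
    mask = np.zeros(len(x), dtype=bool)
    for s, e in intron_intervals:
        mask[max(0, int(s)) : min(len(x), int(e))] = True
    mism = (x != y) & mask
    edges = np.arange(0, len(x) + window, window)
    edges[-1] = len(x)
    cum_m = np.concatenate([[0], np.cumsum(mism)])
    cum_c = np.concatenate([[0], np.cumsum(mask)])
    starts, ends = edges[:-1], edges[1:]
    mm = cum_m[ends] - cum_m[starts]
    cmp_ = cum_c[ends] - cum_c[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = 1.0 - mm / cmp_
    sim[cmp_ < min_bases] = np.nan
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "value": sim, "n_variants": cmp_}
    )
    return WindowTrack(df, window_size=window)


def ranksum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both sides have <= 20
    untied values, otherwise normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def segment_strata(
    similarity: WindowTrack,
    slr_interval: tuple[int, int],
    chromosome: str | None = None,
    alpha: float = 0.05,
    min_windows: int = 6,
    min_seg: int = 3,
) -> SLRCall:
    """Split the SLR into two divergence strata by exhaustive changepoint search.

    Over non-missing similarity windows inside the SLR, the single changepoint
    minimizing the pooled within-segment sum of squared divergence deviations
    is found. Because the changepoint is chosen to maximize separation, the
    split decision uses a Bonferroni-corrected Wilcoxon rank-sum p (raw p
    times the number of candidate changepoints searched); two strata are
    reported iff the corrected p < ``alpha``, else one stratum. The raw
    (uncorrected) p between the two segments is reported in ``wilcoxon_p``.
    """
    chrom = chromosome or similarity.df.chrom.iloc[0]
    d = similarity.values_in(chrom, *slr_interval).dropna(subset=["value"])
    div = (1.0 - d.value.to_numpy())
    starts = d.start.to_numpy()
    n = len(div)
    call = SLRCall(chrom, tuple(slr_interval))
    if n < min_windows:
        call.strata = [(tuple(slr_interval), float(np.mean(div)) if n else float("nan"))]
        return call
    cum = np.concatenate([[0.0], np.cumsum(div)])
    cum2 = np.concatenate([[0.0], np.cumsum(div**2)])

    def sse(i, j):  # windows [i, j)
        s, s2, m = cum[j] - cum[i], cum2[j] - cum2[i], j - i
        return s2 - s * s / m

    cps = range(min_seg, n - min_seg + 1)
    best_c = min(cps, key=lambda c: sse(0, c) + sse(c, n))
    left, right = div[:best_c], div[best_c:]
    p = ranksum_p(left, right)
    call.wilcoxon_p = p
    p_search_adjusted = min(1.0, p * len(cps))
    if p_search_adjusted < alpha:
        boundary = int(starts[best_c])
        call.strata = [
            ((int(slr_interval[0]), boundary), float(left.mean())),
            ((boundary, int(slr_interval[1])), float(right.mean())),
        ]
    else:
        call.strata = [(tuple(map(int, slr_interval)), float(div.mean()))]
    return call


def higher_divergence_stratum(call: SLRCall) -> tuple[tuple[int, int], float] | None:
    """The stratum with the larger mean divergence (R1), if two were called."""
    if len(call.strata) < 2:
        return None
    return max(call.strata, key=lambda s: s[1])
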
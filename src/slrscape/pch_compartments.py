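"""Pericentromeric heterochromatin (PCH) and Hi-C compartment analysis.

PCH is called from windowed repeat content (repeat-dense windows merged into
blocks), H3K9me3 peak enrichment inside PCH is quantified, and binned Hi-C
contact matrices are balanced (symmetric iterative proportional scaling),
turned into observed/expected Pearson-correlation first principal components
(A/B compartments), and compared between PCH and non-PCH bin pairs across
distance strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import interval_overlap, merge_intervals
from .windows import WindowTrack, tile_windows
from .sexlink_scan import ranksum_p


@dataclass
class PCHBlock:
    chromosome: str
    interval: tuple[int, int]
    mean_repeat_frac: float
    contains_centromere: bool = False

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact counts."""

    chromosome: str
    bin_size: int
    counts: np.ndarray
    converged: bool = True

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.isfinite(c).all():
            raise ValueError("contact matrix has non-finite entries")
        if not np.allclose(c, c.T):
            raise ValueError("contact matrix must be symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 of the O/E correlation matrix; A = positive, B = negative."""

    chromosome: str
    bin_size: int
    df: pd.DataFrame = field(default_factory=pd.DataFrame)  # start, end, pc1, label


def repeat_content_track(
    repeats: pd.DataFrame, chrom_lengths: dict[str, int], window: int = 50_000
) -> WindowTrack:
    """Fraction of each tiling window covered by >= 1 repeat interval.

    ``repeats``: DataFrame with chrom, start, end (0-based half-open);
    overlapping intervals are collapsed before counting coverage.
    """
    win = tile_windows(chrom_lengths, window)
    cov = np.zeros(len(win))
    offsets, nwin = {}, {}
    cursor = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = cursor
        nwin[chrom] = int(np.ceil(length / window)) if length else 0
        cursor += nwin[chrom]
    for chrom, grp in repeats.groupby("chrom"):
        if chrom not in offsets:
            continue
        L = chrom_lengths[chrom]
        for s, e in merge_intervals(zip(grp.start, grp.end)):
            s, e = max(0, s), min(L, e)
            if e <= s:
                continue
            w0, w1 = s // window, (e - 1) // window
            if w0 == w1:
                cov[offsets[chrom] + w0] += e - s
            else:
                cov[offsets[chrom] + w0] += (w0 + 1) * window - s
                cov[offsets[chrom] + w1] += e - w1 * window
                if w1 > w0 + 1:
                    cov[offsets[chrom] + w0 + 1 : offsets[chrom] + w1] += window
    sizes = (win.end - win.start).to_numpy()
    win["value"] = cov / sizes
    win["n_variants"] = 0
    return WindowTrack(win, window_size=window)


def call_pch(
    track: WindowTrack,
    centromeres: dict[str, tuple[int, int] | None] | None = None,
    threshold: float = 0.40,
    max_gap_windows: int = 5,
) -> list[PCHBlock]:
    """Merge repeat-dense windows (value > threshold) into PCH blocks.

    Runs of passing windows separated by <= ``max_gap_windows`` failing
    windows are merged; each block records the mean repeat fraction of its
    passing windows and whether it contains a centromere.
    """
    centromeres = centromeres or {}
    blocks: list[PCHBlock] = []
    for chrom in track.df.chrom.unique():
        d = track.on(chrom)
        vals = d.value.to_numpy()
        passing = np.flatnonzero(vals > threshold)
        if len(passing) == 0:
            continue
        runs: list[list[int]] = [[passing[0], passing[0]]]
        for w in passing[1:]:
            if w - runs[-1][1] - 1 <= max_gap_windows:
                runs[-1][1] = w
            else:
                runs.append([w, w])
        cen = centromeres.get(chrom)
        for i0, i1 in runs:
            iv = (int(d.start[i0]), int(d.end[i1]))
            in_run = passing[(passing >= i0) & (passing <= i1)]
            blocks.append(
                PCHBlock(
                    chrom,
                    iv,
                    float(vals[in_run].mean()),
                    bool(cen and interval_overlap(iv, tuple(cen)) > 0),
                )
            )
    return blocks


def pch_summary(blocks: list[PCHBlock], chrom_lengths: dict[str, int]) -> dict:
    """Genome-wide PCH totals and per-chromosome proportions."""
    total = sum(b.length for b in blocks)
    genome = sum(chrom_lengths.values())
    per_chrom = {
        c: sum(b.length for b in blocks if b.chromosome == c) / L
        for c, L in chrom_lengths.items()
    }
    return {
        "pch_bp": int(total),
        "genome_fraction": total / genome if genome else float("nan"),
        "n_blocks": len(blocks),
        "mean_block_mb": float(np.mean([b.length for b in blocks]) / 1e6)
        if blocks
        else float("nan"),
        "per_chromosome_fraction": per_chrom,
    }


def peak_enrichment(
    peaks: pd.DataFrame,
    blocks: list[PCHBlock],
    chrom_lengths: dict[str, int],
    score_min: float = 8.0,
) -> dict:
    """Fraction of (score-filtered) peaks whose midpoint lies in PCH, versus
    the PCH fraction of the genome; peaks with score <= ``score_min`` are
    discarded first."""
    kept = peaks[peaks.score > score_min]
    genome = sum(chrom_lengths.values())
    pch_frac = sum(b.length for b in blocks) / genome if genome else float("nan")
    if len(kept) == 0:
        return {"n_peaks": 0, "peak_fraction_in_pch": None, "pch_genome_fraction": pch_frac, "ratio": None}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b.interval)
    mids = ((kept.start + kept.end) // 2).to_numpy()
    in_pch = 0
    for chrom, grp_idx in kept.groupby("chrom").groups.items():
        ivs = by_chrom.get(chrom, [])
        if not ivs:
            continue
        m = mids[kept.index.get_indexer(grp_idx)]
        for s, e in ivs:
            in_pch += int(((m >= s) & (m < e)).sum())
    frac = in_pch / len(kept)
    return {
        "n_peaks": int(len(kept)),
        "peak_fraction_in_pch": frac,
        "pch_genome_fraction": pch_frac,
        "ratio": frac / pch_frac if pch_frac else None,
    }


def balance_matrix(
    cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 1000
) -> ContactMatrix:
    """Balance a symmetric contact matrix by iterative proportional scaling.

    Zero-sum rows/columns are masked out; the rest is rescaled symmetrically
    (divide by sqrt of relative row sums) until every unmasked row sum is
    within ``tol`` (relative) of the common mean. The overall scale of the
    counts is preserved (mean row sum unchanged).
    """
    a = cm.counts.copy()
    unmasked = a.sum(axis=1) > 0
    sub = a[np.ix_(unmasked, unmasked)]
    converged = False
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        mean = s.mean()
        if np.max(np.abs(s / mean - 1.0)) < tol:
            converged = True
            break
        scale = np.sqrt(s / mean)
        sub /= np.outer(scale, scale)
    if not converged:
        warnings.warn(
            f"balance_matrix: not converged after {max_iter} iterations", RuntimeWarning
        )
    out = np.zeros_like(a)
    out[np.ix_(unmasked, unmasked)] = sub
    return ContactMatrix(cm.chromosome, cm.bin_size, (out + out.T) / 2.0, converged)


def _observed_over_expected(counts: np.ndarray, unmasked: np.ndarray) -> np.ndarray:
    n = counts.shape[0]
    oe = np.zeros_like(counts)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        keep = unmasked[i] & unmasked[j]
        if not keep.any():
            continue
        exp = counts[i[keep], j[keep]].mean()
        if exp > 0:
            oe[i[keep], j[keep]] = counts[i[keep], j[keep]] / exp
            oe[j[keep], i[keep]] = oe[i[keep], j[keep]]
    return oe


def _power_iteration_pc1(mat: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000):
    """Leading eigenvector (by |eigenvalue|) of a symmetric matrix."""
    n = mat.shape[0]
    v = np.linspace(1.0, 2.0, n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = mat @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return v, 0.0
        w /= nrm
        if min(np.linalg.norm(w - v), np.linalg.norm(w + v)) < tol:
            v = w
            lam = float(v @ mat @ v)
            break
        v = w
    else:
        lam = float(v @ mat @ v)
    return v, lam


def oe_pearson_pc1(
    cm: ContactMatrix,
    gene_density: np.ndarray | None = None,
    bin_size_out: int = 250_000,
) -> CompartmentTrack:
    """A/B compartment PC1 at ``bin_size_out`` resolution.

    Counts are aggregated to the output bin size, divided by the per-diagonal
    mean (observed/expected), correlated (Pearson, column pairs), and the
    first principal component of the column-centered correlation matrix is
    extracted by power iteration. The sign is oriented so PC1 correlates
    positively with ``gene_density`` (one value per output bin): positive PC1
    is the active A compartment.
    """
    if bin_size_out % cm.bin_size:
        raise ValueError("output bin size must be a multiple of the matrix bin size")
    f = bin_size_out // cm.bin_size
    n = cm.n_bins
    n_out = int(np.ceil(n / f))
    edges = np.arange(0, n_out * f, f)[:n_out]
    agg = np.add.reduceat(np.add.reduceat(cm.counts, edges, axis=0), edges, axis=1)
    unmasked = agg.sum(axis=1) > 0
    oe = _observed_over_expected(agg, unmasked)
    sub = oe[np.ix_(unmasked, unmasked)]
    # drop constant columns (zero variance) from the correlation
    var_ok = sub.std(axis=0) > 0
    idx = np.flatnonzero(unmasked)[var_ok]
    sub = sub[np.ix_(var_ok, var_ok)]
    pc1 = np.full(n_out, np.nan)
    if sub.shape[0] >= 2:
        corr = np.corrcoef(sub)
        cc = corr - corr.mean(axis=0, keepdims=True)
        cov = cc.T @ cc
        v, _ = _power_iteration_pc1(cov)
        if gene_density is not None:
            gd = np.asarray(gene_density, dtype=float)[idx]
            if np.std(gd) > 0 and np.std(v) > 0:
                r = np.corrcoef(gd, v)[0, 1]
                if r < 0:
                    v = -v
        pc1[idx] = v
    starts = np.arange(n_out) * bin_size_out
    ends = np.minimum(starts + bin_size_out, n * cm.bin_size)
    label = np.where(np.isnan(pc1), "", np.where(pc1 > 0, "A", "B"))
    df = pd.DataFrame({"start": starts, "end": ends, "pc1": pc1, "label": label})
    return CompartmentTrack(cm.chromosome, bin_size_out, df)


def distance_stratified_contacts(
    cm: ContactMatrix,
    blocks: list[PCHBlock],
    min_count: float = 10,
) -> dict:
    """Compare PCH-PCH vs nonPCH-nonPCH contact intensity across distances.

    Bin pairs with value <= ``min_count`` are excluded (strict, matching the
    count>10 rule). A bin is PCH if its midpoint falls in a PCH block on the
    matrix chromosome. Within each log2 distance stratum the per-class mean
    raw intensities are reported. The pooled two-sided Wilcoxon rank-sum test
    compares distance-standardized values (each pair divided by the mean
    contact at its exact bin distance, i.e. observed/expected), restricted to
    strata where both classes occur: raw pooling would confound class with
    distance because PCH pairs sit at shorter distances within a stratum.
    """
    ivs = [b.interval for b in blocks if b.chromosome == cm.chromosome]
    n = cm.n_bins
    mids = np.arange(n) * cm.bin_size + cm.bin_size // 2
    in_pch = np.zeros(n, dtype=bool)
    for s, e in ivs:
        in_pch |= (mids >= s) & (mids < e)
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.counts[iu, ju]
    keep = vals > min_count
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    both_pch = in_pch[iu] & in_pch[ju]
    both_non = ~in_pch[iu] & ~in_pch[ju]
    dist = ju - iu
    # expected value per exact distance (all retained pairs)
    oe = np.empty_like(vals)
    for d in np.unique(dist):
        m = dist == d
        oe[m] = vals[m] / vals[m].mean()
    strata = np.floor(np.log2(dist)).astype(int)
    rows = []
    pooled_pch, pooled_non = [], []
    for s in np.unique(strata):
        m = strata == s
        v_p = vals[m & both_pch]
        v_n = vals[m & both_non]
        rows.append(
            {
                "log2_stratum": int(s),
                "n_pch": len(v_p),
                "n_non": len(v_n),
                "mean_pch": float(v_p.mean()) if len(v_p) else np.nan,
                "mean_non": float(v_n.mean()) if len(v_n) else np.nan,
            }
        )
        if len(v_p) and len(v_n):
            pooled_pch.append(oe[m & both_pch])
            pooled_non.append(oe[m & both_non])
    report = {"strata": pd.DataFrame(rows), "p": None, "note": None}
    if not pooled_pch or not pooled_non:
        report["note"] = "one class empty after filtering; comparison skipped"
        return report
    report["p"] = ranksum_p(np.concatenate(pooled_pch), np.concatenate(pooled_non))
    return report


def pch_size_correlation(
    blocks: list[PCHBlock], chrom_lengths: dict[str, int]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided t-test p) between per-chromosome
    total PCH bp and chromosome length, over chromosomes carrying PCH."""
    per_chrom = {}
    for b in blocks:
        per_chrom[b.chromosome] = per_chrom.get(b.chromosome, 0) + b.length
    chroms = sorted(per_chrom)
    if len(chroms) < 3:
        raise ValueError("need PCH on >= 3 chromosomes")
    x = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    y = np.array([per_chrom[c] for c in chroms], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
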
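"""Tandem satellite detection, monomer families, centromeres and karyotype.

Tandem arrays are found by self-comparison at a lag: an interval is an array
of period p when the fraction of positions i with seq[i] != seq[i+p] inside
it is at most ``max_mismatch`` and it spans at least two periods; the period
reported is the smallest achieving this. Families group arrays whose
canonical monomers (minimal rotation over both strands) match; their
chromosomal distribution classifies them as centromeric (one interior locus
per chromosome) or telomere-associated (loci at chromosome ends), the
centromeric family localizes centromeres, and arm ratios give the
metacentric / submetacentric / telocentric karyotype.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._util import decode, encode, revcomp


@dataclass
class TandemArray:
    chromosome: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SatelliteFamily:
    canonical_monomer: str
    monomer_len: int
    total_bp: int
    copy_number: float
    loci: list[TandemArray] = field(default_factory=list)
    label: str = "other"


@dataclass
class ChromosomeMorphology:
    chromosome: str
    centromere: tuple[int, int] | None
    arm_ratio: float
    morphology: str | None  # metacentric | submetacentric | telocentric | None


def find_tandem_arrays(
    seq,
    min_period: int = 10,
    max_period: int = 2000,
    max_mismatch: float = 0.2,
    chrom: str = "seq",
) -> list[TandemArray]:
    """Detect tandem arrays of period in [min_period, max_period].

    For each candidate period the sequence is compared against itself shifted
    by the period; runs where every period-length window has mismatch
    fraction <= ``max_mismatch`` become candidate arrays. Candidates are then
    reconciled: longer arrays win, and among near-identical intervals the
    smallest period is kept (so a p-array is not re-reported at 2p, 3p, ...).
    """
    if not (2 <= min_period <= max_period):
        raise ValueError("need 2 <= min_period <= max_period")
    codes = encode(seq)
    L = len(codes)
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(min_period, min(max_period, L // 2) + 1):
        d = (codes[p:] != codes[:-p]).astype(np.int64)
        if len(d) < p:
            continue
        c = np.concatenate([[0], np.cumsum(d)])
        wm = (c[p:] - c[:-p]) / p  # mismatch frac of window starting at i
        good = wm <= max_mismatch
        if not good.any():
            continue
        idx = np.flatnonzero(good)
        run_start = idx[0]
        prev = idx[0]
        for i in list(idx[1:]) + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            candidates.append((int(run_start), int(prev + 2 * p), p))
            if i is not None:
                run_start = prev = i
    # longer intervals first; among ties the smaller period wins
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[2]))
    # Reconciliation. Kept intervals never contain one another (a contained
    # candidate is pruned), so sorted by start they are sorted by end too and
    # the backward scan stops at the first interval ending before the
    # candidate starts. A candidate at period p extends up to ~p/max_mismatch
    # past the true array edge, so a multiple of the true period can come out
    # slightly longer than the true-period candidate for the same array; a
    # smaller-period candidate covering >= 90% of a kept interval therefore
    # replaces it instead of being suppressed.
    kept: list[tuple[int, int, int]] = []
    kept_starts: list[int] = []
    kept_idx: list[int] = []

    def _rebuild():
        nonlocal kept_starts, kept_idx
        order = sorted(range(len(kept)), key=lambda j: kept[j][0])
        kept_starts = [kept[j][0] for j in order]
        kept_idx = order

    for s, e, p in candidates:
        i = bisect.bisect_right(kept_starts, e) - 1
        replace_at = None
        suppress = False
        while i >= 0:
            ks, ke, kp = kept[kept_idx[i]]
            if ke <= s:
                break
            ov = min(e, ke) - max(s, ks)
            if ov > 0.5 * (e - s):
                if p < kp and ov >= 0.9 * (ke - ks):
                    replace_at = kept_idx[i]
                else:
                    suppress = True
                break
            i -= 1
        if suppress:
            continue
        if replace_at is not None:
            kept[replace_at] = (s, e, p)
            _rebuild()
        else:
            kept.append((s, e, p))
            j = bisect.bisect_left(kept_starts, s)
            kept_starts.insert(j, s)
            kept_idx.insert(j, len(kept) - 1)
    out = []
    for s, e, p in sorted(kept):
        out.append(
            TandemArray(chrom, s, e, p, (e - s) / p, _consensus(codes[s:e], p))
        )
    return out


def _consensus(codes: np.ndarray, period: int) -> str:
    """Per-column majority over the full monomer copies (ties -> lowest base)."""
    n = (len(codes) // period) * period
    rows = codes[:n].reshape(-1, period)
    counts = np.zeros((4, period), dtype=np.int64)
    for b in range(4):
        counts[b] = (rows == b).sum(axis=0)
    return decode(np.argmax(counts, axis=0).astype(np.uint8))


def canonical_monomer(monomer: str) -> str:
    """Lexicographically smallest string over all rotations of the monomer
    and all rotations of its reverse complement. Idempotent."""
    if not monomer:
        raise ValueError("empty monomer")
    if set(monomer.upper()) - set("ACGTN"):
        raise ValueError("monomer contains non-ACGTN characters")
    m = monomer.upper()
    rc = revcomp(m)
    best = min(
        min((s + s)[i : i + len(s)] for i in range(len(s))) for s in (m, rc)
    )
    return best


def _monomer_identity(a: str, b: str) -> float:
    """Identity between two monomers, rotation-tolerant (shorter vs doubled longer)."""
    if a == b:
        return 1.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_ + long_, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(short)


def build_families(
    arrays: list[TandemArray],
    min_identity: float = 0.8,
    length_tol: float = 0.1,
    top_n: int | None = None,
) -> list[SatelliteFamily]:
    """Group arrays into monomer families and rank by total bp.

    Arrays join a family when monomer lengths agree within ``length_tol``
    (relative) and canonical monomers match at >= ``min_identity``.
    """
    families: list[SatelliteFamily] = []
    for arr in sorted(arrays, key=lambda a: -a.length):
        can = canonical_monomer(arr.consensus)
        home = None
        for fam in families:
            if abs(len(can) - fam.monomer_len) > length_tol * max(len(can), fam.monomer_len):
                continue
            if _monomer_identity(can, fam.canonical_monomer) >= min_identity:
                home = fam
                break
        if home is None:
            home = SatelliteFamily(can, len(can), 0, 0.0)
            families.append(home)
        home.loci.append(arr)
        home.total_bp += arr.length
        home.copy_number += arr.copy_number
    families.sort(key=lambda f: -f.total_bp)
    return families[:top_n] if top_n else families


def _clusters(loci: list[TandemArray], cluster_gap: int) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a in sorted(loci, key=lambda a: a.start):
        if out and a.start - out[-1][1] <= cluster_gap:
            out[-1][1] = max(out[-1][1], a.end)
        else:
            out.append([a.start, a.end])
    return [tuple(c) for c in out]


def classify_families(
    families: list[SatelliteFamily],
    chrom_meta: pd.DataFrame,
    end_margin: int = 200_000,
    cluster_gap: int = 500_000,
) -> list[SatelliteFamily]:
    """Label families centromeric / telomere-associated / other.

    Centromeric: on >= 70% of chromosomes carrying it the family forms exactly
    one cluster, and on at least one metacentric/submetacentric chromosome
    (any chromosome if morphology is unknown) that cluster is interior.
    Telomere-associated: >= 90% of its clusters lie within ``end_margin`` of a
    chromosome end. ``chrom_meta``: DataFrame with chrom, length and
    optionally morphology.
    """
    lengths = dict(zip(chrom_meta.chrom, chrom_meta.length))
    morph = (
        dict(zip(chrom_meta.chrom, chrom_meta.morphology))
        if "morphology" in chrom_meta.columns
        else {}
    )
    for fam in families:
        by_chrom: dict[str, list[TandemArray]] = {}
        for a in fam.loci:
            by_chrom.setdefault(a.chromosome, []).append(a)
        clusters = {c: _clusters(ls, cluster_gap) for c, ls in by_chrom.items()}
        if not clusters:
            fam.label = "other"
            continue
        n_single = sum(1 for cl in clusters.values() if len(cl) == 1)
        single_frac = n_single / len(clusters)
        interior_on_biarmed = False
        for c, cl in clusters.items():
            if len(cl) != 1 or c not in lengths:
                continue
            s, e = cl[0]
            interior = s > end_margin and e < lengths[c] - end_margin
            biarmed = morph.get(c) in ("metacentric", "submetacentric") or not morph
            if interior and biarmed:
                interior_on_biarmed = True
        all_clusters = [(c, iv) for c, cl in clusters.items() for iv in cl]
        n_terminal = sum(
            1
            for c, (s, e) in all_clusters
            if c in lengths and (s < end_margin or e > lengths[c] - end_margin)
        )
        if single_frac >= 0.7 and interior_on_biarmed:
            fam.label = "centromeric"
        elif all_clusters and n_terminal / len(all_clusters) >= 0.9:
            fam.label = "telomere-associated"
        else:
            fam.label = "other"
    return families


def locate_centromeres(
    family: SatelliteFamily,
    chrom_meta: pd.DataFrame,
    cluster_gap: int = 500_000,
) -> tuple[dict[str, tuple[int, int] | None], list[str]]:
    """Per-chromosome centromere interval from the centromeric family.

    The centromere is the span of the family's (single) cluster; chromosomes
    without a cluster are unresolved (None). If several clusters are present
    the one with the largest total array bp is taken and the chromosome is
    flagged in the returned notes.
    """
    by_chrom: dict[str, list[TandemArray]] = {}
    for a in family.loci:
        by_chrom.setdefault(a.chromosome, []).append(a)
    out: dict[str, tuple[int, int] | None] = {}
    flags: list[str] = []
    for chrom in chrom_meta.chrom:
        loci = by_chrom.get(chrom, [])
        if not loci:
            out[chrom] = None
            flags.append(f"{chrom}: unresolved (no centromeric cluster)")
            continue
        cls = _clusters(loci, cluster_gap)
        if len(cls) == 1:
            out[chrom] = cls[0]
            continue
        totals = []
        for s, e in cls:
            totals.append(sum(a.length for a in loci if a.start >= s and a.end <= e))
        best = int(np.argmax(totals))
        if totals.count(max(totals)) > 1:
            flags.append(f"{chrom}: tie between clusters, largest-bp taken")
        else:
            flags.append(f"{chrom}: multiple clusters, largest-bp taken")
        out[chrom] = cls[best]
    return out, flags


def classify_morphology(
    chrom_meta: pd.DataFrame,
    centromeres: dict[str, tuple[int, int] | None],
    meta_max: float = 1.7,
    submeta_max: float = 3.0,
) -> tuple[list[ChromosomeMorphology], Counter]:
    """Arm-ratio karyotype: long/short arm <= 1.7 metacentric, <= 3.0
    submetacentric (boundary inclusive), > 3.0 telocentric. Chromosomes with
    unresolved centromeres are left unassigned."""
    out = []
    counts: Counter = Counter()
    for _, row in chrom_meta.iterrows():
        cen = centromeres.get(row.chrom)
        if cen is None:
            out.append(ChromosomeMorphology(row.chrom, None, float("nan"), None))
            continue
        mid = (cen[0] + cen[1]) / 2.0
        short = max(1.0, min(mid, row.length - mid))
        long_ = max(mid, row.length - mid)
        ratio = long_ / short
        if ratio <= meta_max:
            cls = "metacentric"
        elif ratio <= submeta_max:
            cls = "submetacentric"
        else:
            cls = "telocentric"
        counts[cls] += 1
        out.append(ChromosomeMorphology(row.chrom, tuple(cen), float(ratio), cls))
    return out, counts
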
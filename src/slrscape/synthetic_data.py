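"""Synthetic diploid genome generator with a planted young XY system.

Generates every input the downstream analyses consume — haplotype sequences,
chromosome metadata, repeat/gene tracks, population genotypes, HiFi-like
reads, H3K9me3 peaks, Hi-C contact matrices and gonadal expression counts —
with the planted ground truth kept alongside, so recovery can be tested
without any external data.

The default ``zigzag`` preset emulates a 24-chromosome fish genome with a
submetacentric XY pair: a sex-linked region (SLR) at 17-24 Mb of a 27.9-Mb
sex chromosome spanning the centromere, pseudoautosomal regions at both
ends, ~1% X-Y divergence split into two strata (1.2% / 0.8% around a 20-Mb
boundary), tandem satellites with 524-bp (centromeric) and 190-bp
(telomere-associated) monomers plus (TTAGGG)n termini, and pericentromeric
heterochromatin blocks of ~4.2 Mb with ~55% repeat content against a ~15%
background.

In ``track_only`` mode no bases are generated — only coordinate tracks —
so whole-genome-scale runs stay fast; scans that never read sequence
(SLR demarcation, PCH calling, enrichment) work identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import child_rng, decode, encode
from .gonad_expression import EARLY_INTERSEX_STAGES as EARLY_STAGES
from .pch_compartments import ContactMatrix
from .sexlink_scan import HET, HOM_REF, MISSING, VariantTable

TELOMERE_MOTIF = "TTAGGG"


class ConfigError(ValueError):
    """Raised when a GeneratorConfig is internally inconsistent."""


@dataclass
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return out

    @property
    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 24
    chrom_lengths: list[int] = field(default_factory=list)
    sex_chrom_index: int | None = None
    slr_interval: tuple[int, int] | None = None
    strata_boundary: int | None = None
    divergence_r1: float = 0.012
    divergence_r2: float = 0.008
    cen_monomer_len: int = 524
    tel_monomer_len: int = 190
    cen_copies: int = 96
    tel_copies: int = 100
    pch_mean_len: int = 4_200_000
    pch_sd_len: int = 500_000
    pch_min_len: int = 1_000_000
    pch_repeat_frac: float = 0.55
    background_repeat_frac: float = 0.15
    snp_density: float = 1e-3
    n_males: int = 10
    n_females: int = 10
    hifi_error_rate: float = 0.00086
    track_only: bool = False
    missing_rate: float = 0.0
    # centromere placement: relative position per chromosome (None -> derived)
    cen_positions: list[float] | None = None
    morphologies: list[str] | None = None
    telomere_motif_copies: int = 50
    repeat_mean_len: int = 1000
    # gene models
    gene_spacing: int = 40_000
    exons_per_gene: int = 6
    exon_len: int = 250
    intron_len: int = 2000
    # epigenome
    peak_density_bg: float = 1e-5
    peak_pch_ratio: float = 4.0
    peak_width: int = 500
    hic_bin_size: int = 50_000
    hic_scale: float = 2000.0
    hic_decay: float = -1.0
    hic_pch_factor: float = 2.0
    hic_checker: float = 0.3
    hic_comp_bins: int = 20
    hic_noise: bool = True
    # expression
    n_replicates: int = 5
    nb_dispersion: float = 0.1
    pch_expr_factor: float = 1.0
    seq_depth_factor: float = 30.0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigError("chrom_lengths length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigError("chrom_lengths must all be positive")
        for name in (
            "divergence_r1", "divergence_r2", "pch_repeat_frac",
            "background_repeat_frac", "hifi_error_rate", "missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.sex_chrom_index is not None:
            if not (0 <= self.sex_chrom_index < self.n_chromosomes):
                raise ConfigError("sex_chrom_index out of range")
            L = self.chrom_lengths[self.sex_chrom_index]
            if self.slr_interval is None:
                raise ConfigError("slr_interval required when sex_chrom_index is set")
            s, e = self.slr_interval
            if not (0 <= s < e <= L):
                raise ConfigError("slr_interval must lie within the sex chromosome")
            if self.strata_boundary is not None and not (s < self.strata_boundary < e):
                raise ConfigError("strata_boundary must lie within slr_interval")
        if self.pch_mean_len > max(self.chrom_lengths):
            raise ConfigError("pch_mean_len longer than every chromosome")
        for name in ("cen_monomer_len", "tel_monomer_len"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")


# the zigzag preset karyotype: 5 metacentric, 3 submetacentric (one of them
# the 27.9-Mb XY pair), 16 telocentric; ~615 Mb total
_ZIGZAG_MB = [
    (43.5, "metacentric"), (41.0, "metacentric"), (39.2, "metacentric"),
    (38.0, "metacentric"), (36.5, "metacentric"),
    (32.0, "submetacentric"), (27.9, "submetacentric"), (26.5, "submetacentric"),
    (27.0, "telocentric"), (25.5, "telocentric"), (24.0, "telocentric"),
    (23.0, "telocentric"), (22.0, "telocentric"), (21.5, "telocentric"),
    (21.0, "telocentric"), (20.5, "telocentric"), (20.0, "telocentric"),
    (19.5, "telocentric"), (19.0, "telocentric"), (18.5, "telocentric"),
    (18.0, "telocentric"), (17.5, "telocentric"), (17.0, "telocentric"),
    (16.0, "telocentric"),
]
_CEN_POS = {"metacentric": 0.48, "submetacentric": 0.28, "telocentric": 0.004}


def zigzag_config(seed: int = 0, track_only: bool = False) -> GeneratorConfig:
    """The default study preset (see module docstring)."""
    lengths = [int(mb * 1e6) for mb, _ in _ZIGZAG_MB]
    morphs = [m for _, m in _ZIGZAG_MB]
    sex_idx = 6  # the 27.9-Mb submetacentric pair
    cen_pos = [_CEN_POS[m] for m in morphs]
    cen_pos[sex_idx] = 19.4e6 / 27.9e6  # centromere inside the SLR
    cfg = GeneratorConfig(
        seed=seed,
        n_chromosomes=24,
        chrom_lengths=lengths,
        sex_chrom_index=sex_idx,
        slr_interval=(17_000_000, 24_000_000),
        strata_boundary=20_000_000,
        cen_positions=cen_pos,
        morphologies=morphs,
        track_only=track_only,
    )
    cfg.validate()
    return cfg


def single_chrom_config(
    length: int,
    seed: int = 0,
    sex: bool = True,
    slr_interval: tuple[int, int] | None = None,
    strata_boundary: int | None = None,
    track_only: bool = False,
    **overrides,
) -> GeneratorConfig:
    """One-chromosome config, by default a zigzag-like sex chromosome."""
    cfg = GeneratorConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_lengths=[length],
        sex_chrom_index=0 if sex else None,
        slr_interval=slr_interval if sex else None,
        strata_boundary=strata_boundary if sex else None,
        cen_positions=[0.695 if sex else 0.48],
        morphologies=["submetacentric" if sex else "metacentric"],
        track_only=track_only,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class GenomeBundle:
    """A generated genome: sequences (unless track-only), per-chromosome
    metadata, repeat and gene tracks, and the planted truth."""

    config: GeneratorConfig
    meta: pd.DataFrame  # chrom, length, cen_start, cen_end, morphology
    sequences: dict[str, dict[str, np.ndarray]]  # chrom -> {hap1, hap2} 2-bit codes
    repeat_track: pd.DataFrame  # chrom, start, end, label
    genes: list[Gene]
    truth: dict

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.meta.chrom, self.meta.length))

    @property
    def sex_chrom(self) -> str | None:
        i = self.config.sex_chrom_index
        return None if i is None else self.meta.chrom.iloc[i]

    @property
    def centromeres(self) -> dict[str, tuple[int, int]]:
        return {
            r.chrom: (int(r.cen_start), int(r.cen_end)) for r in self.meta.itertuples()
        }

    def haplotypes(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        h = self.sequences[chrom]
        return h["hap1"], h["hap2"]

    def intron_intervals(self, chrom: str) -> list[tuple[int, int]]:
        out = []
        for g in self.genes:
            if g.chrom == chrom:
                out.extend(g.introns)
        return out

    def gene_positions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": [g.chrom for g in self.genes],
             "start": [g.start for g in self.genes],
             "end": [g.end for g in self.genes]},
            index=[g.name for g in self.genes],
        )

    def gene_density(self, chrom: str, bin_size: int) -> np.ndarray:
        L = self.chrom_lengths[chrom]
        n = int(math.ceil(L / bin_size))
        dens = np.zeros(n)
        for g in self.genes:
            if g.chrom == chrom:
                dens[min(n - 1, ((g.start + g.end) // 2) // bin_size)] += 1
        return dens


def _trunc_normal(rng, mean, sd, lo, hi) -> int:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(x)
    return int(np.clip(mean, lo, hi))


def _repeat_segments(rng, start: int, end: int, frac: float, mean_len: int):
    """Alternating repeat/gap segments with expected coverage ``frac``."""
    if end <= start or frac <= 0:
        return []
    if frac >= 1:
        return [(start, end)]
    gap_mean = mean_len * (1 - frac) / frac
    span = end - start
    n = int(span / (mean_len + gap_mean) * 1.6) + 20
    reps = np.maximum(1, rng.exponential(mean_len, n).astype(np.int64))
    gaps = np.maximum(1, rng.exponential(gap_mean, n).astype(np.int64))
    steps = np.empty(2 * n, dtype=np.int64)
    steps[0::2] = gaps
    steps[1::2] = reps
    edges = start + np.cumsum(steps)
    starts = edges[0::2]  # position right after each gap = repeat start
    ends = edges[1::2]
    keep = starts < end
    starts, ends = starts[keep], np.minimum(ends[keep], end)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e > s]


def gen_genome(config: GeneratorConfig) -> GenomeBundle:
    """Generate a genome bundle (sequences omitted in track-only mode)."""
    config.validate()
    n = config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(n)]
    lengths = list(config.chrom_lengths)
    morphs = config.morphologies or ["submetacentric"] * n
    cen_positions = config.cen_positions or [_CEN_POS.get(m, 0.3) for m in morphs]
    cen_len = max(1, config.cen_copies * config.cen_monomer_len)
    tel_len = config.tel_copies * config.tel_monomer_len
    motif_len = config.telomere_motif_copies * len(TELOMERE_MOTIF)

    meta_rows, pch_rows, repeat_rows = [], [], []
    sat_truth = []
    for i, chrom in enumerate(chroms):
        L = lengths[i]
        cen_mid = int(cen_positions[i] * L)
        cen_start = int(np.clip(cen_mid - cen_len // 2, 0, max(0, L - cen_len)))
        cen_end = min(L, cen_start + cen_len)
        meta_rows.append((chrom, L, cen_start, cen_end, morphs[i]))

        # PCH: a block of the drawn length containing the centromere, shifted
        # inside the chromosome (telocentric domains extend inward).
        rng_pch = child_rng(config.seed, "pch", chrom)
        if config.pch_mean_len > 0:
            plen = _trunc_normal(
                rng_pch, config.pch_mean_len, config.pch_sd_len,
                config.pch_min_len, L,
            )
            ps = int(np.clip(cen_mid - plen // 2, 0, L - plen))
            pch_rows.append((chrom, ps, ps + plen))

        # interspersed repeats at the PCH/background coverage fractions
        rng_rep = child_rng(config.seed, "repeats", chrom)
        pch_iv = (pch_rows[-1][1], pch_rows[-1][2]) if config.pch_mean_len > 0 else None
        regions = (
            [(0, pch_iv[0], config.background_repeat_frac),
             (pch_iv[0], pch_iv[1], config.pch_repeat_frac),
             (pch_iv[1], L, config.background_repeat_frac)]
            if pch_iv
            else [(0, L, config.background_repeat_frac)]
        )
        for rs, re_, frac in regions:
            for s, e in _repeat_segments(rng_rep, rs, re_, frac, config.repeat_mean_len):
                repeat_rows.append((chrom, s, e, "interspersed"))

        # satellite arrays and telomeric motif termini
        if config.cen_copies > 0:
            repeat_rows.append((chrom, cen_start, cen_end, "satellite_cen"))
            sat_truth.append((chrom, cen_start, cen_end, "cen"))
        if config.tel_copies > 0 and L > 2 * (motif_len + tel_len):
            for s in (motif_len, L - motif_len - tel_len):
                repeat_rows.append((chrom, s, s + tel_len, "satellite_tel"))
                sat_truth.append((chrom, s, s + tel_len, "tel"))
        if config.telomere_motif_copies > 0 and L > 2 * motif_len:
            repeat_rows.append((chrom, 0, motif_len, "telomere_motif"))
            repeat_rows.append((chrom, L - motif_len, L, "telomere_motif"))

    meta = pd.DataFrame(
        meta_rows, columns=["chrom", "length", "cen_start", "cen_end", "morphology"]
    )
    repeat_track = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "label"])
    pch_truth = pd.DataFrame(pch_rows, columns=["chrom", "start", "end"])

    # fixed-seed random monomers (the consensus monomer sequences themselves
    # are not part of the planted truth; only lengths and placement are)
    cen_monomer = decode(
        child_rng(config.seed, "cen_monomer").integers(0, 4, config.cen_monomer_len).astype(np.uint8)
    )
    tel_monomer = decode(
        child_rng(config.seed, "tel_monomer").integers(0, 4, config.tel_monomer_len).astype(np.uint8)
    )

    sequences: dict[str, dict[str, np.ndarray]] = {}
    slr_variants = np.empty(0, dtype=np.int64)
    if not config.track_only:
        motif_codes = encode(TELOMERE_MOTIF)
        cen_codes = encode(cen_monomer)
        tel_codes = encode(tel_monomer)
        for i, chrom in enumerate(chroms):
            L = lengths[i]
            rng_seq = child_rng(config.seed, "seq", chrom)
            hap1 = rng_seq.integers(0, 4, L, dtype=np.int64).astype(np.uint8)
            for _, row in repeat_track[repeat_track.chrom == chrom].iterrows():
                unit = {
                    "satellite_cen": cen_codes,
                    "satellite_tel": tel_codes,
                    "telomere_motif": motif_codes,
                }.get(row.label)
                if unit is None:
                    continue
                span = row.end - row.start
                tiled = np.tile(unit, span // len(unit) + 1)[:span]
                hap1[row.start : row.end] = tiled
            if i == config.sex_chrom_index:
                hap2 = hap1.copy()
                s, e = config.slr_interval
                b = config.strata_boundary if config.strata_boundary else e
                pos_all = []
                rng_div = child_rng(config.seed, "divergence", chrom)
                for rs, re_, rate in ((s, b, config.divergence_r1), (b, e, config.divergence_r2)):
                    if re_ <= rs or rate <= 0:
                        continue
                    hit = np.flatnonzero(rng_div.random(re_ - rs) < rate) + rs
                    shift = rng_div.integers(1, 4, len(hit)).astype(np.uint8)
                    hap2[hit] = (hap2[hit] + shift) % 4
                    pos_all.append(hit)
                slr_variants = (
                    np.sort(np.concatenate(pos_all)) if pos_all else slr_variants
                )
            else:
                hap2 = hap1  # autosomes: identical haplotypes (shared array)
            sequences[chrom] = {"hap1": hap1, "hap2": hap2}

    genes: list[Gene] = []
    exon_span = config.exons_per_gene * config.exon_len
    gene_span = exon_span + (config.exons_per_gene - 1) * config.intron_len
    for i, chrom in enumerate(chroms):
        L = lengths[i]
        k = 0
        for gs in range(150_000, L - 150_000 - gene_span, config.gene_spacing):
            exons = []
            pos = gs
            for _ in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_len))
                pos += config.exon_len + config.intron_len
            genes.append(Gene(f"{chrom}_g{k}", chrom, gs, gs + gene_span, exons))
            k += 1

    truth = {
        "config": config,
        "pch": pch_truth,
        "satellites": pd.DataFrame(
            sat_truth, columns=["chrom", "start", "end", "family"]
        ),
        "cen_monomer": cen_monomer,
        "tel_monomer": tel_monomer,
        "slr_variant_positions": slr_variants,
    }
    return GenomeBundle(config, meta, sequences, repeat_track, genes, truth)


def gen_population_genotypes(bundle: GenomeBundle, config: GeneratorConfig | None = None) -> VariantTable:
    """Genotypes for n_males + n_females samples.

    Every planted X-Y difference in the SLR becomes a site heterozygous in
    all males and homozygous-reference in all females; autosomal and PAR
    sites are drawn under Hardy-Weinberg at random allele frequencies
    (``snp_density`` per bp).
    """
    config = config or bundle.config
    if config.n_males + config.n_females == 0:
        raise ValueError("need at least one sample")
    samples = [f"M{i+1}" for i in range(config.n_males)] + [
        f"F{i+1}" for i in range(config.n_females)
    ]
    sex = {s: ("male" if s.startswith("M") else "female") for s in samples}
    n_samp = len(samples)
    sex_chrom = bundle.sex_chrom
    slr = config.slr_interval

    site_rows, geno_blocks = [], []
    for chrom, L in bundle.chrom_lengths.items():
        rng = child_rng(config.seed, "geno", chrom)
        n_bg = rng.poisson(L * config.snp_density)
        bg = np.unique(rng.integers(0, L, n_bg))
        if chrom == sex_chrom and slr is not None:
            bg = bg[(bg < slr[0]) | (bg >= slr[1])]
            if len(bundle.truth.get("slr_variant_positions", [])) > 0:
                slr_pos = np.asarray(bundle.truth["slr_variant_positions"])
            else:  # track-only: plant sex-linked sites at snp_density
                n_slr = rng.poisson((slr[1] - slr[0]) * config.snp_density)
                slr_pos = np.unique(rng.integers(slr[0], slr[1], n_slr))
                bundle.truth["slr_variant_positions"] = slr_pos
        else:
            slr_pos = np.empty(0, dtype=np.int64)

        pos = np.sort(np.concatenate([bg, slr_pos]))
        is_slr = np.isin(pos, slr_pos)
        n_sites = len(pos)
        g = np.empty((n_sites, n_samp), dtype=np.int8)
        p = rng.uniform(0.05, 0.95, n_sites)
        g[:] = rng.binomial(2, p[:, None], (n_sites, n_samp)).astype(np.int8)
        g[is_slr, : config.n_males] = HET
        g[is_slr, config.n_males :] = HOM_REF
        if config.missing_rate > 0:
            g[rng.random(g.shape) < config.missing_rate] = MISSING
        refalt = rng.integers(0, 4, (n_sites, 2))
        refalt[:, 1] = (refalt[:, 0] + rng.integers(1, 4, n_sites)) % 4
        bases = np.array(list("ACGT"))
        site_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos + 1,
                 "ref": bases[refalt[:, 0]], "alt": bases[refalt[:, 1]]}
            )
        )
        geno_blocks.append(g)
    sites = pd.concat(site_rows, ignore_index=True)
    return VariantTable(sites, np.vstack(geno_blocks), samples, sex)


def gen_kmer_reads(
    bundle: GenomeBundle,
    coverage: float,
    read_len: int,
    error_rate: float,
    seed: int,
) -> list[str]:
    """Uniformly sampled reads with i.i.d. substitution errors.

    Total bases ~= coverage x genome size (distinct haplotype sequences;
    autosomes contribute one copy since their haplotypes are identical).
    """
    if not bundle.sequences:
        raise ValueError("bundle has no sequences (track-only mode)")
    seqs: list[np.ndarray] = []
    for chrom in bundle.sequences:
        h1, h2 = bundle.haplotypes(chrom)
        seqs.append(h1)
        if h2 is not h1:
            seqs.append(h2)
    lens = np.array([len(s) for s in seqs])
    if read_len > lens.min():
        raise ValueError("read_len longer than the shortest chromosome")
    genome = int(lens.sum())
    n_reads = int(round(coverage * genome / read_len))
    # positions and errors use separate streams, so the same seed samples the
    # same read loci at any error rate
    rng_pos = child_rng(seed, "reads")
    rng_err = child_rng(seed, "read_errors")
    which = rng_pos.choice(len(seqs), n_reads, p=lens / lens.sum())
    reads = []
    for w in which:
        start = rng_pos.integers(0, len(seqs[w]) - read_len + 1)
        r = seqs[w][start : start + read_len]
        if error_rate > 0:
            r = r.copy()
            hit = np.flatnonzero(rng_err.random(read_len) < error_rate)
            r[hit] = (r[hit] + rng_err.integers(1, 4, len(hit)).astype(np.uint8)) % 4
        reads.append(decode(r))
    return reads


def gen_epigenome(
    bundle: GenomeBundle,
    config: GeneratorConfig | None = None,
    chromosomes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, ContactMatrix]]:
    """H3K9me3-like scored peaks and distance-decaying contact matrices.

    Peaks are a Poisson process with density ratio ``peak_pch_ratio`` : 1
    inside vs outside planted PCH; each carries a -log10 p score. Contacts
    follow a power-law distance decay, elevated multiplicatively within PCH
    and modulated by an alternating two-compartment checkerboard outside,
    with Poisson noise on counts (unless ``hic_noise`` is off).
    """
    config = config or bundle.config
    pch = bundle.truth["pch"]
    chroms = chromosomes or list(bundle.chrom_lengths)
    peak_rows = []
    matrices: dict[str, ContactMatrix] = {}
    for chrom in chroms:
        L = bundle.chrom_lengths[chrom]
        if L <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
        rng = child_rng(config.seed, "epi", chrom)
        pch_ivs = [
            (int(r.start), int(r.end)) for r in pch[pch.chrom == chrom].itertuples()
        ]
        # peaks
        cuts = sorted({0, L, *[x for iv in pch_ivs for x in iv]})
        for s, e in zip(cuts, cuts[1:]):
            inside = any(ps <= s and e <= pe for ps, pe in pch_ivs)
            lam = config.peak_density_bg * (config.peak_pch_ratio if inside else 1.0)
            n_pk = rng.poisson(lam * (e - s))
            mids = rng.integers(s, e, n_pk)
            for m in np.sort(mids):
                peak_rows.append(
                    (chrom, max(0, m - config.peak_width // 2),
                     min(L, m + config.peak_width // 2), float(rng.uniform(1, 30)))
                )
        # contacts
        bs = config.hic_bin_size
        nb = int(math.ceil(L / bs))
        mids = np.arange(nb) * bs + bs // 2
        in_pch = np.zeros(nb, dtype=bool)
        for s, e in pch_ivs:
            in_pch |= (mids >= s) & (mids < e)
        comp = (np.arange(nb) // config.hic_comp_bins) % 2
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        expected = config.hic_scale * (1.0 + d) ** config.hic_decay
        both_pch = np.outer(in_pch, in_pch)
        both_non = np.outer(~in_pch, ~in_pch)
        same_comp = np.equal.outer(comp, comp)
        expected = expected * np.where(both_pch, config.hic_pch_factor, 1.0)
        expected = expected * np.where(
            both_non, np.where(same_comp, 1 + config.hic_checker, 1 - config.hic_checker), 1.0
        )
        if config.hic_noise:
            iu, ju = np.triu_indices(nb)
            counts = np.zeros((nb, nb))
            counts[iu, ju] = rng.poisson(expected[iu, ju])
            counts = counts + np.triu(counts, 1).T
        else:
            counts = expected
        matrices[chrom] = ContactMatrix(chrom, bs, counts)
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "score"])
    return peaks, matrices


GONAD_GROUPS = {"testis", "ovary", "intersex_early", "intersex_late"}


def gen_expression(
    bundle: GenomeBundle, config: GeneratorConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial counts for gonads (+2 somatic tissues) with planted
    sex-determining candidate patterns.

    Returns (counts genes x samples, sample sheet, gene lengths). Two SLR
    genes are planted: one expressed exclusively in testis, one expressed in
    testis and early intersex but depleted in ovary. Genes inside PCH get
    their baseline multiplied by ``pch_expr_factor``.
    """
    config = config or bundle.config
    if not bundle.genes:
        raise ValueError("bundle has no genes")
    reps = config.n_replicates
    rows = []
    for i in range(reps):
        rows.append((f"M{i+1}", "testis", "", "testis"))
    for i in range(reps):
        rows.append((f"F{i+1}", "ovary", "", "ovary"))
    for i in range(reps):
        stage = f"I{i % 5 + 1}"
        grp = "intersex_early" if stage in EARLY_STAGES else "intersex_late"
        rows.append((f"I{i+1}", "intersex", stage, grp))
    rows.append(("L1", "liver", "", "liver"))
    rows.append(("B1", "brain", "", "brain"))
    sheet = pd.DataFrame(rows, columns=["sample", "tissue", "stage", "group"])

    rng = child_rng(config.seed, "expr")
    gene_names = [g.name for g in bundle.genes]
    base = rng.lognormal(np.log(30.0), 1.0, len(gene_names))
    pch = bundle.truth["pch"]
    if config.pch_expr_factor != 1.0 and len(pch):
        for gi, g in enumerate(bundle.genes):
            mid = (g.start + g.end) // 2
            sub = pch[(pch.chrom == g.chrom) & (pch.start <= mid) & (pch.end > mid)]
            if len(sub):
                base[gi] *= config.pch_expr_factor

    level = np.tile(base[:, None], (1, len(sheet)))
    # planted candidates: first two genes inside the SLR
    candidates = {}
    if bundle.sex_chrom and config.slr_interval:
        s, e = config.slr_interval
        slr_genes = [
            gi for gi, g in enumerate(bundle.genes)
            if g.chrom == bundle.sex_chrom and s <= (g.start + g.end) // 2 < e
        ]
        grp = sheet.group.to_numpy()
        if len(slr_genes) >= 1:
            gi = slr_genes[0]
            level[gi] = 0.0  # exclusive: not detected outside testis
            level[gi, grp == "testis"] = 80.0
            candidates["testis_exclusive"] = gene_names[gi]
        if len(slr_genes) >= 2:
            gi = slr_genes[1]
            level[gi] = 0.5
            level[gi, grp == "testis"] = 50.0
            level[gi, grp == "intersex_early"] = 40.0
            level[gi, grp == "intersex_late"] = 10.0
            candidates["testis_plus_early_intersex"] = gene_names[gi]
    bundle.truth["candidates"] = candidates

    lengths = pd.Series([g.exon_bp for g in bundle.genes], index=gene_names, dtype=float)
    mu = level * lengths.to_numpy()[:, None] / 1000.0 * config.seq_depth_factor
    d = config.nb_dispersion
    if d <= 0:
        counts = np.round(mu)
    else:
        counts = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * mu))
    counts_df = pd.DataFrame(counts, index=gene_names, columns=sheet["sample"])
    return counts_df, sheet, lengths
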
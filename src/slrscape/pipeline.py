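"""Pipeline orchestration: run the stages on a declarative config and emit
one structured report.

A config carries either a ``simulate`` block (GeneratorConfig fields) or an
``inputs`` block (paths to VCF + sex labels, repeat/peak BEDs, contact
matrix, counts), a list of enabled stages, an output directory and a seed.
Every stage threshold can be overridden under ``params`` with
module-qualified names (e.g. ``sexlink_scan.min_count``). Reruns with the
same config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gonad_expression as ge
from . import io as sio
from . import kmer_profile as kp
from . import pch_compartments as pc
from . import satellite_karyotype as sk
from . import sexlink_scan as sx
from . import synthetic_data as sd

log = logging.getLogger("slrscape")

STAGES = ("simulate", "kmer", "satellites", "sexscan", "pch", "expr")


@dataclass
class PipelineConfig:
    simulate: dict | None = None
    inputs: dict | None = None
    stages: list[str] = field(default_factory=lambda: ["simulate", "sexscan", "pch", "expr"])
    outdir: str = "slrscape_out"
    seed: int = 0
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.inputs:
            missing = [
                f"{k}: {v}" for k, v in self.inputs.items()
                if isinstance(v, str) and not Path(v).exists()
            ]
            if missing:
                raise FileNotFoundError("missing input files: " + "; ".join(missing))


def _p(cfg: PipelineConfig, qualified: str, default):
    return cfg.params.get(qualified, default)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    return x


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run enabled stages in dependency order; return the aggregated report."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in sorted(cfg.params.items()):
        log.info("param override %s = %r", key, val)
    report: dict = {
        "version": __version__,
        "config": _jsonable(dataclasses.asdict(cfg)),
        "stages": {},
    }

    bundle = None
    vt = None
    if "simulate" in cfg.stages:
        sim = dict(cfg.simulate or {})
        preset = sim.pop("preset", None)
        if preset == "zigzag" or not sim:
            gcfg = sd.zigzag_config(seed=cfg.seed, track_only=sim.pop("track_only", False))
            gcfg = dataclasses.replace(gcfg, **sim)
        else:
            gcfg = sd.GeneratorConfig(seed=cfg.seed, **sim)
        gcfg.validate()
        bundle = sd.gen_genome(gcfg)
        sio.write_bundle(bundle, out / "simulate")
        report["stages"]["simulate"] = {
            "n_chromosomes": gcfg.n_chromosomes,
            "genome_bp": int(sum(gcfg.chrom_lengths)),
            "track_only": gcfg.track_only,
            "sex_chrom": bundle.sex_chrom,
        }

    if "kmer" in cfg.stages:
        if bundle is None or not bundle.sequences:
            raise ValueError("kmer stage needs a simulated bundle with sequences")
        reads = sd.gen_kmer_reads(
            bundle,
            coverage=_p(cfg, "kmer_profile.coverage", 40),
            read_len=_p(cfg, "kmer_profile.read_len", 10_000),
            error_rate=bundle.config.hifi_error_rate,
            seed=cfg.seed,
        )
        spec = kp.count_kmers(reads, k=_p(cfg, "kmer_profile.k", 21))
        fit = kp.fit_spectrum(spec)
        report["stages"]["kmer"] = _jsonable(fit)

    if "satellites" in cfg.stages:
        if bundle is None or not bundle.sequences:
            raise ValueError("satellites stage needs sequences")
        arrays = []
        for chrom in bundle.sequences:
            h1, _ = bundle.haplotypes(chrom)
            arrays += sk.find_tandem_arrays(
                h1,
                min_period=_p(cfg, "satellite_karyotype.min_period", 10),
                max_period=_p(cfg, "satellite_karyotype.max_period", 2000),
                max_mismatch=_p(cfg, "satellite_karyotype.max_mismatch", 0.2),
                chrom=chrom,
            )
        fams = sk.build_families(arrays, top_n=10)
        sk.classify_families(fams, bundle.meta.rename(columns={"length": "length"}))
        cen_fams = [f for f in fams if f.label == "centromeric"]
        morph_counts = {}
        if cen_fams:
            cens, _flags = sk.locate_centromeres(cen_fams[0], bundle.meta)
            _, counts = sk.classify_morphology(bundle.meta, cens)
            morph_counts = dict(counts)
        report["stages"]["satellites"] = {
            "families": [
                {"monomer_len": f.monomer_len, "total_bp": f.total_bp, "label": f.label}
                for f in fams
            ],
            "morphology_counts": morph_counts,
        }

    if "sexscan" in cfg.stages:
        if bundle is not None:
            vt = sd.gen_population_genotypes(bundle)
            chrom_lengths = bundle.chrom_lengths
        else:
            sex = sio.read_sex_tsv(cfg.inputs["sex"])
            vt = sio.read_vcf(cfg.inputs["vcf"], sex)
            chrom_lengths = {
                c: int(vt.sites[vt.sites.chrom == c].pos.max())
                for c in vt.sites.chrom.unique()
            }
        sss = sx.call_sex_specific_snps(vt)
        dens = sx.window_counts(sss, chrom_lengths, window=_p(cfg, "sexlink_scan.window", 50_000))
        call = sx.demarcate_slr(
            dens,
            min_count=_p(cfg, "sexlink_scan.min_count", 3),
            max_gap_windows=_p(cfg, "sexlink_scan.max_gap_windows", 5),
        )
        dens.to_bedgraph(out / "male_specific_density.bedgraph")
        stage = {
            "n_male_specific": int(len(sss)),
            "slr": {"chrom": call.chromosome, "interval": call.interval,
                    "length_mb": call.length / 1e6, "pars": call.par_intervals},
        }
        if bundle is not None and bundle.sequences and bundle.sex_chrom and call.interval:
            x, y = bundle.haplotypes(bundle.sex_chrom)
            sim = sx.xy_window_similarity(
                x, y, bundle.intron_intervals(bundle.sex_chrom),
                window=_p(cfg, "sexlink_scan.similarity_window", 100_000),
                chrom=bundle.sex_chrom,
            )
            strata_call = sx.segment_strata(sim, call.interval, bundle.sex_chrom)
            stage["strata"] = [
                {"interval": iv, "mean_divergence": dv} for iv, dv in strata_call.strata
            ]
            stage["wilcoxon_p"] = strata_call.wilcoxon_p
        report["stages"]["sexscan"] = _jsonable(stage)

    if "pch" in cfg.stages:
        if bundle is not None:
            repeats = bundle.repeat_track
            chrom_lengths = bundle.chrom_lengths
            cens = bundle.centromeres
            peaks, matrices = sd.gen_epigenome(
                bundle, chromosomes=[bundle.sex_chrom] if bundle.sex_chrom else None
            )
        else:
            repeats = sio.read_bed(cfg.inputs["repeats"])
            meta = pd.read_csv(cfg.inputs["chromosomes"], sep="\t")
            chrom_lengths = dict(zip(meta.chrom, meta.length))
            cens = {
                r.chrom: (int(r.cen_start), int(r.cen_end)) for r in meta.itertuples()
            }
            peaks = sio.read_bed(cfg.inputs["peaks"], extra=("score",))
            matrices = {}
            if "matrix" in cfg.inputs:
                cm = sio.read_contact_matrix(cfg.inputs["matrix"])
                matrices[cm.chromosome] = cm
        track = pc.repeat_content_track(
            repeats, chrom_lengths, window=_p(cfg, "pch_compartments.window", 50_000)
        )
        blocks = pc.call_pch(
            track, cens, threshold=_p(cfg, "pch_compartments.threshold", 0.40)
        )
        stage = {
            "summary": pc.pch_summary(blocks, chrom_lengths),
            "enrichment": pc.peak_enrichment(
                peaks, blocks, chrom_lengths,
                score_min=_p(cfg, "pch_compartments.score_min", 8.0),
            ),
        }
        if len({b.chromosome for b in blocks}) >= 3:
            r, p = pc.pch_size_correlation(blocks, chrom_lengths)
            stage["size_correlation"] = {"pearson_r": r, "p": p}
        for chrom, cm in matrices.items():
            bal = pc.balance_matrix(cm)
            gd = (
                bundle.gene_density(chrom, 250_000) if bundle is not None else None
            )
            comp = pc.oe_pearson_pc1(bal, gene_density=gd)
            contacts = pc.distance_stratified_contacts(bal, blocks)
            stage.setdefault("hic", {})[chrom] = {
                "n_A_bins": int((comp.df.label == "A").sum()),
                "n_B_bins": int((comp.df.label == "B").sum()),
                "pch_vs_nonpch_p": contacts["p"],
            }
        pd.DataFrame(
            [{"chrom": b.chromosome, "start": b.interval[0], "end": b.interval[1]} for b in blocks]
        ).to_csv(out / "pch_blocks.bed", sep="\t", header=False, index=False)
        report["stages"]["pch"] = _jsonable(stage)

    if "expr" in cfg.stages:
        if bundle is not None:
            counts, sheet, lengths = sd.gen_expression(bundle)
            gene_pos = bundle.gene_positions()
        else:
            tab = pd.read_csv(cfg.inputs["counts"], sep="\t", index_col=0)
            lengths = tab.pop("length")
            counts = tab
            sheet = pd.read_csv(cfg.inputs["samples"], sep="\t")
            genes = sio.read_genes_gff3(cfg.inputs["gff"])
            gene_pos = pd.DataFrame(
                {"chrom": [g.chrom for g in genes], "start": [g.start for g in genes],
                 "end": [g.end for g in genes]},
                index=[g.name for g in genes],
            )
        expr = ge.tpm(counts, lengths)
        groups = pd.Series(sheet.group.to_numpy(), index=sheet["sample"])
        slr = report["stages"].get("sexscan", {}).get("slr", {})
        slr_genes = None
        if slr.get("interval"):
            s, e = slr["interval"]
            sub = gene_pos[(gene_pos.chrom == slr["chrom"])]
            mid = (sub.start + sub.end) // 2
            slr_genes = set(sub.index[(mid >= s) & (mid < e)])
        cands = ge.screen_candidates(
            expr, groups, slr_genes, fold=_p(cfg, "gonad_expression.fold", 4.0)
        )
        hits = [c for c in cands if c.pattern != "none"]
        stage = {
            "n_genes": int(len(expr)),
            "n_screened": len(cands),
            "candidates": [
                {"gene": c.gene, "pattern": c.pattern} for c in hits
            ],
        }
        report["stages"]["expr"] = _jsonable(stage)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
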
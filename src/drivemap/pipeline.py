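"""End-to-end pipeline: simulate -> mating protocol -> scan -> colocalize -> contrast.

A run is a pure function of its :class:`RunConfig`: the master seed is hashed
with each stage name to derive per-stage streams, so adding a stage never
perturbs earlier ones and identical configs give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cross_io
from .coloc import IntervalWidths, combined_probability, matching_probability
from .contrasts import GenotypeGroup, fertility_contrast, sexratio_contrast
from .crosses import (
    IntrogressionSegment,
    IntrogressionSpec,
    make_introgression_genotype,
    simulate_mapping_population,
    study_design,
)
from .genome import build_study_map, map_to_json
from .phenotypes import (
    EffectModel,
    default_effect_model,
    simulate_phenotypes,
    simulate_vial_series,
)
from .protocol import ProtocolConfig, interpolate_total, observed_sex_ratio
from .qtl import lod_scan, permutation_threshold, support_interval, transform_trait
from .studydata import QTL_INTERVAL_WIDTHS, S3_DOMINANCE_SEX_RATIOS

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "make_fixtures", "simulate_introgression_group"]

log = logging.getLogger("drivemap")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing the master seed with the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


@dataclass
class RunConfig:
    design_label: str = "Exp2"
    n_males: int | None = None
    effect_model: EffectModel | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    transforms: tuple[str, ...] = ("T", "log10T1", "binary", "sexratio")
    n_perm: int = 500
    alpha: float = 0.05
    step_cM: float = 1.0
    lifespan: int = 18
    decay: str = "linear"
    seed: int = 0

    @property
    def focal_line(self) -> str:
        return "shl2-hap1" if self.design_label == "Exp3" else "alb267"


def simulate_introgression_group(
    label: str,
    loci: list[str],
    model: EffectModel,
    gmap,
    n: int,
    rng,
    homozygous: set[str] = frozenset(),
    halfwidth_cM: float = 2.0,
) -> GenotypeGroup:
    """Phenotyped males of one introgression genotype (loci by model name)."""
    by_name = {l.name: l for l in model.loci}
    segs = []
    for nm in loci:
        loc = by_name[nm]
        pm = gmap.positions(loc.chromosome)
        center = float(pm[np.argmin(np.abs(pm - loc.position))])  # snap to marker
        segs.append(
            IntrogressionSegment(
                loc.chromosome,
                center - halfwidth_cM,
                center + halfwidth_cM,
                loc.line,
                homozygous=nm in homozygous,
            )
        )
    g = make_introgression_genotype(IntrogressionSpec(segs), gmap)
    phen = simulate_phenotypes([g] * n, model, gmap, rng)
    return GenotypeGroup(label, phen)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages and write tables + JSON summary + log under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    summary: dict = {"config_seed": config.seed, "design": config.design_label, "stages": {}}
    try:
        model = config.effect_model or default_effect_model()
        gmap = build_study_map(config.design_label)
        (outdir / "map.json").write_text(map_to_json(gmap))

        design = study_design(config.design_label, config.n_males)
        seed_g = stage_seed(config.seed, "genotypes")
        log.info("simulating %d %s males (seed %d)", design.n_males, design.label, seed_g)
        genotypes = simulate_mapping_population(design, gmap, seed_g)
        (outdir / "genotypes.csv").write_text(
            cross_io.genotypes_to_cross_csv(genotypes, gmap, config.focal_line)
        )

        seed_p = stage_seed(config.seed, "phenotypes")
        phenotypes = simulate_phenotypes(genotypes, model, gmap, seed_p)
        ids = [f"m{i + 1:04d}" for i in range(len(phenotypes))]
        (outdir / "phenotypes.csv").write_text(cross_io.phenotypes_to_csv(phenotypes, ids))

        seed_v = stage_seed(config.seed, "vials")
        rng_v = np.random.default_rng(seed_v)
        series = {
            mid: simulate_vial_series(
                p, config.protocol, config.decay, config.lifespan, rng=rng_v
            )
            for mid, p in zip(ids, phenotypes)
        }
        cross_io.vial_series_to_frame(series).to_csv(outdir / "vials.csv", index=False)
        interp = [interpolate_total(series[m]) for m in ids]
        sexr = [observed_sex_ratio(series[m], config.protocol) for m in ids]
        cross_io.male_summary_frame(ids, interp, sexr).to_csv(
            outdir / "male_summary.csv", index=False
        )
        summary["stages"]["protocol"] = {
            "mean_T_interpolated": float(np.mean([r.total for r in interp])),
            "n_sex_ratio_eligible": int(sum(s.eligible for s in sexr)),
        }

        thresholds: dict = {}
        intervals: dict = {}
        fitted_widths: dict[str, list[float]] = {}
        for kind in config.transforms:
            trait = transform_trait(
                phenotypes, kind, config.protocol.sex_ratio_min_T
            )
            scan = lod_scan(
                genotypes,
                trait,
                gmap,
                config.step_cM,
                cross_label=config.design_label,
                focal_line=config.focal_line,
            )
            scan.to_dataframe().to_csv(outdir / f"scan_{kind}.csv", index=False)
            entry: dict = {"max_lod": scan.max_lod()}
            if config.n_perm > 0:
                thr = permutation_threshold(
                    genotypes,
                    trait,
                    gmap,
                    config.n_perm,
                    config.alpha,
                    stage_seed(config.seed, f"perm-{kind}"),
                    step_cM=config.step_cM,
                    cross_label=config.design_label,
                    focal_line=config.focal_line,
                )
                entry["cutoff"] = thr.cutoff
                ivs = []
                for chrom in {c.name for c in gmap.chromosomes}:
                    pk = scan.peak(chrom)
                    if scan.lod[pk] > thr.cutoff:
                        iv = support_interval(scan, pk)
                        ivs.append(
                            {
                                "chromosome": iv.chromosome,
                                "peak_cM": iv.peak_cM,
                                "start_cM": iv.start_cM,
                                "end_cM": iv.end_cM,
                                "U": iv.U,
                            }
                        )
                        if kind == "sexratio":
                            fitted_widths.setdefault(iv.chromosome, []).append(iv.U)
                intervals[kind] = ivs
            else:
                entry["cutoff"] = None
                summary.setdefault("flags", []).append(f"no permutations for {kind}")
            thresholds[kind] = entry
        (outdir / "thresholds.json").write_text(json.dumps(thresholds, indent=1))
        (outdir / "intervals.json").write_text(json.dumps(intervals, indent=1))

        coloc = {
            "printed": {
                "per_chromosome": {
                    c: matching_probability(w) for c, w in QTL_INTERVAL_WIDTHS.items()
                },
                "combined": combined_probability(
                    [IntervalWidths(c, w) for c, w in QTL_INTERVAL_WIDTHS.items()]
                ),
            },
            "fitted_sexratio_widths": fitted_widths,
        }
        (outdir / "coloc.json").write_text(json.dumps(coloc, indent=1))

        rng_c = np.random.default_rng(stage_seed(config.seed, "contrasts"))
        groups = {
            "V": simulate_introgression_group("V", [], model, gmap, 40, rng_c),
            "M": simulate_introgression_group("M", ["D2", "D3", "D4"], model, gmap, 40, rng_c),
            "K": simulate_introgression_group(
                "K", ["D2", "D3", "D4", "S3"], model, gmap, 40, rng_c
            ),
        }
        rows = []
        for a, b, what in (("K", "M", "S3"), ("M", "V", "D2D3D4")):
            u, p_f = fertility_contrast(groups[a], groups[b])
            lr, p_k, adj = sexratio_contrast(groups[a], groups[b])
            rows.append(
                {
                    "contrast": f"{a} vs {b}",
                    "locus": what,
                    "wilcoxon_U": u,
                    "p_fertility": p_f,
                    "LR": lr,
                    "p_sexratio": p_k,
                    "adjusted": adj,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "contrasts.csv", index=False)
        summary["stages"]["coloc"] = coloc["printed"]
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        log.info("pipeline finished in %.1fs", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary


def make_fixtures(target: str, seed: int, outdir: str | Path) -> Path:
    """Small deterministic datasets for tests and worked examples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if target == "coloc_published":
        path = outdir / "coloc_published.json"
        path.write_text(json.dumps(QTL_INTERVAL_WIDTHS, indent=1))
    elif target == "dominance_s3":
        path = outdir / "dominance_s3.json"
        path.write_text(json.dumps({"k0_k1_k2": list(S3_DOMINANCE_SEX_RATIOS)}))
    elif target == "toy_bc1":
        from .genome import Chromosome, GeneticMap, Marker

        gmap = GeneticMap(
            [Chromosome("X-3", 100.0, True), Chromosome("2", 60.0)],
            [Marker(f"t{i}", "X-3", p) for i, p in enumerate(np.linspace(5, 95, 7))]
            + [Marker(f"a{i}", "2", p) for i, p in enumerate(np.linspace(5, 55, 5))],
        )
        design = study_design("Exp2", 50)
        genos = simulate_mapping_population(design, gmap, stage_seed(seed, "toy"))
        path = outdir / "toy_bc1.csv"
        path.write_text(cross_io.genotypes_to_cross_csv(genos, gmap))
    else:
        raise ValueError(f"unknown fixture target {target!r}")
    return path
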
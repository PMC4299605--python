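"""End-to-end orchestration: simulate -> genotype -> normalize -> map -> downstream.

One YAML-serializable :class:`RunConfig` drives every stage; all randomness
derives from its master seed, so an identical config yields byte-identical
TSV outputs and an identical manifest.  Stages can be toggled off, in which
case later stages must find their inputs in the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .genotyping import (
    build_markers,
    correct_isolated_discordant,
    detect_breakpoints,
    filter_sites,
    impute_missing,
    infer_inheritance,
)
from .expression import normalize_antisense, normalize_sense
from .postqtl import classify_cis_trans, detect_hotspots, directionality
from .qtl import (
    PredictorMatrix,
    RFConfig,
    empirical_p_and_fdr,
    group_qtls,
    kinship,
    marker_ld,
    permutation_null,
    rf_selection_frequency,
    structure_covariates,
)
from .simulate import (
    CallParams,
    EffectConfig,
    SimConfig,
    TransEffect,
    make_genome,
    simulate_cross,
    simulate_expression,
    simulate_genotype_calls,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("segqtl")


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    seed: int = 1
    outdir: str = "segqtl_run"
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "genotype": True,
            "normalize": True,
            "map": True,
            "postqtl": True,
        }
    )
    # simulate
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    n_segregants: int = 24
    generation: str = "F1"
    crossover_rate: float = 1.4
    inversion_suppression: float = 0.1
    n_cis: int = 3
    n_trans: int = 3
    cis_size: float = 2.0
    trans_size: float = 1.5
    call_params: dict = field(default_factory=dict)  # CallParams overrides
    # genotype
    min_quality: float = 20.0
    flank_kb: float = 50.0
    min_called_fraction: float = 0.5
    maf_min: float = 0.10
    # map
    rf: dict = field(default_factory=dict)  # RFConfig overrides (observed)
    rf_null: dict | None = None  # RFConfig overrides for the permutation null
    n_perm: int = 50
    fdr: float = 0.10
    fixed_k: int = 8
    max_traits: int | None = 20  # cap mapped traits for desk-scale runs
    # postqtl
    bin_size: int = 50_000
    hotspot_alpha: float = 8e-4

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def params_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        params = asdict(self)
        params.pop("outdir")
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _planted_effects(genome, rng, config: RunConfig) -> EffectConfig:
    """Pick cis targets (genes hosting a variant) and distant trans pairs."""
    host = genome.variant_gene_index()
    hosted_genes = sorted({genome.genes[h].gene_id for h in host if h >= 0})
    rng.shuffle(hosted_genes)
    cis = [(g, config.cis_size) for g in hosted_genes[: config.n_cis]]

    trans = []
    gene_by_id = {g.gene_id: g for g in genome.genes}
    candidates = [g.gene_id for g in genome.genes
                  if g.gene_id not in {c[0] for c in cis}]
    rng.shuffle(candidates)
    for target in candidates[: config.n_trans]:
        tg = gene_by_id[target]
        distant = [
            v for v in genome.variants
            if v.chrom != tg.chrom or abs(v.pos - tg.cds_start) > 200_000
        ]
        v = distant[int(rng.integers(len(distant)))]
        trans.append(TransEffect((v.chrom, v.pos), [target], [config.trans_size]))
    return EffectConfig(cis_effects=cis, trans_effects=trans)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the manifest dictionary."""
    outdir = sio.ensure_dir(config.outdir)
    manifest: dict = {
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": {},
        "files": {},
    }
    t_all = time.time()

    def _register(name: str, path: str) -> None:
        manifest["files"][name] = {
            "path": os.path.basename(path), "sha256": _sha256(path)
        }

    def _stage_done(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    state: dict = {}
    try:
        if config.stages.get("simulate", True):
            t0 = time.time()
            sim_cfg = SimConfig(**config.sim)
            genome = make_genome(sim_cfg, config.seed)
            truth = simulate_cross(
                genome, config.n_segregants, config.generation,
                config.crossover_rate, config.inversion_suppression,
                seed=config.seed,
            )
            rng = np.random.default_rng(config.seed)
            effects = _planted_effects(genome, rng, config)
            expr = simulate_expression(genome, truth, effects, seed=config.seed)
            calls = simulate_genotype_calls(
                truth, expr.sense_counts, CallParams(**config.call_params),
                seed=config.seed,
            )
            state.update(genome=genome, truth=truth, effects=effects,
                         expr=expr, calls=calls)

            sio.write_gff3(genome, os.path.join(outdir, "genome.gff3"))
            sio.write_vcf(genome, os.path.join(outdir, "variants.vcf"))
            sio.write_counts_tsv(expr.sense_counts,
                                 os.path.join(outdir, "sense_counts.tsv"))
            sio.write_counts_tsv(expr.antisense_counts,
                                 os.path.join(outdir, "antisense_counts.tsv"))
            sio.write_calls_tsv(calls, os.path.join(outdir, "calls.tsv"))
            expr.truth.to_csv(os.path.join(outdir, "planted_effects.tsv"),
                              sep="\t", index=False)
            for f in ("genome.gff3", "variants.vcf", "sense_counts.tsv",
                      "antisense_counts.tsv", "calls.tsv",
                      "planted_effects.tsv"):
                _register(f, os.path.join(outdir, f))
            _stage_done("simulate", t0)

        if config.stages.get("genotype", True):
            t0 = time.time()
            calls = state["calls"]
            inh = infer_inheritance(calls, min_quality=config.min_quality)
            inh, report = filter_sites(
                inh, np.ones(len(inh.sites), dtype=bool), maf_min=config.maf_min
            )
            inh, n_corr = correct_isolated_discordant(
                inh, max_flank_distance=int(config.flank_kb * 1000)
            )
            inh = impute_missing(
                inh, max_flank_distance=int(config.flank_kb * 1000)
            )
            markers = build_markers(
                inh, min_called_fraction=config.min_called_fraction
            )
            breakpoints = detect_breakpoints(inh)
            state.update(inh=inh, markers=markers, breakpoints=breakpoints)

            sio.write_genotypes_tsv(inh, os.path.join(outdir, "genotypes.tsv"))
            sio.write_markers_tsv(markers, os.path.join(outdir, "markers.tsv"))
            sio.write_breakpoints_bed(
                breakpoints, os.path.join(outdir, "breakpoints.bed")
            )
            report.to_csv(os.path.join(outdir, "discarded_sites.tsv"),
                          sep="\t", index=False)
            for f in ("genotypes.tsv", "markers.tsv", "breakpoints.bed",
                      "discarded_sites.tsv"):
                _register(f, os.path.join(outdir, f))
            manifest["stages"]["genotype_corrections"] = n_corr
            _stage_done("genotype", t0)

        if config.stages.get("normalize", True):
            t0 = time.time()
            expr = state["expr"]
            sense_norm, dropped = normalize_sense(expr.sense_counts,
                                                  expr.batch)
            anti_norm, a_dropped, _ = normalize_antisense(
                expr.antisense_counts, expr.batch,
                totals=expr.sense_counts.sum(axis=0),
            )
            state.update(sense_norm=sense_norm, anti_norm=anti_norm)
            sio.write_counts_tsv(sense_norm,
                                 os.path.join(outdir, "sense_normalized.tsv"))
            sio.write_counts_tsv(anti_norm,
                                 os.path.join(outdir, "antisense_normalized.tsv"))
            for f in ("sense_normalized.tsv", "antisense_normalized.tsv"):
                _register(f, os.path.join(outdir, f))
            _stage_done("normalize", t0)

        if config.stages.get("map", True):
            t0 = time.time()
            markers = state["markers"]
            sense_norm = state["sense_norm"]
            pred_raw = PredictorMatrix.from_marker_map(markers)
            kin = kinship(pred_raw.markers)
            cov = structure_covariates(kin, fixed_k=config.fixed_k)
            predictors = PredictorMatrix(
                pred_raw.strains, pred_raw.marker_ids, pred_raw.markers, cov
            )
            traits = sense_norm.loc[:, predictors.strains]
            planted = set(state["expr"].truth["trait_id"]) if "expr" in state else set()
            if config.max_traits is not None and len(traits) > config.max_traits:
                keep = [g for g in traits.index if g in planted]
                rest = [g for g in traits.index if g not in planted]
                traits = traits.loc[keep + rest[: config.max_traits - len(keep)]]

            rf_cfg = RFConfig(**config.rf)
            null_cfg = RFConfig(**config.rf_null) if config.rf_null else rf_cfg
            observed = pd.DataFrame(
                [
                    rf_selection_frequency(
                        traits.loc[t].to_numpy(), predictors, rf_cfg,
                        seed=config.seed + ti,
                    )
                    for ti, t in enumerate(traits.index)
                ],
                index=traits.index, columns=predictors.marker_ids,
            )
            null = permutation_null(
                traits, predictors, n_perm=config.n_perm, config=null_cfg,
                seed=config.seed,
            )
            result = empirical_p_and_fdr(observed, null)
            state.update(predictors=predictors, result=result, traits=traits)

            result.to_long().to_csv(os.path.join(outdir, "linkages.tsv"),
                                    sep="\t", index=False)
            _register("linkages.tsv", os.path.join(outdir, "linkages.tsv"))
            _stage_done("map", t0)

        if config.stages.get("postqtl", True):
            t0 = time.time()
            genome = state["genome"]
            markers = state["markers"]
            predictors = state["predictors"]
            result = state["result"]
            traits = state["traits"]
            ld = marker_ld(predictors.markers)
            chrom_lengths = dict(genome.chromosomes)
            gene_by_id = {g.gene_id: g for g in genome.genes}
            linked = result.linked(config.fdr)

            group_rows, qtl_pos = [], []
            for trait_id, sub in linked.groupby("trait_id"):
                idx = [predictors.marker_ids.index(m) for m in sub["marker_id"]]
                group = group_qtls(
                    idx, markers.markers, ld, chrom_lengths=chrom_lengths,
                    trait_id=trait_id,
                )
                if group is None:
                    continue
                g = gene_by_id.get(trait_id)
                flag = (
                    classify_cis_trans(
                        group.member_markers, g.chrom,
                        (g.cds_start, g.cds_end), markers.markers, ld,
                    )
                    if g is not None else "trans"
                )
                peak = sub.loc[sub["score"].idxmax(), "marker_id"]
                pk = predictors.marker_ids.index(peak)
                direction = directionality(
                    traits.loc[trait_id].to_numpy(),
                    np.nan_to_num(predictors.markers[:, pk], nan=-1).astype(int),
                )
                qtl_pos.append({
                    "trait_id": trait_id,
                    "chrom": markers.markers["chrom"].iloc[pk],
                    "pos": markers.markers["start"].iloc[pk],
                })
                for r in group.regions:
                    group_rows.append({
                        "trait_id": trait_id, "chrom": r.chrom,
                        "start": r.start, "end": r.end,
                        "n_members": len(r.members),
                        "multi_region": group.multi_region,
                        "cis_trans": flag, "direction": direction,
                    })
            groups_df = pd.DataFrame(
                group_rows,
                columns=["trait_id", "chrom", "start", "end", "n_members",
                         "multi_region", "cis_trans", "direction"],
            )
            groups_df.to_csv(os.path.join(outdir, "qtl_groups.tsv"),
                             sep="\t", index=False)
            hotspots = detect_hotspots(
                pd.DataFrame(qtl_pos, columns=["trait_id", "chrom", "pos"]),
                genome, bin_size=config.bin_size, alpha=config.hotspot_alpha,
            )
            pd.DataFrame(
                [{"chrom": h.chrom, "start": h.start, "end": h.end,
                  "count": h.count, "expected": h.expected, "p": h.p_value,
                  "n_targets": len(h.targets)} for h in hotspots],
                columns=["chrom", "start", "end", "count", "expected", "p",
                         "n_targets"],
            ).to_csv(os.path.join(outdir, "hotspots.tsv"), sep="\t", index=False)
            for f in ("qtl_groups.tsv", "hotspots.tsv"):
                _register(f, os.path.join(outdir, f))
            _stage_done("postqtl", t0)
    except Exception as exc:  # partial outputs stay in place for debugging
        stage = next(
            (s for s in ("simulate", "genotype", "normalize", "map", "postqtl")
             if s not in manifest["stages"] and config.stages.get(s, True)),
            "unknown",
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    # content hash covers outputs and parameters but not wall times
    manifest["content_hash"] = hashlib.sha256(
        json.dumps(
            {"files": manifest["files"], "params": manifest["params_hash"],
             "seed": config.seed},
            sort_keys=True,
        ).encode()
    ).hexdigest()
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
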
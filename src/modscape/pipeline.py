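"""End-to-end orchestration: simulate/load inputs, then run every stage.

Stage order mirrors the analysis: preprocessing and sample QC, three
two-group differential expression contrasts, reference-guided module
detection with the DEM test, directional signature statistics, the
disease-gene resampling null, GWAS-proximity statistics, promoter motif
enrichment, and a final summary table. Each stage writes its tables before
the next starts, and a JSON manifest records seeds, per-stage timings and
output checksums so resampling stages are exactly replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, comod, diffexpr, gwasprox, motifscan, preprocess, setstats
from .io import ExpressionMatrix, write_expression_tsv, write_gmt, write_groups_tsv
from .synthio import (
    GroundTruth,
    SimParams,
    load_builtin_signatures,
    simulate_disease_sources,
    simulate_experiment,
    simulate_genome_and_loci,
    simulate_promoters,
    simulate_reference,
    simulate_signature,
    synthetic_irf_pwms,
)


@dataclass
class RunConfig:
    outdir: str = "modscape_out"
    seed: int = 0
    comparisons: tuple[str, ...] = ("MMF", "DRF", "IDMF")
    sim: SimParams = field(default_factory=SimParams)
    filter_params: preprocess.FilterParams = field(default_factory=preprocess.FilterParams)
    module_params: comod.ModuleParams = field(default_factory=comod.ModuleParams)
    deg_criteria: diffexpr.DEGCriteria = field(default_factory=diffexpr.DEGCriteria)
    proximity: gwasprox.ProximityParams = field(default_factory=gwasprox.ProximityParams)
    fc_null_trials: int = 10_000
    n_loci: int = 120
    promoter_genes: int = 600
    promoter_length: int = 1500
    n_irf_pwms: int = 19

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "sim" in raw:
            kwargs["sim"] = SimParams(**raw.pop("sim"))
        if "filter" in raw:
            kwargs["filter_params"] = preprocess.FilterParams(**raw.pop("filter"))
        if "modules" in raw:
            kwargs["module_params"] = comod.ModuleParams(**raw.pop("modules"))
        if "degs" in raw:
            kwargs["deg_criteria"] = diffexpr.DEGCriteria(**raw.pop("degs"))
        if "proximity" in raw:
            kwargs["proximity"] = gwasprox.ProximityParams(**raw.pop("proximity"))
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(raw.pop("comparisons"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run the full synthetic-data pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # halt with stage-named error
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            return fn

        return deco

    sim = dataclasses.replace(config.sim, seed=config.seed)

    @stage("simulate")
    def _simulate():
        matrix, truth = simulate_experiment(sim)
        ref, ref_truth = simulate_reference(sim)
        truth.planted_modules = ref_truth.planted_modules
        write_expression_tsv(matrix, outdir / "expression.tsv", seed=config.seed)
        write_groups_tsv(matrix.groups, outdir / "groups.tsv")
        write_expression_tsv(ref, outdir / "reference.tsv", seed=config.seed)
        truth.to_json(outdir / "ground_truth.json")
        results["matrix"], results["ref"], results["truth"] = matrix, ref, truth

    @stage("preprocess")
    def _preprocess():
        matrix = results["matrix"]
        scores, extreme, g, p = preprocess.sample_pca_outlier_test(matrix)
        linkage_matrix, labels = preprocess.cluster_samples(matrix)
        reports = {}
        for grp in config.comparisons:
            samples = matrix.samples_in_group(grp) + matrix.samples_in_group("CTL")
            reports[grp] = preprocess.filter_report(matrix, samples, config.filter_params)
        results["filters"] = reports
        payload = {
            "pca_outlier": {"sample": extreme, "G": g, "p": p},
            "filter_counts": {g_: r.counts() for g_, r in reports.items()},
        }
        (outdir / "preprocess.json").write_text(json.dumps(payload, indent=1))

    @stage("diffexpr")
    def _diffexpr():
        matrix = results["matrix"]
        de_tables = {}
        deg_sets = {}
        for grp in config.comparisons:
            retained = results["filters"][grp].retained
            sub = ExpressionMatrix(matrix.data.loc[retained], matrix.groups)
            de, prior = diffexpr.fit_moderated_t(
                sub, matrix.samples_in_group(grp), matrix.samples_in_group("CTL")
            )
            de_tables[grp] = de
            up, down = diffexpr.call_degs(de, config.deg_criteria, "lenient")
            deg_sets[grp] = {"up": up, "down": down}
            diffexpr.write_de_tsv(de, outdir / f"de_{grp.lower()}.tsv")
        results["de"] = de_tables
        results["degs"] = deg_sets
        arrows = diffexpr.pc_treatment_vectors(matrix)
        summary = {
            "deg_counts": {
                g_: {"up": len(s["up"]), "down": len(s["down"])} for g_, s in deg_sets.items()
            },
            "arrow_lengths": {g_: a["length"] for g_, a in arrows.items()},
        }
        if len(config.comparisons) >= 2:
            pairs = {}
            comps = list(config.comparisons)
            for i in range(len(comps)):
                for j in range(i + 1, len(comps)):
                    r, p = diffexpr.fc_scatter_stats(de_tables[comps[i]], de_tables[comps[j]])
                    pairs[f"{comps[i]}:{comps[j]}"] = {"spearman_r": r, "p": p}
            summary["fc_correlations"] = pairs
        (outdir / "diffexpr_summary.json").write_text(json.dumps(summary, indent=1))

    @stage("comod")
    def _comod():
        z, _ = comod.standardize_reference(results["ref"])
        module_set = comod.detect_modules(z, config.module_params)
        rng = np.random.default_rng([config.seed, 10])
        go_counts = {g_: int(c) for g_, c in zip(z.index, rng.poisson(5, size=len(z)))}
        comod.label_modules(module_set, go_counts)
        comod.module_medoids(z, module_set)
        module_set.to_json(outdir / "modules.json")
        results["modules"] = module_set
        dem_tables = {}
        for grp in config.comparisons:
            dem = comod.dem_test(results["de"][grp], module_set)
            dem.to_csv(outdir / f"dem_{grp.lower()}.tsv", sep="\t")
            dem_tables[grp] = dem
        results["dem"] = dem_tables

    @stage("setstats")
    def _setstats():
        truth: GroundTruth = results["truth"]
        universe = list(results["matrix"].genes)
        sigs = []
        for grp, direction, n_members, conc in (
            ("IDMF", "up", 80, 0.7),
            ("IDMF", "down", 80, 0.7),
            ("MMF", "up", 60, 0.5),
        ):
            try:
                sigs.append(
                    simulate_signature(
                        truth, grp, direction, n_members, conc, universe,
                        seed=config.seed, name=f"{grp}_{direction.upper()}",
                    )
                )
            except ValueError:
                pass  # too few planted genes under this configuration
        sigs.extend(load_builtin_signatures().values())
        write_gmt(sigs, outdir / "signatures.gmt", seed=config.seed)
        rows = []
        for grp in config.comparisons:
            de = results["de"][grp]
            for sig in sigs:
                try:
                    d = setstats.direction_fisher(de, sig)
                    a = setstats.cumulative_overlap_area(de, sig)
                except ValueError:
                    continue
                rows.append(
                    {
                        "comparison": grp,
                        "signature": sig.name,
                        "n_expressed": d.n_expressed,
                        "frac_up": d.frac_up,
                        "fisher_p": d.fisher_p,
                        "area": a.area,
                        "area_p": a.wilcoxon_p,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "signature_stats.tsv", sep="\t", index=False)

        sources = simulate_disease_sources(universe, seed=config.seed)
        table = setstats.aggregate_disease_sources(sources)
        table.to_csv(outdir / "disease_genes.tsv", sep="\t")
        ms4 = list(table.index[table["tier"] >= 4])
        null_rows = []
        for grp in config.comparisons:
            de = results["de"][grp]
            try:
                obs, _, p = setstats.random_set_fc_null(
                    de, ms4, n_trials=config.fc_null_trials, seed=config.seed
                )
            except ValueError:
                continue
            null_rows.append({"comparison": grp, "observed_mean_absfc": obs, "p": p})
        pd.DataFrame(null_rows).to_csv(outdir / "disease_fc_null.tsv", sep="\t", index=False)
        results["disease_table"] = table

    @stage("gwasprox")
    def _gwasprox():
        universe = list(results["matrix"].genes)
        tops = {
            grp: list(
                results["de"][grp]["log2fc"]
                .sort_values(ascending=False)
                .index[: config.proximity.top_n]
            )
            for grp in config.comparisons
        }
        # plant half the strongest up-regulated genes of the last comparison
        # (the IDMF-like group) near loci so the proximity signal is real
        planted = tops[config.comparisons[-1]]
        genes_bed, loci_bed, _ = simulate_genome_and_loci(
            len(universe),
            config.n_loci,
            planted_fraction=0.5,
            seed=config.seed,
            designated=planted,
        )
        locus_map = gwasprox.LocusMap.from_bed(genes_bed, loci_bed)
        prox = dataclasses.replace(config.proximity, seed=config.seed)
        out = {}
        for grp in config.comparisons:
            de = results["de"][grp]
            top = tops[grp]
            scan = gwasprox.window_overlap_scan(top, universe, locus_map, prox)
            null = gwasprox.mean_distance_null(top, universe, locus_map, prox)
            out[grp] = {
                "windows": scan.reset_index().to_dict(orient="records"),
                "mean_distance": {
                    "observed": null["observed_mean"],
                    "p": null["p"],
                    "n_infinite": null["n_infinite"],
                },
            }
        (outdir / "gwas_proximity.json").write_text(json.dumps(out, indent=1))
        results["gwas"] = out

    @stage("motifscan")
    def _motifscan():
        pwms = [motifscan.PWM.from_record(r) for r in synthetic_irf_pwms(config.n_irf_pwms, config.seed)]
        universe = list(results["matrix"].genes)[: config.promoter_genes]
        down = [g for g in results["degs"]["IDMF"]["down"] if g in set(universe)]
        promoters, _ = simulate_promoters(
            universe,
            pwms[0],
            plant_in=down,
            length=config.promoter_length,
            seed=config.seed,
        )
        deg_sets = {
            f"{grp}_{d}": [g for g in results["degs"][grp][d] if g in set(universe)]
            for grp in config.comparisons
            for d in ("up", "down")
        }
        deg_sets = {k: v for k, v in deg_sets.items() if len(v) >= 20}
        if deg_sets:
            table, hists = motifscan.irf_profile(deg_sets, pwms, promoters)
            table.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
            results["motifs"] = table

    @stage("summary")
    def _summary():
        rows = []
        for grp in config.comparisons:
            degs = results["degs"][grp]
            dem = results["dem"][grp]
            row = {
                "comparison": grp,
                "degs_up": len(degs["up"]),
                "degs_down": len(degs["down"]),
                "dems": int(dem["significant"].sum()) if len(dem) else 0,
                "gwas_mean_distance_p": results["gwas"][grp]["mean_distance"]["p"],
            }
            motifs = results.get("motifs")
            if motifs is not None:
                sub = motifs[motifs["deg_set"].str.startswith(grp)]
                row["top_motif"] = sub.iloc[0]["pwm"] if len(sub) else ""
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "summary_table.tsv", sep="\t", index=False)

    for f in sorted(outdir.iterdir()):
        if f.is_file():
            manifest["checksums"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
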
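"""End-to-end orchestration of the analysis stages from a single config.

A run config (YAML or dict) names the stages to execute, a global seed and an
output directory, plus optional per-stage parameter blocks. Stages execute in
the fixed order

    simulate -> qc -> de -> vuln -> converge -> xspecies -> annotate
    -> saturate -> pheno

and each stage reads its inputs from the shared run directory, so a subset of
stages can be re-run against existing outputs. The global seed is expanded
into independent per-stage substreams, and a JSON manifest records per stage
the parameters, seed and SHA256 of every file written, so reruns with the
same config are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import convergence, detest, io, phenoscores, preprocess, saturation, synthgen, vulnmodel, xspecies

logger = logging.getLogger("vulnscan")

STAGE_ORDER = [
    "simulate",
    "qc",
    "de",
    "vuln",
    "converge",
    "xspecies",
    "annotate",
    "saturate",
    "pheno",
]
_KNOWN_TOP_KEYS = {"stages", "seed", "outdir", "control", "params"}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    """Check structure, stage order and per-stage parameter blocks."""
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages")
    if not stages:
        raise ConfigError("config must name at least one stage")
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    order = [STAGE_ORDER.index(s) for s in stages]
    if order != sorted(order) or len(set(order)) != len(order):
        raise ConfigError(f"stages must follow the order {STAGE_ORDER}")
    if "outdir" not in config:
        raise ConfigError("config must set outdir")
    params = config.get("params", {}) or {}
    unknown_blocks = set(params) - set(STAGE_ORDER)
    if unknown_blocks:
        raise ConfigError(f"parameter blocks for unknown stages: {sorted(unknown_blocks)}")
    control = config.get("control", synthgen.CONTROL)
    sim = params.get("simulate", {}) or {}
    if "simulate" in stages and sim.get("control", control) != synthgen.CONTROL:
        raise ConfigError(
            f"the generator always names its control genotype {synthgen.CONTROL!r}; "
            "downstream contrasts require it"
        )
    return config


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGE_ORDER))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGE_ORDER, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, dry_run: bool = False) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config = validate_config(config)
    outdir = Path(config["outdir"])
    stages = config["stages"]
    params = config.get("params", {}) or {}
    seed = int(config.get("seed", 0))
    control = config.get("control", synthgen.CONTROL)
    seeds = _stage_seeds(seed)
    if dry_run:
        return {"stages": stages, "seed": seed, "outdir": str(outdir), "dry_run": True}

    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "outdir": str(outdir), "stages": {}}
    for stage in stages:
        stage_params = dict(params.get(stage, {}) or {})
        logger.info("stage %s: params=%s seed=%d", stage, stage_params, seeds[stage])
        try:
            outputs = _STAGE_FUNCS[stage](outdir, stage_params, seeds[stage], control)
        except Exception:
            logger.exception("stage %s failed; partial outputs preserved in %s", stage, outdir)
            raise
        manifest["stages"][stage] = {
            "params": stage_params,
            "seed": seeds[stage],
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------- stages


def _stage_simulate(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    planted_human_overlap = params.pop("planted_human_overlap", 0.3)
    noise_sd = params.pop("panel_noise_sd", 0.1)
    cfg = synthgen.CohortConfig(**{**params, "seed": params.get("seed", seed)})
    adata, truth = synthgen.generate_cohort(cfg)
    cohort_dir = outdir / "cohort"
    io.write_cohort(adata, cohort_dir)
    io.write_json(truth.to_dict(), outdir / "truth.json")

    panel = synthgen.generate_bulk_references(adata, noise_sd=noise_sd, seed=seed + 1)
    io.write_panel(panel, outdir / "panel.tsv")

    human_genes = [f"HS{i:05d}" for i in range(cfg.n_genes)]
    omap = synthgen.generate_ortholog_map(
        list(adata.var_names), human_genes, score_range=(1, 15), seed=seed + 2
    )
    io.write_ortholog_map(omap, outdir / "orthologs.tsv")

    # Synthetic "human DEG" list: high-score orthologues of a fraction of the
    # planted shared genes, topped up with random human genes.
    rng = np.random.default_rng(seed + 3)
    shared = truth.shared_up + truth.shared_down
    mapped, _ = xspecies.map_orthologs(shared, omap, min_score=5)
    n_keep = int(round(planted_human_overlap * len(mapped)))
    human_deg = list(dict.fromkeys(mapped))[:n_keep]
    n_extra = max(0, 3 * len(human_deg))
    extras = [g for g in rng.permutation(human_genes)[: n_extra + len(human_deg)] if g not in human_deg]
    human_deg = human_deg + extras[:n_extra]
    pd.DataFrame({"human_gene": human_deg}).to_csv(outdir / "human_deg.tsv", sep="\t", index=False)

    return [
        cohort_dir / "matrix.mtx",
        cohort_dir / "cells.tsv",
        cohort_dir / "genes.tsv",
        outdir / "truth.json",
        outdir / "panel.tsv",
        outdir / "orthologs.tsv",
        outdir / "human_deg.tsv",
    ]


def _stage_qc(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    if "thresholds" in params:
        thresholds = preprocess.QCThresholds(**params["thresholds"])
    else:
        thresholds = preprocess.PRESETS[params.get("preset", "fly")]
    adata = io.read_cohort(outdir / "cohort")
    filtered, report = preprocess.filter_cells(adata, thresholds)
    io.write_cohort(filtered, outdir / "filtered")
    io.write_json(report.to_dict(), outdir / "qc_report.json")
    return [
        outdir / "filtered" / "matrix.mtx",
        outdir / "filtered" / "cells.tsv",
        outdir / "filtered" / "genes.tsv",
        outdir / "qc_report.json",
    ]


def _load_filtered(outdir: Path):
    src = outdir / "filtered" if (outdir / "filtered").exists() else outdir / "cohort"
    return io.read_cohort(src)


def _stage_de(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    route = params.get("route", "ranksum")
    alpha = params.get("alpha", 0.05)
    adata = _load_filtered(outdir)
    adata = preprocess.log_normalize(adata)
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    genotypes = [g for g in sorted(adata.obs["genotype"].unique()) if g != control]
    if control not in set(adata.obs["genotype"]):
        raise ConfigError(f"control genotype {control!r} absent from the cohort")
    outputs = []
    ndeg_rows = []
    for mutant in genotypes:
        for cluster in sorted(adata.obs["cluster"].astype(str).unique()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", detest.ClusterSkippedWarning)
                if route == "pseudobulk":
                    pbs = detest.make_pseudobulks(adata, cluster)
                    table = detest.pseudobulk_de(pbs, mutant, control)
                else:
                    table = detest.ranksum_de(adata, cluster, mutant, control)
            if table is None:
                continue
            path = de_dir / f"{mutant}_cluster{cluster}.tsv"
            io.write_de_table(table, path)
            outputs.append(path)
            mask = (adata.obs["cluster"].astype(str) == cluster).to_numpy()
            ndeg_rows.append(
                {
                    "genotype": mutant,
                    "cluster": cluster,
                    "ndeg": detest.count_deg(table, alpha=alpha),
                    "x1": int((mask & (adata.obs["genotype"] == mutant).to_numpy()).sum()),
                    "x2": int((mask & (adata.obs["genotype"] == control).to_numpy()).sum()),
                }
            )
    ndeg = pd.DataFrame(ndeg_rows)
    ndeg.to_csv(outdir / "ndeg.tsv", sep="\t", index=False)
    outputs.append(outdir / "ndeg.tsv")
    return outputs


def _stage_vuln(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    top_k = params.get("top_k", 8)
    ndeg = pd.read_csv(outdir / "ndeg.tsv", sep="\t", dtype={"cluster": str})
    residuals = {}
    fits = {}
    for genotype, grp in ndeg.groupby("genotype"):
        stats = [
            vulnmodel.ClusterStats(cluster=row.cluster, y=int(row.ndeg), x1=int(row.x1), x2=int(row.x2))
            for row in grp.itertuples()
        ]
        fit = vulnmodel.fit_nb_model(stats)
        fits[genotype] = vars(fit)
        residuals[genotype] = vulnmodel.cluster_residuals(fit, stats)
    resid_table = pd.concat(
        [df.assign(genotype=g) for g, df in residuals.items()], ignore_index=True
    )
    resid_table.to_csv(outdir / "residuals.tsv", sep="\t", index=False)
    consensus = vulnmodel.rank_vulnerable(residuals, top_k=top_k)
    consensus.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    io.write_json(fits, outdir / "nb_fits.json")
    return [outdir / "residuals.tsv", outdir / "consensus.tsv", outdir / "nb_fits.json"]


def _stage_converge(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    tail = params.get("tail_fraction", 0.05)
    consensus = pd.read_csv(outdir / "consensus.tsv", sep="\t", dtype={"cluster": str})
    affected = consensus.loc[consensus.get("top", True) == True, "cluster"].tolist()  # noqa: E712
    adata = _load_filtered(outdir)
    adata = preprocess.log_normalize(adata)
    # Pool the affected clusters into one merged contrast per genotype.
    merged = adata[adata.obs["cluster"].astype(str).isin(affected)].copy()
    merged.obs["cluster"] = "affected"
    tables = {}
    for mutant in sorted(set(merged.obs["genotype"]) - {control}):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", detest.ClusterSkippedWarning)
            t = detest.ranksum_de(merged, "affected", mutant, control)
        if t is not None:
            tables[mutant] = t
    result = convergence.converge(tables, tail_fraction=tail)
    pd.DataFrame({"gene": result.common_up}).to_csv(outdir / "common_up.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": result.common_down}).to_csv(outdir / "common_down.tsv", sep="\t", index=False)
    result.summed.rename_axis("gene").reset_index().to_csv(
        outdir / "summed_ranks.tsv", sep="\t", index=False
    )
    return [outdir / "common_up.tsv", outdir / "common_down.tsv", outdir / "summed_ranks.tsv"]


def _stage_xspecies(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    min_score = params.get("min_score", 5)
    omap = io.read_ortholog_map(outdir / "orthologs.tsv")
    up = pd.read_csv(outdir / "common_up.tsv", sep="\t")["gene"].tolist()
    down = pd.read_csv(outdir / "common_down.tsv", sep="\t")["gene"].tolist()
    human_deg = pd.read_csv(outdir / "human_deg.tsv", sep="\t")["human_gene"].tolist()
    fly_tails_mapped, unmapped = xspecies.map_orthologs(up + down, omap, min_score=min_score)
    mappable_all, _ = xspecies.map_orthologs(sorted(set(omap["fly_gene"])), omap, min_score=min_score)
    universe = sorted(set(mappable_all) | set(human_deg))
    human_in_universe = [g for g in human_deg if g in set(universe)]
    result = xspecies.overlap_stats(set(human_in_universe), set(fly_tails_mapped), universe)
    io.write_json(
        {
            "n_fly_tail_genes": len(up + down),
            "n_unmapped": unmapped,
            "universe": result.N,
            "overlap": vars(result),
        },
        outdir / "overlap.json",
    )
    return [outdir / "overlap.json"]


def _stage_annotate(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    penalty = params.get("penalty", 0.01)
    threshold = params.get("threshold", 0.1)
    adata = _load_filtered(outdir)
    profiles = annotate_mod.cluster_profiles(adata)
    panel = io.read_panel(outdir / "panel.tsv")
    table = annotate_mod.annotate_clusters(
        profiles, panel, penalty=penalty, threshold=threshold, seed=seed
    )
    table.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return [outdir / "annotations.tsv"]


def _stage_saturate(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    adata = _load_filtered(outdir)
    labels = adata.obs["cluster"].astype(str).tolist()
    step = params.get("step", max(1, len(labels) // 50))
    reps = params.get("reps", 50)
    thresholds = params.get("thresholds", [1, 5, 10])
    max_n = params.get("max_n", len(labels))
    frames = []
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for thr in thresholds:
            curve = saturation.subsample_curve(
                labels, max_n=max_n, step=step, reps=reps, threshold=thr, seed=seed
            )
            frames.append(curve.to_frame().assign(threshold=thr))
            fit = saturation.fit_michaelis_menten(curve)
            fits[str(thr)] = vars(fit)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "saturation.tsv", sep="\t", index=False)
    io.write_json(fits, outdir / "mm_fits.json")
    return [outdir / "saturation.tsv", outdir / "mm_fits.json"]


def _stage_pheno(outdir: Path, params: dict, seed: int, control: str) -> list[Path]:
    traces, truth = synthgen.generate_traces(
        n_rois=params.get("n_rois", 5),
        frame_rate=params.get("frame_rate", 5.0),
        n_frames=params.get("n_frames", 300),
        baseline=params.get("baseline", 10.0),
        spike_times=params.get("spike_times", [100, 150, 200]),
        spike_amp=params.get("spike_amp", 5.0),
        noise_sd=params.get("noise_sd", 0.05),
        seed=seed,
        stimulus_frame=params.get("stimulus_frame", 50),
    )
    dff = phenoscores.dff_trace(traces, baseline_mode="prestim_mean5")
    fraction, amplitude = phenoscores.activity_metrics(dff, baseline_frames=np.arange(0, 50))
    sing = phenoscores.sing_score(phenoscores.TubeCounts(tuple(params.get("tubes", (2, 2, 2, 2, 2)))))
    pref = phenoscores.preference_index(
        params.get("n_a", 30), params.get("n_b", 20), params.get("n_total", 50)
    )
    io.write_json(
        {
            "sing_score": sing,
            "preference_index": pref,
            "nicotine_dose_ug_per_mg_day": phenoscores.nicotine_dose(),
            "activity_fraction": fraction,
            "max_amplitude": amplitude,
            "planted_active_fraction": truth["active_fraction"],
        },
        outdir / "pheno.json",
    )
    return [outdir / "pheno.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "de": _stage_de,
    "vuln": _stage_vuln,
    "converge": _stage_converge,
    "xspecies": _stage_xspecies,
    "annotate": _stage_annotate,
    "saturate": _stage_saturate,
    "pheno": _stage_pheno,
}
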
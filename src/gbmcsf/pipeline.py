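"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the single-cell arm (simulate -> QC -> scoring ->
states -> differential expression -> GSEA) and the two parallel assay arms
(plate cytotoxicity, MEA spike metrics) from a single YAML-style config,
communicating between stages through files so each stage is independently
re-runnable from its inputs.  A run manifest (software version, config
hash, per-file checksums, seeds, timestamps) is written last; re-running
with the same config and seed reproduces identical output checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assays, de, gsea, io, mea, qc, scoring, simulate, states
from .genesets import write_gmt

__all__ = ["default_config", "load_config", "run_pipeline"]

log = logging.getLogger("gbmcsf")


def default_config() -> dict:
    """The default run configuration; every stage constant is reachable here."""
    return {
        "seed": 0,
        "sc": {
            "sim": {},  # ScSimConfig overrides
            "qc": {
                "min_genes_per_cell": 200,
                "min_cells_per_gene": 3,
                "max_reads": 55_000,
                "max_reads_overrides": {},
                # panel-scaled low-complexity floor for the 2,000-gene
                # simulated panel (the whole-transcriptome default is 2,000)
                "min_genes_outlier": 1_000,
                "min_genes_overrides": {},
                "min_housekeeping": 70,
                "housekeeping_list_size": 98,
                "max_mito_fraction": 0.20,
                "keep_flagged": False,
            },
            "scoring": {
                "scale_factor": 10_000.0,
                "n_hvg": 2_000,
                "n_bins": 24,
                "n_ctrl": 100,
                "cycling_mode": "average",
            },
            "states": {"mode": "corrected"},
            "de": {"quota": 700, "top_k": 20},
            "gsea": {"n_perm": 1_000, "weight": 1.0},
        },
        "assays": {
            "sim": {},  # PlateSimConfig overrides
            "cutpoints": [50.0, 90.0],
        },
        "mea": {
            "sim": {},  # SpikeSimConfig overrides
            "active_min_rate": 5.0,
            "burst": {"min_spikes": 5, "max_isi": 0.100},
            "network": {"min_spikes": 50, "max_isi": 0.080},
            "population_window": 0.5,
        },
    }


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in ref:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(ref[key], dict) and key not in ("sim", "max_reads_overrides", "min_genes_overrides"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            _check_keys(val, ref[key], path=f"{path}{key}.")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a config, merging onto the defaults.  Unknown keys
    are rejected; ``sim`` blocks are validated by their config dataclasses."""
    cfg = default_config()
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge(user, overrides)
    _check_keys(user, cfg)
    cfg = _merge(cfg, user)
    # sim blocks: unknown keys rejected by the dataclass constructors
    simulate.config_from_dict(simulate.ScSimConfig, cfg["sc"]["sim"])
    simulate.config_from_dict(simulate.PlateSimConfig, cfg["assays"]["sim"])
    simulate.config_from_dict(simulate.SpikeSimConfig, cfg["mea"]["sim"])
    return cfg


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _run_sc_arm(cfg: dict, outdir: Path, seed: int, report: dict) -> None:
    t0 = time.time()
    sc_cfg = cfg["sc"]
    sim_cfg = simulate.config_from_dict(simulate.ScSimConfig, sc_cfg["sim"])
    sim_cfg.seed = seed
    adata, truth = simulate.simulate_sc_dataset(sim_cfg)
    simdir = outdir / "sc" / "simulated"
    io.write_sc_dataset(adata, simdir)
    simulate.save_ground_truth(truth, simdir / "ground_truth.json")
    gsc = simulate.program_gene_sets(sim_cfg)
    write_gmt(gsc, outdir / "sc" / "gene_sets.gmt")
    log.info("sc/simulate done (%.1fs)", time.time() - t0)

    # QC
    qc_keys = {k: v for k, v in sc_cfg["qc"].items() if k != "keep_flagged"}
    thresholds = qc.QCThresholds(**qc_keys)
    qc.annotate_qc_metrics(adata)
    filtered = qc.prefilter(adata, thresholds)
    qc.annotate_qc_metrics(filtered)
    flags = qc.flag_outliers(filtered, thresholds)
    if not sc_cfg["qc"]["keep_flagged"]:
        filtered = filtered[~flags["outlier"].to_numpy()].copy()
    balanced = qc.balance_conditions(filtered, seed=seed + 1)
    report_qc = qc.qc_report(adata, balanced, flags=None)
    report_qc.to_csv(outdir / "sc" / "qc_report.tsv", sep="\t", index=False)
    io.write_sc_dataset(balanced, outdir / "sc" / "filtered")
    log.info("sc/qc done: %d -> %d cells", adata.n_obs, balanced.n_obs)

    # scoring
    sco = sc_cfg["scoring"]
    scoring.log_normalize(balanced, scale_factor=sco["scale_factor"])
    hvg = scoring.select_hvg(balanced, n=min(sco["n_hvg"], balanced.n_vars))
    pd.Series(hvg, name="gene").to_csv(outdir / "sc" / "hvg.tsv", sep="\t", index=False)
    score_tbl = states.meta_module_scores(
        balanced, gsc, n_bins=sco["n_bins"], n_ctrl=sco["n_ctrl"], seed=seed + 2
    )
    for i, name in enumerate(("G1S", "G2M", "quiescence")):
        score_tbl[name] = scoring.module_score(
            balanced, gsc[name], n_bins=sco["n_bins"], n_ctrl=sco["n_ctrl"],
            seed=seed + 10 + i,
        )
    labels = scoring.cycle_labels(score_tbl, mode=sco["cycling_mode"])
    score_tbl = score_tbl.join(labels)
    score_tbl.to_csv(outdir / "sc" / "scores.tsv", sep="\t")

    # states
    sa = states.project_2d(score_tbl, mode=sc_cfg["states"]["mode"])
    sa.table.to_csv(outdir / "sc" / "state_assignment.tsv", sep="\t")
    comp = states.composition(sa, balanced.obs)
    comp.to_csv(outdir / "sc" / "state_composition.tsv", sep="\t", index=False)

    # planted-effect recovery summary
    cond = balanced.obs["condition"].astype(str).to_numpy()
    mes_csf = score_tbl.loc[cond == "CSF", "MES"]
    mes_gm = score_tbl.loc[cond == "GM", "MES"]
    from scipy import stats as sps

    mw = sps.mannwhitneyu(mes_csf, mes_gm, alternative="greater")
    q_frac = (
        score_tbl.join(balanced.obs[["condition"]])
        .groupby("condition", observed=True)["quiescent"]
        .apply(lambda s: float((s == "Quiescent").mean()))
    )
    report["sc"] = {
        "n_cells_final": int(balanced.n_obs),
        "mes_score_shift": float(mes_csf.mean() - mes_gm.mean()),
        "mes_shift_p_one_sided": float(mw.pvalue),
        "quiescent_fraction": {k: float(v) for k, v in q_frac.items()},
    }

    # differential expression + GSEA
    de_cfg = sc_cfg["de"]
    quota = min(
        de_cfg["quota"],
        int(
            balanced.obs.groupby(["line", "condition"], observed=True)
            .size()
            .min()
        ),
    )
    down = de.downsample_balanced(balanced, per_cell_quota=quota, seed=seed + 3)
    det = de.wilcoxon_de(down)
    det.to_csv(outdir / "sc" / "de_table.tsv", sep="\t")
    up, dn = de.rank_and_topk(det, k=de_cfg["top_k"])
    pd.DataFrame({"up_in_csf": up, "up_in_gm": dn}).to_csv(
        outdir / "sc" / "top_genes.tsv", sep="\t", index=False
    )
    de.write_rnk(det, outdir / "sc" / "ranks.rnk")
    rl = gsea.read_rnk(outdir / "sc" / "ranks.rnk")
    test_sets = gsc.subset(
        [n for n in ("MES", "MES1", "MES2", "G1S", "G2M", "quiescence") if n in gsc]
    )
    gsea_cfg = sc_cfg["gsea"]
    res = gsea.gsea_collection(
        rl, test_sets, n_perm=gsea_cfg["n_perm"], seed=seed + 4,
        weight=gsea_cfg["weight"],
    )
    res.to_csv(outdir / "sc" / "gsea_results.tsv", sep="\t")
    planted = [g for g, fc in sim_cfg.planted_de if fc > 0]
    report["sc"].update(
        {
            "downsampled_cells": int(down.n_obs),
            "planted_up_gene_in_csf_topk": bool(any(g in up for g in planted)),
            "gsea_p": {name: float(res.loc[name, "p_perm"]) for name in res.index},
        }
    )
    log.info("sc arm done (%.1fs)", time.time() - t0)


def _run_assay_arm(cfg: dict, outdir: Path, seed: int, report: dict) -> None:
    plate_cfg = simulate.config_from_dict(simulate.PlateSimConfig, cfg["assays"]["sim"])
    plate_cfg.seed = seed + 20
    plate, truth = simulate.simulate_plate(plate_cfg)
    adir = outdir / "assays"
    adir.mkdir(parents=True, exist_ok=True)
    plate.to_csv(adir / "plate.csv", index=False)
    simulate.save_ground_truth(truth, adir / "ground_truth.json")
    vr = assays.viability(plate)
    vr.to_csv(adir / "viability.csv", index=False)
    means = assays.mean_viability(vr)
    groups = assays.stratify(means, cutpoints=tuple(cfg["assays"]["cutpoints"]))
    groups.to_csv(adir / "groups.tsv", sep="\t", index=False)
    fits = {}
    for line, grp in vr.groupby("line", observed=True):
        prof = grp.groupby("dose", observed=True)["viability"].mean()
        fit = assays.fit_4pl(prof.index.to_numpy(), prof.to_numpy())
        fits[line] = fit
    fit_tbl = pd.DataFrame(
        {
            "line": list(fits),
            "ic50": [f.ic50 for f in fits.values()],
            "hill": [f.hill for f in fits.values()],
            "top": [f.top for f in fits.values()],
            "bottom": [f.bottom for f in fits.values()],
            "reliable": [f.reliable for f in fits.values()],
        }
    )
    fit_tbl.to_csv(adir / "dose_response_fits.tsv", sep="\t", index=False)
    rel_err = [
        abs(f.ic50 - truth["true_ic50"][line]) / truth["true_ic50"][line]
        for line, f in fits.items()
        if f.reliable
    ]
    report["assays"] = {
        "n_lines": len(fits),
        "median_ic50_rel_error": float(np.median(rel_err)) if rel_err else None,
        "groups": {g: int((groups["group"] == g).sum()) for g in assays.GROUP_LABELS},
    }


def _run_mea_arm(cfg: dict, outdir: Path, seed: int, report: dict) -> None:
    spike_cfg = simulate.config_from_dict(simulate.SpikeSimConfig, cfg["mea"]["sim"])
    spike_cfg.seed = seed + 30
    sd, truth = simulate.simulate_spike_trains(spike_cfg)
    mdir = outdir / "mea"
    mdir.mkdir(parents=True, exist_ok=True)
    sd.to_frame().to_csv(mdir / "spikes.csv", index=False)
    simulate.save_ground_truth(truth, mdir / "ground_truth.json")
    active = mea.filter_active(sd, min_rate_per_min=cfg["mea"]["active_min_rate"])
    b_cfg, n_cfg = cfg["mea"]["burst"], cfg["mea"]["network"]
    bursts = mea.detect_bursts(active, min_spikes=b_cfg["min_spikes"], max_isi=b_cfg["max_isi"])
    events = mea.detect_network_events(
        active, min_spikes=n_cfg["min_spikes"], max_isi=n_cfg["max_isi"]
    )
    burst_rows = [
        {"neuron": n, "start": e.start, "end": e.end, "n_spikes": e.n_spikes}
        for n, evs in bursts.items()
        for e in evs
    ]
    pd.DataFrame(burst_rows, columns=["neuron", "start", "end", "n_spikes"]).to_csv(
        mdir / "bursts.tsv", sep="\t", index=False
    )
    ev_rows = [
        {
            "well": w,
            "start": e.start,
            "end": e.end,
            "n_spikes": e.n_spikes,
            "n_neurons": len(e.neurons),
        }
        for w, evs in events.items()
        for e in evs
    ]
    pd.DataFrame(
        ev_rows, columns=["well", "start", "end", "n_spikes", "n_neurons"]
    ).to_csv(mdir / "network_events.tsv", sep="\t", index=False)
    times, pv = mea.population_vector(active if active.trains else sd, window=cfg["mea"]["population_window"])
    np.savetxt(mdir / "population_vector.tsv", np.column_stack([times, pv]),
               delimiter="\t", header="time\tactivity", comments="")
    report["mea"] = {
        "n_neurons_active": len(active.trains),
        "n_bursts": sum(len(v) for v in bursts.values()),
        "n_network_events": sum(len(v) for v in events.values()),
    }


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run every arm; returns the manifest dict (also written to
    ``manifest.json``).  A failure in one arm is recorded and does not
    corrupt the others; if any arm failed the manifest carries
    ``"failed_arms"`` and the caller should exit nonzero."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "sc").mkdir(exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {}
    failed: dict[str, str] = {}
    for name, fn in (("sc", _run_sc_arm), ("assays", _run_assay_arm), ("mea", _run_mea_arm)):
        try:
            fn(cfg, outdir, seed, report)
        except Exception as err:  # halt the arm, keep the others
            log.error("arm %s failed: %s", name, err)
            failed[name] = str(err)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": checksums,
        "failed_arms": failed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
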
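"""Synthetic-data generators for every pipeline input.

Three generators emulate the study design the analysis assumes:

* :func:`simulate_sc_dataset` — a multi-patient, two-condition (GM vs CSF)
  single-cell count matrix with plantable transcriptional-program shifts,
  planted differentially expressed genes, and planted QC outliers.  Counts
  follow a gamma-Poisson (negative binomial) model with lognormal library
  sizes — the minimal noise model that exercises QC, normalization and
  control-bin module scoring.
* :func:`simulate_plate` — nuclei counts for a treated plate generated from
  a known four-parameter logistic (4PL) dose-response curve with paired
  vehicle-control wells.
* :func:`simulate_spike_trains` — per-neuron spike timestamp trains:
  background Poisson firing plus planted bursts and planted multi-neuron
  network events.

Every generator takes an explicit seed and returns its ground truth
alongside the data, so recovery tests never need to re-derive what was
planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .genesets import GeneSetCollection
from .mea import SpikeData

__all__ = [
    "ScSimConfig",
    "PlateSimConfig",
    "SpikeSimConfig",
    "simulate_sc_dataset",
    "simulate_plate",
    "simulate_spike_trains",
    "program_gene_sets",
]

#: default program sizes; MES is scored from MES1 + MES2 combined (n=100)
DEFAULT_PROGRAM_SIZES = {
    "AC": 50,
    "MES1": 50,
    "MES2": 50,
    "NPC": 50,
    "OPC": 50,
    "G1S": 43,
    "G2M": 54,
    "quiescence": 100,
}

#: CSF shifts (log2 program activity) defining the default planted effects:
#: mesenchymal and quiescence programs up, cell-cycle programs down.
DEFAULT_CSF_EFFECTS = {"MES": 1.0, "quiescence": 0.5, "G1S": -0.5, "G2M": -0.5}

#: planted per-gene effects: (gene symbol, log2 fold change in CSF).  The
#: NUPR1-like stress-response gene is the strongest planted up-regulation.
DEFAULT_PLANTED_DE = [("NUPR1", 1.5), ("CSF_UP1", 1.0), ("GM_UP1", -1.0)]


@dataclass
class ScSimConfig:
    """Configuration of the single-cell count simulator."""

    n_patients: int = 10
    n_cells_per_condition: int = 800
    n_genes: int = 2000
    program_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_SIZES)
    )
    #: natural-log range of per-gene baseline relative rates
    baseline_log_mean_range: tuple[float, float] = (-1.0, 2.2)
    #: negative-binomial size parameter (shared or per gene); var = m + m^2/disp
    dispersion: float = 2.0
    #: (mu, sigma) of the natural-log library size
    library_size_lognormal: tuple[float, float] = (9.2, 0.35)
    mito_gene_count: int = 13
    housekeeping_gene_count: int = 98
    csf_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CSF_EFFECTS)
    )
    planted_de: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED_DE)
    )
    outlier_fraction: float = 0.02
    #: sd of patient-level program-activity baselines (log2)
    patient_effect_sd: float = 0.15
    #: sd of cell-level program-activity noise (log2)
    cell_noise_sd: float = 0.25
    #: fraction of total rate carried by mitochondrial genes in normal cells
    mito_rate_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_cells_per_condition <= 0 or self.n_genes <= 0:
            raise ValueError("all counts must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(s <= 0 for s in self.program_sizes.values()):
            raise ValueError("program sizes must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        special = (
            sum(self.program_sizes.values())
            + self.mito_gene_count
            + self.housekeeping_gene_count
        )
        if special >= self.n_genes:
            raise ValueError(
                f"program + mito + housekeeping genes ({special}) must leave "
                f"room for background genes within n_genes ({self.n_genes})"
            )
        valid_keys = set(self.program_sizes) | {"MES"}
        bad = set(self.csf_effects) - valid_keys
        if bad:
            raise ValueError(f"csf_effects refer to unknown programs: {sorted(bad)}")


def _gene_names(cfg: ScSimConfig) -> tuple[list[str], dict[str, list[str]], list[str], list[str]]:
    """Assign disjoint gene symbols: program genes, mito, housekeeping,
    background.  Planted DE genes take over leading background slots."""
    programs: dict[str, list[str]] = {}
    names: list[str] = []
    for prog, size in cfg.program_sizes.items():
        genes = [f"{prog}.{i + 1:03d}" for i in range(size)]
        programs[prog] = genes
        names.extend(genes)
    mito = [f"MT-G{i + 1}" for i in range(cfg.mito_gene_count)]
    housekeeping = [f"HK{i + 1:03d}" for i in range(cfg.housekeeping_gene_count)]
    names.extend(mito)
    names.extend(housekeeping)
    n_background = cfg.n_genes - len(names)
    background = [f"BG{i + 1:04d}" for i in range(n_background)]
    planted = [g for g, _ in cfg.planted_de]
    if len(planted) > n_background:
        raise ValueError("more planted DE genes than background gene slots")
    for i, g in enumerate(planted):
        background[i] = g
    names.extend(background)
    return names, programs, mito, housekeeping


def program_gene_sets(cfg: ScSimConfig | None = None) -> GeneSetCollection:
    """Gene sets matching the simulated programs, ready for scoring/GSEA.

    ``MES`` is the 100-gene union of MES1 and MES2, mirroring how the
    combined mesenchymal meta-module relates to its two sub-modules.
    """
    cfg = cfg or ScSimConfig()
    _, programs, _, _ = _gene_names(cfg)
    cat = {
        "AC": "state", "MES": "state", "MES1": "state", "MES2": "state",
        "NPC": "state", "OPC": "state",
        "G1S": "cycle", "G2M": "cycle", "quiescence": "quiescence",
    }
    gsc = GeneSetCollection()
    for prog, genes in programs.items():
        gsc.add(prog, genes, category=cat.get(prog, "custom"))
    if "MES1" in programs and "MES2" in programs and "MES" not in gsc:
        gsc.add("MES", programs["MES1"] + programs["MES2"], category="state")
    return gsc


def _program_effect(cfg: ScSimConfig, prog: str) -> float:
    """Planted CSF log2 activity shift for a program; the ``MES`` key
    applies to both MES1 and MES2 sub-programs."""
    if prog in cfg.csf_effects:
        return cfg.csf_effects[prog]
    if prog in ("MES1", "MES2") and "MES" in cfg.csf_effects:
        return cfg.csf_effects["MES"]
    return 0.0


def simulate_sc_dataset(cfg: ScSimConfig) -> tuple[ad.AnnData, dict]:
    """Simulate a multi-patient GM/CSF single-cell dataset.

    Generative model, per cell ``c`` of patient ``p`` in condition ``k``:

    * program activity  ``A(P,c) = b(P,p) + 1[k = CSF] * e(P) + n(P,c)``
      with patient baseline ``b ~ N(0, patient_effect_sd)``, planted effect
      ``e`` (log2), and cell noise ``n ~ N(0, cell_noise_sd)``;
    * relative rate ``r(g,c) = exp(base_g) * 2**A(P(g),c)`` for program
      genes (``* 2**fc_g`` in CSF for planted DE genes), ``exp(base_g)``
      otherwise;
    * expected counts ``m(g,c) = L_c * r(g,c) / sum_g r(g,c)`` with library
      size ``L_c`` lognormal;
    * counts ``~ Poisson(Gamma(shape=dispersion, mean=m))`` i.e. negative
      binomial with variance ``m + m**2 / dispersion``.

    Planted QC outliers each violate exactly one threshold (reads, genes,
    housekeeping, mito), cycling through the four violation types.

    Returns ``(adata, truth)`` where ``truth`` records every planted effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names, programs, mito, housekeeping = _gene_names(cfg)
    n_genes = cfg.n_genes
    gene_index = {g: i for i, g in enumerate(names)}

    # per-gene baselines (natural log of relative rate)
    lo, hi = cfg.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=n_genes)
    # housekeeping genes sit at the top of the range so normal cells
    # reliably detect >= 70 of the 98 (the QC rule being exercised)
    hk_idx = np.array([gene_index[g] for g in housekeeping])
    base[hk_idx] = rng.uniform(max(hi - 0.7, lo), hi, size=len(hk_idx))
    # planted DE genes are well-expressed (the NUPR1-like stress gene is
    # abundant), so their fold changes are not flattened by the +1
    # pseudocount of the fold-change convention
    for g, _ in cfg.planted_de:
        base[gene_index[g]] = hi - 0.1
    # rescale mitochondrial rates to a fixed fraction of the total so the
    # mito-fraction QC rule has a well-defined normal regime
    mt_idx = np.array([gene_index[g] for g in mito])
    other = np.exp(base).sum() - np.exp(base[mt_idx]).sum()
    target = cfg.mito_rate_fraction / (1.0 - cfg.mito_rate_fraction) * other
    base[mt_idx] += np.log(target / np.exp(base[mt_idx]).sum())

    n_cells = cfg.n_patients * 2 * cfg.n_cells_per_condition
    lines = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    cell_line = np.repeat(lines, 2 * cfg.n_cells_per_condition)
    cond_block = np.repeat(["GM", "CSF"], cfg.n_cells_per_condition)
    cell_cond = np.tile(cond_block, cfg.n_patients)

    # patient-level program baselines
    prog_names = list(cfg.program_sizes)
    patient_base = {
        (line, prog): rng.normal(0.0, cfg.patient_effect_sd)
        for line in lines
        for prog in prog_names
    }

    # log2 rate multipliers, cells x genes
    log2_mult = np.zeros((n_cells, n_genes))
    is_csf = cell_cond == "CSF"
    for prog in prog_names:
        idx = np.array([gene_index[g] for g in programs[prog]])
        pat = np.array([patient_base[(l, prog)] for l in cell_line])
        act = pat + rng.normal(0.0, cfg.cell_noise_sd, size=n_cells)
        act[is_csf] += _program_effect(cfg, prog)
        log2_mult[:, idx] = act[:, None]
    for gene, fc in cfg.planted_de:
        log2_mult[is_csf, gene_index[gene]] += fc

    rate = np.exp(base)[None, :] * np.exp2(log2_mult)
    rate /= rate.sum(axis=1, keepdims=True)
    mu_lib, sd_lib = cfg.library_size_lognormal
    lib = np.exp(rng.normal(mu_lib, sd_lib, size=n_cells))
    mean = rate * lib[:, None]
    lam = rng.gamma(cfg.dispersion, mean / cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    # planted QC outliers: one violation type per outlier cell
    n_out = int(round(cfg.outlier_fraction * n_cells))
    out_cells = rng.choice(n_cells, size=n_out, replace=False) if n_out else np.array([], int)
    out_types = ["reads", "genes", "housekeeping", "mito"]
    outliers: list[tuple[int, str]] = []
    for j, c in enumerate(out_cells):
        kind = out_types[j % 4]
        if kind == "reads":
            # inflate the library beyond the default 55,000-read threshold
            f = int(np.ceil(70_000 / max(counts[c].sum(), 1)))
            counts[c] *= max(f, 2)
        elif kind == "genes":
            # keep ~400 detected genes: above the 200-gene prefilter but
            # below any sensible low-complexity threshold for this panel
            nz = np.flatnonzero(counts[c])
            if len(nz) > 400:
                drop = rng.choice(nz, size=len(nz) - 400, replace=False)
                keep_hk = drop[np.isin(drop, hk_idx)]
                counts[c, drop] = 0
                counts[c, keep_hk] = 1  # keep housekeeping detection intact
        elif kind == "housekeeping":
            drop = rng.choice(hk_idx, size=45, replace=False)
            counts[c, drop] = 0
        else:  # mito
            tot = counts[c].sum()
            mito_tot = counts[c, mt_idx].sum()
            f = int(np.ceil(0.30 * tot / max(mito_tot, 1) / 0.70))
            counts[c, mt_idx] *= max(f, 2)
        outliers.append((int(c), kind))

    obs = pd.DataFrame(
        {"line": pd.Categorical(cell_line), "condition": pd.Categorical(cell_cond)},
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(
        {
            "is_mito": np.isin(np.arange(n_genes), mt_idx),
            "is_housekeeping": np.isin(np.arange(n_genes), hk_idx),
        },
        index=names,
    )
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)

    truth = {
        "programs": {p: list(g) for p, g in programs.items()},
        "mito_genes": mito,
        "housekeeping_genes": housekeeping,
        "csf_effects": dict(cfg.csf_effects),
        "planted_de": [[g, float(fc)] for g, fc in cfg.planted_de],
        "patient_program_baselines": {
            f"{line}:{prog}": float(v) for (line, prog), v in patient_base.items()
        },
        "outliers": [[adata.obs_names[c], kind] for c, kind in outliers],
        "seed": cfg.seed,
    }
    return adata, truth


# ---------------------------------------------------------------------------
# plate simulator


def four_pl(dose, top, bottom, ic50, hill):
    """Four-parameter logistic viability curve (percent of control)."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(top))
    nz = dose > 0
    out[nz] = bottom + (top - bottom) / (1.0 + (dose[nz] / ic50) ** hill)
    return out


@dataclass
class PlateSimConfig:
    """Configuration of the cytotoxicity-plate simulator."""

    n_lines: int = 8
    doses: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0)
    #: true IC50 per line (cycled if shorter than n_lines), in µM
    true_ic50: tuple[float, ...] = (25.0,)
    hill: float = 1.5
    top: float = 100.0
    bottom: float = 5.0
    replicate_cv: float = 0.05
    n_replicates: int = 6
    control_mean: float = 2000.0
    condition: str = "GM"
    treatment: str = "TMZ"
    seed: int = 0

    def validate(self) -> None:
        if not self.doses:
            raise ValueError("dose list is empty")
        d = np.asarray(self.doses, float)
        if (d < 0).any() or (np.diff(d) < 0).any():
            raise ValueError("doses must be non-negative and sorted")
        if not 0 < self.bottom <= self.top:
            raise ValueError("require 0 < bottom <= top")
        if self.n_lines <= 0 or self.n_replicates <= 0:
            raise ValueError("all counts must be positive")


def simulate_plate(cfg: PlateSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate nuclei counts per well from a known 4PL curve.

    Treated wells draw ``control_mean * 4PL(dose)/100 * (1 + noise)`` with
    multiplicative Gaussian noise of CV ``replicate_cv``; dose-0 wells act
    as the paired vehicle controls of their line/condition.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    ic50s = {}
    for i in range(cfg.n_lines):
        line = f"L{i + 1:02d}"
        ic50 = float(cfg.true_ic50[i % len(cfg.true_ic50)])
        ic50s[line] = ic50
        ctrl_group = f"{line}:{cfg.condition}:control"
        for dose in cfg.doses:
            v = four_pl(np.array([dose]), cfg.top, cfg.bottom, ic50, cfg.hill)[0]
            for rep in range(cfg.n_replicates):
                noise = rng.normal(0.0, cfg.replicate_cv) if cfg.replicate_cv else 0.0
                count = cfg.control_mean * v / 100.0 * (1.0 + noise)
                rows.append(
                    {
                        "well": f"{line}-{cfg.condition}-d{dose:g}-r{rep + 1}",
                        "line": line,
                        "condition": cfg.condition,
                        "treatment": cfg.treatment if dose > 0 else "vehicle",
                        "dose": float(dose),
                        "replicate": rep + 1,
                        "nuclei_count": max(float(count), 0.0),
                        "control_group": ctrl_group,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "true_ic50": ic50s,
        "hill": cfg.hill,
        "top": cfg.top,
        "bottom": cfg.bottom,
        "control_mean": cfg.control_mean,
        "seed": cfg.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# spike-train simulator


@dataclass
class SpikeSimConfig:
    """Configuration of the MEA spike-train simulator.

    Durations are seconds; planted bursts are ``(neuron, start, n_spikes,
    isi_ms)`` and planted network events ``(start, n_spikes, isi_ms,
    neurons)`` with spikes dealt round-robin across the participants.
    """

    n_neurons: int = 12
    duration: float = 420.0  # the 7-minute minimum recording
    background_rate: float = 0.5  # Hz
    planted_bursts: list[tuple[int, float, int, float]] = field(default_factory=list)
    planted_network_events: list[tuple[float, int, float, tuple[int, ...]]] = field(
        default_factory=list
    )
    well: str = "W1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons <= 0 or self.duration <= 0:
            raise ValueError("n_neurons and duration must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for neuron, start, n, isi in self.planted_bursts:
            if not 0 <= neuron < self.n_neurons:
                raise ValueError(f"burst neuron {neuron} out of range")
            end = start + (n - 1) * isi / 1000.0
            if start < 0 or end > self.duration:
                raise ValueError("planted burst outside recording window")
        for start, n, isi, neurons in self.planted_network_events:
            end = start + (n - 1) * isi / 1000.0
            if start < 0 or end > self.duration:
                raise ValueError("planted network event outside recording window")
            if any(not 0 <= nn < self.n_neurons for nn in neurons):
                raise ValueError("network-event neuron out of range")


def simulate_spike_trains(cfg: SpikeSimConfig) -> tuple[SpikeData, dict]:
    """Simulate spike trains: homogeneous Poisson background merged with
    planted bursts and network events; per-neuron timestamps are strictly
    increasing."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spikes: dict[int, list[float]] = {i: [] for i in range(cfg.n_neurons)}
    for i in range(cfg.n_neurons):
        n_bg = rng.poisson(cfg.background_rate * cfg.duration)
        spikes[i].extend(rng.uniform(0.0, cfg.duration, size=n_bg).tolist())
    truth_bursts = []
    for neuron, start, n, isi in cfg.planted_bursts:
        ts = start + np.arange(n) * isi / 1000.0
        spikes[neuron].extend(ts.tolist())
        truth_bursts.append(
            {"neuron": neuron, "start": start, "n_spikes": n, "isi_ms": isi}
        )
    truth_events = []
    for start, n, isi, neurons in cfg.planted_network_events:
        ts = start + np.arange(n) * isi / 1000.0
        for j, t in enumerate(ts):
            spikes[neurons[j % len(neurons)]].append(float(t))
        truth_events.append(
            {"start": start, "n_spikes": n, "isi_ms": isi, "neurons": list(neurons)}
        )
    trains = {}
    for i, ts in spikes.items():
        arr = np.sort(np.asarray(ts, dtype=float))
        # enforce strictly increasing timestamps (duplicates nudged by 1 µs)
        if arr.size > 1:
            for k in range(1, arr.size):
                if arr[k] <= arr[k - 1]:
                    arr[k] = arr[k - 1] + 1e-6
        trains[i] = arr
    sd = SpikeData(
        trains=trains,
        wells={i: cfg.well for i in range(cfg.n_neurons)},
        window=(0.0, cfg.duration),
    )
    truth = {
        "bursts": truth_bursts,
        "network_events": truth_events,
        "background_rate": cfg.background_rate,
        "seed": cfg.seed,
    }
    return sd, truth


# ---------------------------------------------------------------------------
# serialization helpers used by the CLI and pipeline


def save_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def config_from_dict(cls, d: dict):
    """Build a sim config dataclass from a plain dict, rejecting unknown keys."""
    valid = {f for f in cls.__dataclass_fields__}
    bad = set(d) - valid
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    kwargs = dict(d)
    if cls is ScSimConfig and "planted_de" in kwargs:
        kwargs["planted_de"] = [tuple(x)[:2] for x in kwargs["planted_de"]]
    if cls is SpikeSimConfig:
        if "planted_bursts" in kwargs:
            kwargs["planted_bursts"] = [tuple(x) for x in kwargs["planted_bursts"]]
        if "planted_network_events" in kwargs:
            kwargs["planted_network_events"] = [
                (x[0], x[1], x[2], tuple(x[3])) for x in kwargs["planted_network_events"]
            ]
    if cls is PlateSimConfig:
        for k in ("doses", "true_ic50"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
    return cls(**kwargs)
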
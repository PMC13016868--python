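"""Configuration, file formats, and the resumable end-to-end pipeline.

Stages: simulate -> preprocess -> qc -> factors -> fit -> decompose ->
report.  Each stage writes its outputs into the run directory and is
skipped on rerun when they already exist, so partial runs resume per
stage.  Every output is reproducible bit-for-bit from the same config and
seed; the manifest records the config hash alongside the file list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import factors as fa
from . import inference as inf
from . import preprocess as pp
from . import qc as qcmod
from . import simulate as sim
from . import sofr

STAGES = ("simulate", "preprocess", "qc", "factors", "fit", "decompose", "report")


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run settings; defaults follow the emulated study protocol."""

    seed: int = 0
    n_participants: int = 8
    depth_fraction: float = 0.01
    min_trials: int = 8
    lag_frames: int = 1
    envelope_hz: float = 4.0
    target_hz: float = 5.0
    window_start_s: float = 0.0
    window_len_s: float = 6.0
    basis_k: int = 8
    basis_kind: str = "tprs"
    split_fraction: float = 0.75
    n_factors: int | None = 3     # None = automatic selection
    simulation: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def simulation_config(self) -> sim.SimulationConfig:
        kw = dict(self.simulation)
        kw.setdefault("n_participants", self.n_participants)
        kw.setdefault("window_start_s", self.window_start_s)
        kw.setdefault("window_len_s", self.window_len_s)
        if "loadings" in kw and isinstance(kw["loadings"], dict):
            kw["loadings"] = pd.DataFrame(kw["loadings"])
        return sim.SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# epoch container IO (HDF5)
# ---------------------------------------------------------------------------

def write_epochs(path, epochs: pp.TrialEpochSet, *, config_hash: str = "") -> None:
    """Persist a TrialEpochSet with full stage/grid/provenance metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=4)
        g = f.create_group("trials")
        for col in epochs.trials.columns:
            vals = epochs.trials[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
        f.attrs["columns"] = json.dumps(list(epochs.trials.columns))
        f.attrs["channels"] = json.dumps(epochs.channels)
        f.attrs["rate_hz"] = epochs.rate_hz
        f.attrs["t0"] = epochs.t0
        f.attrs["stage"] = epochs.stage
        f.attrs["config_hash"] = config_hash
        meta = {str(k): v for k, v in epochs.meta.items() if not isinstance(v, dict)}
        norm = epochs.meta.get("norm_sd")
        if norm:
            meta["norm_sd"] = {f"{p}|{c}": v for (p, c), v in norm.items()}
        fp = epochs.meta.get("filter_params")
        if fp:
            meta["filter_params"] = fp
        f.attrs["meta"] = json.dumps(meta)


def read_epochs(path) -> pp.TrialEpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        cols = json.loads(f.attrs["columns"])
        tr = {}
        for col in cols:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            tr[col] = v
        meta = json.loads(f.attrs["meta"])
        if "norm_sd" in meta:
            meta["norm_sd"] = {tuple(k.split("|")): v for k, v in meta["norm_sd"].items()}
        return pp.TrialEpochSet(
            data=data, trials=pd.DataFrame(tr), channels=json.loads(f.attrs["channels"]),
            rate_hz=float(f.attrs["rate_hz"]), t0=float(f.attrs["t0"]),
            stage=str(f.attrs["stage"]), meta=meta)


def read_recordings(path):
    """Read continuous recordings from long-format CSV.

    Expects columns ``participant_id, channel, time_s, value``; returns
    ``{participant: {channel: (times, values)}}``.  Schema violations name
    the offending columns.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "channel", "time_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"recordings file missing columns: {sorted(missing)}")
    out: dict = {}
    for (pid, ch), grp in df.groupby(["participant_id", "channel"]):
        out.setdefault(pid, {})[ch] = (grp["time_s"].to_numpy(), grp["value"].to_numpy())
    return out


def write_truth(path, truth: sim.GroundTruth) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth.to_dict()), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _seeds(config: PipelineConfig) -> dict:
    ss = np.random.SeedSequence(config.seed)
    names = ("truth", "trials", "split", "parallel")
    return {n: int(s.generate_state(1)[0] % (2 ** 31)) for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: PipelineConfig, outdir, *, until: str = "report",
                 resume: bool = True) -> Path:
    """Execute the pipeline up to stage ``until``, writing into ``outdir``.

    Rerunning with an identical config reproduces all numeric outputs
    bit-for-bit; completed stages are skipped when ``resume`` is true.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    chash = config.hash()
    seeds = _seeds(config)
    last = STAGES.index(until)

    # --- simulate ---
    design_f, ratings_f, truth_f, raw_f = (out / n for n in
                                           ("design.csv", "ratings.csv", "truth.yaml", "epochs_raw.h5"))
    scfg = config.simulation_config()
    truth = sim.simulate_truth(scfg, seeds["truth"])
    if not (resume and design_f.exists() and ratings_f.exists() and raw_f.exists()):
        design = sim.generate_design(config.n_participants, seeds["truth"],
                                     isi_s=scfg.isi_s, odor_s=scfg.odor_s, start_s=scfg.start_s)
        epochs_raw, ratings = sim.simulate_trials(design, truth, seeds["trials"])
        design.to_csv(design_f, index=False)
        ratings.to_csv(ratings_f, index=False)
        write_truth(truth_f, truth)
        write_epochs(raw_f, epochs_raw, config_hash=chash)
    else:
        design = pd.read_csv(design_f)
        ratings = pd.read_csv(ratings_f)
        epochs_raw = read_epochs(raw_f)
    if last <= STAGES.index("simulate"):
        return _write_manifest(out, config, chash)

    # --- preprocess ---
    norm_f = out / "epochs_normalized.h5"
    if not (resume and norm_f.exists()):
        filt = pp.filter_epochs(epochs_raw, envelope_hz=config.envelope_hz)
        corr = pp.baseline_correct(filt)
        corr = pp.respiration_correct_hr(corr, lag=config.lag_frames)
        down = pp.downsample(corr, config.target_hz)
        normed = pp.normalize_participant(down)
        write_epochs(norm_f, normed, config_hash=chash)
    else:
        normed = read_epochs(norm_f)
    if last <= STAGES.index("preprocess"):
        return _write_manifest(out, config, chash)

    # --- qc ---
    depth_f, report_f, qc_epochs_f, qc_ratings_f = (out / n for n in
        ("depth.csv", "qc_report.csv", "epochs_qc.h5", "ratings_qc.csv"))
    if not (resume and qc_epochs_f.exists() and qc_ratings_f.exists()):
        depths = qcmod.depth_by_channel(normed)
        flagged = qcmod.flag_outliers(depths, config.depth_fraction)
        kept_epochs, kept_ratings, report = qcmod.apply_exclusions(
            normed, ratings, flagged, min_trials=config.min_trials)
        flagged.table.to_csv(depth_f, index=False)
        report.to_frame().to_csv(report_f, index=False)
        write_epochs(qc_epochs_f, kept_epochs, config_hash=chash)
        kept_ratings.to_csv(qc_ratings_f, index=False)
    else:
        kept_epochs = read_epochs(qc_epochs_f)
        kept_ratings = pd.read_csv(qc_ratings_f)
    if last <= STAGES.index("qc"):
        return _write_manifest(out, config, chash)

    # --- factors ---
    scores_f, loadings_f, variance_f = (out / n for n in
                                        ("scores.csv", "loadings.csv", "efa_variance.csv"))
    if not (resume and scores_f.exists()):
        wide = fa.pivot_ratings_wide(kept_ratings).dropna()
        k = fa.select_n_factors(wide.to_numpy(), seed=seeds["parallel"],
                                force=config.n_factors)
        solution = fa.fit_efa(wide, k)
        sc = fa.factor_scores(solution, wide)
        scored = fa.broadcast_scores(kept_ratings, wide.index, sc)
        solution.loadings.to_csv(loadings_f)
        pd.DataFrame({"prop_var": solution.prop_var}).to_csv(variance_f)
        scored.to_csv(scores_f, index=False)
    else:
        scored = pd.read_csv(scores_f)
        solution = None
    factor_names = [c for c in scored.columns if c.startswith("F") and c[1:].isdigit()]
    if last <= STAGES.index("factors"):
        return _write_manifest(out, config, chash)

    # --- fit ---
    scored = kept_epochs.trials[["participant_id", "trial"]].merge(
        scored, on=["participant_id", "trial"], how="left")
    signals = pp.model_window(kept_epochs, config.window_start_s, config.window_len_s)
    valid = scored[factor_names].notna().all(axis=1).to_numpy()
    scored = scored[valid].reset_index(drop=True)
    signals = signals[valid]
    basis = sofr.build_basis(
        sim.analysis_grid(config.simulation_config())[: signals.shape[2]],
        K=config.basis_k, kind=config.basis_kind)
    train, test = inf.train_test_split(scored, config.split_fraction, seeds["split"])

    metrics_f = out / "metrics.csv"
    wald_f = out / "wald_tests.csv"
    pe_f = out / "partial_effects.csv"
    marg_f = out / "marginal_estimates.csv"
    fits = {}
    if not (resume and metrics_f.exists() and marg_f.exists()):
        mrows, wrows, perows, margrows = [], [], [], []
        for dim in factor_names:
            y = scored[dim].to_numpy(float)
            des_tr = sofr.assemble_design(scored[train], signals[train], y[train],
                                          sofr.ModelSpec(dimension=dim), basis)
            fit = sofr.fit_reml(des_tr)
            fits[dim] = fit
            des_te = sofr.assemble_design(scored[test], signals[test], y[test],
                                          sofr.ModelSpec(dimension=dim), basis)
            for part, des in (("train", des_tr), ("test", des_te)):
                m = inf.fit_metrics(fit, des.y, des.X)
                mrows.append({"dimension": dim, "partition": part, **dataclasses.asdict(m)})
            for c in sim.CHANNELS:
                for kind in ("group", "indiv"):
                    w = inf.smooth_wald_test(fit, f"{kind}:{c}")
                    wrows.append({"dimension": dim, **dataclasses.asdict(w)})
                pe = sofr.partial_effect(fit, f"group:{c}")
                df = pe.to_frame()
                df.insert(0, "dimension", dim)
                perows.append(df)
            marg = inf.marginal_odor_estimates(fit)
            marg.insert(0, "dimension", dim)
            margrows.append(marg)
        pd.DataFrame(mrows).to_csv(metrics_f, index=False)
        pd.DataFrame(wrows).to_csv(wald_f, index=False)
        pd.concat(perows, ignore_index=True).to_csv(pe_f, index=False)
        pd.concat(margrows, ignore_index=True).to_csv(marg_f, index=False)
    if last <= STAGES.index("fit"):
        return _write_manifest(out, config, chash)

    # --- decompose ---
    decomp_f = out / "decomposition.csv"
    if not (resume and decomp_f.exists()):
        drows = []
        for dim in factor_names:
            y = scored[dim].to_numpy(float)
            dec = inf.variance_decomposition(scored[train], signals[train], y[train],
                                             sofr.ModelSpec(dimension=dim), basis)
            t = dec.to_frame()
            t.insert(0, "dimension", dim)
            t.insert(1, "full_adj_r2", dec.table.attrs["full_adj_r2"])
            drows.append(t)
        pd.concat(drows, ignore_index=True).to_csv(decomp_f, index=False)
    return _write_manifest(out, config, chash)


def _write_manifest(out: Path, config: PipelineConfig, chash: str) -> Path:
    import physofr

    files = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "version": getattr(physofr, "__version__", "0"),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
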
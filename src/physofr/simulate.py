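"""Synthetic study generator: trial designs, ground truth, signals and ratings.

Emulates a within-participant olfactory psychophysiology experiment: 6
monomolecular odorants x 8 rated perceptual properties x 2 repetitions
(96 trials per participant), four 500 Hz physiological channels
(respiration, heart rate, corrugator EMG, zygomaticus EMG) recorded around
each odor onset, and 0-100 visual-analog ratings produced by a known
generative model so every downstream stage can be tested against ground
truth.

The generative model for the latent score of perceptual dimension ``d`` on
trial ``i`` (participant ``p``, odor ``o``) is::

    z_di = alpha_{d,o} + gamma_d * 1{second half} + u_{d,p}
           + sum_c  int_0^6  x_c(t) [beta_{d,c}(t) + b_{d,p,c}(t)] dt
           + eps_di,   eps_di ~ N(0, sigma_d^2)

with the integral evaluated by the rectangle rule on the 5 Hz analysis grid
(block means of the emitted 500 Hz signal).  A rated property j maps to the
VAS scale as ``rating = clip(50 + 20 * (Lambda_j . z + eta), 0, 100)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

ODORS = ["Amycap", "Maltol", "Benzyl", "Decan", "Carvone", "Tolyl"]
#: fixed odor-to-block partition (hardware constraint of the emulated setup)
BLOCK_ODORS = {1: ["Amycap", "Maltol", "Benzyl"], 2: ["Decan", "Carvone", "Tolyl"]}
PROPERTIES = [
    "pleasantness",
    "disgust",
    "edibility",
    "irritability",
    "familiarity",
    "intensity",
    "warmth",
    "coldness",
]
CHANNELS = ["respiration", "heart_rate", "emg_cor", "emg_zyg"]
DIMENSIONS = ["valence", "temperature", "intensity"]

RAW_RATE_HZ = 500
EPOCH_START_S = -1.0
EPOCH_LEN_S = 15.0

#: default per-dimension odor effects (latent factor-score scale)
DEFAULT_ODOR_EFFECTS = {
    "valence": {
        "Tolyl": -0.61, "Amycap": -0.25, "Benzyl": -0.21,
        "Decan": -0.20, "Carvone": 0.56, "Maltol": 0.88,
    },
    "temperature": {
        "Tolyl": 0.03, "Amycap": -0.02, "Benzyl": -0.28,
        "Decan": 0.17, "Carvone": -0.48, "Maltol": 0.74,
    },
    "intensity": {
        "Tolyl": 0.12, "Amycap": 0.22, "Benzyl": 0.13,
        "Decan": -0.20, "Carvone": 0.17, "Maltol": -0.28,
    },
}

#: default group coefficient functions, lists of Gaussian bumps (center s,
#: width s, amplitude).  Temperature deliberately has none.
DEFAULT_GROUP_COEF = {
    "valence": {
        "respiration": [(1.9, 0.8, 0.5)],
        "heart_rate": [],
        "emg_cor": [(0.8, 0.5, -0.25), (3.0, 0.7, -0.25)],
        "emg_zyg": [],
    },
    "temperature": {c: [] for c in CHANNELS},
    "intensity": {
        "respiration": [(2.2, 0.8, -0.35)],
        "heart_rate": [],
        "emg_cor": [(1.5, 1.0, 0.25)],
        "emg_zyg": [(1.5, 1.0, 0.2)],
    },
}

#: SD of the random individual coefficient-function deviations, per
#: dimension and channel (0 = no idiosyncratic effect for that pairing)
DEFAULT_INDIV_SD = {
    "valence": {"respiration": 0.30, "heart_rate": 0.20, "emg_cor": 0.05, "emg_zyg": 0.05},
    "temperature": {"respiration": 0.10, "heart_rate": 0.30, "emg_cor": 0.30, "emg_zyg": 0.05},
    "intensity": {"respiration": 0.30, "heart_rate": 0.10, "emg_cor": 0.10, "emg_zyg": 0.05},
}

#: default 8x3 loading pattern of the rated properties on the latent
#: dimensions.  Valence is dominated by pleasantness/disgust, temperature by
#: cold/warm, intensity by intensity/irritability; secondary loadings (sharp
#: odors feel cold and irritating, intense odors less edible) keep every
#: factor overdetermined (3+ salient items) so the structure is identified.
def _stationary_loadings() -> pd.DataFrame:
    from .factors import varimax

    # pleasantness/disgust and warm/cold are near-mirror ends of one scale,
    # so their salient loadings are strong; secondary loadings keep every
    # factor overdetermined
    raw = np.array([
        [0.90, 0.00, 0.00],    # pleasantness
        [-0.88, 0.00, 0.00],   # disgust
        [0.75, 0.00, -0.30],   # edibility
        [0.00, 0.45, 0.75],    # irritability
        [0.55, 0.00, 0.00],    # familiarity
        [0.00, 0.10, 0.88],    # intensity
        [0.25, -0.88, 0.15],   # warmth
        [0.00, 0.90, 0.15],    # coldness
    ])
    # snap to the varimax-stationary orientation so the generating truth is
    # exactly what a varimax-rotated EFA estimates
    rot = varimax(raw)
    for j in range(rot.shape[1]):
        if rot[np.argmax(np.abs(rot[:, j])), j] < 0:
            rot[:, j] = -rot[:, j]
    return pd.DataFrame(np.round(rot, 4), index=PROPERTIES, columns=DIMENSIONS)


DEFAULT_LOADINGS = _stationary_loadings()

#: centers/width of the bump basis used for smooth random functions
_RAND_FN_CENTERS = np.array([0.6, 1.8, 3.0, 4.2, 5.4])
_RAND_FN_WIDTH = 0.9


def gaussian_bumps(t: np.ndarray, bumps) -> np.ndarray:
    """Evaluate a sum of Gaussian bumps ``amp * exp(-((t-c)/w)^2)``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c, w, a in bumps:
        out += a * np.exp(-(((t - c) / w) ** 2))
    return out


def channel_shape(channel: str, t: np.ndarray) -> np.ndarray:
    """Canonical per-channel response shape (zero before odor onset).

    Respiration: inhalation peak near 1.9 s then exhalation trough; heart
    rate: acceleration peak near 1.3 s then deceleration; corrugator: local
    maximum near 2.8 s; zygomaticus: gradual post-stimulus rise.
    """
    t = np.asarray(t, dtype=float)
    if channel == "respiration":
        out = gaussian_bumps(t, [(1.9, 0.9, 1.0), (4.6, 1.6, -0.55)])
    elif channel == "heart_rate":
        out = gaussian_bumps(t, [(1.3, 0.7, 1.0), (4.0, 1.8, -0.6)])
    elif channel == "emg_cor":
        out = gaussian_bumps(t, [(2.8, 1.0, 0.8)])
    elif channel == "emg_zyg":
        out = gaussian_bumps(t, [(6.0, 2.5, 0.6)])
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return np.where(t < 0, 0.0, out)


@dataclass
class SimulationConfig:
    """Tunable study conditions of the generator (defaults = emulated study)."""

    n_participants: int = 41
    isi_s: float = 15.0          # minimum self-paced inter-stimulus interval
    odor_s: float = 3.0          # odor presentation duration
    start_s: float = 5.0         # first onset (leaves baseline history)
    odor_effects: dict = field(default_factory=lambda: {d: dict(v) for d, v in DEFAULT_ODOR_EFFECTS.items()})
    half_effect: dict = field(default_factory=lambda: {"valence": 0.05, "temperature": -0.05, "intensity": 0.10})
    participant_sd: dict = field(default_factory=lambda: {"valence": 0.40, "temperature": 0.50, "intensity": 0.70})
    noise_sd: dict = field(default_factory=lambda: {"valence": 0.60, "temperature": 0.55, "intensity": 0.60})
    group_coef: dict = field(default_factory=lambda: {d: {c: list(v) for c, v in m.items()} for d, m in DEFAULT_GROUP_COEF.items()})
    indiv_sd: dict = field(default_factory=lambda: {d: dict(v) for d, v in DEFAULT_INDIV_SD.items()})
    loadings: pd.DataFrame = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    rating_noise_sd: float = 0.35     # unique (item-specific) noise on z-scale
    signal_noise_sd: float = 0.30     # white noise SD at 500 Hz
    drift_sd: float = 0.20            # per-trial slow drift coefficient SD
    idio_sd: float = 0.20             # per-participant signal idiosyncrasy SD
    trial_fn_sd: float = 0.35         # per-trial smooth response variability SD
    emg_mode: str = "am"              # "am" carrier-modulated | "direct"
    window_start_s: float = 0.0
    window_len_s: float = 6.0
    analysis_rate_hz: int = 5

    def validate(self) -> None:
        for name in ("rating_noise_sd", "signal_noise_sd", "drift_sd", "idio_sd", "trial_fn_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for d, sd in self.participant_sd.items():
            if sd < 0:
                raise ValueError(f"participant_sd[{d}] must be nonnegative")
        for d, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{d}] must be nonnegative")
        for d, m in self.indiv_sd.items():
            for c, sd in m.items():
                if sd < 0:
                    raise ValueError(f"indiv_sd[{d}][{c}] must be nonnegative")
        if self.emg_mode not in ("am", "direct"):
            raise ValueError("emg_mode must be 'am' or 'direct'")


@dataclass
class GroundTruth:
    """Frozen generative parameters, sufficient to recompute every latent score."""

    participants: list
    odor_effects: dict            # dim -> odor -> float
    half_effect: dict             # dim -> float
    participant_intercepts: dict  # dim -> pid -> float
    group_coef: dict              # dim -> channel -> bump list
    indiv_coef: dict              # dim -> (pid, channel) -> bump-basis coefs
    noise_sd: dict                # dim -> float
    template_amps: dict           # channel -> odor -> float
    loadings: pd.DataFrame
    rating_noise_sd: float
    config: SimulationConfig

    def group_coef_fn(self, dim: str, channel: str) -> Callable[[np.ndarray], np.ndarray]:
        bumps = self.group_coef[dim][channel]
        return lambda t: gaussian_bumps(np.asarray(t, float), bumps)

    def indiv_coef_fn(self, dim: str, pid: str, channel: str) -> Callable[[np.ndarray], np.ndarray]:
        coefs = self.indiv_coef[dim][(pid, channel)]

        def f(t):
            t = np.asarray(t, float)[..., None]
            basis = np.exp(-(((t - _RAND_FN_CENTERS) / _RAND_FN_WIDTH) ** 2))
            return basis @ coefs

        return f

    def to_dict(self) -> dict:
        return {
            "participants": list(self.participants),
            "odor_effects": self.odor_effects,
            "half_effect": self.half_effect,
            "participant_intercepts": {d: {p: float(v) for p, v in m.items()} for d, m in self.participant_intercepts.items()},
            "group_coef": self.group_coef,
            "indiv_coef": {d: {f"{p}|{c}": [float(x) for x in v] for (p, c), v in m.items()} for d, m in self.indiv_coef.items()},
            "noise_sd": self.noise_sd,
            "template_amps": self.template_amps,
            "loadings": self.loadings.to_dict(),
            "rating_noise_sd": self.rating_noise_sd,
        }


def _participant_ids(n: int) -> list:
    return [f"P{i + 1:03d}" for i in range(n)]


def generate_design(n_participants: int, seed: int, *, isi_s: float = 15.0,
                    odor_s: float = 3.0, start_s: float = 5.0) -> pd.DataFrame:
    """Generate the 96-trial design table for each participant.

    Each of the two odor blocks (3 fixed odors) contains every
    (odor, property) pair twice in fully randomized order; block order is
    randomized per participant.  Onsets are spaced by the odor duration plus
    the (fixed, minimum) inter-stimulus interval.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    rows = []
    for p, ss in zip(_participant_ids(n_participants), streams):
        rng = np.random.default_rng(ss)
        block_order = [1, 2] if rng.random() < 0.5 else [2, 1]
        idx = 0
        for half, block in enumerate(block_order, start=1):
            combos = [(o, pr, r) for o in BLOCK_ODORS[block]
                      for pr in PROPERTIES for r in (1, 2)]
            order = rng.permutation(len(combos))
            seen: dict = {}
            for j in order:
                odor, prop, _ = combos[j]
                rep = seen.get((odor, prop), 0) + 1
                seen[(odor, prop)] = rep
                rows.append({
                    "participant_id": p, "trial": idx, "odor": odor,
                    "property": prop, "repetition": rep, "block": block,
                    "test_half": half,
                    "onset_s": start_s + idx * (odor_s + isi_s),
                })
                idx += 1
    return pd.DataFrame(rows)


def simulate_truth(config: SimulationConfig | None = None, seed: int = 0) -> GroundTruth:
    """Draw the random ground-truth components on top of the configured fixed ones.

    Participant intercepts are i.i.d. normal per dimension; individual
    coefficient-function deviations are smooth random functions (Gaussian-bump
    basis with i.i.d. normal coefficients) centered across participants.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pids = _participant_ids(config.n_participants)

    intercepts = {}
    indiv = {}
    for d in DIMENSIONS:
        intercepts[d] = dict(zip(pids, rng.normal(0.0, config.participant_sd[d], len(pids))))
        coefs = {}
        for c in CHANNELS:
            sd = config.indiv_sd[d][c]
            draws = rng.normal(0.0, sd, (len(pids), len(_RAND_FN_CENTERS))) if sd > 0 else np.zeros((len(pids), len(_RAND_FN_CENTERS)))
            draws = draws - draws.mean(axis=0, keepdims=True)  # centered deviations
            for p, row in zip(pids, draws):
                coefs[(p, c)] = row
        indiv[d] = coefs

    # mild odor modulation of the per-channel template amplitude, tied to
    # the configured odor effects so channels covary with what they predict;
    # kept small so signals do not simply re-encode odor identity
    alpha_v = config.odor_effects["valence"]
    alpha_i = config.odor_effects["intensity"]
    amps = {
        "respiration": {o: 1.0 + 0.15 * alpha_v[o] for o in ODORS},
        "heart_rate": {o: 1.0 + 0.08 * alpha_v[o] for o in ODORS},
        "emg_cor": {o: 1.0 - 0.10 * alpha_v[o] + 0.10 * alpha_i[o] for o in ODORS},
        "emg_zyg": {o: 1.0 + 0.10 * alpha_i[o] for o in ODORS},
    }

    return GroundTruth(
        participants=pids,
        odor_effects={d: dict(config.odor_effects[d]) for d in DIMENSIONS},
        half_effect=dict(config.half_effect),
        participant_intercepts=intercepts,
        group_coef={d: {c: list(config.group_coef[d][c]) for c in CHANNELS} for d in DIMENSIONS},
        indiv_coef=indiv,
        noise_sd=dict(config.noise_sd),
        template_amps=amps,
        loadings=config.loadings.copy(),
        rating_noise_sd=config.rating_noise_sd,
        config=config,
    )


def analysis_grid(config: SimulationConfig | None = None) -> np.ndarray:
    """Midpoints of the 5 Hz analysis bins over the modeling window [0, 6) s."""
    config = config or SimulationConfig()
    dt = 1.0 / config.analysis_rate_hz
    n = int(round(config.window_len_s * config.analysis_rate_hz))
    return config.window_start_s + dt * (np.arange(n) + 0.5)


def _random_fn(rng: np.random.Generator, sd: float, t: np.ndarray) -> np.ndarray:
    """Smooth random function on the bump basis evaluated at ``t``."""
    if sd <= 0:
        return np.zeros_like(t)
    coefs = rng.normal(0.0, sd, len(_RAND_FN_CENTERS))
    basis = np.exp(-(((t[:, None] - _RAND_FN_CENTERS) / _RAND_FN_WIDTH) ** 2))
    return basis @ coefs


def _latent_scores(design_p: pd.DataFrame, truth: GroundTruth, x5: np.ndarray,
                   grid: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Latent dimension scores for one participant given 5 Hz activity x5 (n,4,T)."""
    cfg = truth.config
    w = 1.0 / cfg.analysis_rate_hz
    pid = design_p["participant_id"].iloc[0]
    out = {}
    for d in DIMENSIONS:
        alpha = design_p["odor"].map(truth.odor_effects[d]).to_numpy(float)
        half = truth.half_effect[d] * (design_p["test_half"].to_numpy() == 2)
        u = truth.participant_intercepts[d][pid]
        contrib = np.zeros(len(design_p))
        for ci, c in enumerate(CHANNELS):
            coef = gaussian_bumps(grid, truth.group_coef[d][c])
            coef = coef + truth.indiv_coef_fn(d, pid, c)(grid)
            contrib += x5[:, ci, :] @ (w * coef)
        eps = rng.normal(0.0, truth.noise_sd[d], len(design_p))
        out[f"latent_{d}"] = alpha + half + u + contrib + eps
    return pd.DataFrame(out, index=design_p.index)


def _ratings_from_latent(design_p: pd.DataFrame, latent: pd.DataFrame,
                         truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """Map each trial's latent vector through its rated property's loadings."""
    z = latent.to_numpy()                               # (n, 3)
    lam = truth.loadings.loc[design_p["property"]].to_numpy()  # (n, 3)
    eta = rng.normal(0.0, truth.rating_noise_sd, len(design_p))
    return np.clip(50.0 + 20.0 * ((lam * z).sum(axis=1) + eta), 0.0, 100.0)


def _check_levels(design: pd.DataFrame, truth: GroundTruth) -> None:
    missing_p = set(design["participant_id"]) - set(truth.participants)
    missing_o = set(design["odor"]) - set(ODORS)
    if missing_p or missing_o:
        raise ValueError(f"design/truth level mismatch: participants {sorted(missing_p)}, odors {sorted(missing_o)}")


def simulate_trials(design: pd.DataFrame, truth: GroundTruth, seed: int = 0):
    """Simulate 500 Hz per-trial epochs and the rating table.

    Returns ``(epochs, ratings)`` where ``epochs`` is a
    :class:`physofr.preprocess.TrialEpochSet` (stage ``raw``, grid
    [-1, 14) s) and ``ratings`` carries the per-trial VAS rating of the
    rated property plus the latent dimension scores used to produce it.

    The latent-score integral uses the 5 Hz block means of the emitted
    signal itself, so an independent quadrature over the stored epochs and
    truth functions reproduces the emitted scores exactly (up to the stored
    noise draw).
    """
    from .preprocess import TrialEpochSet  # local import to avoid cycle

    _check_levels(design, truth)
    cfg = truth.config
    fs = RAW_RATE_HZ
    n_samp = int(EPOCH_LEN_S * fs)
    t500 = EPOCH_START_S + np.arange(n_samp) / fs
    grid = analysis_grid(cfg)
    block = fs // cfg.analysis_rate_hz
    w0 = int(round((cfg.window_start_s - EPOCH_START_S) * fs))
    w1 = w0 + int(round(cfg.window_len_s * fs))

    pids = sorted(design["participant_id"].unique())
    streams = {p: s for p, s in zip(pids, np.random.SeedSequence(seed).spawn(len(pids)))}

    all_data, all_ratings, order = [], [], []
    for pid in pids:
        rng = np.random.default_rng(streams[pid])
        dsub = design[design["participant_id"] == pid].sort_values("trial")
        n = len(dsub)
        idio = {c: _random_fn(rng, cfg.idio_sd, np.where(t500 < 0, 0.0, t500)) * (t500 >= 0)
                for c in CHANNELS}
        data = np.empty((n, len(CHANNELS), n_samp))
        activity5 = np.empty((n, len(CHANNELS), len(grid)))
        for i, (_, row) in enumerate(dsub.iterrows()):
            for ci, c in enumerate(CHANNELS):
                amp = truth.template_amps[c][row["odor"]]
                act = (amp * channel_shape(c, t500) + idio[c]
                       + _random_fn(rng, cfg.trial_fn_sd, np.clip(t500, 0.0, None)) * (t500 >= 0))
                drift = (rng.normal(0.0, cfg.drift_sd)
                         + rng.normal(0.0, cfg.drift_sd) * (t500 - EPOCH_START_S) / EPOCH_LEN_S)
                noise = rng.normal(0.0, cfg.signal_noise_sd, n_samp) if cfg.signal_noise_sd > 0 else 0.0
                carrier_act = act + drift + noise
                if c.startswith("emg") and cfg.emg_mode == "am":
                    carrier = _bandpass_noise(rng, n_samp, fs)
                    data[i, ci] = (0.3 + np.clip(act, 0.0, None) + drift) * carrier
                    # score integral uses the modulating activity, the
                    # quantity the EMG envelope estimates
                    sig5 = carrier_act[w0:w1].reshape(-1, block).mean(axis=1)
                else:
                    data[i, ci] = carrier_act
                    sig5 = carrier_act[w0:w1].reshape(-1, block).mean(axis=1)
                activity5[i, ci] = sig5
        latent = _latent_scores(dsub, truth, activity5, grid, rng)
        ratings = dsub.copy()
        ratings["rating"] = _ratings_from_latent(dsub, latent, truth, rng)
        for col in latent.columns:
            ratings[col] = latent[col]
        all_data.append(data)
        all_ratings.append(ratings)
        order.append(dsub)

    epochs = TrialEpochSet(
        data=np.concatenate(all_data, axis=0),
        trials=pd.concat(order, ignore_index=True),
        channels=list(CHANNELS),
        rate_hz=fs,
        t0=EPOCH_START_S,
        stage="raw",
    )
    return epochs, pd.concat(all_ratings, ignore_index=True)


def _bandpass_noise(rng: np.random.Generator, n: int, fs: int) -> np.ndarray:
    """Unit-SD 20-50 Hz noise carrier for amplitude-modulated synthetic EMG."""
    from scipy.signal import butter, sosfilt

    sos = butter(2, [20, 50], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def simulate_model_data(design: pd.DataFrame, truth: GroundTruth, seed: int = 0):
    """Fast path: emit 5 Hz model-window signals and latent scores directly.

    Equivalent in distribution to block-averaging the 500 Hz path over the
    [0, 6) s window (white noise variance scaled by the block size); used
    for model-level studies where the raw-rate signal is not needed.

    Returns ``(signals, scores)`` with ``signals`` of shape
    (n_trials, 4 channels, 30 samples) aligned with ``scores`` rows.
    """
    _check_levels(design, truth)
    cfg = truth.config
    grid = analysis_grid(cfg)
    block = RAW_RATE_HZ // cfg.analysis_rate_hz
    noise5 = cfg.signal_noise_sd / np.sqrt(block)

    pids = sorted(design["participant_id"].unique())
    streams = {p: s for p, s in zip(pids, np.random.SeedSequence(seed).spawn(len(pids)))}
    sig_all, score_all = [], []
    for pid in pids:
        rng = np.random.default_rng(streams[pid])
        dsub = design[design["participant_id"] == pid].sort_values("trial")
        n = len(dsub)
        idio = {c: _random_fn(rng, cfg.idio_sd, grid) for c in CHANNELS}
        x5 = np.empty((n, len(CHANNELS), len(grid)))
        for i, (_, row) in enumerate(dsub.iterrows()):
            for ci, c in enumerate(CHANNELS):
                amp = truth.template_amps[c][row["odor"]]
                drift = (rng.normal(0.0, cfg.drift_sd)
                         + rng.normal(0.0, cfg.drift_sd) * (grid - EPOCH_START_S) / EPOCH_LEN_S)
                noise = rng.normal(0.0, noise5, len(grid)) if noise5 > 0 else 0.0
                x5[i, ci] = (amp * channel_shape(c, grid) + idio[c]
                             + _random_fn(rng, cfg.trial_fn_sd, grid) + drift + noise)
        latent = _latent_scores(dsub, truth, x5, grid, rng)
        scores = dsub.copy()
        scores["rating"] = _ratings_from_latent(dsub, latent, truth, rng)
        for col in latent.columns:
            scores[col] = latent[col]
        sig_all.append(x5)
        score_all.append(scores)
    return np.concatenate(sig_all, axis=0), pd.concat(score_all, ignore_index=True)


def simulate_factor_items(n: int, seed: int = 0,
                          loadings: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sample item responses from an orthogonal common-factor model.

    ``x = F L' + E diag(sqrt(psi))`` with standard-normal factors; used to
    exercise factor-count selection and loading recovery on data with a
    known varimax-simple structure.
    """
    L = (loadings if loadings is not None else DEFAULT_LOADINGS).to_numpy()
    if n < 2:
        raise ValueError("n must be >= 2")
    psi = 1.0 - (L ** 2).sum(axis=1)
    if np.any(psi <= 0):
        raise ValueError("loadings imply nonpositive uniqueness")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, L.shape[1]))
    E = rng.standard_normal((n, L.shape[0])) * np.sqrt(psi)
    X = F @ L.T + E
    cols = list((loadings if loadings is not None else DEFAULT_LOADINGS).index)
    return pd.DataFrame(X, columns=cols)
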
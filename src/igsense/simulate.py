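"""Synthetic infant cohorts: looking times, saccades, look-aways, outcomes.

Emulates the statistical structure the analysis pipeline assumes, so every
downstream stage is testable without restricted participant data:

* a population of infants with heterogeneous sensitivity to information
  (individual looking-time slopes on trial-wise information gain);
* per-trial looking times in the 1500 ms target window, modulated by
  information gain, surprise, predictability and trial number, with
  look-away truncation of sequences and experiment-level attrition;
* saccadic latencies that are faster on predictable trials;
* later IQ outcomes (full-scale plus three subindices) that depend on the
  sensitivity slope through a configurable link (linear, exponential or
  threshold), plus a socioeconomic-status covariate and noise.

Defaults are calibrated to the study conditions: 90 infants recruited with
attrition to ~60 analyzable, ~7 sequences and ~8 trials per sequence
watched, a 66 ms/SD population looking-time effect of information gain, a
180 ms predictable-trial saccade advantage, and outcome IQ ~ N(106, 12.6).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .task import TaskDesign

TARGET_WINDOW_MS = 1500.0

#: Per-caregiver education-level probabilities over 1..4; gives ~94% of
#: two-caregiver households at least one level-3+ education.
EDUCATION_PROBS = (0.05, 0.20, 0.45, 0.30)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class InfantParams:
    """Generative parameters of a single infant."""

    infant_id: str
    baseline_lt: float  # ms, looking time at zero-standardized predictors
    sensitivity_ig: float  # ms per SD of information gain (individual slope)
    beta_surprise: float  # ms/SD
    beta_pred: float  # ms/SD
    beta_trial: float  # ms per trial
    resid_sd: float  # ms
    latency_base: float  # ms
    latency_pred_effect: float  # ms slow-down on unpredictable trials
    latency_resid_sd: float  # ms
    lookaway_intercept: float  # log-odds of looking away on a trial
    lookaway_ig_coef: float  # log-odds reduction per SD of information gain
    continue_logit: float  # log-odds of starting the next sequence
    usable: bool = True  # eye-tracking data usable at 8 months
    followed_up: bool = True  # outcome measured at 3.5 years


@dataclass(frozen=True)
class PopulationHyperparams:
    """Population mean and SD for every infant-level parameter.

    ``attrition_rate`` is the probability that an infant yields no usable
    eye-tracking data; ``dropout_rate`` the probability that a usable
    infant misses the outcome follow-up. Defaults mirror a 90-infant
    cohort with 60 analyzable children.
    """

    baseline_lt: tuple[float, float] = (900.0, 120.0)
    sensitivity_ig: tuple[float, float] = (66.0, 40.0)
    beta_surprise: tuple[float, float] = (-18.0, 10.0)
    beta_pred: tuple[float, float] = (-58.0, 15.0)
    beta_trial: tuple[float, float] = (-8.0, 4.0)
    resid_sd: tuple[float, float] = (250.0, 40.0)
    latency_base: tuple[float, float] = (400.0, 60.0)
    latency_pred_effect: tuple[float, float] = (180.0, 40.0)
    latency_resid_sd: tuple[float, float] = (150.0, 30.0)
    lookaway_intercept: tuple[float, float] = (-2.2, 0.4)
    lookaway_ig_coef: tuple[float, float] = (0.5, 0.2)
    continue_logit: tuple[float, float] = (1.95, 0.6)
    attrition_rate: float = 2.0 / 9.0
    dropout_rate: float = 1.0 / 7.0


def simulate_infants(
    n: int = 90,
    hyperparams: PopulationHyperparams | None = None,
    seed: int = 0,
) -> list[InfantParams]:
    """Draw ``n`` infants from the population distribution.

    Each scalar parameter is Normal(mean, sd); residual SDs are floored at
    1 ms and baselines clipped into (0, 1500]. With all SDs zero the
    parameters equal the population means exactly.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 infants, got {n}")
    hp = hyperparams or PopulationHyperparams()
    for f in dc_fields(hp):
        v = getattr(hp, f.name)
        if isinstance(v, tuple) and v[1] < 0:
            raise ValueError(f"negative population SD for {f.name}: {v[1]}")
    if not (0 <= hp.attrition_rate <= 1 and 0 <= hp.dropout_rate <= 1):
        raise ValueError("attrition/dropout rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def draw(name: str) -> np.ndarray:
        mean, sd = getattr(hp, name)
        return mean + sd * rng.standard_normal(n)

    cols = {
        name: draw(name)
        for name in (
            "baseline_lt",
            "sensitivity_ig",
            "beta_surprise",
            "beta_pred",
            "beta_trial",
            "resid_sd",
            "latency_base",
            "latency_pred_effect",
            "latency_resid_sd",
            "lookaway_intercept",
            "lookaway_ig_coef",
            "continue_logit",
        )
    }
    cols["resid_sd"] = np.maximum(cols["resid_sd"], 1e-12)
    cols["latency_resid_sd"] = np.maximum(cols["latency_resid_sd"], 1e-12)
    cols["latency_base"] = np.maximum(cols["latency_base"], 1.0)
    cols["baseline_lt"] = np.clip(cols["baseline_lt"], 1.0, TARGET_WINDOW_MS)
    usable = rng.random(n) >= hp.attrition_rate
    followed = rng.random(n) >= hp.dropout_rate

    width = max(3, len(str(n)))
    return [
        InfantParams(
            infant_id=f"inf{i:0{width}d}",
            usable=bool(usable[i]),
            followed_up=bool(followed[i]),
            **{k: float(v[i]) for k, v in cols.items()},
        )
        for i in range(n)
    ]


def infants_to_frame(infants: list[InfantParams]) -> pd.DataFrame:
    return pd.DataFrame(
        [{f.name: getattr(p, f.name) for f in dc_fields(p)} for p in infants]
    )


def standardize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append z-scored information gain, surprise and predictability.

    Z-scores are computed over the design's full metric table, so every
    infant shares one scale regardless of truncation.
    """
    out = metrics.copy()
    for col in ("information_gain", "surprise", "predictability"):
        v = out[col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"metric {col} has zero variance; cannot standardize")
        out[col + "_z"] = (v - v.mean()) / sd
    return out


def simulate_looking(
    design: TaskDesign,
    metrics: pd.DataFrame,
    infants: list[InfantParams],
    seed: int = 0,
    censor: bool = True,
    truncate: bool = True,
) -> pd.DataFrame:
    """Simulate per-trial looking records with look-away truncation.

    looking_time = clip(baseline + slope*zIG + b_s*zS + b_p*zP
    + b_t*trial + noise, 0, 1500). Each trial carries a Bernoulli
    look-away with logit = lookaway_intercept - lookaway_ig_coef*zIG; a
    look-away ends the sequence after the current trial, and after each
    sequence the infant continues to the next with probability
    sigmoid(continue_logit). Infants flagged unusable produce no records.
    ``censor=False`` disables the [0, 1500] clipping (latent-scale output);
    ``truncate=False`` disables look-away and attrition, so every usable
    infant watches the complete design.
    """
    z = standardize_metrics(metrics)
    n_design_trials = sum(len(s.trial_locations) for s in design.sequences)
    if len(z) != n_design_trials:
        raise ValueError(
            f"metrics table has {len(z)} rows but design has "
            f"{n_design_trials} trials"
        )
    z = z.sort_values(["sequence_index", "trial_index"], kind="stable")
    by_seq = {k: g for k, g in z.groupby("sequence_index")}
    modal = {s.sequence_index: s.modal_location for s in design.sequences}

    rng = np.random.default_rng(seed)
    rows = []
    for inf in infants:
        if not inf.usable:
            continue
        p_continue = float(_sigmoid(inf.continue_logit))
        for seq in design.sequences:
            g = by_seq[seq.sequence_index]
            zig = g["information_gain_z"].to_numpy()
            zs = g["surprise_z"].to_numpy()
            zp = g["predictability_z"].to_numpy()
            locs = g["observed_location"].to_numpy()
            tidx = g["trial_index"].to_numpy()
            n_t = len(g)
            noise = inf.resid_sd * rng.standard_normal(n_t)
            lt = (
                inf.baseline_lt
                + inf.sensitivity_ig * zig
                + inf.beta_surprise * zs
                + inf.beta_pred * zp
                + inf.beta_trial * tidx
                + noise
            )
            if censor:
                lt = np.clip(lt, 0.0, TARGET_WINDOW_MS)
            p_away = _sigmoid(inf.lookaway_intercept - inf.lookaway_ig_coef * zig)
            away = (rng.random(n_t) < p_away) if truncate else np.zeros(n_t, bool)
            stop_at = int(np.argmax(away)) if away.any() else n_t - 1
            looked_away = away.any()
            for t in range(stop_at + 1):
                rows.append(
                    {
                        "infant_id": inf.infant_id,
                        "sequence_index": seq.sequence_index,
                        "trial_index": int(tidx[t]),
                        "looking_time": float(lt[t]),
                        "looked_away": bool(t == stop_at and looked_away),
                        "trial_predictable": bool(
                            locs[t] == modal[seq.sequence_index]
                        ),
                    }
                )
            if truncate and rng.random() >= p_continue:
                break
    return pd.DataFrame(rows)


def simulate_saccades(
    records: pd.DataFrame,
    infants: list[InfantParams],
    seed: int = 0,
) -> pd.DataFrame:
    """Add saccadic latencies to a looking-record table.

    latency = latency_base + latency_pred_effect * (trial unpredictable)
    + Normal(0, latency_resid_sd), floored at 1 ms: infants orient faster
    to targets in the learned high-probability location.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.infant_id: p for p in infants}
    out = records.copy()
    base = np.array([by_id[i].latency_base for i in out["infant_id"]])
    eff = np.array([by_id[i].latency_pred_effect for i in out["infant_id"]])
    sd = np.array([by_id[i].latency_resid_sd for i in out["infant_id"]])
    unpred = (~out["trial_predictable"].to_numpy(dtype=bool)).astype(float)
    lat = base + eff * unpred + sd * rng.standard_normal(len(out))
    out["saccadic_latency"] = np.maximum(lat, 1.0)
    return out


def simulate_study(
    design: TaskDesign,
    metrics: pd.DataFrame,
    infants: list[InfantParams],
    seed: int = 0,
    censor: bool = True,
    truncate: bool = True,
) -> pd.DataFrame:
    """Looking records with saccadic latencies merged in."""
    looking = simulate_looking(
        design, metrics, infants, seed=seed, censor=censor, truncate=truncate
    )
    # independent substream so latency noise does not perturb looking noise
    return simulate_saccades(looking, infants, seed=seed + 1_000_003)


@dataclass(frozen=True)
class OutcomeConfig:
    """Generative curiosity-to-IQ link and outcome noise.

    ``link`` maps the standardized sensitivity slope z to an IQ
    contribution f(z): ``linear`` a*z, ``exponential`` b*exp(z) (convex:
    gains concentrate in the most information-sensitive infants),
    ``threshold`` a*max(z - tau, 0). The exponential default b=3.75 with
    intercept/noise chosen so full-scale IQ is approximately N(106, 12.6).
    """

    link: str = "exponential"
    linear_coef: float = 8.0
    exp_coef: float = 3.75
    threshold_coef: float = 12.0
    threshold_loc: float = 0.5
    intercept: float = 99.8
    ses_coef: float = 2.0
    noise_sd: float = 9.0
    # subindex loadings on the curiosity signal and noise correlations
    index_means: tuple[float, float, float] = (106.0, 103.0, 109.0)  # VCI, VSI, WMI
    index_loadings: tuple[float, float, float] = (1.0, 0.7, 0.6)
    index_noise_sd: tuple[float, float, float] = (13.4, 9.8, 8.2)
    noise_corr: tuple[float, float, float] = (0.4, 0.5, 0.2)  # VCI-VSI, VCI-WMI, VSI-WMI


def curiosity_link(z: np.ndarray, config: OutcomeConfig) -> np.ndarray:
    """Evaluate the configured link f on standardized sensitivity values."""
    z = np.asarray(z, dtype=float)
    if config.link == "linear":
        return config.linear_coef * z
    if config.link == "exponential":
        return config.exp_coef * np.exp(z)
    if config.link == "threshold":
        return config.threshold_coef * np.maximum(z - config.threshold_loc, 0.0)
    raise ValueError(
        f"unknown link {config.link!r}; expected linear, exponential or threshold"
    )


def simulate_ses(n: int, rng: np.random.Generator) -> np.ndarray:
    """Average education level of two caregivers, each on the 1-4 scale."""
    levels = np.arange(1, 5)
    draws = rng.choice(levels, size=(n, 2), p=EDUCATION_PROBS)
    return draws.mean(axis=1)


def simulate_outcomes(
    infants: list[InfantParams],
    config: OutcomeConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate IQ outcomes at follow-up from infant sensitivity slopes.

    fsiq = intercept + f(z) + ses_coef*(ses - 3) + noise, where z is the
    standardized true sensitivity slope. The three subindices share the
    curiosity signal with index-specific loadings, means and correlated
    noise, reproducing positive verbal-comprehension associations with
    the visual-spatial and working-memory indices.
    """
    config = config or OutcomeConfig()
    rng = np.random.default_rng(seed)
    sens = np.array([p.sensitivity_ig for p in infants], dtype=float)
    if len(infants) > 1 and sens.std() > 0:
        z = (sens - sens.mean()) / sens.std()
    else:
        z = np.zeros_like(sens)
    f = curiosity_link(z, config)
    n = len(infants)
    ses = simulate_ses(n, rng)
    fsiq = (
        config.intercept
        + f
        + config.ses_coef * (ses - 3.0)
        + config.noise_sd * rng.standard_normal(n)
    )

    r_vv, r_vw, r_sw = config.noise_corr
    corr = np.array([[1.0, r_vv, r_vw], [r_vv, 1.0, r_sw], [r_vw, r_sw, 1.0]])
    sds = np.asarray(config.index_noise_sd)
    cov = corr * np.outer(sds, sds)
    noise = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    fc = f - f.mean()
    idx = {
        name: config.index_means[j] + config.index_loadings[j] * fc + noise[:, j]
        for j, name in enumerate(("vci", "vsi", "wmi"))
    }
    return pd.DataFrame(
        {
            "infant_id": [p.infant_id for p in infants],
            "fsiq": fsiq,
            "vci": idx["vci"],
            "vsi": idx["vsi"],
            "wmi": idx["wmi"],
            "ses": ses,
            "followed_up": [p.followed_up for p in infants],
        }
    )
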
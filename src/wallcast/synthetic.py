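"""Seeded synthetic marathon cohorts with a recoverable HTW risk structure.

Real per-runner IMU telemetry from race services is private, so every stage
of the pipeline is exercised on synthetic cohorts that emulate its assumed
statistical structure:

* smooth per-runner curves of 17 running-form variables (pace included) over
  the first half of the race: population mean + three smooth random-effect
  modes (Legendre-type: level, linear drift, curvature) + segment-level
  measurement noise, sampled as 250/500/1000 m segment averages;
* a latent logistic risk of "hitting the wall" driven by distance-varying
  weight curves on step length, ground contact time and vertical stiffness
  (positive step-length weight early that turns negative after ~10 km;
  contact-time and stiffness weights positive at the start, near zero at
  5-10 km, rising again after), integrated against the centred form curves;
* a second-half pace profile rendered from the drawn outcome: HTW runners
  ramp to a relative-pace plateau well above 1.25 sustained past 25 km,
  non-HTW runners stay comfortably below 1.10, and an "excluded" fraction
  plateaus in between so that neither labeling criterion fires;
* demographics (sex ratio ~1277:160, age 50.4 +/- 8.6 y) for the stratified
  split, and a default labeled-class prevalence of 0.46 obtained by
  calibrating the risk intercept numerically.

Pace is generated as a noisy linear blend of the step-length and cadence
random effects (running speed is mechanically their product), which induces
the multicollinearity among FPC scores that the downstream screen is meant
to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit

from .labeling import LabelRule, PaceLabel, PaceProfile, classify_race

#: the 17 per-segment telemetry variables, pace first
VARIABLE_NAMES = [
    "pace",
    "cadence",
    "step_length",
    "pelvic_backward_lean",
    "vertical_motion",
    "body_drop",
    "pelvic_drop",
    "pelvic_elevation",
    "pelvic_rotation",
    "pelvic_rotation_timing",
    "horizontal_impact_force",
    "kicking_phase_duration",
    "ground_contact_time",
    "landing_impact",
    "kicking_acceleration",
    "amount_of_braking",
    "vertical_stiffness",
]

#: variables carrying nonzero default risk weight
ACTIVE_VARIABLES = ["step_length", "ground_contact_time", "vertical_stiffness"]

#: half-race domain (km) on which form curves live
FORM_DOMAIN = (0.0, 21.0)

# per-variable defaults: population level, linear drift over the first half,
# random-effect scale (level mode; drift/curvature modes get 0.3x and 0.2x),
# and per-500m-segment measurement noise SD, all in the variable's units
_VARIABLE_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "pace": (360.0, 8.0, 45.0, 2.0),                 # s/km
    "cadence": (170.0, -1.0, 8.0, 0.8),              # steps/min
    "step_length": (62.0, -1.5, 4.5, 0.35),          # % height
    "pelvic_backward_lean": (5.0, 0.5, 2.0, 0.3),    # deg
    "vertical_motion": (6.5, 0.1, 1.0, 0.12),        # % height
    "body_drop": (1.5, 0.1, 0.4, 0.06),              # % height
    "pelvic_drop": (7.0, 0.3, 2.0, 0.25),            # deg
    "pelvic_elevation": (5.0, 0.2, 1.5, 0.2),        # deg
    "pelvic_rotation": (10.0, -0.5, 3.0, 0.4),       # deg
    "pelvic_rotation_timing": (50.0, 0.0, 8.0, 1.0),
    "horizontal_impact_force": (6.0, 0.3, 1.5, 0.2),  # m/s^2
    "kicking_phase_duration": (180.0, 5.0, 20.0, 2.5),  # ms
    "ground_contact_time": (62.0, 1.0, 3.0, 0.3),    # % gait cycle
    "landing_impact": (10.0, 0.5, 2.0, 0.3),         # m/s^2
    "kicking_acceleration": (14.0, -0.5, 3.0, 0.4),  # m/s^2
    "amount_of_braking": (0.25, 0.01, 0.06, 0.01),   # m/s
    "vertical_stiffness": (0.35, -0.02, 0.08, 0.008),  # kN/m/kg
}

_MODE_RELATIVE_SD = (1.0, 0.3, 0.2)

# v-shaped weight template shared by contact time and stiffness: positive at
# the start, ~zero at 5-10 km, rising again thereafter
_V_SHAPE = [(0.0, 1.0), (5.0, 0.05), (7.5, 0.0), (10.0, 0.05), (14.0, 0.35), (21.0, 1.8)]

_DEFAULT_RISK_WEIGHTS: dict[str, list[tuple[float, float]]] = {
    "step_length": [(0.0, 0.06), (10.0, 0.0), (21.0, -0.066)],
    "ground_contact_time": [(km, 0.035 * w) for km, w in _V_SHAPE],
    "vertical_stiffness": [(km, 1.3 * w) for km, w in _V_SHAPE],
}

# standardized-loading blend making pace collinear with step length and
# cadence (faster pace = longer steps at higher cadence); residual fraction
# keeps its score-column VIF just above the screen's threshold of 10
_DEFAULT_PACE_COUPLING = {"step_length": -0.82, "cadence": -0.50, "residual": 0.28}


@dataclass(frozen=True)
class SlowdownParams:
    """Second-half relative-pace synthesis parameters (distances in km)."""

    onset_range_km: tuple[float, float] = (20.0, 30.0)
    htw_magnitude_range: tuple[float, float] = (1.30, 1.45)
    nhtw_magnitude_range: tuple[float, float] = (1.00, 1.07)
    excluded_magnitude_range: tuple[float, float] = (1.14, 1.21)
    ramp_km: float = 3.0
    pace_noise_rel: float = 0.003  # relative SD per 500 m segment, clipped at 3 SD


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort draw."""

    n_runners: int = 700
    segment_length_m: int | str = 500        # 250, 500, 1000 or "mixed"
    race_distance_m: float = 42195.0
    variable_names: list[str] = field(default_factory=lambda: list(VARIABLE_NAMES))
    population_means: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    random_effect_sd: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    risk_weights: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {v: list(w) for v, w in _DEFAULT_RISK_WEIGHTS.items()}
    )
    risk_intercept: float | None = None       # None -> calibrate to target_prevalence
    target_prevalence: float = 0.46
    pace_coupling: dict[str, float] | None = field(
        default_factory=lambda: dict(_DEFAULT_PACE_COUPLING)
    )
    slowdown: SlowdownParams = field(default_factory=SlowdownParams)
    excluded_fraction: float = 0.537
    female_fraction: float = 160.0 / 1437.0
    age_mean: float = 50.4
    age_sd: float = 8.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.variable_names:
            if name not in _VARIABLE_DEFAULTS:
                raise ValueError(f"variable_names contains unknown variable {name!r}")
            level, drift, sd0, noise = _VARIABLE_DEFAULTS[name]
            self.population_means.setdefault(name, [(0.0, level), (21.0, level + drift)])
            self.random_effect_sd.setdefault(
                name, tuple(sd0 * r for r in _MODE_RELATIVE_SD)
            )
            self.noise_sd.setdefault(name, noise)
        self.risk_weights = {v: list(map(tuple, w)) for v, w in self.risk_weights.items()}

    def validate(self) -> None:
        if self.n_runners < 1:
            raise ValueError(f"n_runners must be >= 1, got {self.n_runners}")
        if self.segment_length_m not in (250, 500, 1000, "mixed"):
            raise ValueError(
                f"segment_length_m must be 250, 500, 1000 or 'mixed', got {self.segment_length_m}"
            )
        if len(self.variable_names) != 17 or "pace" not in self.variable_names:
            raise ValueError(
                "variable_names must have exactly 17 entries including 'pace'"
            )
        for var, sds in self.random_effect_sd.items():
            if any(s < 0 for s in sds):
                raise ValueError(f"random_effect_sd[{var!r}] has negative entries")
        for var, s in self.noise_sd.items():
            if s < 0:
                raise ValueError(f"noise_sd[{var!r}] is negative")
        if not 0.0 <= self.excluded_fraction <= 1.0:
            raise ValueError(
                f"excluded_fraction must be in [0, 1], got {self.excluded_fraction}"
            )
        if self.slowdown.htw_magnitude_range[0] <= 1.25:
            raise ValueError(
                "slowdown.htw_magnitude_range must start above 1.25 so HTW races "
                "satisfy the labeling rule"
            )
        if self.slowdown.nhtw_magnitude_range[1] >= 1.10:
            raise ValueError(
                "slowdown.nhtw_magnitude_range must stay below 1.10 so non-HTW "
                "races satisfy the labeling rule"
            )
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "slowdown" in d and isinstance(d["slowdown"], dict):
            sd = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in d["slowdown"].items()
            }
            d["slowdown"] = SlowdownParams(**sd)
        for key in ("population_means", "risk_weights"):
            if key in d:
                d[key] = {v: [tuple(p) for p in pts] for v, pts in d[key].items()}
        if "random_effect_sd" in d:
            d["random_effect_sd"] = {v: tuple(s) for v, s in d["random_effect_sd"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunnerRecord:
    """One synthetic runner: telemetry plus generator truth."""

    runner_id: str
    sex: str
    age_years: float
    finish_time_min: float
    segment_length_m: int
    first_half_mid_km: np.ndarray
    first_half: dict[str, np.ndarray]         # variable -> values at midpoints
    pace_start_m: np.ndarray                  # full-race pace profile
    pace_length_m: np.ndarray
    pace_s_per_km: np.ndarray
    latent_label: PaceLabel
    latent_risk: float
    mode_loadings: dict[str, np.ndarray]      # variable -> 3 loadings
    slowdown_onset_km: float
    slowdown_magnitude: float

    def pace_profile(self) -> PaceProfile:
        return PaceProfile(self.pace_start_m, self.pace_length_m, self.pace_s_per_km)


@dataclass
class CohortTelemetry:
    """A generated cohort: runner records plus the config that made them."""

    config: CohortConfig
    runners: list[RunnerRecord]

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "runner_id": r.runner_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "finish_time_min": r.finish_time_min,
                "segment_length_m": r.segment_length_m,
                "latent_label": r.latent_label.value,
                "latent_risk": r.latent_risk,
            }
            for r in self.runners
        ]
        return pd.DataFrame(rows)

    def telemetry_frame(self) -> pd.DataFrame:
        """Long-format telemetry: runner_id, segment_start_m, segment_length_m, variable, value."""
        parts = []
        for r in self.runners:
            seg = r.segment_length_m
            start = (r.first_half_mid_km * 1000.0 - seg / 2.0).round(3)
            for var, vals in r.first_half.items():
                if var == "pace":
                    continue
                parts.append(
                    pd.DataFrame(
                        {
                            "runner_id": r.runner_id,
                            "segment_start_m": start,
                            "segment_length_m": float(seg),
                            "variable": var,
                            "value": vals,
                        }
                    )
                )
            parts.append(
                pd.DataFrame(
                    {
                        "runner_id": r.runner_id,
                        "segment_start_m": r.pace_start_m,
                        "segment_length_m": r.pace_length_m,
                        "variable": "pace",
                        "value": r.pace_s_per_km,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tele, meta = out / "telemetry.csv", out / "metadata.csv"
        self.telemetry_frame().to_csv(tele, index=False)
        self.metadata_frame().to_csv(meta, index=False)
        return tele, meta

    def grouped_first_half(self) -> dict[int, tuple[list[str], np.ndarray, dict[str, np.ndarray]]]:
        """Runners grouped by segment length, with stacked first-half matrices.

        Returns {segment_length: (runner_ids, midpoints_km, {variable: (n, m) matrix})}.
        """
        groups: dict[int, list[RunnerRecord]] = {}
        for r in self.runners:
            groups.setdefault(r.segment_length_m, []).append(r)
        out = {}
        for seg, runners in sorted(groups.items()):
            ids = [r.runner_id for r in runners]
            mids = runners[0].first_half_mid_km
            mats = {
                var: np.stack([r.first_half[var] for r in runners])
                for var in self.config.variable_names
            }
            out[seg] = (ids, mids, mats)
        return out


def mode_functions(t_km: np.ndarray, domain: tuple[float, float] = FORM_DOMAIN) -> np.ndarray:
    """The three smooth random-effect modes evaluated at ``t_km`` -> (3, len).

    Legendre-type level / drift / curvature shapes, orthonormal under the
    length-normalised measure dt/T so loading SDs read in the variable's units.
    """
    s = (np.asarray(t_km, float) - domain[0]) / (domain[1] - domain[0])
    return np.stack(
        [
            np.ones_like(s),
            np.sqrt(3.0) * (2.0 * s - 1.0),
            np.sqrt(5.0) * (6.0 * s * s - 6.0 * s + 1.0),
        ]
    )


def _interp_curve(points: list[tuple[float, float]], t_km: np.ndarray) -> np.ndarray:
    pts = sorted(points)
    return np.interp(t_km, [p[0] for p in pts], [p[1] for p in pts])


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def risk_logit_sd(config: CohortConfig, n_grid: int = 2101) -> float:
    """SD of the latent logit over runners, by exact Gaussian propagation.

    The logit is linear in the (Gaussian) mode loadings, with coefficients
    ``sd_jm * <w_j, m_m>`` computed by trapezoid quadrature on a fine grid.
    """
    t = np.linspace(*FORM_DOMAIN, n_grid)
    modes = mode_functions(t)
    var = 0.0
    for v, points in config.risk_weights.items():
        w = _interp_curve(points, t)
        inner = np.trapezoid(w * modes, t, axis=1)
        sds = np.asarray(config.random_effect_sd[v])
        var += float(np.sum((sds * inner) ** 2))
    return float(np.sqrt(var))


def calibrate_intercept(config: CohortConfig) -> float:
    """Intercept making E[logistic(b0 + sigma Z)] equal the target prevalence."""
    sigma = risk_logit_sd(config)
    nodes, weights = hermgauss(81)
    weights = weights / np.sqrt(np.pi)

    def mean_prob(b0: float) -> float:
        return float(weights @ expit(b0 + sigma * np.sqrt(2.0) * nodes))

    target = config.target_prevalence
    return float(brentq(lambda b: mean_prob(b) - target, -30.0, 30.0, xtol=1e-10))


def _render_second_half(
    config: CohortConfig,
    seg: int,
    base_pace: float,
    onset_km: float,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second-half pace segments from the relative-pace ramp model."""
    sd = config.slowdown
    half_m = 1000.0 * FORM_DOMAIN[1]
    starts = np.arange(half_m, config.race_distance_m, float(seg))
    lengths = np.minimum(starts + seg, config.race_distance_m) - starts
    mid_km = (starts + lengths / 2.0) / 1000.0
    ratio = 1.0 + (magnitude - 1.0) * _smoothstep((mid_km - onset_km) / sd.ramp_km)
    noise_sd = sd.pace_noise_rel * np.sqrt(500.0 / seg)
    eps = np.clip(rng.standard_normal(len(starts)), -3.0, 3.0) * noise_sd
    return starts, lengths, base_pace * ratio * (1.0 + eps)


def render_runner(
    config: CohortConfig,
    runner_id: str,
    seg: int,
    sex: str,
    age: float,
    loadings: dict[str, np.ndarray],
    logit: float,
    label: PaceLabel,
    onset_km: float,
    magnitude: float,
    rng: np.random.Generator,
) -> RunnerRecord:
    """Render segment telemetry for one runner from its latent draws."""
    starts = np.arange(0.0, 1000.0 * FORM_DOMAIN[1], float(seg))
    mid_km = (starts + seg / 2.0) / 1000.0
    modes = mode_functions(mid_km)
    noise_scale = np.sqrt(500.0 / seg)
    first_half: dict[str, np.ndarray] = {}
    for var in config.variable_names:
        mean = _interp_curve(config.population_means[var], mid_km)
        dev = loadings[var] @ modes
        noise = config.noise_sd[var] * noise_scale * rng.standard_normal(len(mid_km))
        first_half[var] = mean + dev + noise
    # pace must stay physical; the floor is far below any plausible draw
    first_half["pace"] = np.maximum(first_half["pace"], 120.0)

    lo, hi = 5000.0, 20000.0
    in_base = (starts >= lo) & (starts + seg <= hi)
    base_pace = float(first_half["pace"][in_base].mean())
    s2, l2, p2 = _render_second_half(config, seg, base_pace, onset_km, magnitude, rng)
    pace_start = np.concatenate([starts, s2])
    pace_len = np.concatenate([np.full(len(starts), float(seg)), l2])
    pace = np.concatenate([first_half["pace"], p2])
    finish = float(np.sum(pace * pace_len / 1000.0) / 60.0)
    return RunnerRecord(
        runner_id=runner_id,
        sex=sex,
        age_years=age,
        finish_time_min=finish,
        segment_length_m=seg,
        first_half_mid_km=mid_km,
        first_half=first_half,
        pace_start_m=pace_start,
        pace_length_m=pace_len,
        pace_s_per_km=pace,
        latent_label=label,
        latent_risk=logit,
        mode_loadings=loadings,
        slowdown_onset_km=onset_km,
        slowdown_magnitude=magnitude,
    )


def generate_cohort(config: CohortConfig) -> CohortTelemetry:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    b0 = config.risk_intercept
    if b0 is None:
        b0 = calibrate_intercept(config)

    fine = np.linspace(*FORM_DOMAIN, 2101)
    fine_modes = mode_functions(fine)
    weight_inner = {
        v: np.trapezoid(_interp_curve(pts, fine) * fine_modes, fine, axis=1)
        for v, pts in config.risk_weights.items()
    }
    sd_table = {v: np.asarray(config.random_effect_sd[v], float) for v in config.variable_names}
    coupling = config.pace_coupling
    sdp = config.slowdown

    runners: list[RunnerRecord] = []
    width = len(str(config.n_runners))
    for i in range(config.n_runners):
        rid = f"R{i:0{width}d}"
        seg = (
            int(rng.choice([250, 500, 1000]))
            if config.segment_length_m == "mixed"
            else int(config.segment_length_m)
        )
        sex = "F" if rng.random() < config.female_fraction else "M"
        age = float(rng.normal(config.age_mean, config.age_sd))

        loadings = {v: sd_table[v] * rng.standard_normal(3) for v in config.variable_names}
        if coupling is not None:
            blend = np.zeros(3)
            for v, beta in coupling.items():
                if v == "residual":
                    continue
                blend += beta * loadings[v] / np.where(sd_table[v] > 0, sd_table[v], 1.0)
            blend += coupling.get("residual", 0.0) * rng.standard_normal(3)
            loadings["pace"] = sd_table["pace"] * blend

        logit = b0 + sum(
            float(loadings[v] @ weight_inner[v]) for v in weight_inner
        )
        if rng.random() < config.excluded_fraction:
            label = PaceLabel.EXCLUDED
            magnitude = float(rng.uniform(*sdp.excluded_magnitude_range))
        elif rng.random() < expit(logit):
            label = PaceLabel.HTW
            magnitude = float(rng.uniform(*sdp.htw_magnitude_range))
        else:
            label = PaceLabel.NHTW
            magnitude = float(rng.uniform(*sdp.nhtw_magnitude_range))
        onset = float(rng.uniform(*sdp.onset_range_km))
        runners.append(
            render_runner(
                config, rid, seg, sex, age, loadings, logit, label, onset, magnitude, rng
            )
        )
    return CohortTelemetry(config=config, runners=runners)


def resample_runner(
    cohort: CohortTelemetry, runner_id: str, segment_length_m: int, seed: int = 0
) -> RunnerRecord:
    """Re-render one runner's telemetry at a different segment length.

    The latent draws (mode loadings, outcome, slowdown) are reused; only the
    segment grid and the measurement noise are redrawn.
    """
    r = next(x for x in cohort.runners if x.runner_id == runner_id)
    return render_runner(
        cohort.config,
        r.runner_id,
        int(segment_length_m),
        r.sex,
        r.age_years,
        r.mode_loadings,
        r.latent_risk,
        r.latent_label,
        r.slowdown_onset_km,
        r.slowdown_magnitude,
        np.random.default_rng(seed),
    )


@dataclass
class LabelingConsistencyReport:
    """Latent-vs-labeled confusion of the generator's own cohort."""

    confusion: dict[tuple[str, str], int]
    n: int
    agreement: float
    mismatched_ids: list[str]


def apply_labeling_consistency(
    cohort: CohortTelemetry, rule: LabelRule = LabelRule()
) -> LabelingConsistencyReport:
    """Run the pace-label rule on every runner and compare with generator truth."""
    confusion: dict[tuple[str, str], int] = {}
    mismatched = []
    for r in cohort.runners:
        if r.latent_label is None:
            raise ValueError(f"runner {r.runner_id} has no latent label")
        labeled = classify_race(r.pace_profile(), rule)
        key = (r.latent_label.value, labeled.value)
        confusion[key] = confusion.get(key, 0) + 1
        if labeled != r.latent_label:
            mismatched.append(r.runner_id)
    n = len(cohort.runners)
    agree = sum(c for (a, b), c in confusion.items() if a == b)
    return LabelingConsistencyReport(confusion, n, agree / n if n else 1.0, mismatched)


def load_cohort_csv(
    telemetry_path: str | Path, metadata_path: str | Path, config: CohortConfig | None = None
) -> CohortTelemetry:
    """Rebuild a cohort object from the long-format telemetry + metadata CSVs."""
    tele = pd.read_csv(telemetry_path)
    meta = pd.read_csv(metadata_path).set_index("runner_id")
    config = config or CohortConfig(n_runners=max(1, len(meta)))
    runners = []
    for rid, df in tele.groupby("runner_id", sort=False):
        m = meta.loc[rid]
        seg = int(m["segment_length_m"])
        pace = df[df["variable"] == "pace"].sort_values("segment_start_m")
        half_m = 1000.0 * FORM_DOMAIN[1]
        first_half = {}
        fh = df[(df["variable"] != "pace") & (df["segment_start_m"] < half_m)]
        mid_km = None
        for var, vdf in fh.groupby("variable"):
            vdf = vdf.sort_values("segment_start_m")
            mid_km = (vdf["segment_start_m"].to_numpy() + seg / 2.0) / 1000.0
            first_half[var] = vdf["value"].to_numpy()
        fh_pace = pace[pace["segment_start_m"] < half_m]
        first_half["pace"] = fh_pace["value"].to_numpy()
        runners.append(
            RunnerRecord(
                runner_id=str(rid),
                sex=str(m["sex"]),
                age_years=float(m["age_years"]),
                finish_time_min=float(m["finish_time_min"]),
                segment_length_m=seg,
                first_half_mid_km=mid_km,
                first_half=first_half,
                pace_start_m=pace["segment_start_m"].to_numpy(float),
                pace_length_m=pace["segment_length_m"].to_numpy(float),
                pace_s_per_km=pace["value"].to_numpy(float),
                latent_label=PaceLabel(m["latent_label"]) if "latent_label" in m else None,
                latent_risk=float(m.get("latent_risk", np.nan)),
                mode_loadings={},
                slowdown_onset_km=np.nan,
                slowdown_magnitude=np.nan,
            )
        )
    return CohortTelemetry(config=config, runners=runners)
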
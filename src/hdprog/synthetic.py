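"""Synthetic conversion-aligned cohort generator.

Emulates the statistical structure of a two-group longitudinal volumetric
study around Huntington's disease motor conversion: 49 HD gene carriers and
49 age-matched controls, 3-7 annual MRI visits each inside the window
t in [-6, 5] years around conversion, region-specific exponential atrophy
with group offsets at diagnosis and CAG-dependent decay concentrated in
striatal / occipital / parietal regions, a strong negative CAG - onset-age
correlation, additive measurement noise, and motor (TMS) / cognitive (SDMT)
scores generated as linear readouts of the latent states on a [0, 100]
worsening scale.

Default numerical calibrations (visit-count laws, CAG marginal, copula
correlation, striatal decay rates, behavioral decade changes) reproduce the
published summary statistics of the cohort this generator emulates; see
docs/methods.md for every default and its justification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import RegionalTimeSeries, Subject
from .regions import (
    BEHAVIOR_CHANNELS,
    N_STATES,
    REGION_STATE_INDEX,
    STATE_LOBES,
    STATE_NAMES,
)

SITES = ["Leiden", "London", "Paris", "Vancouver"]


class InvalidConfigError(ValueError):
    """Raised for infeasible generator configurations."""


# ---------------------------------------------------------------------------
# calibrated default laws
# ---------------------------------------------------------------------------

#: HD visit-count law on {3..7}: mean 5.83, sd 1.63
DEFAULT_VISIT_LAW_HD = {3: 0.18, 4: 0.10, 5: 0.04, 6: 0.07, 7: 0.61}
#: control visit-count law on {3..7}: mean 6.09, sd 1.47
DEFAULT_VISIT_LAW_CONTROL = {3: 0.13, 4: 0.07, 5: 0.05, 6: 0.08, 7: 0.67}

#: CAG marginal: discretized truncated normal on [39, 50] whose discretized
#: moments are exactly mean 43.67 / sd 2.77
_CAG_LOC, _CAG_SCALE = 43.242322, 3.448911
#: attenuation of the Pearson correlation induced by discretizing the CAG
#: margin of the Gaussian copula (measured once at large n)
_CAG_COPULA_ATTENUATION = 0.98429

#: reference CAG around which the decay slope is centered
CAG_REFERENCE = 42

#: per-decade fractional volume loss implied by decay a over 10 years
def decade_loss_from_decay(a: float) -> float:
    return 100.0 * (1.0 - np.exp(10.0 * a))


def decay_from_decade_loss(loss_percent: float) -> float:
    """Per-year decay rate a (negative) giving the stated % loss per decade."""
    return float(np.log(1.0 - loss_percent / 100.0) / 10.0)


# HD per-year decay-rate magnitudes (the generator uses a = -rate).  Striatal
# values are set from the published decade losses (18.7% putamen, 15.4%
# caudate); cortical values by lobe follow the published ordering (occipital
# and parietal fastest).
_LOBE_DECADE_LOSS_HD = {
    "frontal": 3.5, "parietal": 6.0, "occipital": 6.5, "temporal": 3.0,
    "limbic": 3.0, "white_matter": 5.0,
}


def _default_true_decay() -> dict[str, dict[str, float]]:
    hd = {}
    for name in STATE_NAMES:
        if name == "putamen":
            hd[name] = -decay_from_decade_loss(18.7)
        elif name == "caudate":
            hd[name] = -decay_from_decade_loss(15.4)
        else:
            hd[name] = -decay_from_decade_loss(_LOBE_DECADE_LOSS_HD[STATE_LOBES[name]])
    control = {name: -decay_from_decade_loss(1.0) for name in STATE_NAMES}
    return {"HD": hd, "control": control}


def _default_group_offset() -> dict[str, float]:
    """HD minus control volume offset (% points) at t = 0, by state."""
    by_lobe = {"frontal": -2.0, "parietal": -2.5, "occipital": -3.0,
               "temporal": -2.0, "limbic": -1.5, "white_matter": -3.0}
    off = {name: by_lobe[STATE_LOBES[name]] for name in STATE_NAMES
           if STATE_LOBES[name] != "striatal"}
    off["caudate"] = -10.0
    off["putamen"] = -12.0
    return off


def _default_cag_slope() -> dict[str, float]:
    """Additional per-year decay per CAG unit above the reference, by state."""
    slope = {name: 0.0 for name in STATE_NAMES}
    for name in STATE_NAMES:
        lobe = STATE_LOBES[name]
        if lobe == "striatal":
            slope[name] = 5.0e-4
        elif lobe == "occipital":
            slope[name] = 8.0e-4
        elif lobe == "parietal":
            slope[name] = 4.0e-4
    return slope


def _default_cag_law() -> dict[int, float]:
    vals = np.arange(39, 51)
    p = stats.norm.pdf(vals, _CAG_LOC, _CAG_SCALE)
    p = p / p.sum()
    return {int(v): float(q) for v, q in zip(vals, p)}


# unit (pre-calibration) behavioral readout patterns; negative weights make
# scores rise as volumes fall (increase = worsening)
_TMS_PATTERN_REGIONS = [
    "entorhinal_area", "cingulate_gyrus", "parahippocampal_gyrus", "caudate",
    "calcarine_cortex", "supplementary_motor_cortex", "temporal_pole",
    "middle_frontal_gyrus", "lingual_gyrus", "cuneus", "planum_temporale",
]
_SDMT_PATTERN_REGIONS = {
    "cingulate_gyrus": -1.0, "orbital_gyrus": -1.0, "occipital_gyrus": -1.0,
    "lingual_gyrus": -1.0, "entorhinal_area": -1.0, "putamen": 0.5,
}

#: target mean noise-free score increase over the decade t = -6 .. +4
BEHAVIOR_DECADE_TARGETS = {"tms": 57.80, "sdmt": 16.78}
#: target mean noise-free score at window start t = -6
_BEHAVIOR_START_LEVEL = 20.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the calibrated study
    conditions.  Maps over states may be partial: missing states get 0."""

    n_hd: int = 49
    n_control: int = 49
    visit_count_law: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_LAW_HD))
    control_visit_count_law: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_LAW_CONTROL))
    time_window: tuple[float, float] = (-6.0, 5.0)
    region_labels: tuple[str, ...] = tuple(STATE_NAMES)
    true_decay: dict[str, dict[str, float]] = field(default_factory=_default_true_decay)
    group_offset: dict[str, float] = field(default_factory=_default_group_offset)
    cag_slope: dict[str, float] = field(default_factory=_default_cag_slope)
    cag_law: dict[int, float] = field(default_factory=_default_cag_law)
    cag_onset_corr: float = -0.85
    age_mean: float = 44.59
    age_sd: float = 9.28
    p_female: dict[str, float] = field(
        default_factory=lambda: {"HD": 0.551, "control": 0.61})
    site_laws: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "HD": {"Leiden": 0.449, "London": 0.204, "Paris": 0.204,
               "Vancouver": 0.143},
        "control": {"Leiden": 0.2857, "London": 0.2041, "Paris": 0.2857,
                    "Vancouver": 0.2245},
    })
    noise_sd: float = 1.0
    behavior_weights: dict[str, dict[str, float]] | None = None
    behavior_intercepts: dict[str, float] | None = None
    behavior_noise_sd: float = 2.0
    behavior_decade_targets: dict[str, float] = field(
        default_factory=lambda: dict(BEHAVIOR_DECADE_TARGETS))
    seed: int = 0

    def __post_init__(self):
        for law in (self.visit_count_law, self.control_visit_count_law):
            if not set(law) <= {3, 4, 5, 6, 7}:
                raise InvalidConfigError("visit count support must be within 3..7")
            if abs(sum(law.values()) - 1.0) > 1e-8 or min(law.values()) < 0:
                raise InvalidConfigError("visit count law must be a distribution")
        if self.noise_sd < 0 or self.behavior_noise_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        if not all(isinstance(k, (int, np.integer)) and 39 <= k <= 50
                   for k in self.cag_law):
            raise InvalidConfigError("CAG support must be integers in [39, 50]")
        if abs(sum(self.cag_law.values()) - 1.0) > 1e-8:
            raise InvalidConfigError("cag_law must be a distribution")
        if abs(self.cag_onset_corr) >= 1:
            raise InvalidConfigError("|cag_onset_corr| must be < 1")
        lo, hi = self.time_window
        if hi - lo < max(self.visit_count_law) - 1:
            raise InvalidConfigError("time window too short for the visit law")
        for name in self.group_offset:
            self._state_index(name)
        for name in self.cag_slope:
            self._state_index(name)
        if self.behavior_weights is None:
            w, b = calibrate_behavior_weights(self)
            self.behavior_weights, self.behavior_intercepts = w, b
        else:
            for ch, wmap in self.behavior_weights.items():
                for name in wmap:
                    self._state_index(name)
            if self.behavior_intercepts is None:
                self.behavior_intercepts = {ch: 0.0 for ch in self.behavior_weights}

    def _state_index(self, name: str) -> int:
        try:
            return STATE_NAMES.index(name)
        except ValueError:
            raise InvalidConfigError(f"unknown region-state {name!r}") from None

    # ---- vectorized views -------------------------------------------------
    def decay_vector(self, group: str) -> np.ndarray:
        d = self.true_decay[group]
        return np.array([d.get(name, 0.0) for name in STATE_NAMES])

    def offset_vector(self) -> np.ndarray:
        return np.array([self.group_offset.get(name, 0.0) for name in STATE_NAMES])

    def cag_slope_vector(self) -> np.ndarray:
        return np.array([self.cag_slope.get(name, 0.0) for name in STATE_NAMES])

    def weight_vector(self, channel: str) -> np.ndarray:
        wmap = self.behavior_weights[channel]
        return np.array([wmap.get(name, 0.0) for name in STATE_NAMES])

    def x0_for_subject(self, group: str) -> np.ndarray:
        off = self.offset_vector()
        return 100.0 + (off / 2.0 if group == "HD" else -off / 2.0)


def _decay_a(config: CohortConfig, group: str, cag: int | None) -> np.ndarray:
    """Per-year decay a_i = -(true_decay + cag_slope (CAG - 42)) (negative
    for atrophy) for one subject."""
    rate = config.decay_vector(group)
    if group == "HD" and cag is not None:
        rate = rate + config.cag_slope_vector() * (cag - CAG_REFERENCE)
    return -rate


def mean_hd_state_trajectory(config: CohortConfig, times) -> np.ndarray:
    """Expected noise-free HD latent states at ``times``, averaged over the
    CAG law (exact: the law has finite support)."""
    times = np.atleast_1d(np.asarray(times, float))
    x0 = config.x0_for_subject("HD")
    out = np.zeros((len(times), N_STATES))
    for cag, p in config.cag_law.items():
        a = _decay_a(config, "HD", cag)
        out += p * x0[None, :] * np.exp(np.outer(times, a))
    return out


def calibrate_behavior_weights(config: CohortConfig):
    """Scale the unit readout patterns so the expected noise-free decade
    change (t = -6 .. +4) of each channel equals its configured target, and
    set intercepts so the expected score at t = -6 is a safe on-scale level."""
    patterns = {
        "tms": {name: -1.0 for name in _TMS_PATTERN_REGIONS},
        "sdmt": dict(_SDMT_PATTERN_REGIONS),
    }
    xs = mean_hd_state_trajectory(config, [-6.0, 4.0])
    weights, intercepts = {}, {}
    for ch in BEHAVIOR_CHANNELS:
        v = np.array([patterns[ch].get(name, 0.0) for name in STATE_NAMES])
        delta = float(v @ (xs[1] - xs[0]))
        if abs(delta) < 1e-12:
            raise InvalidConfigError(
                f"behavior pattern for {ch} produces no decade change")
        scale = config.behavior_decade_targets[ch] / delta
        w = v * scale
        weights[ch] = {name: float(w[i]) for i, name in enumerate(STATE_NAMES)
                       if w[i] != 0.0}
        intercepts[ch] = float(_BEHAVIOR_START_LEVEL - w @ xs[0])
    return weights, intercepts


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_visit_schedule(config: CohortConfig, n: int, seed: int,
                          group: str = "HD") -> list[np.ndarray]:
    """Draw ``n`` annual-spaced visit-time vectors inside the window.

    The visit count follows the group's count law; the window placement is
    uniform over alignments that keep every visit inside ``time_window`` and
    include the conversion point t = 0.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    law = (config.visit_count_law if group == "HD"
           else config.control_visit_count_law)
    lo, hi = config.time_window
    if hi - lo < max(law) - 1:
        raise InvalidConfigError("time window too short to host the visit count")
    rng = np.random.default_rng(seed)
    counts = rng.choice(list(law), size=n, p=list(law.values()))
    schedules = []
    for k in counts:
        start_lo = int(np.ceil(max(lo, -(k - 1))))
        start_hi = int(np.floor(min(0, hi - (k - 1))))
        start = rng.integers(start_lo, start_hi + 1)
        schedules.append(start + np.arange(k, dtype=float))
    return schedules


def sample_covariates(config: CohortConfig, seed: int) -> list[Subject]:
    """Draw subjects with covariates and visit schedules.

    HD subjects get (CAG, age at conversion) from a Gaussian copula whose
    latent correlation is inflated for discretization so the sample Pearson
    correlation approaches ``cag_onset_corr``; each control mirrors the age
    of its matched HD partner (age-matched alignment by construction).
    """
    if not -1 < config.cag_onset_corr <= 0:
        raise InvalidConfigError("cag_onset_corr must be in (-1, 0]")
    ss = np.random.SeedSequence(seed)
    rng_cov, rng_sched_hd, rng_sched_c = [
        np.random.default_rng(s) for s in ss.spawn(3)]

    rho = np.clip(config.cag_onset_corr / _CAG_COPULA_ATTENUATION,
                  -0.999999, 0.0)
    L = np.array([[1.0, 0.0], [rho, np.sqrt(1 - rho**2)]])
    z = rng_cov.standard_normal((config.n_hd, 2)) @ L.T
    cag_vals = np.array(sorted(config.cag_law))
    cdf = np.cumsum([config.cag_law[v] for v in cag_vals])
    u = stats.norm.cdf(z[:, 0])
    cags = cag_vals[np.searchsorted(cdf, u, side="left").clip(0, len(cag_vals) - 1)]
    ages = config.age_mean + config.age_sd * z[:, 1]

    sched_hd = ([] if config.n_hd == 0 else sample_visit_schedule(
        config, config.n_hd, rng_sched_hd.integers(2**31), group="HD"))
    sched_c = ([] if config.n_control == 0 else sample_visit_schedule(
        config, config.n_control, rng_sched_c.integers(2**31), group="control"))

    def draw_site(group):
        law = config.site_laws[group]
        return rng_cov.choice(list(law), p=np.array(list(law.values()))
                              / sum(law.values()))

    def draw_tiv(gender):
        mean = 1550.0 if gender == "M" else 1400.0
        return float(rng_cov.normal(mean, 110.0))

    subjects = []
    for i in range(config.n_hd):
        gender = "F" if rng_cov.random() < config.p_female["HD"] else "M"
        subjects.append(Subject(
            id=f"hd{i:03d}", group="HD", cag=int(cags[i]), gender=gender,
            age_at_alignment=float(ages[i]), tiv=draw_tiv(gender),
            site=str(draw_site("HD")), visit_times=sched_hd[i]))
    for i in range(config.n_control):
        gender = "F" if rng_cov.random() < config.p_female["control"] else "M"
        # controls mirror the ages of their matched HD partners
        age = float(ages[i % config.n_hd]) if config.n_hd else config.age_mean
        subjects.append(Subject(
            id=f"ct{i:03d}", group="control", cag=None, gender=gender,
            age_at_alignment=age, tiv=draw_tiv(gender),
            site=str(draw_site("control")), visit_times=sched_c[i]))
    return subjects


def generate_behavior(states: np.ndarray, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Behavioral scores from latent states: w . x + b + noise, clipped to
    [0, 100]; an increase indicates worsening."""
    states = np.asarray(states, float)
    if states.ndim != 2 or states.shape[1] != N_STATES:
        raise InvalidConfigError("states must be [time x 28]")
    out = np.empty((states.shape[0], len(BEHAVIOR_CHANNELS)))
    for j, ch in enumerate(BEHAVIOR_CHANNELS):
        w = config.weight_vector(ch)
        out[:, j] = states @ w + config.behavior_intercepts[ch]
    if rng is not None and config.behavior_noise_sd > 0:
        out = out + rng.normal(0.0, config.behavior_noise_sd, out.shape)
    return np.clip(out, 0.0, 100.0)


def generate_cohort(config: CohortConfig):
    """Generate (subjects, regional time series); deterministic given seed.

    Volumes follow x_i(t) = x_i(0) exp(a_i t) per bilateral state, with
    a_i = -(true_decay + cag_slope (CAG - 42)) for HD, group-specific
    offsets at t = 0, both hemisphere columns read from the shared state,
    plus i.i.d. Gaussian measurement noise.  Behavioral scores are generated
    for HD subjects only.
    """
    master = np.random.default_rng(config.seed)
    seed_cov, seed_noise, seed_beh = master.integers(2**31, size=3)
    subjects = sample_covariates(config, int(seed_cov))
    rng_noise = np.random.default_rng(seed_noise)
    rng_beh = np.random.default_rng(seed_beh)

    series = []
    for s in subjects:
        a = _decay_a(config, s.group, s.cag)
        x0 = config.x0_for_subject(s.group)
        states = x0[None, :] * np.exp(np.outer(s.visit_times, a))
        clean = states[:, REGION_STATE_INDEX]
        if np.any(clean <= 0) or not np.all(np.isfinite(clean)):
            raise InvalidConfigError(
                f"configuration produces non-positive volumes for {s.id}")
        vols = clean + rng_noise.normal(0.0, config.noise_sd, clean.shape)
        vols = np.maximum(vols, 1e-3)  # measurement noise cannot cross zero
        behavior = None
        if s.group == "HD":
            behavior = generate_behavior(states, config, rng_beh)
        series.append(RegionalTimeSeries(
            subject_id=s.id, times=s.visit_times, volumes=vols,
            behavior=behavior))
    return subjects, series


def rescale_scores(raw_scores, hd_sample_min: float, hd_sample_max: float,
                   higher_is_worse: bool) -> np.ndarray:
    """Affine map of raw clinical scores onto [0, 100], oriented so that an
    increase indicates worsening; min/max are taken from the HD sample."""
    if not hd_sample_max > hd_sample_min:
        raise InvalidConfigError("degenerate score range: max must exceed min")
    raw = np.asarray(raw_scores, float)
    scaled = (raw - hd_sample_min) / (hd_sample_max - hd_sample_min) * 100.0
    return scaled if higher_is_worse else 100.0 - scaled
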
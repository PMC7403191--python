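"""Seeded synthetic cohorts emulating the orthopedic-injury immunophenotyping study.

The generator produces per-cell event tables for a cross-sectional cohort
(default 8 mice per sex per timepoint at baseline, 12 h, 7 d and 7 wk, each
animal sampled once, mirroring terminal blood collection), with 21 immune
populations separable by a 20-marker surface panel and 12 functional markers
per cell.  Functional intensities are drawn directly on the arcsinh scale as
Gaussians — the analysis consumes arcsinh medians only — with configurable
sex-by-time effects injected as shifts of the generating median.  Ground
truth (realized frequencies and generating medians) is recorded for
parameter-recovery tests.

Also provides generators for the behavioral inputs: per-paw gait tables with
a controlled fraction of truly shifted parameters, and von Frey up-down
response sequences under a logistic psychometric model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior
from .behavior import NO_RESPONSE, RESPONSE, VonFreyTrial
from .gating import (
    DEFAULT_POPULATIONS,
    EventTable,
    default_gating_scheme,
    population_signature,
)
from .panel import FREQUENCY, PanelConfig

TIMEPOINTS: tuple[str, ...] = ("BL", "12h", "7d", "7wk")
SEXES: tuple[str, ...] = ("M", "F")


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class EffectSpec:
    """One injected ground-truth effect.

    ``marker`` is a functional marker name or ``FREQUENCY``; ``delta`` shifts
    the arcsinh-scale generating median (functional markers) or adds to the
    baseline mixture fraction (frequency), for the given sexes at the given
    timepoint.
    """

    population: str
    marker: str
    timepoint: str
    sex_scope: str  # "M", "F" or "both"
    delta: float

    def applies(self, sex: str, timepoint: str) -> bool:
        return self.timepoint == timepoint and self.sex_scope in (sex, "both")


@dataclass(frozen=True)
class PopulationSpec:
    """Name, per-sex baseline mixture fraction, and surface signature."""

    name: str
    base_frequency: dict[str, float]  # sex -> fraction of events
    surface_means: dict[str, float]  # marker -> arcsinh mean


# Baseline mixture fractions (fraction of all events).  Only the neutrophil
# fraction is sex-specific (male > female), offset in B cells so both sexes
# sum to the same total.
_BASE_FREQUENCIES: dict[str, float | dict[str, float]] = {
    "Neutrophils": {"M": 0.21, "F": 0.15},
    "cMC": 0.06, "intMC": 0.01, "ncMC": 0.03, "Macrophages": 0.01,
    "mDC": 0.02, "pDC": 0.01, "Eosinophils": 0.02, "Basophils": 0.005,
    "NK": 0.05, "ILC": 0.005, "NKT": 0.01, "gdT": 0.01,
    "Bcells": {"M": 0.17, "F": 0.23},
    "Bmem": 0.05, "Plasmablasts": 0.005,
    "CD4Tnaive": 0.12, "CD4Tmem": 0.04, "Tregs": 0.02,
    "CD8Tnaive": 0.08, "CD8Tmem": 0.03,
}

# Cosmetic high markers not used by any gate (kept realistic).
_EXTRA_HI = {
    "Neutrophils": ("CD11b",), "cMC": ("CD11b",), "intMC": ("CD11b",),
    "ncMC": ("CD11b",), "Macrophages": ("CD11b",), "Eosinophils": ("CD11b",),
    "Basophils": ("CD11b",),
}


def default_populations(
    surface_hi: float = 6.5, surface_lo: float = 0.3
) -> tuple[PopulationSpec, ...]:
    """The 21 default populations with gate-consistent surface signatures."""
    scheme = default_gating_scheme()
    specs = []
    for name in DEFAULT_POPULATIONS:
        sig = population_signature(scheme, name, hi=surface_hi, lo=surface_lo)
        for extra in _EXTRA_HI.get(name, ()):
            sig.setdefault(extra, surface_hi)
        freq = _BASE_FREQUENCIES[name]
        if not isinstance(freq, dict):
            freq = {"M": freq, "F": freq}
        specs.append(PopulationSpec(name=name, base_frequency=dict(freq), surface_means=sig))
    return tuple(specs)


def default_effects() -> tuple[EffectSpec, ...]:
    """Default injected effect template.

    Emulates the reported sex-divergent findings — female-elevated neutrophil
    pSTAT3 and female-suppressed Treg pSTAT1/pSTAT6 in the immediate
    postoperative phase, female-elevated CD4 memory T-cell MAPK signaling
    (p-p38, pNFkB, pERK) in the subacute phase — together with sex-shared
    injury kinetics (neutrophil CD62L shedding and expansion at 12 h,
    classical-monocyte CD62L up-then-down and pSTAT3 activation).
    """
    return (
        EffectSpec("Neutrophils", "pSTAT3", "12h", "F", +1.2),
        EffectSpec("Tregs", "pSTAT1", "12h", "F", -1.0),
        EffectSpec("Tregs", "pSTAT6", "12h", "F", -1.0),
        EffectSpec("CD4Tmem", "p-p38", "7d", "F", +1.0),
        EffectSpec("CD4Tmem", "pNFkB", "7d", "F", +1.0),
        EffectSpec("CD4Tmem", "pERK", "7d", "F", +1.0),
        EffectSpec("Neutrophils", "CD62L", "12h", "both", -1.0),
        EffectSpec("cMC", "CD62L", "12h", "both", +1.0),
        EffectSpec("cMC", "CD62L", "7d", "both", -0.8),
        EffectSpec("cMC", "pSTAT3", "12h", "both", +1.0),
        EffectSpec("Neutrophils", FREQUENCY, "12h", "both", +0.08),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Design of one synthetic cohort.

    ``n_per_group`` animals per sex per timepoint are generated, each a
    distinct animal (cross-sectional design).  Functional markers are drawn
    on the arcsinh scale as N(baseline + animal-level shift + injected
    deltas, ``functional_sd``), where the animal-level shift decomposes into
    a global factor, a per-population factor and independent per-feature
    noise (``global_factor_sd``, ``population_factor_sd``,
    ``between_animal_sd``).
    """

    n_per_group: int = 8
    timepoints: tuple[str, ...] = TIMEPOINTS
    populations: tuple[PopulationSpec, ...] = field(default_factory=default_populations)
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    events_per_sample: int = 2000
    functional_baseline: float = 2.0
    functional_sd: float = 0.5
    # Animal-level biological variation of the functional medians (arcsinh
    # units): independent per-feature noise plus a global inflammatory-tone
    # factor shared by every feature of an animal and a per-population
    # factor, so immune features are intercorrelated within an animal as in
    # real cytometry cohorts.
    between_animal_sd: float = 0.08
    global_factor_sd: float = 0.10
    population_factor_sd: float = 0.10
    surface_sd: float = 0.4
    freq_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        if self.events_per_sample < 1:
            raise ConfigError("events_per_sample must be >= 1")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        for sex in SEXES:
            total = sum(p.base_frequency.get(sex, 0.0) for p in self.populations)
            if total > 1.0 + 1e-9:
                raise ConfigError(f"population frequencies for sex {sex!r} sum to {total} > 1")

    def validate_effects(self, panel: PanelConfig) -> None:
        names = {p.name for p in self.populations}
        for eff in self.effects:
            if eff.population not in names:
                raise ConfigError(f"effect references unknown population {eff.population!r}")
            if eff.marker != FREQUENCY and eff.marker not in panel.functional_markers:
                raise ConfigError(f"effect references unknown marker {eff.marker!r}")
            if eff.timepoint not in self.timepoints:
                raise ConfigError(f"effect references unknown timepoint {eff.timepoint!r}")
            if eff.sex_scope not in ("M", "F", "both"):
                raise ConfigError(f"invalid sex_scope {eff.sex_scope!r}")


def cohort_config_to_yaml(config: CohortConfig, path) -> None:
    """Serialize a cohort configuration (populations, effects, noise model)."""
    import yaml

    doc = {
        "n_per_group": config.n_per_group,
        "timepoints": list(config.timepoints),
        "events_per_sample": config.events_per_sample,
        "functional_baseline": config.functional_baseline,
        "functional_sd": config.functional_sd,
        "between_animal_sd": config.between_animal_sd,
        "global_factor_sd": config.global_factor_sd,
        "population_factor_sd": config.population_factor_sd,
        "surface_sd": config.surface_sd,
        "freq_jitter_sd": config.freq_jitter_sd,
        "seed": config.seed,
        "populations": [
            {"name": p.name, "base_frequency": dict(p.base_frequency),
             "surface_means": dict(p.surface_means)}
            for p in config.populations
        ],
        "effects": [
            {"population": e.population, "marker": e.marker,
             "timepoint": e.timepoint, "sex_scope": e.sex_scope,
             "delta": e.delta}
            for e in config.effects
        ],
    }
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def cohort_config_from_yaml(path) -> CohortConfig:
    import yaml
    from pathlib import Path

    doc = yaml.safe_load(Path(path).read_text())
    doc["timepoints"] = tuple(doc["timepoints"])
    doc["populations"] = tuple(
        PopulationSpec(p["name"], p["base_frequency"], p["surface_means"])
        for p in doc["populations"]
    )
    doc["effects"] = tuple(EffectSpec(**e) for e in doc["effects"])
    return CohortConfig(**doc)


def without_effects(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with all injected effects removed (null cohort)."""
    return replace(config, effects=())


#: Reduced population roster used by simulation studies: 8 populations
#: x (1 frequency + 12 functional markers) = 104 features, covering every
#: population carrying a default injected effect.
SIM_POPULATIONS: tuple[str, ...] = (
    "Neutrophils", "cMC", "NK", "Bcells", "CD4Tnaive", "CD4Tmem",
    "Tregs", "CD8Tnaive",
)


def simulation_cohort_config(
    populations: tuple[str, ...] = SIM_POPULATIONS,
    n_per_group: int = 8,
    events_per_sample: int = 600,
    effect_timepoints: tuple[str, ...] | None = None,
    null: bool = False,
    seed: int = 0,
) -> CohortConfig:
    """Reduced-scale cohort for calibration/power simulation studies.

    Baseline population frequencies are equalized between sexes so the only
    sex signal is the injected effect template, optionally restricted to
    ``effect_timepoints``; ``null=True`` removes all effects.
    """
    keep = set(populations)
    pops = []
    for p in default_populations():
        if p.name not in keep:
            continue
        mean_freq = float(np.mean(list(p.base_frequency.values())))
        pops.append(replace(p, base_frequency={"M": mean_freq, "F": mean_freq}))
    effects: tuple[EffectSpec, ...] = ()
    if not null:
        effects = tuple(
            e for e in default_effects()
            if e.population in keep
            and (effect_timepoints is None or e.timepoint in effect_timepoints)
        )
    return CohortConfig(
        n_per_group=n_per_group,
        populations=tuple(pops),
        effects=effects,
        events_per_sample=events_per_sample,
        seed=seed,
    )


def generate_cohort(
    config: CohortConfig, panel: PanelConfig | None = None, seed: int | None = None
) -> tuple[EventTable, pd.DataFrame]:
    """Generate one cohort; returns (events, ground_truth).

    Ground truth is a long table with one row per sample x population x
    (FREQUENCY or functional marker): the realized mixture fraction and the
    generating arcsinh median actually used for that sample.  The in-memory
    event table additionally carries a per-cell ``true_population`` column
    (generator ground truth for label-recovery tests; marker files written
    to disk contain only the panel channels).
    """
    panel = panel or PanelConfig()
    config.validate_effects(panel)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    pops = config.populations
    fmarkers = list(panel.functional_markers)
    smarkers = list(panel.surface_markers)
    surface_lo = min(min(p.surface_means.values()) for p in pops)

    rows = []
    truth_rows = []
    animal_counter = 0
    for tp in config.timepoints:
        for sex in SEXES:
            for _ in range(config.n_per_group):
                animal_counter += 1
                animal_id = f"m{animal_counter:03d}"
                sample_id = f"{tp}_{sex}_{animal_id}"

                # mixture fractions: baseline + frequency effects, jittered
                base = np.array([p.base_frequency[sex] for p in pops])
                for eff in config.effects:
                    if eff.marker == FREQUENCY and eff.applies(sex, tp):
                        i = next(k for k, p in enumerate(pops) if p.name == eff.population)
                        base[i] += eff.delta
                base = np.clip(base, 1e-6, None)
                jitter = np.exp(rng.normal(0.0, config.freq_jitter_sd, size=len(pops)))
                probs = base * jitter
                probs /= probs.sum()
                counts = rng.multinomial(config.events_per_sample, probs)

                # animal-level functional medians: global tone + population
                # factor + independent feature noise
                g_global = rng.normal(0.0, config.global_factor_sd)
                g_pop = rng.normal(0.0, config.population_factor_sd, size=len(pops))
                animal_shift = (
                    g_global + g_pop[:, None]
                    + rng.normal(0.0, config.between_animal_sd,
                                 size=(len(pops), len(fmarkers)))
                )
                arc_parts: list[np.ndarray] = []
                pop_col: list[str] = []
                for ip, pop in enumerate(pops):
                    medians = np.full(len(fmarkers), config.functional_baseline)
                    medians += animal_shift[ip]
                    for eff in config.effects:
                        if (eff.marker != FREQUENCY and eff.population == pop.name
                                and eff.applies(sex, tp)):
                            medians[fmarkers.index(eff.marker)] += eff.delta

                    n = int(counts[ip])
                    if n > 0:
                        surf_mu = np.array(
                            [pop.surface_means.get(m, surface_lo) for m in smarkers]
                        )
                        surf = rng.normal(surf_mu, config.surface_sd, size=(n, len(smarkers)))
                        func = rng.normal(medians, config.functional_sd,
                                          size=(n, len(fmarkers)))
                        arc_parts.append(np.hstack([surf, func]))
                        pop_col.extend([pop.name] * n)

                    truth_rows.append({
                        "sample_id": sample_id, "animal_id": animal_id, "sex": sex,
                        "timepoint": tp, "population": pop.name, "marker": FREQUENCY,
                        "value": n / config.events_per_sample,
                    })
                    for im, m in enumerate(fmarkers):
                        truth_rows.append({
                            "sample_id": sample_id, "animal_id": animal_id, "sex": sex,
                            "timepoint": tp, "population": pop.name, "marker": m,
                            "value": medians[im],
                        })

                raw = panel.inverse_arcsinh(np.vstack(arc_parts))
                block = pd.DataFrame(raw, columns=smarkers + fmarkers)
                block.insert(0, "true_population", pop_col)
                block.insert(0, "timepoint", tp)
                block.insert(0, "sex", sex)
                block.insert(0, "animal_id", animal_id)
                block.insert(0, "sample_id", sample_id)
                rows.append(block)

    data = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return EventTable(data=data, panel=panel), truth


# ---------------------------------------------------------------------------
# Gait tables
# ---------------------------------------------------------------------------

def generate_gait_table(
    n_params: int = 42,
    n_mice: int = 8,
    effect_fraction: float = 0.0,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    paw: str = "RH",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-paw gait table: baseline and day-7 rows for ``n_mice`` mice.

    A fraction ``effect_fraction`` of the parameters carries a true mean
    shift of ``effect_size * noise_sd`` at day 7; the rest are null.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if not 0.0 <= effect_fraction <= 1.0:
        raise ValueError("effect_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shift = int(round(effect_fraction * n_params))
    shifts = np.zeros(n_params)
    shifts[:n_shift] = effect_size * noise_sd

    frames = []
    for tp, shifted in ((behavior.BASELINE, False), (behavior.DAY7, True)):
        vals = rng.normal(0.0, noise_sd, size=(n_mice, n_params))
        if shifted:
            vals = vals + shifts
        df = pd.DataFrame(vals, columns=[f"param_{i + 1:02d}" for i in range(n_params)])
        df.insert(0, "paw", paw)
        df.insert(0, "timepoint", tp)
        df.insert(0, "mouse", [f"m{i + 1:02d}" for i in range(n_mice)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Von Frey staircases
# ---------------------------------------------------------------------------

def generate_vonfrey_sequences(
    true_threshold: float,
    filaments=behavior.DEFAULT_FILAMENTS,
    n: int = 1,
    slope: float = 0.15,
    start_index: int | None = None,
    seed: int | None = None,
) -> list[VonFreyTrial]:
    """Simulate ``n`` up-down staircases under a logistic response model.

    The probability of withdrawal at force f is
    ``expit((log10 f - log10 true_threshold) / slope)`` (slope in log10
    units; smaller is steeper).  Filament selection follows the up-down rule
    (X steps down, O steps up), stopping after the post-reversal count or at
    the range limits.
    """
    if true_threshold <= 0:
        raise ValueError("true_threshold must be positive")
    filaments = tuple(filaments)
    logs = np.log10(np.asarray(filaments, dtype=float))
    if np.any(np.diff(logs) <= 0):
        raise ValueError("filaments must be strictly increasing")
    if start_index is None:
        start_index = len(filaments) // 2
    rng = np.random.default_rng(seed)
    log_thr = np.log10(true_threshold)

    trials = []
    top = len(filaments) - 1
    for _ in range(n):
        idx = start_index
        seq = []
        first_reversal = None
        while True:
            p = 1.0 / (1.0 + np.exp(-(logs[idx] - log_thr) / slope))
            r = RESPONSE if rng.random() < p else NO_RESPONSE
            seq.append(r)
            i = len(seq) - 1
            if first_reversal is None and i > 0 and r != seq[i - 1]:
                first_reversal = i
            if r == RESPONSE:
                if idx == 0:
                    break
                idx -= 1
            else:
                if idx == top:
                    break
                idx += 1
            if first_reversal is not None and i == first_reversal + behavior.N_POST_REVERSAL:
                break
        trials.append(VonFreyTrial(responses="".join(seq), filaments=filaments,
                                   start_index=start_index))
    return trials
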
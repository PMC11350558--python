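"""Synthetic event-level cytometry with known ground truth.

Emulates the statistical structure of a low-volume murine peripheral
blood study: a fixed catalogue of immune populations with per-channel
expression signatures, log-normal abundance noise split into a
per-animal (inter-individual) and a per-occasion (intra-individual)
component on the log10 scale, multinomial event sampling, and
log-normal intensity draws per expression level.

The generating model for population ``p`` in animal ``a`` at occasion
``t`` is::

    log10 c_{a,t,p} = log10 c_p  +  u_{a,p}  +  v_{a,t,p}
    u ~ Normal(0, sigma_inter^2)      shared by all occasions of an animal
    v ~ Normal(0, sigma_intra^2)      drawn fresh each occasion

Event counts per sample are multinomial over the normalized
concentrations.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gating import EventTable
from .panel_model import GatingHierarchy

#: canonical expression levels: log10 intensity (location, scale).
#: Locations are spaced so adjacent levels sit >= ~6 SD apart after the
#: asinh transform — the "well separated" regime the recovery analyses
#: assume; real marker distributions overlap more (see docs/methods.md).
DEFAULT_INTENSITY_MODEL: dict[str, tuple[float, float]] = {
    "negative": (2.0, 0.15),
    "low": (2.7, 0.15),
    "intermediate": (3.7, 0.15),
    "high": (4.4, 0.15),
}

LEVELS = tuple(DEFAULT_INTENSITY_MODEL)

#: linear scatter model per morphology class: channel -> (mean, sd)
SCATTER_MODEL = {
    "intact": {"FSC": (60000.0, 9000.0), "SSC": (40000.0, 8000.0)},
    "debris": {"FSC": (5000.0, 2000.0), "SSC": (3000.0, 1200.0)},
}


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: expression signature and abundance.

    ``signature`` maps channel -> expression level; channels not listed
    are negative.  ``scatter`` selects the morphology class ("debris"
    populations fall outside the intact-cell scatter gate).
    """

    population_name: str
    signature: dict[str, str]
    base_concentration: float  # cells/µL of whole blood
    scatter: str = "intact"

    def __post_init__(self):
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be > 0")
        for ch, lvl in self.signature.items():
            if lvl not in LEVELS:
                raise ValueError(f"unknown expression level {lvl!r} on {ch!r}")
        if self.scatter not in SCATTER_MODEL:
            raise ValueError(f"unknown scatter class {self.scatter!r}")

    def level(self, channel: str) -> str:
        return self.signature.get(channel, "negative")


@dataclass
class SimulationConfig:
    """Design and noise parameters of a simulated longitudinal study."""

    populations: list[PopulationSpec]
    n_animals: int = 5
    n_timepoints: int = 5
    events_per_sample: int | None = None  # None: derive from volumes
    sigma_inter: float = 0.2  # SD of per-animal log10-abundance effect
    sigma_intra: float = 0.1  # SD of per-occasion log10-abundance effect
    intensity_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MODEL)
    )
    blood_volume: float = 50.0  # µL whole blood per panel
    diluent_volume: float = 500.0  # µL anticoagulant/diluent
    acquired_volume: float = 100.0  # µL of suspension run on the instrument
    spillover: np.ndarray | None = None  # optional square mixing matrix
    scatter_channels: tuple[str, str] = ("FSC", "SSC")
    seed: int = 0

    def __post_init__(self):
        if not self.populations:
            raise ValueError("need at least one population")
        if self.sigma_inter < 0 or self.sigma_intra < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.events_per_sample is not None and self.events_per_sample < 1:
            raise ValueError("events_per_sample must be >= 1")
        if min(self.blood_volume, self.acquired_volume) <= 0 or self.diluent_volume < 0:
            raise ValueError("volumes must be positive")
        names = [p.population_name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")

    @property
    def dilution_factor(self) -> float:
        return (self.blood_volume + self.diluent_volume) / self.blood_volume

    @property
    def population_names(self) -> list[str]:
        return [p.population_name for p in self.populations]

    def channels(self) -> list[str]:
        chans: list[str] = list(self.scatter_channels)
        for p in self.populations:
            for ch in p.signature:
                if ch not in chans:
                    chans.append(ch)
        return chans


@dataclass
class GroundTruth:
    """What the generator actually did for one sample.

    ``table`` has one row per population: the model concentration
    (cells/µL blood after random effects), the realized concentration
    implied by the drawn event count and the acquisition volumes, and
    the drawn count.  ``event_labels`` assigns every event its
    generating population.
    """

    sample_id: str
    animal_id: str
    timepoint: str
    table: pd.DataFrame
    event_labels: np.ndarray

    def count(self, population: str) -> int:
        return int(self.table.set_index("population").loc[population, "count"])


def _sample_rng(config: SimulationConfig, animal_index: int, occasion_index: int):
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1, animal_index, occasion_index)
    )
    return np.random.default_rng(ss)


def draw_animal_effects(
    config: SimulationConfig, animal_index: int
) -> dict[str, float]:
    """Per-animal log10-abundance random effects, one per population.

    Deterministic in (seed, animal_index); shared by all of the
    animal's occasions.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0, animal_index))
    )
    u = rng.normal(0.0, config.sigma_inter, size=len(config.populations))
    return dict(zip(config.population_names, u))


def generate_sample(
    config: SimulationConfig,
    animal_effects: dict[str, float],
    occasion_index: int,
    animal_index: int = 0,
    animal_id: str | None = None,
    timepoint: str | None = None,
) -> tuple[EventTable, GroundTruth]:
    """Generate one acquired sample plus its ground truth.

    Event counts are multinomial over the occasion's concentrations;
    the total is ``events_per_sample`` if set, otherwise the cell yield
    implied by the concentrations and acquisition volumes (which makes
    realized and model concentrations agree up to multinomial noise).
    """
    rng = _sample_rng(config, animal_index, occasion_index)
    animal_id = animal_id or f"A{animal_index + 1}"
    timepoint = timepoint or f"T{occasion_index + 1}"
    sample_id = f"{animal_id}_{timepoint}"

    missing = [p.population_name for p in config.populations if p.population_name not in animal_effects]
    if missing:
        raise KeyError(f"animal_effects missing populations: {missing}")

    base = np.array([p.base_concentration for p in config.populations])
    u = np.array([animal_effects[p.population_name] for p in config.populations])
    v = rng.normal(0.0, config.sigma_intra, size=len(base))
    conc = 10.0 ** (np.log10(base) + u + v)
    total = conc.sum()
    if total <= 0:
        raise ValueError("zero total concentration")

    if config.events_per_sample is not None:
        n_events = int(config.events_per_sample)
    else:
        # cells in the acquired suspension volume
        n_events = max(1, int(round(total / config.dilution_factor * config.acquired_volume)))

    counts = rng.multinomial(n_events, conc / total)

    channels = config.channels()
    fluor = [c for c in channels if c not in config.scatter_channels]
    labels = np.repeat(config.population_names, counts)
    mat = np.empty((n_events, len(channels)))
    row = 0
    for p, k in zip(config.populations, counts):
        if k == 0:
            continue
        sl = slice(row, row + k)
        for j, ch in enumerate(channels):
            if ch in config.scatter_channels:
                mu, sd = SCATTER_MODEL[p.scatter][ch]
                mat[sl, j] = np.clip(rng.normal(mu, sd, size=k), 0, None)
            else:
                loc, scale = config.intensity_model[p.level(ch)]
                mat[sl, j] = 10.0 ** rng.normal(loc, scale, size=k)
        row += k

    if config.spillover is not None:
        s = np.asarray(config.spillover, dtype=float)
        if s.shape != (len(fluor), len(fluor)):
            raise ValueError("spillover matrix must be square over fluorescence channels")
        idx = [channels.index(c) for c in fluor]
        mat[:, idx] = mat[:, idx] @ s.T

    events = pd.DataFrame(mat, columns=channels)
    table = EventTable(
        sample_id=sample_id,
        events=events,
        scatter_channels=list(config.scatter_channels),
        animal_id=animal_id,
        timepoint=timepoint,
        acquired_volume=config.acquired_volume,
        blood_volume=config.blood_volume,
        diluent_volume=config.diluent_volume,
    )
    realized = counts / config.acquired_volume * config.dilution_factor
    truth = GroundTruth(
        sample_id=sample_id,
        animal_id=animal_id,
        timepoint=timepoint,
        table=pd.DataFrame(
            {
                "population": config.population_names,
                "model_concentration": conc,
                "concentration": realized,
                "count": counts,
            }
        ),
        event_labels=labels,
    )
    return table, truth


def generate_study(config: SimulationConfig) -> list[tuple[EventTable, GroundTruth]]:
    """Full longitudinal design: n_animals x n_timepoints samples.

    Animal effects are drawn once per animal and shared across its
    timepoints; occasion noise is fresh per sample.
    """
    out = []
    for a in range(config.n_animals):
        effects = draw_animal_effects(config, a)
        for t in range(config.n_timepoints):
            out.append(generate_sample(config, effects, t, animal_index=a))
    return out


def generate_abundances(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth concentration table of a study, without event data.

    Tidy frame (animal_id, timepoint, population, concentration,
    log10_concentration) under the same hierarchical noise model; the
    fast path for Monte-Carlo work on the abundance model alone.
    """
    rows = []
    base = np.array([p.base_concentration for p in config.populations])
    for a in range(config.n_animals):
        effects = draw_animal_effects(config, a)
        u = np.array([effects[n] for n in config.population_names])
        for t in range(config.n_timepoints):
            rng = _sample_rng(config, a, t)
            v = rng.normal(0.0, config.sigma_intra, size=len(base))
            logc = np.log10(base) + u + v
            for name, lc in zip(config.population_names, logc):
                rows.append((f"A{a + 1}", f"T{t + 1}", name, 10.0 ** lc, lc))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "timepoint", "population", "concentration", "log10_concentration"],
    )


def generate_challenge_study(
    config: SimulationConfig,
    n_blocks: int = 3,
    effect_log10: dict[str, float] | None = None,
    treated_label: str = "treated",
    control_label: str = "control",
) -> list[tuple[EventTable, GroundTruth]]:
    """Blocked two-group challenge design with a known treatment effect.

    Animals are split into ``n_blocks`` blocks, half treated and half
    control within each block (``config.n_animals`` must be divisible
    by ``2 * n_blocks``).  Occasion 0 is baseline for everyone; from
    occasion 1 on, treated animals' population concentrations are
    shifted by ``effect_log10`` (population -> log10 shift, e.g. -0.3
    for a ~50% drop).  Randomness reuses the same per-(animal,
    occasion) streams as :func:`generate_study`.
    """
    effect_log10 = effect_log10 or {}
    unknown = set(effect_log10) - set(config.population_names)
    if unknown:
        raise KeyError(f"effect on unknown populations: {sorted(unknown)}")
    per_block = config.n_animals // n_blocks
    if per_block * n_blocks != config.n_animals or per_block % 2:
        raise ValueError("n_animals must split into blocks of even size")

    shifted_pops = [
        replace(
            p,
            base_concentration=p.base_concentration
            * 10.0 ** effect_log10.get(p.population_name, 0.0),
        )
        for p in config.populations
    ]
    treated_cfg = replace(config, populations=shifted_pops)

    out = []
    for a in range(config.n_animals):
        block = f"B{a // per_block + 1}"
        treated = (a % per_block) < per_block // 2
        group = treated_label if treated else control_label
        effects = draw_animal_effects(config, a)
        for t in range(config.n_timepoints):
            cfg = treated_cfg if (treated and t > 0) else config
            ev, truth = generate_sample(cfg, effects, t, animal_index=a)
            ev = replace(ev, group=group, block=block)
            out.append((ev, truth))
    return out


# ---------------------------------------------------------------------------
# population truth vs a gating hierarchy


def _level_satisfies(level: str, relation: str) -> bool:
    if relation == "positive":
        return level != "negative"
    if relation == "negative":
        return level == "negative"
    if relation == "high":
        return level == "high"
    if relation == "low":
        return level in ("negative", "low")
    return level == "intermediate"


def population_node_membership(
    hierarchy: GatingHierarchy, population: PopulationSpec
) -> dict[str, bool]:
    """Which hierarchy nodes a population's signature places it in."""
    out: dict[str, bool] = {}
    if population.scatter == "debris":
        return {n.node_name: False for n in hierarchy.nodes()}
    for node in hierarchy.nodes():
        out[node.node_name] = all(
            _level_satisfies(population.level(c.channel), c.relation)
            for c in node.path_conditions()
        )
    return out


def expected_node_counts(
    hierarchy: GatingHierarchy, truth: GroundTruth, populations: list[PopulationSpec]
) -> dict[str, int]:
    """Ground-truth event count per hierarchy node for one sample."""
    counts = dict(zip(truth.table["population"], truth.table["count"].astype(int)))
    node_counts = {n.node_name: 0 for n in hierarchy.nodes()}
    for pop in populations:
        member = population_node_membership(hierarchy, pop)
        k = counts.get(pop.population_name, 0)
        for name, inside in member.items():
            if inside:
                node_counts[name] += k
    return node_counts


def expected_node_concentrations(
    hierarchy: GatingHierarchy,
    truth: GroundTruth,
    populations: list[PopulationSpec],
    which: str = "concentration",
) -> dict[str, float]:
    """Ground-truth cells/µL of blood per hierarchy node for one sample."""
    conc = dict(zip(truth.table["population"], truth.table[which]))
    node_conc = {n.node_name: 0.0 for n in hierarchy.nodes()}
    for pop in populations:
        member = population_node_membership(hierarchy, pop)
        c = conc.get(pop.population_name, 0.0)
        for name, inside in member.items():
            if inside:
                node_conc[name] += c
    return node_conc


# ---------------------------------------------------------------------------
# shipped population catalogues, one per built-in panel
#
# Concentrations are order-of-magnitude plausible for healthy adult mouse
# peripheral blood (total leukocytes a few thousand cells/µL, lymphocytes
# the majority, dendritic subsets rare); they are deliberately not
# calibrated to any measured data set.  Debris sits outside the scatter
# gate at ~2% of events.

_H = "high"


def myeloid_populations() -> list[PopulationSpec]:
    common = {"CD45": _H}
    mk = lambda name, conc, **sig: PopulationSpec(name, {**common, **sig}, conc)
    pops = [
        mk("neutrophils", 500, CD11b=_H, Ly6G=_H, Ly6C="intermediate", CD172a=_H),
        mk("pmn_mdsc", 60, CD11b=_H, Ly6G=_H, Ly6C="low", CD172a=_H),
        mk("eosinophils", 100, CD11b=_H, Ly6G=_H, **{"Siglec-F": _H}, Ly6C="low", CD172a=_H),
        mk("classical_monocytes", 150, CD11b=_H, F4_80=_H, Ly6C=_H, CCR2=_H, CD172a=_H),
        mk("nonclassical_monocytes", 80, CD11b=_H, F4_80=_H, Ly6C="low", CD172a=_H),
        mk("m_mdsc", 40, CD11b=_H, F4_80=_H, Ly6C=_H, CD172a=_H),
        mk("basophils", 30, CD11b=_H, CD49b=_H, Ly6C="low", CD172a=_H),
        mk("pdc_immature", 15, CD11c=_H, B220=_H, Ly6C="low"),
        mk("pdc_mature", 8, CD11c=_H, B220=_H, **{"MHC-II": _H}, Ly6C="low"),
        mk("cdc1", 12, CD11c=_H, **{"MHC-II": _H}, Ly6C="low"),
        mk("cdc1_mature", 5, CD11c=_H, **{"MHC-II": _H}, CD80=_H, CD86=_H, Ly6C="low"),
        mk("lymphocytes_bulk", 2000, Ly6C="low"),
    ]
    total = sum(p.base_concentration for p in pops)
    # debris carries Ly6C at the "low" level so the three-level channel
    # stays trimodal for threshold estimation; it is excluded from every
    # gate by the scatter rectangle regardless
    pops.append(
        PopulationSpec("debris", {"Ly6C": "low"}, round(total * 0.0204, 1), scatter="debris")
    )
    return pops


def lymphoid_populations() -> list[PopulationSpec]:
    common = {"CD45": _H}
    mk = lambda name, conc, **sig: PopulationSpec(
        name, {**common, **{k.replace("NK1_1", "NK1.1").replace("TNF_RII", "TNF-RII"): v for k, v in sig.items()}}, conc
    )
    pops = [
        mk("cd4_naive", 75, CD3=_H, CD4=_H, CD62L=_H),
        mk("cd4_act_eff", 60, CD3=_H, CD4=_H),
        mk("cd4_cmem", 25, CD3=_H, CD4=_H, CD44=_H, CD62L=_H),
        mk("cd4_emem", 20, CD3=_H, CD4=_H, CD44=_H),
        mk("th1_resting", 4, CD3=_H, CD4=_H, CXCR3=_H, CD44=_H, CD62L=_H),
        mk("th1_eff", 2, CD3=_H, CD4=_H, CXCR3=_H, CD44=_H),
        mk("th2_resting", 3, CD3=_H, CD4=_H, CCR4=_H, CD44=_H, CD62L=_H),
        mk("th2_eff", 1.5, CD3=_H, CD4=_H, CCR4=_H, CD44=_H),
        mk("th17_resting", 3, CD3=_H, CD4=_H, CCR4=_H, CCR6=_H, CD44=_H, CD62L=_H),
        mk("th17_eff", 1.2, CD3=_H, CD4=_H, CCR4=_H, CCR6=_H, CD44=_H),
        mk("th9", 4, CD3=_H, CD4=_H, CCR6=_H, CD44=_H, CD62L=_H),
        mk("treg", 8, CD3=_H, CD4=_H, CD25=_H, TNF_RII=_H, CD44=_H, CD62L=_H),
        mk("cd8_naive", 85, CD3=_H, CD8=_H, CD62L=_H),
        mk("cd8_act_eff", 40, CD3=_H, CD8=_H),
        mk("cd8_cmem", 22, CD3=_H, CD8=_H, CD44=_H, CD62L=_H),
        mk("cd8_emem", 9, CD3=_H, CD8=_H, CD44=_H),
        mk("nkt", 53, CD3=_H, NK1_1=_H, CD44=_H),
        mk("nk", 70, NK1_1=_H),
        mk("b_cells", 1400, CD19=_H),
        mk("plasma_cells", 18, CD19=_H, CD138=_H),
        mk("myeloid_rest", 800),
    ]
    total = sum(p.base_concentration for p in pops)
    pops.append(PopulationSpec("debris", {}, round(total * 0.0204, 1), scatter="debris"))
    return pops


def intracellular_populations() -> list[PopulationSpec]:
    mk = lambda name, conc, **sig: PopulationSpec(
        name, {k.replace("NK1_1", "NK1.1"): v for k, v in sig.items()}, conc
    )
    pops = [
        mk("cd4_conv", 250, CD3=_H, CD4=_H),
        mk("treg_resting", 15, CD3=_H, CD4=_H, CD25=_H, FOXP3=_H),
        mk("treg_eff_ccr5", 6, CD3=_H, CD4=_H, CD25=_H, FOXP3=_H, CD44=_H, CCR5=_H),
        mk("cd8_conv", 160, CD3=_H, CD8=_H),
        mk("cd8_cytotoxic", 25, CD3=_H, CD8=_H, GranzymeB=_H, Perforin=_H),
        mk("nkt_plain", 35, CD3=_H, NK1_1=_H),
        mk("nkt_gzmb", 12, CD3=_H, NK1_1=_H, GranzymeB=_H),
        mk("nk_resting", 40, NK1_1=_H),
        mk("nk_perf_gzmb", 20, NK1_1=_H, Perforin=_H, GranzymeB=_H),
        mk("nk_act_perf", 10, NK1_1=_H, Perforin=_H, CD25=_H),
        mk("b_and_rest", 1500),
        mk("dead_cells", 80, Viability=_H),
    ]
    total = sum(p.base_concentration for p in pops)
    pops.append(PopulationSpec("debris", {}, round(total * 0.0204, 1), scatter="debris"))
    return pops


def default_populations(panel_name: str) -> list[PopulationSpec]:
    """The shipped population catalogue for a built-in panel."""
    table = {
        "myeloid": myeloid_populations,
        "lymphoid": lymphoid_populations,
        "intracellular": intracellular_populations,
    }
    if panel_name not in table:
        raise KeyError(f"no population catalogue for panel {panel_name!r}")
    return table[panel_name]()


def default_study_config(panel_name: str = "myeloid", **overrides) -> SimulationConfig:
    """A 5-animal x 5-timepoint study over the panel's shipped populations."""
    cfg = SimulationConfig(populations=default_populations(panel_name))
    return replace(cfg, **overrides) if overrides else cfg
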
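"""Ground-truth simulator for a two-compartment in vitro colon experiment.

Emulates the study conditions the pipeline is meant to analyse: a continuous
one-stage fermenter (24-h mean retention, so a washout rate of 1/day) whose
luminal vessel is inoculated with a donor stool community, coupled to a
mucin-bead compartment that adsorbs luminal biomass and is swapped for fresh
beads every two days.  On days 9 and 10 a 9-h enriched saliva from the same
donor is injected twice a day, planting a known set of oral invader species.
Sequencing is emulated by multinomial read sampling over a miniaturized
gut + oral gene-catalogue pair, with a per-sample unassigned (host/unknown)
read fraction.

The generator returns both the observable data (gene count tables, sample
metadata, catalogue) and the planted truth (niche labels, compositions,
invader set), so recovery by the quantification and invasion modules can be
scored exactly.

Community dynamics are a discrete-time logistic chemostat,

    x_i(t+dt) = x_i(t) * exp([g_i (1 - X/K) - D] dt)          (lumen)
    m_i(t+dt) = m_i(t) + dt (a_i x_i - delta_i m_i)           (mucosa)

with the adhesion rate ``a_i`` multiplied by ``oral_mucosal_affinity`` for
oral-niche species.  All randomness flows from one root seed through named
substreams so each stage can be re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    ConfigError,
    GeneAbundanceTable,
    GeneCatalogue,
    InputError,
    SampleMeta,
)

__all__ = [
    "SimulationConfig",
    "CommunityState",
    "GroundTruth",
    "SimulatedDataset",
    "stream_rng",
    "build_catalogue_pair",
    "build_taxonomy",
    "species_from_catalogue",
    "enrich_saliva",
    "step_lumen",
    "step_mucosa",
    "run_simulation",
    "emit_gene_counts",
    "simulate_dataset",
]


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the root seed (stable across runs and platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Full parameterization of the fermentation + sequencing scenario.

    Rates are per day, durations in days unless noted.  The defaults encode
    the study conditions: 11-day horizon with a first batch day (no
    dilution), washout 1/day from the 24-h retention time, bead swaps every
    2 days, a 9-h saliva enrichment retaining ~70% of species, and twice-a-day
    saliva injections on days 9 and 10.
    """

    n_gut_only: int = 200
    n_oral_only: int = 100
    n_shared: int = 30
    markers_per_msp: int = 100
    genes_per_msp: int = 200
    dilution_rate: float = 1.0          # 1 / (24-h retention time)
    growth_rate_median: float = 0.8     # lognormal median, per day
    growth_rate_sdlog: float = 0.5
    carrying_capacity: float = 10.0
    initial_biomass: float = 1.0        # total luminal biomass at inoculation
    adhesion_rate: float = 0.1          # lumen -> mucosa, per day
    detachment_rate: float = 0.5        # mucosa -> out, per day
    oral_mucosal_affinity: float = 5.0  # adhesion multiplier, oral species
    bead_replacement_period: float = 2.0
    bead_retention_fraction: float = 0.2
    enrichment_hours: float = 9.0
    enrichment_dropout: float = 0.7     # per-species survival probability
    saliva_dose: float = 0.033          # fraction of luminal biomass per injection
    injection_days: tuple[int, ...] = (9, 10)
    injections_per_day: int = 2
    sequencing_depth: int = 100_000
    unassigned_fraction_fecal: float = 0.05
    unassigned_fraction_saliva: float = 0.5
    dirichlet_alpha: float = 0.5        # niche-exclusive species
    dirichlet_alpha_shared: float = 5.0  # species resident in both habitats
    length_weight_low: float = 0.5
    length_weight_high: float = 1.5
    n_days: int = 11
    dt: float = 0.01
    donor: str = "S1"
    seed: int = 0

    def validate(self) -> None:
        c = self
        if min(c.n_gut_only, c.n_oral_only, c.n_shared) < 0:
            raise ConfigError("species counts must be >= 0")
        if c.n_gut_only + c.n_shared == 0 or c.n_oral_only + c.n_shared == 0:
            raise ConfigError("both the stool and the saliva community must be non-empty")
        if c.markers_per_msp < 10:
            raise ConfigError("markers_per_msp must be >= 10")
        if c.genes_per_msp < c.markers_per_msp:
            raise ConfigError("genes_per_msp must be >= markers_per_msp")
        for name in (
            "dilution_rate", "growth_rate_median", "growth_rate_sdlog",
            "adhesion_rate", "detachment_rate", "enrichment_hours",
        ):
            if getattr(c, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if c.carrying_capacity <= 0:
            raise ConfigError("carrying_capacity must be > 0")
        if c.initial_biomass <= 0:
            raise ConfigError("initial_biomass must be > 0")
        if c.oral_mucosal_affinity < 1:
            raise ConfigError("oral_mucosal_affinity must be >= 1")
        for name in (
            "bead_retention_fraction", "enrichment_dropout", "saliva_dose",
            "unassigned_fraction_fecal", "unassigned_fraction_saliva",
        ):
            if not 0.0 <= getattr(c, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if c.bead_replacement_period <= 0:
            raise ConfigError("bead_replacement_period must be > 0")
        if c.sequencing_depth < 1:
            raise ConfigError("sequencing_depth must be >= 1")
        if c.injections_per_day < 1:
            raise ConfigError("injections_per_day must be >= 1")
        if c.n_days < 1 or c.dt <= 0 or c.dt > 1:
            raise ConfigError("need n_days >= 1 and 0 < dt <= 1")
        for d in c.injection_days:
            if not 1 <= d <= c.n_days:
                raise ConfigError(
                    f"injection day {d} outside the simulated horizon [1, {c.n_days}]"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["injection_days"] = list(d["injection_days"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        if "injection_days" in d:
            d["injection_days"] = tuple(int(x) for x in d["injection_days"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class CommunityState:
    """Per-species biomass in each bioreactor compartment at one time."""

    time: float
    lumen: np.ndarray
    mucosa: np.ndarray

    def copy(self) -> "CommunityState":
        return CommunityState(self.time, self.lumen.copy(), self.mucosa.copy())


@dataclass
class Scenario:
    """A config with its per-species random draws materialized."""

    config: SimulationConfig
    species: pd.DataFrame       # index species_id; niche, gut_msp_id, oral_msp_id, merged_msp_id
    growth_rates: np.ndarray
    adhesion: np.ndarray        # affinity multiplier already applied
    detachment: np.ndarray
    stool: np.ndarray           # baseline compositions over the species axis
    saliva: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class GroundTruth:
    """The planted truth a recovery analysis is scored against."""

    species: pd.DataFrame                      # as in Scenario
    niche_labels: pd.Series                    # merged_msp_id -> gut|oral|ND
    stool_composition: np.ndarray
    saliva_composition: np.ndarray
    enriched_compositions: dict[int, np.ndarray]
    trajectory: list[CommunityState]           # states at sampled times
    sample_compositions: dict[str, np.ndarray]  # sample_id -> normalized weights
    planted_invaders: set[str]                 # merged msp ids, oral niche only


@dataclass
class SimulatedDataset:
    """Everything one simulated donor run produces."""

    config: SimulationConfig
    catalogue: GeneCatalogue
    taxonomy: pd.DataFrame
    meta: list[SampleMeta]
    gene_table: GeneAbundanceTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# catalogue construction
# ---------------------------------------------------------------------------


def build_catalogue_pair(config: SimulationConfig) -> GeneCatalogue:
    """Build the miniaturized gut + oral catalogue pair for a scenario.

    Gut catalogue holds all gut-only and shared species, oral catalogue all
    oral-only and shared species; each shared species has one MSP per
    catalogue linked by an overlap pair.  Gene length weights are uniform on
    [length_weight_low, length_weight_high], drawn from the 'catalogue'
    seed stream.
    """
    config.validate()
    rng = stream_rng(config.seed, "catalogue")
    gene_ids: list[str] = []
    msp_col: list[str] = []
    is_marker: list[bool] = []
    cat_col: list[str] = []
    pairs: list[tuple[str, str]] = []

    def add_msp(msp_id: str, catalogue: str) -> None:
        for k in range(config.genes_per_msp):
            gene_ids.append(f"{msp_id}.g{k:04d}")
            msp_col.append(msp_id)
            is_marker.append(k < config.markers_per_msp)
            cat_col.append(catalogue)

    for i in range(config.n_gut_only):
        add_msp(f"msp_gut_{i:04d}", "gut")
    for i in range(config.n_shared):
        gut_id = f"msp_gut_sh{i:04d}"
        oral_id = f"msp_oral_sh{i:04d}"
        add_msp(gut_id, "gut")
        add_msp(oral_id, "oral")
        pairs.append((gut_id, oral_id))
    for i in range(config.n_oral_only):
        add_msp(f"msp_oral_{i:04d}", "oral")

    genes = pd.DataFrame(
        {
            "msp_id": msp_col,
            "is_marker": is_marker,
            "length_weight": rng.uniform(
                config.length_weight_low, config.length_weight_high, size=len(gene_ids)
            ),
            "catalogue": cat_col,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneCatalogue(genes=genes, overlap_pairs=pairs, markers_per_msp=config.markers_per_msp)


def species_from_catalogue(cat: GeneCatalogue) -> pd.DataFrame:
    """Recover the species table (one row per biological species) from a catalogue.

    Overlap-paired MSPs collapse to a single shared species whose merged id
    is the gut-catalogue member (the id the merge step retains).
    """
    cat_of = cat.catalogue_of_msp()
    paired_gut = {g: o for g, o in cat.overlap_pairs}
    paired_oral = {o for _, o in cat.overlap_pairs}
    rows = []
    for msp in cat_of.index:
        if msp in paired_oral:
            continue  # represented by its gut partner
        if msp in paired_gut:
            rows.append((msp, "ND", msp, paired_gut[msp], msp))
        elif cat_of[msp] == "gut":
            rows.append((msp, "gut", msp, None, msp))
        else:
            rows.append((msp, "oral", None, msp, msp))
    df = pd.DataFrame(
        rows, columns=["species_id", "niche", "gut_msp_id", "oral_msp_id", "merged_msp_id"]
    ).set_index("species_id")
    return df


_PHYLA = {
    "gut": ["Bacillota", "Bacteroidota", "Actinomycetota", "Pseudomonadota", "Verrucomicrobiota"],
    "oral": ["Bacillota", "Bacteroidota", "Fusobacteriota", "Pseudomonadota", "Actinomycetota"],
}


def build_taxonomy(cat: GeneCatalogue, seed: int = 0) -> pd.DataFrame:
    """Synthetic taxonomy for every MSP of the catalogue pair.

    Labels are invented (deterministically from the seed) but structured
    like real annotations: a phylum drawn from niche-typical pools, one
    family per phylum slot, genus shared by blocks of species, and a ~5%
    chance of a missing family to exercise the 'unclassified' pooling.
    """
    rng = stream_rng(seed, "taxonomy")
    species = species_from_catalogue(cat)
    rows = {}
    for species_id, row in species.iterrows():
        pool = _PHYLA["oral" if row["niche"] == "oral" else "gut"]
        phylum = pool[int(rng.integers(len(pool)))]
        family = f"{phylum[:6]}aceae_{int(rng.integers(4))}"
        if rng.random() < 0.05:
            family = ""
        genus = f"g__{species_id[-6:]}"
        name = f"s__{species_id}"
        for msp in (row["gut_msp_id"], row["oral_msp_id"]):
            if msp is not None:
                rows[msp] = (name, genus, family, phylum)
    tax = pd.DataFrame.from_dict(
        rows, orient="index", columns=["species", "genus", "family", "phylum"]
    )
    tax.index.name = "msp_id"
    return tax


# ---------------------------------------------------------------------------
# community dynamics
# ---------------------------------------------------------------------------


def draw_scenario(config: SimulationConfig, cat: GeneCatalogue | None = None) -> Scenario:
    """Materialize per-species rates and baseline compositions from the config."""
    config.validate()
    if cat is None:
        cat = build_catalogue_pair(config)
    species = species_from_catalogue(cat)
    n = len(species)
    niche = species["niche"].to_numpy()

    rng = stream_rng(config.seed, "rates")
    growth = rng.lognormal(np.log(config.growth_rate_median), config.growth_rate_sdlog, size=n)
    adhesion = np.full(n, config.adhesion_rate)
    adhesion[niche == "oral"] *= config.oral_mucosal_affinity
    detachment = np.full(n, config.detachment_rate)

    rng_c = stream_rng(config.seed, "communities")
    in_stool = (niche == "gut") | (niche == "ND")
    in_saliva = (niche == "oral") | (niche == "ND")
    stool = np.zeros(n)
    saliva = np.zeros(n)
    # Shared (ND) species model taxa genuinely resident in both habitats, so
    # they get a tighter (higher-concentration) Dirichlet component than the
    # long-tailed niche-exclusive species.
    alpha_stool = np.where(niche[in_stool] == "ND", config.dirichlet_alpha_shared, config.dirichlet_alpha)
    alpha_saliva = np.where(niche[in_saliva] == "ND", config.dirichlet_alpha_shared, config.dirichlet_alpha)
    stool[in_stool] = rng_c.dirichlet(alpha_stool)
    saliva[in_saliva] = rng_c.dirichlet(alpha_saliva)

    return Scenario(
        config=config,
        species=species,
        growth_rates=growth,
        adhesion=adhesion,
        detachment=detachment,
        stool=stool,
        saliva=saliva,
    )


def enrich_saliva(
    raw: np.ndarray,
    growth_rates: np.ndarray,
    hours: float,
    dropout: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the pre-injection saliva enrichment culture.

    Each species independently survives with probability ``dropout`` (a
    survival probability; the default 0.7 reproduces the ~70% richness
    retention the enrichment is designed for).  Survivors grow
    exponentially for ``hours`` at their per-day rate; the result is
    renormalized to a composition.
    """
    raw = np.asarray(raw, dtype=float)
    if hours < 0:
        raise InputError("enrichment hours must be >= 0")
    survive = rng.random(raw.shape) < dropout
    weights = np.where(survive, raw * np.exp(growth_rates * hours / 24.0), 0.0)
    total = weights.sum()
    if total <= 0:
        raise InputError("enrichment extinguished community")
    return weights / total


def step_lumen(
    state: CommunityState,
    scenario: Scenario,
    dt: float,
    dilution: float | None = None,
) -> CommunityState:
    """One explicit step of the logistic chemostat (lumen only)."""
    if dt <= 0:
        raise InputError("dt must be > 0")
    cfg = scenario.config
    if cfg.carrying_capacity <= 0:
        raise ConfigError("carrying_capacity must be > 0")
    D = cfg.dilution_rate if dilution is None else dilution
    x = state.lumen
    x_tot = x.sum()
    rate = scenario.growth_rates * (1.0 - x_tot / cfg.carrying_capacity) - D
    return CommunityState(state.time + dt, x * np.exp(rate * dt), state.mucosa.copy())


def step_mucosa(
    state: CommunityState,
    scenario: Scenario,
    dt: float,
    bead_swap: bool = False,
) -> CommunityState:
    """One explicit step of mucosal adhesion/detachment, plus optional bead swap.

    The adhesion vector already carries the oral-affinity multiplier.  A
    bead swap (every ``bead_replacement_period`` days in the full run)
    keeps only ``bead_retention_fraction`` of the mucosal biomass.
    """
    if dt <= 0:
        raise InputError("dt must be > 0")
    cfg = scenario.config
    m = state.mucosa + dt * (scenario.adhesion * state.lumen - scenario.detachment * state.mucosa)
    m = np.clip(m, 0.0, None)
    if bead_swap:
        m = m * cfg.bead_retention_fraction
    return CommunityState(state.time, state.lumen.copy(), m)


# ---------------------------------------------------------------------------
# full scenario run
# ---------------------------------------------------------------------------


def _sampling_grid(config: SimulationConfig) -> list[SampleMeta]:
    """The experiment's sampling schedule: daily luminal, 2-daily mucosal,
    baseline stool and raw saliva, enriched saliva on each injection day."""
    donor = config.donor
    metas = [
        SampleMeta(f"{donor}_stool", donor, "stool", day=0, is_baseline=True),
        SampleMeta(f"{donor}_raw_saliva", donor, "raw_saliva", day=None, is_baseline=True),
    ]
    for d in range(1, config.n_days + 1):
        metas.append(SampleMeta(f"{donor}_luminal_d{d:02d}", donor, "luminal", day=d))
    d = int(config.bead_replacement_period)
    while d <= config.n_days:
        metas.append(SampleMeta(f"{donor}_mucosal_d{d:02d}", donor, "mucosal", day=d))
        d += int(config.bead_replacement_period)
    for d in config.injection_days:
        metas.append(SampleMeta(f"{donor}_enriched_saliva_d{d:02d}", donor, "enriched_saliva", day=d))
    return metas


def run_simulation(
    config: SimulationConfig,
) -> tuple[GroundTruth, dict[SampleMeta, np.ndarray]]:
    """Run the fermentation scenario and return truth + sample compositions.

    Timeline: the baseline stool inoculates the lumen at t=0; day 1 is batch
    amplification (no dilution), continuous fermentation follows until
    ``n_days``.  Bead swaps happen every ``bead_replacement_period`` days
    (mucosa is sampled before the swap).  On each injection day,
    ``injections_per_day`` saliva additions occur at t = day + k/3; samples
    scheduled at the same instant are taken after the injection, matching a
    morning-injection-then-sampling protocol.  Deterministic given the
    config (including its seed).
    """
    config.validate()
    scenario = draw_scenario(config)
    cfg = config
    n_steps = int(round(cfg.n_days / cfg.dt))

    # enrichment draws, one independent culture per injection day
    enriched: dict[int, np.ndarray] = {}
    for d in cfg.injection_days:
        rng = stream_rng(cfg.seed, f"enrichment_day{d}")
        enriched[d] = enrich_saliva(
            scenario.saliva, scenario.growth_rates, cfg.enrichment_hours,
            cfg.enrichment_dropout, rng,
        )

    def as_step(t: float) -> int:
        return int(round(t / cfg.dt))

    injections: dict[int, int] = {}  # step -> injection day
    for d in cfg.injection_days:
        for k in range(cfg.injections_per_day):
            injections[as_step(d + k / 3.0)] = d

    swap_steps = set()
    t = cfg.bead_replacement_period
    while t <= cfg.n_days:
        swap_steps.add(as_step(t))
        t += cfg.bead_replacement_period

    metas = _sampling_grid(cfg)
    lum_samples = {as_step(m.day): m for m in metas if m.sample_type == "luminal"}
    muc_samples = {as_step(m.day): m for m in metas if m.sample_type == "mucosal"}

    state = CommunityState(
        0.0, scenario.stool * cfg.initial_biomass, np.zeros(scenario.n_species)
    )
    samples: dict[SampleMeta, np.ndarray] = {}
    trajectory: list[CommunityState] = []

    def normalize(v: np.ndarray, what: str) -> np.ndarray:
        tot = v.sum()
        if tot <= 0:
            raise InputError(f"{what}: community washed out entirely")
        return v / tot

    for meta in metas:
        if meta.sample_type == "stool":
            samples[meta] = scenario.stool.copy()
        elif meta.sample_type == "raw_saliva":
            samples[meta] = scenario.saliva.copy()
        elif meta.sample_type == "enriched_saliva":
            samples[meta] = enriched[meta.day].copy()

    for step in range(n_steps + 1):
        # event order at a step boundary: inject, sample, swap beads, advance
        if step in injections:
            dose = cfg.saliva_dose * state.lumen.sum()
            state.lumen = state.lumen + dose * enriched[injections[step]]
        took_sample = False
        if step in lum_samples:
            samples[lum_samples[step]] = normalize(state.lumen, lum_samples[step].sample_id)
            took_sample = True
        if step in muc_samples:
            samples[muc_samples[step]] = normalize(state.mucosa, muc_samples[step].sample_id)
            took_sample = True
        if took_sample:
            trajectory.append(state.copy())
        if step == n_steps:
            break
        swap = step in swap_steps
        dilution = 0.0 if state.time < 1.0 else None  # batch amplification day
        new_lumen = step_lumen(state, scenario, cfg.dt, dilution=dilution).lumen
        new_mucosa = step_mucosa(state, scenario, cfg.dt, bead_swap=swap).mucosa
        state = CommunityState((step + 1) * cfg.dt, new_lumen, new_mucosa)

    first_injection = min(cfg.injection_days) if cfg.injection_days else None
    oral_mask = (scenario.species["niche"] == "oral").to_numpy()
    planted = np.zeros(scenario.n_species, dtype=bool)
    if first_injection is not None:
        for meta, comp in samples.items():
            if meta.sample_type in ("luminal", "mucosal") and meta.day >= first_injection:
                planted |= comp > 0
    planted &= oral_mask
    merged_ids = scenario.species["merged_msp_id"].to_numpy()
    niche_labels = pd.Series(
        scenario.species["niche"].to_numpy(), index=merged_ids, name="niche"
    )

    truth = GroundTruth(
        species=scenario.species,
        niche_labels=niche_labels,
        stool_composition=scenario.stool,
        saliva_composition=scenario.saliva,
        enriched_compositions=enriched,
        trajectory=trajectory,
        sample_compositions={m.sample_id: c for m, c in samples.items()},
        planted_invaders=set(merged_ids[planted]),
    )
    return truth, samples


# ---------------------------------------------------------------------------
# sequencing emulation
# ---------------------------------------------------------------------------


@dataclass
class _GeneModel:
    """Precomputed gene-level sampling layout for a catalogue pair."""

    gene_index: pd.Index
    species_idx: np.ndarray   # per gene, position on the species axis
    length_weight: np.ndarray

    @classmethod
    def build(cls, cat: GeneCatalogue, species: pd.DataFrame) -> "_GeneModel":
        msp_to_species = {}
        for pos, (_, row) in enumerate(species.iterrows()):
            for msp in (row["gut_msp_id"], row["oral_msp_id"]):
                if msp is not None:
                    msp_to_species[msp] = pos
        idx = cat.genes["msp_id"].map(msp_to_species).to_numpy()
        return cls(
            gene_index=cat.genes.index,
            species_idx=idx.astype(int),
            length_weight=cat.genes["length_weight"].to_numpy(),
        )

    def sample_counts(
        self,
        composition: np.ndarray,
        depth: int,
        unassigned_fraction: float,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, int]:
        composition = np.asarray(composition, dtype=float)
        if composition.sum() <= 0:
            raise InputError("composition has no positive weight")
        n_unassigned = int(rng.binomial(depth, unassigned_fraction))
        p = composition[self.species_idx] * self.length_weight
        p = p / p.sum()
        counts = rng.multinomial(depth - n_unassigned, p)
        return counts, n_unassigned


def emit_gene_counts(
    composition: np.ndarray,
    cat: GeneCatalogue,
    depth: int,
    unassigned_fraction: float,
    rng: np.random.Generator | int,
    sample_id: str = "sample",
) -> GeneAbundanceTable:
    """Emit one sample's gene counts by multinomial read sampling.

    Reads land on gene g of species s with probability proportional to
    ``composition[s] * length_weight[g]``; an independent Binomial fraction
    of the depth is set aside as unassigned.  Assigned + unassigned always
    equals ``depth`` exactly.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    species = species_from_catalogue(cat)
    model = _GeneModel.build(cat, species)
    counts, n_unassigned = model.sample_counts(composition, depth, unassigned_fraction, rng)
    df = pd.DataFrame({sample_id: counts}, index=model.gene_index)
    unassigned = pd.Series({sample_id: float(n_unassigned)})
    return GeneAbundanceTable(counts=df.astype(float), unassigned=unassigned)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: catalogue, dynamics, sampling grid, sequencing."""
    config.validate()
    cat = build_catalogue_pair(config)
    truth, samples = run_simulation(config)
    model = _GeneModel.build(cat, truth.species)

    metas = sorted(samples, key=lambda m: m.sample_id)
    columns = {}
    unassigned = {}
    for meta in metas:
        frac = (
            config.unassigned_fraction_saliva
            if meta.sample_type in ("raw_saliva", "enriched_saliva")
            else config.unassigned_fraction_fecal
        )
        rng = stream_rng(config.seed, f"sequencing:{meta.sample_id}")
        counts, n_un = model.sample_counts(
            samples[meta], config.sequencing_depth, frac, rng
        )
        columns[meta.sample_id] = counts
        unassigned[meta.sample_id] = float(n_un)

    gene_table = GeneAbundanceTable(
        counts=pd.DataFrame(columns, index=model.gene_index, dtype=float),
        unassigned=pd.Series(unassigned),
    )
    taxonomy = build_taxonomy(cat, seed=config.seed)
    return SimulatedDataset(
        config=config,
        catalogue=cat,
        taxonomy=taxonomy,
        meta=metas,
        gene_table=gene_table,
        truth=truth,
    )
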
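"""Structured coalescent simulation with serial (ancient) sampling.

The simulator realizes genealogies of haploid (mitochondrial) samples drawn
at different times from a multi-deme demography with epoch-wise constant
effective sizes, backward-in-time migration matrices, and lineage-movement
events (backward merges and replacement/discontinuity events).  A finite-site
mutation overlay turns genealogies into alignments.

Time runs backward from the present in generations.  Effective sizes are
haploid (mtDNA): within a deme of size Ne, k lineages coalesce at rate
k(k-1)/(2*Ne) per generation (continuous-time approximation).

The module also ships a library of demographic-model templates describing an
11-group ancient+modern island time transect (full continuity, discontinuity
at the forager/farmer, Bronze- or Iron-Age boundary, variants with two-way
migration, and panmictic vs east-west structured modern demes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .mito_data import Alignment, SampleMetadata

DEFAULT_GENERATION_TIME = 25.0  # years


class ModelError(ValueError):
    """Invalid demographic model or sampling scheme."""


class SimulationError(RuntimeError):
    """Raised when a simulation cannot complete (e.g. non-coalescence)."""


# ---------------------------------------------------------------------------
# Model types


@dataclass(frozen=True)
class Event:
    """Backward-in-time lineage movement at ``time_gen``.

    All lineages currently in ``source`` are moved to ``sink``.  ``kind``
    distinguishes a plain backward merge (population split, forward in time)
    from a replacement/discontinuity (the sink's recent lineages derive
    entirely from the source population forward in time); the engine treats
    both identically — the semantics live in which samples are old enough
    to enter the source deme after (backward of) the event.
    """

    time_gen: float
    kind: str  # "merge" | "replacement"
    source: str
    sink: str


@dataclass(frozen=True)
class MigrationEpoch:
    """Backward migration rates active on [t_start_gen, t_end_gen).

    ``rates[i][j]`` is the per-generation probability that a lineage in
    deme i moves to deme j, backward in time.
    """

    t_start_gen: float
    t_end_gen: float
    rates: dict[str, dict[str, float]]


@dataclass
class DemographicModel:
    """Named demes with epoch-wise haploid Ne, events and migration."""

    demes: dict[str, list[tuple[float, float]]]  # name -> [(t_start_gen, Ne), ...]
    events: list[Event] = field(default_factory=list)
    migration_epochs: list[MigrationEpoch] = field(default_factory=list)
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        for name, epochs in self.demes.items():
            if not epochs:
                raise ModelError(f"deme {name}: no epochs")
            times = [t for t, _ in epochs]
            if times != sorted(times):
                raise ModelError(f"deme {name}: epochs must be time-sorted")
            if any(ne <= 0 for _, ne in epochs):
                raise ModelError(f"deme {name}: Ne must be > 0")
        last = -math.inf
        for ev in self.events:
            if ev.time_gen < last:
                raise ModelError("events must be sorted by time")
            last = ev.time_gen
            for d in (ev.source, ev.sink):
                if d not in self.demes:
                    raise ModelError(f"event references unknown deme {d!r}")
        for me in self.migration_epochs:
            if me.t_end_gen <= me.t_start_gen:
                raise ModelError("migration epoch must have t_end > t_start")
            for src, row in me.rates.items():
                if src not in self.demes:
                    raise ModelError(f"migration from unknown deme {src!r}")
                total = 0.0
                for dst, r in row.items():
                    if dst not in self.demes:
                        raise ModelError(f"migration to unknown deme {dst!r}")
                    if not (0.0 <= r <= 1.0):
                        raise ModelError("migration rates must lie in [0, 1]")
                    total += r
                if total > 1.0 + 1e-12:
                    raise ModelError("migration row sums must be <= 1")

    def ne_at(self, deme: str, t: float) -> float:
        ne = self.demes[deme][0][1]
        for t_start, size in self.demes[deme]:
            if t_start <= t:
                ne = size
            else:
                break
        return ne


@dataclass(frozen=True)
class SampleGroup:
    """A sampling group: n tips from one deme at a (possibly uncertain) age.

    ``age_mean_years``/``age_sd_years`` describe a normal radiocarbon prior
    in years B.P. (sd 0 means fixed).  Ages are truncated at 0.
    """

    name: str
    deme: str
    n: int
    age_mean_years: float = 0.0
    age_sd_years: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ModelError(f"group {self.name}: n must be >= 1")
        if self.age_mean_years < 0 or self.age_sd_years < 0:
            raise ModelError(f"group {self.name}: ages must be >= 0")


@dataclass
class SamplingScheme:
    groups: list[SampleGroup]

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def draw_ages(self, rng: np.random.Generator) -> dict[str, float]:
        """One age (years B.P.) per group from its truncated-normal prior."""
        ages = {}
        for g in self.groups:
            if g.age_sd_years == 0:
                ages[g.name] = g.age_mean_years
            else:
                a = rng.normal(g.age_mean_years, g.age_sd_years)
                ages[g.name] = max(0.0, a)
        return ages


@dataclass(frozen=True)
class MutationModel:
    """Finite-site mutation overlay: repeat hits allowed.

    ``mu_site_gen`` is the per-site per-generation rate; ``ts_tv_ratio`` is
    kappa, the transition:transversion rate bias (1 = unbiased).
    """

    L: int = 16_569
    mu_site_gen: float = 4.16e-7
    ts_tv_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ModelError("L must be >= 1")
        if self.mu_site_gen < 0:
            raise ModelError("mu_site_gen must be >= 0")


# ---------------------------------------------------------------------------
# Priors


@dataclass(frozen=True)
class Prior:
    """A univariate prior: uniform, loguniform, normal or fixed."""

    dist: str
    a: float
    b: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.a
        if self.dist == "uniform":
            return float(rng.uniform(self.a, self.b))
        if self.dist == "loguniform":
            if self.a <= 0:
                raise ModelError("loguniform requires a > 0")
            return float(np.exp(rng.uniform(np.log(self.a), np.log(self.b))))
        if self.dist == "normal":
            return float(rng.normal(self.a, self.b))
        raise ModelError(f"unknown prior distribution {self.dist!r}")


PriorSpec = dict[str, Prior]


def draw_parameters(priors: PriorSpec, rng: np.random.Generator) -> dict[str, float]:
    """One draw per parameter, in the order the spec dict declares them."""
    return {name: p.draw(rng) for name, p in priors.items()}


# ---------------------------------------------------------------------------
# Genealogy


@dataclass
class Genealogy:
    """Rooted genealogy; node times in generations backward from present.

    Tips are nodes ``0 .. n_tips-1``; internal nodes follow in coalescence
    order, the last being the root (parent -1).
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    tip_ids: list[str]
    tip_groups: list[str]
    tip_demes: list[str]
    node_deme: list[str]

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.time[p] - self.time[node])

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def total_branch_length(self) -> float:
        return float(
            sum(self.branch_length(i) for i in range(len(self.parent)) if self.parent[i] >= 0)
        )


def simulate_genealogy(
    model: DemographicModel,
    scheme: SamplingScheme,
    rng: np.random.Generator | int,
    tip_times_gen: dict[str, float] | None = None,
    max_time_gen: float = 5e7,
) -> Genealogy:
    """Exact structured-coalescent realization honoring tip sampling times.

    ``tip_times_gen`` fixes each group's entry time in generations; when
    omitted, group ages are drawn from their radiocarbon priors and divided
    by the model's generation time.

    Raises :class:`SimulationError` if lineages fail to find a common
    ancestor before ``max_time_gen`` (e.g. isolated demes with no
    migration or merge events).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if scheme.n_total < 2:
        raise ModelError("need at least 2 samples")

    if tip_times_gen is None:
        ages = scheme.draw_ages(rng)
        tip_times_gen = {g.name: ages[g.name] / model.generation_time for g in scheme.groups}

    # Tip nodes, ordered by scheme group then index.
    tip_ids, tip_groups, tip_demes, tip_time = [], [], [], []
    for g in scheme.groups:
        if g.deme not in model.demes:
            raise ModelError(f"group {g.name}: unknown deme {g.deme!r}")
        for i in range(g.n):
            tip_ids.append(f"{g.name}_{i}")
            tip_groups.append(g.name)
            tip_demes.append(g.deme)
            tip_time.append(tip_times_gen[g.name])

    n_tips = len(tip_ids)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    node_time[:n_tips] = tip_time
    node_deme: list[str] = list(tip_demes) + [""] * (n_tips - 1)

    pending = sorted(range(n_tips), key=lambda i: tip_time[i])
    lineages: dict[str, list[int]] = {d: [] for d in model.demes}
    next_node = n_tips

    # Rate-change breakpoints: tip entries, model events, deme epoch starts
    # and migration epoch boundaries.
    breakpoints: set[float] = set()
    for epochs in model.demes.values():
        breakpoints.update(t for t, _ in epochs)
    for me in model.migration_epochs:
        breakpoints.update((me.t_start_gen, me.t_end_gen))
    event_iter = iter(model.events)

    t = 0.0
    p_idx = 0  # index into pending tips
    next_event = next(event_iter, None)
    n_active = 0

    def enter_tips_at(t_now: float) -> None:
        nonlocal p_idx, n_active
        while p_idx < len(pending) and tip_time[pending[p_idx]] <= t_now + 1e-12:
            i = pending[p_idx]
            lineages[tip_demes[i]].append(i)
            n_active += 1
            p_idx += 1

    enter_tips_at(0.0)

    def migration_rates_at(t_now: float) -> dict[str, dict[str, float]] | None:
        for me in model.migration_epochs:
            if me.t_start_gen <= t_now < me.t_end_gen:
                return me.rates
        return None

    while n_active > 1 or p_idx < len(pending):
        if t > max_time_gen:
            raise SimulationError(f"no common ancestor before {max_time_gen:g} generations")
        # Next structural breakpoint.
        candidates = []
        if p_idx < len(pending):
            candidates.append(tip_time[pending[p_idx]])
        if next_event is not None:
            candidates.append(next_event.time_gen)
        candidates.extend(b for b in breakpoints if b > t + 1e-12)
        next_bp = min(candidates) if candidates else math.inf

        # Current total rates.
        coal_rate: dict[str, float] = {}
        mig = migration_rates_at(t)
        mig_rate: dict[str, float] = {}
        total = 0.0
        for d, lin in lineages.items():
            k = len(lin)
            if k >= 2:
                r = k * (k - 1) / (2.0 * model.ne_at(d, t))
                coal_rate[d] = r
                total += r
            if mig is not None and k >= 1 and d in mig:
                r = k * sum(mig[d].values())
                if r > 0:
                    mig_rate[d] = r
                    total += r

        if total <= 0.0:
            if math.isinf(next_bp):
                raise SimulationError(
                    "lineages cannot coalesce: isolated demes with no "
                    "migration or merge events"
                )
            t = next_bp
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= next_bp:
                t = next_bp
                if math.isinf(t):  # pragma: no cover - guarded above
                    raise SimulationError("no further rate changes")
            else:
                t += wait
                u = rng.uniform(0.0, total)
                acc = 0.0
                done = False
                for d, r in coal_rate.items():
                    acc += r
                    if u < acc:
                        lin = lineages[d]
                        i, j = rng.choice(len(lin), size=2, replace=False)
                        a, b = lin[i], lin[j]
                        for idx in sorted((i, j), reverse=True):
                            lin.pop(idx)
                        parent[a] = parent[b] = next_node
                        node_time[next_node] = t
                        node_deme[next_node] = d
                        lin.append(next_node)
                        next_node += 1
                        n_active -= 1
                        done = True
                        break
                if not done:
                    for d, r in mig_rate.items():
                        acc += r
                        if u < acc:
                            lin = lineages[d]
                            i = int(rng.integers(len(lin)))
                            node = lin.pop(i)
                            row = mig[d]  # type: ignore[index]
                            dests = list(row)
                            w = np.array([row[x] for x in dests])
                            dest = dests[int(rng.choice(len(dests), p=w / w.sum()))]
                            lineages[dest].append(node)
                            done = True
                            break
                continue

        # Arrived at a breakpoint: admit tips and apply events due now.
        enter_tips_at(t)
        while next_event is not None and next_event.time_gen <= t + 1e-12:
            moved = lineages[next_event.source]
            lineages[next_event.sink].extend(moved)
            lineages[next_event.source] = []
            next_event = next(event_iter, None)
        breakpoints = {b for b in breakpoints if b > t + 1e-12}

    return Genealogy(
        parent=parent,
        time=node_time,
        n_tips=n_tips,
        tip_ids=tip_ids,
        tip_groups=tip_groups,
        tip_demes=tip_demes,
        node_deme=node_deme,
    )


# ---------------------------------------------------------------------------
# Mutation overlay

# Transition partner of each base (A<->G, C<->T) in the 0-5 code.
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# Transversion partners of each base.
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def mutate(
    genealogy: Genealogy,
    mut: MutationModel,
    rng: np.random.Generator | int,
    root_sequence: np.ndarray | None = None,
) -> Alignment:
    """Overlay finite-site mutations on a genealogy.

    Mutation counts per branch are Poisson(branch_length * mu * L); sites
    are uniform with repeat hits allowed; base changes are drawn with
    transition bias kappa (transition probability kappa/(kappa+2)).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    L = mut.L
    if root_sequence is None:
        root_sequence = rng.integers(0, 4, size=L).astype(np.uint8)
    else:
        root_sequence = np.asarray(root_sequence, dtype=np.uint8)
        if root_sequence.shape != (L,):
            raise ModelError("root sequence length mismatch")

    kappa = mut.ts_tv_ratio
    p_ts = kappa / (kappa + 2.0)
    children = genealogy.children()
    seqs: dict[int, np.ndarray] = {genealogy.root: root_sequence}
    tip_rows: dict[int, np.ndarray] = {}
    stack = [genealogy.root]
    while stack:
        node = stack.pop()
        seq = seqs.pop(node)
        if node < genealogy.n_tips:
            tip_rows[node] = seq
        for child in children[node]:
            blen = genealogy.branch_length(child)
            cseq = seq.copy()
            n_mut = rng.poisson(blen * mut.mu_site_gen * L)
            if n_mut:
                sites = rng.integers(0, L, size=n_mut)
                for s in sites:
                    base = cseq[s]
                    if rng.random() < p_ts:
                        cseq[s] = _TRANSITION[base]
                    else:
                        cseq[s] = _TRANSVERSIONS[base][int(rng.integers(2))]
            seqs[child] = cseq
            stack.append(child)

    matrix = np.vstack([tip_rows[i] for i in range(genealogy.n_tips)])
    return Alignment(list(genealogy.tip_ids), matrix)


# ---------------------------------------------------------------------------
# Model library: 11-group island time transect


#: The 11 analysis groups: (name, deme-in-structured-models, n,
#: mean age yr B.P., age sd yr).  Ages are representative midpoints of the
#: period each group occupies; the modern group is fixed at 0.
GROUPS_11: list[tuple[str, str, int, float, float]] = [
    ("uzzo_mesolithic", "sicily", 8, 9_100.0, 400.0),
    ("uzzo_neolithic", "sicily", 8, 7_000.0, 300.0),
    ("buffa_chalcolithic", "sicily", 4, 4_600.0, 200.0),
    ("buffa_bronze", "sicily", 3, 3_800.0, 200.0),
    ("bronze_sicily", "sicily", 14, 3_600.0, 300.0),
    ("iron_sicily", "sicily", 55, 2_700.0, 100.0),
    ("motya_phoenician", "phoenician", 3, 2_500.0, 100.0),
    ("baucina_greek", "greek", 3, 2_450.0, 100.0),
    ("segesta_islamic", "islamic", 5, 1_000.0, 80.0),
    ("segesta_christian", "sicily", 6, 800.0, 80.0),
    ("modern", "sicily", 236, 0.0, 0.0),
]

#: Period boundaries in years B.P. used as fixed event times.
BOUNDARY_MESO_NEO = 7_950.0
BOUNDARY_BRONZE = 4_449.0
BOUNDARY_IRON = 2_899.0
BOUNDARY_IRON_END = 2_550.0
BOUNDARY_MEDIEVAL = 1_399.0
BOUNDARY_MEDIEVAL_END = 458.0
DEEP_ANCESTRY = 25_000.0

#: Modern geogroup partition (sums to 236).
GEOGROUPS: dict[str, int] = {
    "agrigento": 36,
    "caltanissetta_enna": 21,
    "catania_siracusa": 17,
    "gela": 21,
    "messina": 17,
    "palermo_city": 65,
    "palermo_outer": 27,
    "ragusa": 12,
    "trapani": 20,
}

#: East/west geogroup blocks used by the structured modern model.  The
#: memberships follow geography (Palermo, Trapani and Agrigento on the
#: western side); the block labels themselves are arbitrary deme names.
GEOGROUP_WEST = ["palermo_city", "palermo_outer", "trapani", "agrigento"]
GEOGROUP_EAST = ["caltanissetta_enna", "catania_siracusa", "gela", "messina", "ragusa"]

MODEL_NAMES = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "Gpan", "Gst"]

#: Discontinuity boundary used by each lettered model (None = continuity).
_DISCONTINUITY = {
    "A": None,
    "B": None,
    "C": BOUNDARY_MESO_NEO,
    "D": BOUNDARY_BRONZE,
    "E": BOUNDARY_IRON,
    "F": None,
    "G": BOUNDARY_MESO_NEO,
    "H": BOUNDARY_BRONZE,
    "I": BOUNDARY_IRON,
    "Gpan": BOUNDARY_MESO_NEO,
    "Gst": BOUNDARY_MESO_NEO,
}
_WITH_MIGRATION = {"F", "G", "H", "I", "Gpan", "Gst"}


def default_priors(name: str) -> PriorSpec:
    """Shipped default priors: log-uniform Ne in [1e2, 1e5], uniform
    migration in [0, 0.01] (modern geogroup exchange up to 0.05)."""
    ne = lambda: Prior("loguniform", 1e2, 1e5)  # noqa: E731
    priors: PriorSpec = {"ne_sicily": ne(), "ne_ancestral": ne()}
    if name != "A":
        priors.update(
            ne_phoenician=ne(),
            ne_greek=ne(),
            ne_islamic=ne(),
        )
    if _DISCONTINUITY[name] is not None:
        priors["ne_forager"] = ne()
        priors["ne_incoming"] = ne()
    if name in _WITH_MIGRATION:
        priors["m_iron"] = Prior("uniform", 0.0, 0.01)
        priors["m_medieval"] = Prior("uniform", 0.0, 0.01)
    if name in ("Gpan", "Gst"):
        priors["ne_geogroup"] = Prior("loguniform", 1e2, 1e5)
        priors["m_modern"] = Prior("uniform", 0.0, 0.05)
    return priors


@dataclass
class ModelTemplate:
    """A demographic-model template: priors plus a builder over draws."""

    name: str
    priors: PriorSpec
    scheme: SamplingScheme
    builder: Callable[[dict[str, float]], DemographicModel]

    def instantiate(self, params: dict[str, float]) -> DemographicModel:
        return self.builder(params)


def _scaled_groups(scale: float) -> list[tuple[str, str, int, float, float]]:
    if scale == 1.0:
        return GROUPS_11
    return [
        (name, deme, max(2, math.ceil(n * scale)), age, sd)
        for name, deme, n, age, sd in GROUPS_11
    ]


def model_library(
    name: str,
    priors: PriorSpec | None = None,
    generation_time: float = DEFAULT_GENERATION_TIME,
    sample_scale: float = 1.0,
) -> ModelTemplate:
    """Build one of the named demographic-model templates.

    Models: A full continuity (single deme); B-E separate Mediterranean
    demes (Phoenician/Punic, Greek, Islamic) with a discontinuity at
    none / forager-farmer / Bronze / Iron boundary; F-I are B-E plus
    continuous two-way migration in the Iron-Age and medieval epochs;
    Gpan/Gst restructure the modern population into nine geogroup demes,
    panmictic vs an east-west split.

    ``sample_scale`` shrinks every group size (floor 2) for reduced-scale
    experiments.
    """
    if name not in MODEL_NAMES:
        raise ModelError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if priors is None:
        priors = default_priors(name)
    gt = generation_time
    groups_def = _scaled_groups(sample_scale)

    geo_demes = name in ("Gpan", "Gst")
    groups = []
    for gname, deme, n, age, sd in groups_def:
        if name == "A":
            deme = "sicily"
        if gname == "modern" and geo_demes:
            for geo, gn in GEOGROUPS.items():
                gn_scaled = max(2, math.ceil(gn * sample_scale))
                groups.append(SampleGroup(f"modern_{geo}", geo, gn_scaled, 0.0, 0.0))
        else:
            groups.append(SampleGroup(gname, deme, n, age, sd))
    scheme = SamplingScheme(groups)

    disc = _DISCONTINUITY[name]

    def builder(params: dict[str, float]) -> DemographicModel:
        t_deep = DEEP_ANCESTRY / gt
        demes: dict[str, list[tuple[float, float]]] = {}
        events: list[Event] = []
        migration: list[MigrationEpoch] = []

        sic_epochs: list[tuple[float, float]] = [(0.0, params["ne_sicily"])]
        if disc is not None:
            t_disc = disc / gt
            # Backward of the discontinuity the "sicily" deme holds the
            # pre-event (forager) population; post-event lineages move to
            # the incoming source which merges back at deep time.
            sic_epochs.append((t_disc, params["ne_forager"]))
            demes["incoming"] = [(0.0, params["ne_incoming"])]
            events.append(Event(t_disc, "replacement", "sicily", "incoming"))
            events.append(Event(t_deep, "merge", "incoming", "sicily"))
        sic_epochs.append((t_deep, params["ne_ancestral"]))
        demes["sicily"] = sic_epochs

        if name != "A":
            for d, key, t_split in (
                ("phoenician", "ne_phoenician", BOUNDARY_IRON / gt),
                ("greek", "ne_greek", BOUNDARY_IRON / gt),
                ("islamic", "ne_islamic", BOUNDARY_MEDIEVAL / gt),
            ):
                demes[d] = [(0.0, params[key])]
                events.append(Event(t_split, "merge", d, "sicily"))

        if name in _WITH_MIGRATION and name != "A":
            m_iron = params["m_iron"]
            if m_iron > 0:
                rates = {
                    "sicily": {"phoenician": m_iron, "greek": m_iron},
                    "phoenician": {"sicily": m_iron, "greek": m_iron},
                    "greek": {"sicily": m_iron, "phoenician": m_iron},
                }
                migration.append(
                    MigrationEpoch(BOUNDARY_IRON_END / gt, BOUNDARY_IRON / gt, rates)
                )
            m_med = params["m_medieval"]
            if m_med > 0:
                migration.append(
                    MigrationEpoch(
                        BOUNDARY_MEDIEVAL_END / gt,
                        BOUNDARY_MEDIEVAL / gt,
                        {
                            "sicily": {"islamic": m_med},
                            "islamic": {"sicily": m_med},
                        },
                    )
                )

        if geo_demes:
            t_geo = BOUNDARY_MEDIEVAL / gt
            for geo in GEOGROUPS:
                demes[geo] = [(0.0, params["ne_geogroup"])]
            # Merge order: all geogroups into sicily at the medieval boundary.
            for geo in GEOGROUPS:
                events.append(Event(t_geo, "merge", geo, "sicily"))
            m = params["m_modern"]
            if m > 0:
                if name == "Gpan":
                    blocks = [list(GEOGROUPS)]
                else:  # Gst: exchange only within the east / west blocks
                    blocks = [GEOGROUP_WEST, GEOGROUP_EAST]
                rates: dict[str, dict[str, float]] = {}
                for block in blocks:
                    for src in block:
                        rates[src] = {dst: m for dst in block if dst != src}
                migration.append(MigrationEpoch(0.0, t_geo, rates))

        events.sort(key=lambda e: e.time_gen)
        return DemographicModel(
            demes=demes,
            events=events,
            migration_epochs=migration,
            generation_time=gt,
        )

    return ModelTemplate(name=name, priors=priors, scheme=scheme, builder=builder)


# ---------------------------------------------------------------------------
# Dataset simulation


@dataclass
class SimulatedDataset:
    """One simulated study: alignment, metadata, drawn parameters."""

    alignment: Alignment
    metadata: list[SampleMetadata]
    params: dict[str, float]
    model_name: str
    genealogy: Genealogy | None = None


def simulate_dataset(
    template: ModelTemplate,
    mut: MutationModel,
    rng: np.random.Generator | int,
    keep_genealogy: bool = False,
) -> SimulatedDataset:
    """Draw parameters, simulate a genealogy and overlay mutations."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    params = draw_parameters(template.priors, rng)
    model = template.instantiate(params)
    ages = template.scheme.draw_ages(rng)
    tip_times = {g.name: ages[g.name] / model.generation_time for g in template.scheme.groups}
    genealogy = simulate_genealogy(model, template.scheme, rng, tip_times_gen=tip_times)
    aln = mutate(genealogy, mut, rng)
    meta = []
    for sid, group in zip(genealogy.tip_ids, genealogy.tip_groups):
        age = ages[group]
        geo = group.removeprefix("modern_") if group.startswith("modern_") else None
        meta.append(
            SampleMetadata(
                sample_id=sid,
                group=group,
                geogroup=geo,
                age_bp=age,
                age_ci95=(age, age),
            )
        )
    return SimulatedDataset(
        alignment=aln,
        metadata=meta,
        params=params,
        model_name=template.name,
        genealogy=genealogy if keep_genealogy else None,
    )
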
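"""Synthetic datasets with the statistical structure the analyses assume.

Generates genealogies of known age (star, Kingman coalescent, or serial
founder), drops Poisson mutations on them under the linear clock, structures
clades across regions by diagnostic motifs with target frequency profiles,
and emits a truth table (true ages, true centers, true native regions) so
every pipeline stage can be tested against known ground truth without any
external data.

Each sample's mutation history is recorded as an ordered event sequence;
shared ancestry is shared sequence prefix, so the true genealogy (with
branch labels, including back-mutations from intra-lineage repeat hits) is
reconstructed exactly as a prefix tree over those sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chronometry import ClockCalibration
from .colonization_model import FounderScenario
from .mtdna_io import Haplotype, HaplogroupDef, Mutation, cumulative_motif
from .network_builder import RootedCladeTree
from .phylogeography import GeoPoint, RegionTable, assign_native_region

#: Published-style regional frequency profiles of the four main U3 subclades
#: (columns U3*, U3a*, U3c*, U3b*) with per-region sample sizes; the default
#: target for synthetic region-structured datasets.
U3_REGION_PROFILES: dict[str, tuple[int, tuple[float, float, float, float]]] = {
    "Arabia": (34, (0.088, 0.294, 0.0, 0.618)),
    "East Africa": (25, (0.160, 0.360, 0.120, 0.360)),
    "West Africa": (62, (0.032, 0.500, 0.016, 0.452)),
    "Near East": (148, (0.338, 0.311, 0.040, 0.311)),
    "Middle East": (176, (0.188, 0.233, 0.074, 0.505)),
    "Caucasus": (68, (0.220, 0.147, 0.118, 0.515)),
    "Central Asia": (45, (0.267, 0.333, 0.0, 0.400)),
    "Russia": (30, (0.467, 0.300, 0.0, 0.233)),
    "North Europe": (51, (0.176, 0.667, 0.020, 0.137)),
    "West Europe": (84, (0.262, 0.548, 0.047, 0.143)),
    "East Europe": (29, (0.448, 0.173, 0.0, 0.379)),
    "The Balkans": (79, (0.430, 0.342, 0.0, 0.228)),
    "South Europe": (186, (0.210, 0.435, 0.027, 0.328)),
}
U3_SUBCLADE_COLUMNS = ("U3*", "U3a*", "U3c*", "U3b*")


@dataclass
class SitePool:
    """Positions available for mutation placement, with relative weights.

    The default pool spans the molecule (excluding the np 3107 placeholder)
    with a small hotspot set mutating 5x faster, so synthetic data exhibits
    the homoplasy that reticulation resolution and homoplasy counting need.
    """

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.positions) != len(self.weights) or (self.weights <= 0).any():
            raise ValueError("positions and positive weights must align")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def default(cls, hotspot_factor: float = 5.0) -> "SitePool":
        positions = np.array([p for p in range(100, 16300) if p != 3107])
        weights = np.ones(len(positions))
        hotspots = {16093, 16129, 16189, 16311, 16362, 152, 146, 150, 195, 16519}
        for i, p in enumerate(positions):
            if p in hotspots:
                weights[i] = hotspot_factor
        return cls(positions, weights)


@dataclass
class SimulationConfig:
    """Study-condition bundle for one synthetic dataset.

    ``clade_frequencies`` maps clade name -> {region -> target frequency};
    per-region frequencies may sum to less than 1, the remainder going to the
    forest root clade.  ``model`` is ``star`` (default: a clade radiating at
    ``age_years``), ``kingman`` (neutral coalescent rescaled to that root
    age), or ``serial-founder`` (colonization chain; regions = demes).
    """

    samples_per_region: dict[str, int]
    haplogroup_defs: Sequence[HaplogroupDef]
    clade_frequencies: Mapping[str, Mapping[str, float]]
    region_points: Mapping[str, GeoPoint] = field(default_factory=dict)
    model: str = "star"
    age_years: float = 50_000.0
    clock: ClockCalibration = field(default_factory=ClockCalibration)
    site_pool: SitePool = field(default_factory=SitePool.default)
    kingman_pop_size: float = 5_000.0
    founder_scenario: FounderScenario | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("star", "kingman", "serial-founder"):
            raise ValueError(f"unknown model {self.model!r}")
        for region in self.samples_per_region:
            tot = sum(f.get(region, 0.0) for f in self.clade_frequencies.values())
            if tot > 1 + 1e-9:
                raise ValueError(f"clade frequencies in {region!r} sum to {tot} > 1")


@dataclass
class SimulatedDataset:
    haplotypes: list[Haplotype]
    tree: RootedCladeTree
    truth: dict

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": sid, "true_clade": clade}
                for sid, clade in self.truth["sample_clade"].items()
            ]
        )


class _EventDraw:
    """Sequential mutation placement with intra-lineage repeat -> reversion."""

    def __init__(self, pool: SitePool, rng: np.random.Generator):
        self.pool = pool
        self.rng = rng
        self.counter = itertools.count()

    def events_for(self, n: int, state: set[int]) -> list[tuple[int, Mutation]]:
        """Draw n events given the lineage's current on-position set (mutated
        in place); each event carries a unique id for ancestry tracking."""
        out = []
        idx = self.rng.choice(len(self.pool.positions), size=n, p=self.pool.weights)
        for i in idx:
            pos = int(self.pool.positions[i])
            if pos in state:
                state.discard(pos)
                mut = Mutation(pos, "transition", back=True)
            else:
                state.add(pos)
                mut = Mutation(pos, "transition")
            out.append((next(self.counter), mut))
        return out


def _tree_from_event_sequences(
    samples: list[tuple[str, str, list[tuple[int, Mutation]]]],
    clade_roots: dict[str, tuple[Mutation, ...]],
) -> RootedCladeTree:
    """Prefix tree over (clade, event-sequence): the true genealogy.

    Samples are grouped under their clade node (branch label = cumulative
    motif); within a clade, shared event prefixes become internal branches.
    """
    tree = RootedCladeTree()
    root = tree.add_node("root", None)
    for clade in sorted(clade_roots):
        cnode = tree.add_node(clade, root, clade_roots[clade])
        members = [(sid, ev) for sid, c, ev in samples if c == clade]
        _insert_trie(tree, cnode, members)
    return tree


def _insert_trie(tree, parent, members, depth=0):
    finished = [sid for sid, ev in members if len(ev) == depth]
    ongoing: dict[int, list] = {}
    for sid, ev in members:
        if len(ev) > depth:
            ongoing.setdefault(ev[depth][0], []).append((sid, ev))
    for sid in finished:
        # sampled haplotype sits exactly at this node
        node = tree.nodes[parent]
        node.multiplicity += 1
        node.sample_ids = tuple(list(node.sample_ids) + [sid])
        if node.name == "" or node.name.startswith("anc"):
            node.name = sid
    for eid in sorted(ongoing):
        group = ongoing[eid]
        # extend the shared prefix as far as it stays shared
        j = depth
        first = group[0][1]
        while True:
            j += 1
            if any(len(ev) <= j for _, ev in group) or len(
                {ev[j][0] for _, ev in group}
            ) > 1:
                break
        label = tuple(m for _, m in first[depth:j])
        name = group[0][0] if len(group) == 1 and len(first) == j else f"anc{eid}"
        child = tree.add_node(name, parent, label)
        _insert_trie(tree, child, group, j)


def _clade_state(motif: tuple[Mutation, ...]) -> set[int]:
    return {m.position for m in motif if not m.back}


def _haplotype_from_state(
    state: set[int], sid: str, region: str, population: str
) -> Haplotype:
    muts = tuple(Mutation(p, "transition") for p in sorted(state))
    return Haplotype(muts, sid, region, population)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate haplotypes, the true genealogy, and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    draw = _EventDraw(cfg.site_pool, rng)
    defs = {d.name: d for d in cfg.haplogroup_defs}
    clades = sorted(cfg.clade_frequencies)
    roots = [d.name for d in cfg.haplogroup_defs if d.parent is None]
    root_clade = roots[0]
    clade_motifs = {c: cumulative_motif(c, defs) for c in clades}
    clade_motifs.setdefault(root_clade, cumulative_motif(root_clade, defs))

    # assign clades per region per the target profiles
    sample_specs: list[tuple[str, str, str]] = []  # (sid, region, clade)
    counter = itertools.count(1)
    for region in sorted(cfg.samples_per_region):
        n = cfg.samples_per_region[region]
        freqs = [cfg.clade_frequencies[c].get(region, 0.0) for c in clades]
        rest = max(0.0, 1.0 - sum(freqs))
        picks = rng.choice(
            len(clades) + 1, size=n, p=np.array(freqs + [rest])
        )
        for k in picks:
            clade = clades[k] if k < len(clades) else root_clade
            sample_specs.append((f"S{next(counter):04d}", region, clade))

    rate = 1.0 / cfg.clock.years_per_mutation
    samples: list[tuple[str, str, list]] = []  # (sid, clade, events)
    haps: list[Haplotype] = []

    if cfg.model == "star":
        for sid, region, clade in sample_specs:
            state = _clade_state(clade_motifs[clade])
            n_events = rng.poisson(cfg.age_years * rate)
            events = draw.events_for(n_events, state)
            samples.append((sid, clade, events))
            haps.append(_haplotype_from_state(state, sid, region, clade))
    elif cfg.model == "kingman":
        import msprime

        by_clade: dict[str, list[tuple[str, str]]] = {}
        for sid, region, clade in sample_specs:
            by_clade.setdefault(clade, []).append((sid, region))
        for clade in sorted(by_clade):
            members = by_clade[clade]
            if len(members) == 1:
                sid, region = members[0]
                state = _clade_state(clade_motifs[clade])
                events = draw.events_for(rng.poisson(cfg.age_years * rate), state)
                samples.append((sid, clade, events))
                haps.append(_haplotype_from_state(state, sid, region, clade))
                continue
            ts = msprime.sim_ancestry(
                samples=len(members),
                ploidy=1,
                population_size=cfg.kingman_pop_size,
                random_seed=int(rng.integers(1, 2**31 - 1)),
            )
            t = ts.first()
            scale = cfg.age_years / t.time(t.root)
            node_events: dict[int, list] = {}
            node_state: dict[int, set[int]] = {t.root: _clade_state(clade_motifs[clade])}
            node_prefix: dict[int, list] = {t.root: []}
            for u in t.nodes(order="preorder"):
                if u == t.root:
                    continue
                parent = t.parent(u)
                branch_years = (t.time(parent) - t.time(u)) * scale
                state = set(node_state[parent])
                events = draw.events_for(rng.poisson(branch_years * rate), state)
                node_state[u] = state
                node_prefix[u] = node_prefix[parent] + events
            for leaf, (sid, region) in zip(sorted(t.leaves(t.root)), members):
                samples.append((sid, clade, node_prefix[leaf]))
                haps.append(_haplotype_from_state(node_state[leaf], sid, region, clade))
    else:  # serial-founder
        sc = cfg.founder_scenario or FounderScenario(seed=cfg.seed)
        regions = sorted(cfg.samples_per_region)
        lam_step = sc.step_years * rate
        clade = root_clade
        base_state = _clade_state(clade_motifs[clade])
        pool_n = max(cfg.samples_per_region.values()) + sc.founders_per_step
        lineages = [
            (set(base_state), []) for _ in range(pool_n)
        ]  # (state, events) in deme 0
        demes = [lineages]
        for step in range(min(sc.n_steps, len(regions) - 1)):
            frontier = demes[-1]
            chosen = rng.choice(len(frontier), size=sc.founders_per_step, replace=False)
            demes.append([(set(frontier[i][0]), list(frontier[i][1])) for i in sorted(chosen)])
            for deme in demes:
                for state, events in deme:
                    events.extend(draw.events_for(rng.poisson(lam_step), state))
        for d_idx, region in enumerate(regions[: len(demes)]):
            n = cfg.samples_per_region[region]
            deme = demes[d_idx]
            take = rng.choice(len(deme), size=min(n, len(deme)), replace=False)
            for k, i in enumerate(sorted(take)):
                state, events = deme[i]
                sid = f"S{next(counter):04d}"
                samples.append((sid, clade, list(events)))
                haps.append(_haplotype_from_state(set(state), sid, region, clade))

    tree = _tree_from_event_sequences(
        samples, {c: clade_motifs[c] for c in {c for _, c, _ in samples}}
    )

    expected = _expected_region_table(cfg)
    truth = {
        "sample_clade": {sid: clade for sid, clade in
                         ((s, c) for s, c, _ in samples)},
        "clade_ages": {c: cfg.age_years for c in clades},
        "region_centers": dict(cfg.region_points),
        "native_region": assign_native_region(expected) if len(
            cfg.samples_per_region) >= 2 else {},
        "seed": cfg.seed,
    }
    return SimulatedDataset(haps, tree, truth)


def _expected_region_table(cfg: SimulationConfig) -> RegionTable:
    regions = sorted(cfg.samples_per_region)
    clades = sorted(cfg.clade_frequencies)
    counts = pd.DataFrame(0.0, index=clades, columns=regions)
    for c in clades:
        for r in regions:
            counts.loc[c, r] = cfg.clade_frequencies[c].get(r, 0.0) * cfg.samples_per_region[r]
    return RegionTable(counts.round(6))


def emit_region_profile_table(
    profiles: Mapping[str, tuple[int, tuple[float, ...]]] | None = None,
    columns: Sequence[str] = U3_SUBCLADE_COLUMNS,
    n_override: int | None = None,
    seed: int = 0,
) -> RegionTable:
    """Multinomial draws per region at the configured n against target
    frequency profiles (default: the packaged U3 regional profiles)."""
    profiles = profiles or U3_REGION_PROFILES
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(0, index=list(columns), columns=sorted(profiles), dtype=int)
    for region in sorted(profiles):
        n, freqs = profiles[region]
        n = n_override or n
        p = np.asarray(freqs, dtype=float)
        rest = max(0.0, 1.0 - p.sum())
        draw = rng.multinomial(n, np.append(p, rest) / (p.sum() + rest))
        counts[region] = draw[: len(columns)]
    return RegionTable(counts)


def default_region_points() -> dict[str, GeoPoint]:
    """Approximate representative coordinates for the packaged region names
    (synthetic configuration echoes for tests and demos)."""
    raw = {
        "Arabia": (23.0, 45.0), "East Africa": (9.0, 40.0),
        "West Africa": (31.0, -7.0), "Near East": (33.0, 36.0),
        "Middle East": (33.0, 44.0), "Caucasus": (42.0, 44.0),
        "Central Asia": (41.0, 64.0), "Russia": (55.0, 37.0),
        "North Europe": (60.0, 15.0), "West Europe": (47.0, 2.0),
        "East Europe": (50.0, 30.0), "The Balkans": (42.0, 21.0),
        "South Europe": (40.0, 4.0),
    }
    return {k: GeoPoint(lat, lon, k) for k, (lat, lon) in raw.items()}
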
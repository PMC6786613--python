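"""Single-run simulation engine.

Each time step every household, in this order:

1. grows its herd by the growth rate if the system total is still below
   carrying capacity at its (randomly ordered) turn;
2. suffers an individual environmental disaster with probability
   ``disaster_prob``, losing ``disaster_intensity`` of its herd (or a
   Uniform[0,1] fraction under the uniform-intensity variant);
3. if poor (herd < poverty threshold), receives the fixed transfer from its
   patron, or recruits a new patron among households above the patron
   threshold; with no patron available and herd below the death threshold,
   the household dies and is removed;
4. at end of step, any patron whose herd fell below the patron floor loses
   its status and its client links dissolve.

The engine stores the population as flat numpy arrays; a one-step random
stream protocol (documented per phase below) makes runs bit-reproducible
from a seed and lets a deliberately naive per-agent reference engine
reproduce results exactly for cross-validation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import NetworkTracker, gini
from .params import SimParams

NO_PATRON = -1

__all__ = [
    "Household",
    "World",
    "RunResult",
    "EventLog",
    "init_world",
    "grow_herds",
    "apply_disasters",
    "resolve_poverty",
    "update_patron_status",
    "step_world",
    "run_simulation",
]


@dataclass(frozen=True)
class Household:
    """Immutable snapshot of one herding household."""

    id: int
    herd: float
    alive: bool
    patron_id: int | None
    client_ids: frozenset[int]


@dataclass(frozen=True)
class RunResult:
    """Per-run dependent variables.

    ``final_gini`` is the population Gini index of end-of-run wealth, with
    wealth counted in whole animals (herds rounded to the nearest animal):
    the herd state is continuous, but a household whose herd has decayed to
    a vanishing fraction of an animal owns nothing measurable. When no
    alive household owns at least one animal (including total extinction)
    no household is distinguishable by wealth and the index is recorded
    as 0.
    """

    final_gini: float
    largest_network_size: int
    largest_network_duration: int
    end_population: int
    seed: int | None
    params: SimParams


class EventLog:
    """Optional per-step accounting and network-event trace.

    ``steps`` holds one dict per completed step with the animal flows
    (growth added, disaster losses, transfer volume, animals removed by
    deaths) and end-of-step aggregates. ``network_events`` holds
    (step, patron_id, client_id, "formed" | "dissolved") tuples.
    """

    def __init__(self) -> None:
        self.steps: list[dict] = []
        self.network_events: list[tuple[int, int, int, str]] = []


class World:
    """Mutable state of one simulation run.

    Households live in flat arrays indexed by id: ``herd`` (float animals),
    ``alive``, ``patron`` (id of patron or -1), ``n_clients`` and
    ``network_formed_step`` (step at which the current patron stint gained
    its first client; -1 when not a patron). ``capacity`` starts at
    ``params.carrying_capacity`` and may be changed between steps (the
    capacity-shift experiment does so).
    """

    def __init__(
        self,
        params: SimParams,
        seed: int | None = None,
        record_events: bool = False,
    ) -> None:
        params.validate()
        if seed is None:
            seed = params.seed
        self.params = params
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        n = params.n_households
        self.herd = np.full(n, float(params.initial_herd))
        self.alive = np.ones(n, dtype=bool)
        self.patron = np.full(n, NO_PATRON, dtype=np.int64)
        self.n_clients = np.zeros(n, dtype=np.int64)
        self.network_formed_step = np.full(n, -1, dtype=np.int64)
        self.capacity = float(params.carrying_capacity)
        self.step = 0
        self.tracker = NetworkTracker()
        self.log = EventLog() if record_events else None

    # -- inspection ------------------------------------------------------
    @property
    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    @property
    def total_animals(self) -> float:
        return float(self.herd[self.alive].sum())

    @property
    def households(self) -> list[Household]:
        out = []
        for i in range(self.params.n_households):
            pid = int(self.patron[i])
            clients = (
                frozenset(np.flatnonzero(self.patron == i).tolist())
                if self.n_clients[i] > 0
                else frozenset()
            )
            out.append(
                Household(
                    id=i,
                    herd=float(self.herd[i]),
                    alive=bool(self.alive[i]),
                    patron_id=pid if pid != NO_PATRON else None,
                    client_ids=clients,
                )
            )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, World):
            return NotImplemented
        return (
            self.params == other.params
            and self.step == other.step
            and self.capacity == other.capacity
            and np.array_equal(self.herd, other.herd)
            and np.array_equal(self.alive, other.alive)
            and np.array_equal(self.patron, other.patron)
            and np.array_equal(self.n_clients, other.n_clients)
            and self.rng.bit_generator.state == other.rng.bit_generator.state
        )


def init_world(
    params: SimParams, seed: int | None = None, record_events: bool = False
) -> World:
    """Create a world of ``n_households`` alive households, each holding
    ``initial_herd`` animals, with no links and a deterministically seeded
    random stream."""
    return World(params, seed=seed, record_events=record_events)


def grow_herds(world: World) -> World:
    """Growth phase.

    Households are visited in a fresh uniform random permutation; each grows
    its herd by ``growth_rate`` iff the running system total is still below
    capacity at its turn. The running total is the pre-phase total plus the
    growth granted so far, so a single grant may overshoot capacity (growth
    is not clipped). Random stream: one permutation of the alive ids.
    """
    p = world.params
    ids = world.alive_ids
    if ids.size == 0:
        return world
    order = ids[world.rng.permutation(ids.size)]
    total0 = float(world.herd[ids].sum())
    growth_added = 0.0
    if total0 < world.capacity:
        g = p.growth_rate
        h = world.herd[order]
        csum_prev = np.cumsum(h) - h
        # household j grows iff total0 + g * (herd mass already granted) < cap;
        # the check threshold is nondecreasing along the permutation, so the
        # grantees are exactly a prefix.
        m = int(np.searchsorted(total0 + g * csum_prev, world.capacity, side="left"))
        grown = order[:m]
        growth_added = float(g * h[:m].sum())
        world.herd[grown] *= 1.0 + g
    if world.log is not None:
        world.log.steps.append({"step": world.step, "growth": growth_added})
    return world


def apply_disasters(world: World) -> World:
    """Disaster phase.

    Each alive household independently suffers a disaster with probability
    ``disaster_prob``, losing the configured fraction of its herd (a fresh
    Uniform[0,1] fraction per event under the uniform-intensity variant).
    With ``enable_global_disasters`` one extra system-wide draw at the same
    probability hits every herd simultaneously. Random stream: one uniform
    per alive household (ascending id), then one uniform per hit household
    if intensities are random, then one uniform (plus one intensity draw if
    random) for the global event if enabled.
    """
    p = world.params
    ids = world.alive_ids
    loss = 0.0
    if ids.size > 0:
        u = world.rng.random(ids.size)
        hit = ids[u < p.disaster_prob]
        if hit.size > 0:
            if p.uniform_intensity:
                intens = world.rng.random(hit.size)
            else:
                intens = p.disaster_intensity
            removed = world.herd[hit] * intens
            loss += float(np.sum(removed))
            world.herd[hit] -= removed
        if p.enable_global_disasters:
            if world.rng.random() < p.disaster_prob:
                intensity = (
                    world.rng.random() if p.uniform_intensity else p.disaster_intensity
                )
                removed = world.herd[ids] * intensity
                loss += float(np.sum(removed))
                world.herd[ids] -= removed
    if world.log is not None:
        world.log.steps[-1]["disaster_loss"] = loss
    return world


def _dissolve_network(world: World, patron_id: int) -> None:
    clients = np.flatnonzero(world.patron == patron_id)
    if world.log is not None:
        for c in clients:
            world.log.network_events.append(
                (world.step, int(patron_id), int(c), "dissolved")
            )
    world.patron[clients] = NO_PATRON
    world.n_clients[patron_id] = 0
    world.network_formed_step[patron_id] = -1


def _die(world: World, i: int) -> float:
    """Remove household ``i`` permanently; returns animals removed."""
    removed = float(world.herd[i])
    world.herd[i] = 0.0
    world.alive[i] = False
    pid = int(world.patron[i])
    if pid != NO_PATRON:
        if world.log is not None:
            world.log.network_events.append((world.step, pid, int(i), "dissolved"))
        world.n_clients[pid] -= 1
        world.patron[i] = NO_PATRON
    if world.n_clients[i] > 0:
        _dissolve_network(world, i)
    return removed


def resolve_poverty(world: World) -> World:
    """Poverty / transfer / death phase (no-op with networks disabled).

    Households are visited in a fresh random permutation; each household
    whose herd is below the poverty threshold at its turn either (a)
    receives the fixed transfer from its live patron — granted only when the
    patron's herd covers the full amount, keeping herds non-negative — or
    (b) recruits a patron uniformly at random among alive, unlinked
    households above the patron threshold (existing patrons may accept new
    clients; linked clients may not serve), or (c), with no patron available
    and herd below the death threshold, dies and is removed (when deaths are
    enabled). Transfers conserve total animals exactly. Random stream: one
    permutation of the alive ids; one uniform integer per successful patron
    search.
    """
    p = world.params
    if not p.enable_networks:
        if world.log is not None:
            world.log.steps[-1].update(transfer_volume=0.0, death_loss=0.0)
        return world
    ids = world.alive_ids
    if ids.size == 0:
        if world.log is not None:
            world.log.steps[-1].update(transfer_volume=0.0, death_loss=0.0)
        return world
    order = ids[world.rng.permutation(ids.size)]

    herd = world.herd
    patron = world.patron
    n_clients = world.n_clients
    poverty = p.poverty_threshold
    amount = p.transfer_amount
    transfer_volume = 0.0
    death_loss = 0.0

    # Only households poor at phase start, or patrons (whose herds outgoing
    # transfers may deplete below the threshold mid-phase), can be poor at
    # their turn: transfers only ever reduce patron herds.
    candidates = order[(herd[order] < poverty) | (n_clients[order] > 0)]

    for i in candidates:
        i = int(i)
        if not world.alive[i] or herd[i] >= poverty:
            continue
        pid = int(patron[i])
        if pid != NO_PATRON:
            if herd[pid] >= amount:
                herd[pid] -= amount
                herd[i] += amount
                transfer_volume += amount
        elif n_clients[i] == 0:
            eligible = np.flatnonzero(
                world.alive & (herd > p.patron_threshold) & (patron == NO_PATRON)
            )
            if eligible.size > 0:
                k = int(eligible[world.rng.integers(eligible.size)])
                herd[k] -= amount
                herd[i] += amount
                transfer_volume += amount
                patron[i] = k
                if n_clients[k] == 0:
                    world.network_formed_step[k] = world.step
                n_clients[k] += 1
                if world.log is not None:
                    world.log.network_events.append((world.step, k, i, "formed"))
            elif p.enable_deaths and herd[i] < p.death_threshold:
                death_loss += _die(world, i)
        else:
            # A patron cannot become a client (role exclusivity): no patron
            # is available to it, so the death rule applies unchanged.
            if p.enable_deaths and herd[i] < p.death_threshold:
                death_loss += _die(world, i)

    if world.log is not None:
        world.log.steps[-1].update(
            transfer_volume=transfer_volume, death_loss=death_loss
        )
    return world


def update_patron_status(world: World) -> World:
    """End-of-step bookkeeping: every patron whose herd dropped below the
    patron floor loses patron status and all its client links dissolve
    (clients keep the animals already received). No-op with networks
    disabled."""
    if not world.params.enable_networks:
        return world
    collapsed = np.flatnonzero(
        world.alive & (world.n_clients > 0) & (world.herd < world.params.patron_floor)
    )
    for pid in collapsed:
        _dissolve_network(world, int(pid))
    return world


def step_world(world: World) -> World:
    """Advance the world by one time step (growth, disasters, poverty
    resolution, patron-floor check, network tracking)."""
    grow_herds(world)
    apply_disasters(world)
    resolve_poverty(world)
    update_patron_status(world)
    world.tracker.record(world)
    if world.log is not None:
        world.log.steps[-1].update(
            total_animals=world.total_animals,
            n_alive=int(world.alive.sum()),
        )
    world.step += 1
    return world


def _finalize(world: World) -> RunResult:
    # Wealth is counted in whole animals for the inequality measurement;
    # the continuous herd state is untouched.
    counted = np.round(world.herd[world.alive])
    if counted.size > 0 and counted.sum() > 0:
        final_gini = gini(counted)
    else:
        final_gini = 0.0
    size, duration = world.tracker.finalize()
    return RunResult(
        final_gini=final_gini,
        largest_network_size=size,
        largest_network_duration=duration,
        end_population=int(world.alive.sum()),
        seed=world.seed,
        params=world.params,
    )


def run_simulation(
    params: SimParams, seed: int | None = None, record_events: bool = False
) -> RunResult:
    """Run ``params.n_steps`` steps from a fresh world and return the
    dependent variables. Replaying the same seed reproduces the result
    bit-exactly."""
    world = init_world(params, seed=seed, record_events=record_events)
    for _ in range(params.n_steps):
        step_world(world)
    return _finalize(world)
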
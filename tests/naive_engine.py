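"""Deliberately naive per-agent reference engine used as an independent
oracle: plain Python objects, per-agent loops, per-visit capacity re-checks.

It shares the documented random-stream protocol with the production engine
(one permutation per phase, one uniform per alive household for disasters,
one integer draw per patron search) so that, given the same seed, it must
reproduce the optimized engine's results exactly.
"""
from __future__ import annotations

import numpy as np

from herdnet.metrics import gini
from herdnet.params import SimParams


class NaiveHousehold:
    def __init__(self, hid: int, herd: float) -> None:
        self.id = hid
        self.herd = herd
        self.alive = True
        self.patron: "NaiveHousehold | None" = None
        self.clients: set["NaiveHousehold"] = set()


class NaiveResult:
    def __init__(self, final_gini, size, duration, end_population, herds):
        self.final_gini = final_gini
        self.largest_network_size = size
        self.largest_network_duration = duration
        self.end_population = end_population
        self.herds = herds


def naive_run(params: SimParams, seed: int) -> NaiveResult:
    rng = np.random.default_rng(seed)
    hh = [NaiveHousehold(i, float(params.initial_herd)) for i in range(params.n_households)]
    capacity = float(params.carrying_capacity)
    formed: dict[int, int] = {}

    run_max_size = 0
    run_max_key = None
    cur_key = None
    cur_len = 0
    best: dict[tuple, int] = {}

    def die(h: NaiveHousehold) -> None:
        h.alive = False
        h.herd = 0.0
        if h.patron is not None:
            h.patron.clients.remove(h)
            h.patron = None
        for c in list(h.clients):
            c.patron = None
        h.clients.clear()
        formed.pop(h.id, None)

    for t in range(params.n_steps):
        alive = [h for h in hh if h.alive]
        if alive:
            # growth: visit in random order; the running total is the
            # pre-phase total plus growth granted so far
            order = [alive[j] for j in rng.permutation(len(alive))]
            total0 = float(np.sum([h.herd for h in alive]))
            granted = 0.0
            for h in order:
                if total0 + params.growth_rate * granted < capacity:
                    granted = granted + h.herd
                    h.herd *= 1.0 + params.growth_rate

            # disasters: one uniform per alive household in id order
            us = [rng.random() for _ in alive]
            hits = [h for h, u in zip(alive, us) if u < params.disaster_prob]
            if hits:
                if params.uniform_intensity:
                    intens = [rng.random() for _ in hits]
                else:
                    intens = [params.disaster_intensity] * len(hits)
                for h, inten in zip(hits, intens):
                    h.herd = h.herd - h.herd * inten
            if params.enable_global_disasters:
                if rng.random() < params.disaster_prob:
                    inten = rng.random() if params.uniform_intensity else params.disaster_intensity
                    for h in alive:
                        h.herd = h.herd - h.herd * inten

        # poverty resolution
        if params.enable_networks:
            alive = [h for h in hh if h.alive]
            if alive:
                order = [alive[j] for j in rng.permutation(len(alive))]
                for h in order:
                    if not h.alive or h.herd >= params.poverty_threshold:
                        continue
                    if h.patron is not None:
                        if h.patron.herd >= params.transfer_amount:
                            h.patron.herd -= params.transfer_amount
                            h.herd += params.transfer_amount
                    elif not h.clients:
                        eligible = [
                            o
                            for o in hh
                            if o.alive
                            and o.herd > params.patron_threshold
                            and o.patron is None
                        ]
                        if eligible:
                            k = eligible[int(rng.integers(len(eligible)))]
                            k.herd -= params.transfer_amount
                            h.herd += params.transfer_amount
                            h.patron = k
                            if not k.clients:
                                formed[k.id] = t
                            k.clients.add(h)
                        elif params.enable_deaths and h.herd < params.death_threshold:
                            die(h)
                    else:
                        if params.enable_deaths and h.herd < params.death_threshold:
                            die(h)

            # patron floor check
            for h in hh:
                if h.alive and h.clients and h.herd < params.patron_floor:
                    for c in list(h.clients):
                        c.patron = None
                    h.clients.clear()
                    formed.pop(h.id, None)

        # network tracking
        pats = [h for h in hh if h.alive and h.clients]
        if not pats:
            cur_key = None
            cur_len = 0
        else:
            size = max(len(h.clients) for h in pats)
            cands = [h for h in pats if len(h.clients) == size]
            lead = min(cands, key=lambda h: (formed[h.id], h.id))
            key = (lead.id, formed[lead.id])
            if key == cur_key:
                cur_len += 1
            else:
                cur_key = key
                cur_len = 1
            if cur_len > best.get(key, 0):
                best[key] = cur_len
            if size > run_max_size:
                run_max_size = size
                run_max_key = key

    survivors = [h for h in hh if h.alive]
    counted = np.round([h.herd for h in survivors])
    if len(counted) > 0 and counted.sum() > 0:
        final_gini = gini(counted)
    else:
        final_gini = 0.0
    duration = best.get(run_max_key, 0) if run_max_key is not None else 0
    return NaiveResult(
        final_gini,
        run_max_size,
        duration,
        len(survivors),
        np.array([h.herd for h in hh]),
    )
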
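"""Shared fixtures: small simulated worlds and hand-built trajectories."""
import warnings

import numpy as np
import pandas as pd
import pytest

import coalrank as cr
from coalrank.config import EloParams


def presence_frame(males, entry="2020-01-01", exit="2021-12-31",
                   group="G1", birth="2008-06-01"):
    """Presence table for hand-built scenarios (all males share the dates
    unless per-male tuples are given)."""
    rows = []
    for m in males:
        if isinstance(m, tuple):
            male, e, x = m
            rows.append((male, group, e, x, birth))
        else:
            rows.append((m, group, entry, exit, birth))
    return pd.DataFrame(rows, columns=["male", "group", "entry", "exit",
                                       "birth_date"])


def manual_trajectories(presence, updates, params=None):
    """EloTrajectories with update series set directly (oracle scaffolding).

    ``updates`` maps male -> list of (date, rating) pairs.
    """
    from coalrank.elo import EloTrajectories, _check_presence_frame, _day

    packed = {
        m: (np.array([_day(d) for d, _ in ups], dtype=int),
            np.array([r for _, r in ups], dtype=float))
        for m, ups in updates.items() if ups
    }
    return EloTrajectories(params or EloParams(), _check_presence_frame(presence),
                           packed)


@pytest.fixture(scope="session")
def small_world():
    """One small simulated world with injected effects, shared by the
    dataset/inference/bootstrap tests (single group, ~15 events)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pop = cr.generate_population(cr.PopulationConfig(
            n_groups=1, adult_males_per_group=10, study_days=400, seed=11))
        base = cr.simulate_agonism(pop, cr.AgonismConfig(), seed=12)
        events, roles, perturbed, truth = cr.simulate_coalitions(
            pop, base, cr.CoalitionSimConfig(event_rate=0.06), seed=13)
        inter = cr.simulate_agonism(perturbed, cr.AgonismConfig(), seed=12)
        traj = cr.compute_trajectories(inter, pop.presence)
        metrics = cr.event_metrics(events, traj, pop.presence)
        focal = cr.simulate_focal(pop, seed=14)
        rank = cr.build_rank_dataset(events, metrics, traj, pop.presence, focal)
    return {
        "population": pop, "interactions": inter, "events": events,
        "roles": roles, "trajectories": traj, "metrics": metrics,
        "focal": focal, "rank": rank, "truth": truth,
    }


@pytest.fixture(scope="session")
def rank_table(small_world):
    return small_world["rank"].dropna().reset_index(drop=True)
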
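"""Shared fixtures: toy structure builders and precomputed benchmark runs.

The benchmark fixtures are session-scoped because each involves grid tunnel
prediction over an ensemble; they are shared between the unit tests and the
acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest


from tunnelkit.ensembles import mixed_ensemble, time_point_ensemble
from tunnelkit.structures import Atom, Ensemble, Structure
from tunnelkit.synth import make_benchmark
from tunnelkit.tunnelcluster import cluster_tunnels
from tunnelkit.tunnelfinder import tunnels_for_structure

ORIGIN_START = (0.0, 0.0, 0.0)


def build_structure(
    coords,
    elements=None,
    names=None,
    resids=None,
    resnames=None,
    label="toy",
    time_ps=0.0,
    source_tag="frame",
    state_tag="synthetic",
    hetatm=None,
):
    """Construct a Structure from bare coordinates (defaults: all carbon)."""
    from tunnelkit.structures import vdw_radius_for

    coords = np.atleast_2d(np.asarray(coords, float))
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or [f"C{i+1}" for i in range(n)]
    resids = resids or [("A", 1 + i // 8, "") for i in range(n)]
    resnames = resnames or ["TOY"] * n
    hetatm = hetatm or [False] * n
    atoms = [
        Atom(
            serial=i + 1,
            name=names[i],
            element=elements[i],
            residue_id=resids[i],
            residue_name=resnames[i],
            coord=coords[i],
            vdw_radius=vdw_radius_for(elements[i]),
            is_hetatm=hetatm[i],
        )
        for i in range(n)
    ]
    return Structure(atoms, label, time_ps, source_tag, state_tag)


def pool_tunnels(ensemble, **kwargs):
    pool = []
    for member in ensemble:
        pool.extend(tunnels_for_structure(member, ORIGIN_START, **kwargs))
    return pool


@pytest.fixture(scope="session")
def basic_bundle():
    return make_benchmark("basic", seed=1)


@pytest.fixture(scope="session")
def basic_run(basic_bundle):
    d = basic_bundle["apo"]
    ens = time_point_ensemble(
        d["trajectory"], 100.0, d["crystal"], d["minimized"], name="basic"
    )
    pool = pool_tunnels(ens)
    return {
        "ensemble": ens,
        "pool": pool,
        "clusters": cluster_tunnels(pool),
        "truth": d["ground_truth"],
    }


@pytest.fixture(scope="session")
def gated_run():
    bundle = make_benchmark("gated", seed=1)
    d = bundle["apo"]
    # sample the 101-frame trajectory every 500 ps to keep the run small
    ens = time_point_ensemble(
        d["trajectory"], 500.0, d["crystal"], d["minimized"], name="gated"
    )
    pool = pool_tunnels(ens)
    return {
        "ensemble": ens,
        "pool": pool,
        "clusters": cluster_tunnels(pool),
        "truth": d["ground_truth"],
    }


@pytest.fixture(scope="session")
def pvr_run():
    bundle = make_benchmark("preferred_vs_rare", seed=1)
    d = bundle["apo"]
    ens = time_point_ensemble(
        d["trajectory"], 500.0, d["crystal"], d["minimized"], name="pvr"
    )
    pools = {
        0.75: pool_tunnels(ens),
        1.25: pool_tunnels(ens, probe_radius=1.25),
    }
    return {
        "ensemble": ens,
        "pools": pools,
        "clusters": cluster_tunnels(pools[0.75]),
        "truth": d["ground_truth"],
    }


@pytest.fixture(scope="session")
def apo_holo_run():
    bundle = make_benchmark("apo_holo", seed=1)
    parents = {}
    pools = {}
    clusters = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for state, d in bundle.items():
            parents[state] = time_point_ensemble(
                d["trajectory"], 2000.0, d["crystal"], name=state
            )
            pools[state] = pool_tunnels(parents[state])
            clusters[state] = cluster_tunnels(pools[state])
    mixed = mixed_ensemble(parents["apo"], parents["holo"])
    pools["mixed"] = pools["apo"] + pools["holo"]
    clusters["mixed"] = cluster_tunnels(pools["mixed"])
    return {
        "bundle": bundle,
        "parents": parents,
        "mixed": mixed,
        "pools": pools,
        "clusters": clusters,
        "truth": bundle["apo"]["ground_truth"],
    }
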
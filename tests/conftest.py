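import numpy as np
import pandas as pd
import pytest

from sociodep.sightings_io import Dataset, Photograph, Sighting


def ts(year=2020, month=1, day=1, hour=10, minute=0):
    return pd.Timestamp(year, month, day, hour, minute, tz="UTC")


def photo(pid, t, platform="shore", bay="bay1", vessel=None, inds=(),
          lon=51.0, lat=-46.3):
    return Photograph(pid, t, platform, vessel, bay, lon, lat,
                      frozenset(inds))


def sighting(sid, inds, year=2020, month=1, day=1, hour=10, n_photos=50,
             platform="vessel", vessel="V1", lon=50.0, lat=-46.0, site=None):
    t = ts(year, month, day, hour)
    return Sighting(sid, platform, t, t + pd.Timedelta(minutes=30), lon, lat,
                    n_photos, frozenset(inds), vessel_id=vessel if platform == "vessel" else None,
                    site_or_set_id=site or f"SET-{sid}")


@pytest.fixture(scope="session")
def small_dataset():
    """79-individual synthetic dataset used across read-only tests."""
    from sociodep.synthetic_data import generate
    ds, truth = generate(n_vessel_sightings=400, n_shore_sightings=60, seed=11)
    return ds, truth


def null_association_dataset(seed, n_ind=12, n_days=30, groups_per_day=2,
                             group_size=4):
    """Independent random group membership: no preferred associations."""
    rng = np.random.default_rng(seed)
    ids = [f"I{k:02d}" for k in range(n_ind)]
    out = []
    for d in range(n_days):
        for g in range(groups_per_day):
            mem = rng.choice(n_ind, size=group_size, replace=False)
            t = ts(2020, 1, 1) + pd.Timedelta(days=d, hours=2 * g)
            out.append(Sighting(f"S{d}-{g}", "vessel", t,
                                t + pd.Timedelta(minutes=30), 50.0, -46.0, 50,
                                frozenset(ids[m] for m in mem),
                                vessel_id="V1", site_or_set_id=f"SET{d}-{g}"))
    return Dataset(out)


def two_clique_dataset(n_days=30, clique_size=5):
    """Two disjoint always-together cliques sighted every day."""
    a = [f"A{k}" for k in range(clique_size)]
    b = [f"B{k}" for k in range(clique_size)]
    out = []
    for d in range(n_days):
        t = ts(2020, 1, 1) + pd.Timedelta(days=d)
        out.append(Sighting(f"SA{d}", "vessel", t, t + pd.Timedelta(minutes=30),
                            50.0, -46.0, 50, frozenset(a), vessel_id="V1",
                            site_or_set_id=f"SA{d}"))
        out.append(Sighting(f"SB{d}", "vessel", t + pd.Timedelta(hours=3),
                            t + pd.Timedelta(hours=3, minutes=30), 50.0, -46.0,
                            50, frozenset(b), vessel_id="V1",
                            site_or_set_id=f"SB{d}"))
    return Dataset(out)
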
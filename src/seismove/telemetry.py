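"""GPS telemetry ingestion and step construction.

Turns raw fix tables into season-labelled, weighted movement steps:
rarefaction to the analysis fix interval, classification of fixes into
movement vs stationary bouts (resting, feeding on a kill), biological-season
assignment per species, step geometry (length, turn angle, rate in m/h) and
the minimum-locations inclusion filters.

Fixes are carried as a pandas DataFrame with columns ``animal_id``,
``species`` (wolf|bear), ``sex`` (F|M), ``group`` (pack/unit), ``t``
(timezone-naive pandas Timestamp), ``x``, ``y`` (planar metres) and
``weight`` (1/PFix, >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIX_COLUMNS = ["animal_id", "species", "sex", "group", "t", "x", "y", "weight"]

#: Species-specific stationary-bout thresholds: (radius m, min duration h).
STATIONARY_THRESHOLDS = {"wolf": (300.0, 6.0), "bear": (100.0, 7.0)}

#: Gap beyond which successive steps count as independent clusters (hours).
CLUSTER_GAPS_H = {"wolf": 5 * 24.0, "bear": 24.0}

#: Nominal fix interval per species (hours).
NOMINAL_INTERVALS_H = {"wolf": 2.0, "bear": 1.0}


@dataclass
class Track:
    """Time-ordered fixes of one animal.

    ``fixes`` rows are sorted by time; timestamps must be strictly
    increasing and all rows share ``animal_id``.
    """

    animal_id: str
    fixes: pd.DataFrame
    nominal_interval: float  # hours

    def __post_init__(self) -> None:
        f = self.fixes.reset_index(drop=True)
        if len(f) and not f["animal_id"].eq(self.animal_id).all():
            raise ValueError("all fixes must share the track's animal_id")
        if len(f) > 1:
            dt = f["t"].diff().dropna()
            if (dt <= pd.Timedelta(0)).any():
                raise ValueError("timestamps must be strictly increasing")
        if len(f) and not np.isfinite(f[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")
        self.fixes = f

    def __len__(self) -> int:
        return len(self.fixes)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(track: Track, interval: float, tolerance_min: float = 5.0) -> Track:
    """Thin a track to one fix per `interval` hours.

    Greedy forward walk: keep the first fix, then the next fix whose spacing
    from the last kept fix is `interval` +/- `tolerance_min` minutes; fixes
    arriving early are dropped, and if a gap overshoots the window the next
    available fix restarts the schedule (gaps are preserved, never filled).
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    f = track.fixes
    if len(f) == 0:
        raise ValueError("rarefied track is empty")
    target = pd.Timedelta(hours=interval)
    tol = pd.Timedelta(minutes=tolerance_min)
    keep = [0]
    for i in range(1, len(f)):
        dt = f["t"].iloc[i] - f["t"].iloc[keep[-1]]
        if dt < target - tol:
            continue  # too soon
        keep.append(i)
    out = f.iloc[keep].reset_index(drop=True)
    return Track(track.animal_id, out, nominal_interval=interval)


# ---------------------------------------------------------------------------
# Stationary classification
# ---------------------------------------------------------------------------

def classify_stationary(track: Track, radius: float,
                        min_duration: float) -> np.ndarray:
    """Label each fix ``"movement"`` or ``"stationary"``.

    A maximal run of consecutive fixes is stationary iff its time span
    exceeds ``min_duration`` hours and every fix lies within ``radius``
    metres of the run centroid. Runs are grown greedily from the earliest
    unlabelled fix, which makes the labels deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    f = track.fixes
    n = len(f)
    labels = np.full(n, "movement", dtype=object)
    if n == 0:
        return labels
    t = f["t"].to_numpy()
    xy = f[["x", "y"]].to_numpy(dtype=float)
    min_dt = np.timedelta64(int(min_duration * 3600), "s")

    i = 0
    while i < n:
        # grow [i, j] while all member fixes stay within radius of the
        # running centroid
        j = i
        best_j = -1
        while j + 1 < n:
            window = xy[i:j + 2]
            centroid = window.mean(axis=0)
            if np.hypot(*(window - centroid).T).max() <= radius:
                j += 1
                if t[j] - t[i] > min_dt:
                    best_j = j
            else:
                break
        if best_j >= 0:
            labels[i:best_j + 1] = "stationary"
            i = best_j + 1
        else:
            i += 1
    return labels


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

_BEAR_SEASONS = [  # (season, (start month, day), (end month, day)) inclusive
    ("spring", (5, 1), (6, 15)),
    ("summer", (6, 16), (7, 31)),
    ("fall", (8, 1), (10, 15)),
]
_WOLF_SEASONS = [
    ("denning", (4, 20), (6, 30)),
    ("rendezvous", (7, 1), (9, 20)),
    # nomadic 21 Sep - 19 Apr wraps the year boundary; handled below
]

OUTSIDE_SEASON = "outside-study-season"


def assign_season(t, species: str):
    """Biological season of a timestamp.

    Wolves: denning 20 Apr-30 Jun, rendezvous 1 Jul-20 Sep, nomadic
    21 Sep-19 Apr (the calendar covers every day). Bears: spring
    1 May-15 Jun, summer 16 Jun-31 Jul, fall 1 Aug-15 Oct; dates outside
    those windows return ``"outside-study-season"``.
    """
    ts = pd.Series(pd.to_datetime(t))
    md = ts.dt.month * 100 + ts.dt.day
    if species == "wolf":
        out = pd.Series("nomadic", index=ts.index, dtype=object)
        for season, (m0, d0), (m1, d1) in _WOLF_SEASONS:
            out[(md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)] = season
    elif species == "bear":
        out = pd.Series(OUTSIDE_SEASON, index=ts.index, dtype=object)
        for season, (m0, d0), (m1, d1) in _BEAR_SEASONS:
            out[(md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)] = season
    else:
        raise ValueError(f"unknown species: {species!r}")
    if np.isscalar(t) or isinstance(t, (pd.Timestamp, str)):
        return out.iloc[0]
    return out.to_numpy()


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

STEP_COLUMNS = ["animal_id", "species", "sex", "group", "t0", "x0", "y0",
                "x1", "y1", "length", "duration", "rate", "bearing",
                "turn_angle", "season", "weight"]


def build_steps(track: Track, states=None,
                duration_tolerance_min: float = 5.0) -> pd.DataFrame:
    """Steps between consecutive movement fixes at the nominal interval.

    One step per consecutive pair of movement-state fixes whose spacing
    matches the track's nominal interval (+/- tolerance). Turn angle is the
    signed change in bearing from the previous retained step and is NaN for
    a step with no predecessor. Rates are m/h: a 1,000-m step over 2 h is
    500 m/h.

    Returns a DataFrame with columns ``animal_id``, ``species``, ``sex``,
    ``group``, ``t0``, ``x0``, ``y0``, ``x1``, ``y1``, ``length``,
    ``duration``, ``rate``, ``bearing``, ``turn_angle``, ``season``,
    ``weight``.
    """
    f = track.fixes
    if states is None:
        states = np.full(len(f), "movement", dtype=object)
    states = np.asarray(states, dtype=object)
    move_idx = np.flatnonzero(states == "movement")
    if len(move_idx) < 2:
        return pd.DataFrame(columns=STEP_COLUMNS)
    a = move_idx[:-1]
    b = move_idx[1:]
    t = f["t"].to_numpy()
    tol = np.timedelta64(int(duration_tolerance_min * 60), "s")
    target = np.timedelta64(int(track.nominal_interval * 3600), "s")
    ok = np.abs((t[b] - t[a]) - target) <= tol
    a, b = a[ok], b[ok]
    if len(a) == 0:
        return pd.DataFrame(columns=STEP_COLUMNS)
    x = f["x"].to_numpy(dtype=float)
    y = f["y"].to_numpy(dtype=float)
    dx, dy = x[b] - x[a], y[b] - y[a]
    length = np.hypot(dx, dy)
    duration = (t[b] - t[a]) / np.timedelta64(1, "h")
    bearing = np.arctan2(dy, dx)
    # turn angle only where the previous retained step ends at this start
    turn = np.full(len(a), np.nan)
    chained = np.flatnonzero(b[:-1] == a[1:]) + 1
    turn[chained] = ((bearing[chained] - bearing[chained - 1] + np.pi)
                     % (2 * np.pi) - np.pi)
    species = f["species"].iloc[0]
    return pd.DataFrame({
        "animal_id": track.animal_id,
        "species": f["species"].to_numpy()[a],
        "sex": f["sex"].to_numpy()[a],
        "group": f["group"].to_numpy()[a],
        "t0": t[a],
        "x0": x[a], "y0": y[a], "x1": x[b], "y1": y[b],
        "length": length,
        "duration": duration,
        "rate": length / duration,
        "bearing": bearing,
        "turn_angle": turn,
        "season": assign_season(pd.Series(t[a]), species),
        "weight": f["weight"].to_numpy(dtype=float)[a],
    })


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

def apply_inclusion_filters(steps: pd.DataFrame, min_per_season: int = 40):
    """Drop animal-seasons with too few movement locations.

    An animal is retained for a season only if it has at least
    ``min_per_season`` steps there. Returns ``(filtered steps, report)``
    where the report lists per animal-season counts and the keep decision.
    """
    if len(steps) == 0:
        raise ValueError("no steps to filter")
    counts = (steps.groupby(["animal_id", "season"], observed=True)
              .size().rename("n_locations").reset_index())
    counts["retained"] = counts["n_locations"] >= min_per_season
    keep_keys = set(map(tuple, counts.loc[counts["retained"],
                                          ["animal_id", "season"]].to_numpy()))
    mask = [(a, s) in keep_keys
            for a, s in zip(steps["animal_id"], steps["season"])]
    out = steps.loc[mask].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(
            "all data excluded by inclusion filter; report:\n"
            + counts.to_string(index=False))
    return out, counts


def tracks_from_fixes(fixes: pd.DataFrame) -> list[Track]:
    """Split a fix table into per-animal Tracks (nominal interval by species)."""
    tracks = []
    for animal_id, grp in fixes.groupby("animal_id", sort=True):
        grp = grp.sort_values("t")
        species = grp["species"].iloc[0]
        tracks.append(Track(animal_id, grp,
                            NOMINAL_INTERVALS_H.get(species, 1.0)))
    return tracks
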
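"""Suspicion-of-infection detection: antibiotic courses, qualifying starts,
and culture pairing under the 24 h / 72 h proximity rules.

A *course* groups doses of one drug whose consecutive gaps are at most 48 h
("within two days"); only the first dose of a course can anchor a suspicion.
A course start qualifies only if at least two doses of *any* antibiotic fall
within 96 h of it (one-off prophylaxis never qualifies). A qualifying start
``t_abx`` pairs with a culture drawn at ``t_cult`` when the antibiotic came
first and the culture followed within 24 h, or the culture came first and the
antibiotic followed within 72 h. All boundaries are inclusive, and
simultaneous events count as antibiotic-first. ``t_suspicion`` of an episode
is the earlier of the pair; a stay's suspicion time is its earliest episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COURSE_GAP_HOURS = 48.0
QUALIFY_WINDOW_HOURS = 96.0
ABX_FIRST_LIMIT_HOURS = 24.0
CULTURE_FIRST_LIMIT_HOURS = 72.0


@dataclass(frozen=True)
class AbxCourse:
    stay_id: int
    drug: str
    start_time: float
    dose_times: tuple[float, ...]


@dataclass(frozen=True)
class SuspicionEpisode:
    stay_id: int
    t_abx: float
    t_cult: float
    t_suspicion: float


def build_courses(doses: pd.DataFrame) -> list[AbxCourse]:
    """Partition dose events into courses per (stay, drug).

    Doses are taken in time order; a gap above 48 h starts a new course
    (a gap of exactly 48 h stays in-course).
    """
    courses: list[AbxCourse] = []
    if len(doses) == 0:
        return courses
    for (stay_id, drug), g in doses.groupby(["stay_id", "drug"], sort=True):
        times = np.sort(g["time"].to_numpy(dtype=float))
        current = [times[0]]
        for t in times[1:]:
            if t - current[-1] > COURSE_GAP_HOURS:
                courses.append(AbxCourse(stay_id, drug, current[0], tuple(current)))
                current = [t]
            else:
                current.append(t)
        courses.append(AbxCourse(stay_id, drug, current[0], tuple(current)))
    courses.sort(key=lambda c: (c.stay_id, c.start_time, c.drug))
    return courses


def qualifying_abx_times(courses: list[AbxCourse], all_doses: pd.DataFrame) -> pd.DataFrame:
    """Course starts with >= 2 doses (pooled over drugs, per stay) within 96 h.

    Returns a DataFrame (stay_id, t_abx) sorted ascending within stay.
    """
    rows = []
    dose_by_stay = {
        sid: np.sort(g["time"].to_numpy(dtype=float))
        for sid, g in all_doses.groupby("stay_id", sort=False)
    } if len(all_doses) else {}
    for course in courses:
        pool = dose_by_stay.get(course.stay_id, np.empty(0))
        s = course.start_time
        n_in_window = int(np.sum((pool >= s) & (pool <= s + QUALIFY_WINDOW_HOURS)))
        if n_in_window >= 2:
            rows.append((course.stay_id, s))
    out = pd.DataFrame(rows, columns=["stay_id", "t_abx"])
    return out.drop_duplicates().sort_values(["stay_id", "t_abx"], kind="mergesort").reset_index(drop=True)


def pair_suspicion(abx_times: pd.DataFrame, cultures: pd.DataFrame,
                   include_other_specimens: bool = False) -> list[SuspicionEpisode]:
    """All (qualifying antibiotic start, culture) pairs meeting the proximity rule.

    Cultures are restricted to blood specimens unless
    ``include_other_specimens`` is set. Episodes are sorted by
    (stay, t_suspicion, t_abx, t_cult).
    """
    episodes: list[SuspicionEpisode] = []
    if len(cultures):
        cult = cultures if include_other_specimens else cultures[cultures["specimen"] == "blood"]
    else:
        cult = cultures
    if len(abx_times) == 0 or len(cult) == 0:
        return episodes
    cult_by_stay = {sid: g["time"].to_numpy(dtype=float) for sid, g in cult.groupby("stay_id", sort=False)}
    for sid, t_abx in zip(abx_times["stay_id"].to_numpy(), abx_times["t_abx"].to_numpy(dtype=float)):
        for t_cult in cult_by_stay.get(sid, ()):
            if t_abx <= t_cult:
                ok = (t_cult - t_abx) <= ABX_FIRST_LIMIT_HOURS
            else:
                ok = (t_abx - t_cult) <= CULTURE_FIRST_LIMIT_HOURS
            if ok:
                episodes.append(SuspicionEpisode(sid, float(t_abx), float(t_cult),
                                                float(min(t_abx, t_cult))))
    episodes.sort(key=lambda e: (e.stay_id, e.t_suspicion, e.t_abx, e.t_cult))
    return episodes


def first_suspicion(episodes: list[SuspicionEpisode]) -> float | None:
    """Earliest t_suspicion among the episodes, or None."""
    if not episodes:
        return None
    return min(e.t_suspicion for e in episodes)


def compute_suspicion(doses: pd.DataFrame, cultures: pd.DataFrame, stays: pd.DataFrame,
                      include_other_specimens: bool = False) -> pd.DataFrame:
    """Per-stay suspicion summary: earliest episode's t_abx, t_cult, t_suspicion.

    One row per stay in ``stays``; NaN where no qualifying episode exists.
    """
    courses = build_courses(doses)
    qualifying = qualifying_abx_times(courses, doses)
    episodes = pair_suspicion(qualifying, cultures, include_other_specimens)
    first: dict[int, SuspicionEpisode] = {}
    for ep in episodes:  # sorted by (stay, t_suspicion)
        first.setdefault(ep.stay_id, ep)
    rows = []
    for sid in stays["stay_id"].to_numpy():
        ep = first.get(sid)
        if ep is None:
            rows.append((sid, np.nan, np.nan, np.nan))
        else:
            rows.append((sid, ep.t_abx, ep.t_cult, ep.t_suspicion))
    return pd.DataFrame(rows, columns=["stay_id", "t_abx", "t_cult", "t_suspicion"])
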
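"""Synthetic rosters and desk-study replication for the ID codec.

The reference study design: 89 responders (medical students given
fictitious jobs D/N/P/V but their real initials and ages) each triage
the same 10 printed casualties in the same order, copying each
casualty's printed triage number as the serial, with the real
wall-clock minute recorded — a design deliberately prone to duplicate
IDs (one cohort, narrow age range, shared serials and clock).  This
module generates such rosters at arbitrary scale and estimates
duplication rates by Monte Carlo.

Randomness: a single root seed; the stream for replicate ``r`` is
``numpy.random.default_rng([seed, r, k])`` with ``k`` = 0 for the
roster, 1 for the time stamps, 2 for transcription errors.  A
single-shot run is replicate 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .codec import (
    JOB_CATEGORIES,
    UNKNOWN,
    CasualtyRecord,
    IDCode,
    ResponderProfile,
    decode_id,
    encode_id,
)
from .dupstats import DuplicationReport, IDDuplicationStats, id_duplication_stats, pattern_duplication_stats

__all__ = [
    "ScenarioConfig",
    "SimulationResult",
    "MonteCarloSummary",
    "default_casualties",
    "skewed_initial_distribution",
    "DEFAULT_FAMILY_INITIAL_FREQS",
    "DEFAULT_GIVEN_INITIAL_FREQS",
    "DEFAULT_JOB_MIX",
    "generate_roster",
    "run_desk_study",
    "monte_carlo",
    "inject_transcription_errors",
    "reconstruct_desk_study",
    "KEY_SUBSETS",
]

_LETTERS = tuple(chr(c) for c in range(ord("A"), ord("Z") + 1))

# Participant-key subsets reported by the desk study, in refinement order.
KEY_SUBSETS = ("initials", "initials_age", "initials_age_job")


def skewed_initial_distribution(top: Mapping[str, float]) -> dict[str, float]:
    """Categorical over A-Z with named high-mass letters.

    ``top`` assigns explicit probabilities (summing to < 1); the
    remaining mass is spread uniformly over the other letters.
    """
    rest = 1.0 - sum(top.values())
    others = [c for c in _LETTERS if c not in top]
    if rest < 0 or (others and rest < 0):
        raise ValueError("top probabilities exceed 1")
    dist = {c: top.get(c, rest / len(others)) for c in _LETTERS}
    return dist


# Stand-ins for the heavy concentration of common family names (Sato,
# Suzuki, Saito, Kato, Tanaka, Takahashi, ...) and popular given names
# (Tomoko, Takako, Tatsuya, Takuya, ...) in a single-country cohort;
# fully overridable in ScenarioConfig.
DEFAULT_FAMILY_INITIAL_FREQS = skewed_initial_distribution(
    {"S": 0.16, "K": 0.14, "T": 0.10, "M": 0.08, "N": 0.07, "I": 0.06,
     "H": 0.06, "O": 0.05, "Y": 0.05, "A": 0.04, "W": 0.04, "F": 0.03}
)
DEFAULT_GIVEN_INITIAL_FREQS = skewed_initial_distribution(
    {"T": 0.12, "K": 0.11, "S": 0.09, "M": 0.09, "Y": 0.08, "A": 0.07,
     "H": 0.06, "N": 0.05, "R": 0.05, "J": 0.04}
)

# Job mix of the reference desk study: D 29, N 15, P 19, V 26 of 89.
DEFAULT_JOB_MIX = {"D": 29 / 89, "N": 15 / 89, "P": 19 / 89, "V": 26 / 89}

# Cohort of same-grade students: median age 23, interquartile range 22-24.
DEFAULT_AGE_DISTRIBUTION = {22: 1 / 3, 23: 1 / 3, 24: 1 / 3}


def default_casualties() -> list[CasualtyRecord]:
    """The ten printed virtual casualties shipped with the package.

    Five dated the 31st, five the 1st; triage numbers 1..123 including
    the 100/101 serial wrap; two casualties share name initial, age and
    gender; three have unknown names and one an unknown gender.
    """
    from .io import read_casualties

    ref = resources.files("mcid.data") / "casualties_table1.csv"
    with resources.as_file(ref) as path:
        return read_casualties(path)


def _check_distribution(name: str, dist: Mapping) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has a negative probability")


@dataclass
class ScenarioConfig:
    """Everything that defines one simulated desk study.

    Defaults state the reference-study conditions: 89 responders with
    the study's exact job allocation, a narrow student age range,
    skewed name-initial frequencies, the ten packaged casualties, and a
    20-minute completion window with ~90-second pacing per casualty.

    ``serial_mode``: ``"printed"`` copies each casualty's printed triage
    number (identical across responders, the duplication-prone study
    design); ``"free"`` lets every responder run their own counter from
    their profile, as on a real scene.
    """

    n_responders: int = 89
    job_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_JOB_MIX))
    job_allocation: str = "exact"  # "exact" (largest-remainder counts) or "iid"
    family_initial_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_INITIAL_FREQS)
    )
    given_initial_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GIVEN_INITIAL_FREQS)
    )
    age_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    casualties: Optional[Sequence[CasualtyRecord]] = None  # None -> packaged ten
    start_hour: int = 10  # arbitrary wall-clock start of the exercise
    time_window_minutes: int = 20  # every responder finishes within this
    pacing: Mapping[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.5})
    serial_mode: str = "printed"
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.casualties is None:
            self.casualties = default_casualties()
        if self.n_responders < 1:
            raise ValueError("n_responders must be >= 1")
        if not self.casualties:
            raise ValueError("casualties must be non-empty")
        if set(self.job_mix) - set(JOB_CATEGORIES):
            raise ValueError(f"job_mix keys must be within {JOB_CATEGORIES}")
        if self.job_allocation not in ("exact", "iid"):
            raise ValueError("job_allocation must be 'exact' or 'iid'")
        if self.serial_mode not in ("printed", "free"):
            raise ValueError("serial_mode must be 'printed' or 'free'")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if any(int(i) < 1 for i in self.pacing):
            raise ValueError("pacing increments must be positive minutes")
        _check_distribution("job_mix", self.job_mix)
        _check_distribution("family_initial_freqs", self.family_initial_freqs)
        _check_distribution("given_initial_freqs", self.given_initial_freqs)
        _check_distribution("age_distribution", self.age_distribution)
        _check_distribution("pacing", self.pacing)


@dataclass
class SimulationResult:
    """One replicate: the emitted IDs plus duplication reports."""

    ids: list[IDCode]
    roster: list[ResponderProfile]
    roster_reports: dict[str, DuplicationReport]
    id_stats: IDDuplicationStats


@dataclass
class MonteCarloSummary:
    """Per-metric mean/sd/min/max over replicates, plus raw traces."""

    n_replicates: int
    metrics: dict[str, dict[str, float]]
    per_replicate: dict[str, list[float]]


def _rng_for(cfg: ScenarioConfig, replicate: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, replicate, stream])


def _sample(rng: np.random.Generator, dist: Mapping, size: int) -> list:
    values = list(dist.keys())
    probs = np.asarray([dist[v] for v in values], dtype=float)
    probs = probs / probs.sum()  # exact renormalisation of ~1 sums
    idx = rng.choice(len(values), size=size, p=probs)
    return [values[i] for i in idx]


def _exact_job_counts(job_mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n responders to job categories."""
    jobs = [j for j in JOB_CATEGORIES if job_mix.get(j, 0) > 0]
    raw = {j: job_mix[j] * n for j in jobs}
    counts = {j: int(raw[j]) for j in jobs}
    short = n - sum(counts.values())
    for j in sorted(jobs, key=lambda j: raw[j] - counts[j], reverse=True)[:short]:
        counts[j] += 1
    return counts


def generate_roster(
    cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> list[ResponderProfile]:
    """Draw ``cfg.n_responders`` profiles; deterministic given the seed.

    In ``exact`` allocation mode the job histogram is fixed by
    largest-remainder apportionment of ``job_mix`` (the default
    reproduces the study's D29/N15/P19/V26) and only its ordering is
    random; ``iid`` mode samples jobs independently.
    """
    rng = _rng_for(cfg, 0, 0) if rng is None else rng
    n = cfg.n_responders
    if cfg.job_allocation == "exact":
        counts = _exact_job_counts(cfg.job_mix, n)
        jobs = [j for j, c in counts.items() for _ in range(c)]
        jobs = [jobs[i] for i in rng.permutation(n)]
    else:
        jobs = _sample(rng, cfg.job_mix, n)
    fam = _sample(rng, cfg.family_initial_freqs, n)
    giv = _sample(rng, cfg.given_initial_freqs, n)
    ages = _sample(rng, cfg.age_distribution, n)
    return [
        ResponderProfile(
            job_category=jobs[i],
            initial_1=fam[i],
            initial_2=giv[i],
            age_years=int(ages[i]),
            next_triage_number=1,
        )
        for i in range(n)
    ]


def draw_time_stamps(
    cfg: ScenarioConfig, n_responders: int, rng: np.random.Generator
) -> np.ndarray:
    """Absolute minute-of-day stamps, shape (n_responders, n_casualties).

    All responders start together at ``start_hour``; each works down the
    casualty list with positive per-casualty increments drawn from
    ``pacing``, so each row is strictly increasing and, under the
    default pacing, finishes within the 20-minute window.
    """
    n_cas = len(cfg.casualties)
    increments = np.asarray(
        _sample(rng, cfg.pacing, n_responders * n_cas), dtype=int
    ).reshape(n_responders, n_cas)
    start = cfg.start_hour * 60
    return start + np.cumsum(increments, axis=1)


def _roster_reports(roster: Sequence[ResponderProfile]) -> dict[str, DuplicationReport]:
    keys = {
        "initials": [(r.initial_1, r.initial_2) for r in roster],
        "initials_age": [(r.initial_1, r.initial_2, r.age_years % 100) for r in roster],
        "initials_age_job": [
            (r.job_category, r.initial_1, r.initial_2, r.age_years % 100) for r in roster
        ],
    }
    return {name: pattern_duplication_stats(k) for name, k in keys.items()}


def run_desk_study(
    roster: Sequence[ResponderProfile],
    cfg: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    stamps: Optional[np.ndarray] = None,
) -> SimulationResult:
    """One desk-study replicate: every responder encodes every casualty.

    Casualties are taken in listed order; the serial comes from the
    casualty's printed triage number (``printed`` mode) or the
    responder's own counter (``free`` mode); the triage day is the
    casualty's printed date and the hour/minute come from the drawn (or
    supplied) time stamps.  Emits ``len(roster) * len(casualties)`` IDs.
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    rng = _rng_for(cfg, 0, 1) if rng is None else rng
    casualties = list(cfg.casualties)
    if stamps is None:
        stamps = draw_time_stamps(cfg, len(roster), rng)
    stamps = np.asarray(stamps, dtype=int)
    if stamps.shape != (len(roster), len(casualties)):
        raise ValueError(f"stamps must have shape {(len(roster), len(casualties))}")

    ids: list[IDCode] = []
    workers = [replace(r) for r in roster]  # keep caller's counters untouched
    for i, responder in enumerate(workers):
        for j, casualty in enumerate(casualties):
            if cfg.serial_mode == "printed":
                if casualty.triage_number is None:
                    raise ValueError(f"casualty {j + 1} has no printed triage number")
                responder.next_triage_number = int(casualty.triage_number)
            t = int(stamps[i, j])
            stamped = casualty.stamped(hour=(t // 60) % 24, minute=t % 60)
            ids.append(encode_id(responder, stamped))

    if cfg.error_rate > 0:
        ids = inject_transcription_errors(ids, cfg.error_rate, _rng_for(cfg, 0, 2))

    return SimulationResult(
        ids=ids,
        roster=list(roster),
        roster_reports=_roster_reports(roster),
        id_stats=id_duplication_stats(ids),
    )


def monte_carlo(cfg: ScenarioConfig, n_replicates: int) -> MonteCarloSummary:
    """Replicate the desk study and summarise duplication rates.

    Tracked metrics: percent of responders in duplicated patterns for
    each key subset, percent and count of completely duplicated IDs.
    Deterministic given ``cfg.seed``; replicate r uses its own derived
    substreams.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    traces: dict[str, list[float]] = {
        **{f"percent_dup_{k}": [] for k in KEY_SUBSETS},
        "percent_complete_dup": [],
        "n_complete_duplicates": [],
    }
    for rep in range(n_replicates):
        roster = generate_roster(cfg, _rng_for(cfg, rep, 0))
        result = run_desk_study(roster, cfg, _rng_for(cfg, rep, 1))
        for k in KEY_SUBSETS:
            traces[f"percent_dup_{k}"].append(
                result.roster_reports[k].percent_items_in_duplicated
            )
        traces["percent_complete_dup"].append(result.id_stats.percent_duplicates)
        traces["n_complete_duplicates"].append(float(result.id_stats.n_complete_duplicates))
    metrics = {}
    for name, vals in traces.items():
        arr = np.asarray(vals, dtype=float)
        metrics[name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return MonteCarloSummary(n_replicates=n_replicates, metrics=metrics, per_replicate=traces)


def inject_transcription_errors(
    ids: Sequence[IDCode | str],
    rate: float,
    rng: np.random.Generator | int,
) -> list[IDCode]:
    """Perturb each ID independently with probability ``rate``.

    A perturbed ID gets one random single-field clerical mistake of the
    kinds seen on real forms — an incorrect gender or an incorrect
    date — while remaining grammar-valid.  ``rate`` 0 returns the input
    unchanged; ``rate`` 1 changes exactly one field of every ID.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[IDCode] = []
    for item in ids:
        code = item if isinstance(item, IDCode) else decode_id(item)
        if rate == 0.0 or rng.random() >= rate:
            out.append(code)
            continue
        s = code.canonical
        if rng.integers(2) == 0:  # gender mix-up
            g = s[14]
            new_g = {"M": "F", "F": "M"}.get(g) or ("M", "F")[rng.integers(2)]
            s = s[:14] + new_g + s[15:]
        else:  # date mix-up: a different valid day of month
            day = int(s[7:9])
            new_day = day
            while new_day == day:
                new_day = int(rng.integers(1, 32))
            s = s[:7] + f"{new_day:02d}" + s[9:]
        out.append(decode_id(s))
    return out


def reconstruct_desk_study(seed: int = 0) -> SimulationResult:
    """A constructed 89-responder replicate matching the reference study.

    The roster has the exact job allocation D29/N15/P19/V26 and exactly
    one pair of responders — two paramedics — sharing the full
    7-character responder prefix (same initials and age); every other
    responder's prefix is unique.  The pair's time stamps are forced to
    coincide on exactly the first casualty and to differ on the other
    nine.  With the ten packaged casualties this yields 890 IDs of
    which exactly two are complete duplicates (0.2%) and 888 unique
    (99.8%).
    """
    cfg = ScenarioConfig(seed=seed)
    roster_rng = _rng_for(cfg, 0, 0)
    roster = generate_roster(cfg, roster_rng)

    prefix = lambda r: f"{r.job_category}{r.initial_1}{r.initial_2}{r.age_years % 100:02d}"
    pair = [i for i, r in enumerate(roster) if r.job_category == "P"][:2]
    p1, p2 = pair
    roster[p2] = replace(
        roster[p1], job_category="P", next_triage_number=1
    )  # p1 is a paramedic too, so prefixes now match

    # De-collide everyone else: resample initials/age until each prefix
    # is unique and distinct from the forced pair's.
    seen = {prefix(roster[p1])}
    for i, r in enumerate(roster):
        if i in (p1, p2):
            continue
        while prefix(r) in seen:
            r = replace(
                r,
                initial_1=_sample(roster_rng, cfg.family_initial_freqs, 1)[0],
                initial_2=_sample(roster_rng, cfg.given_initial_freqs, 1)[0],
                age_years=int(_sample(roster_rng, cfg.age_distribution, 1)[0]),
            )
        roster[i] = r
        seen.add(prefix(r))

    stamps = draw_time_stamps(cfg, len(roster), _rng_for(cfg, 0, 1))
    stamps[p2] = stamps[p1] + 1  # differ everywhere ...
    stamps[p2][0] = stamps[p1][0]  # ... except the first casualty
    return run_desk_study(roster, cfg, stamps=stamps)
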
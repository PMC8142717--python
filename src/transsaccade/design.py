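"""Trial-design generation for the two transsaccadic integration experiments.

Experiment 1 manipulates pre-saccadic set size (1-4 colored disks); every
trial shows the probed item both before and after the saccade, with its
color shifted 25 deg on the wheel during the eye movement. Each
participant contributes 480 trials in 4 blocks of 120 with set size
exactly balanced within block and probed location exactly balanced within
set size across the session.

Experiment 2 fixes set size at 4 and crosses cue validity (valid /
invalid / no cue; an arrow pre-cue makes the cued item three times more
likely to be probed than any uncued item) with presentation condition
(PRE-only / POST-only / BOTH). Each participant contributes 792 trials in
8 blocks of 99, 11 trials per condition per block, with shift direction
balanced within condition.

The generator emits a tidy trial table (one row per trial); responses are
added separately by the observer simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import to_circle_deg

__all__ = [
    "SHIFT_MAGNITUDE_DEG",
    "LOCATIONS",
    "INNER_LOCATIONS",
    "OUTER_LOCATIONS",
    "TRIAL_COLUMNS",
    "CUE_CONDITIONS",
    "PRESENTATIONS",
    "generate_design",
    "stimulus_geometry",
]

#: intrasaccadic color-wheel shift applied to the probed item (degrees)
SHIFT_MAGNITUDE_DEG = 25.0

LOCATIONS = ("A", "B", "C", "D")
#: array positions at +-20 deg polar angle, nearer the post-saccadic fixation
INNER_LOCATIONS = ("B", "C")
#: array positions at +-60 deg polar angle, farther from post-saccadic fixation
OUTER_LOCATIONS = ("A", "D")
#: polar angle of each location on the pre-saccadic array circle (degrees,
#: 0 = horizontal toward the display center)
LOCATION_ANGLES_DEG = {"A": -60.0, "B": -20.0, "C": 20.0, "D": 60.0}

CUE_CONDITIONS = ("valid", "invalid", "no_cue")
PRESENTATIONS = ("pre_only", "post_only", "both")

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "block",
    "set_size",
    "cue_condition",
    "presentation",
    "cued_location",
    "probed_location",
    "location_class",
    "pre_color_deg",
    "shift_dir",
    "post_color_deg",
    "response_deg",
    "saccade_latency_ms",
    "aware",
]

# Observed fractions of participants aware of the intrasaccadic change.
DEFAULT_P_AWARE = {1: 4.0 / 14.0, 2: 9.0 / 15.0}

# Mean saccade latencies (ms) by set size; latencies exist only to
# exercise the correlation analyses.
_LATENCY_MEANS_EXP1 = {1: 223.0, 2: 232.3, 3: 241.7, 4: 251.0}
_LATENCY_MEAN_EXP2 = 240.0
_LATENCY_SHIFT_MS = 120.0
_LATENCY_SHAPE = 9.0


def _location_class(loc: str) -> str:
    return "inner" if loc in INNER_LOCATIONS else "outer"


def _latency(rng, mean_ms, size):
    scale = (mean_ms - _LATENCY_SHIFT_MS) / _LATENCY_SHAPE
    return _LATENCY_SHIFT_MS + rng.gamma(_LATENCY_SHAPE, scale, size=size)


def _interleave_within_block(df, rng):
    """Randomly interleave trial order within each block."""
    order = np.lexsort((rng.random(len(df)), df["block"].to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def _balanced_dirs(rng, n):
    """n shift directions with counts as equal as parity allows."""
    dirs = np.repeat([1, -1], [n - n // 2, n // 2])
    rng.shuffle(dirs)
    return dirs


def _exp1_participant(rng, pid, aware):
    rows = []
    for set_size in (1, 2, 3, 4):
        # 120 trials per set size: 30 per probed location, 15 per shift
        # direction within each (set size, location) cell; dealt into 4
        # blocks of 30 so set size is exactly balanced within block.
        cell = []
        for loc in LOCATIONS:
            for d in (1, -1):
                cell.extend([(loc, d)] * 15)
        cell = np.array(cell, dtype=object)
        rng.shuffle(cell)
        for block in range(1, 5):
            for loc, d in cell[(block - 1) * 30 : block * 30]:
                rows.append((block, set_size, loc, int(d)))
    df = pd.DataFrame(rows, columns=["block", "set_size", "probed_location", "shift_dir"])
    df = _interleave_within_block(df, rng)
    n = len(df)
    pre = rng.uniform(0.0, 360.0, size=n)
    out = pd.DataFrame(
        {
            "participant_id": pid,
            "experiment": 1,
            "block": df["block"].to_numpy(),
            "set_size": df["set_size"].to_numpy(),
            "cue_condition": "none",
            "presentation": "both",
            "cued_location": "",
            "probed_location": df["probed_location"].to_numpy(),
            "location_class": [_location_class(l) for l in df["probed_location"]],
            "pre_color_deg": pre,
            "shift_dir": df["shift_dir"].to_numpy(),
            "post_color_deg": to_circle_deg(
                pre + df["shift_dir"].to_numpy() * SHIFT_MAGNITUDE_DEG
            ),
            "response_deg": np.nan,
            "saccade_latency_ms": _latency(
                rng, df["set_size"].map(_LATENCY_MEANS_EXP1).to_numpy(), n
            ),
            "aware": aware,
        }
    )
    return out


def _exp2_participant(rng, pid, aware):
    conditions = [(c, p) for c in CUE_CONDITIONS for p in PRESENTATIONS]
    rows = []
    for cue, pres in conditions:
        # 88 trials per condition: 44 per shift direction, 11 per block.
        dirs = _balanced_dirs(rng, 88)
        blocks = np.repeat(np.arange(1, 9), 11)
        perm = rng.permutation(88)
        for b, d in zip(blocks, dirs[perm]):
            rows.append((int(b), cue, pres, int(d)))
    df = pd.DataFrame(rows, columns=["block", "cue_condition", "presentation", "shift_dir"])
    df = _interleave_within_block(df, rng)
    n = len(df)
    cued = np.array(LOCATIONS)[rng.integers(0, 4, size=n)]
    probed = np.empty(n, dtype=object)
    for i, (cue, cl) in enumerate(zip(df["cue_condition"], cued)):
        if cue == "valid":
            probed[i] = cl
        elif cue == "invalid":
            others = [l for l in LOCATIONS if l != cl]
            probed[i] = others[rng.integers(0, 3)]
        else:
            probed[i] = LOCATIONS[rng.integers(0, 4)]
    cued = np.where(df["cue_condition"].to_numpy() == "no_cue", "", cued)
    pre = rng.uniform(0.0, 360.0, size=n)
    out = pd.DataFrame(
        {
            "participant_id": pid,
            "experiment": 2,
            "block": df["block"].to_numpy(),
            "set_size": 4,
            "cue_condition": df["cue_condition"].to_numpy(),
            "presentation": df["presentation"].to_numpy(),
            "cued_location": cued,
            "probed_location": probed,
            "location_class": [_location_class(l) for l in probed],
            "pre_color_deg": pre,
            "shift_dir": df["shift_dir"].to_numpy(),
            # both colors are recorded on every trial; the presentation
            # condition governs which views inform the simulated response
            "post_color_deg": to_circle_deg(
                pre + df["shift_dir"].to_numpy() * SHIFT_MAGNITUDE_DEG
            ),
            "response_deg": np.nan,
            "saccade_latency_ms": _latency(rng, _LATENCY_MEAN_EXP2, n),
            "aware": aware,
        }
    )
    return out


def generate_design(
    experiment: int,
    n_participants: int,
    seed: int,
    p_aware: float | None = None,
) -> pd.DataFrame:
    """Generate the trial table for one experiment (without responses).

    Parameters
    ----------
    experiment : {1, 2}
        1 = set-size manipulation (480 trials/participant); 2 = cue x
        presentation manipulation (792 trials/participant).
    n_participants : int
        Number of simulated participants (ids "P01", "P02", ...).
    seed : int
        Master seed; each participant gets a deterministically derived
        substream so individual participants reproduce in isolation.
    p_aware : float, optional
        Probability a participant is flagged aware of the color change.
        Defaults to the observed fractions (4/14 for Exp 1, 9/15 for Exp 2).

    Returns
    -------
    pandas.DataFrame
        One row per trial with the :data:`TRIAL_COLUMNS` columns;
        ``response_deg`` is NaN.
    """
    if experiment not in (1, 2):
        raise ValueError(f"unknown experiment id {experiment!r}; expected 1 or 2")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if p_aware is None:
        p_aware = DEFAULT_P_AWARE[experiment]
    tables = []
    for i in range(1, n_participants + 1):
        rng = np.random.default_rng([seed, experiment, 1, i])
        aware = bool(rng.uniform() < p_aware)
        builder = _exp1_participant if experiment == 1 else _exp2_participant
        tables.append(builder(rng, f"P{i:02d}", aware))
    return pd.concat(tables, ignore_index=True)[TRIAL_COLUMNS]


def stimulus_geometry(
    saccade_amplitude_deg: float = 12.0,
    array_radius_deg: float = 4.0,
    location_angles_deg=None,
):
    """Stimulus eccentricities implied by the display layout.

    The four items sit on a circle of `array_radius_deg` around the
    pre-saccadic fixation point at the given polar angles (0 deg pointing
    horizontally toward the display center); the post-saccadic fixation
    lies `saccade_amplitude_deg` along that horizontal. All items are
    equidistant from pre-saccadic fixation, so the quantity that differs
    between inner and outer positions is the offset from POST-saccadic
    fixation.

    Returns
    -------
    pandas.DataFrame indexed by location letter with columns
    ``angle_deg``, ``ecc_pre_deg``, ``horiz_offset_post_deg`` (the
    horizontal component of the post-saccadic offset) and
    ``dist_post_deg`` (full Euclidean offset).
    """
    if location_angles_deg is None:
        location_angles_deg = LOCATION_ANGLES_DEG
    recs = {}
    for loc, ang in location_angles_deg.items():
        x = array_radius_deg * np.cos(np.radians(ang))
        y = array_radius_deg * np.sin(np.radians(ang))
        recs[loc] = {
            "angle_deg": ang,
            "ecc_pre_deg": array_radius_deg,
            "horiz_offset_post_deg": saccade_amplitude_deg - x,
            "dist_post_deg": float(np.hypot(saccade_amplitude_deg - x, y)),
        }
    return pd.DataFrame(recs).T
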
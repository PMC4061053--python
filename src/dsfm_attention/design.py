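"""Block/trial experimental design for the attention experiment.

One scan presents six conditions — attend-left-same, attend-left-different,
attend-right-same, attend-right-different, and two passive (static
zero-disparity dots) conditions cued left or right — in 10 blocks each, 4
trials per block, 4 s per trial, so a scan lasts 6*10*4*4 = 960 s = 240
volumes at TR = 4 s.  Block order is pseudo-randomized with a maximum run
length of identical conditions.  "Same"/"different" refers to whether the
attended cylinder rotates in the same direction as the unattended one; the
unattended cylinder keeps a single rotation direction within a scan, which
alternates across scans.

Each active trial is a two-interval speed discrimination: the attended
cylinder may speed up by a factor ``speed_factor`` in the second interval
(coin flip per trial).  The unattended cylinder never changes speed within
a trial and rotates at a speed drawn independently of the attended one, so
cross-cylinder comparisons cannot solve the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ACTIVE_CONDITIONS",
    "DesignParams",
    "TrialSpec",
    "Block",
    "ScanDesign",
    "Design",
    "build_design",
    "design_to_events",
    "build_validity_design",
    "write_events",
    "read_events",
]

CONDITIONS = (
    "attend_left_same",
    "attend_left_different",
    "attend_right_same",
    "attend_right_different",
    "passive_left",
    "passive_right",
)
ACTIVE_CONDITIONS = CONDITIONS[:4]

_OPPOSITE = {"clockwise": "counterclockwise", "counterclockwise": "clockwise"}


@dataclass(frozen=True)
class DesignParams:
    tr: float = 4.0                 # seconds per volume
    trial_s: float = 4.0            # trial duration, seconds
    trials_per_block: int = 4
    blocks_per_condition: int = 10
    max_run: int = 2                # max identical consecutive blocks
    speed_range: tuple[float, float] = (100.0, 177.0)  # deg of rotation / s
    speed_factor: float = 1.41      # speed-change multiplier (75% threshold scale)
    p_change: float = 0.5           # probability the attended cylinder speeds up
    interval_split: tuple[float, float, float] = (1.5, 1.5, 1.0)
    # seconds for interval 1, interval 2, response window (sums to trial_s)

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0 or self.blocks_per_condition <= 0:
            raise ValueError("block geometry must be positive")
        if abs(sum(self.interval_split) - self.trial_s) > 1e-9:
            raise ValueError("interval_split must sum to trial_s")


@dataclass(frozen=True)
class TrialSpec:
    condition: str
    cue_side: str                    # "left" | "right"
    similarity: str | None           # "same" | "different"; None for passive
    attended_direction: str | None   # rotation of the cued cylinder
    unattended_direction: str | None
    attended_base_speed: float | None  # deg of rotation / s, interval 1
    unattended_speed: float | None     # constant across both intervals
    speed_change: bool               # attended cylinder faster in interval 2?
    speed_factor: float
    duration: float = 4.0
    intervals: int = 2


@dataclass
class Block:
    condition: str
    trials: list[TrialSpec]


@dataclass
class ScanDesign:
    blocks: list[Block]
    tr: float
    unattended_direction: str

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)


@dataclass
class Design:
    """Full multi-scan block design."""

    scans: list[ScanDesign]
    params: DesignParams

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def volumes_per_scan(self) -> int:
        p = self.params
        total_s = (len(CONDITIONS) * p.blocks_per_condition
                   * p.trials_per_block * p.trial_s)
        n, r = divmod(total_s, p.tr)
        if r:
            raise ValueError("scan duration is not a whole number of volumes")
        return int(n)

    @property
    def n_volumes(self) -> int:
        return self.n_scans * self.volumes_per_scan


def _condition_order(rng: np.random.Generator, params: DesignParams) -> list[str]:
    """Pseudo-randomized, counterbalanced block order for one scan.

    Random permutations are drawn until no condition occurs more than
    ``max_run`` times consecutively (rejection sampling; acceptance is fast
    for the default geometry).
    """
    base = np.repeat(np.arange(len(CONDITIONS)), params.blocks_per_condition)
    for _ in range(10_000):
        order = rng.permutation(base)
        run, ok = 1, True
        for a, b in zip(order[:-1], order[1:]):
            run = run + 1 if a == b else 1
            if run > params.max_run:
                ok = False
                break
        if ok:
            return [CONDITIONS[i] for i in order]
    raise RuntimeError("could not satisfy the run-length constraint")


def _make_trial(condition: str, unatt_dir: str, rng: np.random.Generator,
                params: DesignParams) -> TrialSpec:
    lo, hi = params.speed_range
    if condition.startswith("passive"):
        return TrialSpec(condition=condition,
                         cue_side=condition.split("_")[1],
                         similarity=None, attended_direction=None,
                         unattended_direction=None, attended_base_speed=None,
                         unattended_speed=None, speed_change=False,
                         speed_factor=params.speed_factor,
                         duration=params.trial_s)
    _, side, similarity = condition.split("_")
    if similarity == "same":
        att_dir = unatt_dir
    else:
        att_dir = _OPPOSITE[unatt_dir]
    return TrialSpec(
        condition=condition,
        cue_side=side,
        similarity=similarity,
        attended_direction=att_dir,
        unattended_direction=unatt_dir,
        attended_base_speed=float(rng.uniform(lo, hi)),
        unattended_speed=float(rng.uniform(lo, hi)),
        speed_change=bool(rng.random() < params.p_change),
        speed_factor=params.speed_factor,
        duration=params.trial_s,
    )


def build_design(seed: int, n_scans: int = 1,
                 params: DesignParams | None = None) -> Design:
    """Build a reproducible multi-scan block design.

    The unattended cylinder's rotation direction is constant within a scan
    and alternates across scans (counter-clockwise on even scans).
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    params = params or DesignParams()
    rng = np.random.default_rng(seed)
    scans = []
    for s in range(n_scans):
        unatt_dir = "counterclockwise" if s % 2 == 0 else "clockwise"
        blocks = []
        for cond in _condition_order(rng, params):
            trials = [_make_trial(cond, unatt_dir, rng, params)
                      for _ in range(params.trials_per_block)]
            blocks.append(Block(condition=cond, trials=trials))
        scans.append(ScanDesign(blocks=blocks, tr=params.tr,
                                unattended_direction=unatt_dir))
    return Design(scans=scans, params=params)


def design_to_events(design: Design) -> pd.DataFrame:
    """Flatten a design into a BIDS-style event table, one row per trial.

    Onsets are seconds from the start of each scan; ``volume`` indexes the
    volume within the scan (0-based) and ``global_volume`` across the
    concatenated scans.
    """
    p = design.params
    vols = design.volumes_per_scan
    rows = []
    for s, scan in enumerate(design.scans):
        t = 0.0
        for b, block in enumerate(scan.blocks):
            for trial in block.trials:
                v = int(round(t / p.tr))
                rows.append({
                    "scan": s, "block": b,
                    "onset_s": t, "duration_s": trial.duration,
                    "volume": v, "global_volume": s * vols + v,
                    "condition": trial.condition,
                    "trial_type": trial.condition,
                    "cue_side": trial.cue_side,
                    "similarity": trial.similarity,
                    "attended_direction": trial.attended_direction,
                    "unattended_direction": trial.unattended_direction,
                    "attended_base_speed": trial.attended_base_speed,
                    "unattended_speed": trial.unattended_speed,
                    "speed_change": trial.speed_change,
                    "speed_factor": trial.speed_factor,
                })
                t += trial.duration
        if abs(t - vols * p.tr) > 1e-9:
            raise ValueError("events do not sum to the scan duration")
    ev = pd.DataFrame(rows)
    for s in range(design.n_scans):
        onsets = ev.loc[ev["scan"] == s, "onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("overlapping or non-increasing events")
    return ev


def build_validity_design(p_valid: float, n_trials: int, seed: int,
                          params: DesignParams | None = None) -> pd.DataFrame:
    """Cue-validity control trials.

    Every trial contains a speed change on one side (left/right coin flip).
    With probability ``p_valid`` the cue points at the changing side
    (valid); otherwise it points the other way.  Returns one row per trial
    with the speed ratio of the change.
    """
    if not 0.0 <= p_valid <= 1.0:
        raise ValueError("p_valid must lie in [0, 1]")
    params = params or DesignParams()
    rng = np.random.default_rng(seed)
    change_side = np.where(rng.random(n_trials) < 0.5, "left", "right")
    valid = rng.random(n_trials) < p_valid
    cue_side = np.where(valid, change_side,
                        np.where(change_side == "left", "right", "left"))
    return pd.DataFrame({
        "trial": np.arange(n_trials),
        "change_side": change_side,
        "cue_side": cue_side,
        "cue_valid": valid,
        "speed_ratio": params.speed_factor,
    })


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
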
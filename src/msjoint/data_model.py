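"""Subject-level joint data and block-specific dataset construction.

One subject carries (i) a sparse longitudinal biomarker series, (ii) constant
baseline covariates and (iii) an observed path through the multistate graph,
right-censored at ``C_i``.  Blockwise inference conditions each block on a
risk set ``I_B`` (subjects entering the block's initial state), a per-subject
longitudinal index set ``T_B(i)`` (historical or concurrent) and a
competing-risk or single-transition view of the event outcome.

File formats are the standard long formats: a longitudinal CSV
``id,time,value,w1..wq`` and a counting-process event CSV
``id,from,to,tstart,tstop,status``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .state_graph import CompetingRiskBlock, TransitionBlock, TransitionGraph

__all__ = [
    "SubjectRecord",
    "BlockDataset",
    "LongitudinalStrategy",
    "DataValidationError",
    "read_joint_data",
    "write_joint_data",
    "subjects_to_frames",
    "build_block_dataset",
    "single_transition_view",
]

LongitudinalStrategy = Literal["historical", "concurrent"]


class DataValidationError(ValueError):
    """Subject data violate the joint-data schema or the transition graph."""


@dataclass
class SubjectRecord:
    """One subject's longitudinal measurements, covariates and event path.

    ``path`` is the ordered list of ``(state, entry_time)`` pairs starting at
    ``(initial_state, 0.0)``; ``censor_time`` is the end of follow-up C_i.
    A subject censored without any transition has a length-1 path.
    """

    id: str
    obs_times: np.ndarray
    obs_values: np.ndarray
    covariates: np.ndarray
    path: list[tuple[int, float]]
    censor_time: float

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        self.path = [(int(s), float(t)) for s, t in self.path]
        self.censor_time = float(self.censor_time)
        if self.obs_times.size != self.obs_values.size:
            raise DataValidationError(f"{self.id}: times/values length mismatch")
        if self.obs_times.size and np.any(np.diff(self.obs_times) <= 0):
            raise DataValidationError(f"{self.id}: measurement times not strictly increasing")
        if not self.path or self.path[0][1] != 0.0:
            raise DataValidationError(f"{self.id}: path must start at time 0")
        times = [t for _, t in self.path]
        if np.any(np.diff(times) <= 0):
            raise DataValidationError(f"{self.id}: transition times not strictly increasing")
        if times[-1] > self.censor_time:
            raise DataValidationError(f"{self.id}: transition after censoring time")
        if self.obs_times.size and self.obs_times[-1] > self.censor_time + 1e-12:
            raise DataValidationError(f"{self.id}: measurement after censoring time")

    @property
    def n_transitions(self) -> int:
        return len(self.path) - 1

    @property
    def transition_times(self) -> list[float]:
        """T_1 < ... < T_N; by convention T_0 = 0 and T_{N+1} = C_i."""
        return [t for _, t in self.path[1:]]

    def sojourns(self) -> list[tuple[int, float, float, int | None]]:
        """Occupied-state intervals ``(state, entry, exit, next_state_or_None)``.

        The censored final interval ends at C_i with ``next_state=None``; a
        zero-length final interval (last state entered exactly at C_i, e.g.
        on reaching an absorbing state) is omitted.
        """
        out = []
        for l, (state, entry) in enumerate(self.path):
            if l + 1 < len(self.path):
                nxt_state, nxt_time = self.path[l + 1]
                out.append((state, entry, nxt_time, nxt_state))
            else:
                if self.censor_time > entry:
                    out.append((state, entry, self.censor_time, None))
        return out

    def validate_against(self, graph: TransitionGraph) -> "SubjectRecord":
        for (j, _), (k, _) in zip(self.path, self.path[1:]):
            if (j, k) not in graph:
                raise DataValidationError(
                    f"{self.id}: observed transition ({j},{k}) not permitted by graph"
                )
        if self.path[0][0] not in graph.states:
            raise DataValidationError(f"{self.id}: unknown initial state {self.path[0][0]}")
        return self


@dataclass
class BlockDataset:
    """The conditioning data for one inference block.

    ``long_index[i]`` indexes into subject i's ``obs_times``; ``entry``,
    ``exit`` and ``event_target`` give the counting-process event view for
    the block (``event_target=-1`` encodes censoring).
    """

    block: CompetingRiskBlock | TransitionBlock
    subjects: list[SubjectRecord]
    long_index: list[np.ndarray]
    entry: np.ndarray
    exit: np.ndarray
    event_target: np.ndarray
    strategy: str = "historical"

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def members(self) -> list[str]:
        return [s.id for s in self.subjects]

    def event_flags(self, target: int) -> np.ndarray:
        return (self.event_target == target).astype(float)


def read_joint_data(
    longitudinal_file,
    event_file,
    graph: TransitionGraph,
) -> list[SubjectRecord]:
    """Read long-format longitudinal + counting-process event CSVs.

    The event file must contain, per subject, the rows of the observed path
    (status 1) plus exactly one final censoring row (status 0) unless the
    subject reaches an absorbing state.  The path is reconstructed from the
    status-1 rows ordered by ``tstop``.
    """
    long_df = pd.read_csv(longitudinal_file, float_precision="round_trip")
    ev_df = pd.read_csv(event_file, float_precision="round_trip")
    for col in ("id", "time", "value"):
        if col not in long_df.columns:
            raise DataValidationError(f"longitudinal file missing column {col!r}")
    for col in ("id", "from", "to", "tstart", "tstop", "status"):
        if col not in ev_df.columns:
            raise DataValidationError(f"event file missing column {col!r}")
    wcols = [c for c in long_df.columns if c not in ("id", "time", "value")]
    subjects: list[SubjectRecord] = []
    ev_groups = dict(tuple(ev_df.groupby("id", sort=False)))
    for sid, g in long_df.groupby("id", sort=False):
        g = g.sort_values("time")
        if sid not in ev_groups:
            raise DataValidationError(f"{sid}: no event rows")
        ev = ev_groups.pop(sid).sort_values("tstop")
        path = [(int(ev.iloc[0]["from"]), 0.0)]
        censor = float(ev.iloc[-1]["tstop"])
        for _, row in ev.iterrows():
            if int(row["status"]) == 1:
                path.append((int(row["to"]), float(row["tstop"])))
        if wcols:
            w = g[wcols].iloc[0].to_numpy(dtype=float)
            if not np.allclose(g[wcols].to_numpy(dtype=float), w):
                raise DataValidationError(f"{sid}: covariates not constant within subject")
        else:
            w = np.empty(0)
        rec = SubjectRecord(
            id=str(sid),
            obs_times=g["time"].to_numpy(),
            obs_values=g["value"].to_numpy(),
            covariates=w,
            path=path,
            censor_time=censor,
        )
        subjects.append(rec.validate_against(graph))
    if ev_groups:
        missing = list(ev_groups)[:5]
        raise DataValidationError(
            f"subjects {missing} have event rows but no longitudinal measurements"
        )
    return subjects


def subjects_to_frames(
    subjects: Sequence[SubjectRecord],
    wcols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize subjects to (longitudinal, event) long-format DataFrames."""
    q = len(subjects[0].covariates) if subjects else 0
    if wcols is None:
        wcols = [f"w{i + 1}" for i in range(q)]
    lrows, erows = [], []
    for s in subjects:
        for t, y in zip(s.obs_times, s.obs_values):
            lrows.append({"id": s.id, "time": t, "value": y,
                          **dict(zip(wcols, s.covariates))})
        for (j, t0), (k, t1) in zip(s.path, s.path[1:]):
            erows.append({"id": s.id, "from": j, "to": k,
                          "tstart": t0, "tstop": t1, "status": 1})
        last_state, last_t = s.path[-1]
        if s.censor_time > last_t:
            erows.append({"id": s.id, "from": last_state, "to": -1,
                          "tstart": last_t, "tstop": s.censor_time, "status": 0})
    return pd.DataFrame(lrows), pd.DataFrame(erows)


def write_joint_data(subjects, longitudinal_file, event_file, wcols=None) -> None:
    long_df, ev_df = subjects_to_frames(subjects, wcols)
    # %.17g guarantees exact float round-trips through the text format
    long_df.to_csv(longitudinal_file, index=False, float_format="%.17g")
    ev_df.to_csv(event_file, index=False, float_format="%.17g")


def _block_event_view(subject: SubjectRecord, initial_state: int):
    """(entry, exit, target) for a subject's passage through ``initial_state``.

    Returns None if the subject never occupies the state (or enters it only
    at the censoring instant, leaving zero exposure).
    """
    for l, (state, entry) in enumerate(subject.path):
        if state != initial_state:
            continue
        if l + 1 < len(subject.path):
            nxt_state, nxt_time = subject.path[l + 1]
            return entry, nxt_time, nxt_state
        if subject.censor_time > entry:
            return entry, subject.censor_time, -1
        return None
    return None


def build_block_dataset(
    subjects: Sequence[SubjectRecord],
    block: CompetingRiskBlock | TransitionBlock,
    strategy: LongitudinalStrategy = "historical",
) -> BlockDataset:
    """Assemble the risk set, longitudinal index sets and event view of a block.

    ``historical`` keeps every measurement from study start up to the block
    exit time; ``concurrent`` keeps only measurements taken strictly after
    block entry and up to block exit, falling back to the historical set for
    subjects with no in-block measurement.  A measurement at exactly the exit
    (transition) time belongs to the state being exited.
    """
    if strategy not in ("historical", "concurrent"):
        raise ValueError(f"unknown longitudinal strategy {strategy!r}")
    members, idx, ent, ext, tgt = [], [], [], [], []
    j0 = block.initial_state
    for s in subjects:
        view = _block_event_view(s, j0)
        if view is None:
            continue
        entry, exit_t, target = view
        hist = np.flatnonzero(s.obs_times <= exit_t + 1e-12)
        if strategy == "concurrent":
            conc = np.flatnonzero(
                (s.obs_times > entry + 1e-12) & (s.obs_times <= exit_t + 1e-12)
            )
            chosen = conc if conc.size else hist
        else:
            chosen = hist
        if chosen.size == 0:
            raise DataValidationError(
                f"{s.id}: no longitudinal measurement available for block {block}"
            )
        members.append(s)
        idx.append(chosen)
        ent.append(entry)
        ext.append(exit_t)
        tgt.append(target)
    terminals = {k for _, k in block.transitions}
    tgt_arr = np.array(
        [t if t in terminals else -1 for t in tgt], dtype=int
    )
    return BlockDataset(
        block=block,
        subjects=members,
        long_index=idx,
        entry=np.array(ent, dtype=float),
        exit=np.array(ext, dtype=float),
        event_target=tgt_arr,
        strategy=strategy,
    )


def single_transition_view(block_dataset: BlockDataset, target_state: int) -> BlockDataset:
    """Recast a competing-risk block dataset as a single-transition dataset.

    Subjects transitioning to a competing state are treated as censored at
    the same exit time; members and longitudinal index sets are unchanged.
    """
    block = block_dataset.block
    terminals = {k for _, k in block.transitions}
    if target_state not in terminals:
        raise ValueError(f"state {target_state} is not a terminal state of {block}")
    new_target = np.where(
        block_dataset.event_target == target_state, target_state, -1
    )
    return replace(
        block_dataset,
        block=TransitionBlock(block.initial_state, target_state),
        event_target=new_target,
    )
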
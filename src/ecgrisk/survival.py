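"""Discrete-time survival machinery.

Time is partitioned into K intervals (t_{j-1}, t_j]. A model emits the
conditional hazard h_j = P(death in interval j | alive at t_{j-1}) for
each interval. Survival is the cumulative product S_k = prod_{j<=k}(1-h_j)
and the likelihood of a record factorises over the intervals it was
observed in, which is what makes censoring easy to handle: a censored
subject simply contributes fewer Bernoulli terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # hazard clipping bound inside the loss


@dataclass(frozen=True)
class SurvivalRecord:
    """One censored time-to-event observation (time in days)."""

    subject_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


class IntervalGrid:
    """Ordered interval boundaries 0 = t_0 < t_1 < ... < t_K, in days."""

    def __init__(self, boundaries) -> None:
        b = np.asarray(boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two boundaries")
        if b[0] != 0:
            raise ValueError(f"first boundary must be 0, got {b[0]}")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b

    @classmethod
    def half_years(cls, n_intervals: int = 10) -> "IntervalGrid":
        """Default grid: half-year intervals (n=10 spans 5 years)."""
        return cls(np.arange(n_intervals + 1) * 182.625)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    @property
    def horizon(self) -> float:
        return float(self.boundaries[-1])

    def __repr__(self) -> str:
        return f"IntervalGrid(K={self.n_intervals}, horizon={self.horizon:g} d)"


@dataclass
class SurvivalTargets:
    """Per-record event vector y and observation mask m over the K intervals.

    y_j = 1 iff the death happened in interval j. m_j = 1 iff interval j
    contributes a likelihood term; the mask is always a prefix.
    """

    y: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=float))
        if self.y.shape != self.mask.shape:
            raise ValueError("y and mask shapes differ")

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


def encode_targets(record: SurvivalRecord, grid: IntervalGrid) -> SurvivalTargets:
    """Encode one record onto the interval grid.

    Death at t in interval k: y_k = 1, m_1..m_k = 1.
    Censoring at t in interval k: y = 0, m_1..m_{k-1} = 1 — only intervals
    the subject fully survived count (no partial-interval credit).
    Times at or beyond the horizon contribute all K intervals as survived;
    an event past the horizon is treated as censoring at t_K.
    """
    K = grid.n_intervals
    y = np.zeros(K)
    m = np.zeros(K)
    t = record.time
    if t >= grid.horizon:
        m[:] = 1.0
        return SurvivalTargets(y, m)
    if record.event == 1:
        # interval index k (1-based) holding t: t in (t_{k-1}, t_k]; t == 0 -> k = 1
        k = int(np.searchsorted(grid.boundaries[1:-1], t, side="left")) + 1
        y[k - 1] = 1.0
        m[:k] = 1.0
    else:
        # number of fully survived intervals: boundaries t_j <= t
        n_full = int(np.searchsorted(grid.boundaries[1:], t, side="right"))
        m[:n_full] = 1.0
    return SurvivalTargets(y, m)


def encode_target_batch(records, grid: IntervalGrid) -> SurvivalTargets:
    """Stack :func:`encode_targets` over a sequence of records."""
    encoded = [encode_targets(r, grid) for r in records]
    return SurvivalTargets(
        np.vstack([e.y for e in encoded]), np.vstack([e.mask for e in encoded])
    )


def discrete_survival_loss(
    hazards: np.ndarray, targets: SurvivalTargets, reduce: bool = True
) -> np.ndarray | float:
    """Negative log-likelihood of the discrete-time survival model.

    Per record: -sum_j m_j [ y_j ln h_j + (1-y_j) ln(1-h_j) ]. With
    ``reduce`` the mean over records is returned. Hazards at exactly 0 or 1
    are clipped to [EPS, 1-EPS].
    """
    h = np.atleast_2d(np.asarray(hazards, dtype=float))
    if h.shape != targets.y.shape:
        raise ValueError(f"hazard shape {h.shape} != target shape {targets.y.shape}")
    h = np.clip(h, EPS, 1.0 - EPS)
    ll = targets.mask * (targets.y * np.log(h) + (1.0 - targets.y) * np.log(1.0 - h))
    per_record = -ll.sum(axis=1)
    return float(per_record.mean()) if reduce else per_record


def hazards_to_survival(hazards: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Survival curve and cumulative-hazard risk score from hazards.

    S_k = prod_{j<=k}(1 - h_j); risk = -sum_j ln(1 - h_j). Works on a single
    hazard vector or a (n, K) batch; the batch dimension is preserved.
    """
    h = np.asarray(hazards, dtype=float)
    squeeze = h.ndim == 1
    h = np.atleast_2d(np.clip(h, 0.0, 1.0 - EPS))
    survival = np.cumprod(1.0 - h, axis=1)
    risk = -np.log(1.0 - h).sum(axis=1)
    if squeeze:
        return survival[0], float(risk[0])
    return survival, risk


# ---------------------------------------------------------------------------
# Cohort filtering and patient-level splitting


@dataclass
class CohortSplits:
    """Index arrays (into the filtered record list) for train/val/test."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    kept: np.ndarray  # indices into the original record list that survived filtering


def has_five_year_status(record: SurvivalRecord, days: float = 5 * 365.25) -> bool:
    """True when 5-year life status is known: died any time, or followed >= 5 y."""
    return record.event == 1 or record.time >= days


def prepare_cohort(
    records,
    seed: int,
    ratios: tuple[float, float, float] = (0.5, 0.1, 0.4),
    min_followup_days: float = 30.0,
) -> CohortSplits:
    """Filter and split a cohort at the subject level.

    Records with follow-up shorter than ``min_followup_days`` and no event
    are dropped (life status at 30 days unknown). Remaining subjects are
    split 50/10/40 into train/val/test, stratified by whether 5-year life
    status is available, with every subject's records confined to one split.
    """
    records = list(records)
    kept = np.array(
        [
            i
            for i, r in enumerate(records)
            if r.event == 1 or r.time >= min_followup_days
        ],
        dtype=int,
    )
    subjects: dict[str, list[int]] = {}
    strata: dict[str, bool] = {}
    for i in kept:
        r = records[i]
        subjects.setdefault(r.subject_id, []).append(int(i))
        strata[r.subject_id] = strata.get(r.subject_id, False) or has_five_year_status(r)
    if len(subjects) < 3:
        raise ValueError(f"cohort has only {len(subjects)} subjects after filtering")

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for stratum in (True, False):
        ids = sorted(s for s in subjects if strata[s] == stratum)
        if not ids:
            continue
        perm = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        for rank, p in enumerate(perm):
            split = 0 if rank < n_train else (1 if rank < n_train + n_val else 2)
            assignment[ids[p]] = split

    buckets: list[list[int]] = [[], [], []]
    for sid, idxs in subjects.items():
        buckets[assignment[sid]].extend(idxs)
    return CohortSplits(
        train=np.array(sorted(buckets[0]), dtype=int),
        val=np.array(sorted(buckets[1]), dtype=int),
        test=np.array(sorted(buckets[2]), dtype=int),
        kept=kept,
    )
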
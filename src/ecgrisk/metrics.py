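"""Fidelity and discrimination metrics.

Digitization fidelity is per-lead Pearson correlation and mean absolute
error against the matched source signal, restricted to the samples the
digitizer actually recovered (extracted or interpolated; zero-padded
out-of-window samples are excluded). Model discrimination is Harrell's
concordance index under right censoring, with a bootstrap CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digitize import DigitizedECG
from .signals import ECGSignal


@dataclass
class FidelityReport:
    """Per-lead fidelity of recovered signals across a set of records."""

    r_values: np.ndarray  # all per-lead correlations, pooled over records
    mae_values: np.ndarray  # all per-lead MAEs (mV)
    n_records: int
    n_excluded_leads: int = 0  # zero-variance leads where r is undefined
    n_failed_records: int = 0

    @property
    def median_r(self) -> float:
        return float(np.median(self.r_values))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae_values))

    @property
    def median_mae(self) -> float:
        return float(np.median(self.mae_values))

    def r_quantiles(self, qs=(0.25, 0.5, 0.75)) -> np.ndarray:
        return np.quantile(self.r_values, qs)

    def summary(self) -> dict:
        q25, q50, q75 = self.r_quantiles()
        return {
            "n_records": self.n_records,
            "n_lead_comparisons": int(self.r_values.size),
            "median_r": self.median_r,
            "r_iqr": [float(q25), float(q75)],
            "mean_mae_mv": self.mean_mae,
            "median_mae_mv": self.median_mae,
            "n_excluded_leads": self.n_excluded_leads,
            "n_failed_records": self.n_failed_records,
        }


def lead_fidelity(reference: np.ndarray, recovered: np.ndarray) -> tuple[float | None, float]:
    """(Pearson r or None if undefined, MAE) for one aligned lead pair."""
    ref = np.asarray(reference, dtype=float)
    rec = np.asarray(recovered, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    mae = float(np.mean(np.abs(ref - rec)))
    if np.std(ref) == 0 or np.std(rec) == 0:
        return None, mae
    r = float(np.corrcoef(ref, rec)[0, 1])
    return r, mae


def fidelity_metrics(reference: ECGSignal, recovered: DigitizedECG) -> FidelityReport:
    """Per-lead r and MAE over the in-window (non-padded) samples."""
    if reference.fs != recovered.fs:
        raise ValueError("reference and recovered sampling rates differ")
    rs, maes, excluded = [], [], 0
    for name in recovered.lead_names:
        m = recovered.lead_mask(name) > 0
        if not m.any():
            excluded += 1
            continue
        ref = reference.lead(name)[: recovered.samples.shape[1]][m]
        rec = recovered.lead(name)[m]
        r, mae = lead_fidelity(ref, rec)
        maes.append(mae)
        if r is None:
            excluded += 1
        else:
            rs.append(r)
    return FidelityReport(np.array(rs), np.array(maes), n_records=1,
                          n_excluded_leads=excluded)


def pool_fidelity(reports: list[FidelityReport], n_failed: int = 0) -> FidelityReport:
    """Pool per-record reports into one distribution across all leads/records."""
    if not reports:
        raise ValueError("no successful records to pool")
    return FidelityReport(
        np.concatenate([r.r_values for r in reports]),
        np.concatenate([r.mae_values for r in reports]),
        n_records=len(reports),
        n_excluded_leads=sum(r.n_excluded_leads for r in reports),
        n_failed_records=n_failed,
    )


# ---------------------------------------------------------------------------
# Concordance index


@dataclass
class MetricResult:
    """Point estimate with a percentile bootstrap confidence interval."""

    estimate: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise ValueError("CI must bracket the estimate")


def _concordance(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C for one sample (vectorized over all pairs).

    Comparable pairs: t_i < t_j with event_i = 1 (equal-time pairs are not
    comparable). Concordant when risk_i > risk_j; risk ties count 1/2.
    """
    ti = time[:, None]
    tj = time[None, :]
    comparable = (ti < tj) & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = (ri > rj) & comparable
    tied = (ri == rj) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def concordance_index(
    risk, time, event, n_bootstrap: int = 200, seed: int = 0
) -> MetricResult:
    """Censoring-aware C-index with a percentile bootstrap CI over records."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (risk.shape == time.shape == event.shape):
        raise ValueError("risk, time and event must have equal lengths")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    est = _concordance(risk, time, event)
    rng = np.random.default_rng(seed)
    boots = []
    n = risk.size
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(_concordance(risk[idx], time[idx], event[idx]))
        except ValueError:  # resample without comparable pairs
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, est), max(hi, est)
    else:
        lo = hi = est
    return MetricResult(est, float(lo), float(hi), n_bootstrap, seed)


# ---------------------------------------------------------------------------
# Round-trip benchmark


def roundtrip_benchmark(
    n: int = 50,
    seed: int = 0,
    style=None,
    layout=None,
    degradation: dict | None = None,
    heart_rate_range: tuple[float, float] = (50.0, 120.0),
) -> FidelityReport:
    """Generate → render → (degrade) → digitize → score, fully seeded.

    The reference for each record is the source signal passed through the
    same filter/resample chain the digitizer applies, so the report isolates
    geometric digitization error from filter response. Per-record failures
    are logged, excluded from the pooled statistics and counted.
    """
    from .render import LayoutSpec, RenderStyle, render_paper_ecg, apply_scan_degradation
    from .prep import filter_resample
    from .synthetic import WaveTemplate, generate_signal
    from .digitize import digitize_ecg, DigitizationError

    if n < 1:
        raise ValueError("n must be >= 1")
    layout = layout or LayoutSpec()
    style = style or RenderStyle()
    rng = np.random.default_rng(seed)
    template = WaveTemplate()
    reports, failed = [], 0
    for i in range(n):
        hr = rng.uniform(*heart_rate_range)
        qrs = rng.uniform(0.8, 1.6)
        amp = rng.uniform(0.8, 1.2)
        sig_seed = int(rng.integers(0, 2**31 - 1))
        tpl = template.with_qrs_scale(qrs).scaled_amplitudes(amp)
        signal = generate_signal(tpl, hr, fs=500.0, duration=layout.panel_duration,
                                 noise_sd=0.01, seed=sig_seed)
        page = render_paper_ecg(signal, layout, style)
        if degradation:
            page = apply_scan_degradation(page, seed=sig_seed, **degradation)
        try:
            dig = digitize_ecg(page, layout)
        except DigitizationError:
            failed += 1
            continue
        reference = filter_resample(signal)
        reports.append(fidelity_metrics(reference, dig))
    return pool_fidelity(reports, n_failed=failed)
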
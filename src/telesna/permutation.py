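"""Pre-network datastream permutations (null model).

High-resolution telemetry produces autocorrelated relocation streams.  A
null model that randomises whom an animal meets — while leaving its home
range and within-day movement untouched — is obtained by segmenting each
individual's stream into daily tracks and shuffling the dates on which
those tracks were walked, independently per individual and only within
that individual's own observed date set.  Coordinates and times-of-day
are never altered, so each animal's multiset of daily tracks is exactly
preserved; only the alignment between individuals is randomised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import Thresholds, build_network
from .io import TelemetryDataset
from .metrics import DEFAULT_GLOBAL_METRICS, global_metrics

logger = logging.getLogger(__name__)


def _local_parts(ds: TelemetryDataset) -> tuple[pd.Series, pd.Series]:
    """(calendar day, time-of-day offset) of every fix in day_timezone."""
    local = ds.fixes["timestamp"].dt.tz_convert(ds.day_timezone).dt.tz_localize(None)
    day = local.dt.normalize()
    tod = local - day
    return day, tod


def daily_tracks(ds: TelemetryDataset) -> pd.DataFrame:
    """Fix table annotated with the animal's calendar day and time of day."""
    day, tod = _local_parts(ds)
    return ds.fixes.assign(day=day, time_of_day=tod)


def permute_datastream(ds: TelemetryDataset, rng: np.random.Generator) -> TelemetryDataset:
    """One permuted version of the raw datastream.

    For each individual independently, a uniform random permutation of
    its own observed dates is applied to its daily tracks; each fix's new
    timestamp is the permuted date plus the original time-of-day (in the
    dataset's day timezone).  Spatial coordinates are untouched.
    """
    day, tod = _local_parts(ds)
    fixes = ds.fixes
    new_local = pd.Series(pd.NaT, index=fixes.index, dtype="datetime64[ns]")
    for _, idx in fixes.groupby("animal_id", sort=True).groups.items():
        days = day.loc[idx]
        observed = days.unique()  # order of first appearance; deterministic
        perm = observed[rng.permutation(len(observed))]
        mapping = pd.Series(perm, index=observed)
        new_local.loc[idx] = days.map(mapping).to_numpy() + tod.loc[idx].to_numpy()
    ts = (
        new_local.dt.tz_localize(ds.day_timezone, nonexistent="shift_forward", ambiguous=True)
        .dt.tz_convert("UTC")
    )
    out = fixes.assign(timestamp=ts).sort_values(
        ["animal_id", "timestamp"], kind="mergesort"
    )
    return ds.with_fixes(out)


@dataclass
class NullDistribution:
    """Null distribution of one global metric under datastream permutation.

    p-values use the add-one permutation correction, e.g.
    p_upper = (1 + #{null >= observed}) / (n_valid + 1), so p > 0 always.
    Permutations where the metric is undefined (NA) are excluded from the
    counts; ``n_na`` reports how many.
    """

    metric: str
    observed: float
    null_values: np.ndarray
    n_na: int = 0
    p_upper: float = field(init=False)
    p_lower: float = field(init=False)
    p_two_sided: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.null_values, dtype=float)
        valid = vals[np.isfinite(vals)]
        n = len(valid)
        if n == 0 or not np.isfinite(self.observed):
            self.p_upper = self.p_lower = self.p_two_sided = np.nan
            return
        self.p_upper = (1 + int((valid >= self.observed).sum())) / (n + 1)
        self.p_lower = (1 + int((valid <= self.observed).sum())) / (n + 1)
        self.p_two_sided = min(1.0, 2.0 * min(self.p_upper, self.p_lower))

    def quantile(self, q: float) -> float:
        vals = np.asarray(self.null_values, dtype=float)
        return float(np.nanquantile(vals, q))


def null_distribution(
    ds: TelemetryDataset,
    thresholds: Thresholds,
    metrics: set[str] | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    **network_kw,
) -> dict[str, NullDistribution]:
    """Global-metric null distributions from permuted datastreams.

    Builds ``n_perm`` permuted datastreams, a network from each, and
    records the requested global metrics; the observed values come from
    the unpermuted stream.  Per-permutation RNG streams are spawned from
    the passed generator so runs are reproducible and order-independent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    metrics = set(metrics) if metrics is not None else set(DEFAULT_GLOBAL_METRICS)
    rng = rng if rng is not None else np.random.default_rng()
    observed_net = build_network(ds, thresholds, **network_kw)
    observed = global_metrics(observed_net, metrics)
    children = rng.spawn(n_perm)
    null_vals = {m: np.empty(n_perm) for m in metrics}
    for k, child in enumerate(children):
        perm_net = build_network(permute_datastream(ds, child), thresholds, **network_kw)
        gm = global_metrics(perm_net, metrics)
        for m in metrics:
            null_vals[m][k] = gm[m]
    out = {}
    for m in metrics:
        n_na = int(np.isnan(null_vals[m]).sum())
        if n_na:
            logger.info("metric %s undefined in %d/%d permutations", m, n_na, n_perm)
        out[m] = NullDistribution(m, observed[m], null_vals[m], n_na=n_na)
    return out


def null_summary(dists: dict[str, NullDistribution]) -> pd.DataFrame:
    """Tidy summary: observed value, null mean/quantiles, p-values."""
    rows = []
    for m in sorted(dists):
        d = dists[m]
        vals = np.asarray(d.null_values, dtype=float)
        rows.append(
            {
                "metric": m,
                "observed": d.observed,
                "null_mean": float(np.nanmean(vals)),
                "null_q025": float(np.nanquantile(vals, 0.025)),
                "null_q50": float(np.nanquantile(vals, 0.50)),
                "null_q975": float(np.nanquantile(vals, 0.975)),
                "n_na": d.n_na,
                "p_upper": d.p_upper,
                "p_lower": d.p_lower,
                "p_two_sided": d.p_two_sided,
            }
        )
    return pd.DataFrame(rows)


def null_values_table(dists: dict[str, NullDistribution]) -> pd.DataFrame:
    """Long table: one row per permutation per metric."""
    frames = [
        pd.DataFrame(
            {"metric": m, "permutation": np.arange(len(d.null_values)), "value": d.null_values}
        )
        for m, d in sorted(dists.items())
    ]
    return pd.concat(frames, ignore_index=True)
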
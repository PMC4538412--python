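"""Probe-intensity normalization and differential-expression screening.

The screening pipeline follows the standard RMA-style sequence for
single-channel arrays — per-sample background adjustment, quantile
normalization, log2 transform, optional median-polish summarization — and
then screens each probe with a one-way ANOVA across the dose groups
(control, low dose, high dose) followed by a signed fold-change cut.
Down-regulation is reported on the signed scale (ratio r < 1 becomes
-1/r), so a screened probe satisfies p < p_cut and |fc| >= fc_cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProbeMatrix:
    """Probe x sample intensity matrix with group assignments.

    ``values`` is a DataFrame indexed by probe id with sample-id columns;
    ``groups`` maps every sample id to its group label; ``scale`` is
    ``"linear"`` (all values > 0) or ``"log2"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be > 0")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group: {', '.join(map(str, missing))}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class ScreenThresholds:
    """Significance and fold-change cut-offs for the DE screen."""

    p_cut: float = 0.05
    fc_cut: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cut <= 1.0:
            raise ValueError("p_cut must be in (0, 1]")
        if self.fc_cut < 1.0:
            raise ValueError("fc_cut must be >= 1")


@dataclass
class DEResult:
    """Per-probe ANOVA p-value and per-contrast signed fold change."""

    probe_id: str
    p_value: float
    fc_signed: dict[str, float]
    direction: dict[str, str]  # contrast -> up | down | flat


def background_adjust(m: ProbeMatrix, percentile: float = 2.0) -> ProbeMatrix:
    """Subtract a per-sample background (given intensity percentile), floor at 1.

    A simple percentile-shift background stands in for the normal+exponential
    convolution model; the floor at 1.0 keeps log2 defined.
    """
    if m.scale != "linear":
        raise ValueError("background adjustment operates on linear intensities")
    vals = m.values.to_numpy(dtype=float)
    bg = np.percentile(vals, percentile, axis=0)
    adjusted = np.maximum(vals - bg[None, :], 1.0)
    return ProbeMatrix(
        values=pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns),
        groups=dict(m.groups),
        scale="linear",
    )


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Force every sample onto the mean distribution of order statistics.

    After the call every column has the identical sorted value vector and
    within-sample rank order is preserved. Tied input values receive the
    mean of the target values at the ranks they occupy, which makes the
    transform idempotent.
    """
    vals = m.values.to_numpy(dtype=float)
    n_probes, n_samples = vals.shape
    if n_samples < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        return ProbeMatrix(values=m.values.copy(), groups=dict(m.groups), scale=m.scale)
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        provisional = np.empty(n_probes)
        provisional[order] = target
        # ties: average the target values over each run of equal inputs
        s = pd.Series(provisional)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return ProbeMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        groups=dict(m.groups),
        scale=m.scale,
    )


def log2_transform(m: ProbeMatrix) -> ProbeMatrix:
    if m.scale != "linear":
        raise ValueError("matrix already on log2 scale")
    return ProbeMatrix(values=np.log2(m.values), groups=dict(m.groups), scale="log2")


def median_polish_summarize(
    probe_groups: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    max_iter: int = 10,
    tol: float = 0.01,
) -> ProbeMatrix:
    """Summarize each probeset's log2 sub-matrix into one row by median polish.

    Tukey's additive decomposition by iterated row/column median sweeps;
    the summarized value per sample is overall effect + column effect.
    """
    rows = {}
    columns = None
    for probeset, sub in probe_groups.items():
        if sub.shape[0] == 0:
            raise ValueError(f"empty probeset {probeset!r}")
        x = sub.to_numpy(dtype=float).copy()
        overall = 0.0
        col_eff = np.zeros(x.shape[1])
        for _ in range(max_iter):
            row_med = np.median(x, axis=1)
            x -= row_med[:, None]
            delta_o = np.median(row_med)  # recentre row effects into the overall
            overall += delta_o
            col_med = np.median(x, axis=0)
            x -= col_med[None, :]
            col_eff += col_med
            delta_c = np.median(col_eff)
            col_eff -= delta_c
            overall += delta_c
            if max(np.abs(row_med).max(initial=0.0), np.abs(col_med).max(initial=0.0)) < tol:
                break
        rows[probeset] = overall + col_eff
        columns = list(sub.columns)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return ProbeMatrix(values=values, groups=dict(groups), scale="log2")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def anova_one_way(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: F = between-group MS / within-group MS.

    Degenerate within-group variance is resolved by the group means: p = 0
    (with a warning) if they differ, p = 1 if they do not.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(len(g) for g in groups)
    df_b, df_w = k - 1, n - k
    if df_w < 1:
        raise ValueError("error degrees of freedom < 1")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        if ssb > 0.0:
            warnings.warn("zero within-group variance with unequal means: p = 0")
            return AnovaResult(float("inf"), 0.0, df_b, df_w)
        warnings.warn("zero within-group variance with equal means: p = 1")
        return AnovaResult(0.0, 1.0, df_b, df_w)
    f = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(float(f), float(stats.f.sf(f, df_b, df_w)), df_b, df_w)


def signed_fold_change(mean_log2_treated: float, mean_log2_control: float) -> float:
    """2^(treated - control) on the signed scale: ratios < 1 reported as -1/r."""
    r = 2.0 ** (float(mean_log2_treated) - float(mean_log2_control))
    return r if r >= 1.0 else -1.0 / r


def _direction(fc: float, fc_cut: float) -> str:
    if fc >= fc_cut:
        return "up"
    if fc <= -fc_cut:
        return "down"
    return "flat"


def differential_expression(
    m: ProbeMatrix,
    control_group: str = "control",
    treated_groups: Sequence[str] = ("dose_low", "dose_high"),
    background: bool = True,
    background_percentile: float = 2.0,
    fc_cut_for_direction: float = 1.5,
) -> list[DEResult]:
    """Normalize and test every probe: ANOVA across all groups + per-contrast FC.

    A linear-scale matrix is background-adjusted (optional), quantile
    normalized and log2 transformed; a log2-scale matrix is used as-is.
    """
    if m.scale == "linear":
        if background:
            m = background_adjust(m, percentile=background_percentile)
        m = quantile_normalize(m)
        m = log2_transform(m)
    all_groups = [control_group, *treated_groups]
    cols = {g: m.samples_in_group(g) for g in all_groups}
    for g, c in cols.items():
        if not c:
            raise ValueError(f"group {g!r} has no samples")
    vals = m.values
    results = []
    for probe_id, row in vals.iterrows():
        by_group = {g: row[cols[g]].to_numpy() for g in all_groups}
        p = anova_one_way(by_group).p_value
        control_mean = by_group[control_group].mean()
        fc = {g: signed_fold_change(by_group[g].mean(), control_mean) for g in treated_groups}
        direction = {g: _direction(v, fc_cut_for_direction) for g, v in fc.items()}
        results.append(DEResult(probe_id=str(probe_id), p_value=p, fc_signed=fc, direction=direction))
    return results


def de_screen(
    results: Sequence[DEResult], th: ScreenThresholds, contrast: str
) -> tuple[list[DEResult], dict[str, int]]:
    """Keep probes with p < p_cut and |fc| >= fc_cut for the given contrast.

    Returns the screened list plus counts {total, up, down}.
    """
    missing = [r.probe_id for r in results if contrast not in r.fc_signed]
    if missing:
        raise ValueError(f"contrast {contrast!r} missing for probes: {missing[:5]}")
    kept = [
        r
        for r in results
        if r.p_value < th.p_cut and abs(r.fc_signed[contrast]) >= th.fc_cut
    ]
    up = sum(1 for r in kept if r.fc_signed[contrast] >= th.fc_cut)
    down = sum(1 for r in kept if r.fc_signed[contrast] <= -th.fc_cut)
    return kept, {"total": len(kept), "up": up, "down": down}


def results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Flatten DE results to a tidy frame (one fc/direction column per contrast)."""
    contrasts = sorted({c for r in results for c in r.fc_signed})
    data = {"probe_id": [r.probe_id for r in results], "p_value": [r.p_value for r in results]}
    for c in contrasts:
        data[f"fc_{c}"] = [r.fc_signed[c] for r in results]
        data[f"direction_{c}"] = [r.direction[c] for r in results]
    return pd.DataFrame(data)


def read_matrix_tsv(matrix_path, samples_path, scale: str = "linear") -> ProbeMatrix:
    """Read a TSV matrix (first column probe id) and sample sheet (sample_id, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
    return ProbeMatrix(values=values, groups=groups, scale=scale)
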
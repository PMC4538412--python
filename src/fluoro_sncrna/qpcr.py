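"""Relative quantification by the ddCt method, plus LC50 interpolation.

The 2^-ddCt method compares a target gene's Ct to a reference aggregate in
treated vs control conditions:

    dCt   = mean Ct(target) - mean(per-reference mean Ct)   per condition
    ddCt  = dCt(treated) - dCt(control)
    FC    = 2^-ddCt

Fold changes are reported on the signed scale (FC >= 1 kept as-is, FC < 1
reported as -1/FC), so down-regulation carries a negative sign and |fc| >= 1.
Amplification efficiency is fixed at 2 per cycle (the ddCt assumption).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = ("sample", "condition", "gene", "replicate", "ct")


@dataclass(frozen=True)
class FoldChangeResult:
    """ddCt-derived signed fold change for one gene at one dose/condition."""

    gene_id: str
    dose: str
    ddct: float
    fc_signed: float
    dispersion: float  # SD of |fc| across treated replicates (0 if single replicate)


def _signed(linear_fc: float) -> float:
    return linear_fc if linear_fc >= 1.0 else -1.0 / linear_fc


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {', '.join(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    return table


def _mean_ct(table: pd.DataFrame, condition: str, gene: str) -> float:
    sel = table[(table["condition"] == condition) & (table["gene"] == gene)]["ct"]
    if sel.empty:
        raise ValueError(f"no Ct values for gene {gene!r} in condition {condition!r}")
    return float(sel.mean())


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    reference_genes: Sequence[str],
    dose: str = "",
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> FoldChangeResult:
    """Signed 2^-ddCt fold change of ``gene`` vs the reference aggregate.

    The reference aggregate is the arithmetic mean of the per-reference-gene
    mean Cts (equivalent to the geometric mean of their relative
    quantities). Dispersion is the SD of the linear fold-change magnitudes
    obtained by re-evaluating ddCt per treated replicate; a single treated
    replicate yields dispersion 0 with a warning.
    """
    validate_ct_table(table)
    if not reference_genes:
        raise ValueError("reference_genes must be non-empty")
    ref_agg = {
        cond: float(np.mean([_mean_ct(table, cond, g) for g in reference_genes]))
        for cond in (control_condition, treated_condition)
    }
    dct_control = _mean_ct(table, control_condition, gene) - ref_agg[control_condition]
    dct_treated = _mean_ct(table, treated_condition, gene) - ref_agg[treated_condition]
    ddct = dct_treated - dct_control
    fc_signed = _signed(2.0 ** (-ddct))

    treated_cts = table[
        (table["condition"] == treated_condition) & (table["gene"] == gene)
    ]["ct"].to_numpy(dtype=float)
    if len(treated_cts) < 2:
        warnings.warn(f"single treated replicate for {gene!r}: dispersion reported as 0")
        dispersion = 0.0
    else:
        per_rep = 2.0 ** (-((treated_cts - ref_agg[treated_condition]) - dct_control))
        mags = np.abs([_signed(v) for v in per_rep])
        dispersion = float(np.std(mags, ddof=1))
    return FoldChangeResult(gene_id=gene, dose=dose, ddct=float(ddct), fc_signed=fc_signed, dispersion=dispersion)


def fold_change_table(
    table: pd.DataFrame, genes: Sequence[str], reference_genes: Sequence[str], dose: str = ""
) -> pd.DataFrame:
    """ddCt fold changes for several genes as a tidy frame."""
    rows = [ddct_fold_change(table, g, reference_genes, dose=dose) for g in genes]
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in rows],
            "dose": [r.dose for r in rows],
            "ddct": [r.ddct for r in rows],
            "fc_signed": [r.fc_signed for r in rows],
            "dispersion": [r.dispersion for r in rows],
        }
    )


def read_ct_tsv(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t"))


def lc50_interpolate(doses: Sequence[float], viability: Sequence[float]) -> float:
    """Dose at which viability crosses 0.5, by linear interpolation on log10(dose).

    The first crossing is used if the curve crosses 0.5 more than once.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if len(doses) != len(viability):
        raise ValueError("doses and viability must have equal length")
    if len(doses) < 2:
        raise ValueError("need at least 2 dose points")
    if not np.all(np.diff(doses) > 0):
        raise ValueError("doses must be strictly increasing")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive for log interpolation")
    for i in range(len(doses)):
        if viability[i] == 0.5:
            return float(doses[i])
        if i + 1 < len(doses) and (viability[i] - 0.5) * (viability[i + 1] - 0.5) < 0:
            f = (viability[i] - 0.5) / (viability[i] - viability[i + 1])
            logd = math.log10(doses[i]) + f * (math.log10(doses[i + 1]) - math.log10(doses[i]))
            return float(10.0 ** logd)
    raise ValueError("viability never crosses 0.5; LC50 undefined in the tested range")
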
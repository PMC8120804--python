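"""RT-qPCR relative quantification.

The chain is Ct -> RQ -> cRQ -> normalized relative mRNA:

* RQ = (1 + E)^(Ct_ref - Ct), the quantity relative to the first sample of
  the experiment (E = amplification efficiency, 1.0 for the ~100%-efficient
  TaqMan assays used here, giving the familiar 2^dCt),
* cRQ divides by the geometric mean of the paired GAPDH/PGK1 housekeeping
  RQs, cancelling any per-sample loading offset on the Ct scale,
* normalization maps the baseline (pre-stimulation) value to 0 and the mean
  dark-arm cRQ over the 180-240 min window to 1.

Ct tables are DataFrames with columns (time_min, condition, gene, replicate,
ct).  Technical replicates are averaged on the Ct scale (geometric averaging
on the quantity scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING",
    "ct_to_rq",
    "correct_rq",
    "crq_table",
    "normalize_crq",
    "light_dark_series",
]

HOUSEKEEPING = ("GAPDH", "PGK1")
CT_COLUMNS = ["time_min", "condition", "gene", "replicate", "ct"]


def ct_to_rq(ct, ct_reference, efficiency: float = 1.0):
    """Relative quantity (1 + efficiency)^(ct_reference - ct); vectorized."""
    ct = np.asarray(ct, dtype=float)
    return (1.0 + efficiency) ** (np.asarray(ct_reference, dtype=float) - ct)


def correct_rq(rq_target, rq_gapdh, rq_pgk1):
    """Housekeeping-corrected cRQ = RQ / sqrt(RQ_GAPDH * RQ_PGK1)."""
    rq_gapdh = np.asarray(rq_gapdh, dtype=float)
    rq_pgk1 = np.asarray(rq_pgk1, dtype=float)
    if np.any(rq_gapdh <= 0) or np.any(rq_pgk1 <= 0):
        raise ValueError("housekeeping RQs must be positive")
    return np.asarray(rq_target, dtype=float) / np.sqrt(rq_gapdh * rq_pgk1)


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"Ct table missing columns {missing}")
    return table.groupby(["time_min", "condition", "gene"], as_index=False)["ct"].mean()


def crq_table(table: pd.DataFrame, efficiency: float = 1.0) -> pd.DataFrame:
    """Full Ct -> RQ -> cRQ computation for a tidy Ct table.

    The RQ reference for each (gene, condition) arm is the Ct at the earliest
    time point of the experiment.  Returns columns (time_min, condition,
    gene, rq, crq).
    """
    mean_ct = _mean_ct(table)
    for gene in HOUSEKEEPING:
        if gene not in set(mean_ct["gene"]):
            raise ValueError(f"housekeeping gene {gene} absent from Ct table")
    t0 = mean_ct["time_min"].min()
    out = []
    for condition, arm in mean_ct.groupby("condition"):
        wide = arm.pivot(index="time_min", columns="gene", values="ct")
        if wide.isna().any().any():
            raise ValueError(f"condition {condition}: missing Ct values for some (time, gene)")
        ref = wide.loc[t0] if t0 in wide.index else wide.iloc[0]
        rq = pd.DataFrame(ct_to_rq(wide, ref, efficiency), index=wide.index, columns=wide.columns)
        hk = np.sqrt(rq[HOUSEKEEPING[0]] * rq[HOUSEKEEPING[1]])
        crq = rq.div(hk, axis=0)
        long = crq.reset_index().melt(id_vars="time_min", var_name="gene", value_name="crq")
        long["rq"] = rq.reset_index().melt(id_vars="time_min", var_name="gene", value_name="rq")["rq"]
        long["condition"] = condition
        out.append(long)
    return pd.concat(out, ignore_index=True)[["time_min", "condition", "gene", "rq", "crq"]]


def normalize_crq(
    crq: pd.DataFrame,
    gene: str,
    window: tuple[float, float] = (180.0, 240.0),
    baseline_time: float | None = None,
) -> pd.DataFrame:
    """Normalize one gene's cRQ series to ~[0, 1].

    baseline (the pre-stimulation cRQ, default the earliest sample) maps to
    0; the mean dark-arm cRQ over the 180-240 min window maps to 1.  Both
    arms are normalized with the same dark-arm scale so the light/dark ratio
    is meaningful.  Returns columns (time_min, condition, relative_mrna).
    """
    sub = crq[crq["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not in cRQ table")
    dark = sub[sub["condition"] == "dark"]
    in_window = dark[(dark["time_min"] >= window[0]) & (dark["time_min"] <= window[1])]
    if len(in_window) < 2:
        raise ValueError(f"need >= 2 dark-arm points in the {window} min window")
    t0 = sub["time_min"].min() if baseline_time is None else baseline_time
    baseline = float(sub[sub["time_min"] == t0]["crq"].mean())
    scale = float(in_window["crq"].mean()) - baseline
    if scale <= 0:
        raise ValueError("normalization window mean does not exceed baseline")
    out = sub.copy()
    out["relative_mrna"] = (out["crq"] - baseline) / scale
    return out[["time_min", "condition", "relative_mrna"]].reset_index(drop=True)


def light_dark_series(normalized: pd.DataFrame, t_illumination: float = 180.0) -> tuple[pd.Series, pd.Series]:
    """Paired light and dark relative-mRNA series from illumination onward.

    Returns (light, dark) Series indexed by minutes since illumination,
    suitable for :func:`optokinetics.kinetics_fit.ratio_decay_halflife`.
    Unmatched time grids raise.
    """
    sel = normalized[normalized["time_min"] >= t_illumination]
    light = sel[sel["condition"] == "light"].set_index("time_min")["relative_mrna"].sort_index()
    dark = sel[sel["condition"] == "dark"].set_index("time_min")["relative_mrna"].sort_index()
    if not np.array_equal(light.index.values, dark.index.values):
        raise ValueError("light and dark arms have unmatched time grids")
    light.index = light.index - t_illumination
    dark.index = dark.index - t_illumination
    return light, dark
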
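"""Relative qPCR quantification by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference) per sample (EF1-a is the usual mRNA
reference, U6 the miRNA reference); ddCt = dCt(sample) - dCt(calibrator);
RQ = 2^-ddCt, so the calibrator sample always has RQ = 1. Technical
replicates are averaged on the Ct scale before any differencing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def relative_quantity(
    measurements: pd.DataFrame,
    calibrator: str,
) -> pd.DataFrame:
    """Compute RQ per (sample, target gene).

    *measurements* is tidy with columns sample, gene, role ('target' or
    'reference'), ct; technical replicates appear as repeated rows and are
    averaged first. Returns a frame with columns sample, gene, dct, ddct,
    rq. Raises if the calibrator sample or any reference Ct is missing.
    """
    required = {"sample", "gene", "role", "ct"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    if not np.isfinite(measurements["ct"]).all() or (measurements["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    mean_ct = (
        measurements.groupby(["sample", "gene", "role"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["role"] == "reference"].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["role"] == "target"]
    samples = targets["sample"].unique()
    missing_ref = [s for s in samples if s not in ref.index]
    if missing_ref:
        raise ValueError(f"missing reference Ct for samples {missing_ref}")
    if calibrator not in set(samples):
        raise ValueError(f"calibrator sample {calibrator!r} not present")

    out = targets.copy()
    out["dct"] = out["ct"] - out["sample"].map(ref)
    cal_dct = out[out["sample"] == calibrator].set_index("gene")["dct"]
    missing_cal = [g for g in out["gene"].unique() if g not in cal_dct.index]
    if missing_cal:
        raise ValueError(f"calibrator lacks measurements for genes {missing_cal}")
    out["ddct"] = out["dct"] - out["gene"].map(cal_dct)
    out["rq"] = 2.0 ** (-out["ddct"])
    return out[["sample", "gene", "dct", "ddct", "rq"]].reset_index(drop=True)


def profile_correlation(
    qpcr_rq: pd.Series,
    pipeline_expr: pd.Series,
) -> float:
    """Pearson correlation of log2 qPCR RQ vs log2 pipeline expression.

    Series must share an index of (genotype, stage) cells. A constant
    series makes the correlation undefined; NaN is returned in that case.
    """
    if len(qpcr_rq) != len(pipeline_expr):
        raise ValueError("profile length mismatch")
    a = np.log2(np.asarray(qpcr_rq, dtype=float))
    b = np.log2(np.asarray(pipeline_expr, dtype=float))
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
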
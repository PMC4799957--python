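"""Relative qPCR quantification (2^-ddCt) with group testing and BH FDR.

Per sample, dCt = Ct(target) - Ct(housekeeping); ddCt subtracts the
control-group mean dCt (Livak baseline), and the relative quantity is
2^-ddCt, i.e. fold expression versus the control group.  Under this
baseline the control group's geometric mean relative quantity is exactly 1
(its arithmetic mean is 1 in noiseless data).  Group differences are
tested per gene on the relative quantities with a two-sided unpaired
Student's t-test (equal variance by default; Welch via a flag), followed
by Benjamini-Hochberg FDR across the gene panel; q < 0.1 is called
significant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CrossCnaError

logger = logging.getLogger(__name__)


def ddct_fold_change(ct: pd.DataFrame, control_group: str = "control",
                     ) -> pd.DataFrame:
    """Per-sample relative quantities by the 2^-ddCt method.

    ``ct`` columns: sample_id, group, gene_id, ct_target, ct_housekeeping.
    Samples missing either Ct for a gene are excluded from that gene with
    a warning.  Genes with no usable control sample (e.g. undetected in
    controls) are excluded with a warning — no fold change is defined for
    them.  Returns rows (gene_id, sample_id, group, delta_ct, ddct,
    rel_quantity).
    """
    required = {"sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"}
    missing = required - set(ct.columns)
    if missing:
        raise CrossCnaError(f"Ct table missing columns {sorted(missing)}")
    if not (ct["group"] == control_group).any():
        raise CrossCnaError(f"empty control group {control_group!r}")
    out = []
    for gene, sub in ct.groupby("gene_id", sort=True):
        usable = sub["ct_target"].notna() & sub["ct_housekeeping"].notna()
        n_bad = int((~usable).sum())
        if n_bad:
            logger.warning("gene %s: excluded %d sample(s) with missing Ct",
                           gene, n_bad)
        sub = sub[usable]
        ctrl = sub[sub["group"] == control_group]
        if len(ctrl) == 0:
            logger.warning("gene %s: no usable control sample; no fold change "
                           "defined (reported descriptively only)", gene)
            continue
        delta = sub["ct_target"].to_numpy(float) - sub["ct_housekeeping"].to_numpy(float)
        baseline = float(np.mean(ctrl["ct_target"].to_numpy(float)
                                 - ctrl["ct_housekeeping"].to_numpy(float)))
        ddct = delta - baseline
        out.append(pd.DataFrame({
            "gene_id": gene,
            "sample_id": sub["sample_id"].to_numpy(),
            "group": sub["group"].to_numpy(),
            "delta_ct": delta,
            "ddct": ddct,
            "rel_quantity": np.power(2.0, -ddct),
        }))
    if not out:
        raise CrossCnaError("no gene had usable control measurements")
    return pd.concat(out, ignore_index=True)


def ttest_fdr(rel: pd.DataFrame, control_group: str = "control",
              q_threshold: float = 0.1, equal_var: bool = True) -> pd.DataFrame:
    """Per-gene group test on relative quantities with BH correction.

    Genes with fewer than 2 usable samples in either group get a missing
    p-value and are excluded from the BH panel (with a warning).  Returns
    one row per gene: group means +- sd of the relative quantities,
    t_p_value, fdr_q, significant (q < ``q_threshold``).
    """
    rows = []
    for gene, sub in rel.groupby("gene_id", sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "rel_quantity"].to_numpy(float)
        trt = sub.loc[sub["group"] != control_group, "rel_quantity"].to_numpy(float)
        if len(ctrl) >= 2 and len(trt) >= 2:
            p = float(stats.ttest_ind(ctrl, trt, equal_var=equal_var).pvalue)
        else:
            p = float("nan")
            logger.warning("gene %s: <2 usable samples in a group; excluded "
                           "from the FDR panel", gene)
        rows.append({
            "gene_id": gene,
            "n_control": len(ctrl),
            "n_treated": len(trt),
            "control_mean": float(np.mean(ctrl)) if len(ctrl) else float("nan"),
            "control_sd": float(np.std(ctrl, ddof=1)) if len(ctrl) > 1 else float("nan"),
            "treated_mean": float(np.mean(trt)) if len(trt) else float("nan"),
            "treated_sd": float(np.std(trt, ddof=1)) if len(trt) > 1 else float("nan"),
            "t_p_value": p,
        })
    res = pd.DataFrame(rows)
    res["fdr_q"] = np.nan
    tested = res["t_p_value"].notna()
    if tested.any():
        res.loc[tested, "fdr_q"] = bh_qvalues(res.loc[tested, "t_p_value"].to_numpy())
    res["significant"] = res["fdr_q"] < q_threshold
    return res


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a panel of p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.isnan(pvalues).any():
        raise CrossCnaError("bh_qvalues requires finite p-values")
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return q


def write_qpcr_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
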
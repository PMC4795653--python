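"""Relative-expression arithmetic: 2^-dCt, 2^-ddCt and normalization
fold drop.

Replicate Ct values are averaged per (sample, gene) before any delta is
computed; no amplification-efficiency correction is applied (plain base-2
arithmetic).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def rel_expression_dct(ct_target: float, ct_reference: float) -> float:
    """Expression of a target relative to a reference gene: 2^-(Ct_t - Ct_r)."""
    _check_ct(ct_target, ct_reference)
    return float(2.0 ** -(ct_target - ct_reference))


def rel_expression_ddct(ct_target_trt: float, ct_ref_trt: float,
                        ct_target_ctl: float, ct_ref_ctl: float) -> float:
    """Treated-vs-control fold change: 2^-[(dCt_treated) - (dCt_control)]."""
    _check_ct(ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl)
    ddct = (ct_target_trt - ct_ref_trt) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** -ddct)


def fold_drop(freq_before: float, freq_after: float) -> float:
    """Depletion of a marker clone across normalization: f_before / f_after."""
    if freq_after <= 0:
        raise ValueError("fold drop undefined for zero post-normalization "
                         "frequency")
    return freq_before / freq_after


def _check_ct(*cts: float) -> None:
    for ct in cts:
        if not np.isfinite(ct) or ct <= 0:
            raise ValueError(f"Ct values must be finite and positive, got {ct}")


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def load_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a Ct table TSV with columns sample, gene, ct (replicates as
    repeated rows)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return df


def mean_ct(df: pd.DataFrame) -> pd.DataFrame:
    return df.groupby(["sample", "gene"], as_index=False)["ct"].mean()


def dct_table(df: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-sample 2^-dCt of every gene against the reference gene."""
    m = mean_ct(df)
    ref = m[m["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    out = m[m["gene"] != reference_gene].copy()
    out["rel_expression"] = [
        rel_expression_dct(ct, ref[s]) for s, ct in zip(out["sample"], out["ct"])
    ]
    out["method"] = "dct"
    return out.reset_index(drop=True)


def ddct_table(df: pd.DataFrame, reference_gene: str, control_sample: str
               ) -> pd.DataFrame:
    """Per-gene 2^-ddCt of every non-control sample against the control."""
    m = mean_ct(df)
    piv = m.pivot(index="gene", columns="sample", values="ct")
    if control_sample not in piv.columns:
        raise ValueError(f"control sample {control_sample!r} absent")
    rows = []
    for sample in piv.columns:
        if sample == control_sample:
            continue
        for gene in piv.index:
            if gene == reference_gene:
                continue
            rows.append({
                "sample": sample, "gene": gene,
                "rel_expression": rel_expression_ddct(
                    piv.loc[gene, sample], piv.loc[reference_gene, sample],
                    piv.loc[gene, control_sample],
                    piv.loc[reference_gene, control_sample]),
                "method": "ddct",
            })
    return pd.DataFrame(rows)
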
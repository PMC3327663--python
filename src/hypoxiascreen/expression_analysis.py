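"""Relative quantification of gene expression by qPCR (delta-delta-Ct).

Target Ct values are normalized to a reference gene (beta-actin) within
each condition, and the hypoxia/normoxia expression fold change is
2**(-ddCt).  A gene is called hypoxia-*induced* when the between-condition
t-test on replicate dCt values is significant and the fold change clears
a minimum (default 2-fold, either direction).  The HIF-1 targets GLUT1
(~7-fold) and PDK1 (~4-fold) serve as positive controls; the screen's
candidate genes are expected to fail this test, which is the point — they
respond to oxygen through growth, not transcription.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth_assay import ttest_two_sided
from .screen_sim import HYPOXIA, NORMOXIA


def _delta_ct(ct: pd.DataFrame, gene: str, reference: str, condition: str) -> np.ndarray:
    """Replicate-paired dCt = Ct(target) - Ct(reference) for one condition."""
    sel = ct[ct["condition"] == condition]
    tgt = sel[sel["gene_id"] == gene].sort_values("replicate")["ct"].to_numpy(float)
    ref = sel[sel["gene_id"] == reference].sort_values("replicate")["ct"].to_numpy(float)
    if len(ref) == 0:
        raise ValueError(f"reference gene {reference!r} missing from {condition} records")
    if len(tgt) == 0:
        raise ValueError(f"gene {gene!r} missing from {condition} records")
    if len(tgt) != len(ref):
        raise ValueError(f"replicate mismatch for {gene} vs {reference} in {condition}")
    return tgt - ref


def ddct_fold_change(ct: pd.DataFrame, gene: str, reference: str = "ACTB") -> float:
    """Hypoxia/normoxia expression fold change, 2**(-ddCt).

    dCt is the condition mean of (Ct_target - Ct_reference); ddCt is
    dCt_hypoxia - dCt_normoxia.  A plate-wide Ct shift cancels.
    """
    d_hyp = _delta_ct(ct, gene, reference, HYPOXIA).mean()
    d_norm = _delta_ct(ct, gene, reference, NORMOXIA).mean()
    return float(2.0 ** (-(d_hyp - d_norm)))


def induction_test(
    ct: pd.DataFrame,
    gene: str,
    reference: str = "ACTB",
    alpha: float = 0.05,
    fold_min: float = 2.0,
    use_welch: bool = False,
) -> dict:
    """Test whether a gene's expression is altered under hypoxia.

    induced iff the two-sided t-test on replicate dCt between conditions
    has p < alpha AND the fold change is beyond ``fold_min`` in either
    direction.  Both criteria are required: a large but noisy fold, or a
    significant but sub-threshold shift, is not called induced.
    """
    d_hyp = _delta_ct(ct, gene, reference, HYPOXIA)
    d_norm = _delta_ct(ct, gene, reference, NORMOXIA)
    fold = float(2.0 ** (-(d_hyp.mean() - d_norm.mean())))
    p = ttest_two_sided(d_hyp, d_norm, equal_var=not use_welch)
    induced = (p < alpha) and (fold > fold_min or fold < 1.0 / fold_min)
    return {"gene_id": gene, "fold_change": fold, "p_value": float(p), "induced": induced}


def analyze_induction(
    ct: pd.DataFrame,
    reference: str = "ACTB",
    alpha: float = 0.05,
    fold_min: float = 2.0,
    use_welch: bool = False,
) -> pd.DataFrame:
    """Induction test for every non-reference gene on the plate."""
    genes = [g for g in ct["gene_id"].unique() if g != reference]
    rows = [induction_test(ct, g, reference, alpha, fold_min, use_welch) for g in genes]
    return pd.DataFrame(rows)


def detect_expression(
    truth: pd.DataFrame,
    false_negative_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Expressed-gene detection (the RT-PCR expression check).

    Exposes the ground-truth expressed flag, optionally dropping each
    expressed gene with the given false-negative probability to emulate
    detection failures.  Unexpressed genes are never falsely detected.
    """
    if not 0.0 <= false_negative_rate <= 1.0:
        raise ValueError("false_negative_rate must lie in [0, 1]")
    expressed = truth.loc[truth["expressed"].astype(bool), "gene_id"].to_numpy()
    if false_negative_rate > 0:
        if rng is None:
            raise ValueError("a generator is required when false_negative_rate > 0")
        keep = rng.random(len(expressed)) >= false_negative_rate
        expressed = expressed[keep]
    return set(expressed)


def gene_expressed(truth: pd.DataFrame, gene_id: str) -> bool:
    """Ground-truth expressed flag of one gene; unknown gene is an error."""
    sel = truth.loc[truth["gene_id"] == gene_id, "expressed"]
    if sel.empty:
        raise KeyError(f"unknown gene {gene_id!r}")
    return bool(sel.iloc[0])
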
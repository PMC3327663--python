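"""Screen readout: probe ratios, 5-fold classification, gene aggregation.

The calling procedure is deliberately the deterministic threshold rule of
the original screen rather than a ranking statistic: a probe is
*overrepresented* if its hypoxia/normoxia abundance ratio exceeds the
fold threshold (default 5, strict), *underrepresented* if it falls below
the reciprocal, and a gene joins a direction group when at least
``min_shrnas`` (default 4) of its probes agree on the direction.  Genes
reaching the threshold in both directions are flagged ``conflicting`` and
assigned to no group.  The final candidate list is the grouped genes that
are expressed in the assayed cell line (the screen's 73 -> 56 filter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

OVER = "overrepresented"
UNDER = "underrepresented"
NEUTRAL = "neutral"
NONE = "none"

_SIGNAL_COLS = ("signal_normoxia", "signal_hypoxia")


def normalize_arms(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each arm to relative abundance (signals summing to 1).

    Idempotent; raises on an arm with no positive signal.
    """
    out = table.copy()
    for col in _SIGNAL_COLS:
        sig = out[col].to_numpy(float)
        if (sig < 0).any():
            raise ValueError(f"negative signal in {col}")
        total = sig.sum()
        if total <= 0:
            raise ValueError(f"arm {col} has all-zero signal")
        out[col] = sig / total
    return out


def probe_ratios(table: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-probe hypoxia/normoxia abundance ratio.

    ratio = (a_hyp + pseudocount) / (a_norm + pseudocount).  With
    pseudocount 0 a zero normoxia signal is an error naming the probe.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    a_norm = table["signal_normoxia"].to_numpy(float) + pseudocount
    a_hyp = table["signal_hypoxia"].to_numpy(float) + pseudocount
    if (a_norm <= 0).any():
        bad = table.loc[a_norm <= 0, "probe_id"].iloc[0]
        raise ZeroDivisionError(
            f"probe {bad} has zero normoxia signal; use a pseudocount > 0"
        )
    out = table[["probe_id", "gene_id"]].copy()
    out["ratio"] = a_hyp / a_norm
    return out


def classify_probes(calls: pd.DataFrame, fold_threshold: float = 5.0) -> pd.DataFrame:
    """Three-way classification at a strict two-sided fold threshold.

    A ratio of exactly ``fold_threshold`` is neutral ("more than five
    times" is a strict inequality).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    ratio = calls["ratio"].to_numpy(float)
    out = calls.copy()
    out["cls"] = np.select(
        [ratio > fold_threshold, ratio < 1.0 / fold_threshold],
        [OVER, UNDER],
        default=NEUTRAL,
    )
    return out


def aggregate_genes(
    calls: pd.DataFrame,
    min_shrnas: int = 4,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Collapse probe classes to per-gene direction groups.

    With ``require_direction`` (default) a gene needs ``min_shrnas``
    probes beyond the threshold *in the same direction*; genes reaching
    the count in both directions are flagged conflicting with group
    "none".  With ``require_direction=False`` the count pools both
    directions and the majority direction wins (a tie is conflicting).
    """
    grouped = (
        calls.assign(
            over=(calls["cls"] == OVER).astype(int),
            under=(calls["cls"] == UNDER).astype(int),
        )
        .groupby("gene_id", sort=True)
        .agg(n_total=("probe_id", "size"), n_over=("over", "sum"), n_under=("under", "sum"))
        .reset_index()
    )
    n_over = grouped["n_over"].to_numpy()
    n_under = grouped["n_under"].to_numpy()
    if require_direction:
        over_hit = n_over >= min_shrnas
        under_hit = n_under >= min_shrnas
        conflicting = over_hit & under_hit
        group = np.select(
            [over_hit & ~conflicting, under_hit & ~conflicting], [OVER, UNDER], default=NONE
        )
    else:
        reached = (n_over + n_under) >= min_shrnas
        conflicting = reached & (n_over == n_under)
        group = np.select(
            [reached & (n_over > n_under), reached & (n_under > n_over)],
            [OVER, UNDER],
            default=NONE,
        )
    grouped["group"] = group
    grouped["conflicting"] = conflicting
    return grouped


def apply_expression_filter(gene_calls: pd.DataFrame, expressed: set[str]) -> pd.DataFrame:
    """Keep only expressed genes as candidates (the 73 -> 56 step).

    Non-candidates are retained with ``candidate = False`` so the funnel
    stays auditable.
    """
    out = gene_calls.copy()
    out["expressed"] = out["gene_id"].isin(expressed)
    out["candidate"] = (out["group"] != NONE) & out["expressed"]
    return out


def call_hits(
    table: pd.DataFrame,
    expressed: set[str],
    fold_threshold: float = 5.0,
    min_shrnas: int = 4,
    pseudocount: float = 0.0,
    require_direction: bool = True,
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: normalize -> ratios -> classify -> aggregate -> filter.

    Returns (probe_calls, gene_calls).
    """
    t = normalize_arms(table) if normalize else table
    probes = classify_probes(probe_ratios(t, pseudocount), fold_threshold)
    genes = aggregate_genes(probes, min_shrnas, require_direction)
    genes = apply_expression_filter(genes, expressed)
    return probes, genes
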
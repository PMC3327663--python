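"""Independent brute-force oracles, coded separately from the package.

Plain-Python loop re-implementations of the hit-calling chain and the
recovery confusion matrix, used to cross-check the vectorised pandas
implementations.  Deliberately kept free of numpy/pandas so they share
no code path with the package.
"""

from __future__ import annotations

import math


def brute_force_gene_calls(
    rows: list[tuple[str, str, float, float]],
    expressed: set[str],
    fold_threshold: float = 5.0,
    min_shrnas: int = 4,
    pseudocount: float = 0.0,
    normalize: bool = True,
) -> dict[str, dict]:
    """rows: (probe_id, gene_id, signal_normoxia, signal_hypoxia)."""
    if normalize:
        tot_n = sum(r[2] for r in rows)
        tot_h = sum(r[3] for r in rows)
        rows = [(p, g, sn / tot_n, sh / tot_h) for p, g, sn, sh in rows]
    genes: dict[str, dict] = {}
    for _, gene, sn, sh in rows:
        ratio = (sh + pseudocount) / (sn + pseudocount)
        if ratio > fold_threshold:
            cls = "overrepresented"
        elif ratio < 1.0 / fold_threshold:
            cls = "underrepresented"
        else:
            cls = "neutral"
        rec = genes.setdefault(gene, {"n_total": 0, "n_over": 0, "n_under": 0})
        rec["n_total"] += 1
        if cls == "overrepresented":
            rec["n_over"] += 1
        elif cls == "underrepresented":
            rec["n_under"] += 1
    for gene, rec in genes.items():
        over = rec["n_over"] >= min_shrnas
        under = rec["n_under"] >= min_shrnas
        rec["conflicting"] = over and under
        if over and not under:
            rec["group"] = "overrepresented"
        elif under and not over:
            rec["group"] = "underrepresented"
        else:
            rec["group"] = "none"
        rec["expressed"] = gene in expressed
        rec["candidate"] = rec["group"] != "none" and rec["expressed"]
    return genes


def brute_force_recovery(
    candidates: set[str], candidate_group: dict[str, str], truth_rows: list[tuple]
) -> dict:
    """truth_rows: (gene_id, expressed, s_normoxia, s_hypoxia)."""
    planted = {g for g, e, sn, sh in truth_rows if e and (sn != 0 or sh != 0)}
    tp = candidates & planted
    expect = {}
    for g, e, sn, sh in truth_rows:
        if sh - sn > 0:
            expect[g] = "overrepresented"
        elif sh - sn < 0:
            expect[g] = "underrepresented"
        else:
            expect[g] = "none"
    directional = [g for g in tp if expect[g] != "none"]
    return {
        "precision": len(tp) / len(candidates) if candidates else None,
        "recall": len(tp) / len(planted) if planted else None,
        "direction_accuracy": (
            sum(candidate_group[g] == expect[g] for g in directional) / len(directional)
            if directional
            else None
        ),
    }


def welch_p_value(a: list[float], b: list[float]) -> float:
    """Welch two-sided p via the t-distribution CDF, coded from the formula."""
    from scipy.special import stdtr  # CDF only; no scipy.stats code path

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1) / na
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1) / nb
    t = (ma - mb) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return 2.0 * float(stdtr(df, -abs(t)))
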
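"""End-to-end orchestration: simulate -> call hits -> confirm -> induction.

Mirrors the original screen's funnel: probe-level 5-fold calls, gene
aggregation at >= 4 concordant shRNAs, the expressed-gene filter, a
growth-assay confirmation round on the candidates (plus negative
controls), and a qPCR induction check on the confirmed genes.  Every
stage persists its table as TSV and the run ends with a JSON report of
the funnel counts, thresholds, seeds and — when ground truth is
available — planted-hit recovery metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_analysis, growth_assay, hit_calling, io, screen_sim
from .config import SimConfig

log = logging.getLogger("hypoxiascreen")


@dataclass
class RecoveryMetrics:
    """Planted-hit recovery of the hit-calling stage.

    ``direction_accuracy`` is computed over recovered hits whose two
    condition effects differ (equal effects produce no differential
    signal and have no defined direction).  Ratios with an empty
    denominator are ``None`` (undefined), never 0.
    """

    n_planted: int
    n_candidates: int
    n_recovered: int
    precision: float | None
    recall: float | None
    direction_accuracy: float | None
    n_confirmed: int | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def truth_direction(s_normoxia: float, s_hypoxia: float) -> str:
    """Expected probe-ratio direction implied by a gene's planted effects."""
    delta = s_hypoxia - s_normoxia
    if delta > 0:
        return hit_calling.OVER
    if delta < 0:
        return hit_calling.UNDER
    return hit_calling.NONE


def evaluate_recovery(
    gene_calls: pd.DataFrame,
    truth: pd.DataFrame,
    confirmed: pd.DataFrame | None = None,
) -> RecoveryMetrics:
    """Precision/recall/direction accuracy of candidates vs planted hits.

    A planted hit is an expressed gene with a nonzero effect in either
    condition.  Precision is the planted fraction of candidate genes,
    recall the candidate fraction of planted genes.
    """
    t = truth.set_index("gene_id")
    planted = t[(t["expressed"].astype(bool)) & ((t["s_normoxia"] != 0) | (t["s_hypoxia"] != 0))]
    missing = set(gene_calls["gene_id"]) - set(t.index)
    if missing:
        raise ValueError(f"truth does not cover called genes: {sorted(missing)[:5]}")

    cand = gene_calls[gene_calls["candidate"]]
    cand_ids = set(cand["gene_id"])
    hit_ids = set(planted.index)
    recovered = cand_ids & hit_ids

    precision = len(recovered) / len(cand_ids) if cand_ids else None
    recall = len(recovered) / len(hit_ids) if hit_ids else None

    directional = [
        g for g in recovered
        if truth_direction(planted.loc[g, "s_normoxia"], planted.loc[g, "s_hypoxia"])
        != hit_calling.NONE
    ]
    if directional:
        groups = cand.set_index("gene_id")["group"]
        correct = sum(
            groups[g] == truth_direction(planted.loc[g, "s_normoxia"], planted.loc[g, "s_hypoxia"])
            for g in directional
        )
        direction_accuracy = correct / len(directional)
    else:
        direction_accuracy = None

    n_confirmed = None
    if confirmed is not None and len(confirmed):
        n_confirmed = int(confirmed["confirmed"].sum())

    return RecoveryMetrics(
        n_planted=len(hit_ids),
        n_candidates=len(cand_ids),
        n_recovered=len(recovered),
        precision=precision,
        recall=recall,
        direction_accuracy=direction_accuracy,
        n_confirmed=n_confirmed,
    )


def _growth_round(
    genes: list[str],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the two-shRNA growth assay for a list of genes."""
    t = truth.set_index("gene_id")
    tables = []
    for gene in genes:
        effs = tuple(rng.uniform(config.efficacy_low, config.efficacy_high, 2))
        tables.append(
            screen_sim.simulate_growth_assay(
                gene,
                float(t.loc[gene, "s_normoxia"]),
                float(t.loc[gene, "s_hypoxia"]),
                effs,  # type: ignore[arg-type]
                config.growth,
                rng,
            )
        )
    if not tables:
        return pd.DataFrame(columns=io.GROWTH_COLS)
    return pd.concat(tables, ignore_index=True)


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run the whole screen-and-confirm workflow; returns the report dict.

    Confirmation assays are run only for the candidate genes plus
    ``config.analysis.n_negative_controls`` expressed non-candidate
    genes, mirroring the original workflow where only the filtered
    candidates entered the growth assays.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    ana = config.analysis
    rng = np.random.default_rng(config.seed)

    log.info("stage simulate: %d genes, %d passages, seed %d",
             config.n_genes, config.passages, config.seed)
    abundance, library, truth = screen_sim.simulate_screen(config, rng)
    io.write_tsv(library.probes, out / "library.tsv")
    io.write_tsv(truth, out / "truth.tsv")
    io.write_tsv(abundance, out / "abundance.tsv")

    expressed = expression_analysis.detect_expression(
        truth, ana.expression_fn_rate, rng if ana.expression_fn_rate > 0 else None
    )
    io.write_gene_list(expressed, out / "expressed_genes.txt")

    log.info("stage call-hits: fold threshold %g, min shRNAs %d",
             config.fold_threshold, config.min_shrnas)
    probe_calls, gene_calls = hit_calling.call_hits(
        abundance,
        expressed,
        fold_threshold=config.fold_threshold,
        min_shrnas=config.min_shrnas,
        pseudocount=ana.pseudocount,
        require_direction=ana.require_direction,
    )
    io.write_tsv(probe_calls, out / "probe_calls.tsv")
    io.write_tsv(gene_calls, out / "gene_calls.tsv")

    candidates = sorted(gene_calls.loc[gene_calls["candidate"], "gene_id"])
    neutral_pool = sorted(
        set(gene_calls.loc[~gene_calls["candidate"], "gene_id"]) & expressed
    )
    n_neg = min(ana.n_negative_controls, len(neutral_pool))
    negatives = list(rng.choice(neutral_pool, size=n_neg, replace=False)) if n_neg else []

    log.info("stage confirm: %d candidates + %d negative controls",
             len(candidates), len(negatives))
    growth = _growth_round(candidates + negatives, truth, config, rng)
    io.write_tsv(growth, out / "growth.tsv")
    results = (
        growth_assay.analyze_growth_table(growth, ana.alpha, ana.use_welch)
        if len(growth)
        else pd.DataFrame(columns=["gene_id", "confirmed", "direction", "mechanism"])
    )
    io.write_tsv(results, out / "growth_results.tsv")
    confirmed_genes = sorted(results.loc[results["confirmed"] == True, "gene_id"])  # noqa: E712

    # induction check on the confirmed genes: planted hits act through
    # growth, not transcription, so their simulated induction fold is 1
    log.info("stage induction: %d confirmed genes + positive controls",
             len(confirmed_genes))
    ct = screen_sim.simulate_qpcr({g: 1.0 for g in confirmed_genes}, config.qpcr, rng)
    io.write_tsv(ct, out / "ct.tsv")
    induction = expression_analysis.analyze_induction(
        ct, config.qpcr.reference_gene, ana.alpha, ana.fold_min, ana.use_welch
    )
    io.write_tsv(induction, out / "induction.tsv")

    metrics = evaluate_recovery(gene_calls, truth, results)
    probe_cls = probe_calls["cls"].value_counts()
    report = {
        "config": config.to_dict(),
        "funnel": {
            "n_probes": int(len(probe_calls)),
            "probes_overrepresented": int(probe_cls.get(hit_calling.OVER, 0)),
            "probes_underrepresented": int(probe_cls.get(hit_calling.UNDER, 0)),
            "genes_grouped": int((gene_calls["group"] != hit_calling.NONE).sum()),
            "genes_candidate": len(candidates),
            "genes_assayed": len(candidates) + len(negatives),
            "genes_confirmed": len(confirmed_genes),
            "genes_induced": int(induction["induced"].sum()) if len(induction) else 0,
            "confirmed_genes_induced": int(
                induction.loc[induction["gene_id"].isin(confirmed_genes), "induced"].sum()
            ) if len(induction) else 0,
        },
        "recovery": metrics.to_dict(),
        "notes": "probe ratios are pipeline-normalized relative abundances",
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    f = report["funnel"]
    r = report["recovery"]
    lines = [
        "Pooled shRNA screen — pipeline summary",
        f"  probes measured:            {f['n_probes']}",
        f"  >5x overrepresented probes: {f['probes_overrepresented']}",
        f"  >5x underrepresented probes:{f['probes_underrepresented']}",
        f"  genes with >=min concordant shRNAs: {f['genes_grouped']}",
        f"  expressed candidate genes:  {f['genes_candidate']}",
        f"  genes confirmed by growth assay: {f['genes_confirmed']}",
        f"  confirmed genes hypoxia-induced: {f['confirmed_genes_induced']}",
        "Recovery vs planted truth:",
        f"  planted hits: {r['n_planted']}  recovered: {r['n_recovered']}",
        f"  precision: {r['precision']}  recall: {r['recall']}"
        f"  direction accuracy: {r['direction_accuracy']}",
    ]
    return "\n".join(lines) + "\n"
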
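"""Forward simulator of the pooled shRNA dropout/enrichment screen.

The simulated experiment mirrors the pooled-library design: a lentiviral
shRNA library (~4 hairpins per gene) is transduced into a cell pool, the
pool is split into a normoxic (21% O2) and a hypoxic (1% O2) arm, grown
for ten serial passages with a sampling bottleneck at each split, and the
final relative abundance of every hairpin is read out with multiplicative
measurement noise.  Knocking down a gene whose product matters for growth
in one condition changes the growth rate of every clone carrying one of
its hairpins in that arm only, so those hairpins become over- or
underrepresented in the hypoxia/normoxia comparison.

Growth law
----------
A clone carrying a probe with knockdown efficacy ``e`` against a gene with
condition effect ``s`` multiplies by ``2**(d * (1 + e*s))`` per passage,
where ``d`` is the number of doublings a neutral clone achieves.  ``s`` is
the per-passage relative growth-rate change under *full* knockdown; the
observed effect scales with achieved efficacy.  With noise and bottleneck
disabled the final hypoxia/normoxia count ratio of a probe has the closed
form ``2**(e * (s_hyp - s_norm) * d * passages)``, which the test suite
exploits.

All randomness flows from one integer seed through NumPy's splittable
``SeedSequence``; the normoxic arm is always simulated first so that a
config plus seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ConfigError, GrowthConfig, QpcrConfig, SimConfig

NORMOXIA = "normoxia"
HYPOXIA = "hypoxia"
CONDITIONS = (NORMOXIA, HYPOXIA)


class ExtinctionError(RuntimeError):
    """The whole selected population died out during a passage."""


@dataclass
class ShRNALibrary:
    """A pooled shRNA library.

    ``probes`` has one row per hairpin: ``probe_id``, ``gene_id`` and
    ``efficacy`` (the fraction of target mRNA removed, in [0, 1]).
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "efficacy"}
        if not required.issubset(self.probes.columns):
            raise ValueError(f"library probes need columns {sorted(required)}")
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in library")
        eff = self.probes["efficacy"].to_numpy()
        if ((eff < 0) | (eff > 1)).any():
            raise ValueError("efficacy must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.probes["gene_id"].unique())


@dataclass
class PopulationState:
    """Cell counts per clone (probe) in one arm at one passage."""

    condition: str
    passage_index: int
    counts: np.ndarray  # aligned with the library's probe order

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ExtinctionError(f"{self.condition} arm is extinct")
        return self.counts / total


def build_library(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ShRNALibrary, pd.DataFrame]:
    """Construct the library and the per-gene ground truth.

    Per-gene probe counts follow a shifted Poisson (1 + Poisson(mean-1),
    so every gene keeps at least one hairpin) and efficacies are uniform
    on the configured range, [0.7, 1.0] by default to match hairpins
    validated for >70% knockdown.  Hit genes from ``config.hit_spec`` are
    planted only among expressed genes carrying at least
    ``config.hit_probe_floor`` probes; every other gene is neutral, and
    non-expressed genes are neutral by definition (knocking down a gene
    that is not transcribed cannot have a phenotype).

    Returns the library plus a truth table with columns ``gene_id``,
    ``expressed``, ``s_normoxia``, ``s_hypoxia``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    counts = 1 + rng.poisson(config.probes_per_gene_mean - 1.0, size=config.n_genes)
    expressed = rng.random(config.n_genes) < config.fraction_expressed

    s_norm = np.zeros(config.n_genes)
    s_hyp = np.zeros(config.n_genes)
    n_hits = sum(b.n_genes for b in config.hit_spec)
    if n_hits:
        eligible = np.flatnonzero(expressed & (counts >= config.hit_probe_floor))
        if len(eligible) < n_hits:
            raise ConfigError(
                f"hit_spec needs {n_hits} expressed genes with >= "
                f"{config.hit_probe_floor} probes but only {len(eligible)} exist"
            )
        chosen = rng.choice(eligible, size=n_hits, replace=False)
        pos = 0
        for block in config.hit_spec:
            idx = chosen[pos : pos + block.n_genes]
            s_norm[idx] = block.s_normoxia
            s_hyp[idx] = block.s_hypoxia
            pos += block.n_genes

    gene_col = np.repeat(gene_ids, counts)
    n_probes = len(gene_col)
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in range(n_probes)],
            "gene_id": gene_col,
            "efficacy": rng.uniform(config.efficacy_low, config.efficacy_high, n_probes),
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expressed": expressed.astype(int),
            "s_normoxia": s_norm,
            "s_hypoxia": s_hyp,
        }
    )
    return ShRNALibrary(probes), truth


def _probe_effects(library: ShRNALibrary, truth: pd.DataFrame, condition: str) -> np.ndarray:
    """Per-probe growth-rate modifier efficacy * s_condition, library order."""
    col = "s_hypoxia" if condition == HYPOXIA else "s_normoxia"
    s = library.probes["gene_id"].map(truth.set_index("gene_id")[col]).to_numpy(float)
    return library.probes["efficacy"].to_numpy() * s


def step_passage(
    state: PopulationState,
    library: ShRNALibrary,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    _effects: np.ndarray | None = None,
) -> PopulationState:
    """Grow every clone for one passage, then bottleneck.

    Expected growth multiplies clone ``p`` by ``2**(d * (1 + e_p * s_p))``
    (floored at 0, so configured effects with ``1 + e*s < 0`` mean net
    death, which is allowed).  The grown pool is then resampled down to
    ``config.bottleneck`` cells by multinomial sampling; with
    ``bottleneck=None`` the expected counts are carried forward exactly
    (the infinite-population limit used by the closed-form tests).
    """
    if len(state.counts) != library.n_probes:
        raise ValueError("state is inconsistent with the library")
    es = _effects if _effects is not None else _probe_effects(library, truth, state.condition)
    grown = state.counts * np.maximum(2.0 ** (config.doublings_per_passage * (1.0 + es)), 0.0)
    total = grown.sum()
    if total <= 0:
        raise ExtinctionError(f"{state.condition} arm extinct at passage {state.passage_index + 1}")
    if config.bottleneck is None:
        new_counts = grown
    else:
        new_counts = rng.multinomial(config.bottleneck, grown / total).astype(float)
        if new_counts.sum() <= 0:
            raise ExtinctionError(
                f"{state.condition} arm extinct at passage {state.passage_index + 1}"
            )
    return PopulationState(state.condition, state.passage_index + 1, new_counts)


def run_screen(
    library: ShRNALibrary,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run both arms on a given library and measure final abundances.

    Both arms start from the same uniform clone distribution.  The final
    relative abundance ``a_p`` of each probe becomes a signal
    ``scale * a_p * exp(eps)`` with log-normal ``eps`` matched to the
    configured coefficient of variation, floored at the detection floor.
    Returns the abundance table: ``probe_id``, ``gene_id``,
    ``signal_normoxia``, ``signal_hypoxia``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = library.n_probes
    init = (config.bottleneck / n) if config.bottleneck is not None else 1.0
    sigma = float(np.sqrt(np.log1p(config.measurement_cv**2)))

    signals: dict[str, np.ndarray] = {}
    # fixed arm order (normoxia first) keeps the rng stream reproducible
    for condition in CONDITIONS:
        effects = _probe_effects(library, truth, condition)
        state = PopulationState(condition, 0, np.full(n, init, dtype=float))
        for _ in range(config.passages):
            state = step_passage(state, library, truth, config, rng, _effects=effects)
        a = state.frequencies()
        noise = np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else 1.0
        signals[condition] = np.maximum(config.signal_scale * a * noise, config.detection_floor)

    return pd.DataFrame(
        {
            "probe_id": library.probes["probe_id"].to_numpy(),
            "gene_id": library.probes["gene_id"].to_numpy(),
            "signal_normoxia": signals[NORMOXIA],
            "signal_hypoxia": signals[HYPOXIA],
        }
    )


def simulate_screen(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, ShRNALibrary, pd.DataFrame]:
    """Build a library from the config and run the two-arm screen on it."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    library, truth = build_library(config, rng)
    abundance = run_screen(library, truth, config, rng)
    return abundance, library, truth


# ---------------------------------------------------------------------------
# Confirmation-round assays
# ---------------------------------------------------------------------------

CONTROL_SHRNA = "control"  # the luciferase-targeting hairpin, no cellular target


def simulate_growth_assay(
    gene_id: str,
    s_normoxia: float,
    s_hypoxia: float,
    efficacies: tuple[float, float],
    growth: GrowthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the 7-day two-shRNA growth assay for one gene.

    Emits final cell counts for {shRNA-1, shRNA-2, Luc control} x
    {normoxia, hypoxia} x ``n_replicates``:
    ``N0 * 2**(D * (1 + e * s_c)) * exp(eta)`` with replicate noise
    ``eta`` log-normal at the configured CV.  The Luc control carries
    effect 0 in both conditions.
    """
    sigma = float(np.sqrt(np.log1p(growth.replicate_cv**2)))
    rows = []
    arms = [("1", efficacies[0]), ("2", efficacies[1]), (CONTROL_SHRNA, 0.0)]
    for shrna, eff in arms:
        for condition in CONDITIONS:
            s = s_hypoxia if condition == HYPOXIA else s_normoxia
            mean = growth.n0 * 2.0 ** (growth.doublings * (1.0 + eff * s))
            noise = (
                np.exp(rng.normal(0.0, sigma, growth.n_replicates))
                if sigma > 0
                else np.ones(growth.n_replicates)
            )
            for rep, count in enumerate(mean * noise, start=1):
                rows.append((gene_id, shrna, condition, rep, count))
    return pd.DataFrame(
        rows, columns=["gene_id", "shrna", "condition", "replicate", "cell_count"]
    )


def simulate_qpcr(
    induction_folds: dict[str, float],
    qpcr: QpcrConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a triplicate qPCR plate for the induction analysis.

    ``induction_folds`` maps gene -> hypoxia/normoxia expression fold
    (1.0 = not induced).  The reference gene (beta-actin, fold 1) and the
    HIF-1 positive controls GLUT1 (fold 7) and PDK1 (fold 4) are always
    on the plate.  A fold of ``f`` is encoded on the Ct scale as
    ``Ct_hypoxia = Ct_normoxia_mean - log2(f) + noise``.
    """
    folds = {qpcr.reference_gene: 1.0}
    folds.update(qpcr.control_folds)
    folds.update(induction_folds)
    for gene, fold in folds.items():
        if not fold > 0:
            raise ValueError(f"non-positive induction fold for {gene}: {fold}")

    rows = []
    for gene, fold in folds.items():
        if gene == qpcr.reference_gene:
            base = qpcr.reference_ct
        else:
            base = rng.uniform(qpcr.base_ct_low, qpcr.base_ct_high)
        for condition in CONDITIONS:
            mean_ct = base - (np.log2(fold) if condition == HYPOXIA else 0.0)
            noise = (
                rng.normal(0.0, qpcr.noise_sd, 3) if qpcr.noise_sd > 0 else np.zeros(3)
            )
            for rep, ct in enumerate(mean_ct + noise, start=1):
                rows.append((gene, condition, rep, ct))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "ct"])


def closed_form_ratio(
    efficacy: float | np.ndarray,
    s_normoxia: float | np.ndarray,
    s_hypoxia: float | np.ndarray,
    doublings_per_passage: float,
    passages: int,
) -> float | np.ndarray:
    """Noise-free hypoxia/normoxia count ratio of a probe after the screen."""
    return 2.0 ** (efficacy * (np.asarray(s_hypoxia) - np.asarray(s_normoxia))
                   * doublings_per_passage * passages)
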
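"""Three-stage gene-panel selection for the AI-inferred transcriptomic modality.

Stage 1 -- differential expression: a two-sided Mann-Whitney U test per gene
between HRD-High and HRD-Low samples, Benjamini-Hochberg FDR across genes,
retaining genes with q <= alpha_fdr.

Stage 2 -- prediction-fidelity filter: per-gene Pearson correlation between
predicted and true expression over the training samples, retaining genes
with r >= min_pcc (the predictor must actually be able to see the gene).

Stage 3 -- genetic-algorithm subset search: fixed-cardinality chromosomes
over the surviving candidate pool, fitness = mean stratified K-fold
cross-validated AUC of a shallow gradient-boosting classifier trained on the
subset.  The GA exists because the target signal may live in gene *inter-
actions* (predictive synergy) invisible to any marginal filter.

The selected panel is frozen on the training split and never refined on
validation or test data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .io_core import SplitManifest, StateError, TRAIN

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    gene_id: str
    statistic: float
    p_value: float
    q_value: float
    direction: int  # sign of the HRD-High minus HRD-Low location shift


@dataclass
class FidelityResult:
    gene_id: str
    pcc: float


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 20
    panel_size: int = 10
    crossover_rate: float = 0.8
    mutation_rate: float = 0.15
    tournament_k: int = 3
    elitism: int = 2
    n_immigrants: int = 4
    cv_folds: int = 3
    fitness_classifier: str = "tree"
    seed: int = 0

    def validate(self, pool_size: int) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.panel_size > pool_size:
            raise ValueError(
                f"panel_size {self.panel_size} exceeds candidate pool {pool_size}"
            )
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than population_size")


@dataclass
class GenePanel:
    gene_ids: list[str]
    de: dict[str, DEResult] = field(default_factory=dict)
    fidelity: dict[str, FidelityResult] = field(default_factory=dict)
    ga_fitness: float = float("nan")
    ga_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "ga_fitness": self.ga_fitness,
            "ga_history": self.ga_history,
            "provenance": {
                g: {
                    "q_value": self.de[g].q_value if g in self.de else None,
                    "pcc": self.fidelity[g].pcc if g in self.fidelity else None,
                }
                for g in self.gene_ids
            },
        }


# ---------------------------------------------------------------------------
# Stage 1: differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    expression: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    alpha_fdr: float = 0.05,
) -> tuple[list[DEResult], list[str]]:
    """Mann-Whitney U per gene with Benjamini-Hochberg FDR control.

    ``expression`` is samples x genes; ``labels`` is a boolean/0-1 vector
    (True = HRD-High) aligned to rows.  Constant genes get p = 1 by
    convention (no evidence either way) and are logged.
    Returns all per-gene results plus the retained gene ids (q <= alpha_fdr).
    """
    X = np.asarray(expression, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.shape[0] != y.shape[0]:
        raise ValueError("labels are not aligned to expression rows")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    hi, lo = X[y], X[~y]
    const = X.std(axis=0) <= 0
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided", axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    ustat = np.asarray(res.statistic, dtype=float)
    if const.any():
        logger.warning("%d constant gene(s); p set to 1", int(const.sum()))
        pvals[const] = 1.0
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    direction = np.sign(np.median(hi, axis=0) - np.median(lo, axis=0)).astype(int)
    results = [
        DEResult(g, float(u), float(p), float(q), int(d))
        for g, u, p, q, d in zip(gene_ids, ustat, pvals, qvals, direction)
    ]
    retained = [r.gene_id for r in results if r.q_value <= alpha_fdr]
    return results, retained


# ---------------------------------------------------------------------------
# Stage 2: prediction-fidelity filter
# ---------------------------------------------------------------------------


def fidelity_filter(
    predicted: np.ndarray,
    true: np.ndarray,
    gene_ids: list[str],
    min_pcc: float = 0.4,
) -> tuple[list[FidelityResult], list[str]]:
    """Retain genes whose predicted expression tracks the truth (r >= min_pcc).

    Genes with zero variance in either matrix have undefined correlation and
    are dropped with a warning.
    """
    P = np.asarray(predicted, dtype=float)
    T = np.asarray(true, dtype=float)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: predicted {P.shape} vs true {T.shape}")
    sd_p, sd_t = P.std(axis=0), T.std(axis=0)
    # a numerically-constant column (sd at rounding level) is undefined too
    tol_p = 1e-12 * np.maximum(1.0, np.abs(P).mean(axis=0))
    tol_t = 1e-12 * np.maximum(1.0, np.abs(T).mean(axis=0))
    defined = (sd_p > tol_p) & (sd_t > tol_t)
    if not defined.all():
        warnings.warn(
            f"{int((~defined).sum())} gene(s) with zero variance dropped "
            "(undefined correlation)",
            RuntimeWarning,
            stacklevel=2,
        )
    Pc = P - P.mean(axis=0)
    Tc = T - T.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Pc * Tc).mean(axis=0) / (sd_p * sd_t), -1.0, 1.0)
    results = [
        FidelityResult(g, float(ri))
        for g, ri, ok in zip(gene_ids, r, defined)
        if ok
    ]
    # rounding guard so r == 1 genes survive a min_pcc of exactly 1
    retained = [res.gene_id for res in results if res.pcc >= min_pcc - 1e-9]
    return results, retained


# ---------------------------------------------------------------------------
# Stage 3: genetic algorithm
# ---------------------------------------------------------------------------


def _fitness_model(name: str, seed: int):
    """Fitness classifiers must be nonlinear to reward interaction signal.

    The default is a shallow decision tree: orders of magnitude faster than
    boosting at equal ability to expose pairwise (XOR-like) synergy, which
    is what the GA's fitness needs to see.  A 50-tree shallow gradient-
    boosting fitness is available where the extra capacity is worth the cost.
    """
    if name == "tree":
        return DecisionTreeClassifier(max_depth=4, random_state=seed)
    if name == "gbm":
        return GradientBoostingClassifier(
            n_estimators=50, max_depth=2, random_state=seed
        )
    if name == "logistic":
        return LogisticRegression(max_iter=500, random_state=seed)
    raise ValueError(f"unknown fitness classifier {name!r}")


def cv_auc_fitness(
    X: np.ndarray, y: np.ndarray, config: GAConfig, seed: int
) -> float:
    """Mean stratified K-fold cross-validated AUC of the fitness classifier."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        model = _fitness_model(config.fitness_classifier, seed)
        model.fit(X[tr], y[tr])
        scores = model.predict_proba(X[te])[:, 1]
        aucs.append(roc_auc_score(y[te], scores))
    return float(np.mean(aucs))


def _repair(chrom: np.ndarray, pool_size: int, k: int, rng) -> np.ndarray:
    """Restore fixed cardinality after crossover by random add/drop."""
    genes = list(dict.fromkeys(chrom.tolist()))
    while len(genes) > k:
        genes.pop(rng.integers(len(genes)))
    if len(genes) < k:
        absent = np.setdiff1d(np.arange(pool_size), genes)
        extra = rng.choice(absent, size=k - len(genes), replace=False)
        genes.extend(extra.tolist())
    return np.sort(np.asarray(genes))


def ga_select(
    expression: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    config: GAConfig,
) -> GenePanel:
    """Search for the fixed-size gene subset with maximal predictive synergy.

    Chromosomes are gene subsets of cardinality ``panel_size``.  Tournament
    selection, uniform crossover with cardinality repair, per-gene swap
    mutation (a selected gene is swapped for a random unselected one), and
    elitism carrying the best chromosomes unchanged.  Because a synergy
    signal is invisible until all of its genes co-occur in one chromosome,
    the fitness landscape is flat away from the optimum and populations can
    collapse onto lucky noise subsets; ``n_immigrants`` fresh random
    chromosomes per generation keep a uniform-exploration floor (random-
    immigrants strategy).  Fitness values are cached per chromosome; folds
    are fixed per run so fitness is comparable across generations.  Returns
    the best-ever chromosome; the best-fitness history is non-decreasing by
    the elitism guarantee.
    """
    X = np.asarray(expression, dtype=float)
    y = np.asarray(labels).astype(int)
    pool = len(gene_ids)
    config.validate(pool)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"need >= cv_folds={config.cv_folds} samples per class, got {counts}"
        )
    rng = np.random.default_rng(config.seed)
    fold_seed = int(rng.integers(2**31))
    k = config.panel_size

    cache: dict[tuple, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = tuple(chrom.tolist())
        if key not in cache:
            cache[key] = cv_auc_fitness(X[:, chrom], y, config, fold_seed)
        return cache[key]

    if pool == k:
        chrom = np.arange(pool)
        fit = fitness(chrom)
        return GenePanel(
            gene_ids=[gene_ids[i] for i in chrom],
            ga_fitness=fit,
            ga_history=[fit],
        )

    population = [
        np.sort(rng.choice(pool, size=k, replace=False))
        for _ in range(config.population_size)
    ]
    fits = np.array([fitness(c) for c in population])
    best_idx = int(fits.argmax())
    best, best_fit = population[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    for _ in range(config.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [population[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(config.population_size, size=config.tournament_k)
                winner = contenders[np.argmax(fits[contenders])]
                parents.append(population[winner])
            if rng.random() < config.crossover_rate:
                mask = rng.random(k) < 0.5
                child = np.where(mask, parents[0], parents[1])
                child = _repair(child, pool, k, rng)
            else:
                child = parents[0].copy()
            # swap mutation: each selected gene may be exchanged for an
            # unselected one with probability mutation_rate
            for j in range(k):
                if rng.random() < config.mutation_rate:
                    absent = np.setdiff1d(np.arange(pool), child)
                    child[j] = rng.choice(absent)
                    child = np.sort(child)
            new_pop.append(child)
        n_imm = min(config.n_immigrants, config.population_size - config.elitism)
        for slot in range(1, n_imm + 1):
            new_pop[-slot] = np.sort(rng.choice(pool, size=k, replace=False))
        population = new_pop
        fits = np.array([fitness(c) for c in population])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best, best_fit = population[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    return GenePanel(
        gene_ids=[gene_ids[i] for i in best],
        ga_fitness=best_fit,
        ga_history=history,
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


class EmptySurvivorSet(RuntimeError):
    pass


def select_panel(
    true_expr: np.ndarray,
    predicted_expr: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    sample_ids: list[str],
    manifest: SplitManifest,
    alpha_fdr: float = 0.05,
    min_pcc: float = 0.4,
    ga_config: GAConfig | None = None,
) -> GenePanel:
    """Run the full DE -> fidelity -> GA pipeline on training-split data only.

    Every sample id must belong to the manifest's training split; anything
    else raises :class:`StateError` (the panel must never see validation or
    test patients).  DE and the GA run on the *predicted* expression (the
    modality actually available at inference time); the fidelity filter
    compares predicted against true expression.
    """
    train_ids = set(manifest.split(TRAIN))
    outside = [s for s in sample_ids if s not in train_ids]
    if outside:
        raise StateError(
            f"select_panel received non-training samples: {sorted(outside)[:5]}"
        )
    de_results, de_kept = differential_expression(
        predicted_expr, labels, gene_ids, alpha_fdr
    )
    if not de_kept:
        raise EmptySurvivorSet(
            f"no genes pass FDR {alpha_fdr}; consider relaxing alpha_fdr"
        )
    idx1 = [gene_ids.index(g) for g in de_kept]
    fid_results, fid_kept = fidelity_filter(
        predicted_expr[:, idx1], true_expr[:, idx1], de_kept, min_pcc
    )
    if not fid_kept:
        raise EmptySurvivorSet(
            f"no DE genes reach prediction fidelity {min_pcc}; "
            "consider relaxing min_pcc"
        )
    config = ga_config if ga_config is not None else GAConfig()
    if config.panel_size > len(fid_kept):
        config = GAConfig(**{**config.__dict__, "panel_size": len(fid_kept)})
    idx2 = [gene_ids.index(g) for g in fid_kept]
    panel = ga_select(predicted_expr[:, idx2], labels, fid_kept, config)
    panel.de = {r.gene_id: r for r in de_results if r.gene_id in panel.gene_ids}
    panel.fidelity = {r.gene_id: r for r in fid_results if r.gene_id in panel.gene_ids}
    return panel
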
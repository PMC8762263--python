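"""End-to-end drivers: training split, reference construction, scoring of
every method and evaluation — the machinery behind the CLI and the
simulation benchmark.

The workflow mirrors routine pharmacovigilance practice: an early time slice
of the report stream defines the "known association" edges on which the
network model is trained; every method is then scored on the later reports,
and evaluated on a reference set of labeled pairs that are *not* among the
known edges (the early-detection setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dpa, evaluation, icpnm as _icpnm, pnm, psadjust
from .srs_data import (DataError, ReferenceSet, ReportDatabase,
                       build_all_contingencies, POSITIVE, NEGATIVE)
from .synth import SimulationConfig, World, make_world, simulate_reports

logger = logging.getLogger(__name__)

ALL_METHODS = ("ICPNM", "IC", "EBGM", "ROR", "PRR")


def split_by_fraction(db: ReportDatabase, fraction: float):
    """Split a (chronologically ordered) database into a prefix and the rest."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    k = int(round(fraction * db.n_reports))
    return ReportDatabase(db.reports[:k]), ReportDatabase(db.reports[k:])


def extract_training_edges(train_db: ReportDatabase, min_count: int = 3,
                           min_ratio: float = 2.0) -> set:
    """"Known associations" of the training period.

    A pair is a known edge when it was reported at least ``min_count`` times
    and at ``min_ratio`` times its independence expectation — a pragmatic
    stand-in for an externally curated association list.
    """
    if train_db.n_reports == 0:
        return set()
    edges = set()
    for pair, t in build_all_contingencies(train_db).items():
        if t.c_ij >= min_count and t.c_ij >= min_ratio * t.expected:
            edges.add(pair)
    return edges


def known_associations(truth, train_db: ReportDatabase,
                       min_count: int = 2) -> set:
    """Benchmark emulation of a curated association list at training time.

    Real studies train on externally curated knowledge (drug labels,
    SIDER-like resources), not on a disproportionality screen.  In the
    synthetic world, a true pair counts as "known" once it has accrued
    ``min_count`` reports in the training prefix — knowledge follows
    observed evidence, but is never polluted by chance co-occurrences the
    way a purely statistical screen at prefix scale would be.
    """
    out = set()
    for d, a in truth.true_pairs:
        d_set = train_db.drug_index.get(d, set())
        a_set = train_db.ade_index.get(a, set())
        if len(d_set & a_set) >= min_count:
            out.add((d, a))
    return out


def build_reference_set(truth, training_edges: set,
                        max_confounded: int = 60) -> ReferenceSet:
    """Reference pairs for evaluation, disjoint from the training edges.

    Positives: true pairs not yet known (the early-detection targets).
    Negatives: the sampled clean nulls plus up to ``max_confounded``
    confounded nulls — the pairs a crude analysis is fooled by.
    """
    positives = sorted(set(truth.true_pairs) - training_edges)
    if not positives:
        raise DataError("no reference positives: every true pair is already "
                        "a training edge")
    negatives = sorted(set(truth.null_pairs) - training_edges)
    confounded = sorted(set(truth.confounded_null_pairs) - training_edges)
    negatives = negatives + confounded[:max_confounded]
    pairs = ([(d, a, POSITIVE) for d, a in positives]
             + [(d, a, NEGATIVE) for d, a in negatives])
    return ReferenceSet(pairs)


def sample_pnm_training(edges: set, candidate_drugs, ades, seed: int,
                        neg_per_pos: int = 2) -> list:
    """Training pairs for the network model: edges plus sampled non-edges.

    Negatives are drawn among drugs that appear in the training data (so the
    model is not simply taught that unseen drugs are negative).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    drugs = sorted(candidate_drugs)
    ades = sorted(ades)
    n_neg = neg_per_pos * len(edges)
    pool = [(d, a) for d in drugs for a in ades if (d, a) not in edges]
    if len(pool) <= n_neg:
        negs = pool
    else:
        idx = rng.choice(len(pool), size=n_neg, replace=False)
        negs = [pool[i] for i in sorted(idx)]
    return ([(p, True) for p in sorted(edges)] + [(p, False) for p in negs])


def fit_pnm_from_edges(edges: set, attrs, ades, seed: int = 0,
                       folds: int = 10, taxonomy_k: int = 10,
                       neg_per_pos: int = 2):
    """Build the bipartite graph, compute features and fit the network model.

    Returns (model, feature_computer) so callers can reuse the computer's
    similarity caches when featurizing candidate pairs.
    """
    graph = pnm.build_bipartite(edges)
    fc = pnm.FeatureComputer(graph, attrs, taxonomy_k=taxonomy_k)
    training = sample_pnm_training(edges, graph.drug_nodes, ades, seed,
                                   neg_per_pos=neg_per_pos)
    feats = [fc.features(d, a) for (d, a), _ in training]
    labels = [lab for _, lab in training]
    model = pnm.fit_pnm(feats, labels, folds=folds, seed=seed)
    return model, fc


def fit_pnm_time_split(train_db: ReportDatabase, attrs, seed: int = 0,
                       folds: int = 10, taxonomy_k: int = 10,
                       neg_per_pos: int = 2, edge_fn=None):
    """Fit the network model on a time split *within* the training window.

    The graph is built from the first half of the training window; labels
    are the known edges of the full window (positives) against sampled
    non-edges.  Edges that only emerge in the second half — including those
    of drugs unseen in the first half — are therefore positives whose
    featurization matches the prediction-time situation of newly marketed
    drugs, instead of every positive carrying an established-drug degree
    profile.

    Returns (model, edges_full): score candidate pairs with features on the
    full-window graph.

    ``edge_fn(db) -> set`` defines what counts as a known association in a
    window (default: the statistical screen of
    :func:`extract_training_edges`).
    """
    edge_fn = edge_fn or extract_training_edges
    early_db, _ = split_by_fraction(train_db, 0.5)
    edges_early = edge_fn(early_db)
    edges_full = edge_fn(train_db)
    if not edges_full:
        raise DataError("no known associations in the training window")
    # graph from the early half, labels from the full window: the emerged
    # edges give the model positives whose drugs are absent from the graph,
    # exactly the situation of newly marketed drugs at prediction time
    graph_edges = edges_early if edges_early else edges_full
    positives = edges_full
    graph = pnm.build_bipartite(graph_edges)
    fc = pnm.FeatureComputer(graph, attrs, taxonomy_k=taxonomy_k)
    ades = {a for _, a in edges_full}
    training = sample_pnm_training(positives, train_db.drugs, ades, seed,
                                   neg_per_pos=neg_per_pos)
    # negatives must exclude everything known by the end of the window
    training = [(p, lab) for p, lab in training
                if lab or p not in edges_full]
    feats = [fc.features(d, a) for (d, a), _ in training]
    labels = [lab for _, lab in training]
    model = pnm.fit_pnm(feats, labels, folds=folds, seed=seed)
    return model, edges_full


@dataclass
class BenchmarkResult:
    """Everything one simulated benchmark run produced."""

    reference: ReferenceSet
    scores_lower: dict = field(default_factory=dict)  # method -> {pair: bound}
    scores_point: dict = field(default_factory=dict)  # method -> {pair: point}
    score_objects: dict = field(default_factory=dict)  # method -> {pair: score}
    evaluations: dict = field(default_factory=dict)   # method -> EvaluationResult
    pnm_model: pnm.PNMModel | None = None
    n_training_edges: int = 0
    n_test_reports: int = 0


def score_reference_pairs(
    test_db: ReportDatabase,
    ref: ReferenceSet,
    attrs,
    training_edges: set,
    methods=ALL_METHODS,
    seed: int = 0,
    n_components: int | None = None,
    folds: int = 10,
    train_db: ReportDatabase | None = None,
    pa_mode: str = "unexposed",
    edge_fn=None,
) -> BenchmarkResult:
    """Score every reference pair with each requested method on the test data.

    When ``train_db`` is given, the network model is fitted with the
    within-window time split (:func:`fit_pnm_time_split`); otherwise it is
    trained directly on ``training_edges``.  ``pa_mode`` selects the offset
    convention of the adjusted marginal P(A_j).
    """
    methods = [m.upper() for m in methods]
    pairs = [(d, a) for d, a, _ in ref.pairs]
    tables = build_all_contingencies(test_db, pairs)
    result = BenchmarkResult(reference=ref,
                             n_training_edges=len(training_edges),
                             n_test_reports=test_db.n_reports)

    ebgm_prior = None
    if "EBGM" in methods:
        ebgm_prior = dpa.fit_ebgm_prior(build_all_contingencies(test_db).values())
    for m in methods:
        if m == "ICPNM":
            continue
        scored = dpa.score_all(test_db, pairs, m, ebgm_prior=ebgm_prior)
        result.score_objects[m] = scored
        result.scores_lower[m] = {p: s.lower95 for p, s in scored.items()}
        result.scores_point[m] = {p: s.point for p, s in scored.items()}

    if "ICPNM" in methods:
        if not attrs:
            raise DataError("ICPNM requires drug attributes")
        if not training_edges:
            raise DataError("ICPNM requires training-period known associations")
        if train_db is not None:
            model, _ = fit_pnm_time_split(train_db, attrs, seed=seed,
                                          folds=folds, edge_fn=edge_fn)
        else:
            ades = {a for _, a in pairs} | {a for _, a in training_edges}
            model, _ = fit_pnm_from_edges(training_edges, attrs, ades,
                                          seed=seed, folds=folds)
        result.pnm_model = model
        # candidate pairs are featurized on the full training-window graph
        fc = pnm.FeatureComputer(pnm.build_bipartite(training_edges), attrs)
        features = {p: fc.features(*p) for p in pairs}

        exposure = psadjust.build_exposure_matrix(test_db)
        pcs = psadjust.compute_pcs(exposure, n=n_components)
        ps_by_drug: dict = {}
        p_a: dict = {}
        for d, a in pairs:
            if d not in ps_by_drug:
                try:
                    ps_by_drug[d] = psadjust.fit_ps(test_db, d, pcs, exposure).ps
                except DataError as exc:
                    logger.warning("PS unavailable for drug %r: %s", d, exc)
                    ps_by_drug[d] = None
            ps = ps_by_drug[d]
            if ps is None:
                continue
            try:
                adj = psadjust.fit_ps_adjusted(test_db, d, a, ps, mode=pa_mode)
            except DataError as exc:
                logger.warning("PS-adjusted fit unavailable for (%r, %r): %s",
                               d, a, exc)
                continue
            p_a[(d, a)] = adj.p_ade_adjusted
        scores = _icpnm.score_icpnm(pairs, model, features, p_a, tables)
        result.score_objects["ICPNM"] = scores
        result.scores_lower["ICPNM"] = {p: s.lower for p, s in scores.items()}
        result.scores_point["ICPNM"] = {p: s.point for p, s in scores.items()}

    for m in methods:
        try:
            result.evaluations[m] = evaluation.youden(result.scores_lower[m],
                                                      ref, method=m)
        except DataError as exc:
            logger.warning("evaluation failed for %s: %s", m, exc)
    return result


def run_benchmark(cfg: SimulationConfig, methods=ALL_METHODS,
                  world: World | None = None) -> BenchmarkResult:
    """Simulate one world under ``cfg`` and run the full method comparison.

    Known associations are the curated-knowledge emulation of
    :func:`known_associations` (the ground truth filtered by training-prefix
    evidence), as a real study trains on curated knowledge rather than a
    statistical screen.
    """
    world = world if world is not None else make_world(cfg)
    db = simulate_reports(cfg, world)
    train_db, test_db = split_by_fraction(db, cfg.training_fraction)
    edge_fn = lambda d: known_associations(world.truth, d,
                                           cfg.known_edge_min_count)
    edges = edge_fn(train_db)
    ref = build_reference_set(world.truth, edges)
    return score_reference_pairs(test_db, ref, world.attributes, edges,
                                 methods=methods, seed=cfg.seed,
                                 train_db=train_db, edge_fn=edge_fn)


def benchmark_auc_summary(seeds, methods=ALL_METHODS, **cfg_overrides):
    """Mean AUC (and per-seed values) of each method over simulated worlds."""
    per_seed: dict = {m: [] for m in methods}
    for s in seeds:
        res = run_benchmark(SimulationConfig(seed=int(s), **cfg_overrides),
                            methods=methods)
        for m in methods:
            per_seed[m].append(res.evaluations[m].auc)
    return {m: float(np.mean(v)) for m, v in per_seed.items()}, per_seed


def confounding_bias_experiment(seed: int, n_reports: int = 50_000,
                                strength: float = 2.0, **cfg_overrides):
    """Crude vs PS-adjusted drug effect on a confounded null pair.

    A world with no true signals and co-prescription confounding at the
    given strength is simulated; the index pair is the first confounded null
    whose drug and ADE both occur.  The true log-odds effect is 0, so each
    estimate is its own bias.  Returns (crude_beta1, adjusted_beta1).
    """
    # the scenario examines a well-reported pair within a densely
    # co-prescribed therapeutic class: count-dense rates keep the systematic
    # bias well above the sampling-noise floor at this K, and the heavy
    # co-prescription is what makes the prescription profile (hence the PS)
    # informative about the confounder
    scenario = dict(baseline_ade_rates=(0.01, 0.03),
                    exposure_rates=(0.005, 0.03),
                    cluster_comed_boost=20.0)
    scenario.update(cfg_overrides)
    cfg = SimulationConfig(seed=seed, n_reports=n_reports, n_true_signals=0,
                           cluster_confounding_strength=strength, **scenario)
    world = make_world(cfg)
    db = simulate_reports(cfg, world)
    # index pair: the best-reported confounded null (a pair an analyst would
    # actually investigate); ties broken lexicographically
    candidates = []
    for d, a in world.truth.confounded_null_pairs:
        nd = len(db.drug_index.get(d, ()))
        na = len(db.ade_index.get(a, ()))
        c_ij = len(db.drug_index.get(d, set()) & db.ade_index.get(a, set()))
        if nd > 0 and 0 < na < db.n_reports and c_ij >= 5:
            candidates.append((-min(nd, na), d, a))
    if not candidates:
        raise DataError("no usable confounded null pair in this world")
    _, d, a = min(candidates)
    pair = (d, a)
    d, a = pair
    y = np.zeros(db.n_reports)
    y[list(db.ade_index[a])] = 1.0
    x = np.zeros(db.n_reports)
    x[list(db.drug_index[d])] = 1.0
    crude = psadjust._logit_fast(x[:, None], y).params[1]
    exposure = psadjust.build_exposure_matrix(db)
    pcs = psadjust.compute_pcs(exposure)
    ps = psadjust.fit_ps(db, d, pcs, exposure).ps
    adjusted = psadjust.fit_ps_adjusted(db, d, a, ps).beta1
    return float(crude), float(adjusted)


def pnm_holdout_auc(cfg: SimulationConfig, neg_per_pos: int = 2) -> float:
    """Held-out AUC of the network model alone (no report simulation).

    The world's true pairs are split three ways: half become the known-edge
    graph, a quarter are training positives (edges *not* in the graph, the
    prediction-time situation) and the remaining quarter, against the
    world's sampled nulls, form the held-out set.  This isolates how
    informative the attribute/feature families are at the configured
    ``attribute_informativeness``.
    """
    world = make_world(cfg)
    truth = world.truth
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3,)))
    true_pairs = sorted(truth.true_pairs)
    perm = rng.permutation(len(true_pairs))
    n = len(true_pairs)
    graph_idx = set(perm[: n // 2].tolist())
    train_idx = set(perm[n // 2: (3 * n) // 4].tolist())
    edges = {true_pairs[i] for i in graph_idx}
    train_pos = sorted(true_pairs[i] for i in train_idx)
    held = sorted(true_pairs[i] for i in range(n)
                  if i not in graph_idx and i not in train_idx)
    if not train_pos or not held:
        raise DataError("too few true pairs for a three-way split")

    graph = pnm.build_bipartite(edges)
    fc = pnm.FeatureComputer(graph, world.attributes)
    blocked = set(true_pairs) | set(truth.null_pairs)
    pool = [(d, a) for d in truth.drugs for a in truth.ades
            if (d, a) not in blocked]
    k = min(len(pool), neg_per_pos * len(train_pos))
    idx = rng.choice(len(pool), size=k, replace=False)
    train_neg = [pool[i] for i in sorted(idx)]
    feats = [fc.features(*p) for p in train_pos + train_neg]
    labels = [True] * len(train_pos) + [False] * len(train_neg)
    model = pnm.fit_pnm(feats, labels, folds=min(10, len(train_pos)),
                        seed=cfg.seed)
    negs = [p for p in truth.null_pairs if p not in edges]
    ref = ReferenceSet([(d, a, POSITIVE) for d, a in held]
                       + [(d, a, NEGATIVE) for d, a in negs])
    scores = {p: pnm.predict_prob(model, fc.features(*p))
              for p in held + negs}
    return evaluation.roc_auc(scores, ref)
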
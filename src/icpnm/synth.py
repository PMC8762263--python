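"""Synthetic spontaneous-report worlds with known ground truth.

The generator emulates the data-generating structure that signal detection
must exploit and correct for, with the simplest mechanism containing both:

* **True signals.**  A subset of drug-ADE pairs carries a reporting-rate
  ratio RR > 1: a report exposed to the drug mentions the ADE RR times more
  often than baseline.
* **Informative drug attributes.**  Drugs belong to similarity clusters;
  fingerprints, protein targets and taxonomy codes are noisy copies of a
  cluster prototype, and true signals are preferentially placed within
  (cluster, syndrome-ADE) combinations.  ``attribute_informativeness`` dials
  how strongly the attribute structure and the signal placement align: at 0
  attributes carry no information about the truth, at 1 they are maximally
  predictive — the lever that makes (or unmakes) the network model's prior.
* **Silent true associations.**  A fraction of the true pairs
  (``frac_silent_true``) are real associations by the reference standard but
  are *not* expressed as elevated reporting (effective RR 1 in the stream).
  Real reference sets have exactly this property — many labeled-positive
  pairs show no disproportionality in the SRS (mild, expected or
  under-reported reactions) — and it is what separates attribute-informed
  priors from purely count-based statistics.
* **Background events.**  Besides the study ADEs, reports mention background
  adverse events (the vast majority of a real dictionary's terms are outside
  any given study set).  These keep every report non-empty on the event side
  while the study ADEs retain realistic small marginal rates — the
  small-count regime in which shrinkage and priors actually matter.
* **Co-medication confounding.**  Each report draws a prescription cluster;
  drugs of that cluster are co-exposed at an elevated rate, and the
  cluster's confounder ADE is inflated by ``confounder_effect`` raised to
  ``cluster_confounding_strength`` — associating every drug of the cluster
  with that ADE without any causal link.  These pairs are recorded as
  confounded nulls, the target of the propensity-score adjustment.

Every report is guaranteed at least one drug and one ADE (failing rows are
redrawn), as real spontaneous reports contain both by construction.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from .srs_data import DataError, Report, ReportDatabase, ReferenceSet, write_reports, write_reference_set
from .pnm import DrugAttributes, write_drug_attributes


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic world (defaults = benchmark settings)."""

    n_drugs: int = 200
    n_ades: int = 20
    n_reports: int = 100_000
    seed: int = 0
    baseline_ade_rates: tuple = (0.001, 0.006)  # per-study-ADE report probability range
    n_background_ades: int = 30                # events outside the study set
    background_ade_rates: tuple = (0.05, 0.2)
    exposure_rates: tuple = (0.001, 0.01)      # per-drug report probability range
    n_true_signals: int = 200
    rr_range: tuple = (2.0, 8.0)               # reporting-rate ratios of true pairs
    frac_silent_true: float = 0.25             # true pairs not expressed in reporting rates
    n_comed_clusters: int = 10
    cluster_comed_boost: float = 5.0           # within-cluster exposure multiplier
    cluster_confounding_strength: float = 1.0
    confounder_effect: float = 2.0             # ADE multiplier per unit strength
    attribute_informativeness: float = 0.8
    fingerprint_bits: int = 128
    n_target_pool: int = 120
    targets_per_drug: int = 8
    syndrome_ades_per_cluster: int = 2
    n_null_pairs: int = 200                    # sampled clean negatives
    training_fraction: float = 0.2             # time-split prefix for "known" edges
    known_edge_min_count: int = 2              # prefix reports needed before a true pair is "known"
    frac_new_drugs: float = 0.5                # drugs entering after the training window
    new_drug_launch: tuple = (0.25, 0.7)       # launch time range (fraction of period)
    max_ade_prob: float = 0.95
    start_date: str = "2004-01-01"
    span_days: int = 2190

    def __post_init__(self):
        if min(self.n_drugs, self.n_ades, self.n_reports,
               self.n_comed_clusters) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_true_signals < 0:
            raise ValueError("n_true_signals must be >= 0")
        for lo, hi in (self.baseline_ade_rates, self.exposure_rates):
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError("rate ranges must lie in (0, 1)")
        if self.rr_range[0] <= 1.0:
            raise ValueError("rr_range lower bound must exceed 1")
        if not 0.0 <= self.attribute_informativeness <= 1.0:
            raise ValueError("attribute_informativeness must lie in [0, 1]")
        if self.cluster_confounding_strength < 0:
            raise ValueError("cluster_confounding_strength must be >= 0")
        if self.n_true_signals > self.n_drugs * self.n_ades:
            raise ValueError("n_true_signals exceeds the number of pairs")


@dataclass
class GroundTruth:
    """What the generator knows and the evaluation treats as truth."""

    true_pairs: dict                 # (drug, ade) -> RR
    null_pairs: list                 # clean sampled negatives
    confounded_null_pairs: list      # nulls inflated by cluster co-prescription
    drugs: list
    ades: list
    drug_cluster: dict               # drug -> cluster index
    cluster_confounder_ade: dict     # cluster -> its confounded ADE
    exposure_rate: dict              # drug -> baseline exposure probability
    baseline_rate: dict              # study ade -> baseline report probability
    launch_time: dict = field(default_factory=dict)  # drug -> market entry (fraction of period)
    background_rate: dict = field(default_factory=dict)  # background event -> rate
    silent_true_pairs: set = field(default_factory=set)  # true pairs with effective RR 1


class World(NamedTuple):
    attributes: dict  # drug -> DrugAttributes
    truth: GroundTruth


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def make_world(cfg: SimulationConfig) -> World:
    """Draw drugs, attributes and the ground-truth signal/confounder structure."""
    rng = _rng(cfg, 0)
    drugs = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    ades = [f"A{j:03d}" for j in range(cfg.n_ades)]
    cluster = rng.integers(0, cfg.n_comed_clusters, size=cfg.n_drugs)
    info = cfg.attribute_informativeness

    # cluster prototypes
    proto_fp = rng.random((cfg.n_comed_clusters, cfg.fingerprint_bits)) < 0.3
    target_pool = [f"T{t:03d}" for t in range(cfg.n_target_pool)]
    proto_targets = [rng.choice(cfg.n_target_pool, size=cfg.targets_per_drug,
                                replace=False) for _ in range(cfg.n_comed_clusters)]

    attrs = {}
    flip_p = 0.5 * (1.0 - info)  # at info=0, bits are independent of the prototype
    for i, d in enumerate(drugs):
        c = int(cluster[i])
        fp = proto_fp[c] ^ (rng.random(cfg.fingerprint_bits) < flip_p)
        keep = rng.random(cfg.targets_per_drug) < info
        tset = {target_pool[t] for t, k in zip(proto_targets[c], keep) if k}
        while len(tset) < cfg.targets_per_drug:
            tset.add(target_pool[int(rng.integers(cfg.n_target_pool))])
        lvl1 = c if rng.random() < info else int(rng.integers(cfg.n_comed_clusters))
        lvl2 = c if rng.random() < info else int(rng.integers(cfg.n_comed_clusters))
        code = f"{chr(65 + lvl1 % 26)}{lvl2:02d}{i % 100:02d}"
        attrs[d] = DrugAttributes(tuple(int(b) for b in fp), frozenset(tset), code)

    # syndrome ADEs per cluster; true pairs placed preferentially within them
    syndromes = [rng.choice(cfg.n_ades, size=min(cfg.syndrome_ades_per_cluster,
                                                 cfg.n_ades), replace=False)
                 for _ in range(cfg.n_comed_clusters)]
    members = {c: [i for i in range(cfg.n_drugs) if cluster[i] == c]
               for c in range(cfg.n_comed_clusters)}
    true_pairs: dict = {}
    attempts = 0
    while len(true_pairs) < cfg.n_true_signals and attempts < 100 * cfg.n_true_signals:
        attempts += 1
        if rng.random() < info:
            c = int(rng.integers(cfg.n_comed_clusters))
            if not members[c]:
                continue
            di = int(rng.choice(members[c]))
            aj = int(rng.choice(syndromes[c]))
        else:
            di = int(rng.integers(cfg.n_drugs))
            aj = int(rng.integers(cfg.n_ades))
        pair = (drugs[di], ades[aj])
        if pair not in true_pairs:
            true_pairs[pair] = float(rng.uniform(*cfg.rr_range))

    silent = {p for p in sorted(true_pairs)
              if rng.random() < cfg.frac_silent_true}

    confounder = {c: ades[int(rng.integers(cfg.n_ades))]
                  for c in range(cfg.n_comed_clusters)}
    confounded = sorted({(drugs[i], confounder[int(cluster[i])])
                         for i in range(cfg.n_drugs)} - set(true_pairs))

    blocked = set(true_pairs) | set(confounded)
    nulls: list = []
    while len(nulls) < min(cfg.n_null_pairs,
                           cfg.n_drugs * cfg.n_ades - len(blocked)):
        pair = (drugs[int(rng.integers(cfg.n_drugs))],
                ades[int(rng.integers(cfg.n_ades))])
        if pair not in blocked:
            blocked.add(pair)
            nulls.append(pair)

    # market-entry times: established drugs are present from the start, the
    # rest launch after the training window — these are the pairs a prior can
    # detect early, before report counts accrue
    is_new = rng.random(cfg.n_drugs) < cfg.frac_new_drugs
    launch = np.where(is_new, rng.uniform(*cfg.new_drug_launch,
                                          size=cfg.n_drugs), 0.0)

    truth = GroundTruth(
        true_pairs=true_pairs, null_pairs=nulls,
        confounded_null_pairs=confounded,
        drugs=drugs, ades=ades,
        drug_cluster={drugs[i]: int(cluster[i]) for i in range(cfg.n_drugs)},
        cluster_confounder_ade=confounder,
        exposure_rate={d: float(r) for d, r in
                       zip(drugs, rng.uniform(*cfg.exposure_rates, size=cfg.n_drugs))},
        baseline_rate={a: float(r) for a, r in
                       zip(ades, rng.uniform(*cfg.baseline_ade_rates, size=cfg.n_ades))},
        launch_time={d: float(t) for d, t in zip(drugs, launch)},
        background_rate={f"B{j:03d}": float(r) for j, r in enumerate(
            rng.uniform(*cfg.background_ade_rates, size=cfg.n_background_ades))},
        silent_true_pairs=silent,
    )
    return World(attrs, truth)


def simulate_reports(cfg: SimulationConfig, world: World,
                     chunk: int = 20_000) -> ReportDatabase:
    """Simulate the spontaneous-report database for a world.

    Per report: a prescription cluster is drawn; exposures are Bernoulli with
    the within-cluster rates boosted; each ADE fires with probability
    baseline * prod(RR over exposed true-signal drugs) * confounder effect,
    capped at ``max_ade_prob``.  Rows with no drug or no ADE are redrawn.
    """
    attrs, truth = world
    rng = _rng(cfg, 1)
    n_d = cfg.n_drugs
    drugs = truth.drugs
    # event columns: study ADEs first, then background events
    events = list(truth.ades) + sorted(truth.background_rate)
    n_a = len(events)
    base_exp = np.array([truth.exposure_rate[d] for d in drugs])
    log_base = np.log(np.array(
        [truth.baseline_rate[a] for a in truth.ades]
        + [truth.background_rate[b] for b in sorted(truth.background_rate)]))
    cluster_of = np.array([truth.drug_cluster[d] for d in drugs])

    log_rr = np.zeros((n_d, n_a))
    a_index = {a: j for j, a in enumerate(events)}
    d_index = {d: i for i, d in enumerate(drugs)}
    for (d, a), rr in truth.true_pairs.items():
        if (d, a) not in truth.silent_true_pairs:
            log_rr[d_index[d], a_index[a]] = np.log(rr)

    conf_log = np.zeros((cfg.n_comed_clusters, n_a))
    for c, a in truth.cluster_confounder_ade.items():
        conf_log[c, a_index[a]] += (cfg.cluster_confounding_strength
                                    * np.log(cfg.confounder_effect))

    # exposure probability by (cluster, drug): boosted within the cluster
    boost = np.ones((cfg.n_comed_clusters, n_d))
    boost[cluster_of[None, :] == np.arange(cfg.n_comed_clusters)[:, None]] = \
        cfg.cluster_comed_boost
    exp_prob = np.clip(base_exp[None, :] * boost, 0.0, 0.95)
    launch = np.array([truth.launch_time.get(d, 0.0) for d in drugs])

    start = _dt.date.fromisoformat(cfg.start_date)
    reports = []
    for lo in range(0, cfg.n_reports, chunk):
        m = min(chunk, cfg.n_reports - lo)
        t = (lo + np.arange(m)) / cfg.n_reports
        avail = t[:, None] >= launch[None, :]  # drug on the market yet?
        z = rng.integers(0, cfg.n_comed_clusters, size=m)
        probs = exp_prob[z] * avail
        X = rng.random((m, n_d)) < probs
        logp = log_base[None, :] + X @ log_rr + conf_log[z]
        A = rng.random((m, n_a)) < np.minimum(np.exp(logp), cfg.max_ade_prob)
        bad = ~(X.any(axis=1) & A.any(axis=1))
        tries = 0
        while bad.any() and tries < 100:
            idx = np.flatnonzero(bad)
            Xr = rng.random((idx.size, n_d)) < probs[idx]
            logpr = log_base[None, :] + Xr @ log_rr + conf_log[z[idx]]
            Ar = rng.random((idx.size, n_a)) < np.minimum(np.exp(logpr),
                                                          cfg.max_ade_prob)
            X[idx] = Xr
            A[idx] = Ar
            bad = ~(X.any(axis=1) & A.any(axis=1))
            tries += 1
        if bad.any():  # pathological configs only: force the most likely items
            for i in np.flatnonzero(bad):
                if not X[i].any():
                    X[i, int(np.argmax(probs[i]))] = True
                if not A[i].any():
                    A[i, int(np.argmax(log_base))] = True
        for r in range(m):
            i = lo + r
            day = int(i * cfg.span_days / cfg.n_reports)
            reports.append(Report(
                f"R{i:07d}", start + _dt.timedelta(days=day),
                frozenset(drugs[k] for k in np.flatnonzero(X[r])),
                frozenset(events[k] for k in np.flatnonzero(A[r])),
            ))
    return ReportDatabase(reports)


def emit_benchmark(cfg: SimulationConfig, world: World, db: ReportDatabase,
                   outdir) -> dict:
    """Write the benchmark files: reports, attributes, training pairs,
    reference set and a ground-truth/config manifest.

    The training pairs are the "known associations" extracted from the
    time-split prefix of the reports; reference positives are true pairs
    absent from those training edges, negatives are the sampled nulls plus
    the confounded nulls (also outside the training edges).
    """
    from pathlib import Path
    from . import pipeline

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in [
        ("reports", "reports.tsv"), ("attributes", "drug_attributes.tsv"),
        ("training_pairs", "training_pairs.tsv"),
        ("reference_set", "reference_set.tsv"), ("manifest", "manifest.json")]}

    write_reports(db, paths["reports"])
    write_drug_attributes(world.attributes, paths["attributes"])
    train_db, _ = pipeline.split_by_fraction(db, cfg.training_fraction)
    edges = pipeline.known_associations(world.truth, train_db,
                                        cfg.known_edge_min_count)
    with open(paths["training_pairs"], "w") as fh:
        fh.write("drug\tade\n")
        for d, a in sorted(edges):
            fh.write(f"{d}\t{a}\n")
    ref = pipeline.build_reference_set(world.truth, edges)
    write_reference_set(ref, paths["reference_set"])
    manifest = {
        "config": asdict(cfg),
        "true_pairs": {f"{d}|{a}": rr for (d, a), rr in
                       sorted(world.truth.true_pairs.items())},
        "confounded_null_pairs": [list(p) for p in
                                  world.truth.confounded_null_pairs],
        "null_pairs": [list(p) for p in world.truth.null_pairs],
        "n_training_edges": len(edges),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
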
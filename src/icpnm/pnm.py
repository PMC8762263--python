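"""Pharmacological network model: link features on the drug-ADE bipartite
graph and the logistic model that turns them into prior probabilities.

The training-period "known association" edges define a bipartite graph
between drugs and ADEs.  For a candidate pair (d, a) — with the edge (d, a)
itself always excluded, so features never leak the label — three families of
features are computed:

* network features: degrees and neighbor-link structure of the graph itself;
* taxonomic features: agreement between d's position in an ATC-like
  hierarchical code and the drugs already linked to a;
* intrinsic features: chemical-fingerprint Tanimoto and protein-target
  overlap between d and the drugs already linked to a.

A logistic regression on these features (fitted with backward stepwise AIC
selection and 10-fold cross-validated AUC reporting) yields
P(A_j | D_i) = sigmoid(alpha_0 + sum_s alpha_s x_s), the informative prior
consumed by the IC_PNM score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .srs_data import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# graph and attributes


class BipartiteGraph:
    """Drug-ADE bipartite graph of known (training-period) associations."""

    def __init__(self, edges: Iterable):
        self.drug_adj: dict = {}
        self.ade_adj: dict = {}
        for d, a in edges:
            self.drug_adj.setdefault(d, set()).add(a)
            self.ade_adj.setdefault(a, set()).add(d)

    @property
    def drug_nodes(self):
        return self.drug_adj.keys()

    @property
    def ade_nodes(self):
        return self.ade_adj.keys()

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.drug_adj.values())

    def has_edge(self, drug, ade) -> bool:
        return ade in self.drug_adj.get(drug, ())


def build_bipartite(training_pairs: Iterable) -> BipartiteGraph:
    pairs = list(training_pairs)
    if not pairs:
        raise DataError("no training pairs")
    return BipartiteGraph(pairs)


@dataclass(frozen=True)
class DrugAttributes:
    """Per-drug chemistry/biology: fingerprint bits, target set, taxonomy code."""

    fingerprint: tuple  # fixed-length 0/1 tuple
    targets: frozenset
    taxonomy: str

    def __post_init__(self):
        if not self.taxonomy:
            raise ValueError("taxonomy code must be non-empty")
        if any(b not in (0, 1) for b in self.fingerprint):
            raise ValueError("fingerprint must be a 0/1 vector")


def tanimoto(fp_a: Sequence, fp_b: Sequence) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| on bit vectors; 0/0 -> 0."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = int(np.sum(a | b))
    return int(np.sum(a & b)) / union if union else 0.0


def target_jaccard(t_a: frozenset, t_b: frozenset) -> float:
    """Jaccard overlap of protein-target sets; 0/0 -> 0."""
    union = len(t_a | t_b)
    return len(t_a & t_b) / union if union else 0.0


def taxonomy_shared_prefix(code_a: str, code_b: str) -> int:
    n = 0
    for x, y in zip(code_a, code_b):
        if x != y:
            break
        n += 1
    return n


def taxonomy_similarity(code_a: str, code_b: str) -> float:
    """Shared-prefix length normalized by the longer code length."""
    m = max(len(code_a), len(code_b))
    return taxonomy_shared_prefix(code_a, code_b) / m if m else 0.0


# ---------------------------------------------------------------------------
# the feature registry

FEATURE_FAMILIES = {
    "net_drug_degree": "network",
    "net_ade_degree": "network",
    "net_two_step_linked": "network",
    "net_jaccard_link_score": "network",
    "net_pref_attachment": "network",
    "net_common_ade_fraction": "network",
    "tax_knn_linked_fraction": "taxonomic",
    "tax_weighted_link_score": "taxonomic",
    "tax_shared_prefix_depth": "taxonomic",
    "tax_class_prevalence": "taxonomic",
    "chem_tanimoto_link_score": "intrinsic",
    "chem_max_tanimoto": "intrinsic",
    "target_jaccard_link_score": "intrinsic",
    "target_max_overlap": "intrinsic",
}

DEFAULT_FEATURES = tuple(FEATURE_FAMILIES)


@dataclass(frozen=True)
class FeatureVector:
    """The named link features for one candidate drug-ADE pair."""

    drug: str
    ade: str
    names: tuple
    values: np.ndarray
    missing_attributes: bool = False

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


class FeatureComputer:
    """Computes (and caches similarities for) the registered link features.

    ``taxonomy_k`` is the neighborhood size of the k-nearest-taxonomy-neighbor
    feature.  A custom registry maps feature name -> callable(self, drug, ade,
    drug_neighbors, ade_neighbors); the default registry implements the three
    families documented in the module docstring.
    """

    def __init__(self, graph: BipartiteGraph, attrs: Mapping,
                 taxonomy_k: int = 10,
                 registry: Mapping[str, Callable] | None = None):
        self.graph = graph
        self.attrs = dict(attrs)
        self.taxonomy_k = taxonomy_k
        self.registry = dict(registry) if registry is not None else {
            name: getattr(self, "_f_" + name) for name in DEFAULT_FEATURES
        }
        self._sim_cache: dict = {}
        self._knn_cache: dict = {}
        self._attr_drugs = sorted(self.attrs)

    # -- cached pairwise similarities ------------------------------------
    def _sims(self, d1, d2):
        """(tanimoto, target jaccard, tax prefix depth, tax similarity)."""
        key = (d1, d2) if d1 <= d2 else (d2, d1)
        hit = self._sim_cache.get(key)
        if hit is not None:
            return hit
        a1, a2 = self.attrs.get(d1), self.attrs.get(d2)
        if a1 is None or a2 is None:
            out = (0.0, 0.0, 0, 0.0)
        else:
            out = (tanimoto(a1.fingerprint, a2.fingerprint),
                   target_jaccard(a1.targets, a2.targets),
                   taxonomy_shared_prefix(a1.taxonomy, a2.taxonomy),
                   taxonomy_similarity(a1.taxonomy, a2.taxonomy))
        self._sim_cache[key] = out
        return out

    def _taxonomy_knn(self, drug):
        hit = self._knn_cache.get(drug)
        if hit is not None:
            return hit
        scored = [(-self._sims(drug, other)[3], other)
                  for other in self._attr_drugs if other != drug]
        scored.sort()
        out = [other for _, other in scored[: self.taxonomy_k]]
        self._knn_cache[drug] = out
        return out

    # -- network family ---------------------------------------------------
    def _f_net_drug_degree(self, d, a, nd, na):
        return float(len(nd))

    def _f_net_ade_degree(self, d, a, nd, na):
        return float(len(na))

    def _f_net_two_step_linked(self, d, a, nd, na):
        return float(sum(1 for d2 in na if self.graph.drug_adj.get(d2, set()) & nd))

    def _f_net_jaccard_link_score(self, d, a, nd, na):
        total = 0.0
        for d2 in na:
            n2 = self.graph.drug_adj.get(d2, set()) - {a}
            union = len(nd | n2)
            if union:
                total += len(nd & n2) / union
        return total

    def _f_net_pref_attachment(self, d, a, nd, na):
        return float(len(nd) * len(na))

    def _f_net_common_ade_fraction(self, d, a, nd, na):
        if not nd:
            return 0.0
        pooled = set()
        for d2 in na:
            pooled |= self.graph.drug_adj.get(d2, set())
        pooled.discard(a)
        return len(nd & pooled) / len(nd)

    # -- taxonomic family -------------------------------------------------
    def _f_tax_knn_linked_fraction(self, d, a, nd, na):
        knn = self._taxonomy_knn(d)
        return sum(1 for d2 in knn if d2 in na) / len(knn) if knn else 0.0

    def _f_tax_weighted_link_score(self, d, a, nd, na):
        return (sum(self._sims(d, d2)[3] for d2 in na) / len(na)) if na else 0.0

    def _f_tax_shared_prefix_depth(self, d, a, nd, na):
        return (sum(self._sims(d, d2)[2] for d2 in na) / len(na)) if na else 0.0

    def _f_tax_class_prevalence(self, d, a, nd, na):
        me = self.attrs.get(d)
        if me is None:
            return 0.0
        same = [d2 for d2 in self._attr_drugs
                if d2 != d and self.attrs[d2].taxonomy[0] == me.taxonomy[0]]
        return sum(1 for d2 in same if d2 in na) / len(same) if same else 0.0

    # -- intrinsic family -------------------------------------------------
    def _f_chem_tanimoto_link_score(self, d, a, nd, na):
        return (sum(self._sims(d, d2)[0] for d2 in na) / len(na)) if na else 0.0

    def _f_chem_max_tanimoto(self, d, a, nd, na):
        return max((self._sims(d, d2)[0] for d2 in na), default=0.0)

    def _f_target_jaccard_link_score(self, d, a, nd, na):
        return (sum(self._sims(d, d2)[1] for d2 in na) / len(na)) if na else 0.0

    def _f_target_max_overlap(self, d, a, nd, na):
        return max((self._sims(d, d2)[1] for d2 in na), default=0.0)

    # ----------------------------------------------------------------------
    def features(self, drug, ade) -> FeatureVector:
        """Feature vector for (drug, ade); the edge (drug, ade) is excluded."""
        nd = self.graph.drug_adj.get(drug, set()) - {ade}
        # sorted so similarity sums have a deterministic accumulation order
        na = sorted(self.graph.ade_adj.get(ade, set()) - {drug})
        missing = drug not in self.attrs
        if missing:
            logger.warning("drug %r lacks attributes; taxonomic/intrinsic "
                           "features set to 0", drug)
        names = tuple(self.registry)
        values = np.array([self.registry[n](drug, ade, nd, na) for n in names],
                          dtype=float)
        if not np.all(np.isfinite(values)):
            raise DataError(f"non-finite feature for pair ({drug}, {ade})")
        return FeatureVector(drug, ade, names, values, missing)


def compute_features(graph: BipartiteGraph, attrs: Mapping, drug, ade,
                     taxonomy_k: int = 10) -> FeatureVector:
    """One-shot form of :meth:`FeatureComputer.features` (no cache reuse)."""
    return FeatureComputer(graph, attrs, taxonomy_k=taxonomy_k).features(drug, ade)


# ---------------------------------------------------------------------------
# the logistic model


@dataclass
class LogitFit:
    params: np.ndarray  # intercept first
    bse: np.ndarray
    llf: float
    ridge_used: bool


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LogitFit:
    """ML logistic fit with a small-ridge fallback under perfect separation."""
    import warnings as _warnings

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, method="newton", maxiter=200)
        if (res.mle_retvals.get("converged", True)
                and np.all(np.isfinite(res.params))
                and np.all(np.isfinite(res.bse))):
            return LogitFit(np.asarray(res.params), np.asarray(res.bse),
                            float(res.llf), False)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        pass
    logger.debug("logistic fit unstable (separation?); refitting with "
                 "ridge penalty %g", ridge)

    def nll(beta):
        z = Xc @ beta
        return float(np.sum(np.logaddexp(0.0, z) - y * z) + ridge * beta @ beta)

    def grad(beta):
        z = Xc @ beta
        return Xc.T @ (special.expit(z) - y) + 2.0 * ridge * beta

    res = optimize.minimize(nll, np.zeros(Xc.shape[1]), jac=grad, method="L-BFGS-B")
    beta = res.x
    p = special.expit(Xc @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    hess = Xc.T @ (Xc * w[:, None]) + 2.0 * ridge * np.eye(Xc.shape[1])
    cov = np.linalg.inv(hess)
    llf = -float(np.sum(np.logaddexp(0.0, Xc @ beta) - y * (Xc @ beta)))
    return LogitFit(beta, np.sqrt(np.diag(cov)), llf, True)


@dataclass
class PNMModel:
    """Fitted network-model logistic regression producing P(A_j | D_i)."""

    intercept: float
    coefficients: dict  # feature name -> weight, selected features only
    selected_features: tuple
    aic: float
    cv_auc: float
    n_train: int
    seed: int = 0
    bse: dict = field(default_factory=dict)  # name (or "intercept") -> SE
    ridge_used: bool = False

    def linear_predictor(self, fv: FeatureVector) -> float:
        d = fv.as_dict()
        missing = [n for n in self.selected_features if n not in d]
        if missing:
            raise DataError(f"feature vector missing {missing[0]!r}")
        return self.intercept + sum(self.coefficients[n] * d[n]
                                    for n in self.selected_features)

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept, "coefficients": self.coefficients,
            "selected_features": list(self.selected_features), "aic": self.aic,
            "cv_auc": self.cv_auc, "n_train": self.n_train, "seed": self.seed,
            "bse": self.bse, "ridge_used": self.ridge_used}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PNMModel":
        d = json.loads(text)
        d["selected_features"] = tuple(d["selected_features"])
        return cls(**d)


def _aic(llf: float, k: int) -> float:
    return 2.0 * k - 2.0 * llf


def fit_pnm(features: Sequence[FeatureVector], labels: Sequence,
            folds: int = 10, seed: int = 0, stepwise: bool = True,
            ridge: float = 1e-6) -> PNMModel:
    """Fit the logistic network model with AIC selection and CV reporting.

    Backward stepwise selection starts from all registered features and
    repeatedly drops the feature whose removal lowers the AIC most, stopping
    when no removal helps (``stepwise=False`` keeps all features).  The
    reported ``cv_auc`` is the mean out-of-fold AUC of a label-stratified
    ``folds``-fold split seeded by ``seed``; final coefficients are refit on
    all data for the selected subset.
    """
    y = np.asarray(labels, dtype=float)
    if len(features) != len(y):
        raise ValueError("features and labels length mismatch")
    if y.min() == y.max():
        raise DataError("training labels must include both classes")
    names = list(features[0].names)
    X_full = np.vstack([fv.values for fv in features])

    def fit_subset(idx, Xs=None, ys=None):
        Xs = X_full if Xs is None else Xs
        ys = y if ys is None else ys
        return _fit_logit(Xs[:, idx], ys, ridge=ridge)

    selected = list(range(len(names)))
    fit = fit_subset(selected)
    best_aic = _aic(fit.llf, len(selected) + 1)
    if stepwise:
        while len(selected) > 1:
            trials = []
            for j in selected:
                sub = [k for k in selected if k != j]
                f = fit_subset(sub)
                trials.append((_aic(f.llf, len(sub) + 1), j, f))
            trials.sort(key=lambda t: (t[0], t[1]))
            if trials[0][0] < best_aic:
                best_aic, drop, fit = trials[0][0], trials[0][1], trials[0][2]
                selected.remove(drop)
            else:
                break

    # out-of-fold AUC on the selected subset
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X_full, y):
        if y[te].min() == y[te].max() or y[tr].min() == y[tr].max():
            continue
        f = fit_subset(selected, X_full[tr], y[tr])
        p = special.expit(sm.add_constant(X_full[te][:, selected],
                                          has_constant="add") @ f.params)
        aucs.append(roc_auc_score(y[te], p))
    cv_auc = float(np.mean(aucs)) if aucs else float("nan")

    sel_names = tuple(names[j] for j in selected)
    if fit.ridge_used:
        logger.warning("fit_pnm: separation detected, coefficients are "
                       "ridge-regularized (penalty %g)", ridge)
    coeffs = dict(zip(sel_names, map(float, fit.params[1:])))
    bse = {"intercept": float(fit.bse[0])}
    bse.update(dict(zip(sel_names, map(float, fit.bse[1:]))))
    return PNMModel(intercept=float(fit.params[0]), coefficients=coeffs,
                    selected_features=sel_names, aic=float(best_aic),
                    cv_auc=cv_auc, n_train=len(y), seed=seed, bse=bse,
                    ridge_used=fit.ridge_used)


def predict_prob(model: PNMModel, fv: FeatureVector) -> float:
    """P(A_j | D_i) = sigmoid(alpha_0 + sum alpha_s x_s), clipped into (0, 1)."""
    p = float(special.expit(model.linear_predictor(fv)))
    return min(max(p, 1e-15), 1.0 - 1e-15)


# ---------------------------------------------------------------------------
# attribute-table I/O (delimited text; fingerprint as a 0/1 string)


def read_drug_attributes(path, delimiter: str = "\t",
                         cell_separator: str = "|") -> dict:
    """Read a drug-attribute table into {drug: DrugAttributes}."""
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("drug", "fingerprint", "targets", "taxonomy"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        fp = tuple(int(ch) for ch in row.fingerprint)
        targets = frozenset(t for t in row.targets.split(cell_separator) if t)
        out[str(row.drug)] = DrugAttributes(fp, targets, str(row.taxonomy))
    return out


def write_drug_attributes(attrs: Mapping, path, delimiter: str = "\t",
                          cell_separator: str = "|") -> None:
    import pandas as pd

    rows = [
        {"drug": d,
         "fingerprint": "".join(str(b) for b in a.fingerprint),
         "targets": cell_separator.join(sorted(a.targets)),
         "taxonomy": a.taxonomy}
        for d, a in sorted(attrs.items())
    ]
    pd.DataFrame(rows, columns=["drug", "fingerprint", "targets", "taxonomy"]) \
        .to_csv(path, sep=delimiter, index=False)
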
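"""Bipartite drug–ADE link-prediction model (PPN-style logistic regression).

The presence/absence of a drug–HLT association Y_ij is modeled as Bernoulli
with logit linear in twelve covariates drawn from three families:

* **network** covariates depend only on the bipartite network structure
  (degrees and a Jaccard-weighted common-neighbor fraction);
* **taxonomic** covariates combine the network with ATC and MedDRA codes
  (category-restricted link fractions);
* **intrinsic** covariates combine the network with per-drug property
  vectors (similarity-weighted link fraction, standardized properties,
  degree×similarity interaction).

All covariates are total (explicit zero conventions for isolated nodes) and
z-standardized over the training pair set; the standardization constants are
frozen at training time and reused when scoring held-out pairs, so validation
pairs never leak into the feature scaling. Fitting is penalized maximum
likelihood via Newton's method with step-halving; a small ridge on the
non-intercept terms (default 1e-6) stabilizes near-separable networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (ConfigError, ConvergenceError, DegenerateInputError,
                     SchemaError)
from .vocab import AssociationSnapshot, AtcMap, MeddraMap

COVARIATE_NAMES: tuple[str, ...] = (
    "net_log_drug_degree",        # log(1 + deg(i))
    "net_log_term_degree",        # log(1 + deg(j))
    "net_log_degree_product",     # log(1 + deg(i)·deg(j))
    "net_jaccard_neighbor_frac",  # Jaccard-weighted fraction of j-linked drugs
    "tax_atc_top_link_frac",      # frac of same-ATC-top drugs linked to j
    "tax_atc_code_link_frac",     # frac of same-primary-ATC-code drugs linked to j
    "tax_soc_term_link_frac",     # frac of j's SOC siblings linked to i
    "tax_soc_degree_frac",        # frac of i's links falling in j's SOC
    "int_cosine_neighbor_frac",   # cosine-similarity-weighted fraction
    "int_property_1",             # standardized first drug property
    "int_property_2",             # standardized second drug property
    "int_degree_similarity",      # interaction: log-degree × cosine fraction
)


@dataclass(frozen=True)
class BipartiteNetwork:
    """Drugs × terms 0/1 adjacency built from an HLT-level snapshot."""

    drugs: tuple[str, ...]
    terms: tuple[str, ...]
    adjacency: np.ndarray  # shape (n_drugs, n_terms), dtype float64 in {0,1}

    @property
    def drug_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drugs)}

    @property
    def term_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    def degree_drug(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def degree_term(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)


def build_network(s: AssociationSnapshot, drugs: Sequence[str],
                  terms: Sequence[str]) -> BipartiteNetwork:
    """Adjacency A_ij = 1 iff (drug_i, term_j) ∈ s; isolated nodes retained."""
    drugs = tuple(drugs)
    terms = tuple(terms)
    di = {d: i for i, d in enumerate(drugs)}
    ti = {t: j for j, t in enumerate(terms)}
    A = np.zeros((len(drugs), len(terms)))
    for d, t in s.pairs:
        if d not in di or t not in ti:
            raise ConfigError(f"pair ({d!r}, {t!r}) outside declared vocabularies")
        A[di[d], ti[t]] = 1.0
    return BipartiteNetwork(drugs, terms, A)


@dataclass(frozen=True)
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass(frozen=True)
class CovariateMatrix:
    pairs: tuple[tuple[str, str], ...]
    columns: tuple[str, ...]
    values: np.ndarray  # standardized, shape (n_pairs, n_columns); no intercept column
    standardizer: Standardizer

    def with_intercept(self) -> np.ndarray:
        return np.hstack([np.ones((len(self.values), 1)), self.values])


def _raw_covariates(net: BipartiteNetwork, atc: AtcMap, meddra: MeddraMap,
                    props: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Raw (unstandardized) covariates for every (drug, term) cell.

    Returns an array of shape (n_drugs, n_terms, 12). Vectorized over the full
    grid; pair subsets are sliced out afterwards.
    """
    A = net.adjacency
    n_d, n_t = A.shape
    deg_d = A.sum(axis=1)
    deg_t = A.sum(axis=0)

    P = np.asarray([props[d] for d in net.drugs], dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ConfigError("drug property vectors must have dimension >= 2")

    out = np.empty((n_d, n_t, 12))

    n1 = np.log1p(deg_d)                                   # per drug
    n2 = np.log1p(deg_t)                                   # per term
    out[:, :, 0] = n1[:, None]
    out[:, :, 1] = n2[None, :]
    out[:, :, 2] = np.log1p(np.outer(deg_d, deg_t))

    # Jaccard similarity between drug neighborhoods
    inter = A @ A.T
    union = deg_d[:, None] + deg_d[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(J, 0.0)  # sums exclude k = i
    out[:, :, 3] = (J @ A) / np.maximum(1.0, J.sum(axis=1))[:, None]

    # taxonomic: same-ATC-top-level and same-primary-code drug fractions
    for col, key in ((4, [atc.top_level(atc.primary_code(d)) for d in net.drugs]),
                     (5, [atc.primary_code(d) for d in net.drugs])):
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(key):
            groups.setdefault(g, []).append(i)
        frac = np.zeros((n_d, n_t))
        for members in groups.values():
            idx = np.asarray(members)
            size = len(idx) - 1
            if size <= 0:
                continue
            group_links = A[idx].sum(axis=0)  # per term
            frac[idx] = (group_links[None, :] - A[idx]) / size
        out[:, :, col] = frac

    # taxonomic: term-side SOC fractions
    soc_of = [meddra.primary_soc(t) for t in net.terms]
    soc_groups: dict[str, list[int]] = {}
    for j, s in enumerate(soc_of):
        soc_groups.setdefault(s, []).append(j)
    t3 = np.zeros((n_d, n_t))
    for members in soc_groups.values():
        idx = np.asarray(members)
        size = len(idx) - 1
        if size <= 0:
            continue
        soc_links = A[:, idx].sum(axis=1)  # per drug
        t3[:, idx] = (soc_links[:, None] - A[:, idx]) / size
    out[:, :, 6] = t3

    soc_indicator = np.zeros((n_t, len(soc_groups)))
    soc_order = {s: k for k, s in enumerate(soc_groups)}
    for j, s in enumerate(soc_of):
        soc_indicator[j, soc_order[s]] = 1.0
    links_per_soc = A @ soc_indicator  # (n_d, n_socs)
    with np.errstate(invalid="ignore", divide="ignore"):
        t4_by_soc = np.where(deg_d[:, None] > 0,
                             links_per_soc / np.maximum(deg_d, 1e-300)[:, None], 0.0)
    soc_idx = np.asarray([soc_order[s] for s in soc_of])
    out[:, :, 7] = t4_by_soc[:, soc_idx]

    # intrinsic: cosine-similarity-weighted neighbor fraction
    norms = np.linalg.norm(P, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Pn = np.where(norms[:, None] > 0, P / np.maximum(norms, 1e-300)[:, None], 0.0)
    C = np.clip(Pn @ Pn.T, 0.0, 1.0)
    np.fill_diagonal(C, 0.0)
    p1 = (C @ A) / np.maximum(1.0, C.sum(axis=1))[:, None]
    out[:, :, 8] = p1

    for col, k in ((9, 0), (10, 1)):
        v = P[:, k]
        sd = v.std()
        z = (v - v.mean()) / (sd if sd > 0 else 1.0)
        out[:, :, col] = z[:, None]

    out[:, :, 11] = n1[:, None] * p1
    return out


def compute_covariates(net: BipartiteNetwork, atc: AtcMap, meddra: MeddraMap,
                       props: Mapping[str, Sequence[float]],
                       pairs: Sequence[tuple[str, str]],
                       standardizer: Standardizer | None = None) -> CovariateMatrix:
    """The twelve-covariate matrix for ``pairs``, computed from ``net``.

    When ``standardizer`` is None, z-standardization constants are fitted on
    these pairs (training); pass the training standardizer when scoring so
    held-out pairs use the frozen scaling. Constant columns get unit SD so
    standardization never divides by zero.
    """
    grid = _raw_covariates(net, atc, meddra, props)
    di, ti = net.drug_index, net.term_index
    rows = np.asarray([(di[d], ti[t]) for d, t in pairs])
    X = grid[rows[:, 0], rows[:, 1], :] if len(rows) else np.empty((0, 12))
    if standardizer is None:
        mean = X.mean(axis=0) if len(X) else np.zeros(12)
        sd = X.std(axis=0) if len(X) else np.ones(12)
        sd = np.where(sd > 0, sd, 1.0)
        standardizer = Standardizer(mean, sd)
    return CovariateMatrix(tuple(pairs), COVARIATE_NAMES,
                           standardizer.apply(X), standardizer)


@dataclass(frozen=True)
class FitResult:
    beta_hat: np.ndarray          # intercept + 12 coefficients
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    columns: tuple[str, ...]
    standardizer: Standardizer = field(repr=False, default=None)

    def z_scores(self) -> np.ndarray:
        return self.beta_hat / self.se


def sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _penalized_loglik(beta: np.ndarray, Xi: np.ndarray, y: np.ndarray,
                      ridge: float) -> float:
    eta = Xi @ beta
    # log-likelihood via logaddexp for numerical safety
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll - ridge * float(beta[1:] @ beta[1:])


def fit_logistic(X: CovariateMatrix, y: np.ndarray, *, tol: float = 1e-6,
                 max_iter: int = 100, ridge: float = 1e-6) -> FitResult:
    """Penalized-ML logistic fit by Newton's method with step-halving.

    Convergence is declared when the max absolute gradient of the penalized
    log-likelihood falls below ``tol``. Standard errors come from the inverse
    observed information at the optimum. Complete separation at ridge=0 shows
    up as non-convergence and raises with advice to set ridge > 0.
    """
    y = np.asarray(y, dtype=float)
    Xi = X.with_intercept()
    if len(y) != len(Xi):
        raise SchemaError("label length does not match covariate rows")
    if y.min() == y.max():
        raise DegenerateInputError("labels are all one class; cannot fit")
    p = Xi.shape[1]
    beta = np.zeros(p)
    pen = np.full(p, 2.0 * ridge)
    pen[0] = 0.0
    ll = _penalized_loglik(beta, Xi, y, ridge)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = sigmoid(Xi @ beta)
        grad = Xi.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (Xi * w[:, None]).T @ Xi + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # rank-deficient design (e.g. constant columns): minimum-norm step
            step = np.linalg.pinv(H) @ grad
        # step-halving keeps the penalized log-likelihood monotone
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = _penalized_loglik(cand, Xi, y, ridge)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            t /= 2.0
        else:
            break
    else:
        mu = sigmoid(Xi @ beta)
        grad = Xi.T @ (y - mu) - pen * beta
        converged = bool(np.max(np.abs(grad)) < tol)
    if not converged:
        raise ConvergenceError(
            "logistic fit did not converge (possible complete separation); "
            "increase max_iter or set ridge > 0")
    if ridge == 0.0:
        # unpenalized MLE does not exist under complete separation: the
        # iteration stalls at a perfectly-classifying, saturated solution
        eta = Xi @ beta
        if np.all((2 * y - 1) * eta > 0) and np.max(np.abs(eta)) > 10:
            raise ConvergenceError(
                "complete separation: unpenalized MLE diverges; set ridge > 0")
    mu = sigmoid(Xi @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (Xi * w[:, None]).T @ Xi + np.diag(pen)
    se = np.sqrt(np.abs(np.diag(np.linalg.pinv(info))))
    return FitResult(beta_hat=beta, se=se, loglik=ll, converged=True,
                     n_iter=n_iter, columns=("intercept",) + tuple(X.columns),
                     standardizer=X.standardizer)


def training_labels(net: BipartiteNetwork,
                    pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """y_ij = A_ij for an ordered pair list."""
    di, ti = net.drug_index, net.term_index
    return np.asarray([net.adjacency[di[d], ti[t]] for d, t in pairs])


def all_pairs(net: BipartiteNetwork) -> list[tuple[str, str]]:
    """Every drug×term pair, row-major in vocabulary order."""
    return [(d, t) for d in net.drugs for t in net.terms]


def score_pairs(fit: FitResult, X_new: CovariateMatrix) -> dict[tuple[str, str], float]:
    """Predicted probability sigmoid(beta_hat·x) for each pair in X_new."""
    if ("intercept",) + tuple(X_new.columns) != tuple(fit.columns):
        raise SchemaError("covariate columns do not match fitted model")
    probs = sigmoid(X_new.with_intercept() @ fit.beta_hat)
    return dict(zip(X_new.pairs, probs.tolist()))
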
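"""Marginal maximum likelihood (MML) estimation of the Rasch model by EM.

The marginal likelihood integrates the person ability out against a normal
latent distribution,

    L = prod_n  int  prod_i P(X_ni | beta, delta_i)  dPhi(beta; mu, sigma^2),

approximated by quadrature (rescaled Gauss-Hermite nodes by default, or a
low-discrepancy quasi-Monte-Carlo node set for the concurrent estimator).
Estimation follows the classic Bock-Aitkin EM scheme: the E-step computes
posterior node weights per person (which, for the Rasch model, depend on the
data only through the raw sum score, so persons are collapsed into score
groups), and the M-step solves each item's expected-count equation by Newton
iteration and updates the latent normal from posterior moments.

Three calibration modes are supported:

``free``
    one form; latent mean fixed at 0 for identification, variance estimated,
    all difficulties free.
``fixed_anchor``
    one form; a given set of items is held at supplied difficulty values
    (fixed parameter calibration) while the latent mean *and* variance are
    estimated together with the remaining difficulties.
``concurrent``
    several forms fitted jointly, anchor difficulties shared across forms via
    common item ids, one latent normal per form with the first form's mean
    fixed at 0.

Non-convergence is a recorded outcome (``converged=False``), never an
exception, because convergence rates are themselves a quantity of interest in
linking studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp, ndtri, roots_hermitenorm
from scipy.stats import qmc

from .simulate import ConfigurationError, ResponseMatrix

_SOFTPLUS_CAP = 45.0  # log(1+e^x) ~ x beyond this; avoids overflow


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.where(x > _SOFTPLUS_CAP, x, np.log1p(np.exp(np.minimum(x, _SOFTPLUS_CAP))))


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

def build_quadrature(
    kind: str,
    n_nodes: int,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and normalized weights approximating N(mu, sigma^2).

    ``kind='gauss_hermite'`` rescales probabilists' Gauss-Hermite nodes to the
    current latent normal; ``kind='quasi_monte_carlo'`` maps an unscrambled
    Halton sequence through the normal inverse CDF and uses equal weights
    (the first Halton point, u=0, is dropped).
    """
    if n_nodes < 2:
        raise ConfigurationError("quadrature needs at least 2 nodes")
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    if kind == "gauss_hermite":
        z, w = roots_hermitenorm(n_nodes)
        weights = w / w.sum()
        return mu + sigma * z, weights
    if kind == "quasi_monte_carlo":
        u = qmc.Halton(d=1, scramble=False, seed=seed).random(n_nodes + 1).ravel()[1:]
        z = ndtri(u)
        return mu + sigma * z, np.full(n_nodes, 1.0 / n_nodes)
    raise ConfigurationError(f"unknown quadrature kind: {kind!r}")


def _standard_nodes(kind: str, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal base nodes z and weights, rescaled per iteration."""
    return build_quadrature(kind, n_nodes, mu=0.0, sigma=1.0)


# ---------------------------------------------------------------------------
# specifications and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSpec:
    """Settings for one MML calibration."""

    mode: str = "free"  # free | fixed_anchor | concurrent
    fixed_items: dict[str, float] = field(default_factory=dict)
    quadrature: str | None = None  # default: GH separate, QMC concurrent
    n_nodes: int | None = None  # default: 41 GH / 1000 QMC
    max_iter: int = 1000
    tol: float = 1e-4  # max absolute parameter change
    loglik_tol: float = 1e-6  # relative log-likelihood change

    def __post_init__(self):
        if self.mode not in ("free", "fixed_anchor", "concurrent"):
            raise ConfigurationError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "fixed_anchor" and not self.fixed_items:
            raise ConfigurationError("fixed_anchor mode requires fixed_items")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")

    @property
    def quadrature_kind(self) -> str:
        if self.quadrature is not None:
            return self.quadrature
        return "quasi_monte_carlo" if self.mode == "concurrent" else "gauss_hermite"

    @property
    def quadrature_nodes(self) -> int:
        if self.n_nodes is not None:
            return self.n_nodes
        return 1000 if self.mode == "concurrent" else 41


@dataclass
class CalibrationResult:
    """Estimates from one calibration (single-form or concurrent)."""

    difficulties: dict[str, float]
    se: dict[str, float]
    fixed: frozenset[str]
    mu: float | None
    sigma2: float | None
    loglik: float
    n_iter: int
    converged: bool
    mode: str = "free"
    mu_by_form: dict[int, float] | None = None
    sigma2_by_form: dict[int, float] | None = None
    excluded: tuple[str, ...] = ()
    loglik_path: tuple[float, ...] = ()

    def item_table(self) -> pd.DataFrame:
        ids = sorted(self.difficulties)
        return pd.DataFrame(
            {
                "global_id": ids,
                "delta_hat": [self.difficulties[i] for i in ids],
                "se": [self.se.get(i, np.nan) for i in ids],
                "fixed": [i in self.fixed for i in ids],
            }
        )

    def scalar_table(self) -> pd.DataFrame:
        if self.mu_by_form is not None:
            forms = sorted(self.mu_by_form)
            return pd.DataFrame(
                {
                    "form": forms,
                    "mu_hat": [self.mu_by_form[t] for t in forms],
                    "sigma2_hat": [self.sigma2_by_form[t] for t in forms],
                    "loglik": self.loglik,
                    "n_iter": self.n_iter,
                    "converged": self.converged,
                }
            )
        return pd.DataFrame(
            {
                "form": [pd.NA],
                "mu_hat": [self.mu],
                "sigma2_hat": [self.sigma2],
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "difficulties": self.difficulties,
            "se": self.se,
            "fixed": sorted(self.fixed),
            "mu": self.mu,
            "sigma2": self.sigma2,
            "mu_by_form": self.mu_by_form,
            "sigma2_by_form": self.sigma2_by_form,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "excluded": list(self.excluded),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# sufficient statistics (score-group collapse)
# ---------------------------------------------------------------------------

class _FormStats:
    """Score-group sufficient statistics of one response matrix.

    Under any Rasch-model fit, the posterior over quadrature nodes depends on
    the data only through the raw sum score r, so the E-step runs over the
    I+1 score groups instead of N persons.
    """

    def __init__(self, data: np.ndarray):
        self.n_persons, self.n_items = data.shape
        r = data.sum(axis=1)
        self.scores = r
        self.n_r = np.bincount(r, minlength=self.n_items + 1).astype(float)
        # S[i, r] = number of correct responses to item i among persons w/ score r
        S = np.zeros((self.n_items, self.n_items + 1))
        np.add.at(S.T, r, data.astype(float))
        self.S = S
        self.totals = data.sum(axis=0).astype(float)
        self.data = data


def _loglik_matrix(delta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """A[r, q] = r*theta_q - sum_i softplus(theta_q - delta_i)."""
    sp = _softplus(theta[:, None] - delta[None, :]).sum(axis=1)  # (Q,)
    r = np.arange(delta.size + 1, dtype=float)
    return r[:, None] * theta[None, :] - sp[None, :]


def _posterior(stats: _FormStats, delta, theta, logw):
    """Posterior node weights per score group, and the marginal log-likelihood."""
    A = _loglik_matrix(delta, theta) + logw[None, :]
    norm = logsumexp(A, axis=1)
    post = np.exp(A - norm[:, None])
    ll = float(stats.n_r @ norm - delta @ stats.totals)
    return post, ll


def _newton_item_solve(delta, target, f_by_node, theta, max_inner=60, tol=1e-11):
    """Solve sum_q f_q * logistic(theta_q - delta_i) = target_i per item.

    The expected-count equation of the M-step; monotone in delta so plain
    Newton converges in a handful of steps.
    """
    delta = delta.copy()
    for _ in range(max_inner):
        P = expit(theta[None, :] - delta[:, None])  # (I, Q)
        g = P @ f_by_node - target
        h = (P * (1.0 - P)) @ f_by_node
        step = g / np.maximum(h, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        delta += step
        if np.max(np.abs(step)) < tol:
            break
    return delta


# ---------------------------------------------------------------------------
# public likelihood evaluation (also the surface for brute-force checks)
# ---------------------------------------------------------------------------

def marginal_loglik(
    responses: ResponseMatrix,
    difficulties,
    mu: float = 0.0,
    sigma2: float = 1.0,
    quadrature: str = "gauss_hermite",
    n_nodes: int = 41,
) -> float:
    """Quadrature-approximated marginal Rasch log-likelihood of one form.

    ``difficulties`` is a mapping global_id -> delta or an array aligned with
    ``responses.items``.  This is the exact objective the EM fit maximizes,
    exposed so it can be optimized or audited by generic numerical tools.
    """
    if isinstance(difficulties, dict):
        delta = np.array([difficulties[i] for i in responses.items], dtype=float)
    else:
        delta = np.asarray(difficulties, dtype=float)
    stats = _FormStats(responses.data)
    theta, w = build_quadrature(quadrature, n_nodes, mu=mu, sigma=float(np.sqrt(sigma2)))
    _, ll = _posterior(stats, delta, theta, np.log(w))
    return ll


# ---------------------------------------------------------------------------
# single-form fit (free / fixed-anchor)
# ---------------------------------------------------------------------------

def _screen_items(responses: ResponseMatrix):
    """Drop zero-variance items (all 0s or all 1s) with a warning."""
    totals = responses.data.sum(axis=0)
    n = responses.data.shape[0]
    bad = (totals == 0) | (totals == n)
    if not bad.any():
        return responses, ()
    excluded = tuple(np.array(responses.items)[bad])
    warnings.warn(
        f"excluding zero-variance items from calibration: {excluded}",
        stacklevel=3,
    )
    keep = ~bad
    kept = ResponseMatrix(
        items=[it for it, k in zip(responses.items, keep) if k],
        data=responses.data[:, keep],
        timepoint=responses.timepoint,
    )
    return kept, excluded


def fit_mml_em(responses: ResponseMatrix, spec: CalibrationSpec) -> CalibrationResult:
    """Fit the Rasch model to one form by Bock-Aitkin MML-EM.

    In ``free`` mode the latent mean is fixed at 0 and the variance is
    estimated; in ``fixed_anchor`` mode the items in ``spec.fixed_items`` are
    held at the supplied values while latent mean and variance are both
    estimated (fixed parameter calibration).
    """
    if spec.mode not in ("free", "fixed_anchor"):
        raise ConfigurationError("fit_mml_em handles free / fixed_anchor modes only")
    responses, excluded = _screen_items(responses)
    items = responses.items
    if not items:
        raise ConfigurationError("no estimable items remain")
    stats = _FormStats(responses.data)
    I, N = stats.n_items, stats.n_persons

    fixed_mask = np.array([i in spec.fixed_items for i in items])
    estimate_mu = spec.mode == "fixed_anchor"
    z, w = _standard_nodes(spec.quadrature_kind, spec.quadrature_nodes)
    logw = np.log(w)

    # start: logit of observed proportions, fixed items at their given values
    with np.errstate(divide="ignore"):
        delta = np.log((N - stats.totals) / np.maximum(stats.totals, 1e-9))
    delta = np.clip(delta, -5, 5)
    for j, it in enumerate(items):
        if fixed_mask[j]:
            delta[j] = spec.fixed_items[it]
    mu, sigma2 = 0.0, 1.0

    ll_path = []
    ll_old = -np.inf
    converged = False
    n_iter = 0
    free_idx = np.where(~fixed_mask)[0]
    for n_iter in range(1, spec.max_iter + 1):
        theta = mu + np.sqrt(sigma2) * z
        post, ll = _posterior(stats, delta, theta, logw)
        ll_path.append(ll)
        f_by_node = stats.n_r @ post  # expected persons per node
        # M-step: item difficulties (free items), expected-count equations
        new_delta = delta.copy()
        if free_idx.size:
            new_delta[free_idx] = _newton_item_solve(
                delta[free_idx], stats.totals[free_idx], f_by_node, theta
            )
        # M-step: latent normal from posterior moments
        e1 = float(f_by_node @ theta) / N
        e2 = float(f_by_node @ theta**2) / N
        new_mu = e1 if estimate_mu else 0.0
        new_sigma2 = max(e2 - new_mu**2 if estimate_mu else e2, 1e-6)

        change = max(
            np.max(np.abs(new_delta - delta)) if I else 0.0,
            abs(new_mu - mu),
            abs(new_sigma2 - sigma2),
        )
        rel_ll = abs(ll - ll_old) / max(abs(ll), 1.0)
        delta, mu, sigma2 = new_delta, new_mu, new_sigma2
        if change < spec.tol and rel_ll < spec.loglik_tol:
            converged = True
            break
        ll_old = ll

    theta = mu + np.sqrt(sigma2) * z
    post, ll = _posterior(stats, delta, theta, logw)
    ll_path.append(ll)
    if not np.isfinite(ll):
        converged = False

    se = _item_ses(stats, delta, theta, logw, post, free_mask=~fixed_mask)
    se_map = {}
    for j, it in enumerate(items):
        se_map[it] = 0.0 if fixed_mask[j] else se[j]
    return CalibrationResult(
        difficulties=dict(zip(items, delta.tolist())),
        se=se_map,
        fixed=frozenset(i for i in items if i in spec.fixed_items),
        mu=mu,
        sigma2=sigma2,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        mode=spec.mode,
        excluded=excluded,
        loglik_path=tuple(ll_path),
    )


def _item_ses(stats: _FormStats, delta, theta, logw, post, free_mask):
    """Standard errors of free difficulties from the cross-product
    approximation to the expected Fisher information of the marginal
    likelihood (outer product of per-person scores), free-item block."""
    I = stats.n_items
    se = np.full(I, np.nan)
    idx = np.where(free_mask)[0]
    if idx.size == 0:
        return se
    P = expit(theta[None, :] - delta[:, None])  # (I, Q)
    pbar_by_score = post @ P.T  # (R, I): posterior-expected P per score group
    scores = stats.scores
    S = pbar_by_score[scores][:, idx] - stats.data[:, idx]  # (N, k) person scores
    info = S.T @ S
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; SEs unavailable", stacklevel=2)
        return se
    with np.errstate(invalid="ignore"):
        vals = np.sqrt(diag)
    vals[diag <= 0] = np.nan
    se[idx] = vals
    return se


def estimate_item_ses(
    result: CalibrationResult, responses: ResponseMatrix, spec: CalibrationSpec | None = None
) -> dict[str, float]:
    """Recompute difficulty SEs for a fitted single-form calibration."""
    spec = spec or CalibrationSpec(mode=result.mode if result.mode != "concurrent" else "free")
    idx = [j for j, it in enumerate(responses.items) if it in result.difficulties]
    data = responses.data[:, idx]
    items = [responses.items[j] for j in idx]
    delta = np.array([result.difficulties[i] for i in items])
    stats = _FormStats(data)
    theta, w = build_quadrature(
        spec.quadrature_kind, spec.quadrature_nodes,
        mu=result.mu or 0.0, sigma=float(np.sqrt(result.sigma2)),
    )
    post, _ = _posterior(stats, delta, theta, np.log(w))
    free = np.array([i not in result.fixed for i in items])
    se = _item_ses(stats, delta, theta, np.log(w), post, free)
    return {it: (0.0 if it in result.fixed else se[j]) for j, it in enumerate(items)}


def eap_abilities(result: CalibrationResult, responses: ResponseMatrix) -> np.ndarray:
    """Posterior-mean (EAP) ability per person under a single-form fit.

    For the Rasch model the posterior depends on the data only through the raw
    sum score, so equal-score persons receive identical EAPs (sufficiency).
    """
    items = [i for i in responses.items if i in result.difficulties]
    idx = [responses.items.index(i) for i in items]
    delta = np.array([result.difficulties[i] for i in items])
    stats = _FormStats(responses.data[:, idx])
    theta, w = build_quadrature(
        "gauss_hermite", 41, mu=result.mu or 0.0, sigma=float(np.sqrt(result.sigma2))
    )
    post, _ = _posterior(stats, delta, theta, np.log(w))
    eap_by_score = post @ theta
    return eap_by_score[stats.scores]


# ---------------------------------------------------------------------------
# concurrent multi-form fit
# ---------------------------------------------------------------------------

def _check_connected(forms_items: list[list[str]]):
    """The shared-item graph over forms must be connected for one scale."""
    n = len(forms_items)
    sets = [set(it) for it in forms_items]
    seen = {0}
    frontier = [0]
    while frontier:
        cur = frontier.pop()
        for j in range(n):
            if j not in seen and sets[cur] & sets[j]:
                seen.add(j)
                frontier.append(j)
    if len(seen) != n:
        raise ConfigurationError(
            "anchor constraints do not connect all forms into one chain"
        )


def fit_concurrent(
    responses_by_form: list[ResponseMatrix], spec: CalibrationSpec | None = None
) -> CalibrationResult:
    """Joint MML fit of all forms with anchor difficulties constrained equal.

    Items sharing a global id across forms are a single parameter; each form
    has its own latent normal, with the first form's mean fixed at 0 for
    identification.  Quadrature defaults to a 1,000-node quasi-Monte-Carlo
    set shared (after per-form rescaling) by all forms.
    """
    spec = spec or CalibrationSpec(mode="concurrent")
    if spec.mode != "concurrent":
        raise ConfigurationError("fit_concurrent requires a concurrent-mode spec")
    if len(responses_by_form) < 2:
        raise ConfigurationError("concurrent calibration needs at least 2 forms")
    _check_connected([r.items for r in responses_by_form])

    # pooled zero-variance screen on the union of administrations
    union: list[str] = []
    for r in responses_by_form:
        for it in r.items:
            if it not in union:
                union.append(it)
    tot = {it: 0 for it in union}
    cnt = {it: 0 for it in union}
    for r in responses_by_form:
        s = r.data.sum(axis=0)
        for j, it in enumerate(r.items):
            tot[it] += int(s[j])
            cnt[it] += r.n_persons
    excluded = tuple(it for it in union if tot[it] == 0 or tot[it] == cnt[it])
    if excluded:
        warnings.warn(f"excluding zero-variance items: {excluded}", stacklevel=2)
        union = [it for it in union if it not in excluded]
        responses_by_form = [
            ResponseMatrix(
                items=[it for it in r.items if it in union],
                data=r.data[:, [j for j, it in enumerate(r.items) if it in union]],
                timepoint=r.timepoint,
            )
            for r in responses_by_form
        ]

    G = len(responses_by_form)
    col = {it: j for j, it in enumerate(union)}
    stats = [_FormStats(r.data) for r in responses_by_form]
    maps = [np.array([col[it] for it in r.items]) for r in responses_by_form]
    z, w = _standard_nodes(spec.quadrature_kind, spec.quadrature_nodes)
    logw = np.log(w)

    pooled_tot = np.zeros(len(union))
    pooled_n = np.zeros(len(union))
    for g in range(G):
        pooled_tot[maps[g]] += stats[g].totals
        pooled_n[maps[g]] += stats[g].n_persons
    with np.errstate(divide="ignore"):
        delta = np.clip(np.log((pooled_n - pooled_tot) / np.maximum(pooled_tot, 1e-9)), -5, 5)
    mu = np.zeros(G)
    sigma2 = np.ones(G)

    ll_path = []
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        ll = 0.0
        g_acc = np.zeros(len(union))
        # accumulate per-form contributions to the joint expected-count equations
        f_nodes = []
        thetas = []
        for g in range(G):
            theta = mu[g] + np.sqrt(sigma2[g]) * z
            post, ll_g = _posterior(stats[g], delta[maps[g]], theta, logw)
            ll += ll_g
            f_g = stats[g].n_r @ post
            f_nodes.append(f_g)
            thetas.append(theta)
            g_acc[maps[g]] += stats[g].totals
            N_g = stats[g].n_persons
            e1 = float(f_g @ theta) / N_g
            e2 = float(f_g @ theta**2) / N_g
            new_mu_g = e1 if g > 0 else 0.0
            sigma2_g = e2 - new_mu_g**2 if g > 0 else e2
            mu[g], sigma2[g] = new_mu_g, max(sigma2_g, 1e-6)
        ll_path.append(ll)

        new_delta = _newton_item_solve_multi(delta, g_acc, f_nodes, thetas, maps)
        change = float(np.max(np.abs(new_delta - delta)))
        rel_ll = abs(ll - ll_old) / max(abs(ll), 1.0)
        delta = new_delta
        if change < spec.tol and rel_ll < spec.loglik_tol:
            converged = True
            break
        ll_old = ll

    ll = 0.0
    for g in range(G):
        theta = mu[g] + np.sqrt(sigma2[g]) * z
        _, ll_g = _posterior(stats[g], delta[maps[g]], theta, logw)
        ll += ll_g
    ll_path.append(ll)
    if not np.isfinite(ll):
        converged = False

    forms = [r.timepoint if r.timepoint is not None else g + 1
             for g, r in enumerate(responses_by_form)]
    return CalibrationResult(
        difficulties={it: float(delta[col[it]]) for it in union},
        se={it: np.nan for it in union},
        fixed=frozenset(),
        mu=None,
        sigma2=None,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        mode="concurrent",
        mu_by_form={forms[g]: float(mu[g]) for g in range(G)},
        sigma2_by_form={forms[g]: float(sigma2[g]) for g in range(G)},
        excluded=excluded,
        loglik_path=tuple(ll_path),
    )


def _newton_item_solve_multi(delta, target, f_nodes, thetas, maps, max_inner=60, tol=1e-11):
    """Joint expected-count equations, items possibly shared across forms."""
    delta = delta.copy()
    for _ in range(max_inner):
        g = -target.copy()
        h = np.zeros_like(delta)
        for f_g, theta, m in zip(f_nodes, thetas, maps):
            P = expit(theta[None, :] - delta[m][:, None])
            g[m] += P @ f_g
            h[m] += (P * (1.0 - P)) @ f_g
        step = np.clip(g / np.maximum(h, 1e-12), -2.0, 2.0)
        delta += step
        if np.max(np.abs(step)) < tol:
            break
    return delta
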
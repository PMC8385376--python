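"""Bayesian phylogenetic Poisson regression of node counts on time.

The model for tip ``i`` is

    N_Nodes_i ~ Poisson(exp(eta_i))
    eta_i = offset + x_i' beta + u_i + e_i
    u ~ Normal(0, sigma2_phylo * A)        (phylogenetic random effect)
    e_i ~ Normal(0, sigma2_resid)          (additive overdispersion)

where ``A`` is the matrix of shared root-to-node path lengths between tips,
rescaled so its largest diagonal entry is 1.  The linear predictor contains
an intercept (estimated, or fixed on the log-link scale), temporal terms
(Time, Time^2 or sqrt(Time), optionally per clade group), and covariates
such as the log fossil-occurrence count.

Fitting is Metropolis-within-Gibbs: the per-tip latent linear predictors are
updated by vectorised adaptive random-walk Metropolis (their full
conditionals are independent given everything else), while the regression
coefficients, both random-effect vectors and both variance components have
conjugate Gaussian / inverse-gamma conditionals.  An extra joint
translation move on (beta, eta) breaks the slow random walk that otherwise
appears when the overdispersion variance is small.

DIC uses the deviance conditioned on the latent linear predictor:
``DIC = mean(D) + pD`` with ``pD = mean(D) - D(posterior mean of eta)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "TEMPORAL_FORMS",
    "DEFAULT_GROUP_RESTRICTIONS",
    "ModelSpec",
    "DesignMatrix",
    "PhyloCovariance",
    "ChainSettings",
    "PosteriorFit",
    "ModelSpecError",
    "build_design",
    "phylo_covariance",
    "expected_nodes",
    "fit",
    "dic",
    "summarize",
]

TEMPORAL_FORMS = ("linear", "sqrt", "quadratic")
_FORM_ORDER = {"linear": 0, "sqrt": 1, "quadratic": 2}

#: Clades for which only the Time effect is modelled by default: the
#: specialised Late Cretaceous herbivore radiations show no slowdown, so
#: square-root and quadratic terms are dropped for them in group-wise fits.
DEFAULT_GROUP_RESTRICTIONS: Mapping[str, str] = {
    "Ceratopsidae": "linear",
    "Hadrosauriformes": "linear",
}


class ModelSpecError(ValueError):
    """A model specification or design matrix is invalid."""


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: temporal form, grouping, intercept, covariates.

    ``temporal_form``: "linear" (Time), "sqrt" (sqrt(Time)) or "quadratic"
    (Time + Time^2).  ``grouping``: "single" shares one set of temporal
    coefficients across all tips; "group_wise" estimates a separate set per
    clade group.  ``intercept_mode``: "estimated" (one intercept, or one per
    group under group-wise), or a float fixing the intercept at that value
    on the log-link scale for all groups.  ``group_restrictions`` caps the
    temporal form per group (downgrade only, e.g. quadratic -> linear).
    """

    temporal_form: str = "linear"
    grouping: str = "single"
    intercept_mode: str | float = "estimated"
    covariates: tuple[str, ...] = ()
    group_restrictions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RESTRICTIONS)
    )

    def __post_init__(self) -> None:
        if self.temporal_form not in TEMPORAL_FORMS:
            raise ModelSpecError(f"unknown temporal form {self.temporal_form!r}")
        if self.grouping not in ("single", "group_wise"):
            raise ModelSpecError(f"unknown grouping {self.grouping!r}")
        if isinstance(self.intercept_mode, str) and self.intercept_mode != "estimated":
            raise ModelSpecError(
                "intercept_mode must be 'estimated' or a numeric link-scale value"
            )
        for g, f in self.group_restrictions.items():
            if f not in TEMPORAL_FORMS:
                raise ModelSpecError(f"unknown restricted form {f!r} for group {g!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def intercept_estimated(self) -> bool:
        return self.intercept_mode == "estimated"

    @property
    def fixed_intercept(self) -> float:
        return 0.0 if self.intercept_estimated else float(self.intercept_mode)

    def effective_form(self, group: str) -> str:
        """Temporal form for one group after applying restrictions."""
        cap = self.group_restrictions.get(group, self.temporal_form)
        if _FORM_ORDER[cap] < _FORM_ORDER[self.temporal_form]:
            return cap
        return self.temporal_form

    def label(self) -> str:
        parts = [self.temporal_form, self.grouping]
        if not self.intercept_estimated:
            parts.append(f"int{self.fixed_intercept:g}")
        if self.covariates:
            parts.append("+".join(self.covariates))
        return ":".join(parts)


_FORM_TERMS = {"linear": ("time",), "sqrt": ("sqrt_time",), "quadratic": ("time", "time2")}


def _term_values(term: str, t: np.ndarray) -> np.ndarray:
    if term == "time":
        return t
    if term == "time2":
        return t**2
    if term == "sqrt_time":
        return np.sqrt(t)
    raise ModelSpecError(f"unknown temporal term {term!r}")


@dataclass
class DesignMatrix:
    """Named design matrix plus link-scale offset and column->group map."""

    X: pd.DataFrame
    offset: float
    column_groups: dict[str, str | None]
    spec: ModelSpec

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the design matrix for a response table under a model spec.

    Group-wise specs produce block columns: a tip's temporal (and intercept)
    columns are nonzero only for its own group; restricted groups lose their
    Time^2 / sqrt(Time) columns in favour of plain Time.  Covariate columns
    are shared across groups.
    """
    t = table["time"].to_numpy(dtype=float)
    if (t < -1e-9).any():
        raise ModelSpecError("elapsed times must be >= 0")
    cols: dict[str, np.ndarray] = {}
    colgroups: dict[str, str | None] = {}

    if spec.grouping == "single":
        if spec.intercept_estimated:
            cols["intercept"] = np.ones(len(table))
            colgroups["intercept"] = None
        for term in _FORM_TERMS[spec.temporal_form]:
            cols[term] = _term_values(term, t)
            colgroups[term] = None
    else:
        groups = list(dict.fromkeys(table["group"]))  # first-appearance order
        gmask = {g: (table["group"] == g).to_numpy() for g in groups}
        if spec.intercept_estimated:
            for g in groups:
                name = f"intercept[{g}]"
                cols[name] = gmask[g].astype(float)
                colgroups[name] = g
        for g in groups:
            for term in _FORM_TERMS[spec.effective_form(g)]:
                name = f"{term}[{g}]"
                cols[name] = np.where(gmask[g], _term_values(term, t), 0.0)
                colgroups[name] = g

    for cov in spec.covariates:
        if cov not in table.columns:
            raise ModelSpecError(f"covariate {cov!r} not in response table")
        cols[cov] = table[cov].to_numpy(dtype=float)
        colgroups[cov] = None

    X = pd.DataFrame(cols, index=table.index)
    dead = [c for c in X.columns if not np.any(X[c].to_numpy())]
    if dead:
        raise ModelSpecError(f"all-zero design columns: {dead}")
    return DesignMatrix(X=X, offset=spec.fixed_intercept, column_groups=colgroups, spec=spec)


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------


@dataclass
class PhyloCovariance:
    """Shared root-to-node path lengths between tips, rescaled by max depth."""

    matrix: np.ndarray  # rescaled, max diagonal = 1
    raw: np.ndarray  # Myr scale
    labels: list[str]
    depth: float  # max root-to-tip path length used for rescaling

    def aligned(self, labels: Sequence[str]) -> np.ndarray:
        """Rescaled matrix reordered to the given tip-label order."""
        idx = {l: i for i, l in enumerate(self.labels)}
        try:
            order = [idx[l] for l in labels]
        except KeyError as exc:
            raise KeyError(f"tip {exc.args[0]!r} not in covariance") from None
        order = np.asarray(order)
        return self.matrix[np.ix_(order, order)]


def phylo_covariance(tree) -> PhyloCovariance:
    """Brownian shared-path covariance of the tips of a time tree.

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal is the root-to-tip path length.  The matrix is rescaled by its
    maximum diagonal entry so the phylogenetic variance is comparable across
    trees dated under different conventions.
    """
    labels = tree.tip_labels
    n = len(labels)
    pos = {l: i for i, l in enumerate(labels)}
    dtree = tree.dendropy_tree
    raw = np.zeros((n, n))

    depth: dict[int, float] = {}
    tipset: dict[int, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = pos[node.taxon.label]
            tipset[id(node)] = np.array([i])
            raw[i, i] = depth[id(node)]
        else:
            kid_sets = [tipset.pop(id(k)) for k in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kid_sets)):
                for b in range(a + 1, len(kid_sets)):
                    raw[np.ix_(kid_sets[a], kid_sets[b])] = d
                    raw[np.ix_(kid_sets[b], kid_sets[a])] = d
            tipset[id(node)] = np.concatenate(kid_sets)

    dmax = float(raw.diagonal().max())
    if dmax <= 0:
        raise ModelSpecError("tree has zero total depth; covariance is degenerate")
    return PhyloCovariance(matrix=raw / dmax, raw=raw, labels=labels, depth=dmax)


def expected_nodes(intercept: float, linear_predictor_rest: float) -> float:
    """Expected node count on the response scale: exp(intercept + rest)."""
    return float(np.exp(intercept + linear_predictor_rest))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainSettings:
    """MCMC chain configuration.

    Defaults are sized for production runs; tests and large studies use
    shorter chains.  ``fix_phylo_variance`` pins sigma2_phylo at a constant
    (e.g. 1e-8 to switch the phylogenetic effect off); ``beta_prior_var`` is
    the Normal prior variance of each coefficient on the link scale; the
    variance components carry inverse-gamma(shape, rate) priors.
    """

    iterations: int = 110_000
    burn_in: int = 10_000
    thin: int = 100
    beta_prior_var: float = 1e8
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    fix_phylo_variance: float | None = None
    fix_resid_variance: float | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ModelSpecError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ModelSpecError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorFit:
    """MCMC samples and summaries for one fitted model."""

    coef_samples: pd.DataFrame
    sigma2_phylo: np.ndarray
    sigma2_resid: np.ndarray
    eta_samples: np.ndarray  # (n_samples, n_tips)
    deviance: np.ndarray
    dic: float
    pd_effective_params: float
    ess: pd.Series
    rhat: pd.Series
    settings: ChainSettings
    seed: int
    spec_label: str
    data_hash: str
    n_params: int
    offset: float
    y: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.deviance)


def _table_hash(table: pd.DataFrame) -> str:
    cols = [c for c in ("tip_label", "n_nodes", "time", "group", "log_n_occ") if c in table]
    payload = table[cols].round(12).to_csv(index=False).encode()
    return hashlib.md5(payload).hexdigest()


def _poisson_deviance(y: np.ndarray, eta: np.ndarray, lgy: np.ndarray) -> float:
    """-2 log-likelihood of the Poisson given the linear predictor."""
    return float(-2.0 * np.sum(y * eta - np.exp(eta) - lgy))


def _split_chain(x: np.ndarray) -> np.ndarray:
    half = len(x) // 2
    return x[: 2 * half].reshape(2, half)


def fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    cov: PhyloCovariance,
    settings: ChainSettings = ChainSettings(),
    seed: int = 0,
    design: DesignMatrix | None = None,
) -> PosteriorFit:
    """Fit the phylogenetic Poisson mixed model by MCMC.

    ``design`` may be supplied to override :func:`build_design` (e.g. for a
    model with no estimated coefficients at all).  The chain is fully
    reproducible given ``seed`` and ``settings``.
    """
    if design is None:
        design = build_design(table, spec)
    y = table["n_nodes"].to_numpy(dtype=float)
    n = len(y)
    X = design.X.to_numpy(dtype=float)
    p = X.shape[1]
    offset = design.offset

    A = cov.aligned(list(table["tip_label"]))
    lam, Q = np.linalg.eigh(A)
    if lam.min() < -1e-8:
        raise ModelSpecError(
            f"phylogenetic covariance is not positive semi-definite "
            f"(min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 1e-10, None)

    rng = np.random.default_rng(seed)
    a0 = settings.variance_prior_shape
    b0 = settings.variance_prior_rate
    vb = settings.beta_prior_var
    lgy = gammaln(y + 1.0)

    # init
    eta = np.log(y + 0.5)
    if p:
        beta, *_ = np.linalg.lstsq(X, eta - offset, rcond=None)
        XtX = X.T @ X
        # proposal covariance for the joint (beta, eta) translation move,
        # from the Poisson curvature at the initial latent state
        H = X.T @ (np.exp(eta)[:, None] * X) + np.eye(p) / vb
        Lh = np.linalg.cholesky(H)  # delta = s * Lh^{-T} z has covariance s^2 H^{-1}
    else:
        beta = np.zeros(0)
        XtX = np.zeros((0, 0))
        Lh = None
    u = np.zeros(n)
    w = np.zeros(n)
    s2p = settings.fix_phylo_variance if settings.fix_phylo_variance is not None else 0.1
    s2e = settings.fix_resid_variance if settings.fix_resid_variance is not None else 0.1

    step = np.full(n, 0.5)  # per-site RW scales for the latent update
    sb = 1.0  # scale of the translation move
    n_keep = settings.n_samples
    coef_out = np.empty((n_keep, p))
    s2p_out = np.empty(n_keep)
    s2e_out = np.empty(n_keep)
    eta_out = np.empty((n_keep, n))
    dev_out = np.empty(n_keep)
    k = 0

    for it in range(settings.iterations):
        in_burn = it < settings.burn_in
        m = offset + (X @ beta if p else 0.0) + u

        # 1. latent linear predictors: vectorised per-site random-walk MH
        prop = eta + step * rng.standard_normal(n)
        logr = (
            y * (prop - eta)
            - (np.exp(prop) - np.exp(eta))
            - ((prop - m) ** 2 - (eta - m) ** 2) / (2.0 * s2e)
        )
        acc = np.log(rng.random(n)) < logr
        eta = np.where(acc, prop, eta)
        if in_burn:
            step *= np.exp(0.05 * (acc.astype(float) - 0.44))

        # 2. overdispersion variance (conjugate inverse-gamma)
        if settings.fix_resid_variance is None:
            resid = eta - m
            s2e = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * resid @ resid))

        # 3. phylogenetic effect in the eigenbasis of A (conjugate Gaussian)
        r = eta - offset - (X @ beta if p else 0.0)
        rq = Q.T @ r
        post_var = 1.0 / (1.0 / (s2p * lam) + 1.0 / s2e)
        w = post_var * rq / s2e + np.sqrt(post_var) * rng.standard_normal(n)
        u = Q @ w

        # 4. phylogenetic variance (conjugate inverse-gamma)
        if settings.fix_phylo_variance is None:
            ss = np.sum(w * w / lam)
            s2p = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * ss))

        if p:
            # 5. coefficients (conjugate Gaussian regression on eta - u)
            prec = XtX / s2e + np.eye(p) / vb
            L = np.linalg.cholesky(prec)
            rhs = X.T @ (eta - offset - u) / s2e
            mean = np.linalg.solve(prec, rhs)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            # 6. joint translation (beta, eta) -> (beta + d, eta + X d);
            # leaves the overdispersion residuals invariant and lets the
            # coefficients feel the Poisson likelihood directly
            d = sb * np.linalg.solve(Lh.T, rng.standard_normal(p))
            shift = X @ d
            beta_new = beta + d
            logr2 = (
                np.sum(y * shift - (np.exp(eta + shift) - np.exp(eta)))
                + (beta @ beta - beta_new @ beta_new) / (2.0 * vb)
            )
            acc2 = np.log(rng.random()) < logr2
            if acc2:
                beta = beta_new
                eta = eta + shift
            if in_burn:
                sb *= np.exp(0.05 * ((1.0 if acc2 else 0.0) - 0.25))

        if not in_burn and (it - settings.burn_in) % settings.thin == 0 and k < n_keep:
            dev = _poisson_deviance(y, eta, lgy)
            if not np.isfinite(dev):
                raise RuntimeError(f"divergent chain: non-finite deviance at iteration {it}")
            coef_out[k] = beta
            s2p_out[k] = s2p
            s2e_out[k] = s2e
            eta_out[k] = eta
            dev_out[k] = dev
            k += 1

    coef_df = pd.DataFrame(coef_out[:k], columns=list(design.X.columns))
    fit_obj = PosteriorFit(
        coef_samples=coef_df,
        sigma2_phylo=s2p_out[:k],
        sigma2_resid=s2e_out[:k],
        eta_samples=eta_out[:k],
        deviance=dev_out[:k],
        dic=np.nan,
        pd_effective_params=np.nan,
        ess=pd.Series(dtype=float),
        rhat=pd.Series(dtype=float),
        settings=settings,
        seed=seed,
        spec_label=spec.label(),
        data_hash=_table_hash(table),
        n_params=p,
        offset=offset,
        y=y,
    )
    fit_obj.dic, fit_obj.pd_effective_params = dic(fit_obj, return_pd=True)

    # convergence diagnostics (split-chain) for coefficients and variances
    traces = {c: coef_df[c].to_numpy() for c in coef_df.columns}
    if settings.fix_phylo_variance is None:
        traces["sigma2_phylo"] = fit_obj.sigma2_phylo
    if settings.fix_resid_variance is None:
        traces["sigma2_resid"] = fit_obj.sigma2_resid
    ess = {}
    rhat = {}
    for name, tr in traces.items():
        if len(tr) >= 8:
            split = _split_chain(tr)
            ess[name] = float(az.ess(split))
            rhat[name] = float(az.rhat(split))
        else:
            ess[name] = np.nan
            rhat[name] = np.nan
    fit_obj.ess = pd.Series(ess)
    fit_obj.rhat = pd.Series(rhat)
    return fit_obj


def dic(fit: PosteriorFit, return_pd: bool = False):
    """Deviance information criterion of a fit.

    ``DIC = mean(deviance) + pD`` with ``pD = mean(deviance) - deviance at
    the posterior mean of the latent linear predictor`` (the deviance is
    conditioned on the latent layer, as is conventional for this model
    family).
    """
    if fit.n_samples < 10:
        raise ModelSpecError(
            f"need >= 10 retained samples to compute DIC, have {fit.n_samples}"
        )
    dbar = float(fit.deviance.mean())
    eta_bar = fit.eta_samples.mean(axis=0)
    lgy = gammaln(fit.y + 1.0)
    d_at_mean = _poisson_deviance(fit.y, eta_bar, lgy)
    pd_eff = dbar - d_at_mean
    score = dbar + pd_eff
    if return_pd:
        return score, pd_eff
    return score


def summarize(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior summary per coefficient (and variance components).

    Columns: mean, sd, hpd_lower/hpd_upper (95% HPD), pmcmc (twice the
    smaller tail probability relative to zero, floored at 2/n_samples) and a
    ``significant`` flag (pmcmc < 0.05).  Variance components are summarised
    without a pmcmc (they are positive by construction).
    """
    rows = []
    nsamp = fit.n_samples

    def _row(name: str, s: np.ndarray, with_pmcmc: bool) -> dict:
        hdi = np.asarray(az.hdi(s, hdi_prob=0.95))  # 1-D input -> (lower, upper)
        if with_pmcmc:
            p_pos = float(np.mean(s > 0))
            p_neg = float(np.mean(s < 0))
            pmcmc = max(2.0 * min(p_pos, p_neg), 2.0 / nsamp)
            pmcmc = min(pmcmc, 1.0)
        else:
            pmcmc = np.nan
        return {
            "parameter": name,
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "hpd_lower": float(hdi[0]),
            "hpd_upper": float(hdi[1]),
            "pmcmc": pmcmc,
            "significant": bool(pmcmc < 0.05) if with_pmcmc else False,
        }

    for c in fit.coef_samples.columns:
        rows.append(_row(c, fit.coef_samples[c].to_numpy(), True))
    rows.append(_row("sigma2_phylo", fit.sigma2_phylo, False))
    rows.append(_row("sigma2_resid", fit.sigma2_resid, False))
    return pd.DataFrame(rows).set_index("parameter")
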
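"""Phylogenetic generalized least squares (PGLS) with Pagel's lambda.

Species trait values are not independent observations: residual covariance
follows shared ancestry.  Under a Brownian-motion model the expected residual
covariance of two tips is proportional to the branch length they share from
the root.  Pagel's lambda multiplies the off-diagonal entries of that
covariance matrix, interpolating between an ordinary least squares model
(lambda = 0, star phylogeny) and Felsenstein's independent contrasts
(lambda = 1, full Brownian covariance).  Lambda is estimated by maximising
the profile log-likelihood of the regression residuals and its 95% CI is the
chi-square(1) likelihood-ratio set {lambda : 2(l_max - l(lambda)) <= 3.841};
a CI endpoint that runs into the boundary of [0, 1] is reported as ``None``
("na"), and the conservative refit then uses lambda = 1.

Conventions: the ML variance (RSS/n) is used inside the lambda profile
likelihood, the unbiased variance (RSS/(n-p)) for standard errors and t
tests; effect sizes are r = sign(t) sqrt(t^2/(t^2+df)) with a Fisher-z CI
using standard error 1/sqrt(df-3).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "ModelSpec",
    "PGLSFit",
    "LambdaProfile",
    "ModelResult",
    "read_newick",
    "phylo_vcv",
    "lambda_transform",
    "build_design",
    "pgls_fit",
    "profile_lambda",
    "effect_size",
    "run_model_suite",
    "report_table",
    "DEFAULT_MODELS",
]

LR_CUTOFF_95 = 3.841458820694124  # chi-square(1) 0.95 quantile
Z95 = 1.959963984540054  # two-sided 95% normal quantile


class NewickError(ValueError):
    pass


class MissingTipError(KeyError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapped around a dendropy tree."""

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = []
        for leaf in self.tree.leaf_node_iter():
            depths.append(leaf.distance_from_root())
        return max(depths) - min(depths) <= tol * max(max(depths), 1.0)


def read_newick(path_or_string) -> Phylogeny:
    """Parse a Newick tree (file path or literal string) with branch lengths."""
    text = str(path_or_string)
    try:
        if text.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=text, schema="newick")
        else:
            tree = dendropy.Tree.get(path=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dups = sorted({t for t in labels if labels.count(t) > 1})
    if dups:
        raise NewickError(f"duplicate tip label(s): {dups}")
    return Phylogeny(tree=tree)


def phylo_vcv(phylo: Phylogeny, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix for the given tips.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j
    (the tip's root-to-tip depth on the diagonal), computed as
    ``(d(root,i) + d(root,j) - d(i,j)) / 2`` from patristic distances.
    """
    tree = phylo.tree
    tip = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in tip]
    if missing:
        raise MissingTipError(
            f"taxa missing from tree (omitted from the analysis): {missing}"
        )
    depth = {t: tip[t].distance_from_root() for t in taxa}
    pdm = tree.phylogenetic_distance_matrix()
    m = len(taxa)
    C = np.zeros((m, m))
    for i, a in enumerate(taxa):
        C[i, i] = depth[a]
        for j in range(i + 1, m):
            b = taxa[j]
            d = pdm.patristic_distance(tip[a].taxon, tip[b].taxon)
            shared = 0.5 * (depth[a] + depth[b] - d)
            C[i, j] = C[j, i] = max(shared, 0.0)
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal phylogenetic covariances by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


# ---------------------------------------------------------------------------
# design matrices

_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "log10": math.log10,
    "inverse": lambda x: 1.0 / x,
}


@dataclass(frozen=True)
class ModelSpec:
    """A regression model: response and predictors with their transforms."""

    name: str
    response: tuple[str, str]  # (column, transform)
    predictors: tuple[tuple[str, str], ...]  # ((column, transform), ...)


def _apply_transform(value: float, transform: str, column: str, species: str) -> float:
    if transform == "log10" and value <= 0:
        raise ValueError(f"log10 of non-positive {column} for {species}")
    if transform == "inverse" and value == 0:
        raise ValueError(f"inverse of zero {column} for {species}")
    return _TRANSFORMS[transform](value)


def build_design(
    traits: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Response vector, design matrix (intercept first) and surviving taxa.

    ``traits`` is indexed by species.  Rows missing any model variable are
    dropped (complete-case analysis).  Returns ``(y, X, taxa, colnames)``.
    """
    cols = [spec.response[0]] + [c for c, _ in spec.predictors]
    unknown = [c for c in cols if c not in traits.columns]
    if unknown:
        raise KeyError(f"trait column(s) not found: {unknown}")
    sub = traits[cols].dropna()
    taxa = list(sub.index)
    y = np.array(
        [
            _apply_transform(v, spec.response[1], spec.response[0], s)
            for s, v in zip(taxa, sub[spec.response[0]])
        ]
    )
    columns = [np.ones(len(taxa))]
    names = ["intercept"]
    for col, transform in spec.predictors:
        columns.append(
            np.array(
                [
                    _apply_transform(v, transform, col, s)
                    for s, v in zip(taxa, sub[col])
                ]
            )
        )
        names.append(col if transform == "identity" else f"{transform}({col})")
    X = np.column_stack(columns)
    return y, X, taxa, names


# ---------------------------------------------------------------------------
# GLS machinery


@dataclass
class PGLSFit:
    response: str
    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    loglik: float
    lam: float
    n: int
    df_resid: int
    effect_sizes: list[tuple[float, Optional[tuple[float, float]]]] = field(
        default_factory=list
    )
    residuals: Optional[np.ndarray] = None
    lambda_ml: Optional[float] = None
    lambda_ci: Optional[tuple[Optional[float], Optional[float]]] = None


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Cholesky-whitened GLS: returns beta, RSS_V, XtVinvX_inv, logdet(V)."""
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ Xw.T @ yw
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    return beta, rss, xtx_inv, logdet


def _loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Profile ML log-likelihood (beta and sigma^2 maximised out)."""
    n = len(y)
    _, rss, _, logdet = _gls_core(y, X, V)
    sigma2_ml = rss / n
    return -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2_ml) + logdet + n)


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    lam: float,
    response: str = "y",
    columns: Optional[Sequence[str]] = None,
) -> PGLSFit:
    """Fit a PGLS regression at a fixed lambda.

    beta-hat = (X' V^-1 X)^-1 X' V^-1 y with V the lambda-scaled covariance;
    SEs use the unbiased residual variance RSS/(n-p); the reported
    log-likelihood is the ML one (variance RSS/n).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    V = lambda_transform(C, lam)
    beta, rss, xtx_inv, logdet = _gls_core(y, X, V)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    sigma2_ml = rss / n
    ll = -0.5 * (
        n * math.log(2 * math.pi) + n * math.log(max(sigma2_ml, 1e-300)) + logdet + n
    )
    cols = list(columns) if columns is not None else [f"x{i}" for i in range(p)]
    effects = [effect_size(float(ti), df) for ti in t]
    return PGLSFit(
        response=response,
        columns=cols,
        beta=beta,
        se=se,
        t=t,
        p=pvals,
        sigma2=sigma2,
        loglik=ll,
        lam=lam,
        n=n,
        df_resid=df,
        effect_sizes=effects,
        residuals=y - X @ beta,
    )


@dataclass
class LambdaProfile:
    lambda_ml: float
    ci: tuple[Optional[float], Optional[float]]
    grid: np.ndarray
    loglik: np.ndarray
    max_loglik: float
    uninformative: bool = False

    @property
    def lambda_conservative(self) -> float:
        """Upper-CI lambda for the conservative refit; 1.0 when the upper
        bound runs into the boundary ("na")."""
        return 1.0 if self.ci[1] is None else self.ci[1]


def profile_lambda(
    y: np.ndarray, X: np.ndarray, C: np.ndarray, grid_size: int = 101
) -> LambdaProfile:
    """Maximum-likelihood lambda with a likelihood-ratio 95% CI.

    The profile log-likelihood is evaluated on a uniform grid over [0, 1],
    refined around the grid optimum by bounded scalar optimisation (1e-4
    tolerance).  The CI is {lambda : 2(l_max - l(lambda)) <= 3.841}; an
    endpoint is ``None`` ("na") when the deviance never reaches the cutoff
    before the boundary of [0, 1].
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    ll = np.array([_loglik(y, X, lambda_transform(C, g)) for g in grid])
    uninformative = float(ll.max() - ll.min()) < 1e-8
    if uninformative:
        return LambdaProfile(
            lambda_ml=0.0,
            ci=(None, None),
            grid=grid,
            loglik=ll,
            max_loglik=float(ll.max()),
            uninformative=True,
        )
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    neg = lambda lam: -_loglik(y, X, lambda_transform(C, lam))
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
    )
    lam_ml, ll_max = float(res.x), -float(res.fun)
    # grid maximum can beat the refined point at the boundary
    if ll[i] > ll_max:
        lam_ml, ll_max = float(grid[i]), float(ll[i])
    if lam_ml < 1e-4:
        lam_ml = 0.0
    elif lam_ml > 1 - 1e-4:
        lam_ml = 1.0

    def deviance(lam: float) -> float:
        return 2.0 * (ll_max - _loglik(y, X, lambda_transform(C, lam)))

    def bound(a: float, b: float) -> Optional[float]:
        """CI endpoint between a (boundary) and b (the ML point)."""
        if deviance(a) <= LR_CUTOFF_95:
            return None  # CI runs into the [0, 1] boundary -> "na"
        lo_, hi_ = min(a, b), max(a, b)
        root = optimize.brentq(
            lambda lam: deviance(lam) - LR_CUTOFF_95, lo_, hi_, xtol=1e-6
        )
        return float(root)

    lower = None if lam_ml == 0.0 else bound(0.0, lam_ml)
    upper = None if lam_ml == 1.0 else bound(1.0, lam_ml)
    return LambdaProfile(
        lambda_ml=lam_ml,
        ci=(lower, upper),
        grid=grid,
        loglik=ll,
        max_loglik=ll_max,
    )


def effect_size(
    t: float, df: int
) -> tuple[float, Optional[tuple[float, float]]]:
    """Correlation effect size from a t statistic and its residual df.

    r = sign(t) sqrt(t^2 / (t^2 + df)); 95% CI by the Fisher z transform with
    standard error 1/sqrt(df - 3) (undefined for df <= 3).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    r = math.copysign(math.sqrt(t * t / (t * t + df)), t) if t != 0 else 0.0
    if df <= 3:
        return r, None
    z = math.atanh(max(min(r, 1.0 - 1e-15), -1.0 + 1e-15))
    half = Z95 / math.sqrt(df - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


# ---------------------------------------------------------------------------
# model suite

DEFAULT_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec(
        name="relatedness ~ log10(size) + nest_site",
        response=("r", "identity"),
        predictors=(("size", "log10"), ("nest_site", "identity")),
    ),
    ModelSpec(
        name="paternity_frequency ~ log10(size) + nest_site",
        response=("k", "identity"),
        predictors=(("size", "log10"), ("nest_site", "identity")),
    ),
    ModelSpec(
        name="paternity_skew_Binv ~ log10(size) + nest_site",
        response=("B", "inverse"),
        predictors=(("size", "log10"), ("nest_site", "identity")),
    ),
    ModelSpec(
        name="relatedness ~ k + Binv",
        response=("r", "identity"),
        predictors=(("k", "identity"), ("B", "inverse")),
    ),
)

FOOTNOTE_VARIANT = ModelSpec(
    name="paternity_skew_Binv ~ log10(size)",
    response=("B", "inverse"),
    predictors=(("size", "log10"),),
)


@dataclass
class ModelResult:
    spec: ModelSpec
    taxa: list[str]
    profile: LambdaProfile
    fit_ml: PGLSFit
    fit_conservative: PGLSFit


def run_model_suite(
    traits: pd.DataFrame,
    phylo: Phylogeny,
    models: Sequence[ModelSpec] = DEFAULT_MODELS,
    size_column: str = "mean_size",
    include_footnote_variant: bool = True,
    drop_nest_site: bool = False,
) -> list[ModelResult]:
    """Fit each model twice: at lambda = ML and at the upper-95%-CI lambda.

    ``size_column`` selects mean or maximum colony size as the body of the
    ``size`` predictor.  The footnote variant refits the skew model without
    the nest-site cofactor.  Taxa absent from the tree are dropped with the
    complete cases.
    """
    data = traits.copy()
    if size_column in data.columns:
        data["size"] = data[size_column]
    tips = set(phylo.taxa)
    data = data.loc[[s for s in data.index if s in tips]]
    specs = list(models)
    if drop_nest_site:
        specs = [
            ModelSpec(
                name=m.name.replace(" + nest_site", ""),
                response=m.response,
                predictors=tuple(
                    p for p in m.predictors if p[0] != "nest_site"
                ),
            )
            for m in specs
        ]
    if include_footnote_variant and any(
        m.response == ("B", "inverse") and ("nest_site", "identity") in m.predictors
        for m in specs
    ):
        specs.append(FOOTNOTE_VARIANT)
    results = []
    for spec in specs:
        y, X, taxa, names = build_design(data, spec)
        if len(taxa) < X.shape[1] + 1:
            raise ValueError(f"model {spec.name}: too few complete cases ({len(taxa)})")
        C = phylo_vcv(phylo, taxa)
        prof = profile_lambda(y, X, C)
        fit_ml = pgls_fit(y, X, C, prof.lambda_ml, spec.name, names)
        fit_ml.lambda_ml = prof.lambda_ml
        fit_ml.lambda_ci = prof.ci
        fit_cons = pgls_fit(y, X, C, prof.lambda_conservative, spec.name, names)
        results.append(
            ModelResult(
                spec=spec,
                taxa=taxa,
                profile=prof,
                fit_ml=fit_ml,
                fit_conservative=fit_cons,
            )
        )
    return results


def _fmt_ci(ci: Optional[tuple[Optional[float], Optional[float]]]) -> str:
    if ci is None:
        return ""
    lo = "na" if ci[0] is None else f"{ci[0]:.2f}"
    hi = "na" if ci[1] is None else f"{ci[1]:.2f}"
    return f"({lo},{hi})"


def report_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Flat per-predictor report across the lambda = ML and conservative fits."""
    rows = []
    for res in results:
        for label, fit in (("ML", res.fit_ml), ("upper95", res.fit_conservative)):
            for j, col in enumerate(fit.columns):
                if col == "intercept":
                    continue
                r_eff, ci = fit.effect_sizes[j]
                rows.append(
                    {
                        "model": res.spec.name,
                        "lambda_block": label,
                        "lambda": fit.lam,
                        "lambda_ci": _fmt_ci(res.profile.ci) if label == "ML" else "",
                        "predictor": col,
                        "estimate": fit.beta[j],
                        "t": fit.t[j],
                        "p": fit.p[j],
                        "effect_size": r_eff,
                        "effect_ci": _fmt_ci(ci),
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)


def residual_summary(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Residual location/scale/shape summary per fitted model, written so the
    normality of PGLS residuals can be reviewed."""
    rows = []
    for res in results:
        resid = res.fit_ml.residuals
        rows.append(
            {
                "model": res.spec.name,
                "mean": float(np.mean(resid)),
                "sd": float(np.std(resid, ddof=1)),
                "skewness": float(stats.skew(resid)),
                "kurtosis_excess": float(stats.kurtosis(resid)),
                "shapiro_p": float(stats.shapiro(resid).pvalue),
            }
        )
    return pd.DataFrame(rows)


def config_hash(items: dict) -> str:
    """Short stable hash of a flat config dict, for provenance headers."""
    blob = ";".join(f"{k}={items[k]}" for k in sorted(items))
    return hashlib.sha1(blob.encode()).hexdigest()[:12]
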
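"""Model specification and inference for the used-available berry analyses.

This layer sits on top of the quadrature GLMM core (:mod:`berryforage.glmm`)
and provides what the analyses need: treatment-coded formula specs with
explicit reference levels, hurdle (occurrence + zero-truncated count) fits,
a VIF collinearity screen, likelihood-ratio tests, stepwise backward model
selection respecting marginality, single-step-adjusted pairwise contrasts,
and population-level predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .glmm import FAMILIES, GlmmFit, fit_glmm_arrays

__all__ = [
    "FormulaSpec",
    "HurdleFit",
    "LrTestResult",
    "ContrastResult",
    "SelectionTrace",
    "fit_glmm",
    "fit_hurdle",
    "vif_screen",
    "VifResult",
    "lr_test",
    "backward_select",
    "pairwise_contrasts",
    "single_step_adjust",
    "predict_population",
    "pearson_cor",
    "welch_t",
]

MIN_POSITIVE_ROWS = 30


@dataclass(frozen=True)
class FormulaSpec:
    """Fixed-effect terms, factor reference levels, and the grouping variable.

    ``terms`` are term labels such as ``"habitat"`` or ``"plottype:habitat"``;
    an intercept is always included.  Variables listed in ``reference`` are
    treatment-coded against the given reference level (e.g. bog for habitat,
    random plots for plot type); other non-numeric variables are
    treatment-coded against their first level.
    """

    response: str
    terms: tuple[str, ...]
    group: str | None = None
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        atoms = set(v for t in self.terms for v in t.split(":"))
        for t in self.terms:
            if ":" in t:
                for v in t.split(":"):
                    if v not in atoms:
                        raise ValueError(f"interaction {t} uses unknown variable {v}")

    def _code(self, var: str) -> str:
        ref = self.reference.get(var)
        if ref is not None:
            return f"C({var}, Treatment({ref!r}))"
        return var

    def formula(self) -> str:
        rhs = " + ".join(":".join(self._code(v) for v in t.split(":")) for t in self.terms)
        return f"{self.response} ~ {rhs}" if rhs else f"{self.response} ~ 1"

    def without(self, term: str) -> "FormulaSpec":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in spec")
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def droppable_terms(self) -> list[str]:
        """Terms removable without violating marginality.

        A term is protected while a strictly larger interaction containing
        all of its variables remains in the model.
        """
        out = []
        for t in self.terms:
            vs = set(t.split(":"))
            protected = any(
                vs < set(o.split(":")) for o in self.terms if o != t
            )
            if not protected:
                out.append(t)
        return out


def _clean_names(design_info) -> list[str]:
    """Human-readable coefficient names from patsy's C(...) encoding."""
    # textual cleanup: C(var, Treatment('ref'))[T.level] -> var[level]
    cleaned = []
    for name in design_info.column_names:
        while "C(" in name:
            start = name.index("C(")
            depth = 0
            for i in range(start, len(name)):
                if name[i] == "(":
                    depth += 1
                elif name[i] == ")":
                    depth -= 1
                    if depth == 0:
                        end = i
                        break
            inner = name[start + 2 : end]
            var = inner.split(",")[0].strip()
            name = name[:start] + var + name[end + 1 :]
        name = name.replace("[T.", "[")
        cleaned.append(name)
    return cleaned


def fit_glmm(
    data: pd.DataFrame,
    spec: FormulaSpec,
    family: str,
    nodes: int = 10,
    compute_se: bool = True,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Fit a formula-specified GLMM on a data frame.

    Rows with missing values in any model variable must have been removed
    beforehand (``assemble_dataset`` does this); patsy would silently drop
    them otherwise, which is refused here.
    """
    ymat, X = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    if len(X) != len(data):
        raise ValueError("model frame lost rows; remove missing values before fitting")
    y = np.asarray(ymat).ravel()
    groups = data[spec.group].to_numpy() if spec.group is not None else None
    fit = fit_glmm_arrays(
        y,
        X.to_numpy(),
        groups=groups,
        family=family,
        nodes=nodes,
        names=_clean_names(X.design_info),
        start=start,
        compute_se=compute_se,
    )
    fit.design_info = X.design_info
    fit.spec = spec
    return fit


@dataclass
class HurdleFit:
    """Paired occurrence (binomial) and abundance (zero-truncated NB) fits."""

    occurrence: GlmmFit
    abundance: GlmmFit

    @property
    def loglik(self) -> float:
        # the hurdle likelihood factorises into its two parts
        return self.occurrence.loglik + self.abundance.loglik


def fit_hurdle(
    data: pd.DataFrame,
    count: str,
    spec_occurrence: FormulaSpec,
    spec_abundance: FormulaSpec,
    nodes: int = 10,
) -> HurdleFit:
    """Two-part hurdle fit for one berry species.

    The occurrence part models ``count >= 1`` on all rows; the count part
    models the counts on the positive rows only with the zero-truncated NB.
    The parts are independent fits (the hurdle likelihood factorises).
    """
    if (data[count] < 0).any():
        raise ValueError("counts must be non-negative")
    work = data.copy()
    work["_occ"] = (work[count] >= 1).astype(float)
    occ = fit_glmm(work, replace(spec_occurrence, response="_occ"), "binomial", nodes=nodes)
    if work["_occ"].nunique() == 1:
        occ.flags.append("degenerate_occurrence")
    positive = work[work[count] >= 1]
    if len(positive) < MIN_POSITIVE_ROWS:
        raise ValueError(
            f"only {len(positive)} positive-count rows; need >= {MIN_POSITIVE_ROWS} "
            "for a stable zero-truncated count fit"
        )
    abn = fit_glmm(positive, replace(spec_abundance, response=count), "truncnegbin", nodes=nodes)
    return HurdleFit(occurrence=occ, abundance=abn)


@dataclass(frozen=True)
class VifResult:
    vif: dict[str, float]  # at entry, before any drop
    final_vif: dict[str, float]
    retained: tuple[str, ...]
    dropped: tuple[str, ...]


def _vif_once(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    n, p = X.shape
    out = {}
    for j in range(p):
        others = np.c_[np.ones(n), np.delete(X, j, axis=1)]
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if tss <= 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(design: pd.DataFrame, cutoff: float = 3.0) -> VifResult:
    """Iterative variance-inflation-factor screen.

    Each predictor is regressed on all the others; VIF_j = 1 / (1 - R2_j).
    The largest-VIF predictor above ``cutoff`` is dropped and the VIFs are
    recomputed, until all remaining are at or below the cutoff.  Perfectly
    collinear predictors show VIF = inf and are dropped first.
    """
    if design.shape[1] < 2:
        raise ValueError("need >= 2 predictors for a VIF screen")
    if design.isna().any().any():
        raise ValueError("VIF screen requires complete data")
    names = list(design.columns)
    initial = _vif_once(design.to_numpy(dtype=float), names)
    dropped: list[str] = []
    current = dict(initial)
    cols = list(names)
    while len(cols) >= 2:
        worst = max(cols, key=lambda c: current[c])
        if current[worst] <= cutoff:
            break
        dropped.append(worst)
        cols.remove(worst)
        if len(cols) >= 2:
            current = _vif_once(design[cols].to_numpy(dtype=float), cols)
        else:
            current = {cols[0]: 1.0}
    return VifResult(
        vif=initial,
        final_vif={c: current[c] for c in cols},
        retained=tuple(cols),
        dropped=tuple(dropped),
    )


@dataclass(frozen=True)
class LrTestResult:
    statistic: float
    df: int
    p: float
    term: str | None = None


def lr_test(full: GlmmFit, reduced: GlmmFit) -> LrTestResult:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if full.family != reduced.family or full.n_obs != reduced.n_obs:
        raise ValueError("models must share family and data rows")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("the reduced model has more parameters than the full model")
    if full.spec is not None and reduced.spec is not None:
        if not set(reduced.spec.terms) <= set(full.spec.terms):
            raise ValueError("reduced model terms are not a subset of the full model's")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -2e-3:
            warnings.warn(
                f"negative LR statistic ({chi2:.3g}) clamped to 0; "
                "the 'full' fit may not have converged",
                stacklevel=2,
            )
        chi2 = 0.0
    if df == 0:  # identical specifications
        return LrTestResult(statistic=float(chi2), df=0, p=1.0)
    return LrTestResult(statistic=float(chi2), df=int(df), p=float(stats.chi2.sf(chi2, df)))


@dataclass
class SelectionTrace:
    """One backward-selection round: the term dropped and its LR test."""

    dropped: list[tuple[str, LrTestResult]] = field(default_factory=list)
    retained_p: dict[str, float] = field(default_factory=dict)

    def dropped_terms(self) -> list[str]:
        return [t for t, _ in self.dropped]


def _warm_start(fit: GlmmFit, reduced_spec: FormulaSpec, data: pd.DataFrame) -> np.ndarray | None:
    """Carry surviving coefficients over to the reduced design as a start."""
    if fit.params_full is None or fit.design_info is None:
        return None
    # column names of the reduced design
    try:
        X_red = patsy.dmatrix(reduced_spec.formula().split("~", 1)[1], data)
    except Exception:
        return None
    red_names = list(X_red.design_info.column_names)
    full_names = list(fit.design_info.column_names)
    p_full = len(full_names)
    extras = fit.params_full[p_full:]
    beta = []
    for name in red_names:
        beta.append(fit.params_full[full_names.index(name)] if name in full_names else 0.0)
    return np.r_[beta, extras]


def backward_select(
    data: pd.DataFrame,
    spec: FormulaSpec,
    family: str,
    alpha: float = 0.05,
    nodes: int = 10,
) -> tuple[GlmmFit, SelectionTrace]:
    """Stepwise backward elimination by likelihood-ratio tests.

    In each round every droppable term (interactions before the main effects
    they involve) is removed in turn and tested against the current model;
    the single least significant term with LR p > alpha is eliminated and the
    model refit, until every remaining term is significant.  The trace records
    each elimination with its test and the final per-term p values.
    """
    current_spec = spec
    current = fit_glmm(data, current_spec, family, nodes=nodes, compute_se=False)
    trace = SelectionTrace()
    while True:
        candidates = current_spec.droppable_terms()
        if not candidates:
            break
        tests: dict[str, LrTestResult] = {}
        reduced_fits: dict[str, GlmmFit] = {}
        for _scan_pass in range(3):
            for term in candidates:
                red_spec = current_spec.without(term)
                red = fit_glmm(
                    data,
                    red_spec,
                    family,
                    nodes=nodes,
                    compute_se=False,
                    start=_warm_start(current, red_spec, data),
                )
                reduced_fits[term] = red
            best = max(reduced_fits.values(), key=lambda f: f.loglik)
            if best.loglik <= current.loglik + 1e-6:
                break
            # a nested fit beat the current model: the current optimisation
            # stalled; lift the better solution into the full design and refit
            current = fit_glmm(
                data,
                current_spec,
                family,
                nodes=nodes,
                compute_se=False,
                start=_warm_start(best, current_spec, data),
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # residual tiny clamps
            for term in candidates:
                tests[term] = lr_test(current, reduced_fits[term])
        worst = max(candidates, key=lambda t: tests[t].p)
        if tests[worst].p <= alpha:
            trace.retained_p = {t: r.p for t, r in tests.items()}
            break
        trace.dropped.append((worst, tests[worst]))
        current_spec = current_spec.without(worst)
        current = reduced_fits[worst]
    final = fit_glmm(
        data, current_spec, family, nodes=nodes, compute_se=True,
        start=current.params_full,
    )
    return final, trace


def single_step_adjust(
    z: np.ndarray,
    correlation: np.ndarray,
    rng: np.random.Generator | None = None,
    n_draws: int = 100_000,
) -> np.ndarray:
    """Single-step familywise adjustment by the max-|z| distribution.

    ``p_adj_i = P(max_j |Z_j| >= |z_i|)`` under ``Z ~ N(0, correlation)``,
    estimated by seeded Monte Carlo; a single contrast reduces exactly to the
    two-sided normal tail (no adjustment).  Adjusted p values never fall below
    the raw ones and are monotone in |z| for a fixed correlation structure.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    if len(z) == 1:
        return p_raw
    rng = rng or np.random.default_rng(0)
    R = 0.5 * (correlation + correlation.T)
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    draws = rng.standard_normal((n_draws, len(z))) @ L.T
    maxabs = np.max(np.abs(draws), axis=1)
    p_adj = np.array([np.mean(maxabs >= abs(zi)) for zi in z])
    return np.minimum(np.maximum(p_adj, p_raw), 1.0)


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float


def _term_factor_levels(fit: GlmmFit, term: str, data: pd.DataFrame) -> dict[str, list]:
    """Observed levels for each categorical variable in ``term``."""
    levels = {}
    for var in term.split(":"):
        col = data[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            continue  # numeric covariate inside an interaction: not a contrast axis
        levels[var] = sorted(col.unique(), key=str)
    return levels


def pairwise_contrasts(
    fit: GlmmFit,
    term: str,
    data: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_draws: int = 100_000,
) -> list[ContrastResult]:
    """All pairwise comparisons of the cell means spanned by ``term``.

    Cells are the level combinations of the categorical variables in the term
    (e.g. plot type x habitat); every other covariate is held fixed so it
    cancels in the differences.  Estimates are on the link scale, c'beta with
    SE sqrt(c'Vc).  Familywise adjustment is single-step: the adjusted p of a
    contrast is the probability that the maximum |z| over all contrasts,
    under the joint normal with the correlation implied by the coefficient
    covariance, exceeds the observed |z| (Monte-Carlo, seeded).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    if not np.all(np.isfinite(fit.vcov)):
        raise ValueError("fit has no (finite) coefficient covariance")
    lev = _term_factor_levels(fit, term, data)
    if not lev:
        raise ValueError(f"term {term!r} has no categorical variables to contrast")
    # one template row: numerics at mean, factors at first observed level
    template = {}
    for var in data.columns:
        col = data[var]
        if pd.api.types.is_numeric_dtype(col):
            template[var] = float(col.mean())
        else:
            template[var] = sorted(col.unique(), key=str)[0]
    cells = [{}]
    for var, values in lev.items():
        cells = [dict(c, **{var: v}) for c in cells for v in values]
    rows = pd.DataFrame([dict(template, **c) for c in cells])
    (X,) = patsy.build_design_matrices([fit.design_info], rows)
    X = np.asarray(X)

    def cell_label(c):
        return " × ".join(str(c[v]) for v in lev)

    contrasts, labels = [], []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            contrasts.append(X[j] - X[i])
            labels.append(f"{cell_label(cells[j])} - {cell_label(cells[i])}")
    C = np.asarray(contrasts)
    est = C @ fit.beta
    var = np.einsum("ij,jk,ik->i", C, fit.vcov, C)
    if np.any(var <= 0):
        raise ValueError("singular coefficient covariance for the requested contrasts")
    se = np.sqrt(var)
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))

    S = C @ fit.vcov @ C.T
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    p_adj = single_step_adjust(z, R, rng=rng, n_draws=n_draws)
    return [
        ContrastResult(labels[k], float(est[k]), float(se[k]), float(z[k]),
                       float(p_raw[k]), float(min(p_adj[k], 1.0)))
        for k in range(len(labels))
    ]


_INVLINK = {
    "binomial": lambda eta: 1.0 / (1.0 + np.exp(-eta)),
    "negbin": np.exp,
    "truncnegbin": np.exp,
    "gaussian": lambda eta: eta,
}


def predict_population(
    fit: GlmmFit, newdata: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Population-level predictions (random intercept at zero) with Wald CIs.

    The linear predictor and its confidence band are formed on the link scale
    and then transformed through the inverse link; for the count families the
    returned value is the conditional mean ``exp(eta)``.
    """
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    try:
        (X,) = patsy.build_design_matrices([fit.design_info], newdata)
    except patsy.PatsyError as err:
        raise ValueError(f"newdata incompatible with the fitted design: {err}") from err
    X = np.asarray(X)
    eta = X @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.vcov, X))
    zc = stats.norm.ppf(0.5 + level / 2.0)
    inv = _INVLINK[fit.family]
    return pd.DataFrame(
        {
            "eta": eta,
            "se_eta": se,
            "fit": inv(eta),
            "lower": inv(eta - zc * se),
            "upper": inv(eta + zc * se),
        },
        index=newdata.index,
    )


def pearson_cor(x, y) -> tuple[float, float]:
    """Pearson correlation with the usual t-approximation p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.std(x) == 0 and np.std(y) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
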
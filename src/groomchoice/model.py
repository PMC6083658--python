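"""Partner-choice model: binomial logit on (session x candidate) tables.

The response is whether a candidate was the one chosen in its session. The
primary backend is a *conditional logit*: conditioning on the fact that
exactly one candidate per session is chosen, the session-level baseline —
a random session intercept together with the log(1/n_candidates) offset —
drops out of the likelihood exactly, leaving

    L(beta) = prod_s exp(x_chosen(s) beta) / sum_{i in s} exp(x_i beta).

Estimation is Newton-Raphson on this log-likelihood with analytic gradient
and Hessian; standard errors come from the observed information. Covariates
that never vary within a session (the control predictors: focal sex, group,
focal rank main effects) are absorbed by the stratification and are
detected and removed from the design, with a record kept in the result.

A mixed-effects backend with crossed random intercepts for focal, partner,
dyad and session (the direct GLMM formulation) is available behind the same
interface via R's lme4::glmer.

Inference procedure: full-null likelihood-ratio comparison, single-term
deletion respecting marginality, variance-inflation factors on a fixed-
effects-only main-effect design, and leave-one-level-out stability checks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .choices import ChoiceTable

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The optimizer failed; carries diagnostics, never silent estimates."""


class SpecificationError(ValueError):
    """Invalid model specification (unknown term, non-nested comparison...)."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

#: control predictors (the null model): identity of group and the sexes
CONTROL_TERMS = ("focal_sex", "cand_sex", "group",
                 "focal_sex:cand_sex", "cand_sex:group")


def _rank_cols(rank_mode: str) -> tuple[str, str, str]:
    if rank_mode not in ("global", "relative"):
        raise SpecificationError("rank_mode must be 'global' or 'relative'")
    suffix = rank_mode
    return (f"z_focal_rank_{suffix}", f"z_cand_rank_{suffix}",
            f"z_cand_rank_{suffix}_sq")


@dataclasses.dataclass(frozen=True)
class ChoiceModelSpec:
    """Fixed-effect structure of one partner-choice model.

    ``terms`` are patsy-style term strings over the choice-table columns;
    interactions use ':'. Random-effect grouping factors (used by the mixed
    backend and the stability checks) are named in ``random_intercepts``.
    """

    terms: tuple[str, ...]
    rank_mode: str = "global"
    name: str = "custom"
    random_intercepts: tuple[str, ...] = ("focal", "candidate", "dyad",
                                          "session")
    random_slopes: tuple[tuple[str, str], ...] = ()

    @classmethod
    def model1(cls, rank_mode: str = "global") -> "ChoiceModelSpec":
        """All-communities design: every test predictor in interaction with
        group identity; sexes and group as controls."""
        fr, pr, pr2 = _rank_cols(rank_mode)
        ddsi = "z_ddsi" if rank_mode == "global" else "z_ddsi_relative"
        terms = CONTROL_TERMS + (
            fr, pr, pr2,
            f"{fr}:{pr2}", f"{pr}:group", f"{pr2}:group", f"{fr}:{pr2}:group",
            ddsi, f"{ddsi}:group",
            "repro_state", "repro_state:group",
            "prior_aggression", "prior_aggression:group",
            "z_max_bystander_ddsi", "z_max_bystander_ddsi:group",
        )
        return cls(terms, rank_mode, name=f"model1-{rank_mode}")

    @classmethod
    def model2(cls, rank_mode: str = "global") -> "ChoiceModelSpec":
        """Chimpanzee-only design: test predictors in interaction with focal
        sex, three-way sex x sex x group control; previous aggression enters
        without the sex interaction (too few female cases)."""
        fr, pr, pr2 = _rank_cols(rank_mode)
        ddsi = "z_ddsi" if rank_mode == "global" else "z_ddsi_relative"
        terms = (
            "focal_sex", "cand_sex", "group",
            "focal_sex:cand_sex", "cand_sex:group", "focal_sex:group",
            "focal_sex:cand_sex:group",
            fr, pr, pr2,
            f"{fr}:{pr2}", f"{pr}:focal_sex", f"{pr2}:focal_sex",
            ddsi, f"{ddsi}:focal_sex",
            "repro_state", "repro_state:focal_sex",
            "prior_aggression",
            "z_max_bystander_ddsi", "z_max_bystander_ddsi:focal_sex",
        )
        return cls(terms, rank_mode, name=f"model2-{rank_mode}")

    def null(self) -> "ChoiceModelSpec":
        """Control-predictor-only null with the same grouping structure."""
        keep = tuple(t for t in self.terms
                     if set(t.split(":")) <= {"focal_sex", "cand_sex", "group"})
        return dataclasses.replace(self, terms=keep, name=self.name + "-null")

    def drop_term(self, term: str) -> "ChoiceModelSpec":
        if term not in self.terms:
            raise SpecificationError(f"term {term!r} not in specification")
        return dataclasses.replace(
            self, terms=tuple(t for t in self.terms if t != term),
            name=f"{self.name} - {term}")

    def droppable_terms(self) -> list[str]:
        """Test terms droppable under marginality: a term is droppable only
        if its factors are not a proper subset of another term's factors."""
        factor_sets = {t: frozenset(t.split(":")) for t in self.terms}
        out = []
        for t, fs in factor_sets.items():
            if t in CONTROL_TERMS or set(t.split(":")) <= {
                    "focal_sex", "cand_sex", "group"}:
                continue
            if any(fs < other for o, other in factor_sets.items() if o != t):
                continue
            out.append(t)
        return out

    def formula(self) -> str:
        return "1 + " + " + ".join(self.terms) if self.terms else "1"

    def is_nested_in(self, other: "ChoiceModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _frame_of(table) -> pd.DataFrame:
    if isinstance(table, ChoiceTable):
        return table.frame
    return table


def build_design(frame: pd.DataFrame, spec: ChoiceModelSpec
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Patsy design matrix (treatment coding) plus term -> columns map.

    The intercept column is built (so factor coding is the usual treatment
    contrast) but removed afterwards; the conditional-logit backend absorbs
    it anyway and the mixed backend adds its own.
    """
    usable = [t for t in spec.terms
              if all(f in frame.columns for f in t.split(":"))]
    missing = set(spec.terms) - set(usable)
    if missing:
        raise SpecificationError(
            f"spec terms reference unknown columns: {sorted(missing)}")
    dm = patsy.dmatrix(spec.formula(), frame, return_type="dataframe")
    info = dm.design_info
    term_cols: dict[str, list[str]] = {}
    for term, sl in info.term_name_slices.items():
        if term == "Intercept":
            continue
        term_cols[term] = list(dm.columns[sl])
    dm = dm.drop(columns=["Intercept"])
    return dm, term_cols


# ---------------------------------------------------------------------------
# conditional-logit likelihood machinery
# ---------------------------------------------------------------------------

class _CLogitData:
    """Rows sorted by session with segment bookkeeping."""

    def __init__(self, X: np.ndarray, y: np.ndarray, starts: np.ndarray):
        self.X, self.y, self.starts = X, y, starts
        counts = np.diff(np.append(starts, len(y)))
        self.counts = counts
        self.row_session = np.repeat(np.arange(len(starts)), counts)

    def loglike_parts(self, beta: np.ndarray):
        eta = self.X @ beta
        m = np.maximum.reduceat(eta, self.starts)
        ex = np.exp(eta - m[self.row_session])
        denom = np.add.reduceat(ex, self.starts)
        lse = m + np.log(denom)
        ll = float(eta[self.y == 1].sum() - lse.sum())
        p = ex / denom[self.row_session]
        return ll, p

    def score(self, p: np.ndarray) -> np.ndarray:
        return self.X.T @ (self.y - p)

    def hessian(self, p: np.ndarray) -> np.ndarray:
        Xw = self.X * p[:, None]
        M = np.add.reduceat(Xw, self.starts, axis=0)  # per-session E[x]
        return -(self.X.T @ Xw - M.T @ M)

    @property
    def baseline_loglike(self) -> float:
        """Log-likelihood at beta = 0: sum over sessions of log(1/n)."""
        return float(np.log(1.0 / self.counts).sum())


def _prepare_clogit(frame: pd.DataFrame, spec: ChoiceModelSpec):
    dm, term_cols = build_design(frame, spec)
    work = frame[["session", "chosen"]].copy()
    work = pd.concat([work, dm], axis=1)
    # sessions need >= 2 candidates and exactly one chosen row to inform
    sizes = work.groupby("session")["chosen"].agg(["size", "sum"])
    good = sizes[(sizes["size"] >= 2) & (sizes["sum"] == 1)].index
    n_dropped = int(sizes.shape[0] - len(good))
    work = work[work["session"].isin(good)]
    work = work.sort_values("session", kind="stable")
    codes = pd.factorize(work["session"])[0]
    starts = np.flatnonzero(np.diff(np.append(-1, codes)))

    X_full = work[dm.columns].to_numpy(float)
    y = work["chosen"].to_numpy(float)
    # absorb session-constant columns (controls soaked up by stratification)
    sess_min = np.minimum.reduceat(X_full, starts, axis=0)
    sess_max = np.maximum.reduceat(X_full, starts, axis=0)
    varying = np.any(sess_max - sess_min > 1e-12, axis=0)
    kept = [c for c, v in zip(dm.columns, varying) if v]
    absorbed = [c for c, v in zip(dm.columns, varying) if not v]
    X = X_full[:, varying]
    # drop aliased columns: after within-session centring (the variation
    # the conditional likelihood sees) some columns can be exactly
    # collinear, e.g. a state observed in only one group together with its
    # group interaction; keep a maximal linearly independent subset
    aliased: list[str] = []
    if X.shape[1]:
        counts = np.diff(np.append(starts, len(y)))
        row_session = np.repeat(np.arange(len(starts)), counts)
        means = np.add.reduceat(X, starts, axis=0) / counts[:, None]
        Xc = X - means[row_session]
        from scipy.linalg import qr
        R, piv = qr(Xc, mode="r", pivoting=True)[0:2]
        diag = np.abs(np.diag(R)) if R.ndim == 2 else np.abs(R[:1])
        tol = (diag.max() if diag.size else 0.0) * 1e-10
        rank = int(np.sum(diag > tol))
        keep_idx = np.sort(piv[:rank])
        aliased = [kept[i] for i in range(X.shape[1]) if i not in set(keep_idx)]
        if aliased:
            logger.warning("dropping aliased columns: %s", aliased)
            X = X[:, keep_idx]
            kept = [kept[i] for i in keep_idx]
    data = _CLogitData(X, y, starts)
    term_cols = {t: [c for c in cols if c in kept]
                 for t, cols in term_cols.items()}
    meta = {"kept": kept, "absorbed": absorbed, "aliased": aliased,
            "n_sessions_dropped": n_dropped,
            "index": work.index.to_numpy(), "term_cols": term_cols}
    return data, meta


def _newton(data: _CLogitData, gtol: float = 1e-8, maxiter: int = 500):
    k = data.X.shape[1]
    beta = np.zeros(k)
    ll, p = data.loglike_parts(beta)
    for it in range(maxiter):
        g = data.score(p)
        if np.max(np.abs(g)) < gtol:
            if np.any(np.abs(beta) > 15.0):
                raise ConvergenceError(
                    "gradient vanished at extreme coefficients "
                    f"(max|beta| = {np.max(np.abs(beta)):.1f}): complete "
                    "separation — some covariate perfectly predicts choice")
            return beta, ll, p, True, it
        H = data.hessian(p)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H + 1e-8 * np.eye(k), -g, rcond=None)[0]
        # backtracking line search on the exact log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, p_new = data.loglike_parts(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"line search failed at iter {it}, ll={ll:.6f}, "
                f"max|grad|={np.max(np.abs(g)):.3g}")
        beta, ll, p = cand, ll_new, p_new
        if np.max(np.abs(beta)) > 40.0:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 40): possible complete "
                "separation in the choice data")
    raise ConvergenceError(
        f"no convergence in {maxiter} iterations, max|grad|="
        f"{np.max(np.abs(data.score(p))):.3g}")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LRTResult:
    """Likelihood-ratio test between two nested fits."""

    chisq: float
    df: int
    pvalue: float
    description: str = ""

    def __str__(self) -> str:
        return (f"LRT {self.description}: chi2 = {self.chisq:.2f}, "
                f"d.f. = {self.df}, p = {self.pvalue:.4g}")


@dataclasses.dataclass
class VIFReport:
    table: pd.DataFrame  # predictor, vif
    warnings: list[str]

    @property
    def max_vif(self) -> float:
        return float(self.table["vif"].max())


@dataclasses.dataclass
class StabilityReport:
    effect: str
    estimates: pd.DataFrame  # one row per excluded level
    ranges: pd.DataFrame  # param -> full, min, max
    flagged_levels: list[str]
    failures: dict[str, str]


class PartnerChoiceResults:
    """Fitted partner-choice model: estimates, uncertainty, diagnostics."""

    def __init__(self, model: "PartnerChoiceModel", params: pd.Series,
                 cov: pd.DataFrame, llf: float, llnull: float,
                 fittedvalues: pd.Series, converged: bool, backend: str,
                 meta: dict, n_iter: int = 0):
        self.model = model
        self.params = params
        self.cov_params = cov
        self.llf = llf
        self.llnull = llnull
        self.fittedvalues = fittedvalues
        self.converged = converged
        self.backend = backend
        self.meta = meta
        self.n_iter = n_iter

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    @property
    def df_model(self) -> int:
        return int(len(self.params))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def lrt(self, restricted: "PartnerChoiceResults",
            description: str = "") -> LRTResult:
        chisq = 2.0 * (self.llf - restricted.llf)
        if chisq < -1e-6:
            raise SpecificationError(
                "restricted model has higher likelihood; models not nested?")
        chisq = max(chisq, 0.0)
        df = self.df_model - restricted.df_model
        p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
        return LRTResult(float(chisq), int(df), p, description)

    def summary(self) -> str:
        ci = self.conf_int()
        tab = pd.DataFrame({
            "coef": self.params, "std err": self.bse, "z": self.tvalues,
            "P>|z|": self.pvalues, "[0.025": ci["lower"], "0.975]": ci["upper"],
        })
        head = (
            f"Partner choice model ({self.model.spec.name})\n"
            f"Backend: {self.backend}   converged: {self.converged}\n"
            f"Sessions: {self.meta.get('n_sessions', '?')}   "
            f"rows: {self.meta.get('n_rows', '?')}\n"
            f"Log-likelihood: {self.llf:.3f}   "
            f"LL(beta=0): {self.llnull:.3f}\n"
        )
        absorbed = self.meta.get("absorbed", [])
        tail = ""
        if absorbed:
            tail = ("\nAbsorbed by session stratification (no within-session "
                    f"variation): {len(absorbed)} columns\n  "
                    + "\n  ".join(absorbed) + "\n")
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:10.4f}".format):
            return head + "\n" + tab.to_string() + "\n" + tail

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "converged": bool(self.converged),
            "llf": float(self.llf),
            "llnull": float(self.llnull),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "absorbed": list(self.meta.get("absorbed", [])),
            "n_sessions": self.meta.get("n_sessions"),
        }


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class PartnerChoiceModel:
    """Binomial-logit grooming partner choice model.

    Parameters
    ----------
    table : ChoiceTable or DataFrame
        Finalized choice table; needs ``session`` and ``chosen`` columns
        plus every column the spec's terms reference.
    spec : ChoiceModelSpec
        Fixed-effect structure; see :meth:`ChoiceModelSpec.model1` /
        :meth:`ChoiceModelSpec.model2` for the two study designs.
    """

    def __init__(self, table, spec: ChoiceModelSpec):
        self.table = table
        self.frame = _frame_of(table).reset_index(drop=True)
        if "session" not in self.frame or "chosen" not in self.frame:
            raise SpecificationError(
                "choice table needs 'session' and 'chosen' columns")
        self.spec = spec

    @classmethod
    def from_study(cls, frame: pd.DataFrame, terms: tuple[str, ...],
                   name: str = "study") -> "PartnerChoiceModel":
        """Model over a simulated choice-study frame with raw covariates."""
        spec = ChoiceModelSpec(tuple(terms), name=name)
        return cls(frame, spec)

    def fit(self, backend: str = "clogit", gtol: float = 1e-8,
            maxiter: int = 500) -> PartnerChoiceResults:
        if backend == "clogit":
            return self._fit_clogit(gtol, maxiter)
        if backend == "mixed":
            return self._fit_mixed()
        raise SpecificationError(f"unknown backend {backend!r}")

    # -- conditional logit ----------------------------------------------

    def _fit_clogit(self, gtol: float, maxiter: int) -> PartnerChoiceResults:
        data, meta = _prepare_clogit(self.frame, self.spec)
        if data.X.shape[1] == 0:
            beta = np.zeros(0)
            ll, p = data.loglike_parts(beta)
            params = pd.Series(beta, index=[], dtype=float)
            cov = pd.DataFrame(index=[], columns=[], dtype=float)
            fitted = pd.Series(p, index=meta["index"])
            res_meta = self._result_meta(data, meta)
            return PartnerChoiceResults(self, params, cov, ll,
                                        data.baseline_loglike, fitted, True,
                                        "clogit", res_meta)
        beta, ll, p, converged, n_iter = _newton(data, gtol, maxiter)
        H = data.hessian(p)
        try:
            cov_mat = np.linalg.inv(-H)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"observed information singular at optimum: {exc}")
        params = pd.Series(beta, index=meta["kept"])
        cov = pd.DataFrame(cov_mat, index=meta["kept"], columns=meta["kept"])
        fitted = pd.Series(p, index=meta["index"])
        return PartnerChoiceResults(self, params, cov, ll,
                                    data.baseline_loglike, fitted, converged,
                                    "clogit", self._result_meta(data, meta),
                                    n_iter)

    def _result_meta(self, data: _CLogitData, meta: dict) -> dict:
        return {
            "n_sessions": int(len(data.starts)),
            "n_rows": int(len(data.y)),
            "n_sessions_dropped": meta["n_sessions_dropped"],
            "absorbed": meta["absorbed"],
            "aliased": meta.get("aliased", []),
            "term_cols": meta["term_cols"],
        }

    def baseline_loglike(self) -> float:
        """Conditional log-likelihood at beta = 0 (uniform choice):
        sum over usable sessions of log(1/n_candidates)."""
        data, _ = _prepare_clogit(self.frame, self.spec)
        return data.baseline_loglike

    # -- mixed backend via lme4 -----------------------------------------

    def _fit_mixed(self) -> PartnerChoiceResults:
        frame = self.frame
        dm, term_cols = build_design(frame, self.spec)
        cols = list(dm.columns)
        safe = {c: f"x{i}" for i, c in enumerate(cols)}
        data = dm.rename(columns=safe).copy()
        data["chosen"] = frame["chosen"].to_numpy()
        data["offset_col"] = frame["offset"].to_numpy() if "offset" in frame \
            else np.log(1.0 / frame.groupby("session")["chosen"]
                        .transform("size").to_numpy())
        for g in self.spec.random_intercepts:
            data[g] = frame[g].astype(str).to_numpy() if g in frame else "all"
        fixed = " + ".join(safe.values()) or "1"
        rand = " + ".join(f"(1|{g})" for g in self.spec.random_intercepts)
        for col, grp in self.spec.random_slopes:
            rand += f" + (0 + {safe.get(col, col)}|{grp})"
        formula = f"chosen ~ {fixed} + {rand} + offset(offset_col)"
        with tempfile.TemporaryDirectory() as tmp:
            dpath = Path(tmp) / "data.tsv"
            opath = Path(tmp) / "fit.json"
            data.to_csv(dpath, sep="\t", index=False)
            rscript = f"""
suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
d <- read.delim("{dpath}")
fit <- glmer({formula}, data = d, family = binomial,
             control = glmerControl(optimizer = "bobyqa",
                                    calc.derivs = FALSE))
s <- summary(fit)
co <- s$coefficients
out <- list(names = rownames(co), est = unname(co[, 1]),
            se = unname(co[, 2]), logLik = as.numeric(logLik(fit)),
            messages = unlist(fit@optinfo$conv$lme4$messages))
writeLines(toJSON(out, digits = 12, null = "null"), "{opath}")
"""
            proc = subprocess.run(["Rscript", "-e", rscript],
                                  capture_output=True, text=True)
            if proc.returncode != 0 or not opath.exists():
                raise ConvergenceError(
                    "mixed backend (lme4::glmer) failed:\n" + proc.stderr[-2000:])
            res = json.loads(opath.read_text())
        back = {v: k for k, v in safe.items()}
        names = [back.get(n, n) for n in res["names"]]
        params = pd.Series(np.asarray(res["est"], float).ravel(), index=names)
        se = np.asarray(res["se"], float).ravel()
        cov = pd.DataFrame(np.diag(se ** 2), index=names, columns=names)
        messages = res.get("messages") or []
        meta = {"n_sessions": int(frame["session"].nunique()),
                "n_rows": int(len(frame)), "absorbed": [],
                "term_cols": term_cols, "glmer_messages": messages}
        llf = float(np.ravel(res["logLik"])[0])
        return PartnerChoiceResults(self, params, cov, llf, np.nan,
                                    pd.Series(dtype=float),
                                    converged=not messages,
                                    backend="mixed-glmer", meta=meta)


# ---------------------------------------------------------------------------
# inference procedure
# ---------------------------------------------------------------------------

def full_null_comparison(table, full_spec: ChoiceModelSpec,
                         null_spec: ChoiceModelSpec | None = None,
                         backend: str = "clogit"
                         ) -> tuple[LRTResult, PartnerChoiceResults,
                                    PartnerChoiceResults]:
    """Likelihood-ratio test of the full model against the control-only
    null (same rows, same offset/stratification)."""
    if null_spec is None:
        null_spec = full_spec.null()
    if not null_spec.is_nested_in(full_spec):
        raise SpecificationError("null specification is not nested in full")
    full_res = PartnerChoiceModel(table, full_spec).fit(backend=backend)
    null_res = PartnerChoiceModel(table, null_spec).fit(backend=backend)
    return (full_res.lrt(null_res, "full vs null"), full_res, null_res)


def term_tests(table, full_spec: ChoiceModelSpec, backend: str = "clogit",
               full_result: PartnerChoiceResults | None = None
               ) -> list[LRTResult]:
    """Single-term deletion tests (drop1): each droppable term — an
    interaction, or a main effect not contained in any retained interaction
    — is removed in turn and the reduced fit compared by LRT."""
    if full_result is None:
        full_result = PartnerChoiceModel(table, full_spec).fit(backend=backend)
    out = []
    for term in full_spec.droppable_terms():
        reduced = PartnerChoiceModel(
            table, full_spec.drop_term(term)).fit(backend=backend)
        out.append(full_result.lrt(reduced, term))
    return out


def vif_report(table, spec: ChoiceModelSpec) -> VIFReport:
    """Variance-inflation factors from a fixed-effects-only linear design
    with main effects only (interactions and random effects excluded)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    frame = _frame_of(table)
    mains = [t for t in spec.terms if ":" not in t]
    dm = patsy.dmatrix("1 + " + " + ".join(mains), frame,
                       return_type="dataframe")
    # zero-variance columns (e.g. factors with a single observed level)
    # carry no collinearity information
    keep = [c for c in dm.columns
            if c == "Intercept" or dm[c].std() > 0]
    dm = dm[keep]
    cols = [c for c in dm.columns if c != "Intercept"]
    X = dm.to_numpy(float)
    warnings_ = []
    vifs = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in cols:
            j = list(dm.columns).index(name)
            try:
                v = variance_inflation_factor(X, j)
            except (np.linalg.LinAlgError, ZeroDivisionError):
                v = np.inf
            if not np.isfinite(v) or v > 1e10:
                v = np.inf
                warnings_.append(f"perfect collinearity involving {name}")
            vifs.append(v)
    tab = pd.DataFrame({"predictor": cols, "vif": vifs})
    return VIFReport(tab, warnings_)


def stability_check(table, spec: ChoiceModelSpec, random_effect: str,
                    backend: str = "clogit",
                    flip_threshold: float = 0.0) -> StabilityReport:
    """Leave-one-level-out refits for one grouping factor.

    Excluding a level removes its rows; sessions left without their chosen
    row or with fewer than two candidates drop out entirely. Levels whose
    exclusion flips the sign of any coefficient (beyond ``flip_threshold``
    in absolute value on both sides) are flagged.
    """
    frame = _frame_of(table)
    if random_effect not in frame.columns:
        raise SpecificationError(f"unknown random effect {random_effect!r}")
    levels = sorted(frame[random_effect].astype(str).unique())
    if len(levels) < 2:
        raise SpecificationError(
            f"random effect {random_effect!r} has fewer than 2 levels")
    full = PartnerChoiceModel(frame, spec).fit(backend=backend)
    rows, failures = {}, {}
    for level in levels:
        sub = frame[frame[random_effect].astype(str) != level]
        if random_effect != "session":
            ok = sub.groupby("session")["chosen"].transform("sum") == 1
            sub = sub[ok]
        if not len(sub):
            failures[level] = "no data left after exclusion"
            continue
        try:
            res = PartnerChoiceModel(sub, spec).fit(backend=backend)
        except (ConvergenceError, SpecificationError,
                np.linalg.LinAlgError) as exc:
            failures[level] = str(exc)
            continue
        rows[level] = res.params
    est = pd.DataFrame(rows).T.reindex(columns=full.params.index)
    ranges = pd.DataFrame({"full": full.params, "min": est.min(),
                           "max": est.max()})
    flagged = []
    for level, params in est.iterrows():
        flips = (np.sign(params) != np.sign(full.params)) \
            & (params.abs() > flip_threshold) \
            & (full.params.abs() > flip_threshold)
        if flips.any():
            flagged.append(str(level))
    return StabilityReport(random_effect, est, ranges, flagged, failures)
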
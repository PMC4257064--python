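"""Presence-only maximum-entropy deforestation-risk model.

The model treats observed deforestation locations like species-occurrence
records: with no reliable absences (clouds and classifier disagreement make
"no change" unverifiable), the fitted object is the Gibbs distribution

    q(x) = exp(lambda . f(x)) / Z,   Z = sum over background of exp(lambda . f)

over a background sample of study cells, where f(x) expands each
explanatory variable into linear, quadratic and hinge features (continuous)
or per-category indicators (categorical).  lambda maximizes the
L1-penalized log-likelihood of the presences,

    (1/n_p) sum_presence lambda . f(x)  -  ln Z  -  sum_j beta_j |lambda_j|,

whose optimum is the maximum-entropy distribution whose feature expectations
match the presence means within the beta slack (the KKT condition, checked
on every fit).  Prediction offers the raw relative-occurrence rate and the
entropy-calibrated logistic output p = q e^H / (1 + q e^H), the [0,1] risk
scale used downstream.

Usage follows the model/results convention::

    model = MaxentRiskModel.from_stack(stack, presence, background,
                                       ["accessibility", "land_designation"])
    res = model.fit()
    risk = res.predict(stack)           # Grid of logistic risk
    print(res.summary())
    report = model.replicate(k=100, seed=1)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid import Grid, LandscapeStack

__all__ = [
    "FeatureExpansion",
    "MaxentRiskModel",
    "MaxentResults",
    "ModelReport",
    "SavedModel",
    "auc",
    "values_at",
    "stack_to_frame",
]

#: Default L1 regularization per feature class, before the 1/sqrt(n_presence)
#: sample-size scaling.  Hinge features get the loosest penalty because there
#: are many of them per variable.
DEFAULT_BETA = {"linear": 0.05, "quadratic": 0.05, "hinge": 0.5, "categorical": 0.25}


def values_at(stack: LandscapeStack, variables: list[str], points: np.ndarray) -> pd.DataFrame:
    """Extract variable values at (row, col) points into a DataFrame."""
    rows = points[:, 0].astype(int)
    cols = points[:, 1].astype(int)
    data = {v: np.asarray(stack[v].values)[rows, cols] for v in variables}
    return pd.DataFrame(data)


def stack_to_frame(stack: LandscapeStack, variables: list[str]) -> pd.DataFrame:
    """All cells of the named grids, flattened row-major."""
    return pd.DataFrame({v: np.asarray(stack[v].values).ravel() for v in variables})


class FeatureExpansion:
    """Expand raw variables into bounded model features.

    Continuous variables are min-max scaled to [0,1] using constants taken
    from the *background only* (stored, so any later point maps through the
    same transform, clipped into [0,1]), then expanded into a linear, a
    quadratic, and ``n_hinge`` forward-hinge features at equally spaced
    knots.  Categorical variables become one indicator per background
    category.
    """

    def __init__(self, background: pd.DataFrame, categorical: tuple[str, ...] = (),
                 n_hinge: int = 8):
        self.variables = list(background.columns)
        self.categorical = tuple(c for c in self.variables if c in categorical)
        self.n_hinge = int(n_hinge)
        self.scaling: dict[str, tuple[float, float]] = {}
        self.categories: dict[str, list] = {}
        self.feature_names: list[str] = []
        self.feature_class: list[str] = []
        self.feature_variable: list[str] = []
        for v in self.variables:
            col = background[v].to_numpy()
            if not np.isfinite(col.astype(float)).all():
                raise ValueError(f"non-finite values in background variable {v!r}")
            if v in self.categorical:
                cats = sorted(np.unique(col).tolist())
                self.categories[v] = cats
                for c in cats:
                    self._add(f"{v}=={c}", "categorical", v)
            else:
                lo, hi = float(col.min()), float(col.max())
                self.scaling[v] = (lo, hi)
                self._add(f"{v}", "linear", v)
                self._add(f"{v}^2", "quadratic", v)
                for k in range(1, self.n_hinge + 1):
                    self._add(f"hinge({v},{k})", "hinge", v)

    def _add(self, name: str, klass: str, variable: str) -> None:
        self.feature_names.append(name)
        self.feature_class.append(klass)
        self.feature_variable.append(variable)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """(n_points, n_features) matrix; every entry in [0, 1]."""
        n = len(data)
        out = np.empty((n, self.n_features))
        j = 0
        for v in self.variables:
            col = data[v].to_numpy()
            if not np.isfinite(col.astype(float)).all():
                raise ValueError(f"non-finite values in variable {v!r}")
            if v in self.categorical:
                for c in self.categories[v]:
                    out[:, j] = (col == c).astype(float)
                    j += 1
            else:
                lo, hi = self.scaling[v]
                if hi > lo:
                    x = np.clip((col.astype(float) - lo) / (hi - lo), 0.0, 1.0)
                else:
                    x = np.zeros(n)
                out[:, j] = x
                out[:, j + 1] = x**2
                j += 2
                for k in range(1, self.n_hinge + 1):
                    knot = k / (self.n_hinge + 1)
                    out[:, j] = np.maximum(0.0, (x - knot) / (1.0 - knot))
                    j += 1
        return out

    def columns_of(self, variable: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.feature_variable) == variable)


class _IdentityExpansion(FeatureExpansion):
    """Features are the variables themselves (precomputed matrices)."""

    def __init__(self, names: list[str]):
        self.variables = list(names)
        self.categorical = ()
        self.n_hinge = 0
        self.scaling = {}
        self.categories = {}
        self.feature_names = list(names)
        self.feature_class = ["linear"] * len(names)
        self.feature_variable = list(names)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        out = data[self.variables].to_numpy(dtype=float)
        if not np.isfinite(out).all():
            raise ValueError("non-finite feature values")
        return out


def _penalized_objective(lam: np.ndarray, Fp: np.ndarray, Fb: np.ndarray,
                         beta: np.ndarray) -> float:
    """(1/n_p) sum_p lam.f - ln Z - beta.|lam| (to be maximized)."""
    return float(Fp.mean(axis=0) @ lam - logsumexp(Fb @ lam) - beta @ np.abs(lam))


class MaxentRiskModel:
    """Presence-only maximum-entropy model over a background sample.

    Parameters
    ----------
    presence, background : DataFrame
        Variable values at presence points and at the background sample
        (the reference distribution of available environment; also used as
        pseudo-absences when scoring AUC).
    categorical : sequence of str
        Which columns are categorical.
    n_hinge : int
        Hinge features per continuous variable (default 8).
    beta : mapping, optional
        Per-feature-class L1 penalties; defaults to ``DEFAULT_BETA`` scaled
        by 1/sqrt(n_presence).
    """

    def __init__(self, presence: pd.DataFrame, background: pd.DataFrame,
                 categorical: tuple[str, ...] = (), n_hinge: int = 8,
                 beta: dict[str, float] | None = None):
        if len(presence) < 2:
            raise ValueError("need at least 2 presence points")
        self.presence = presence.reset_index(drop=True)
        self.background = background.reset_index(drop=True)
        self.expansion = FeatureExpansion(self.background, categorical, n_hinge)
        self.Fp = self.expansion.transform(self.presence)
        self.Fb = self.expansion.transform(self.background)
        base = beta or DEFAULT_BETA
        scale = 1.0 / np.sqrt(len(self.presence))
        self.beta = np.array(
            [base[k] * scale for k in self.expansion.feature_class]
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_stack(cls, stack: LandscapeStack, presence_points: np.ndarray,
                   background_points: np.ndarray, variables: list[str],
                   categorical: tuple[str, ...] | None = None, **kw) -> "MaxentRiskModel":
        """Build from a landscape stack and sampled (row, col) points.

        Categorical variables default to those whose grid carries a
        category table.
        """
        if categorical is None:
            categorical = tuple(v for v in variables if stack[v].categories)
        model = cls(
            values_at(stack, variables, presence_points),
            values_at(stack, variables, background_points),
            categorical=categorical, **kw,
        )
        model._stack = stack
        return model

    @classmethod
    def from_features(cls, Fp: np.ndarray, Fb: np.ndarray,
                      beta: np.ndarray | float,
                      feature_names: list[str] | None = None) -> "MaxentRiskModel":
        """Build directly from precomputed feature matrices.

        Bypasses the expansion; useful for small hand-constructed problems
        and for refitting on presence subsets.  ``beta`` is a scalar or a
        per-feature array, used as-is (no sample-size rescaling).
        """
        Fp = np.asarray(Fp, dtype=float)
        Fb = np.asarray(Fb, dtype=float)
        d = Fp.shape[1]
        names = feature_names or [f"f{j}" for j in range(d)]
        model = cls.__new__(cls)
        model.presence = pd.DataFrame(Fp, columns=names)
        model.background = pd.DataFrame(Fb, columns=names)
        model.expansion = _IdentityExpansion(names)
        model.Fp = Fp
        model.Fb = Fb
        model.beta = np.broadcast_to(np.asarray(beta, dtype=float), (d,)).copy()
        return model

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, presence_col: str = "presence",
                       **kw) -> "MaxentRiskModel":
        """Build from a long table with a 0/1 presence indicator column.

        Background rows are those with indicator 0 (they characterize the
        available environment, not absences).
        """
        pres = data[data[presence_col] == 1].drop(columns=[presence_col])
        bg = data[data[presence_col] == 0].drop(columns=[presence_col])
        return cls(pres, bg, **kw)

    # -- fitting ------------------------------------------------------------

    def fit(self, maxiter: int = 500, tol: float = 1e-7) -> "MaxentResults":
        """Maximize the L1-penalized presence log-likelihood.

        Uses bound-constrained quasi-Newton (L-BFGS-B) on the standard
        positive/negative split ``lambda = a - b`` with ``a, b >= 0``, which
        makes the penalty linear and the objective smooth; the line search
        makes the penalized objective non-decreasing across iterations.
        Stops when the objective improves by less than ``tol`` or after
        ``maxiter`` iterations.
        """
        Fp, Fb, beta = self.Fp, self.Fb, self.beta
        d = Fp.shape[1]
        fbar = Fp.mean(axis=0)

        spread = Fb.max(axis=0) - Fb.min(axis=0)
        if np.all(spread == 0):
            warnings.warn("all features constant over background; returning uniform model")
            return self._results(np.zeros(d), [0.0], True, 0)

        path: list[float] = []

        def negobj(z: np.ndarray) -> tuple[float, np.ndarray]:
            a, b = z[:d], z[d:]
            lam = a - b
            s = Fb @ lam
            lz = logsumexp(s)
            w = np.exp(s - lz)
            Eq = w @ Fb
            obj = fbar @ lam - lz - beta @ (a + b)
            g = fbar - Eq
            grad = np.concatenate([beta - g, beta + g])
            return -obj, grad

        z0 = np.zeros(2 * d)
        path.append(-negobj(z0)[0])

        def cb(z: np.ndarray) -> None:
            a, b = z[:d], z[d:]
            path.append(
                _penalized_objective(a - b, Fp, Fb, beta)
            )

        res = minimize(
            negobj, z0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * d), callback=cb,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
        )
        a, b = res.x[:d], res.x[d:]
        lam = a - b
        lam[np.abs(lam) < 1e-12] = 0.0
        return self._results(lam, path, bool(res.success), int(res.nit))

    def _results(self, lam: np.ndarray, path: list[float], converged: bool,
                 n_iter: int) -> "MaxentResults":
        s = self.Fb @ lam
        lnZ = float(logsumexp(s))
        q = np.exp(s - lnZ)
        entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
        Eq = q @ self.Fb
        kkt = np.abs(Eq - self.Fp.mean(axis=0)) - self.beta
        return MaxentResults(
            model=self,
            params=pd.Series(lam, index=self.expansion.feature_names),
            lnZ=lnZ,
            entropy=entropy,
            converged=converged,
            n_iter=n_iter,
            objective_path=path,
            max_kkt_violation=float(kkt.max()),
        )

    # -- replication --------------------------------------------------------

    def replicate(self, k: int = 100, holdout: float = 0.3, seed: int = 0,
                  contribution_permutations: int = 10) -> "ModelReport":
        """k fits on reseeded presence subsamples (default 70/30 split).

        Each run refits on the training presences against the full
        background and scores test AUC with background points as
        pseudo-absences.  Reports mean/SD of test AUC and the mean
        permutation percent contribution per variable.
        """
        n = len(self.presence)
        n_test = max(1, int(round(holdout * n)))
        if n - n_test < 2:
            raise ValueError("too few presences for the requested holdout")
        aucs = []
        contribs = []
        for i in range(k):
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            sub = MaxentRiskModel.from_features(
                self.Fp[train_idx], self.Fb, self.beta * np.sqrt(n / len(train_idx))
            )
            sub.expansion = self.expansion
            res = sub.fit()
            lam = res.params.to_numpy()
            test_scores = self.Fp[test_idx] @ lam
            bg_scores = self.Fb @ lam
            aucs.append(auc(test_scores, bg_scores))
            contribs.append(
                res.percent_contribution(m=contribution_permutations, seed=seed + 31 * i)
            )
        aucs = np.asarray(aucs)
        if k == 1:
            warnings.warn("SD of AUC is undefined for a single run; reporting 0")
            sd = 0.0
        else:
            sd = float(aucs.std(ddof=1))
        return ModelReport(
            mean_auc=float(aucs.mean()),
            sd_auc=sd,
            auc_values=aucs,
            contributions=pd.concat(contribs, axis=1).mean(axis=1),
            n_runs=k,
        )


@dataclass
class MaxentResults:
    """Fitted Gibbs weights and derived quantities."""

    model: MaxentRiskModel
    params: pd.Series  # lambda per feature
    lnZ: float
    entropy: float  # H of the fitted distribution over the background
    converged: bool
    n_iter: int
    objective_path: list[float]
    max_kkt_violation: float  # max_j |E_q[f_j] - mean_p[f_j]| - beta_j

    # -- prediction ---------------------------------------------------------

    def score_points(self, data: pd.DataFrame) -> np.ndarray:
        """lambda . f(x) for arbitrary points (monotone in risk)."""
        return self.model.expansion.transform(data) @ self.params.to_numpy()

    def raw_at(self, data: pd.DataFrame) -> np.ndarray:
        """Gibbs probability q(x) = exp(lambda.f - lnZ) per point."""
        return np.exp(self.score_points(data) - self.lnZ)

    def predict(self, stack: LandscapeStack | None = None,
                scale: str = "logistic") -> Grid:
        """Per-cell risk map.

        scale "raw": relative occurrence rate q(x) * n_background (mean 1
        over the background); scale "logistic" (default): the
        entropy-calibrated risk p = q e^H / (1 + q e^H) in [0, 1] — 0.5
        for cells typical of the background under a flat model.
        """
        if stack is None:
            stack = getattr(self.model, "_stack", None)
            if stack is None:
                raise ValueError("no stack bound to the model; pass one explicitly")
        frame = stack_to_frame(stack, self.model.expansion.variables)
        q = self.raw_at(frame)
        if scale == "raw":
            vals = q * len(self.model.background)
        elif scale == "logistic":
            qe = q * np.exp(self.entropy)
            vals = qe / (1.0 + qe)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        ref = stack[self.model.expansion.variables[0]]
        out = vals.reshape(ref.shape)
        return ref.copy_with(values=out, nodata_mask=stack.nodata_mask)

    # -- diagnostics --------------------------------------------------------

    @property
    def training_gain(self) -> float:
        """Penalty-free gain over the uniform background model."""
        lam = self.params.to_numpy()
        return float(self.model.Fp.mean(axis=0) @ lam - self.lnZ
                     + np.log(len(self.model.background)))

    def percent_contribution(self, m: int = 10, seed: int = 0) -> pd.Series:
        """Permutation importance per variable, normalized to sum 100.

        For each variable the feature columns derived from it are permuted
        across the pooled presence + background points (m seeded
        permutations), which breaks the variable's association with
        presence, and the mean drop in training gain is recorded; drops are
        clipped at 0 and normalized.
        """
        lam = self.params.to_numpy()
        exp = self.model.expansion
        Fp, Fb = self.model.Fp, self.model.Fb
        n_p, n_b = len(Fp), len(self.model.background)
        base_gain = self.training_gain
        drops = {}
        rng = np.random.default_rng(seed)
        pool = np.vstack([Fp, Fb])
        for v in exp.variables:
            cols = exp.columns_of(v)
            deltas = []
            for _ in range(m):
                shuffled = pool[rng.permutation(len(pool))][:, cols]
                Fp2, Fb2 = Fp.copy(), Fb.copy()
                Fp2[:, cols] = shuffled[:n_p]
                Fb2[:, cols] = shuffled[n_p:]
                gain = (Fp2.mean(axis=0) @ lam - logsumexp(Fb2 @ lam) + np.log(n_b))
                deltas.append(base_gain - gain)
            drops[v] = max(0.0, float(np.mean(deltas)))
        total = sum(drops.values())
        if total == 0:
            pct = {v: 100.0 / len(drops) for v in drops}
        else:
            pct = {v: 100.0 * d / total for v, d in drops.items()}
        return pd.Series(pct).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Maximum-entropy deforestation-risk model",
            "=" * 48,
            f"presences:            {len(self.model.presence)}",
            f"background points:    {len(self.model.background)}",
            f"features:             {self.model.expansion.n_features}"
            f" ({len(self.model.expansion.variables)} variables)",
            f"converged:            {self.converged} ({self.n_iter} iterations)",
            f"penalized objective:  {self.objective_path[-1]:.6f}",
            f"training gain:        {self.training_gain:.4f}",
            f"entropy H:            {self.entropy:.4f}",
            f"ln Z:                 {self.lnZ:.4f}",
            f"max KKT violation:    {self.max_kkt_violation:.2e}",
            "",
            "nonzero weights (top 10 by |lambda|):",
        ]
        nz = self.params[self.params != 0.0]
        for name, lam in nz.reindex(nz.abs().sort_values(ascending=False).index)[:10].items():
            lines.append(f"  {name:30s} {lam:+.4f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Plain-text model document sufficient for bit-identical prediction."""
        exp = self.model.expansion
        doc = {
            "variables": exp.variables,
            "categorical": list(exp.categorical),
            "n_hinge": exp.n_hinge,
            "scaling": {k: list(v) for k, v in exp.scaling.items()},
            "categories": {k: [_json_safe(c) for c in v] for k, v in exp.categories.items()},
            "feature_names": exp.feature_names,
            "lambda": self.params.to_numpy().tolist(),
            "beta": self.model.beta.tolist(),
            "lnZ": self.lnZ,
            "entropy": self.entropy,
            "n_background": len(self.model.background),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def plot_response(self, variable: str, ax=None, n: int = 200):
        """Marginal response curve: logistic output along one variable,
        others held at their background means."""
        import matplotlib.pyplot as plt

        exp = self.model.expansion
        if ax is None:
            _, ax = plt.subplots()
        means = self.model.background.mean(numeric_only=True)
        lo, hi = exp.scaling.get(variable, (0, 1))
        xs = np.linspace(lo, hi, n)
        frame = pd.DataFrame({v: np.full(n, means.get(v, 0.0)) for v in exp.variables})
        frame[variable] = xs
        q = self.raw_at(frame)
        qe = q * np.exp(self.entropy)
        ax.plot(xs, qe / (1 + qe))
        ax.set_xlabel(variable)
        ax.set_ylabel("risk (logistic output)")
        return ax


def _json_safe(v):
    return v.item() if isinstance(v, np.generic) else v


@dataclass
class SavedModel:
    """Lightweight predictor reconstructed from a saved model document."""

    expansion: FeatureExpansion
    params: np.ndarray
    lnZ: float
    entropy: float
    n_background: int

    @classmethod
    def load(cls, path) -> "SavedModel":
        with open(path) as fh:
            doc = json.load(fh)
        exp = FeatureExpansion.__new__(FeatureExpansion)
        exp.variables = doc["variables"]
        exp.categorical = tuple(doc["categorical"])
        exp.n_hinge = doc["n_hinge"]
        exp.scaling = {k: tuple(v) for k, v in doc["scaling"].items()}
        exp.categories = dict(doc["categories"])
        exp.feature_names = doc["feature_names"]
        exp.feature_class = []
        exp.feature_variable = []
        for v in exp.variables:  # rebuild bookkeeping in construction order
            if v in exp.categorical:
                for _ in exp.categories[v]:
                    exp.feature_class.append("categorical")
                    exp.feature_variable.append(v)
            else:
                exp.feature_class += ["linear", "quadratic"] + ["hinge"] * exp.n_hinge
                exp.feature_variable += [v] * (2 + exp.n_hinge)
        return cls(exp, np.asarray(doc["lambda"]), doc["lnZ"], doc["entropy"],
                   doc["n_background"])

    def predict(self, stack: LandscapeStack, scale: str = "logistic") -> Grid:
        frame = stack_to_frame(stack, self.expansion.variables)
        q = np.exp(self.expansion.transform(frame) @ self.params - self.lnZ)
        if scale == "raw":
            vals = q * self.n_background
        elif scale == "logistic":
            qe = q * np.exp(self.entropy)
            vals = qe / (1.0 + qe)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        ref = stack[self.expansion.variables[0]]
        return ref.copy_with(values=vals.reshape(ref.shape), nodata_mask=stack.nodata_mask)


@dataclass
class ModelReport:
    """Replicate-run summary: Table-1-style AUC and contributions."""

    mean_auc: float
    sd_auc: float
    auc_values: np.ndarray
    contributions: pd.Series
    n_runs: int

    def __post_init__(self) -> None:
        total = float(self.contributions.sum())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"contributions must sum to 100, got {total}")

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "variable": v,
                "percent_contribution": round(float(p), 1),
                "mean_auc": round(self.mean_auc, 3),
                "sd_auc": round(self.sd_auc, 3),
            }
            for v, p in self.contributions.sort_values(ascending=False).items()
        ]
        return pd.DataFrame(rows)


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank AUC: P(random presence outscores random background), ties 0.5.

    Computed from midrank sums (the Mann-Whitney U statistic), which equals
    the all-pairs count exactly, ties counting one half.
    """
    n1, n2 = len(presence_scores), len(background_scores)
    if n1 == 0 or n2 == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([presence_scores, background_scores]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n2))
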
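"""Group-level inference on reconstruction accuracy.

This module answers the study's statistical questions:

* is the overall reconstruction accuracy better than chance?  The null
  distribution is built by mismatched pairing — scoring each reconstructed
  envelope against envelopes of *other* epochs — and compared to the
  observed accuracies with a paired t test and Cohen's d;
* which behavioral indicators (Familiarity, Mind Wandering, Repetition)
  predict accuracy?  A linear mixed model with crossed Subject and
  Stimulus random intercepts is reduced by stepwise backward elimination:
  random intercepts are tested by likelihood ratio, fixed terms by
  Satterthwaite F tests, dropping the weakest term at each step while
  respecting marginality (an interaction leaves before its main effects);
* does the Familiarity effect differ between mind-wandering levels?
  Follow-up models are fitted separately within each level.

Binary factors are treatment-coded (Low / First = reference), so a fixed
effect is always the High-minus-Low (or Second-minus-First) contrast.
Standardized coefficients come from refitting on the z-scored response
with predictors coded +/-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixedlm import MixedLMResult, fit_mixed_lm, likelihood_ratio

__all__ = [
    "FACTORS",
    "LMMSpec",
    "LMMFit",
    "NullComparison",
    "full_factorial_spec",
    "build_design",
    "fit_lmm",
    "stepwise_backward",
    "follow_up_by_level",
    "likelihood_ratio_test",
    "null_distribution",
    "compare_to_null",
    "cell_means",
]

#: factor name -> (column in the trial table, level coded 1)
FACTORS = {
    "Familiarity": ("coded_familiarity", "High"),
    "MindWandering": ("coded_mw_group", "High"),
    "Repetition": ("coded_repetition", "Second"),
}

#: trial-table columns holding the grouping factors for random intercepts
RANDOM_COLUMNS = {"Subject": "subject_id", "Stimulus": "stimulus_id"}


@dataclass(frozen=True)
class LMMSpec:
    """A model formula: fixed terms (tuples of factor names) + random intercepts."""

    fixed_terms: tuple = ()
    random_intercepts: tuple = ("Subject", "Stimulus")
    response: str = "accuracy"

    def __post_init__(self):
        terms = tuple(tuple(t) for t in self.fixed_terms)
        object.__setattr__(self, "fixed_terms", terms)
        for term in terms:
            for sub_order in range(1, len(term)):
                for sub in combinations(term, sub_order):
                    if tuple(sub) not in terms:
                        raise ValueError(
                            f"hierarchy violated: {term} requires {sub} in the model"
                        )

    def formula(self) -> str:
        fixed = " + ".join(":".join(t) for t in self.fixed_terms) or "1"
        rand = " + ".join(f"(1|{r})" for r in self.random_intercepts)
        return f"{self.response} ~ {fixed}" + (f" + {rand}" if rand else "")

    def drop_term(self, term) -> "LMMSpec":
        return LMMSpec(
            fixed_terms=tuple(t for t in self.fixed_terms if t != tuple(term)),
            random_intercepts=self.random_intercepts,
            response=self.response,
        )

    def removable_terms(self) -> list:
        """Fixed terms not marginal to any higher-order term still present."""
        out = []
        for t in self.fixed_terms:
            nested = any(set(t) < set(u) for u in self.fixed_terms)
            if not nested:
                out.append(t)
        return out


def full_factorial_spec() -> LMMSpec:
    """Familiarity * MindWandering * Repetition with both random intercepts."""
    names = list(FACTORS)
    terms = []
    for order in (1, 2, 3):
        terms.extend(combinations(names, order))
    return LMMSpec(fixed_terms=tuple(terms))


@dataclass
class LMMFit:
    """Fixed-effect table plus variance components and fit statistics."""

    spec: LMMSpec
    coef: pd.DataFrame  # index term name; estimate, se, ci_low, ci_high, t, dof, p
    std_coef: pd.DataFrame
    random_variances: dict
    sigma2: float
    r2_marginal: float
    r2_conditional: float
    loglik: float
    aic: float
    n: int
    reml: bool
    result: MixedLMResult = field(repr=False, default=None)
    std_result: MixedLMResult = field(repr=False, default=None)


def _term_name(term) -> str:
    return ":".join(term) if term else "Intercept"


def build_design(records: pd.DataFrame, spec: LMMSpec, standardized: bool = False):
    """Fixed-effects design matrix for a coded trial table.

    Treatment coding (0/1, reference Low / First) by default; with
    ``standardized=True`` predictors are coded +/-0.5 and interactions are
    products of the coded columns (the convention under which the
    standardized coefficient of a balanced binary factor equals the
    between-level mean difference in SD units).
    """
    n = len(records)
    base = {}
    for name, (col, high_level) in FACTORS.items():
        if col in records.columns:
            x = (records[col].astype(str) == high_level).to_numpy(dtype=float)
            base[name] = x - 0.5 if standardized else x
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in spec.fixed_terms:
        missing = [f for f in term if f not in base]
        if missing:
            raise KeyError(f"coded column(s) missing for factor(s) {missing}")
        x = np.ones(n)
        for f in term:
            x = x * base[f]
        cols.append(x)
        names.append(_term_name(term))
    X = np.column_stack(cols)
    return X, names


def _random_factors(records: pd.DataFrame, spec: LMMSpec) -> dict:
    out = {}
    for r in spec.random_intercepts:
        col = RANDOM_COLUMNS[r]
        out[r] = records[col].to_numpy()
    return out


def _coef_table(result: MixedLMResult, names: list[str]) -> pd.DataFrame:
    rows = []
    for i, name in enumerate(names):
        est, se, t, dof, p = result.t_test(i)
        half = sps.t.ppf(0.975, dof) * se
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "ci_low": est - half,
                "ci_high": est + half,
                "t": t,
                "dof": dof,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def fit_lmm(spec: LMMSpec, records: pd.DataFrame, reml: bool = True) -> LMMFit:
    """Fit the model described by ``spec`` on a coded trial table.

    The response column (default ``accuracy``) holds one reconstruction
    accuracy per epoch.  Wald t statistics use Satterthwaite degrees of
    freedom; the 95% CIs use the same dof.  ``r2_marginal`` /
    ``r2_conditional`` follow the variance-partition definitions.
    """
    y = records[spec.response].to_numpy(dtype=float)
    X, names = build_design(records, spec)
    factors = _random_factors(records, spec)
    result = fit_mixed_lm(y, X, factors, reml=reml)
    coef = _coef_table(result, names)

    y_std = (y - y.mean()) / y.std(ddof=1)
    Xs, _ = build_design(records, spec, standardized=True)
    records_std = records.copy()
    std_result = fit_mixed_lm(y_std, Xs, factors, reml=reml)
    std_coef = _coef_table(std_result, names)

    r2m, r2c = result.r2()
    n_par = result.p + len(result.factor_names) + 1
    fit = LMMFit(
        spec=spec,
        coef=coef,
        std_coef=std_coef,
        random_variances=dict(result.var_components),
        sigma2=result.sigma2,
        r2_marginal=r2m,
        r2_conditional=r2c,
        loglik=result.loglik,
        aic=2.0 * n_par - 2.0 * result.loglik,
        n=result.n,
        reml=reml,
        result=result,
        std_result=std_result,
    )
    return fit


def likelihood_ratio_test(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """LRT between two nested fits (chisq, dof, p)."""
    return likelihood_ratio(full.result, reduced.result)


def stepwise_backward(
    full_spec: LMMSpec,
    records: pd.DataFrame,
    alpha_random: float = 0.1,
    alpha_fixed: float = 0.05,
) -> tuple[LMMSpec, pd.DataFrame]:
    """Backward elimination of random intercepts, then fixed terms.

    Phase 1 tests each random intercept by a REML likelihood-ratio test
    against the model without it (keeping the full fixed structure),
    iteratively removing the weakest intercept with p >= ``alpha_random``.
    Phase 2 repeatedly drops the removable (highest-order,
    marginality-respecting) fixed term with the largest Satterthwaite-F
    p-value >= ``alpha_fixed``, refitting after each drop, until every
    remaining term is significant.  Returns the reduced spec and the full
    elimination trace (random-effect section then fixed-effect section;
    ``eliminated`` is the 1-based elimination step, 0 = retained).
    """
    rows = []
    spec = full_spec

    # A factor with a single observed level cannot be estimated: drop the
    # terms that involve it (with a warning) rather than fitting a singular
    # design.
    constant = [
        name
        for name, (col, _high) in FACTORS.items()
        if col in records.columns and records[col].nunique() < 2
    ]
    if constant:
        import warnings

        warnings.warn(
            f"factor(s) {constant} have a single observed level; dropping their terms",
            stacklevel=2,
        )
        spec = LMMSpec(
            fixed_terms=tuple(
                t for t in spec.fixed_terms if not set(t) & set(constant)
            ),
            random_intercepts=spec.random_intercepts,
            response=spec.response,
        )

    # Phase 1: random intercepts by LRT
    step = 0
    while True:
        if not spec.random_intercepts:
            break
        fit_full = fit_lmm(spec, records, reml=True)
        tests = []
        for r in spec.random_intercepts:
            reduced_spec = LMMSpec(
                fixed_terms=spec.fixed_terms,
                random_intercepts=tuple(x for x in spec.random_intercepts if x != r),
                response=spec.response,
            )
            fit_red = fit_lmm(reduced_spec, records, reml=True)
            chisq, dof, p = likelihood_ratio_test(fit_full, fit_red)
            tests.append((r, reduced_spec, chisq, dof, p))
        worst = max(tests, key=lambda t: t[4])
        if worst[4] >= alpha_random:
            step += 1
            rows.append(
                {
                    "section": "random",
                    "term": f"(1|{worst[0]})",
                    "eliminated": step,
                    "statistic": worst[2],
                    "num_dof": float(worst[3]),
                    "den_dof": np.nan,
                    "p": worst[4],
                }
            )
            spec = worst[1]
        else:
            for r, _, chisq, dof, p in tests:
                rows.append(
                    {
                        "section": "random",
                        "term": f"(1|{r})",
                        "eliminated": 0,
                        "statistic": chisq,
                        "num_dof": float(dof),
                        "den_dof": np.nan,
                        "p": p,
                    }
                )
            break

    # Phase 2: fixed terms by Satterthwaite F
    fstep = 0
    while spec.fixed_terms:
        fit = fit_lmm(spec, records, reml=True)
        removable = spec.removable_terms()
        stats = {}
        for term in removable:
            name = _term_name(term)
            row = fit.coef.loc[name]
            stats[term] = (row["t"] ** 2, row["dof"], row["p"])
        worst_term = max(stats, key=lambda t: stats[t][2])
        F, den_dof, p = stats[worst_term]
        if p >= alpha_fixed:
            fstep += 1
            rows.append(
                {
                    "section": "fixed",
                    "term": _term_name(worst_term),
                    "eliminated": fstep,
                    "statistic": F,
                    "num_dof": 1.0,
                    "den_dof": den_dof,
                    "p": p,
                }
            )
            spec = spec.drop_term(worst_term)
        else:
            for term in spec.fixed_terms:
                name = _term_name(term)
                row = fit.coef.loc[name]
                rows.append(
                    {
                        "section": "fixed",
                        "term": name,
                        "eliminated": 0,
                        "statistic": row["t"] ** 2,
                        "num_dof": 1.0,
                        "den_dof": row["dof"],
                        "p": row["p"],
                    }
                )
            break

    table = pd.DataFrame(
        rows, columns=["section", "term", "eliminated", "statistic", "num_dof", "den_dof", "p"]
    )
    return spec, table


def follow_up_by_level(
    records: pd.DataFrame,
    split_factor: str = "MindWandering",
    inner_terms: tuple = (("Familiarity",),),
    random_intercepts: tuple = ("Subject", "Stimulus"),
) -> dict[str, LMMFit]:
    """Fit the inner model separately at each level of ``split_factor``."""
    col, _high = FACTORS[split_factor]
    fits = {}
    for level in ("Low", "High"):
        sub = records[records[col].astype(str) == level]
        if sub.empty:
            raise ValueError(f"no trials at {split_factor} level {level}")
        spec = LMMSpec(fixed_terms=tuple(inner_terms), random_intercepts=random_intercepts)
        fits[level] = fit_lmm(spec, sub, reml=True)
    return fits


# ---- null-distribution comparison ---------------------------------------


def null_distribution(
    reconstructions: dict,
    originals: dict,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject mismatched-pairing null accuracies.

    ``reconstructions[subject]`` and ``originals[subject]`` are equal-length
    lists of 1-D traces.  For every reconstructed epoch, ``n_permutations``
    envelopes of *other* epochs of the same subject are drawn (self-pairs
    never occur) and scored; the subject's null value is the mean over all
    epochs and draws.  Returns a frame with columns ``subject``,
    ``observed_mean_r``, ``null_mean_r``.
    """
    from .decoder import score

    rng = np.random.default_rng(seed)
    rows = []
    for subject in reconstructions:
        recs = reconstructions[subject]
        origs = originals[subject]
        if len(recs) < 2:
            raise ValueError(f"subject {subject}: need >= 2 epochs to mismatch")
        obs = []
        null = []
        for i, rec in enumerate(recs):
            obs.append(score(_match_len(rec, origs[i])[0], _match_len(rec, origs[i])[1]))
            others = [j for j in range(len(origs)) if j != i]
            picks = rng.choice(others, size=n_permutations, replace=True)
            for j in picks:
                a, b = _match_len(rec, origs[j])
                null.append(score(a, b))
        rows.append(
            {
                "subject": subject,
                "observed_mean_r": float(np.mean(obs)),
                "null_mean_r": float(np.mean(null)),
            }
        )
    return pd.DataFrame(rows)


def _match_len(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = min(a.size, b.size)
    return a[:n], b[:n]


@dataclass
class NullComparison:
    """Paired test of observed vs null mean accuracy across subjects."""

    observed_mean_r: float
    null_mean_r: float
    t_statistic: float
    dof: int
    p: float
    cohens_d: float


def compare_to_null(observed: np.ndarray, null: np.ndarray) -> NullComparison:
    """Paired one-sample t test of per-subject (observed - null) accuracies.

    Cohen's d is the mean of the differences over their SD.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape:
        raise ValueError("observed and null must pair up per subject")
    diff = observed - null
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return NullComparison(
                observed_mean_r=float(observed.mean()),
                null_mean_r=float(null.mean()),
                t_statistic=0.0,
                dof=diff.size - 1,
                p=1.0,
                cohens_d=0.0,
            )
        raise ValueError("zero variance of differences: t undefined")
    d = float(diff.mean() / sd)
    t = d * np.sqrt(diff.size)
    dof = diff.size - 1
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return NullComparison(
        observed_mean_r=float(observed.mean()),
        null_mean_r=float(null.mean()),
        t_statistic=float(t),
        dof=dof,
        p=p,
        cohens_d=d,
    )


def cell_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy +/- SEM per Familiarity x MindWandering cell."""
    g = records.groupby(["coded_familiarity", "coded_mw_group"])["accuracy"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
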
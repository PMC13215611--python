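"""Sequence → behaviour: multiple imputation, Rubin pooling, Holm contrasts.

The decoded sequence label of a trial is uncertain; to propagate that
uncertainty into behavioural models, complete datasets are repeatedly
sampled from the trial-level sequence posteriors (default 100 imputations).
Each imputed dataset gets (a) a linear mixed model RT ~ sequence with a
random intercept per participant and (b) a logistic mixed model for
response correctness; coefficients (and pairwise sequence contrasts) are
pooled across imputations with Rubin's rules, and families of contrasts are
Holm-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from .sequences import SEQUENCE_LABELS

M_IMPUTATIONS = 100
REFERENCE_LEVEL = "A"


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled coefficient."""

    name: str
    estimate: float      # Q-bar
    within_var: float    # U-bar
    between_var: float   # B
    total_var: float     # T = U-bar + (1 + 1/m) B
    df: float
    m: int
    ci_low: float
    ci_high: float
    p: float


def pool_rubin(estimates, variances, name: str = "",
               alpha: float = 0.05) -> PooledEstimate:
    """Pool per-imputation estimates and squared standard errors.

    Q̄ = mean(Q_i); Ū = mean(U_i); B = sample variance of Q_i;
    T = Ū + (1 + 1/m)B; df = (m-1)(1 + Ū/((1+1/m)B))²; Wald CI and p from
    the t distribution.  B = 0 (identical imputations) uses the normal
    reference (df = ∞).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    t_var = ubar + (1 + 1 / m) * b
    if b > 0:
        df = (m - 1) * (1 + ubar / ((1 + 1 / m) * b))**2
        crit = sstats.t.ppf(1 - alpha / 2, df)
        z = qbar / np.sqrt(t_var)
        p = 2 * sstats.t.sf(abs(z), df)
    else:
        df = np.inf
        crit = sstats.norm.ppf(1 - alpha / 2)
        z = qbar / np.sqrt(t_var) if t_var > 0 else np.inf * np.sign(qbar)
        p = 2 * sstats.norm.sf(abs(z))
    se = np.sqrt(t_var)
    return PooledEstimate(name=name, estimate=float(qbar),
                          within_var=float(ubar), between_var=float(b),
                          total_var=float(t_var), df=float(df), m=m,
                          ci_low=float(qbar - crit * se),
                          ci_high=float(qbar + crit * se), p=float(p))


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# imputation


def draw_labels(posteriors: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """One label per trial from its sequence posterior over A–F.

    INVALID mass is dropped and the remaining probabilities renormalized
    (INVALID draws are rejected and redrawn, in expectation).  Trials whose
    posterior puts everything on INVALID are unusable and must be excluded
    beforehand.
    """
    probs = posteriors[[f"p_{lab}" for lab in SEQUENCE_LABELS]].to_numpy(float)
    tot = probs.sum(axis=1)
    if np.any(tot <= 0):
        raise ValueError("trial with no valid-label mass; exclude it first")
    probs = probs / tot[:, None]
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    idx = (u[:, None] > cdf).sum(axis=1)
    return np.array(SEQUENCE_LABELS)[idx]


def _fit_rt_model(df: pd.DataFrame, levels):
    """Linear mixed model RT ~ sequence + (1 | participant); returns
    (coef dict, var dict) for the non-reference sequence terms."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("rt ~ C(sequence, Treatment('A'))", df,
                             groups=df["participant"])
            fit = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite mixed fit")
        get = lambda term: (fit.params[term], fit.bse[term]**2)
    except Exception:
        # fixed-effects fallback: participant indicators
        fit = smf.ols("rt ~ C(sequence, Treatment('A')) + C(participant)",
                      df).fit()
        get = lambda term: (fit.params[term], fit.bse[term]**2)
    coefs, varis = {}, {}
    for lab in levels:
        if lab == REFERENCE_LEVEL:
            continue
        term = f"C(sequence, Treatment('A'))[T.{lab}]"
        try:
            c, v = get(term)
        except KeyError:
            continue
        coefs[lab], varis[lab] = float(c), float(v)
    return coefs, varis


def _fit_acc_model(df: pd.DataFrame, levels):
    """Logistic mixed model correct ~ sequence + (1 | participant) via a
    variational Bayes fit; falls back to a participant-indicator GLM."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = BinomialBayesMixedGLM.from_formula(
                "correct ~ C(sequence, Treatment('A'))",
                {"participant": "0 + C(participant)"}, df)
            fit = md.fit_vb()
        k = len(fit.fe_mean)
        names = md.exog_names
        params = dict(zip(names, fit.fe_mean))
        ses = dict(zip(names, fit.fe_sd[:k]))
        get = lambda term: (params[term], ses[term]**2)
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm("correct ~ C(sequence, Treatment('A')) + C(participant)",
                          df, family=sm.families.Binomial()).fit()
        get = lambda term: (fit.params[term], fit.bse[term]**2)
    coefs, varis = {}, {}
    for lab in levels:
        if lab == REFERENCE_LEVEL:
            continue
        term = f"C(sequence, Treatment('A'))[T.{lab}]"
        try:
            c, v = get(term)
        except KeyError:
            continue
        coefs[lab], varis[lab] = float(c), float(v)
    return coefs, varis


def impute_and_fit(posteriors: pd.DataFrame, behavior: pd.DataFrame,
                   m: int = M_IMPUTATIONS, seed: int = 0,
                   responses=("rt", "correct")) -> dict:
    """The imputation loop.

    ``posteriors``: one row per decodable trial with p_A..p_F columns and a
    ``trial`` key; ``behavior``: trial, participant, rt, correct.  For each
    of ``m`` imputations a label is drawn per trial and the requested
    models are fitted.  Returns {response: {term: (estimates, variances)}}
    with per-imputation lists; terms are sequence levels vs reference A.
    Levels absent from an imputation are skipped for that imputation (and
    thus pooled over fewer imputations).
    """
    merged = posteriors.merge(behavior, on="trial")
    if len(merged) < len(posteriors):
        raise ValueError("behavior table is missing decoded trials")
    rng = np.random.default_rng(seed)
    out = {resp: {} for resp in responses}
    for _ in range(m):
        labels = draw_labels(merged, rng)
        df = merged.assign(sequence=labels)
        present = sorted(df["sequence"].unique())
        if len(present) < 2 or REFERENCE_LEVEL not in present:
            continue
        for resp in responses:
            fitter = _fit_rt_model if resp == "rt" else _fit_acc_model
            coefs, varis = fitter(df, present)
            for lab, c in coefs.items():
                est, var = out[resp].setdefault(lab, ([], []))
                est.append(c)
                var.append(varis[lab])
    return out


def pool_all(imputed: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Rubin-pool every term of every response; Holm-adjust per response.

    Returns a tidy frame: response, term, estimate, se, df, ci_low,
    ci_high, p, p_holm.
    """
    rows = []
    for resp, terms in imputed.items():
        pooled = []
        for lab, (est, var) in sorted(terms.items()):
            if len(est) < 2:
                continue
            pe = pool_rubin(est, var, name=f"{resp}:{lab} vs {REFERENCE_LEVEL}",
                            alpha=alpha)
            pooled.append((lab, pe))
        if not pooled:
            continue
        padj = holm_adjust([pe.p for _, pe in pooled])
        for (lab, pe), ph in zip(pooled, padj):
            rows.append({"response": resp, "term": f"{lab} vs {REFERENCE_LEVEL}",
                         "estimate": pe.estimate, "se": np.sqrt(pe.total_var),
                         "df": pe.df, "ci_low": pe.ci_low, "ci_high": pe.ci_high,
                         "p": pe.p, "p_holm": float(ph), "m": pe.m})
    return pd.DataFrame(rows)
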
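"""Stage/size inference workflow for the kinematic variables.

The workflow mirrors the standard mixed-model ANCOVA cascade for repeated
feeding trials on an ontogenetic series:

1. **Size ANOVA** — do the developmental stages (larva, juvenile, adult)
   differ in snout-vent length?  One-way ANOVA on the per-individual SVL
   with Bonferroni-adjusted pairwise contrasts.
2. **Interaction screening** — for every log10 kinematic variable, fit the
   linear mixed model ``log10(y) ~ log10(SVL) * stage`` with a random
   intercept per individual and test the size-by-stage interaction.
   Variables split into a no-interaction and an interaction set at
   ``alpha`` (a p exactly at the threshold counts as not significant).
3. **Main-effects ANCOVA** — variables without interaction are refitted
   additively (the interaction is removed to recover power) and size and
   stage are tested with marginality-respecting (type II) F tests.
4. **Pairwise-stage ANCOVA** — variables with interaction are refitted with
   the interaction on every stage pair (larva-adult, juvenile-adult,
   larva-juvenile, and immature-adult where immature = larvae + juveniles).
5. **Post hoc** — estimated-marginal-mean stage contrasts at the mean of
   log10 SVL with Tukey adjustment, optionally on a stage-only model (the
   follow-up for effects of size alone).

All F tests use the Satterthwaite denominator df from
:mod:`axokin.mixedlm`; type II is implemented by testing each term in the
largest model that respects marginality (mains in the additive model, the
interaction in the full model).  Estimation defaults to REML: with a
25-animal cohort, maximum-likelihood variance estimates give visibly
anticonservative F tests (type-I error near 0.10 for the interaction),
while REML-based Satterthwaite tests hold the nominal level; pass
``method="ml"`` to reproduce ML-based fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .event_extraction import KINEMATIC_VARIABLES
from .mixedlm import FTest, RandomInterceptFit, fit_random_intercept, wald_f

__all__ = [
    "AncovaRow",
    "PosthocContrast",
    "StagePartition",
    "size_anova",
    "screen_interactions",
    "main_effects_ancova",
    "pairwise_stage_ancova",
    "posthoc_stage",
    "STAGE_ORDER",
    "PAIRS",
]

STAGE_ORDER = ("larva", "juvenile", "adult")
_STAGE_LETTER = {"larva": "L", "juvenile": "J", "adult": "A", "immature": "I"}

#: Stage pairs for the pairwise ANCOVAs.  ``I-A`` recodes larvae and
#: juveniles into one immature group before fitting.
PAIRS = {
    "L-A": ("larva", "adult"),
    "J-A": ("juvenile", "adult"),
    "L-J": ("larva", "juvenile"),
    "I-A": ("immature", "adult"),
}


@dataclass
class AncovaRow:
    term: str
    f: float
    p: float
    df_num: float
    df_den: float


@dataclass
class PosthocContrast:
    pair: str
    estimate: float
    t: float
    df: float
    p_raw: float
    adjusted_p: float
    adjustment: str


@dataclass
class StagePartition:
    """Result of the interaction screen over the kinematic variables."""

    no_interaction: list[str]
    interaction: list[str]
    excluded: list[str]
    tests: dict[str, AncovaRow]


def _as_row(t: FTest) -> AncovaRow:
    return AncovaRow(term=t.term, f=t.f, p=t.p, df_num=t.df_num, df_den=t.df_den)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _design(
    df: pd.DataFrame,
    response: str,
    interaction: bool,
    stage_col: str = "stage",
):
    """Treatment-coded design for ``log10(response) ~ log10(svl) [*] stage``.

    Returns (y, X, groups, names, term_slices).
    """
    y = np.log10(df[response].to_numpy(dtype=float))
    size = np.log10(df["svl"].to_numpy(dtype=float))
    stages = [s for s in STAGE_ORDER + ("immature",)
              if s in set(df[stage_col])]
    if len(stages) < 2:
        raise ValueError("need at least 2 stage levels to fit stage effects")
    cols = [np.ones(len(df)), size]
    names = ["Intercept", "size"]
    terms: dict[str, list[int]] = {"size": [1], "stage": [], "size:stage": []}
    for s in stages[1:]:
        cols.append((df[stage_col] == s).to_numpy(dtype=float))
        terms["stage"].append(len(names))
        names.append(f"stage[{s}]")
    if interaction:
        for s in stages[1:]:
            cols.append(size * (df[stage_col] == s).to_numpy(dtype=float))
            terms["size:stage"].append(len(names))
            names.append(f"size:stage[{s}]")
    x = np.column_stack(cols)
    groups = df["individual_id"].to_numpy()
    return y, x, groups, names, terms


def _term_l(terms: dict, name: str, p: int) -> np.ndarray:
    idx = terms[name]
    l_mat = np.zeros((len(idx), p))
    for r, c in enumerate(idx):
        l_mat[r, c] = 1.0
    return l_mat


def _fit(df, response, interaction, method="reml"):
    y, x, groups, names, terms = _design(df, response, interaction)
    fit = fit_random_intercept(y, x, groups, names, method=method)
    return fit, terms


# ---------------------------------------------------------------------------
# 1. Size ANOVA
# ---------------------------------------------------------------------------

def size_anova(meta: pd.DataFrame) -> tuple[AncovaRow, list[PosthocContrast]]:
    """One-way ANOVA of SVL on stage with Bonferroni pairwise contrasts.

    ``meta`` has one row per individual with ``stage`` and ``svl`` columns.
    """
    stages = [s for s in STAGE_ORDER if s in set(meta["stage"])]
    if len(stages) < 2:
        raise ValueError("need at least 2 stages for the size ANOVA")
    samples = [meta.loc[meta["stage"] == s, "svl"].to_numpy(dtype=float)
               for s in stages]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 individuals per stage")
    f, p = stats.f_oneway(*samples)
    n = sum(len(s) for s in samples)
    k = len(samples)
    row = AncovaRow(term="stage", f=float(f), p=float(p),
                    df_num=k - 1, df_den=n - k)

    # pooled-variance pairwise contrasts, Bonferroni adjusted
    sse = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    mse = sse / (n - k)
    m = k * (k - 1) // 2
    out = []
    for (i, a), (j, b) in combinations(enumerate(stages), 2):
        est = samples[i].mean() - samples[j].mean()
        se = np.sqrt(mse * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        t = est / se
        p_raw = 2.0 * stats.t.sf(abs(t), n - k)
        out.append(PosthocContrast(
            pair=f"{_STAGE_LETTER[a]}-{_STAGE_LETTER[b]}",
            estimate=float(est), t=float(t), df=float(n - k),
            p_raw=float(p_raw),
            adjusted_p=float(min(1.0, p_raw * m)),
            adjustment="bonferroni",
        ))
    return row, out


# ---------------------------------------------------------------------------
# 2. Interaction screening
# ---------------------------------------------------------------------------

def screen_interactions(
    records: pd.DataFrame,
    alpha: float = 0.05,
    variables: tuple[str, ...] | None = None,
    method: str = "reml",
) -> StagePartition:
    """Split the kinematic variables by the size-by-stage interaction.

    Each variable's mixed model (with interaction) is tested for the
    interaction term; significance is ``p < alpha``, so a p exactly at the
    threshold lands in the no-interaction set.  Variables whose fit is
    singular are excluded with a warning entry.
    """
    variables = variables or tuple(
        v for v in KINEMATIC_VARIABLES if v in records.columns)
    no_int, with_int, excluded = [], [], []
    tests: dict[str, AncovaRow] = {}
    for var in variables:
        try:
            fit, terms = _fit(records, var, interaction=True, method=method)
            test = wald_f(fit, _term_l(terms, "size:stage", fit.beta.size),
                          term="size:stage")
        except (np.linalg.LinAlgError, ValueError):
            excluded.append(var)
            continue
        tests[var] = _as_row(test)
        (with_int if test.p < alpha else no_int).append(var)
    return StagePartition(no_interaction=no_int, interaction=with_int,
                          excluded=excluded, tests=tests)


# ---------------------------------------------------------------------------
# 3. Main-effects ANCOVA (no-interaction set)
# ---------------------------------------------------------------------------

def main_effects_ancova(records: pd.DataFrame, variable: str,
                        method: str = "reml") -> list[AncovaRow]:
    """Type II F tests of size and stage in the additive mixed model."""
    fit, terms = _fit(records, variable, interaction=False, method=method)
    p = fit.beta.size
    return [
        _as_row(wald_f(fit, _term_l(terms, "size", p), term="size")),
        _as_row(wald_f(fit, _term_l(terms, "stage", p), term="stage")),
    ]


# ---------------------------------------------------------------------------
# 4. Pairwise-stage ANCOVA (interaction set)
# ---------------------------------------------------------------------------

def _subset_pair(records: pd.DataFrame, pair: str) -> pd.DataFrame:
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}; expected one of {sorted(PAIRS)}")
    a, b = PAIRS[pair]
    df = records.copy()
    if a == "immature":
        df.loc[df["stage"].isin(("larva", "juvenile")), "stage"] = "immature"
    sub = df[df["stage"].isin((a, b))]
    for lvl in (a, b):
        if not (sub["stage"] == lvl).any():
            raise ValueError(f"stage {lvl!r} absent from the subset for {pair}")
    return sub


def pairwise_stage_ancova(
    records: pd.DataFrame,
    variable: str,
    pair: str,
    method: str = "reml",
) -> list[AncovaRow]:
    """Type II tests of size, stage and their interaction on a stage pair."""
    sub = _subset_pair(records, pair)
    full, terms_f = _fit(sub, variable, interaction=True, method=method)
    add, terms_a = _fit(sub, variable, interaction=False, method=method)
    return [
        _as_row(wald_f(add, _term_l(terms_a, "size", add.beta.size), term="size")),
        _as_row(wald_f(add, _term_l(terms_a, "stage", add.beta.size), term="stage")),
        _as_row(wald_f(full, _term_l(terms_f, "size:stage", full.beta.size),
                       term="size:stage")),
    ]


# ---------------------------------------------------------------------------
# 5. Post hoc contrasts
# ---------------------------------------------------------------------------

def posthoc_stage(
    records: pd.DataFrame,
    variable: str,
    adjustment: str = "tukey",
    include_size: bool = True,
    method: str = "reml",
) -> list[PosthocContrast]:
    """Estimated-marginal-mean stage contrasts on the mixed model.

    With ``include_size`` the model is the additive ANCOVA and contrasts
    are taken at the mean of log10 SVL; without it the model contains stage
    only (the follow-up used to ask whether stage differences persist when
    size is ignored).  Tukey adjustment uses the studentized range with the
    contrast's Satterthwaite df; with two stages it reduces to the
    unadjusted t test.
    """
    if adjustment not in ("tukey", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    df = records
    stages = [s for s in STAGE_ORDER + ("immature",) if s in set(df["stage"])]
    y = np.log10(df[variable].to_numpy(dtype=float))
    groups = df["individual_id"].to_numpy()
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    if include_size:
        cols.append(np.log10(df["svl"].to_numpy(dtype=float)))
        names.append("size")
    for s in stages[1:]:
        cols.append((df["stage"] == s).to_numpy(dtype=float))
        names.append(f"stage[{s}]")
    x = np.column_stack(cols)
    fit = fit_random_intercept(y, x, groups, names, method=method)

    p = fit.beta.size
    k = len(stages)
    m = k * (k - 1) // 2

    def emm_vec(stage: str) -> np.ndarray:
        l = np.zeros(p)
        l[0] = 1.0
        if include_size:
            l[1] = float(np.mean(np.log10(df["svl"])))
        if stage != stages[0]:
            l[names.index(f"stage[{stage}]")] = 1.0
        return l

    out = []
    for a, b in combinations(stages, 2):
        l = emm_vec(a) - emm_vec(b)
        test = wald_f(fit, l[None, :], term=f"{a}-{b}")
        t = math_copysign_sqrt(test.f, float(l @ fit.beta))
        df_den = test.df_den
        p_raw = 2.0 * stats.t.sf(abs(t), df_den)
        if adjustment == "tukey":
            adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_den)) \
                if k > 2 else p_raw
        elif adjustment == "bonferroni":
            adj = min(1.0, p_raw * m)
        else:
            adj = p_raw
        out.append(PosthocContrast(
            pair=f"{_STAGE_LETTER.get(a, a)}-{_STAGE_LETTER.get(b, b)}",
            estimate=float(l @ fit.beta), t=float(t), df=float(df_den),
            p_raw=float(p_raw), adjusted_p=float(max(adj, p_raw)),
            adjustment=adjustment,
        ))
    return out


def math_copysign_sqrt(f: float, signed: float) -> float:
    """t statistic from a 1-df F, carrying the sign of the estimate."""
    return float(np.copysign(np.sqrt(max(f, 0.0)), signed))
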
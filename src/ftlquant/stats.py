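"""Two-way fixed-effects ANOVA (group x nTS level) and Tukey HSD.

The analysis unit is one response per animal per level.  Designs must be
balanced (equal replicates per group x level cell), which makes the
classical sums-of-squares decomposition unambiguous:

    SS_A   = b n sum_i (ybar_i.. - ybar)^2        df = a - 1
    SS_B   = a n sum_j (ybar_.j. - ybar)^2        df = b - 1
    SS_AB  = n sum_ij (ybar_ij. - ybar_i.. - ybar_.j. + ybar)^2
                                                  df = (a-1)(b-1)
    SS_res = sum_ijk (y_ijk - ybar_ij.)^2         df = a b (n - 1)

F ratios use the residual mean square; p values come from the F
distribution's upper tail.  Post-hoc all-pairs comparisons on a factor's
marginal means use the studentized range statistic
``q = |ybar_i - ybar_j| / sqrt(MS_res / m)`` (m responses per marginal
mean) with adjusted p from the studentized range distribution at the
residual df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateResidualError, DesignError, NoInteractionTestError

__all__ = ["two_way_anova", "tukey_hsd", "AnovaResult", "TukeyResult"]


@dataclass
class EffectTest:
    name: str
    ss: float
    df: int
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    response: str
    factors: tuple[str, str]
    effects: dict[str, EffectTest]
    residual_ss: float
    residual_df: int
    residual_ms: float
    grand_mean: float
    total_ss: float
    n_per_cell: int
    factor_levels: dict[str, list]
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms,
             "F": e.F, "p": e.p}
            for e in self.effects.values()
        ]
        rows.append({"effect": "residual", "SS": self.residual_ss,
                     "df": self.residual_df, "MS": self.residual_ms,
                     "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


@dataclass
class PairComparison:
    pair: tuple
    diff: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class TukeyResult:
    factor: str
    alpha: float
    comparisons: list[PairComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"pair": f"{a} - {b}", "diff": c.diff, "q": c.q,
              "p_adj": c.p_adj, "significant": c.significant}
             for c in self.comparisons for a, b in [c.pair]]
        )

    def significant_pairs(self) -> set[frozenset]:
        return {frozenset(c.pair) for c in self.comparisons if c.significant}


def _cell_layout(records: pd.DataFrame, response: str, factors):
    fa, fb = factors
    for col in (fa, fb, response):
        if col not in records.columns:
            raise DesignError(f"records table lacks column {col!r}")
    a_levels = list(pd.unique(records[fa]))
    b_levels = list(pd.unique(records[fb]))
    counts = records.groupby([fa, fb], observed=True)[response].count()
    if len(counts) != len(a_levels) * len(b_levels):
        raise DesignError("missing group x level cells")
    if counts.nunique() != 1:
        raise DesignError(
            f"unbalanced design: per-cell counts {sorted(set(counts))}"
        )
    n = int(counts.iloc[0])
    y = np.empty((len(a_levels), len(b_levels), n), dtype=float)
    grouped = dict(iter(records.groupby([fa, fb], observed=True)))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[i, j, :] = grouped[(al, bl)][response].to_numpy(dtype=float)
    return y, a_levels, b_levels, n


def _decompose(y: np.ndarray):
    """Balanced two-way decomposition on an (a, b, n) response array."""
    a, b, n = y.shape
    gm = y.mean()
    am = y.mean(axis=(1, 2))
    bm = y.mean(axis=(0, 2))
    cm = y.mean(axis=2)
    ss_a = b * n * float(((am - gm) ** 2).sum())
    ss_b = a * n * float(((bm - gm) ** 2).sum())
    ss_ab = n * float(
        ((cm - am[:, None] - bm[None, :] + gm) ** 2).sum()
    )
    ss_res = float(((y - cm[:, :, None]) ** 2).sum())
    return gm, ss_a, ss_b, ss_ab, ss_res


def two_way_anova(
    records: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("group", "level"),
) -> AnovaResult:
    """Fit the balanced two-way fixed-effects ANOVA.

    Raises :class:`DesignError` on unbalanced input and
    :class:`NoInteractionTestError` when any cell has fewer than two
    replicates.  A zero residual mean square is not an error here — the
    result is flagged ``degenerate`` and effect F statistics with positive
    mean squares are reported as infinite with p = 0.
    """
    fa, fb = factors
    y, a_levels, b_levels, n = _cell_layout(records, response, factors)
    if n < 2:
        raise NoInteractionTestError(
            f"interaction untestable with {n} replicate(s) per cell"
        )
    a, b = len(a_levels), len(b_levels)
    gm, ss_a, ss_b, ss_ab, ss_res = _decompose(y)
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res
    degenerate = ms_res == 0.0

    def effect(name, ss, df):
        ms = ss / df
        if degenerate:
            F = np.inf if ms > 0 else 0.0
            p = 0.0 if ms > 0 else 1.0
        else:
            F = ms / ms_res
            p = float(sps.f.sf(F, df, df_res))
        return EffectTest(name, ss, df, ms, float(F), float(p))

    effects = {
        fa: effect(fa, ss_a, df_a),
        fb: effect(fb, ss_b, df_b),
        f"{fa}:{fb}": effect(f"{fa}:{fb}", ss_ab, df_ab),
    }
    return AnovaResult(
        response=response,
        factors=(fa, fb),
        effects=effects,
        residual_ss=ss_res,
        residual_df=df_res,
        residual_ms=ms_res,
        grand_mean=float(gm),
        total_ss=ss_a + ss_b + ss_ab + ss_res,
        n_per_cell=n,
        factor_levels={fa: a_levels, fb: b_levels},
        degenerate=degenerate,
    )


def tukey_hsd(
    result: AnovaResult,
    records: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
) -> TukeyResult:
    """All-pairs Tukey HSD on one factor's marginal means.

    Uses the fitted ANOVA's residual mean square and df; each comparison's
    adjusted p is the upper tail of the studentized range distribution at
    ``(k, df_res)``.  Raises :class:`DegenerateResidualError` when the
    residual mean square is zero.
    """
    if factor not in result.factors:
        raise DesignError(f"factor {factor!r} was not in the fitted model")
    if result.degenerate or result.residual_ms == 0.0:
        raise DegenerateResidualError(
            "residual mean square is zero; q statistics are undefined"
        )
    levels = result.factor_levels[factor]
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has fewer than 2 levels")
    marg = records.groupby(factor, observed=True)[result.response].mean()
    sizes = records.groupby(factor, observed=True)[result.response].count()
    m = int(sizes.iloc[0])  # balanced: every marginal mean averages m values
    k = len(levels)
    se = np.sqrt(result.residual_ms / m)
    out = TukeyResult(factor=factor, alpha=alpha)
    for la, lb in combinations(levels, 2):
        diff = float(marg[la] - marg[lb])
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, result.residual_df))
        p_adj = min(max(p_adj, 0.0), 1.0)
        out.comparisons.append(
            PairComparison(pair=(la, lb), diff=diff, q=float(q),
                           p_adj=p_adj, significant=p_adj < alpha)
        )
    return out
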
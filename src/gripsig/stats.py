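"""Closed-form ANOVA for balanced designs.

Two-way additive ANOVA for complete subject x task tables with one
observation per cell (the only estimable two-way model for that design, so no
interaction term), and a standard one-way ANOVA for group comparisons such as
the sex effect on GF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AnovaEffect", "AnovaResult", "two_way_anova", "one_way_anova"]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    f: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def ss_total(self) -> float:
        return sum(e.ss for e in self.effects)


def _f_test(ss: float, df: int, ms_res: float, df_res: int) -> tuple[float, float]:
    ms = ss / df
    if ms_res == 0.0:
        # perfectly additive table: residual variance vanishes
        return (np.inf, 0.0) if ms > 0 else (0.0, 1.0)
    f = ms / ms_res
    return f, float(sps.f.sf(f, df, df_res))


def two_way_anova(
    values: np.ndarray, factor_a: str = "task", factor_b: str = "subject"
) -> AnovaResult:
    """Additive two-way ANOVA on a complete A x B table, one value per cell.

    Rows are levels of ``factor_a`` (task), columns of ``factor_b`` (subject).
    SS_A = B * sum_a (mean_a - grand)^2, SS_B symmetric, residual by
    subtraction; F = MS_factor / MS_residual with the usual degrees of
    freedom.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2D table (factor A levels x factor B levels)")
    if np.any(np.isnan(y)):
        raise ValueError("table has missing cells; no imputation is performed")
    na, nb = y.shape
    if na < 2 or nb < 2:
        raise ValueError("each factor needs at least 2 levels")
    grand = y.mean()
    ss_a = nb * float(np.sum((y.mean(axis=1) - grand) ** 2))
    ss_b = na * float(np.sum((y.mean(axis=0) - grand) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))
    ss_res = max(ss_tot - ss_a - ss_b, 0.0)
    df_a, df_b = na - 1, nb - 1
    df_res = df_a * df_b
    ms_res = ss_res / df_res
    f_a, p_a = _f_test(ss_a, df_a, ms_res, df_res)
    f_b, p_b = _f_test(ss_b, df_b, ms_res, df_res)
    return AnovaResult(
        effects=(
            AnovaEffect(factor_a, ss_a, df_a, ss_a / df_a, f_a, p_a),
            AnovaEffect(factor_b, ss_b, df_b, ss_b / df_b, f_b, p_b),
            AnovaEffect("residual", ss_res, df_res, ms_res),
        )
    )


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA: between/within decomposition over named groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    n_total = sum(a.size for a in arrays.values())
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("every group needs at least one observation")
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()))
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if df_w == 0:
        raise ValueError("no within-group degrees of freedom")
    ms_w = ss_within / df_w
    f, p = _f_test(ss_between, df_b, ms_w, df_w)
    return AnovaResult(
        effects=(
            AnovaEffect("group", ss_between, df_b, ss_between / df_b, f, p),
            AnovaEffect("residual", ss_within, df_w, ms_w),
        )
    )
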